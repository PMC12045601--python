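"""End-to-end phantom-cohort analyses: the module stages wired together.

These helpers run the full chain — simulate → landmark registration →
groupwise atlas → proliferation heatmaps → differential-volume correlation
→ Jacobian VBM with the random-mask null → two-block PLS — on phantom
cohorts, and are what the end-to-end tests and the reproduction script
drive.  Each step is a thin call into the corresponding module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import atlas as atlas_mod
from . import morpho, register, stats
from .phantom import PhantomSpec, generate_specimen
from .volio import MESENCHYME, LabeledVolume, mirror


@dataclass
class StageAtlas:
    group: str
    tissue: LabeledVolume
    prolif: "object"  # ProliferationMap
    specimens: list  # (tissue_registered, prolif_map_registered, meta)


def build_stage_atlas(spec: PhantomSpec, group: str, reference_index: int = 0,
                      window_um: float = 150.0, groupwise: bool = True,
                      iterations: int = 100) -> StageAtlas:
    """Per-age tissue + proliferation atlas from a phantom group.

    Head-landmark rigid registration to the reference specimen, optional
    groupwise affine refinement, majority voting, then windowed/normalized
    proliferation maps averaged with their mirrored copies.
    """
    raws = [generate_specimen(spec, group, i) for i in range(spec.n_per_group)]
    ref_head = raws[reference_index][3]
    tissues, prolifs, metas = [], [], []
    for tissue, nuclei, prolif, head5, face37, meta in raws:
        tf = register.fit_landmark_transform(head5, ref_head, "rigid")
        tissues.append(register.apply_transform(tf, tissue, reference=tissue))
        prolifs.append(register.apply_transform(tf, prolif, reference=tissue))
        meta = dict(meta, face37=register.apply_transform(tf, face37))
        metas.append(meta)
    if groupwise and len(tissues) > 1:
        tfs, atl, tissues = register.groupwise_affine(
            tissues, reference_index=reference_index, iterations=iterations)
        prolifs = [register.apply_transform(tf, p, reference=atl.consensus)
                   for tf, p in zip(tfs, prolifs)]
        for meta, tf in zip(metas, tfs):
            meta["face37"] = register.apply_transform(tf, meta["face37"])
        consensus = atl.consensus
    else:
        consensus = atlas_mod.majority_vote_atlas(tissues).consensus
    roi = consensus.foreground
    heat = []
    for p in prolifs:
        dens = atlas_mod.proliferation_density(p, window_um)
        heat.append(atlas_mod.percentile_equalize(dens, roi=roi))
    mean_map = atlas_mod.mean_proliferation_atlas(heat)
    specimens = list(zip(tissues, heat, metas))
    return StageAtlas(group, consensus, mean_map, specimens)


@dataclass
class ShapeChangeResult:
    correlations: list  # per-sample Pearson r
    frac_outward: list
    frac_inward: list
    shuffled_r: np.ndarray
    mask_size: int


def differential_shape_analysis(spec: PhantomSpec, group_prev: str, group_next: str,
                                n_shuffle: int = 100, seed: int = 0,
                                prev_atlas: StageAtlas | None = None) -> ShapeChangeResult:
    """Fig-5-style analysis: similarity-register each next-age specimen to the
    previous-age atlas space, code the differential volume, and correlate it
    with the previous-age proliferation atlas inside a face mask.

    The shuffled control permutes the proliferation values within the mask.
    """
    prev = prev_atlas if prev_atlas is not None else build_stage_atlas(spec, group_prev)
    ref_face = prev.specimens[0][2]["face37"]
    rng = np.random.default_rng(seed)

    samples = []
    for i in range(spec.n_per_group):
        tissue, nuclei, prolif, head5, face37, meta = generate_specimen(
            spec, group_next, i)
        tf = register.fit_landmark_transform(face37, ref_face, "similarity")
        samples.append(register.apply_transform(tf, tissue, reference=prev.tissue))

    mask_vols = [t for t, _, _ in prev.specimens] + samples
    face = atlas_mod.build_face_mask(mask_vols, vote_thresh=0.30,
                                     shell_depth_um=390.0)
    mask = face.voxels

    correlations, f_out, f_in = [], [], []
    shuffled = []
    p_vals = prev.prolif.voxels[mask]
    for s in samples:
        diff = stats.differential_volume(s, prev.tissue, label=MESENCHYME)
        out_f, in_f = stats.change_proportions(diff, mask)
        r = stats.shape_prolif_correlation(diff, prev.prolif, mask)
        correlations.append(r)
        f_out.append(out_f)
        f_in.append(in_f)
        d = diff.values[mask].astype(float)
        dc = d - d.mean()
        denom = np.sqrt((dc**2).sum())
        for _ in range(n_shuffle):
            pp = rng.permutation(p_vals)
            pc = pp - pp.mean()
            shuffled.append(float(dc @ pc / (denom * np.sqrt((pc**2).sum()))))
    return ShapeChangeResult(correlations, f_out, f_in, np.asarray(shuffled),
                             int(mask.sum()))


@dataclass
class VBMResult:
    tmap: stats.TMap
    sig_mask: "object"
    nulls: list  # per-specimen NullDistribution
    expansion_overlap: float
    jacobian_positive_fraction: float


def vbm_analysis(spec: PhantomSpec, group_prev: str, group_next: str,
                 n_masks: int = 100, seed: int = 0, t_alpha: float = 0.05,
                 demons_iterations: int = 40,
                 prev_atlas: StageAtlas | None = None,
                 next_atlas: StageAtlas | None = None) -> VBMResult:
    """Fig-6-style analysis: demons-register each next-age specimen to the
    previous-age atlas, t-test log Jacobians, threshold into a shape
    significance mask, and compare its mean proliferation against random
    voxel masks per specimen."""
    prev = prev_atlas if prev_atlas is not None else build_stage_atlas(spec, group_prev)
    nxt = next_atlas if next_atlas is not None else build_stage_atlas(spec, group_next)

    jacs, warped_prolif, aligned = [], [], []
    for tissue, heat, meta in nxt.specimens:
        # affine pre-alignment to the previous-age atlas, then demons on the
        # residual (local) shape change
        aff = register.affine_register(tissue, prev.tissue)
        tissue_a = register.apply_transform(aff, tissue, reference=prev.tissue)
        heat_a = register.apply_transform(aff, heat, reference=prev.tissue)
        disp = register.nonlinear_register(tissue_a, prev.tissue,
                                           iterations=demons_iterations)
        aligned.append(tissue_a)
        jacs.append(register.jacobian_determinant(disp))
        warped_prolif.append(register.apply_transform(disp, heat_a,
                                                      reference=prev.tissue))
    # analysed domain: union of the two stages' tissue, so voxels the next
    # stage grows *into* (outside the previous atlas) are part of the test
    next_fg = atlas_mod.majority_vote_atlas(aligned).consensus.foreground
    tissue_mask = prev.tissue.foreground | next_fg
    tmap = stats.vbm_tmap(jacs, tissue_mask)
    t_crit = stats.t_critical(tmap.df, t_alpha)
    sig = stats.significance_mask(tmap, t_crit)

    from .phantom import ground_truth

    exp_mask, _ = ground_truth(spec, group_next)
    overlap = _top_t_overlap(tmap, exp_mask.voxels.astype(bool), tissue_mask)

    rng = np.random.default_rng(seed)
    nulls = [stats.random_mask_null(w, sig.voxels, tissue_mask, n_masks=n_masks,
                                    rng=rng)
             for w in warped_prolif]
    jpos = float(np.mean([j.positive_fraction for j in jacs]))
    return VBMResult(tmap, sig, nulls, overlap, jpos)


def _top_t_overlap(tmap: stats.TMap, truth: np.ndarray, universe: np.ndarray) -> float:
    """Fraction of the |truth|-sized top-t voxel set that falls in the truth mask."""
    truth = truth & universe
    k = int(truth.sum())
    if k == 0:
        return float("nan")
    t = np.where(tmap.valid & universe, tmap.t, -np.inf).ravel()
    top = np.argpartition(t, -k)[-k:]
    return float(truth.ravel()[top].mean())


def pls_blocks_from_cohort(stage_atlases, mask=None, downsample: int = 2):
    """Build the PLS blocks: normalized in-mask proliferation vectors (block 1)
    and GPA-aligned face-landmark coordinates (block 2), one row per specimen.

    Every specimen is first brought into one common reference frame by
    similarity registration of its face landmarks to the first specimen of
    the first stage atlas (the bulk-analysis registration), so rows are
    voxel-wise comparable across stages.
    """
    ref_grid = stage_atlases[0].tissue
    ref_face = stage_atlases[0].specimens[0][2]["face37"]
    sl = (slice(None, None, downsample),) * 3
    heats, fg_masks, lm_stack, somites = [], [], [], []
    for sa in stage_atlases:
        for tissue, heat, meta in sa.specimens:
            tf = register.fit_landmark_transform(meta["face37"], ref_face,
                                                 "similarity")
            heats.append(register.apply_transform(tf, heat, reference=ref_grid))
            fg_masks.append(
                register.apply_transform(tf, tissue, reference=ref_grid).foreground)
            lm_stack.append(meta["face37"].coords)
            somites.append(meta["somites"])
    if mask is None:
        mask = np.logical_or.reduce(fg_masks)
    mask_ds = mask[sl]
    prolif_rows = [h.voxels[sl][mask_ds] for h in heats]
    gpa_model = morpho.gpa(np.stack(lm_stack))
    shape_block = gpa_model.coords_.reshape(len(lm_stack), -1)
    return np.asarray(prolif_rows), shape_block, np.asarray(somites)
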