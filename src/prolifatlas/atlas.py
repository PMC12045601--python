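"""Consensus tissue atlases, proliferation heatmaps and analysis masks.

A per-age tissue atlas is the per-voxel majority vote over registered
segmentations.  Proliferation heatmaps are windowed means of the binary
proliferating-cell map (0.15 mm cubic window by default), normalized by
percentile-based equalization between the 1st and 99th in-tissue
percentiles, and averaged per age group together with the mirrored maps
so that left and right sides contribute symmetrically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volio import (
    MESENCHYME,
    CellMap,
    LabeledVolume,
    ProliferationMap,
    distance_from_surface,
    mirror,
)


@dataclass
class TissueAtlas:
    """Per-age consensus segmentation with per-voxel winning-vote fraction."""

    consensus: LabeledVolume
    vote_fraction: np.ndarray
    n_contributors: int


@dataclass
class AnalysisMask:
    """Binary analysis ROI with the parameters that produced it."""

    voxels: np.ndarray
    spacing: tuple
    provenance: str
    parameters: dict

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if not self.voxels.any():
            raise ValueError(f"{self.provenance} mask is empty")

    @property
    def size(self) -> int:
        return int(self.voxels.sum())

    @classmethod
    def allow_empty(cls, voxels, spacing, provenance, parameters) -> "AnalysisMask":
        """Construct without the nonempty check (used for empty significance masks,
        which are a warning rather than an error)."""
        obj = object.__new__(cls)
        obj.voxels = np.asarray(voxels, dtype=bool)
        obj.spacing = spacing
        obj.provenance = provenance
        obj.parameters = parameters
        return obj


def majority_vote_atlas(volumes) -> TissueAtlas:
    """Per-voxel majority vote over registered label volumes.

    Ties are broken deterministically by label priority: the highest label
    code wins (background < mesenchyme < neural ectoderm), so a 1–1 tie
    between mesenchyme and neural ectoderm resolves to neural ectoderm.
    Invariant to the ordering of the input volumes.
    """
    volumes = list(volumes)
    if not volumes:
        raise ValueError("no volumes to vote over")
    ref = volumes[0]
    for v in volumes[1:]:
        if not v.same_grid(ref):
            raise ValueError("all volumes must share a grid")
    labels = sorted(set().union(*[set(np.unique(v.voxels).tolist()) for v in volumes]))
    counts = np.zeros((len(labels),) + ref.shape, dtype=np.int32)
    for v in volumes:
        for li, lab in enumerate(labels):
            counts[li] += v.voxels == lab
    rev = counts[::-1]
    winner_rev = np.argmax(rev, axis=0)
    winner = (len(labels) - 1) - winner_rev
    consensus = np.asarray(labels, dtype=np.int16)[winner]
    vote_fraction = np.take_along_axis(counts, winner[None], axis=0)[0] / len(volumes)
    atlas_vol = LabeledVolume(consensus, ref.spacing, ref.origin, labels=dict(ref.labels))
    return TissueAtlas(atlas_vol, vote_fraction, len(volumes))


def _odd_window_voxels(window_um: float, spacing: tuple) -> tuple:
    sizes = []
    for s in spacing:
        w = max(1, int(round(window_um / s)))
        if w % 2 == 0:
            w += 1
        sizes.append(w)
    return tuple(sizes)


def proliferation_density(prolif: CellMap, window_um: float = 150.0) -> ProliferationMap:
    """Raw local proliferation density: centred box-filter mean of the binary map.

    The 0.15 mm default window is converted to the nearest odd voxel count
    per axis; at the borders the window shrinks to the in-grid voxels, so
    values stay true means in [0, 1].
    """
    size = _odd_window_voxels(window_um, prolif.spacing)
    if any(w < 1 for w in size):
        raise ValueError("window is smaller than one voxel")
    data = prolif.voxels.astype(float)
    num = ndimage.uniform_filter(data, size=size, mode="constant", cval=0.0)
    den = ndimage.uniform_filter(np.ones_like(data), size=size, mode="constant", cval=0.0)
    out = num / den
    return ProliferationMap(np.clip(out, 0.0, 1.0), prolif.spacing, prolif.origin)


def percentile_equalize(raw: ProliferationMap, roi=None, p_low: float = 1.0,
                        p_high: float = 99.0) -> ProliferationMap:
    """Percentile-based equalization: clipped linear rescale between the
    in-ROI P_low and P_high values.

    Invariant to positive affine rescaling of the input; a constant map
    degenerates to all zeros (documented rule).
    """
    roi_mask = np.ones(raw.shape, dtype=bool) if roi is None else np.asarray(roi, bool)
    if not roi_mask.any():
        raise ValueError("ROI is empty")
    vals = raw.voxels[roi_mask]
    lo, hi = np.percentile(vals, [p_low, p_high])
    if hi <= lo:
        return ProliferationMap(np.zeros(raw.shape), raw.spacing, raw.origin,
                                normalized=True)
    out = np.clip((raw.voxels - lo) / (hi - lo), 0.0, 1.0)
    return ProliferationMap(out, raw.spacing, raw.origin, normalized=True)


def mean_proliferation_atlas(maps, include_mirrored: bool = True) -> ProliferationMap:
    """Voxel-wise mean of a group's normalized maps (and their mirrored copies).

    Averaging each specimen together with its midplane mirror makes the
    group atlas left–right symmetric by construction on a midplane-centred
    grid.
    """
    maps = list(maps)
    if not maps:
        raise ValueError("empty group")
    stack = [m.voxels for m in maps]
    if include_mirrored:
        stack += [mirror(m).voxels for m in maps]
    mean = np.mean(stack, axis=0)
    return ProliferationMap(mean, maps[0].spacing, maps[0].origin,
                            normalized=all(m.normalized for m in maps))


def build_face_mask(label_volumes, vote_thresh: float = 0.30,
                    shell_depth_um: float = 390.0, roi=None) -> AnalysisMask:
    """Face-mesenchyme analysis mask from registered segmentations.

    Voxels labeled mesenchyme in strictly more than ``vote_thresh`` of the
    volumes form the primary mask; voxels deeper than ``shell_depth_um``
    from that mask's surface are excluded, keeping a surface shell.  An
    optional binary ROI (stand-in for manual refinement) is intersected
    last.
    """
    label_volumes = list(label_volumes)
    if not label_volumes:
        raise ValueError("no segmentations")
    ref = label_volumes[0]
    mes_frac = np.mean([v.voxels == MESENCHYME for v in label_volumes], axis=0)
    primary = mes_frac > vote_thresh
    if not primary.any():
        raise ValueError("primary mask is empty at this vote threshold")
    dist = distance_from_surface(primary, ref.spacing)
    mask = primary & (dist <= shell_depth_um)
    if roi is not None:
        mask &= np.asarray(roi, dtype=bool)
    return AnalysisMask(
        mask, ref.spacing, "face",
        {"vote_thresh": vote_thresh, "shell_depth_um": shell_depth_um,
         "n_volumes": len(label_volumes), "roi_supplied": roi is not None},
    )


def build_mutant_mask(label_volumes, closing_voxels: int = 40,
                      shell_depth_um: float = 390.0, roi=None) -> AnalysisMask:
    """Prominence mask for heterogeneous (mutant) cohorts.

    Majority vote of the registered segmentations → binary closing with a
    ``closing_voxels``³ cubic element (fills imperfections and
    discontinuities) → surface shell of ``shell_depth_um`` → optional ROI
    intersection.
    """
    atlas = majority_vote_atlas(list(label_volumes))
    ref = atlas.consensus
    mes = ref.voxels == MESENCHYME
    if not mes.any():
        raise ValueError("no mesenchyme in the consensus")
    # closing with a cube = separable max-filter then min-filter; padding avoids
    # border truncation and origin=-1 makes the erosion the exact adjoint for
    # even element sizes (verified against binary_closing)
    w = closing_voxels
    padded = np.pad(mes, w, mode="constant", constant_values=False)
    dil = ndimage.maximum_filter(padded, size=w, mode="constant", cval=False)
    ero = ndimage.minimum_filter(dil, size=w, mode="constant", cval=False,
                                 origin=-1 if w % 2 == 0 else 0)
    closed = ero[w:-w, w:-w, w:-w]
    dist = distance_from_surface(closed, ref.spacing)
    mask = closed & (dist <= shell_depth_um)
    if roi is not None:
        mask &= np.asarray(roi, dtype=bool)
    return AnalysisMask(
        mask, ref.spacing, "prominence",
        {"closing_voxels": closing_voxels, "shell_depth_um": shell_depth_um,
         "roi_supplied": roi is not None},
    )
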