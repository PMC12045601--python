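"""Synthetic embryo-head phantoms with known growth and proliferation patterning.

The phantom emulates the study design the pipeline is built for: cohorts of
five specimens per half-day age group across four groups, staged by tail
somite count, imaged as anisotropic light-sheet stacks, with 14–18% of cells
proliferating and proliferation hotspots at the actively growing facial
prominences.

Geometry is deliberately minimal: a superellipsoid head capped by an interior
neural-ectoderm core, plus three spheroid prominence lobes (one frontonasal
analog on the midline, a mirrored maxillary pair) that expand radially about
fixed centres with stage.  Because the analytic growth field is known, every
downstream stage (registration, VBM, shape–proliferation correlation) can be
tested against ground truth.

Nucleus maps are a thinned, jittered hard-core lattice of small blobs inside
tissue; proliferating maps subsample whole nuclei with a base probability,
elevated inside hotspots.  All random draws are made on one half-grid and
reflected, so a phantom with zero jitter and identity pose is *exactly*
midplane-symmetric, stochastic maps included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volio import (
    BACKGROUND,
    MESENCHYME,
    NEURAL_ECTODERM,
    CellMap,
    Cohort,
    LabeledVolume,
    LandmarkSet,
    Specimen,
    Volume,
)

DEFAULT_GROUPS = ("E10.0", "E10.5", "E11.0", "E11.5")
DEFAULT_SOMITE_RANGES = {
    "E10.0": (8, 10),
    "E10.5": (11, 14),
    "E11.0": (15, 17),
    "E11.5": (18, 20),
}


@dataclass(frozen=True)
class Hotspot:
    """Gaussian excess-proliferation region anchored to a growing prominence.

    ``lobe`` indexes the prominence (0 frontonasal, 1/2 maxillary pair).
    ``excess`` is the peak added proliferation probability.  The Gaussian
    is centred on the lobe and, with ``radius_um=None``, its scale tracks
    the lobe radius as the prominence grows — the whole actively growing
    prominence is elevated, mirroring the high proliferation seen in the
    facial prominences where shape change happens.
    """

    lobe: int
    excess: float
    radius_um: float | None = None


@dataclass
class PhantomSpec:
    """Generator configuration; the defaults are the study conditions."""

    grid_shape: tuple = (128, 128, 128)
    spacing_iso: float = 4.0  # µm per voxel
    n_per_group: int = 5
    age_groups: tuple = DEFAULT_GROUPS
    somite_ranges: dict = field(default_factory=lambda: dict(DEFAULT_SOMITE_RANGES))
    lobe_growth: tuple = (1.15, 1.15, 1.15)  # per-stage radial scale per lobe
    hotspots: tuple = (
        Hotspot(lobe=0, excess=0.12),
        Hotspot(lobe=1, excess=0.10),
        Hotspot(lobe=2, excess=0.10),
    )
    base_prolif_fraction: float = 0.16
    boundary_jitter: float = 2.0  # µm, label-boundary noise amplitude
    landmark_jitter: float = 2.0  # µm, landmark placement sd
    specimen_scale_sd: float = 0.02  # per-specimen global size variation
    specimen_rot_deg: float = 3.0  # per-specimen pose rotation about z
    specimen_shift_um: float = 8.0  # per-specimen translation amplitude
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.base_prolif_fraction <= 1.0:
            raise ValueError("base_prolif_fraction must lie in [0, 1]")
        for h in self.hotspots:
            if self.base_prolif_fraction + h.excess > 1.0:
                raise ValueError(
                    f"hotspot excess {h.excess} pushes local fraction above 1"
                )
        if len(self.lobe_growth) != 3:
            raise ValueError("lobe_growth needs one factor per prominence lobe")

    @property
    def extent_um(self) -> np.ndarray:
        return np.asarray(self.grid_shape) * self.spacing_iso

    def stage_index(self, group: str) -> int:
        if group not in self.age_groups:
            raise ValueError(f"unknown age group {group!r}; known: {self.age_groups}")
        return self.age_groups.index(group)


# ---------------------------------------------------------------------------
# analytic geometry
# ---------------------------------------------------------------------------


class _Geometry:
    """Implicit head+lobes geometry for one stage, in canonical (unposed) frame."""

    def __init__(self, spec: PhantomSpec, stage: int):
        ext = spec.extent_um
        # centre on the voxel-centre midplane so mirroring in the grid is exact
        self.center = (np.asarray(spec.grid_shape) - 1) * spec.spacing_iso / 2.0
        # head superellipsoid semi-axes and exponent
        self.head_axes = np.array([0.30, 0.26, 0.26]) * ext
        self.head_p = 2.5
        self.core_scale = 0.52  # neural-ectoderm core, same shape scaled down
        ax, ay, az = self.head_axes
        r0 = 0.11 * float(ext.min())
        growth = np.asarray(spec.lobe_growth, dtype=float) ** stage
        # lobe centres fixed; radii grow radially with stage
        self.lobe_centers = np.array(
            [
                self.center + [0.0, 0.95 * ay, 0.05 * az],  # frontonasal (midline)
                self.center + [-0.55 * ax, 0.70 * ay, -0.20 * az],  # left maxillary
                self.center + [0.55 * ax, 0.70 * ay, -0.20 * az],  # right maxillary
            ]
        )
        self.lobe_radii = r0 * growth

    def _phi_head(self, pts: np.ndarray) -> np.ndarray:
        d = np.abs(pts - self.center) / self.head_axes
        r = np.power(np.sum(np.power(d, self.head_p), axis=-1), 1.0 / self.head_p)
        return (r - 1.0) * float(self.head_axes.min())

    def phi_core(self, pts: np.ndarray) -> np.ndarray:
        d = np.abs(pts - self.center) / (self.head_axes * self.core_scale)
        r = np.power(np.sum(np.power(d, self.head_p), axis=-1), 1.0 / self.head_p)
        return (r - 1.0) * float(self.head_axes.min()) * self.core_scale

    def phi_tissue(self, pts: np.ndarray) -> np.ndarray:
        """Approximate signed distance (µm) to the tissue surface; <0 inside."""
        phi = self._phi_head(pts)
        for c, r in zip(self.lobe_centers, self.lobe_radii):
            phi = np.minimum(phi, np.linalg.norm(pts - c, axis=-1) - r)
        return phi

    def lobe_tip(self, lobe: int) -> np.ndarray:
        c = self.lobe_centers[lobe]
        u = c - self.center
        u = u / np.linalg.norm(u)
        return c + self.lobe_radii[lobe] * u

    def hotspot_excess(self, spec: PhantomSpec, pts: np.ndarray) -> np.ndarray:
        out = np.zeros(pts.shape[:-1])
        for h in spec.hotspots:
            center = self.lobe_centers[h.lobe]
            r = h.radius_um if h.radius_um is not None else 1.2 * self.lobe_radii[h.lobe]
            d2 = np.sum((pts - center) ** 2, axis=-1)
            out += h.excess * np.exp(-d2 / r**2)
        return out

    def head_landmarks(self) -> LandmarkSet:
        c, (ax, ay, az) = self.center, self.head_axes
        pts = np.array(
            [
                c + [0, ay, 0],  # anterior pole
                c + [0, -ay, 0],  # posterior pole
                c + [-ax, 0, 0],  # left pole
                c + [ax, 0, 0],  # right pole
                c + [0, 0, az],  # superior pole
            ]
        )
        return LandmarkSet(("ant", "post", "left", "right", "sup"), pts)

    def face_landmarks(self) -> LandmarkSet:
        """37 deterministic surface points on the three prominence lobes."""
        names, pts = [], []
        counts = (13, 12, 12)
        for lobe, k in enumerate(counts):
            c = self.lobe_centers[lobe]
            r = self.lobe_radii[lobe]
            outward = c - self.center
            outward = outward / np.linalg.norm(outward)
            dirs = _fibonacci_sphere(4 * k)
            dirs = dirs[dirs @ outward > 0.15][:k]
            for i, u in enumerate(dirs):
                names.append(f"lobe{lobe}_{i:02d}")
                pts.append(c + r * u)
        return LandmarkSet(tuple(names), np.array(pts))


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=-1
    )


@dataclass(frozen=True)
class _Pose:
    """Per-specimen similarity pose: canonical → specimen world."""

    scale: float
    rot: np.ndarray  # 3x3
    shift: np.ndarray  # µm
    center: np.ndarray

    def forward(self, pts: np.ndarray) -> np.ndarray:
        return self.scale * (pts - self.center) @ self.rot.T + self.center + self.shift

    def inverse(self, pts: np.ndarray) -> np.ndarray:
        return ((pts - self.center - self.shift) @ self.rot) / self.scale + self.center


def _specimen_pose(spec: PhantomSpec, rng: np.random.Generator, center) -> _Pose:
    scale = float(np.exp(rng.normal(0.0, spec.specimen_scale_sd)))
    angle = np.deg2rad(rng.uniform(-spec.specimen_rot_deg, spec.specimen_rot_deg))
    ca, sa = np.cos(angle), np.sin(angle)
    rot = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
    shift = rng.uniform(-spec.specimen_shift_um, spec.specimen_shift_um, size=3)
    return _Pose(scale, rot, shift, np.asarray(center, dtype=float))


def _identity_pose(center) -> _Pose:
    return _Pose(1.0, np.eye(3), np.zeros(3), np.asarray(center, dtype=float))


def _world_grid(spec: PhantomSpec) -> np.ndarray:
    axes = [np.arange(n) * spec.spacing_iso for n in spec.grid_shape]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def _boundary_noise(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth, midplane-symmetric noise field (µm) jittering the tissue boundary."""
    if spec.boundary_jitter <= 0:
        return np.zeros(spec.grid_shape)
    coarse = tuple(max(2, n // 8) for n in spec.grid_shape)
    noise = rng.standard_normal(coarse)
    # symmetrize about x so label jitter respects the mirror invariant
    noise = 0.5 * (noise + noise[::-1])
    noise = ndimage.gaussian_filter(noise, 1.0)
    zoom = [n / c for n, c in zip(spec.grid_shape, coarse)]
    noise = ndimage.zoom(noise, zoom, order=1)
    sd = noise.std()
    if sd > 0:
        noise *= spec.boundary_jitter / sd
    return noise


def _hardcore_sites(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Jittered hard-core lattice of candidate nucleus centres (canonical µm).

    Sites are built on the x ≥ midplane half and reflected, so the point set
    (and any per-site random marks, which are shared between a site and its
    mirror image) is exactly midplane-symmetric.
    """
    step_vox = 3
    step = step_vox * spec.spacing_iso
    ext = spec.extent_um
    cx = (spec.grid_shape[0] - 1) * spec.spacing_iso / 2.0
    # half-step offset keeps every site strictly off the midplane (jitter < step/2)
    xs_half = cx + step / 2.0 + np.arange(0, (ext[0] - cx) / step) * step
    ys = np.arange(0, ext[1], step)
    zs = np.arange(0, ext[2], step)
    gx, gy, gz = np.meshgrid(xs_half, ys, zs, indexing="ij")
    half = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
    jitter = rng.uniform(-0.5 * spec.spacing_iso, 0.5 * spec.spacing_iso, size=half.shape)
    half = half + jitter
    mirrored = half.copy()
    mirrored[:, 0] = 2 * cx - mirrored[:, 0]
    ids = np.arange(len(half))
    return np.concatenate([half, mirrored]), np.concatenate([ids, ids])


_BLOB = np.array(
    [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
     if abs(dx) + abs(dy) + abs(dz) <= 1]
)


def _stamp(shape, idx: np.ndarray) -> np.ndarray:
    """Dilate point indices to small nucleus blobs."""
    out = np.zeros(shape, dtype=bool)
    for off in _BLOB:
        p = idx + off
        ok = np.all((p >= 0) & (p < np.asarray(shape)), axis=1)
        p = p[ok]
        out[p[:, 0], p[:, 1], p[:, 2]] = True
    return out


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def generate_specimen(spec: PhantomSpec, group: str, index: int):
    """Generate one phantom specimen.

    Returns ``(tissue, nuclei, prolif, head5, face37, metadata)``.  Identical
    ``(spec, group, index)`` always yields bit-identical output.
    """
    stage = spec.stage_index(group)
    rng = np.random.default_rng([spec.seed, stage, index])
    geom = _Geometry(spec, stage)
    pose = _specimen_pose(spec, rng, geom.center)
    if spec.specimen_scale_sd == 0 and spec.specimen_rot_deg == 0 and spec.specimen_shift_um == 0:
        pose = _identity_pose(geom.center)

    grid = _world_grid(spec)
    pts = pose.inverse(grid.reshape(-1, 3)).reshape(grid.shape)
    noise = _boundary_noise(spec, rng)
    phi = geom.phi_tissue(pts)
    tissue_mask = phi < noise
    core_mask = geom.phi_core(pts) < 0
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    labels[tissue_mask] = MESENCHYME
    labels[tissue_mask & core_mask] = NEURAL_ECTODERM

    # nucleus / proliferation point processes (symmetric-by-construction)
    sites, mark_ids = _hardcore_sites(spec, rng)
    n_marks = mark_ids.max() + 1 if len(mark_ids) else 0
    keep_u = rng.random(n_marks)
    prolif_u = rng.random(n_marks)
    inside = geom.phi_tissue(sites) < -2.0 * spec.spacing_iso
    sites, mark_ids = sites[inside], mark_ids[inside]
    kept = keep_u[mark_ids] < 0.9
    sites, mark_ids = sites[kept], mark_ids[kept]
    p_site = np.clip(
        spec.base_prolif_fraction + geom.hotspot_excess(spec, sites), 0.0, 1.0
    )
    is_prolif = prolif_u[mark_ids] < p_site

    world = pose.forward(sites)
    idx = np.round(world / spec.spacing_iso).astype(int)
    nuclei_vox = _stamp(spec.grid_shape, idx)
    prolif_vox = _stamp(spec.grid_shape, idx[is_prolif])
    nuclei_vox &= tissue_mask
    prolif_vox &= nuclei_vox

    spacing = (spec.spacing_iso,) * 3
    tissue = LabeledVolume(labels, spacing)
    nuclei = CellMap(nuclei_vox, spacing, channel="nuclei")
    prolif = CellMap(prolif_vox, spacing, channel="proliferation")

    head5 = _jittered(pose, geom.head_landmarks(), spec.landmark_jitter, rng)
    face37 = _jittered(pose, geom.face_landmarks(), spec.landmark_jitter, rng)

    lo, hi = spec.somite_ranges.get(group, (8, 20))
    somites = int(round(lo + (hi - lo) * index / max(1, spec.n_per_group - 1)))
    meta = {"id": f"{group}_s{index}", "group": group, "somites": somites,
            "genotype": "WT", "stage_index": stage}
    return tissue, nuclei, prolif, head5, face37, meta


def _jittered(pose: _Pose, lms: LandmarkSet, sd: float, rng) -> LandmarkSet:
    coords = pose.forward(lms.coords)
    if sd > 0:
        coords = coords + rng.normal(0.0, sd, size=coords.shape)
    return LandmarkSet(lms.names, coords)


def generate_cohort(spec: PhantomSpec, groups=None, genotype: str = "WT") -> Cohort:
    """Generate the full phantom cohort (n_per_group specimens per age group)."""
    groups = tuple(groups) if groups is not None else spec.age_groups
    specimens = []
    for g in groups:
        for i in range(spec.n_per_group):
            tissue, nuclei, prolif, head5, face37, meta = generate_specimen(spec, g, i)
            specimens.append(
                Specimen(meta["id"], tissue, nuclei, prolif, head5, face37,
                         g, meta["somites"], genotype)
            )
    return Cohort(specimens, reference_id=specimens[0].id)


def to_anisotropic_stack(vol: Volume, slice_interval: float, inplane: float | None = None):
    """Subsample an isotropic volume in z to emulate light-sheet acquisition.

    Slices are taken every ``slice_interval`` µm (e.g. 5 µm intervals at
    0.9 µm in-plane); the output records anisotropic spacing and is the
    inverse of :func:`prolifatlas.volio.resample_isotropic` up to
    interpolation error.
    """
    if slice_interval <= 0 or (inplane is not None and inplane <= 0):
        raise ValueError("spacings must be positive")
    if inplane is not None and slice_interval < inplane:
        raise ValueError("slice_interval must be ≥ in-plane spacing")
    sz = vol.spacing[2]
    n_out = int(np.ceil(vol.shape[2] * sz / slice_interval))
    src_idx = np.clip(
        np.round(np.arange(n_out) * slice_interval / sz).astype(int), 0, vol.shape[2] - 1
    )
    from dataclasses import replace

    data = vol.voxels[:, :, src_idx]
    spacing = (vol.spacing[0], vol.spacing[1], float(slice_interval))
    return replace(vol, voxels=data.copy(), spacing=spacing)


def ground_truth(spec: PhantomSpec, group: str):
    """Analytic oracle for a stage: (expansion mask, hotspot excess map).

    The expansion mask marks voxels inside tissue at ``group`` but not at
    its predecessor stage (empty for the first group, which has no
    predecessor).  The hotspot map is the analytic excess-proliferation
    probability field at ``group``.  Both are noise-free, identity-pose.
    """
    stage = spec.stage_index(group)
    grid = _world_grid(spec)
    geom = _Geometry(spec, stage)
    tissue_now = geom.phi_tissue(grid) < 0
    if stage == 0:
        expansion = np.zeros(spec.grid_shape, dtype=bool)
    else:
        prev = _Geometry(spec, stage - 1)
        expansion = tissue_now & ~(prev.phi_tissue(grid) < 0)
    hotspot_map = geom.hotspot_excess(spec, grid)
    spacing = (spec.spacing_iso,) * 3
    from .volio import ProliferationMap

    return Volume(expansion, spacing), ProliferationMap(hotspot_map, spacing)


def expanding_region(spec: PhantomSpec, group: str) -> np.ndarray:
    """Boolean mask of voxels where the analytic growth field is expansive.

    Under radial lobe growth the local volume-change factor is g³ > 1
    throughout each growing prominence, so the expanding region is the
    lobe interiors at ``group`` (identity-pose, noise-free).  This is the
    ground-truth counterpart of a shape-significance mask.
    """
    stage = spec.stage_index(group)
    geom = _Geometry(spec, stage)
    grid = _world_grid(spec)
    growth = np.asarray(spec.lobe_growth, dtype=float)
    mask = np.zeros(spec.grid_shape, dtype=bool)
    for lobe, (c, r) in enumerate(zip(geom.lobe_centers, geom.lobe_radii)):
        if growth[lobe] > 1.0:
            mask |= np.linalg.norm(grid - c, axis=-1) < r
    return mask
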