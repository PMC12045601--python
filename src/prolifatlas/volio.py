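"""Core volumetric data types, I/O and grid geometry.

All volumes are dense 3D numpy arrays indexed ``(x, y, z)`` with the
anatomical convention x: left→right, y: posterior→anterior,
z: inferior→superior.  World coordinates are in micrometres (µm);
voxel ``(i, j, k)`` has its *centre* at ``origin + (i, j, k) * spacing``
(0-based NIfTI-style convention).

Tissue label codes are fixed small integers shared by the whole
pipeline: 0 background, 1 mesenchyme, 2 neural ectoderm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

BACKGROUND = 0
MESENCHYME = 1
NEURAL_ECTODERM = 2

DEFAULT_LABELS = {
    BACKGROUND: "background",
    MESENCHYME: "mesenchyme",
    NEURAL_ECTODERM: "neural ectoderm",
}

AXIS_CONVENTION = ("x: left→right", "y: posterior→anterior", "z: inferior→superior")


def _as_spacing(spacing) -> tuple[float, float, float]:
    s = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    if np.any(s <= 0):
        raise ValueError(f"spacing must be positive per axis, got {tuple(s)}")
    return tuple(float(v) for v in s)


@dataclass
class Volume:
    """A dense 3D grid with isotropic or anisotropic spacing (µm)."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        self.spacing = _as_spacing(self.spacing)
        self.origin = tuple(float(v) for v in np.asarray(self.origin, dtype=float))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        return float(np.prod(self.spacing))

    @property
    def is_isotropic(self) -> bool:
        return np.allclose(self.spacing, self.spacing[0])

    def index_to_world(self, idx) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_index(self, pts) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def same_grid(self, other: "Volume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def midsagittal_x(self) -> float:
        """World x of the grid midplane (the mirroring plane)."""
        return self.origin[0] + (self.shape[0] - 1) * self.spacing[0] / 2.0

    def with_voxels(self, voxels: np.ndarray):
        return replace(self, voxels=voxels)


@dataclass
class LabeledVolume(Volume):
    """Integer tissue segmentation (0 background / 1 mesenchyme / 2 neural ectoderm)."""

    labels: dict = field(default_factory=lambda: dict(DEFAULT_LABELS))

    def __post_init__(self):
        super().__post_init__()
        if not np.issubdtype(self.voxels.dtype, np.integer):
            if not np.all(self.voxels == np.round(self.voxels)):
                raise ValueError("LabeledVolume requires integer voxel values")
            self.voxels = self.voxels.astype(np.int16)
        present = set(np.unique(self.voxels).tolist())
        unknown = present - set(self.labels)
        if unknown:
            raise ValueError(f"voxel values {sorted(unknown)} not in label map {sorted(self.labels)}")

    def mask(self, label: int) -> np.ndarray:
        return self.voxels == label

    @property
    def foreground(self) -> np.ndarray:
        return self.voxels != BACKGROUND


@dataclass
class CellMap(Volume):
    """Binary occupancy grid of nucleus or proliferating-cell voxels."""

    channel: str = "nuclei"

    def __post_init__(self):
        super().__post_init__()
        vals = np.unique(self.voxels)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"CellMap must be binary, found values {vals.tolist()[:8]}")
        self.voxels = self.voxels.astype(bool)
        if self.channel not in ("nuclei", "proliferation"):
            raise ValueError(f"unknown channel {self.channel!r}")


@dataclass
class ProliferationMap(Volume):
    """Real-valued local proliferation density; ``normalized`` maps live in [0, 1]."""

    normalized: bool = False

    def __post_init__(self):
        super().__post_init__()
        self.voxels = self.voxels.astype(float)
        if np.any(self.voxels < 0):
            raise ValueError("proliferation densities must be non-negative")
        if self.normalized and np.any(self.voxels > 1 + 1e-9):
            raise ValueError("normalized map has values above 1")


@dataclass
class LandmarkSet:
    """Ordered, named 3D landmarks in world µm.

    The order is fixed across specimens; 5 points for the head set,
    37 for the face set (8 for the mutant facial subset).
    """

    names: tuple
    coords: np.ndarray

    def __post_init__(self):
        self.names = tuple(self.names)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.names), 3):
            raise ValueError("coords must be (n_landmarks, 3)")
        if len(set(self.names)) != len(self.names):
            raise ValueError("landmark names must be unique")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("landmark coordinates must be finite")

    def __len__(self) -> int:
        return len(self.names)


@dataclass
class Specimen:
    id: str
    tissue: LabeledVolume
    nuclei: CellMap
    prolif: CellMap
    head_landmarks: LandmarkSet
    face_landmarks: LandmarkSet
    group: str
    somites: int
    genotype: str = "WT"


@dataclass
class Cohort:
    """A set of specimens sharing grid/axis conventions and a registration reference."""

    specimens: list
    reference_id: str

    def __post_init__(self):
        ids = [s.id for s in self.specimens]
        if len(set(ids)) != len(ids):
            raise ValueError("specimen ids must be unique")
        if self.reference_id not in ids:
            raise ValueError(f"reference_id {self.reference_id!r} not among specimens")

    def __iter__(self):
        return iter(self.specimens)

    def __len__(self):
        return len(self.specimens)

    def by_group(self, group: str) -> list:
        return [s for s in self.specimens if s.group == group]

    @property
    def groups(self) -> list:
        seen = []
        for s in self.specimens:
            if s.group not in seen:
                seen.append(s.group)
        return seen

    def get(self, specimen_id: str) -> Specimen:
        for s in self.specimens:
            if s.id == specimen_id:
                return s
        raise KeyError(specimen_id)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_KINDS = ("labels", "cellmap", "prolif")


def write_volume(vol: Volume, path) -> Path:
    """Write a volume as NIfTI (.nii/.nii.gz) or multi-page TIFF (+spacing sidecar)."""
    path = Path(path)
    if path.suffix in (".nii",) or path.name.endswith(".nii.gz"):
        data = np.asarray(vol.voxels)
        if data.dtype == bool:
            data = data.astype(np.uint8)
        affine = np.diag(list(vol.spacing) + [1.0])
        affine[:3, 3] = vol.origin
        nib.save(nib.Nifti1Image(data, affine), str(path))
    elif path.suffix in (".tif", ".tiff"):
        data = np.asarray(vol.voxels)
        if data.dtype == bool:
            data = data.astype(np.uint8)
        # pages along z; within-page rows y, columns x
        tifffile.imwrite(str(path), data.transpose(2, 1, 0), photometric="minisblack")
        sidecar = path.parent / (path.stem + ".spacing.json")
        sidecar.write_text(
            json.dumps({"spacing_um": list(vol.spacing), "origin_um": list(vol.origin)})
        )
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    return path


def _read_tiff(path: Path) -> tuple[np.ndarray, tuple, tuple]:
    sidecar = path.parent / (path.stem + ".spacing.json")
    if not sidecar.exists():
        raise FileNotFoundError(
            f"TIFF stack {path.name} has no spacing metadata: missing sidecar "
            f"{sidecar.name} with field 'spacing_um'"
        )
    meta = json.loads(sidecar.read_text())
    if "spacing_um" not in meta:
        raise KeyError(f"sidecar {sidecar.name} lacks required field 'spacing_um'")
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    return data.transpose(2, 1, 0), tuple(meta["spacing_um"]), tuple(meta.get("origin_um", (0, 0, 0)))


def read_volume(path, kind: str = "labels"):
    """Read a NIfTI or TIFF(+sidecar) volume as the requested kind.

    kind: 'labels' → LabeledVolume, 'cellmap' → CellMap, 'prolif' → ProliferationMap.
    Label/binary values are validated; a CellMap containing values other
    than {0,1} is rejected.
    """
    if kind not in _KINDS:
        raise ValueError(f"kind must be one of {_KINDS}")
    path = Path(path)
    if path.suffix == ".nii" or path.name.endswith(".nii.gz"):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        affine = img.affine
        spacing = tuple(float(v) for v in np.abs(np.diag(affine)[:3]))
        origin = tuple(float(v) for v in affine[:3, 3])
    elif path.suffix in (".tif", ".tiff"):
        data, spacing, origin = _read_tiff(path)
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    if kind == "labels":
        return LabeledVolume(data, spacing, origin)
    if kind == "cellmap":
        return CellMap(data, spacing, origin)
    return ProliferationMap(data, spacing, origin)


def write_landmarks(lms: LandmarkSet, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(lms.coords, columns=["x", "y", "z"])
    df.insert(0, "name", lms.names)
    df.to_csv(path, index=False)
    return path


def read_landmarks(path) -> LandmarkSet:
    df = pd.read_csv(path)
    missing = {"name", "x", "y", "z"} - set(df.columns)
    if missing:
        raise ValueError(f"landmark CSV missing columns {sorted(missing)}")
    return LandmarkSet(tuple(df["name"]), df[["x", "y", "z"]].to_numpy(float))


# ---------------------------------------------------------------------------
# Grid operations
# ---------------------------------------------------------------------------


def resample_isotropic(vol: Volume, target_spacing: float | None = None,
                       interpolation: str = "nearest"):
    """Resample an (an)isotropic stack to an isotropic grid.

    The output depth per axis is ``ceil(extent / target)`` (never truncates
    tissue); world origin is preserved and voxel centres stay on the
    ``origin + i*target`` lattice.  Label and binary volumes must use
    nearest-neighbour interpolation.

    ``target_spacing`` defaults to the finest (in-plane) spacing of the input.
    """
    if target_spacing is None:
        target_spacing = min(vol.spacing)
    if target_spacing <= 0:
        raise ValueError("target_spacing must be positive")
    if interpolation not in ("nearest", "linear"):
        raise ValueError("interpolation must be 'nearest' or 'linear'")
    integerish = isinstance(vol, (LabeledVolume, CellMap))
    if integerish and interpolation != "nearest":
        raise ValueError("label/binary volumes must be resampled with nearest interpolation")

    out_shape = tuple(
        int(np.ceil(n * s / target_spacing)) for n, s in zip(vol.shape, vol.spacing)
    )
    # map output voxel centres into input index space
    grids = np.meshgrid(
        *[np.arange(n) * target_spacing / s for n, s in zip(out_shape, vol.spacing)],
        indexing="ij",
    )
    order = 0 if interpolation == "nearest" else 1
    src = vol.voxels.astype(float) if vol.voxels.dtype == bool else vol.voxels
    out = ndimage.map_coordinates(src, np.stack(grids), order=order, mode="nearest")
    iso = (float(target_spacing),) * 3
    if isinstance(vol, LabeledVolume):
        return LabeledVolume(np.round(out).astype(vol.voxels.dtype), iso, vol.origin,
                             labels=dict(vol.labels))
    if isinstance(vol, CellMap):
        return CellMap(out > 0.5, iso, vol.origin, channel=vol.channel)
    if isinstance(vol, ProliferationMap):
        return ProliferationMap(out, iso, vol.origin, normalized=vol.normalized)
    return Volume(out, iso, vol.origin)


def mirror(obj, center_x: float | None = None):
    """Reflect a volume or landmark set about the midsagittal (x) plane.

    Volumes are flipped in the grid (label counts preserved exactly;
    applying twice is the identity).  Landmark sets need the world-x of
    the mirror plane, typically ``volume.midsagittal_x()``.
    """
    if isinstance(obj, Volume):
        return obj.with_voxels(obj.voxels[::-1].copy())
    if isinstance(obj, LandmarkSet):
        if center_x is None:
            raise ValueError("mirroring landmarks requires center_x (the midplane world x)")
        coords = obj.coords.copy()
        coords[:, 0] = 2.0 * center_x - coords[:, 0]
        return LandmarkSet(obj.names, coords)
    raise TypeError(f"cannot mirror object of type {type(obj).__name__}")


def distance_from_surface(mask: np.ndarray, spacing) -> np.ndarray:
    """Euclidean distance (µm) of in-mask voxels to the nearest background voxel.

    Voxels outside the grid count as background, so a mask touching the
    border measures distance to the border.  Outside the mask the distance
    is 0.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("distance_from_surface requires a nonempty mask")
    spacing = _as_spacing(spacing)
    padded = np.pad(mask, 1, mode="constant", constant_values=False)
    dist = ndimage.distance_transform_edt(padded, sampling=spacing)
    return dist[1:-1, 1:-1, 1:-1]
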