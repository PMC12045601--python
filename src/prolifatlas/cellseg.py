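"""Cell-map post-processing and proliferative-fraction profiling.

The quantification here is voxel-based rather than per-cell: dense nuclear
stains under-segment neighbouring nuclei, so summing nucleus *voxel volumes*
sidesteps the need to assign voxels to individual cells.  Connected
components are still used to remove size outliers (components below the 1st
or above the 99th volume percentile are treated as segmentation artifacts).

A pluggable segmentation entry point (`baseline_segmenter`) binarizes
intensity phantoms so the pipeline runs end to end without external CNN
segmenters; externally produced binary maps are accepted anywhere a CellMap
is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.filters import threshold_otsu

from .volio import CellMap, Volume

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class ComponentTable:
    """Per-component geometry of a binary cell map."""

    table: pd.DataFrame  # columns: id, voxel_count, volume_um3, centroid_{x,y,z}, bbox
    labels: np.ndarray  # labelled grid (0 = background)
    map: CellMap

    def __len__(self) -> int:
        return len(self.table)


def connected_components(cellmap: CellMap, connectivity: int = 26) -> ComponentTable:
    """Label connected components of a binary map (6/18/26-connectivity).

    Labelling is deterministic (scan order); volumes are
    ``voxel_count × voxel volume`` in µm³, centroids in world µm.
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be 6, 18 or 26")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n = ndimage.label(cellmap.voxels, structure=structure)
    if n == 0:
        df = pd.DataFrame(
            columns=["id", "voxel_count", "volume_um3",
                     "centroid_x", "centroid_y", "centroid_z", "bbox"]
        )
        return ComponentTable(df, labels, cellmap)
    ids = np.arange(1, n + 1)
    counts = ndimage.sum_labels(np.ones_like(labels), labels, ids).astype(int)
    centroids = np.array(ndimage.center_of_mass(cellmap.voxels, labels, ids))
    world = centroids * np.asarray(cellmap.spacing) + np.asarray(cellmap.origin)
    slices = ndimage.find_objects(labels)
    bboxes = [tuple((s.start, s.stop) for s in sl) for sl in slices]
    df = pd.DataFrame(
        {
            "id": ids,
            "voxel_count": counts,
            "volume_um3": counts * cellmap.voxel_volume,
            "centroid_x": world[:, 0],
            "centroid_y": world[:, 1],
            "centroid_z": world[:, 2],
            "bbox": bboxes,
        }
    )
    return ComponentTable(df, labels, cellmap)


def filter_by_volume_percentiles(
    comps: ComponentTable, low: float = 1.0, high: float = 99.0
):
    """Drop components whose volume falls strictly outside the [P_low, P_high]
    band of the table's own volume distribution (linear-interpolation
    percentiles).  Returns ``(kept, rejected, filtered CellMap)``.
    """
    if len(comps) == 0:
        raise ValueError("cannot filter an empty component table")
    vols = comps.table["volume_um3"].to_numpy()
    p_lo, p_hi = np.percentile(vols, [low, high])
    reject = (vols < p_lo) | (vols > p_hi)
    kept = comps.table[~reject].reset_index(drop=True)
    rejected = comps.table[reject].reset_index(drop=True)
    keep_ids = set(kept["id"].tolist())
    lut = np.zeros(len(comps) + 1, dtype=bool)
    lut[list(keep_ids)] = True
    filtered = CellMap(
        lut[comps.labels], comps.map.spacing, comps.map.origin, channel=comps.map.channel
    )
    return (
        ComponentTable(kept, np.where(lut[comps.labels], comps.labels, 0), filtered),
        rejected,
        filtered,
    )


def proliferative_fraction(nuclei: CellMap, prolif: CellMap, roi=None) -> float:
    """Proportion of in-ROI nucleus voxels that also contain a proliferation voxel."""
    if not nuclei.same_grid(prolif):
        raise ValueError("nucleus and proliferation maps must share a grid")
    roi_mask = np.ones(nuclei.shape, dtype=bool) if roi is None else np.asarray(roi, bool)
    if not roi_mask.any():
        raise ValueError("ROI is empty")
    nuc = nuclei.voxels & roi_mask
    denom = int(nuc.sum())
    if denom == 0:
        raise ValueError("no nucleus voxels inside ROI")
    return float((nuc & prolif.voxels).sum() / denom)


@dataclass
class AxisProfile:
    """Binned proliferative fraction along one anatomical axis.

    ``fraction`` and ``sem`` are across-specimen mean and standard error;
    ``cell_volume``/``prolif_volume`` are summed µm³ over specimens per bin.
    """

    axis_direction: np.ndarray
    edges: np.ndarray  # K+1 relative-position bin edges in [0, 1]
    cell_volume: np.ndarray
    prolif_volume: np.ndarray
    fraction: np.ndarray
    sem: np.ndarray
    per_specimen_fraction: np.ndarray  # (n_specimens, K)

    def to_frame(self) -> pd.DataFrame:
        mid = 0.5 * (self.edges[:-1] + self.edges[1:])
        return pd.DataFrame(
            {
                "bin_center": mid,
                "cell_volume_um3": self.cell_volume,
                "prolif_volume_um3": self.prolif_volume,
                "fraction": self.fraction,
                "sem": self.sem,
            }
        )


def _relative_positions(mask: np.ndarray, vol: Volume, direction: np.ndarray):
    """Project in-mask voxel centres on a unit axis, rescaled to [0,1] over the
    ROI extent along that axis."""
    idx = np.argwhere(mask)
    world = idx * np.asarray(vol.spacing) + np.asarray(vol.origin)
    proj = world @ direction
    return proj


def axis_profile(specimens, tissue_roi, axis_direction, n_bins: int = 20) -> AxisProfile:
    """Profile proliferative fraction along an anatomical axis.

    ``specimens`` is a list of ``(nuclei, prolif)`` CellMap pairs sharing the
    grid of ``tissue_roi`` (a binary array).  Each nucleus voxel's relative
    position is its projection onto ``axis_direction`` rescaled to [0, 1]
    over the ROI's extent; volumes and fractions are computed per specimen,
    then averaged, with the s.e.m. across specimens.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be ≥ 1")
    roi = np.asarray(tissue_roi, dtype=bool)
    if not roi.any():
        raise ValueError("tissue ROI is empty")
    direction = np.asarray(axis_direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    first = specimens[0][0]
    roi_proj = _relative_positions(roi, first, direction)
    lo, hi = roi_proj.min(), roi_proj.max()
    if hi - lo <= 0:
        raise ValueError("ROI has zero extent along the requested axis")
    edges = np.linspace(0.0, 1.0, n_bins + 1)

    vox_vol = first.voxel_volume
    cell_v = np.zeros(n_bins)
    prolif_v = np.zeros(n_bins)
    fractions = []
    for nuclei, prolif in specimens:
        nuc_mask = nuclei.voxels & roi
        pro_mask = prolif.voxels & nuc_mask
        rel_n = np.clip((_relative_positions(nuc_mask, nuclei, direction) - lo) / (hi - lo), 0, 1)
        rel_p = np.clip((_relative_positions(pro_mask, prolif, direction) - lo) / (hi - lo), 0, 1)
        cn, _ = np.histogram(rel_n, bins=edges)
        cp, _ = np.histogram(rel_p, bins=edges)
        cell_v += cn * vox_vol
        prolif_v += cp * vox_vol
        with np.errstate(invalid="ignore", divide="ignore"):
            fractions.append(np.where(cn > 0, cp / np.maximum(cn, 1), np.nan))
    fr = np.array(fractions)
    n_eff = np.sum(~np.isnan(fr), axis=0)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(fr, axis=0)
        sem = np.where(
            n_eff > 1,
            np.nanstd(fr, axis=0, ddof=1) / np.sqrt(np.maximum(n_eff, 1)),
            0.0,
        )
    return AxisProfile(direction, edges, cell_v, prolif_v, mean, sem, fr)


def ks_uniformity(positions, reference="nucleus", nucleus_positions=None):
    """Kolmogorov–Smirnov test for nonuniform proliferation along an axis.

    Default is the two-sample test of proliferating-voxel positions against
    nucleus-voxel positions (controls for tissue shape along the axis);
    ``reference='uniform01'`` gives the literal one-sample test of
    uniformity on [0, 1].  Returns ``(D, p)``.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.size < 10:
        raise ValueError("need at least 10 positions for the KS test")
    if reference == "uniform01":
        res = stats.kstest(positions, "uniform")
    elif reference == "nucleus":
        if nucleus_positions is None:
            raise ValueError("two-sample KS needs nucleus_positions")
        res = stats.ks_2samp(positions, np.asarray(nucleus_positions, dtype=float))
    else:
        raise ValueError("reference must be 'uniform01' or 'nucleus'")
    return float(res.statistic), float(res.pvalue)


def baseline_segmenter(intensity: Volume, method="otsu", threshold: float | None = None,
                       channel: str = "nuclei") -> CellMap:
    """Threshold baseline standing in for the pluggable CNN segmenters.

    Binarizes a real-valued volume by Otsu's method or a fixed threshold so
    the pipeline can run end to end on intensity phantoms.
    """
    data = np.asarray(intensity.voxels, dtype=float)
    if method == "otsu":
        if np.ptp(data) == 0:
            raise ValueError("Otsu thresholding is undefined on a constant volume")
        thr = threshold_otsu(data)
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed thresholding needs an explicit threshold")
        thr = threshold
    else:
        raise ValueError("method must be 'otsu' or 'fixed'")
    return CellMap(data > thr, intensity.spacing, intensity.origin, channel=channel)
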