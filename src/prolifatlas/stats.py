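"""Voxel-wise shape-change statistics and the random-mask enrichment null.

Two complementary routes quantify where shape change happens and whether
proliferation is enriched there:

* differential volumes: a −1/0/+1 coding of inward/no/outward change of a
  specimen's mesenchyme against the previous-age atlas, correlated
  voxel-wise (Pearson) with the previous-age proliferation atlas inside a
  face mask;
* Jacobian voxel-based morphometry: per-voxel t-statistics of log Jacobian
  determinants of the nonlinear registration field, thresholded into a
  shape-significance mask whose mean proliferation is compared against
  means over randomly sampled voxel masks of equal size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .atlas import AnalysisMask
from .volio import LabeledVolume, MESENCHYME, ProliferationMap


@dataclass
class DifferentialVolume:
    """Voxel-wise −1/0/+1 shape-change coding on the atlas grid."""

    values: np.ndarray
    spacing: tuple
    sample_id: str = ""
    reference_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        bad = set(np.unique(self.values).tolist()) - {-1, 0, 1}
        if bad:
            raise ValueError(f"differential volume may only contain -1/0/+1, got {bad}")


@dataclass
class TMap:
    """Per-voxel t-statistics; positive t = expansion."""

    t: np.ndarray
    df: int
    valid: np.ndarray  # where the statistic is defined (variance > 0, in mask)
    spacing: tuple


@dataclass
class NullDistribution:
    """Random-mask null for mean proliferation inside a significance mask."""

    null_means: np.ndarray
    observed: float
    p_value: float
    outside_range: bool

    @property
    def n_masks(self) -> int:
        return len(self.null_means)


def differential_volume(sample: LabeledVolume, prev_atlas: LabeledVolume,
                        label: int = MESENCHYME, sample_id: str = "",
                        reference_id: str = "") -> DifferentialVolume:
    """Compare a sample's tissue at age N with the age N−1 atlas.

    +1 where the sample has tissue and the atlas does not (outward change),
    −1 where the atlas has tissue and the sample does not (inward), 0 where
    they agree.  Both inputs must already be size-removed and registered to
    a common grid.
    """
    if not sample.same_grid(prev_atlas):
        raise ValueError("sample and atlas must share a grid")
    s = sample.voxels == label
    a = prev_atlas.voxels == label
    out = np.zeros(s.shape, dtype=np.int8)
    out[s & ~a] = 1
    out[a & ~s] = -1
    return DifferentialVolume(out, sample.spacing, sample_id, reference_id)


def change_proportions(diff: DifferentialVolume, mask) -> tuple[float, float]:
    """Fractions of mask voxels with outward (+1) and inward (−1) change."""
    m = _mask_array(mask)
    n = m.sum()
    if n == 0:
        raise ValueError("mask is empty")
    vals = diff.values[m]
    return float((vals == 1).sum() / n), float((vals == -1).sum() / n)


def shape_prolif_correlation(diff: DifferentialVolume, prolif: ProliferationMap,
                             mask) -> float:
    """Pearson r between −1/0/+1 shape change and prior-age proliferation,
    over mask voxels."""
    m = _mask_array(mask)
    if m.sum() < 3:
        raise ValueError("mask must contain more than 2 voxels")
    x = diff.values[m].astype(float)
    y = prolif.voxels[m].astype(float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance inside the mask")
    return float(np.corrcoef(x, y)[0, 1])


def vbm_tmap(jacobians, mask, use_log: bool = True,
             group_b=None) -> TMap:
    """Voxel-wise t-map of (log) Jacobian determinants.

    Default: one-sample t of log J against 0 across specimens (df = n−1);
    positive t marks expansion relative to the atlas.  If ``group_b`` is
    given, a two-group Welch t between stages is computed instead.  Voxels
    with zero variance (or J ≤ 0 under the log) are masked out of
    ``valid``.
    """
    fields = [j.values if hasattr(j, "values") else np.asarray(j) for j in jacobians]
    if len(fields) < 2:
        raise ValueError("need at least 2 specimens")
    m = _mask_array(mask)
    X = np.stack(fields)
    spacing = jacobians[0].spacing if hasattr(jacobians[0], "spacing") else (1.0,) * 3
    if use_log:
        ok = np.all(X > 0, axis=0)
        X = np.log(np.where(X > 0, X, 1.0))
    else:
        ok = np.ones(X.shape[1:], dtype=bool)
        X = X - 1.0  # centre raw J on "no change"

    if group_b is None:
        n = X.shape[0]
        mean = X.mean(0)
        sd = X.std(0, ddof=1)
        valid = m & ok & (sd > 0)
        t = np.zeros(mean.shape)
        t[valid] = mean[valid] / (sd[valid] / np.sqrt(n))
        return TMap(t, n - 1, valid, spacing)

    fields_b = [j.values if hasattr(j, "values") else np.asarray(j) for j in group_b]
    Y = np.stack(fields_b)
    if use_log:
        ok &= np.all(Y > 0, axis=0)
        Y = np.log(np.where(Y > 0, Y, 1.0))
    else:
        Y = Y - 1.0
    na, nb = X.shape[0], Y.shape[0]
    va, vb = X.var(0, ddof=1), Y.var(0, ddof=1)
    denom = np.sqrt(va / na + vb / nb)
    valid = m & ok & (denom > 0)
    t = np.zeros(denom.shape)
    t[valid] = (X.mean(0)[valid] - Y.mean(0)[valid]) / denom[valid]
    with np.errstate(divide="ignore", invalid="ignore"):
        df_map = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    df = int(np.round(np.nanmedian(df_map[valid]))) if valid.any() else na + nb - 2
    return TMap(t, df, valid, spacing)


def t_critical(df: int, alpha: float = 0.05) -> float:
    """One-sided Student threshold for the expansion test."""
    return float(sps.t.ppf(1 - alpha, df))


def significance_mask(tmap: TMap, t_crit: float) -> AnalysisMask:
    """Voxels with t strictly above the threshold (one-sided expansion)."""
    if t_crit <= 0:
        raise ValueError("t_crit must be positive")
    sel = tmap.valid & (tmap.t > t_crit)
    frac = float(sel.sum() / max(1, tmap.valid.sum()))
    params = {"t_crit": t_crit, "n_voxels": int(sel.sum()),
              "fraction_of_analyzed": frac}
    if not sel.any():
        warnings.warn("significance mask is empty at this threshold", RuntimeWarning)
        return AnalysisMask.allow_empty(sel, tmap.spacing, "significance", params)
    return AnalysisMask(sel, tmap.spacing, "significance", params)


def random_mask_null(prolif: ProliferationMap, sig_mask, universe,
                     n_masks: int = 100, seed: int | None = 0,
                     rng: np.random.Generator | None = None) -> NullDistribution:
    """Compare mean proliferation in the significance mask against R random masks.

    Each replicate draws ``|sig_mask|`` voxels uniformly without replacement
    from the universe mask and records the mean proliferation.  The
    empirical p is ``(#{null ≥ observed}+1)/(R+1)``; ``outside_range``
    flags observed values exceeding every null mean (the criterion used to
    call enrichment per specimen).
    """
    sig = _mask_array(sig_mask)
    uni = _mask_array(universe)
    k = int(sig.sum())
    if k == 0:
        raise ValueError("significance mask is empty")
    vals = prolif.voxels[uni]
    if len(vals) < k:
        raise ValueError("universe smaller than the significance mask")
    if n_masks < 1:
        raise ValueError("need at least one random mask")
    rng = rng if rng is not None else np.random.default_rng(seed)
    observed = float(prolif.voxels[sig].mean())
    null_means = np.empty(n_masks)
    for r in range(n_masks):
        pick = rng.choice(len(vals), size=k, replace=False)
        null_means[r] = vals[pick].mean()
    p = float(((null_means >= observed).sum() + 1) / (n_masks + 1))
    return NullDistribution(null_means, observed, p, bool(observed > null_means.max()))


def percent_increase(mean_sig: float, mean_rand: float) -> float:
    """Percent increase of mean proliferation at shape-change sites over random
    sites: 100·(mean_sig − mean_rand)/mean_rand, reported to one decimal."""
    if mean_rand <= 0:
        raise ValueError("baseline mean must be positive")
    return round(100.0 * (mean_sig - mean_rand) / mean_rand, 1)


def dice(mask_a, mask_b) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|); two empty masks count as identical (1)."""
    a = _mask_array(mask_a)
    b = _mask_array(mask_b)
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / (sa + sb))


def _mask_array(mask) -> np.ndarray:
    if isinstance(mask, AnalysisMask):
        return mask.voxels
    if hasattr(mask, "voxels"):
        return np.asarray(mask.voxels, dtype=bool)
    return np.asarray(mask, dtype=bool)
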