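"""Landmark, groupwise-affine and demons registration, plus Jacobian fields.

Conventions
-----------
A :class:`SpatialTransform` maps *moving* world coordinates to *fixed*
world coordinates (``y = A x + t``); resampling a moving volume onto the
fixed grid therefore pulls voxels through the inverse map.  Dense
displacement fields ``u`` live on the fixed grid and map fixed world
coordinates into the moving volume (``x_moving = x_fixed + u(x_fixed)``),
the standard resampling convention — the Jacobian ``det(I + ∇u)`` is then
>1 where the moving anatomy is locally larger than the fixed.

The landmark solvers are closed-form (absolute orientation / Umeyama);
intensity-based affine and demons registration run through SimpleITK on
the float-cast tissue label volumes, with linear interpolation during
optimization and nearest-neighbour for final label resampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .atlas import majority_vote_atlas
from .volio import CellMap, LabeledVolume, LandmarkSet, ProliferationMap, Volume


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


@dataclass
class SpatialTransform:
    """Affine-family world-coordinate transform ``y = A x + t`` (µm)."""

    kind: str  # rigid | similarity | affine
    matrix: np.ndarray  # 3x3
    translation: np.ndarray  # 3
    rms: float = 0.0  # landmark residual where applicable

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("transform matrix is singular")

    @classmethod
    def identity(cls, kind: str = "rigid") -> "SpatialTransform":
        return cls(kind, np.eye(3), np.zeros(3))

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, dtype=float) @ self.matrix.T + self.translation

    def inverse(self) -> "SpatialTransform":
        inv = np.linalg.inv(self.matrix)
        return SpatialTransform(self.kind, inv, -inv @ self.translation)

    def compose(self, inner: "SpatialTransform") -> "SpatialTransform":
        """Return self ∘ inner (inner applied first)."""
        return SpatialTransform(
            "affine" if self.kind != inner.kind else self.kind,
            self.matrix @ inner.matrix,
            self.matrix @ inner.translation + self.translation,
        )

    @property
    def scale(self) -> float:
        return float(np.cbrt(abs(np.linalg.det(self.matrix))))


@dataclass
class DenseDisplacement:
    """Dense displacement field on a fixed grid; values in µm, indexed (x,y,z,3)."""

    field: np.ndarray
    spacing: tuple
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.field = np.asarray(self.field, dtype=float)
        if self.field.ndim != 4 or self.field.shape[-1] != 3:
            raise ValueError("displacement field must have shape (nx, ny, nz, 3)")
        self.spacing = tuple(float(s) for s in np.broadcast_to(self.spacing, (3,)))
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self):
        return self.field.shape[:3]


def fit_landmark_transform(
    source: LandmarkSet, target: LandmarkSet, kind: str = "rigid"
) -> SpatialTransform:
    """Closed-form least-squares rigid or similarity transform source→target.

    Uses the SVD absolute-orientation solution; the similarity variant adds
    one uniform scale (translation+rotation+scaling).  Requires ≥3
    non-collinear landmarks with matching names and order.
    """
    if kind not in ("rigid", "similarity"):
        raise ValueError("kind must be 'rigid' or 'similarity'")
    if source.names != target.names:
        raise ValueError("landmark sets must share names and order")
    X, Y = source.coords, target.coords
    n = len(X)
    if n < 3:
        raise ValueError("need at least 3 landmarks")
    mu_x, mu_y = X.mean(0), Y.mean(0)
    Xc, Yc = X - mu_x, Y - mu_y
    cov = Xc.T @ Yc / n
    U, S, Vt = np.linalg.svd(cov)
    if S[1] < 1e-9 * max(S[0], 1e-30):
        raise ValueError("landmark configuration is collinear/degenerate")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    if kind == "similarity":
        var_x = (Xc**2).sum() / n
        s = float(np.trace(np.diag(S) @ D) / var_x)
        if s <= 0:
            raise ValueError("degenerate similarity scale")
    else:
        s = 1.0
    A = s * R
    t = mu_y - A @ mu_x
    resid = Y - (X @ A.T + t)
    rms = float(np.sqrt((resid**2).sum(1).mean()))
    return SpatialTransform(kind, A, t, rms=rms)


def apply_transform(transform, obj, reference: Volume | None = None,
                    interpolation: str | None = None):
    """Resample/transform an object through a transform (or chain of them).

    ``transform`` may be a :class:`SpatialTransform`, a
    :class:`DenseDisplacement`, or a list applied moving→fixed in order.
    Volumes are resampled onto the ``reference`` grid (default: their own);
    label and binary volumes require nearest-neighbour interpolation.
    Landmark sets are mapped directly (affine-family transforms only).
    """
    if isinstance(transform, (list, tuple)):
        chain = list(transform)
        affine_prefix = []
        while chain and isinstance(chain[0], SpatialTransform):
            affine_prefix.append(chain.pop(0))
        combined = affine_prefix[0] if affine_prefix else None
        for t in affine_prefix[1:]:
            combined = t.compose(combined)
        out = obj
        if combined is not None:
            out = apply_transform(combined, out, reference, interpolation)
        for t in chain:
            out = apply_transform(t, out, reference, interpolation)
        return out

    if isinstance(obj, LandmarkSet):
        if not isinstance(transform, SpatialTransform):
            raise TypeError("landmarks can only go through affine-family transforms")
        return LandmarkSet(obj.names, transform.apply_points(obj.coords))

    if not isinstance(obj, Volume):
        raise TypeError(f"cannot transform {type(obj).__name__}")
    integerish = isinstance(obj, (LabeledVolume, CellMap))
    if interpolation is None:
        interpolation = "nearest" if integerish else "linear"
    if integerish and interpolation != "nearest":
        raise ValueError("label/binary volumes must use nearest interpolation")
    ref = reference if reference is not None else obj
    idx = np.indices(ref.shape, dtype=float)
    world = np.stack(
        [idx[a] * ref.spacing[a] + ref.origin[a] for a in range(3)], axis=-1
    )
    if isinstance(transform, SpatialTransform):
        inv = transform.inverse()
        src_world = world @ inv.matrix.T + inv.translation
    elif isinstance(transform, DenseDisplacement):
        if transform.shape != ref.shape:
            raise ValueError("displacement field grid must match the reference grid")
        src_world = world + transform.field
    else:
        raise TypeError(f"unsupported transform {type(transform).__name__}")
    coords = np.stack(
        [(src_world[..., a] - obj.origin[a]) / obj.spacing[a] for a in range(3)]
    )
    order = 0 if interpolation == "nearest" else 1
    src = obj.voxels.astype(float) if obj.voxels.dtype == bool else obj.voxels
    data = ndimage.map_coordinates(src, coords, order=order, mode="constant", cval=0.0)
    if isinstance(obj, LabeledVolume):
        return LabeledVolume(np.round(data).astype(obj.voxels.dtype), ref.spacing,
                             ref.origin, labels=dict(obj.labels))
    if isinstance(obj, CellMap):
        return CellMap(data > 0.5, ref.spacing, ref.origin, channel=obj.channel)
    if isinstance(obj, ProliferationMap):
        return ProliferationMap(np.clip(data, 0, None), ref.spacing, ref.origin,
                                normalized=obj.normalized)
    return Volume(data, ref.spacing, ref.origin)


# ---------------------------------------------------------------------------
# SimpleITK bridge
# ---------------------------------------------------------------------------


def _to_sitk(vol: Volume, smooth_sigma_vox: float = 0.0) -> sitk.Image:
    data = np.asarray(vol.voxels, dtype=np.float32)
    if smooth_sigma_vox > 0:
        data = ndimage.gaussian_filter(data, smooth_sigma_vox).astype(np.float32)
    img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(vol.spacing))
    img.SetOrigin(tuple(vol.origin))
    return img


def _sitk_affine_to_transform(tf: sitk.Transform) -> SpatialTransform:
    """Convert a SimpleITK (fixed→moving) affine to our moving→fixed transform."""
    tf = sitk.AffineTransform(tf.Downcast()) if hasattr(tf, "Downcast") else tf
    A = np.array(tf.GetMatrix()).reshape(3, 3)
    c = np.array(tf.GetCenter())
    t = np.array(tf.GetTranslation())
    # sitk: x_m = A (x_f - c) + c + t  →  full affine x_m = A x_f + (c + t - A c)
    offset = c + t - A @ c
    fixed_to_moving = SpatialTransform("affine", A, offset)
    return fixed_to_moving.inverse()


def _as_sitk_affine(tf: sitk.Transform) -> sitk.AffineTransform:
    if not isinstance(tf, sitk.AffineTransform):
        tf = tf.Downcast()
    return sitk.AffineTransform(tf)


def _run_affine_once(fixed: sitk.Image, moving: sitk.Image, resolutions: int,
                     iterations: int, initial: sitk.Transform):
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=8.0, minStep=1e-8, numberOfIterations=iterations,
        relaxationFactor=0.8,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    shrink = [2**k for k in reversed(range(resolutions))]
    reg.SetShrinkFactorsPerLevel(shrink)
    reg.SetSmoothingSigmasPerLevel([max(0, k - 1) for k in reversed(range(resolutions))])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    reg.SetInitialTransform(initial, inPlace=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tf = reg.Execute(fixed, moving)
    return tf, float(reg.GetMetricValue())


def _register_affine_pair(fixed: sitk.Image, moving: sitk.Image,
                          resolutions: int, iterations: int,
                          initial: sitk.Transform | None = None) -> sitk.Transform:
    """Multi-resolution affine registration; without an explicit initial
    transform, both the geometric-centre and moments (centroid)
    initializations are tried and the run with the lower final
    mean-squared metric wins — neither basin is uniformly safe alone."""
    if initial is not None:
        return _run_affine_once(fixed, moving, resolutions, iterations, initial)[0]
    best, best_metric = None, np.inf
    for mode in (sitk.CenteredTransformInitializerFilter.MOMENTS,
                 sitk.CenteredTransformInitializerFilter.GEOMETRY):
        init = sitk.CenteredTransformInitializer(
            fixed, moving, sitk.AffineTransform(3), mode)
        tf, metric = _run_affine_once(fixed, moving, resolutions, iterations, init)
        if metric < best_metric:
            best, best_metric = tf, metric
    return best


def affine_register(moving: LabeledVolume, fixed: LabeledVolume,
                    resolutions: int = 4, iterations: int = 200) -> SpatialTransform:
    """Pairwise multi-resolution affine registration of label volumes
    (mean-squared metric on the smoothed float label images)."""
    f_img = _to_sitk(fixed, smooth_sigma_vox=1.0)
    m_img = _to_sitk(moving, smooth_sigma_vox=1.0)
    tf = _register_affine_pair(f_img, m_img, resolutions, iterations)
    return _sitk_affine_to_transform(tf)


def groupwise_affine(volumes, reference_index: int = 0, resolutions: int = 4,
                     iterations: int = 200, max_outer: int = 10, tol: float = 1e-3):
    """Groupwise affine registration of tissue label volumes via an evolving mean.

    Iterated-mean scheme: the mean starts as the reference volume; each
    volume is affinely registered to it by multi-resolution mean-squared
    optimization of the float label image (linear interpolation during
    optimization, nearest for resampling), then the mean is recomputed by
    per-voxel majority vote.  Stops when the mean's label-change fraction
    drops below ``tol`` or after ``max_outer`` outer iterations.

    Returns ``(transforms, mean_atlas, registered_volumes)`` where each
    transform maps its volume into atlas (mean) space.
    """
    volumes = list(volumes)
    if len(volumes) == 0:
        raise ValueError("no volumes")
    for v in volumes:
        if not v.same_grid(volumes[0]):
            raise ValueError("groupwise registration requires a common grid")
    if len(volumes) == 1:
        atlas = majority_vote_atlas(volumes)
        return [SpatialTransform.identity("affine")], atlas, list(volumes)

    mean_vol = volumes[reference_index]
    transforms = [None] * len(volumes)
    registered = list(volumes)
    sitk_tfs = [None] * len(volumes)
    for outer in range(max_outer):
        fixed = _to_sitk(mean_vol, smooth_sigma_vox=1.0)
        for i, vol in enumerate(volumes):
            moving = _to_sitk(vol, smooth_sigma_vox=1.0)
            # warm-start from the previous outer round so stragglers converge
            init = sitk.AffineTransform(sitk_tfs[i]) if sitk_tfs[i] is not None else None
            tf = _register_affine_pair(fixed, moving, resolutions, iterations,
                                       initial=init)
            sitk_tfs[i] = _as_sitk_affine(tf)
            transforms[i] = _sitk_affine_to_transform(tf)
            registered[i] = apply_transform(
                transforms[i], vol, reference=mean_vol, interpolation="nearest"
            )
        atlas = majority_vote_atlas(registered)
        change = float(np.mean(atlas.consensus.voxels != mean_vol.voxels))
        mean_vol = atlas.consensus
        if change < tol:
            break
    return transforms, atlas, registered


def nonlinear_register(moving: LabeledVolume, fixed: LabeledVolume,
                       iterations: int = 50, smoothing_sigma_vox: float = 2.0,
                       resolutions: int = 3, jmin_fraction: float = 0.99) -> DenseDisplacement:
    """Demons-style dense registration of affinely pre-aligned label volumes.

    Runs symmetric-forces demons with Gaussian field regularization
    (``smoothing_sigma_vox`` in voxels) on the smoothed float label images
    over a small multi-resolution pyramid.  Emits a warning (with the
    measured fraction) if the Jacobian of the result is positive on fewer
    than ``jmin_fraction`` of tissue voxels.
    """
    if not moving.same_grid(fixed):
        raise ValueError("inputs must share a grid (affinely pre-align first)")
    f_img = _to_sitk(fixed, smooth_sigma_vox=1.0)
    m_img = _to_sitk(moving, smooth_sigma_vox=1.0)

    demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
    demons.SetSmoothDisplacementField(True)
    demons.SetStandardDeviations(smoothing_sigma_vox)  # voxel units in ITK

    disp = None
    shrinks = [2**k for k in reversed(range(resolutions))]
    for level, shrink in enumerate(shrinks):
        f_l = sitk.Shrink(f_img, [shrink] * 3) if shrink > 1 else f_img
        m_l = sitk.Shrink(m_img, [shrink] * 3) if shrink > 1 else m_img
        demons.SetNumberOfIterations(iterations)
        if disp is None:
            disp = demons.Execute(f_l, m_l)
        else:
            disp = sitk.Resample(disp, f_l, sitk.Transform(), sitk.sitkLinear, 0.0,
                                 sitk.sitkVectorFloat64)
            disp = demons.Execute(f_l, m_l, disp)
    disp = sitk.Resample(disp, f_img, sitk.Transform(), sitk.sitkLinear, 0.0,
                         sitk.sitkVectorFloat64)
    arr = sitk.GetArrayFromImage(disp)  # (z, y, x, 3) with (x,y,z) components
    field = np.ascontiguousarray(arr.transpose(2, 1, 0, 3))
    out = DenseDisplacement(field, fixed.spacing, fixed.origin)

    jac = jacobian_determinant(out)
    tissue = fixed.foreground
    frac_pos = float((jac.values[tissue] > 0).mean()) if tissue.any() else 1.0
    if frac_pos < jmin_fraction:
        warnings.warn(
            f"displacement field folds: J>0 on only {frac_pos:.3f} of tissue voxels",
            RuntimeWarning,
        )
    return out


@dataclass
class JacobianField:
    """Per-voxel determinant of the local deformation gradient."""

    values: np.ndarray
    spacing: tuple
    origin: tuple = (0.0, 0.0, 0.0)
    positive_fraction: float = field(default=1.0)


def jacobian_determinant(disp: DenseDisplacement) -> JacobianField:
    """J(v) = det(I + ∇u(v)); central differences interior, one-sided at borders.

    For the identity field J ≡ 1; for a uniform scaling displacement
    ``u(x) = (s−1)x`` it is exactly s³.
    """
    u = disp.field
    grads = np.empty(u.shape[:3] + (3, 3))
    for comp in range(3):
        gx, gy, gz = np.gradient(u[..., comp], *disp.spacing)
        grads[..., comp, 0] = gx
        grads[..., comp, 1] = gy
        grads[..., comp, 2] = gz
    grads[..., 0, 0] += 1.0
    grads[..., 1, 1] += 1.0
    grads[..., 2, 2] += 1.0
    a, b, c = grads[..., 0, 0], grads[..., 0, 1], grads[..., 0, 2]
    d, e, f = grads[..., 1, 0], grads[..., 1, 1], grads[..., 1, 2]
    g, h, i = grads[..., 2, 0], grads[..., 2, 1], grads[..., 2, 2]
    det = a * (e * i - f * h) - b * (d * i - f * g) + c * (d * h - e * g)
    return JacobianField(det, disp.spacing, disp.origin,
                         positive_fraction=float((det > 0).mean()))
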