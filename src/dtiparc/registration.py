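"""Diffeomorphic atlas-to-subject registration and local affine refinement.

The global stage is a greedy multi-resolution composed-diffeomorphic
scheme driven by two contrast channels (FA and MD by default): at each
resolution level a demons-like matching force is smoothed by a Gaussian
kernel (standing in for an operator-induced smoothness norm), capped to a
fraction of a voxel, and composed into the running transform so that
invertibility is preserved; candidate steps are accepted only when the
two-channel sum-of-squares energy decreases and the Jacobian determinant
stays positive.  The accumulated norm of the smoothed velocity steps is
recorded as a geodesic-length proxy, used downstream as the deformation
prior (larger deformations weigh less in the fusion selector).

The local stage refines each structure of each atlas with a 12-parameter
affine transform composed with the global field, maximising the Dice
overlap against the current target parcellation plus a diagonal Gaussian
log-prior on the parameters (variance 0.01 on the 9 linear deviations,
100 on the 3 translations).

The registration stage is deliberately pluggable: any backend producing a
positive-Jacobian displacement field plus a deformation-magnitude scalar
can replace :func:`register_two_channel` without touching the fusion loop.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize

from .volumes import LabelMap, ScalarVolume

log = logging.getLogger(__name__)


# -- deformation field -------------------------------------------------------


def _grid_points(shape: tuple[int, int, int]) -> np.ndarray:
    """All voxel-centre coordinates, shape (3, nx, ny, nz)."""
    return np.array(
        np.meshgrid(*(np.arange(n, dtype=np.float64) for n in shape), indexing="ij")
    )


@dataclasses.dataclass
class DeformationField:
    """Dense displacement field mapping subject voxel coords to atlas coords.

    ``disp`` has shape (3, nx, ny, nz); the transform is
    ``phi(x) = x + disp(x)`` with ``disp`` trilinearly interpolated (edge
    values extended) at off-grid points.  ``geodesic_proxy`` accumulates
    the mean norm of the smoothed velocity steps that built the field and
    is 0 for the identity.
    """

    disp: np.ndarray
    geodesic_proxy: float = 0.0
    schedule: tuple = ()

    def __post_init__(self) -> None:
        self.disp = np.asarray(self.disp, dtype=np.float64)
        if self.disp.ndim != 4 or self.disp.shape[0] != 3:
            raise ValueError(f"displacement must be (3, nx, ny, nz), got {self.disp.shape}")

    @classmethod
    def identity(cls, shape: tuple[int, int, int]) -> "DeformationField":
        return cls(np.zeros((3,) + tuple(shape)), 0.0, ())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.disp.shape[1:]  # type: ignore[return-value]

    @property
    def max_displacement(self) -> float:
        return float(np.sqrt((self.disp**2).sum(axis=0)).max())

    def displacement_at(self, points: np.ndarray) -> np.ndarray:
        """Interpolate the displacement at fractional voxel points (N, 3)."""
        pts = np.asarray(points, dtype=np.float64).T  # (3, N)
        return np.stack(
            [ndimage.map_coordinates(self.disp[i], pts, order=1, mode="nearest") for i in range(3)],
            axis=1,
        )

    def transform_points(self, points: np.ndarray) -> np.ndarray:
        """Map subject points (N, 3) to atlas coordinates."""
        pts = np.asarray(points, dtype=np.float64)
        return pts + self.displacement_at(pts)

    def jacobian_determinant(self) -> np.ndarray:
        """det(d phi / dx) via central differences of phi = id + disp."""
        phi = self.disp + _grid_points(self.shape)
        grads = np.empty((3, 3) + self.shape)
        for i in range(3):
            for ax in range(3):
                grads[i, ax] = np.gradient(phi[i], axis=ax)
        return (
            grads[0, 0] * (grads[1, 1] * grads[2, 2] - grads[1, 2] * grads[2, 1])
            - grads[0, 1] * (grads[1, 0] * grads[2, 2] - grads[1, 2] * grads[2, 0])
            + grads[0, 2] * (grads[1, 0] * grads[2, 1] - grads[1, 1] * grads[2, 0])
        )


def warp_volume(
    data: np.ndarray,
    field: DeformationField,
    order: int = 1,
    cval: float = 0.0,
) -> np.ndarray:
    """Pull-back resampling of a whole volume through ``field``."""
    coords = _grid_points(field.shape) + field.disp
    return ndimage.map_coordinates(np.asarray(data, float), coords, order=order, mode="constant", cval=cval)


# -- 12-parameter local affine ----------------------------------------------


@dataclasses.dataclass
class AffineTransform12:
    """Local affine: 9 linear deviations from identity (row order) + 3
    translations in voxels, applied about a fixed centre point.

    ``y = c + (I + M) (x - c) + t``
    """

    params: np.ndarray = dataclasses.field(default_factory=lambda: np.zeros(12))
    center: np.ndarray = dataclasses.field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=np.float64).ravel()
        if self.params.size != 12:
            raise ValueError("affine needs 12 parameters")
        self.center = np.asarray(self.center, dtype=np.float64).ravel()
        if abs(np.linalg.det(self.matrix)) <= 1e-6:
            raise ValueError("affine linear part is singular")

    @property
    def matrix(self) -> np.ndarray:
        return np.eye(3) + self.params[:9].reshape(3, 3)

    @property
    def translation(self) -> np.ndarray:
        return self.params[9:]

    @property
    def is_identity(self) -> bool:
        return bool(np.all(self.params == 0.0))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        return (pts - self.center) @ self.matrix.T + self.center + self.translation


@dataclasses.dataclass
class AffinePrior:
    """Zero-mean diagonal Gaussian prior on the 12 affine parameters.

    Default variances: 0.01 for the 9 linear deviations (they should stay
    near identity) and 100 for the 3 translations (which may be large).
    """

    variances: np.ndarray = dataclasses.field(
        default_factory=lambda: np.concatenate([np.full(9, 0.01), np.full(3, 100.0)])
    )

    def __post_init__(self) -> None:
        self.variances = np.asarray(self.variances, dtype=np.float64).ravel()
        if self.variances.size != 12 or np.any(self.variances <= 0):
            raise ValueError("prior needs 12 strictly positive variances")

    def log_density(self, params: np.ndarray) -> float:
        """Log density up to the normalizing constant (identical across
        atlases, hence irrelevant to the fusion selector)."""
        p = np.asarray(params, dtype=np.float64).ravel()
        return float(-0.5 * np.sum(p * p / self.variances))


# -- global greedy diffeomorphic registration --------------------------------


def _normalize_channels(
    moving: Sequence[np.ndarray], fixed: Sequence[np.ndarray]
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Z-score each channel by the fixed image's statistics so FA (~0.5)
    and MD (~1e-3 mm²/s) contribute on comparable scales."""
    mv, fx = [], []
    for m, f in zip(moving, fixed):
        mu, sd = float(f.mean()), float(f.std())
        sd = sd if sd > 1e-12 else 1.0
        mv.append((np.asarray(m, float) - mu) / sd)
        fx.append((np.asarray(f, float) - mu) / sd)
    return mv, fx


def _resize(arr: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    factors = [t / s for t, s in zip(shape, arr.shape)]
    return ndimage.zoom(arr, factors, order=1, mode="nearest", grid_mode=True)


def _energy(moving: list[np.ndarray], fixed: list[np.ndarray], weights: np.ndarray,
            disp: np.ndarray, grid: np.ndarray) -> float:
    coords = grid + disp
    e = 0.0
    for m, f, w in zip(moving, fixed, weights):
        warped = ndimage.map_coordinates(m, coords, order=1, mode="nearest")
        e += w * float(((warped - f) ** 2).sum())
    return e


def register_two_channel(
    atlas_channels: Sequence[ScalarVolume | np.ndarray],
    subject_channels: Sequence[ScalarVolume | np.ndarray],
    levels: Sequence[int] = (4, 2, 1),
    iterations: Sequence[int] = (100, 60, 30),
    sigma_fluid: float = 2.0,
    step: float = 0.5,
    channel_weights: Sequence[float] | None = None,
) -> DeformationField:
    """Greedy multi-resolution diffeomorphic registration of an atlas onto
    a subject, driven by two (or more) contrast channels.

    Returns a field whose multi-channel sum-of-squares energy never
    exceeds the identity transform's and whose Jacobian determinant is
    positive everywhere.  ``levels`` are downsampling factors coarse to
    fine; ``sigma_fluid`` (voxels, at each level) smooths the velocity
    update, realising a coarse-to-fine smoothness cascade together with
    the level pyramid.  Identical inputs yield the identity field.
    """
    atlas = [c.data if isinstance(c, ScalarVolume) else np.asarray(c, float) for c in atlas_channels]
    subj = [c.data if isinstance(c, ScalarVolume) else np.asarray(c, float) for c in subject_channels]
    if len(atlas) != len(subj) or not atlas:
        raise ValueError("need equally many atlas and subject channels")
    shape = subj[0].shape
    for a, s in zip(atlas, subj):
        if a.shape != shape or s.shape != shape:
            raise ValueError("atlas and subject channels must share one grid")
    weights = np.asarray(
        channel_weights if channel_weights is not None else np.full(len(atlas), 1.0 / len(atlas)),
        dtype=np.float64,
    )
    atlas, subj = _normalize_channels(atlas, subj)

    disp: np.ndarray | None = None
    proxy = 0.0
    for level, n_iter in zip(levels, iterations):
        lshape = tuple(max(4, int(round(n / level))) for n in shape)
        scale = [ls / fs for ls, fs in zip(lshape, shape)]
        a_l = [_resize(ndimage.gaussian_filter(a, max(level / 2.0, 1e-6)), lshape) for a in atlas]
        s_l = [_resize(ndimage.gaussian_filter(s, max(level / 2.0, 1e-6)), lshape) for s in subj]
        grid = _grid_points(lshape)
        if disp is None:
            disp = np.zeros((3,) + lshape)
        else:
            old_shape = disp.shape[1:]
            disp = np.stack(
                [
                    _resize(disp[i], lshape) * (lshape[i] / old_shape[i])
                    for i in range(3)
                ]
            )
        best = _energy(a_l, s_l, weights, disp, grid)
        if not np.isfinite(best):
            raise RuntimeError("non-finite registration energy")
        step_local = step
        sf = sigma_fluid
        for _ in range(n_iter):
            coords = grid + disp
            force = np.zeros((3,) + lshape)
            for m, f, w in zip(a_l, s_l, weights):
                warped = ndimage.map_coordinates(m, coords, order=1, mode="nearest")
                residual = f - warped
                grad = np.gradient(warped)
                for i in range(3):
                    force[i] += w * residual * grad[i]
            u = np.stack([ndimage.gaussian_filter(force[i], sf) for i in range(3)])
            mag = float(np.sqrt((u**2).sum(axis=0)).max())
            if mag < 1e-9:
                break
            u *= step_local / mag
            # compose: phi_new = phi_old o (id + u)
            pts = (grid + u).reshape(3, -1)
            cand = np.stack(
                [
                    u[i]
                    + ndimage.map_coordinates(disp[i], pts, order=1, mode="nearest").reshape(lshape)
                    for i in range(3)
                ]
            )
            jmin = float(DeformationField(cand).jacobian_determinant().min())
            if jmin <= 0.05:
                sf *= 1.5
                step_local *= 0.7
                if step_local < 0.02:
                    break
                continue
            e = _energy(a_l, s_l, weights, cand, grid)
            if np.isfinite(e) and e < best:
                disp = cand
                best = e
                proxy += float(np.sqrt((u**2).sum(axis=0)).mean()) / scale[0]
            else:
                step_local *= 0.6
                if step_local < 0.02:
                    break
        if not np.isfinite(best):
            raise RuntimeError("non-finite registration energy")

    assert disp is not None
    if disp.shape[1:] != shape:
        old_shape = disp.shape[1:]
        disp = np.stack(
            [_resize(disp[i], shape) * (shape[i] / old_shape[i]) for i in range(3)]
        )
    field = DeformationField(disp, geodesic_proxy=proxy, schedule=tuple(levels))
    # final guarantee: never worse than identity at full resolution
    grid = _grid_points(shape)
    e_final = _energy(atlas, subj, weights, disp, grid)
    e_id = _energy(atlas, subj, weights, np.zeros_like(disp), grid)
    if e_final > e_id:
        log.warning("registration did not improve on identity; returning identity field")
        return DeformationField.identity(shape)
    if field.jacobian_determinant().min() <= 0:
        log.warning("non-positive Jacobian after upsampling; returning identity field")
        return DeformationField.identity(shape)
    return field


# -- composition and resampling ----------------------------------------------


def compose_transform_points(
    field: DeformationField,
    affine: AffineTransform12 | None,
    points: np.ndarray,
) -> np.ndarray:
    """Map subject points through affine-then-field (pull-back order)."""
    pts = np.asarray(points, dtype=np.float64)
    if affine is not None and not affine.is_identity:
        pts = affine.apply(pts)
    return pts + field.displacement_at(pts)


def compose_and_resample(
    field: DeformationField,
    affine: AffineTransform12 | None,
    vol: ScalarVolume | LabelMap,
    mode: str | None = None,
) -> ScalarVolume | LabelMap:
    """Resample a volume through ``field`` composed with a local affine.

    Scalars default to trilinear sampling, label maps to nearest-neighbour
    (background fill outside the grid).
    """
    is_labels = isinstance(vol, LabelMap)
    if mode is None:
        mode = "nearest" if is_labels else "trilinear"
    order = {"trilinear": 1, "nearest": 0}[mode]
    shape = field.shape
    pts = _grid_points(shape).reshape(3, -1).T
    mapped = compose_transform_points(field, affine, pts).T
    data = vol.data.astype(np.float64)
    out = ndimage.map_coordinates(data, mapped, order=order, mode="constant", cval=0.0)
    out = out.reshape(shape)
    if is_labels:
        return vol.like(np.rint(out).astype(np.int32))
    return vol.like(out)


# -- deformation prior -------------------------------------------------------


def diffeo_prior(field: DeformationField) -> float:
    """Unnormalized deformation prior exp(-geodesic proxy); 1 for identity."""
    return float(np.exp(-field.geodesic_proxy))


def diffeo_weights(fields: Sequence[DeformationField]) -> np.ndarray:
    """Relative deformation-prior weights across an atlas library."""
    g = np.array([f.geodesic_proxy for f in fields], dtype=np.float64)
    w = np.exp(-(g - g.min()))
    return w / w.sum()


# -- local affine optimisation -----------------------------------------------


def _bbox_from_mask(mask: np.ndarray, dilate: int, shape: tuple[int, int, int]):
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - dilate, 0)
    hi = np.minimum(idx.max(axis=0) + dilate + 1, shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def optimize_local_affine(
    structure: int,
    atlas_labels: LabelMap,
    global_field: DeformationField,
    target_parcellation: LabelMap,
    prior: AffinePrior | None = None,
    smooth_sigma: float = 1.0,
    bbox_dilate: int = 5,
    maxiter_translation: int = 40,
    maxiter_full: int = 80,
    min_improvement: float = 1e-6,
) -> AffineTransform12:
    """Per-structure 12-parameter affine refinement.

    Maximises ``soft Dice(deformed atlas structure, target structure) +
    log prior`` by derivative-free search (Nelder-Mead; translation block
    first, then all 12 parameters) over a structure bounding box dilated
    by ``bbox_dilate`` voxels.  The returned transform never scores worse
    than identity on the objective; an empty structure on either side
    returns identity with a warning.
    """
    prior = prior if prior is not None else AffinePrior()
    atlas_mask = atlas_labels.data == structure
    if not atlas_mask.any():
        log.warning("structure %d empty in atlas; identity affine", structure)
        return AffineTransform12()
    target_mask = target_parcellation.data == structure
    if not target_mask.any():
        log.warning("structure %d empty in target parcellation; identity affine", structure)
        return AffineTransform12()

    shape = target_parcellation.shape
    ind = atlas_mask.astype(np.float64)
    ind_smooth = ndimage.gaussian_filter(ind, smooth_sigma)
    # support region: target structure plus the globally-deformed atlas structure
    base = warp_volume(ind, global_field, order=1)
    support = target_mask | (base > 0.01)
    if not support.any():
        return AffineTransform12()
    box = _bbox_from_mask(support, bbox_dilate, shape)
    grid = np.array(
        np.meshgrid(
            *(np.arange(s.start, s.stop, dtype=np.float64) for s in box), indexing="ij"
        )
    )
    pts = grid.reshape(3, -1).T
    t_vals = target_mask[box].ravel().astype(np.float64)
    t_sum = t_vals.sum()

    w = base[box].ravel()
    if w.sum() > 0:
        center = (pts * w[:, None]).sum(axis=0) / w.sum()
    else:
        center = (pts * t_vals[:, None]).sum(axis=0) / max(t_sum, 1.0)

    def _soft_dice(p: np.ndarray, volume: np.ndarray) -> float:
        aff = AffineTransform12(p, center)
        mapped = compose_transform_points(global_field, aff, pts).T
        vals = ndimage.map_coordinates(volume, mapped, order=1, mode="constant", cval=0.0)
        return 2.0 * float((vals * t_vals).sum()) / (float(vals.sum()) + t_sum + 1e-12)

    def objective(p: np.ndarray) -> float:
        # smoothed indicator: wide capture basin for the search
        return -(_soft_dice(p, ind_smooth) + prior.log_density(p))

    def objective_exact(p: np.ndarray) -> float:
        # trilinear on the raw indicator: identity scores Dice 1 at
        # perfect alignment, so alignment is a true fixpoint
        return -(_soft_dice(p, ind) + prior.log_density(p))

    p0 = np.zeros(12)
    f_id = objective(p0)
    best_p, best_f = p0, f_id

    # stage 1: translations only
    def obj_t(t: np.ndarray) -> float:
        p = np.zeros(12)
        p[9:] = t
        return objective(p)

    res_t = minimize(
        obj_t, np.zeros(3), method="Nelder-Mead",
        options={"maxiter": maxiter_translation, "xatol": 0.05, "fatol": 1e-8},
    )
    p1 = np.zeros(12)
    p1[9:] = res_t.x
    f1 = objective(p1)
    if f1 < best_f:
        best_p, best_f = p1, f1

    # stage 2: all 12 parameters
    res = minimize(
        objective, best_p, method="Nelder-Mead",
        options={"maxiter": maxiter_full, "xatol": 0.01, "fatol": 1e-8},
    )
    if np.isfinite(res.fun) and res.fun < best_f:
        try:
            cand = AffineTransform12(res.x, center)
        except ValueError:
            cand = None
        if cand is not None:
            best_p, best_f = res.x, float(res.fun)

    # accept the candidate only if it genuinely beats identity on the
    # exact (unsmoothed) objective; alignment stays a fixpoint
    if objective_exact(best_p) >= objective_exact(p0) - min_improvement:
        return AffineTransform12(np.zeros(12), center)
    return AffineTransform12(best_p, center)
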