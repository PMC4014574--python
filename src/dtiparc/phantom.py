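"""Synthetic multi-atlas DTI phantoms.

The generator builds a ground-truth labeled multi-contrast volume from
simple geometric primitives (ellipsoids, boxes, axis-aligned tubes
standing in for a ventricle, deep gray nuclei and white-matter tracts),
draws each structure's channel intensities from per-channel Gaussian
mixtures, and produces an atlas library by warping the truth through
random smooth diffeomorphisms and redrawing intensities — emulating a set
of subjects who share topology but differ in shape and noise.

Two stock designs are provided:

* :func:`default_spec` — a 48³ grid at 2.5 mm spacing with 6 structures
  (ventricle, two deep-gray nuclei, two orthogonally-oriented white-matter
  tracts and a peripheral shell mixing CSF-like and cortex-like voxels so
  the MD 0.0015 / FA 0.2 decomposition thresholds are exercised), plus
  background;
* :func:`make_ambiguity_phantom` — five adjacent slabs in which each
  adjacent pair is separable in exactly one channel group (ventricle vs
  tissue by MD, gray vs white by FA, the two tracts only by eigenvector
  orientation), for single-contrast ablation studies.

What the phantom deliberately does not emulate: Rician DWI noise physics,
partial-volume mixing at boundaries, cortical folding, or scanner-specific
intensity non-uniformity.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
from scipy import ndimage

from .intensity import GaussianMixture1D
from .registration import DeformationField, _grid_points
from .volumes import LabelMap, MultiContrastImage, ScalarVolume

log = logging.getLogger(__name__)


# -- spec --------------------------------------------------------------------


@dataclasses.dataclass
class ChannelMixture:
    """Generating 1-D mixture for one (structure, channel)."""

    weights: tuple[float, ...]
    means: tuple[float, ...]
    sigmas: tuple[float, ...]

    def as_model(self) -> GaussianMixture1D:
        return GaussianMixture1D(
            np.asarray(self.weights), np.asarray(self.means), np.asarray(self.sigmas) ** 2
        )

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.choice(len(self.weights), size=n, p=np.asarray(self.weights))
        return rng.normal(np.asarray(self.means)[comp], np.asarray(self.sigmas)[comp])


@dataclasses.dataclass
class StructureDef:
    """One phantom structure: geometry plus generating intensity models.

    ``geometry`` is a dict with ``kind`` in {"ellipsoid", "box", "tube"}
    and its parameters in voxel units.  ``ev_axis`` is the mean primary
    eigenvector direction (renormalized to unit norm); ``ev_sigma`` is the
    isotropic spread of the direction before normalization — large values
    give near-uniform orientations (gray-matter-like), small values a
    tight fiber orientation (tract-like).
    """

    label: int
    name: str
    geometry: dict
    fa: ChannelMixture
    md: ChannelMixture
    ev_axis: tuple[float, float, float] = (1.0, 1.0, 1.0)
    ev_sigma: float = 0.6

    def __post_init__(self) -> None:
        ax = np.asarray(self.ev_axis, dtype=np.float64)
        n = np.linalg.norm(ax)
        if n <= 0:
            raise ValueError("ev_axis must be non-zero")
        self.ev_axis = tuple(ax / n)


@dataclasses.dataclass
class PhantomSpec:
    """Full description of a synthetic study."""

    shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    structures: Sequence[StructureDef] = ()
    background_fa: ChannelMixture = dataclasses.field(
        default_factory=lambda: ChannelMixture((1.0,), (0.06,), (0.02,))
    )
    background_md: ChannelMixture = dataclasses.field(
        default_factory=lambda: ChannelMixture((1.0,), (0.0004,), (0.0001,))
    )
    deform_magnitude: float = 2.5
    deform_smoothness_mm: float = 10.0
    seed: int = 0


@dataclasses.dataclass
class AtlasPair:
    """An equally-formatted multi-contrast image plus its label map."""

    image: MultiContrastImage
    labels: LabelMap
    name: str = ""


@dataclasses.dataclass
class PhantomLibrary:
    """A ground truth, a deformed held-out subject and n deformed atlases."""

    truth: AtlasPair
    subject: AtlasPair
    subject_true_field: DeformationField
    atlases: list[AtlasPair]
    atlas_true_fields: list[DeformationField]
    spec: PhantomSpec


# -- geometry rasterization --------------------------------------------------


def _rasterize(geometry: dict, shape: tuple[int, int, int]) -> np.ndarray:
    gx, gy, gz = _grid_points(shape)
    kind = geometry["kind"]
    if kind == "ellipsoid":
        c = geometry["center"]
        r = geometry["radii"]
        return ((gx - c[0]) / r[0]) ** 2 + ((gy - c[1]) / r[1]) ** 2 + (
            (gz - c[2]) / r[2]
        ) ** 2 <= 1.0
    if kind == "shell":
        c = geometry["center"]
        r_in, r_out = geometry["radii_inner"], geometry["radii_outer"]
        d_out = ((gx - c[0]) / r_out[0]) ** 2 + ((gy - c[1]) / r_out[1]) ** 2 + (
            (gz - c[2]) / r_out[2]
        ) ** 2
        d_in = ((gx - c[0]) / r_in[0]) ** 2 + ((gy - c[1]) / r_in[1]) ** 2 + (
            (gz - c[2]) / r_in[2]
        ) ** 2
        return (d_out <= 1.0) & (d_in > 1.0)
    if kind == "box":
        lo, hi = geometry["lo"], geometry["hi"]
        return (
            (gx >= lo[0]) & (gx < hi[0]) & (gy >= lo[1]) & (gy < hi[1]) & (gz >= lo[2]) & (gz < hi[2])
        )
    if kind == "tube":
        axis = geometry["axis"]
        c = geometry["center"]
        r = geometry["radius"]
        lo, hi = geometry["extent"]
        coords = [gx, gy, gz]
        along = coords[axis]
        others = [coords[i] - c_i for i, c_i in zip([i for i in range(3) if i != axis],
                                                    [c[i] for i in range(3) if i != axis])]
        return (others[0] ** 2 + others[1] ** 2 <= r**2) & (along >= lo) & (along < hi)
    raise ValueError(f"unknown geometry kind {kind!r}")


def rasterize_labels(spec: PhantomSpec) -> LabelMap:
    """Paint structures in list order; later entries win on overlap."""
    out = np.zeros(spec.shape, dtype=np.int32)
    for s in spec.structures:
        mask = _rasterize(s.geometry, spec.shape)
        overlap = int(((out != 0) & mask).sum())
        if overlap:
            log.info("structure %d overwrites %d voxels of earlier structures", s.label, overlap)
        out[mask] = s.label
    return LabelMap(out, spec.spacing)


# -- intensity sampling ------------------------------------------------------


def _sample_ev(axis: tuple[float, float, float], sigma: float, n: int,
               rng: np.random.Generator) -> np.ndarray:
    """Draw |unit eigenvector| triples around a mean axis.

    A Gaussian perturbation of the axis is renormalized to unit norm and
    taken componentwise absolute — the same degeneracy-resolving absolute
    value used on real primary eigenvectors.
    """
    v = np.asarray(axis)[None, :] + rng.normal(0.0, sigma, size=(n, 3))
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    norms[norms < 1e-12] = 1.0
    return np.abs(v / norms)


def make_ground_truth(spec: PhantomSpec, seed: int | None = None) -> AtlasPair:
    """Rasterize the geometry and draw intensities from the generating
    mixtures; deterministic for a given seed."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    labels = rasterize_labels(spec)
    shape = spec.shape
    fa = np.empty(shape)
    md = np.empty(shape)
    ev = np.empty(shape + (3,))

    n_bg = int((labels.data == 0).sum())
    bg = labels.data == 0
    fa[bg] = spec.background_fa.sample(n_bg, rng)
    md[bg] = spec.background_md.sample(n_bg, rng)
    ev[bg] = _sample_ev((1.0, 1.0, 1.0), 1.0, n_bg, rng)

    for s in spec.structures:
        sel = labels.data == s.label
        n = int(sel.sum())
        if n == 0:
            log.warning("structure %d (%s) rasterized to zero voxels", s.label, s.name)
            continue
        fa[sel] = s.fa.sample(n, rng)
        md[sel] = s.md.sample(n, rng)
        ev[sel] = _sample_ev(s.ev_axis, s.ev_sigma, n, rng)

    fa = np.clip(fa, 0.0, 1.0)
    md = np.clip(md, 0.0, None)
    img = MultiContrastImage.from_arrays(
        fa, md, ev[..., 0], ev[..., 1], ev[..., 2], spacing=spec.spacing
    )
    return AtlasPair(img, labels, name="truth")


def resample_intensities(
    labels: LabelMap, spec: PhantomSpec, seed: int
) -> MultiContrastImage:
    """Fresh intensity draw from the generating mixtures on a label map."""
    tmp = dataclasses.replace(spec, seed=seed)
    rng = np.random.default_rng(seed)
    shape = labels.shape
    fa = np.empty(shape)
    md = np.empty(shape)
    ev = np.empty(shape + (3,))
    bg = labels.data == 0
    n_bg = int(bg.sum())
    fa[bg] = tmp.background_fa.sample(n_bg, rng)
    md[bg] = tmp.background_md.sample(n_bg, rng)
    ev[bg] = _sample_ev((1.0, 1.0, 1.0), 1.0, n_bg, rng)
    for s in spec.structures:
        sel = labels.data == s.label
        n = int(sel.sum())
        if n == 0:
            continue
        fa[sel] = s.fa.sample(n, rng)
        md[sel] = s.md.sample(n, rng)
        ev[sel] = _sample_ev(s.ev_axis, s.ev_sigma, n, rng)
    fa = np.clip(fa, 0.0, 1.0)
    md = np.clip(md, 0.0, None)
    return MultiContrastImage.from_arrays(
        fa, md, ev[..., 0], ev[..., 1], ev[..., 2], spacing=labels.spacing
    )


# -- random diffeomorphisms --------------------------------------------------


def random_diffeo(
    shape: tuple[int, int, int],
    magnitude: float,
    smoothness_mm: float,
    spacing: Sequence[float],
    seed: int,
    max_retries: int = 5,
) -> tuple[DeformationField, DeformationField]:
    """Random smooth invertible field plus its (approximate) inverse.

    Gaussian-filtered white noise is scaled to ``magnitude`` voxels (max
    norm) and exponentiated by scaling-and-squaring, which keeps the
    Jacobian determinant positive; if it is not, the magnitude is reduced
    with a warning.  Returns ``(forward, inverse)``.
    """
    rng = np.random.default_rng(seed)
    sigma = [smoothness_mm / sp for sp in spacing]
    v = rng.standard_normal((3,) + tuple(shape))
    for i in range(3):
        v[i] = ndimage.gaussian_filter(v[i], sigma[i % len(sigma)])
    norm = np.sqrt((v**2).sum(axis=0)).max()
    if norm <= 0:
        return DeformationField.identity(shape), DeformationField.identity(shape)
    v *= magnitude / norm

    mag = magnitude
    for attempt in range(max_retries):
        fwd = _exponentiate(v * (mag / magnitude))
        inv = _exponentiate(-v * (mag / magnitude))
        if fwd.jacobian_determinant().min() > 0 and inv.jacobian_determinant().min() > 0:
            return fwd, inv
        log.warning("random diffeo magnitude %.2f produced folding; reducing", mag)
        mag *= 0.7
    return DeformationField.identity(shape), DeformationField.identity(shape)


def _exponentiate(v: np.ndarray) -> DeformationField:
    """Scaling-and-squaring exponential of a stationary velocity field."""
    shape = v.shape[1:]
    max_norm = float(np.sqrt((v**2).sum(axis=0)).max())
    n_steps = max(0, int(np.ceil(np.log2(max(max_norm, 1e-12) / 0.25))))
    disp = v / (2**n_steps)
    grid = _grid_points(shape)
    for _ in range(n_steps):
        pts = (grid + disp).reshape(3, -1)
        disp = disp + np.stack(
            [
                ndimage.map_coordinates(disp[i], pts, order=1, mode="nearest").reshape(shape)
                for i in range(3)
            ]
        )
    return DeformationField(disp, geodesic_proxy=max_norm)


def deform_copy(
    truth: AtlasPair,
    magnitude: float,
    smoothness_mm: float,
    seed: int,
) -> tuple[AtlasPair, DeformationField, DeformationField]:
    """Warp a ground-truth pair through a random diffeomorphism.

    The returned copy ``C`` satisfies ``C(x) = truth(fwd(x))`` with labels
    resampled nearest-neighbour and channels trilinearly.  Returns
    ``(copy, fwd, inv)`` so registration oracles can use the true fields.
    Magnitude 0 returns an identical copy.
    """
    shape = truth.labels.shape
    if magnitude == 0:
        ident = DeformationField.identity(shape)
        img = MultiContrastImage(
            [c.like(c.data.copy()) for c in truth.image.channels], validate="none"
        )
        return AtlasPair(img, truth.labels.like(truth.labels.data.copy())), ident, ident

    fwd, inv = random_diffeo(shape, magnitude, smoothness_mm, truth.labels.spacing, seed)
    grid = _grid_points(shape)
    coords = grid + fwd.disp
    new_labels = ndimage.map_coordinates(
        truth.labels.data.astype(np.float64), coords, order=0, mode="constant", cval=0.0
    ).astype(np.int32)
    chans = []
    for c in truth.image.channels:
        chans.append(
            c.like(ndimage.map_coordinates(c.data, coords, order=1, mode="nearest"))
        )
    img = MultiContrastImage(chans, validate="clamp")
    return AtlasPair(img, truth.labels.like(new_labels)), fwd, inv


def make_library(
    spec: PhantomSpec,
    n_atlases: int = 4,
    seed: int | None = None,
    redraw_intensities: bool = True,
) -> PhantomLibrary:
    """Ground truth + a deformed held-out subject + ``n_atlases`` deformed
    atlas copies.

    Each copy gets its own random deformation; with
    ``redraw_intensities`` (default) the copy's channels are freshly drawn
    from the generating mixtures on its deformed label map, so atlases
    differ in both shape and noise, like distinct subjects.
    """
    if n_atlases < 1:
        raise ValueError("need at least one atlas")
    base_seed = spec.seed if seed is None else seed
    truth = make_ground_truth(spec, seed=base_seed)

    def one_copy(tag: str, s: int):
        pair, fwd, inv = deform_copy(
            truth, spec.deform_magnitude, spec.deform_smoothness_mm, seed=s
        )
        if redraw_intensities and spec.deform_magnitude != 0:
            pair = AtlasPair(
                resample_intensities(pair.labels, spec, seed=s + 500009), pair.labels, name=tag
            )
        else:
            pair = AtlasPair(pair.image, pair.labels, name=tag)
        return pair, fwd, inv

    subject, subj_fwd, _ = one_copy("subject", base_seed + 1000003)
    atlases, fields = [], []
    for i in range(n_atlases):
        pair, fwd, _ = one_copy(f"atlas{i}", base_seed + 7919 * (i + 1))
        atlases.append(pair)
        fields.append(fwd)
    return PhantomLibrary(truth, subject, subj_fwd, atlases, fields, spec)


# -- stock designs -----------------------------------------------------------

_TISSUE_MD = ChannelMixture((1.0,), (0.0007,), (0.0001,))
_CSF_MD = ChannelMixture((1.0,), (0.0030,), (0.0002,))


def default_spec(seed: int = 0) -> PhantomSpec:
    """The 6-structure 48³ phantom used for recovery studies.

    MD means: tissue ~0.0007, CSF ~0.0030 mm²/s so the 0.0015 threshold is
    exercised; the peripheral shell mixes CSF-like and cortex-like voxels
    (two-component mixtures).
    """
    c = (24.0, 24.0, 24.0)
    structures = [
        StructureDef(
            6, "peripheral-shell",
            {"kind": "shell", "center": c, "radii_inner": (15.0, 15.0, 14.0),
             "radii_outer": (18.0, 18.0, 17.0)},
            fa=ChannelMixture((0.5, 0.5), (0.12, 0.08), (0.04, 0.04)),
            md=ChannelMixture((0.5, 0.5), (0.0008, 0.0030), (0.0001, 0.0002)),
            ev_axis=(1.0, 1.0, 1.0), ev_sigma=1.0,
        ),
        StructureDef(
            1, "ventricle",
            {"kind": "ellipsoid", "center": (24.0, 24.0, 26.0), "radii": (5.0, 7.0, 5.0)},
            fa=ChannelMixture((1.0,), (0.10, ), (0.03,)),
            md=_CSF_MD,
            ev_axis=(1.0, 1.0, 1.0), ev_sigma=1.0,
        ),
        StructureDef(
            2, "caudate",
            {"kind": "ellipsoid", "center": (14.0, 22.0, 24.0), "radii": (4.0, 6.0, 4.5)},
            fa=ChannelMixture((1.0,), (0.15,), (0.03,)),
            md=_TISSUE_MD,
            ev_axis=(1.0, 1.0, 1.0), ev_sigma=1.0,
        ),
        StructureDef(
            3, "thalamus",
            {"kind": "ellipsoid", "center": (33.0, 25.0, 22.0), "radii": (5.0, 5.5, 5.0)},
            fa=ChannelMixture((1.0,), (0.32,), (0.04,)),
            md=_TISSUE_MD,
            ev_axis=(1.0, 1.0, 1.0), ev_sigma=1.0,
        ),
        StructureDef(
            4, "tract-x",
            {"kind": "tube", "axis": 0, "center": (0.0, 14.0, 18.0), "radius": 4.0,
             "extent": (10.0, 38.0)},
            fa=ChannelMixture((1.0,), (0.60,), (0.05,)),
            md=_TISSUE_MD,
            ev_axis=(1.0, 0.0, 0.0), ev_sigma=0.12,
        ),
        StructureDef(
            5, "tract-z",
            {"kind": "tube", "axis": 2, "center": (24.0, 33.0, 0.0), "radius": 4.0,
             "extent": (10.0, 38.0)},
            fa=ChannelMixture((1.0,), (0.60,), (0.05,)),
            md=_TISSUE_MD,
            ev_axis=(0.0, 0.0, 1.0), ev_sigma=0.12,
        ),
    ]
    return PhantomSpec(structures=structures, seed=seed)


def make_ambiguity_phantom(seed: int = 0) -> PhantomSpec:
    """Five adjacent slabs, each adjacent pair separable in exactly one
    channel group.

    Slabs 1|2 differ only in MD (ventricle vs tissue, >= 5 sigma apart with
    identical FA and EV models); slabs 2|3 only in FA (gray vs white);
    slabs 3|4 and 4|5 only in eigenvector orientation (diffuse vs x-tract
    vs z-tract).  FA-only likelihoods therefore cannot separate the two
    tracts and MD-only cannot separate anything except the ventricle.
    """
    shape = (36, 36, 36)
    gray_fa = ChannelMixture((1.0,), (0.15,), (0.03,))
    white_fa = ChannelMixture((1.0,), (0.50,), (0.03,))
    slabs = []
    defs = [
        (1, "ventricle", gray_fa, _CSF_MD, (1.0, 1.0, 1.0), 1.0),
        (2, "gray", gray_fa, _TISSUE_MD, (1.0, 1.0, 1.0), 1.0),
        (3, "white-diffuse", white_fa, _TISSUE_MD, (1.0, 1.0, 1.0), 1.0),
        (4, "tract-x", white_fa, _TISSUE_MD, (1.0, 0.0, 0.0), 0.10),
        (5, "tract-z", white_fa, _TISSUE_MD, (0.0, 0.0, 1.0), 0.10),
    ]
    x0 = 5.0
    thickness = 5.2
    for i, (label, name, fa, md, axis, sig) in enumerate(defs):
        lo = x0 + i * thickness
        slabs.append(
            StructureDef(
                label, name,
                {"kind": "box", "lo": (lo, 7.0, 7.0), "hi": (lo + thickness, 29.0, 29.0)},
                fa=fa, md=md, ev_axis=axis, ev_sigma=sig,
            )
        )
    return PhantomSpec(
        shape=shape, spacing=(2.5, 2.5, 2.5), structures=slabs,
        deform_magnitude=2.0, deform_smoothness_mm=10.0, seed=seed,
    )
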