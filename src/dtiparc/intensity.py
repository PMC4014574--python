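"""Per-structure per-channel Gaussian-mixture intensity signatures.

Each anatomical structure in each atlas is summarised, channel by channel,
by a 1-D Gaussian mixture fitted with a deterministic seeded EM.  The
multi-contrast voxel likelihood is the product of the per-channel mixture
densities, assuming conditional independence across contrasts; restricting
the channel mask reproduces the single-contrast ablations (FA-only,
MD-only, EV-only).

A structure whose intensity in some channel is broad and unstructured is
fitted by a wide, multi-component mixture whose density is nearly flat
over the observed range — that channel then contributes almost nothing to
likelihood ratios between structures, which is exactly the behaviour
wanted for, e.g., fiber-orientation channels inside gray matter.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .volumes import CHANNEL_NAMES, LabelMap, MultiContrastImage

log = logging.getLogger(__name__)

#: hard floor applied to per-channel densities before taking products
DENSITY_FLOOR = 1e-300
LOG_DENSITY_FLOOR = np.log(DENSITY_FLOOR)

#: components with weight below this are pruned and weights renormalized
MIN_COMPONENT_WEIGHT = 1e-4

#: relative variance floor (fraction of the sample variance); guards EM
#: against singular components without flattening low-variance channels
VAR_FLOOR_REL = 1e-6
VAR_FLOOR_ABS = 1e-12


def component_count_rule(
    volume_mm3: float,
    k_small: int = 2,
    k_large: int = 3,
    cutoff_mm3: float = 1000.0,
) -> int:
    """Size-dependent mixture order: ``k_small`` below the cutoff volume,
    ``k_large`` at or above it (default cutoff 1000 mm³)."""
    if volume_mm3 < 0:
        raise ValueError("volume must be non-negative")
    if k_small < 1 or k_large < 1:
        raise ValueError("component counts must be >= 1")
    return k_small if volume_mm3 < cutoff_mm3 else k_large


@dataclasses.dataclass
class GaussianMixture1D:
    """A 1-D Gaussian mixture: weights, means and variances per component.

    Weights sum to 1 and are non-negative; variances are floored.  This is
    the intensity signature of one (atlas, structure, channel) triple.
    """

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=np.float64))
        self.means = np.atleast_1d(np.asarray(self.means, dtype=np.float64))
        self.variances = np.atleast_1d(np.asarray(self.variances, dtype=np.float64))
        k = self.weights.size
        if not (self.means.size == k and self.variances.size == k and k >= 1):
            raise ValueError("weights, means, variances must have equal length >= 1")
        if np.any(self.weights < -1e-12):
            raise ValueError("negative mixture weight")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be positive")

    @property
    def n_components(self) -> int:
        return self.weights.size

    def log_pdf(self, x: np.ndarray | float) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        z = (x[..., None] - self.means) ** 2 / self.variances
        comp = (
            np.log(np.maximum(self.weights, 1e-300))
            - 0.5 * np.log(2.0 * np.pi * self.variances)
            - 0.5 * z
        )
        return logsumexp(comp, axis=-1)

    def pdf(self, x: np.ndarray | float) -> np.ndarray:
        return np.exp(self.log_pdf(x))

    def log_likelihood(self, x: np.ndarray) -> float:
        return float(self.log_pdf(np.asarray(x)).sum())


def _kmeanspp_centers(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    centers = [x[rng.integers(x.size)]]
    for _ in range(1, k):
        d2 = np.min((x[:, None] - np.asarray(centers)[None, :]) ** 2, axis=1)
        total = d2.sum()
        if total <= 0:
            centers.append(x[rng.integers(x.size)])
        else:
            centers.append(x[rng.choice(x.size, p=d2 / total)])
    return np.asarray(centers)


def fit_gmm(
    samples: Sequence[float] | np.ndarray,
    n_components: int,
    seed: int = 0,
    tol: float = 1e-7,
    max_iter: int = 500,
) -> GaussianMixture1D:
    """Maximum-likelihood EM fit of a 1-D Gaussian mixture.

    Initialisation is k-means++-style seeding from ``seed``; the per-sample
    mean log-likelihood is asserted non-decreasing across EM iterations and
    the fit stops when its gain drops below ``tol`` or after ``max_iter``
    iterations.  Components whose weight falls below 1e-4 are pruned and
    the weights renormalized, which realises the weight-1 collapse on
    homogeneous data.  Fewer samples than components reduces the order with
    a warning; zero-variance samples give a single floored point mass.
    """
    x = np.asarray(samples, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("cannot fit a mixture to zero samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("samples must be finite")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    k = int(n_components)
    if x.size < k:
        log.warning("only %d samples for K=%d; reducing K", x.size, k)
        k = x.size

    sample_var = float(x.var())
    var_floor = max(VAR_FLOOR_ABS, VAR_FLOOR_REL * sample_var)
    if sample_var <= 0:
        return GaussianMixture1D([1.0], [float(x[0])], [var_floor])

    rng = np.random.default_rng(seed)
    centers = _kmeanspp_centers(x, k, rng)
    assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
    weights = np.empty(k)
    means = np.empty(k)
    variances = np.empty(k)
    for j in range(k):
        sel = assign == j
        if not sel.any():
            weights[j] = 1.0 / x.size
            means[j] = centers[j]
            variances[j] = sample_var
        else:
            weights[j] = sel.sum() / x.size
            means[j] = x[sel].mean()
            variances[j] = max(x[sel].var(), var_floor)
    weights = weights / weights.sum()

    prev_ll = -np.inf
    pruned = False
    for _ in range(max_iter):
        # E-step in log space
        log_comp = (
            np.log(np.maximum(weights, 1e-300))
            - 0.5 * np.log(2.0 * np.pi * variances)
            - 0.5 * (x[:, None] - means) ** 2 / variances
        )
        log_norm = logsumexp(log_comp, axis=1)
        ll = float(log_norm.mean())
        if not pruned and ll < prev_ll - 1e-10 * max(1.0, abs(prev_ll)):
            raise AssertionError(f"EM log-likelihood decreased: {prev_ll} -> {ll}")
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            prev_ll = ll
            break
        prev_ll = ll
        pruned = False
        resp = np.exp(log_comp - log_norm[:, None])
        # M-step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        weights = nk / x.size
        means = (resp * x[:, None]).sum(axis=0) / nk
        variances = (resp * (x[:, None] - means) ** 2).sum(axis=0) / nk
        variances = np.maximum(variances, var_floor)
        if weights.size > 1 and np.any(weights < MIN_COMPONENT_WEIGHT):
            keep = weights >= MIN_COMPONENT_WEIGHT
            if not keep.any():
                keep[np.argmax(weights)] = True
            weights, means, variances = weights[keep], means[keep], variances[keep]
            weights = weights / weights.sum()
            pruned = True

    weights = weights / weights.sum()
    return GaussianMixture1D(weights, means, variances)


def gmm_density(model: GaussianMixture1D, value: float | np.ndarray) -> np.ndarray | float:
    """Mixture density at ``value`` (weighted sum of Gaussian densities)."""
    out = model.pdf(value)
    return float(out) if np.isscalar(value) or np.asarray(value).ndim == 0 else out


# -- atlas signatures --------------------------------------------------------


@dataclasses.dataclass
class AtlasSignature:
    """All per-structure per-channel mixtures of one atlas.

    ``models[s]`` is a 5-tuple of :class:`GaussianMixture1D` in canonical
    channel order (fa, md, evx, evy, evz); ``structure_volumes`` holds the
    atlas structure volumes in mm³ (background stored under 0).
    """

    models: dict[int, tuple[GaussianMixture1D, ...]]
    structure_volumes: dict[int, float]
    atlas_id: str = ""

    @property
    def structures(self) -> tuple[int, ...]:
        return tuple(sorted(self.models))

    def has(self, structure: int) -> bool:
        return structure in self.models

    def channel_model(self, structure: int, channel: int) -> GaussianMixture1D:
        return self.models[structure][channel]


def fit_atlas_signature(
    image: MultiContrastImage,
    labels: LabelMap,
    k_small: int = 2,
    k_large: int = 3,
    cutoff_mm3: float = 1000.0,
    seed: int = 0,
    include_background: bool = True,
    max_samples: int = 10000,
    atlas_id: str = "",
) -> AtlasSignature:
    """Fit the intensity signature of one atlas-label pair.

    The mixture order per structure follows :func:`component_count_rule`
    on the structure volume.  Structures larger than ``max_samples`` voxels
    are subsampled with the seeded generator for speed; the background
    (label 0) is fitted like any other label when ``include_background``
    so it can compete in the fusion posterior.
    """
    if not labels.same_grid(image.fa):
        raise ValueError("label and image grids differ")
    rng = np.random.default_rng(seed)
    voxvol = labels.voxel_volume_mm3
    structure_ids = list(labels.label_set)
    if include_background:
        structure_ids = [0] + structure_ids
    models: dict[int, tuple[GaussianMixture1D, ...]] = {}
    volumes: dict[int, float] = {}
    stacked = image.stacked()
    for s in structure_ids:
        sel = labels.data == s
        n = int(sel.sum())
        if n == 0:
            continue
        volumes[s] = n * voxvol
        k = component_count_rule(volumes[s], k_small, k_large, cutoff_mm3)
        idx = np.flatnonzero(sel.ravel())
        if idx.size > max_samples:
            idx = rng.choice(idx, size=max_samples, replace=False)
        per_channel = []
        for c in range(5):
            samples = stacked[c].ravel()[idx]
            per_channel.append(fit_gmm(samples, k, seed=seed + 13 * s + c))
        models[s] = tuple(per_channel)
    return AtlasSignature(models, volumes, atlas_id=atlas_id)


def voxel_likelihood(
    intensity: Sequence[float] | np.ndarray,
    structure: int,
    signature: AtlasSignature,
    channel_mask: Iterable[int] | None = None,
) -> float:
    """Product of per-channel mixture densities for one voxel.

    ``channel_mask`` selects the contrasts used (default all 5); a
    structure missing from the signature yields zero likelihood with a
    warning.
    """
    mask = tuple(channel_mask) if channel_mask is not None else tuple(range(5))
    if not mask:
        raise ValueError("channel_mask must be non-empty")
    if not signature.has(structure):
        log.warning("structure %d missing from signature; zero likelihood", structure)
        return 0.0
    vec = np.asarray(intensity, dtype=np.float64)
    logp = 0.0
    for c in mask:
        logp += float(signature.channel_model(structure, c).log_pdf(vec[c]))
    return float(np.exp(max(logp, LOG_DENSITY_FLOOR)))


def log_likelihood_volume(
    image: MultiContrastImage,
    structure: int,
    signature: AtlasSignature,
    channel_mask: Iterable[int] | None = None,
) -> np.ndarray:
    """Voxelwise log-likelihood of the whole image under one structure model."""
    mask = tuple(channel_mask) if channel_mask is not None else tuple(range(5))
    if not mask:
        raise ValueError("channel_mask must be non-empty")
    if not signature.has(structure):
        log.warning("structure %d missing from signature; floored likelihood", structure)
        return np.full(image.shape, LOG_DENSITY_FLOOR)
    logp = np.zeros(image.shape, dtype=np.float64)
    for c in mask:
        logp += signature.channel_model(structure, c).log_pdf(image.channel(c).data)
    return np.maximum(logp, LOG_DENSITY_FLOOR)


# -- JSON serialization ------------------------------------------------------


def signatures_to_json(signatures: Sequence[AtlasSignature], path: str | Path) -> None:
    """Write signatures as ``{atlas: {structure: {channel: {...}}}}`` JSON."""
    doc = {}
    for i, sig in enumerate(signatures):
        key = sig.atlas_id or str(i)
        entry: dict = {"structure_volumes": {str(s): v for s, v in sig.structure_volumes.items()}}
        for s, chans in sig.models.items():
            entry[str(s)] = {
                CHANNEL_NAMES[c]: {
                    "K": m.n_components,
                    "weights": m.weights.tolist(),
                    "means": m.means.tolist(),
                    "variances": m.variances.tolist(),
                }
                for c, m in enumerate(chans)
            }
        doc[key] = entry
    Path(path).write_text(json.dumps(doc, indent=1))


def signatures_from_json(path: str | Path) -> list[AtlasSignature]:
    doc = json.loads(Path(path).read_text())
    out = []
    for key, entry in doc.items():
        volumes = {int(s): float(v) for s, v in entry.pop("structure_volumes").items()}
        models = {}
        for s, chans in entry.items():
            models[int(s)] = tuple(
                GaussianMixture1D(
                    chans[name]["weights"], chans[name]["means"], chans[name]["variances"]
                )
                for name in CHANNEL_NAMES
            )
        out.append(AtlasSignature(models, volumes, atlas_id=key))
    return out
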