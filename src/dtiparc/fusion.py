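"""Multi-contrast multi-atlas likelihood fusion (EM/MAP loop).

The parcellation of a subject image I is posed as MAP estimation of the
label field W given I, with the atlas-label pair used to interpret each
voxel treated as a latent variable.  The loop alternates:

1. *selector* (E-step): the posterior weight of each atlas at each voxel,
   proportional to the product of (a) the atlas's multi-contrast mixture
   likelihood of the subject intensity under the voxel's current label,
   (b) a structure-constant Dice term between the current structure and
   the deformed atlas structure (a computable surrogate for the label
   likelihood), (c) the deformation-magnitude prior of the atlas's global
   registration, and (d) the Gaussian prior density of the structure's
   local affine — normalized over atlases per voxel;
2. *parcellation* (M-step): per voxel, the new label maximises the sum
   over atlases of selector x intensity likelihood x trilinearly
   interpolated deformed-atlas label probability, over all labels with
   atlas support (background included); ties break to the smallest label;
3. *transforms*: each (atlas, structure) local affine is re-optimised
   against the new parcellation.

Iteration stops when the changed-voxel fraction drops below the stop
tolerance or after 30 iterations (the cap).  With all intensity models
identical the update provably reduces to trilinear-probability-weighted
majority voting; with the subject as its own single atlas under identity
registration, its own labels are a fixpoint.

The statsmodels-style surface is :class:`MultiAtlasFusion` (model) whose
``fit()`` returns :class:`FusionResults`.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intensity import (
    AtlasSignature,
    LOG_DENSITY_FLOOR,
    fit_atlas_signature,
    log_likelihood_volume,
)
from .phantom import AtlasPair
from .registration import (
    AffinePrior,
    AffineTransform12,
    DeformationField,
    _grid_points,
    compose_and_resample,
    compose_transform_points,
    diffeo_weights,
    optimize_local_affine,
    register_two_channel,
)
from .volumes import LabelMap, MultiContrastImage

log = logging.getLogger(__name__)


@dataclasses.dataclass
class FusionConfig:
    """Tunable parameters of the fusion loop.

    ``init_atlas`` is either "vote" (majority vote of all propagated
    atlases, the symmetric default) or the index of a designated atlas
    whose propagated labels initialise the parcellation.
    ``channel_mask`` restricts the contrasts used in the intensity
    likelihood (the single-contrast ablations).
    """

    max_iterations: int = 30
    stop_tolerance: float = 1e-4
    channel_mask: tuple[int, ...] = (0, 1, 2, 3, 4)
    init_atlas: int | str = "vote"
    optimize_affines: bool = True
    affine_prior: AffinePrior = dataclasses.field(default_factory=AffinePrior)
    dice_floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not self.channel_mask:
            raise ValueError("channel_mask must be non-empty")
        if isinstance(self.init_atlas, str) and self.init_atlas != "vote":
            raise ValueError("init_atlas must be 'vote' or an atlas index")


@dataclasses.dataclass
class FusionState:
    """Mutable state of the EM loop."""

    parcellation: LabelMap
    labels_all: tuple[int, ...]  # sorted, background first
    affines: dict[tuple[int, int], AffineTransform12]
    label_priors: np.ndarray  # (A, L, nx, ny, nz)
    selector: np.ndarray  # (A, nx, ny, nz)
    structure_dice: np.ndarray  # (A, L)
    iteration: int = 0
    history: list[dict] = dataclasses.field(default_factory=list)
    diverged: bool = False
    cycled: bool = False
    # per (atlas, structure): hash of the target structure mask the local
    # affine was last optimised against; lets Step 4 skip structures whose
    # parcellation did not change (the optimisation is deterministic)
    _opt_target_hash: dict = dataclasses.field(default_factory=dict)

    @property
    def n_atlases(self) -> int:
        return self.label_priors.shape[0]

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.history)


# -- building blocks ---------------------------------------------------------


def propagate_labels(atlas: AtlasPair, field: DeformationField) -> LabelMap:
    """Nearest-neighbour pull-back of the atlas labels onto the subject grid."""
    return compose_and_resample(field, None, atlas.labels, mode="nearest")


def majority_vote(propagated: Sequence[LabelMap], labels_all: Sequence[int]) -> LabelMap:
    """Per-voxel majority label; ties break to the smallest label index."""
    ref = propagated[0]
    counts = np.zeros((len(labels_all),) + ref.shape, dtype=np.int32)
    for p in propagated:
        for j, lab in enumerate(labels_all):
            counts[j] += p.data == lab
    idx = counts.argmax(axis=0)  # first (smallest label) wins ties
    labels_arr = np.asarray(labels_all, dtype=np.int32)[idx]
    return ref.like(labels_arr)


def label_prior_cube(
    atlases: Sequence[AtlasPair],
    fields: Sequence[DeformationField],
    affines: dict[tuple[int, int], AffineTransform12],
    labels_all: Sequence[int],
    shape: tuple[int, int, int],
) -> np.ndarray:
    """Trilinear deformed-atlas label probabilities, shape (A, L, *grid).

    Per (atlas a, label l), the indicator of l in atlas a is sampled at
    the composed transform of that structure (its local affine followed by
    the atlas's global field).  Outside the atlas grid the probability
    mass belongs to the background.
    """
    from scipy.ndimage import map_coordinates

    A, L = len(atlases), len(labels_all)
    out = np.zeros((A, L) + tuple(shape), dtype=np.float64)
    base_pts = _grid_points(shape).reshape(3, -1).T
    for a, (atlas, field) in enumerate(zip(atlases, fields)):
        cache: dict[tuple, np.ndarray] = {}
        for j, lab in enumerate(labels_all):
            aff = affines.get((a, lab))
            key = tuple(aff.params) + tuple(aff.center) if aff is not None else ()
            if key not in cache:
                cache[key] = compose_transform_points(field, aff, base_pts).T
            mapped = cache[key]
            ind = (atlas.labels.data == lab).astype(np.float64)
            cval = 1.0 if lab == 0 else 0.0
            vals = map_coordinates(ind, mapped, order=1, mode="constant", cval=cval)
            out[a, j] = vals.reshape(shape)
    return out


def compute_likelihood_cube(
    subject: MultiContrastImage,
    signatures: Sequence[AtlasSignature],
    labels_all: Sequence[int],
    channel_mask: Iterable[int],
) -> np.ndarray:
    """Voxelwise intensity likelihood per (atlas, label), floored in log
    space and exponentiated; shape (A, L, *grid)."""
    mask = tuple(channel_mask)
    A, L = len(signatures), len(labels_all)
    out = np.empty((A, L) + subject.shape, dtype=np.float64)
    for a, sig in enumerate(signatures):
        for j, lab in enumerate(labels_all):
            out[a, j] = np.exp(log_likelihood_volume(subject, lab, sig, mask))
    return out


def structure_dice_factors(
    parcellation: LabelMap,
    label_priors: np.ndarray,
    labels_all: Sequence[int],
    floor: float = 1e-6,
) -> np.ndarray:
    """Dice between each current structure and each atlas's deformed
    structure (prior mass >= 0.5), floored; shape (A, L)."""
    A, L = label_priors.shape[:2]
    out = np.empty((A, L))
    for j, lab in enumerate(labels_all):
        cur = parcellation.data == lab
        ncur = int(cur.sum())
        for a in range(A):
            dm = label_priors[a, j] >= 0.5
            ndm = int(dm.sum())
            if ncur == 0 and ndm == 0:
                out[a, j] = 1.0
            else:
                out[a, j] = 2.0 * int((cur & dm).sum()) / max(ncur + ndm, 1)
    return np.maximum(out, floor)


# -- the EM steps ------------------------------------------------------------


def initialize(
    atlases: Sequence[AtlasPair],
    subject: MultiContrastImage,
    fields: Sequence[DeformationField],
    cfg: FusionConfig,
) -> FusionState:
    """Step 1: identity local affines; initial parcellation from label
    propagation (single designated atlas or majority vote)."""
    if not atlases:
        raise ValueError("empty atlas list")
    if len(fields) != len(atlases):
        raise ValueError("one deformation field per atlas required")
    for f in fields:
        if f.shape != subject.shape:
            raise ValueError("fields must live on the subject grid")
    labels_all: tuple[int, ...] = tuple(
        sorted({0} | {lab for a in atlases for lab in a.labels.label_set})
    )
    propagated = [propagate_labels(a, f) for a, f in zip(atlases, fields)]
    if cfg.init_atlas == "vote":
        parc = majority_vote(propagated, labels_all)
    else:
        idx = int(cfg.init_atlas)
        if not 0 <= idx < len(atlases):
            raise ValueError(f"init_atlas index {idx} out of range")
        parc = propagated[idx]
    affines: dict[tuple[int, int], AffineTransform12] = {}
    priors = label_prior_cube(atlases, fields, affines, labels_all, subject.shape)
    A = len(atlases)
    selector = np.full((A,) + subject.shape, 1.0 / A)
    dice = structure_dice_factors(parc, priors, labels_all, cfg.dice_floor)
    return FusionState(parc, labels_all, affines, priors, selector, dice)


def compute_selector(
    state: FusionState,
    lik_cube: np.ndarray,
    diffeo_w: np.ndarray,
    cfg: FusionConfig,
) -> np.ndarray:
    """Step 2: per-voxel posterior weight of each atlas under the current
    parcellation, normalized over atlases.

    The intensity factor varies voxelwise; the Dice, deformation-prior and
    affine-prior factors are constant within a structure.  Voxels where
    every atlas underflows fall back to uniform weights (count logged).
    """
    A = state.n_atlases
    labels_arr = np.asarray(state.labels_all)
    j_map = np.searchsorted(labels_arr, state.parcellation.data)
    shape = state.parcellation.shape
    n = int(np.prod(shape))
    jf = j_map.ravel()
    cols = np.arange(n)

    affine_logp = np.zeros((A, len(labels_arr)))
    for (a, lab), aff in state.affines.items():
        j = int(np.searchsorted(labels_arr, lab))
        affine_logp[a, j] = cfg.affine_prior.log_density(aff.params)

    logw = np.empty((A, n))
    log_dice = np.log(state.structure_dice)
    log_diffeo = np.log(np.maximum(diffeo_w, 1e-300))
    for a in range(A):
        lik = lik_cube[a].reshape(len(labels_arr), n)[jf, cols]
        logw[a] = (
            np.log(np.maximum(lik, 1e-300))
            + log_dice[a][jf]
            + affine_logp[a][jf]
            + log_diffeo[a]
        )
    m = logw.max(axis=0)
    bad = ~np.isfinite(m)
    w = np.exp(logw - np.where(bad, 0.0, m))
    total = w.sum(axis=0)
    degenerate = bad | (total <= 0)
    if degenerate.any():
        log.info("%d voxels with degenerate selector; uniform fallback", int(degenerate.sum()))
        w[:, degenerate] = 1.0
        total = w.sum(axis=0)
    w = w / total
    return w.reshape((A,) + shape)


def update_parcellation(
    state: FusionState,
    lik_cube: np.ndarray,
    cfg: FusionConfig,
) -> tuple[LabelMap, np.ndarray]:
    """Step 3: per-voxel argmax of the fused posterior score.

    score(l, x) = sum_a selector(a, x) * likelihood(a, l, x) * prior(a, l, x)

    Candidates are the labels with nonzero interpolated probability at x
    under any atlas; ties break to the smallest label.  Returns the new
    label map and the per-voxel winning score.
    """
    A, L = state.label_priors.shape[:2]
    shape = state.parcellation.shape
    sel = state.selector
    scores = np.zeros((L,) + shape)
    for j in range(L):
        scores[j] = (sel * lik_cube[:, j] * state.label_priors[:, j]).sum(axis=0)
    candidate = (state.label_priors > 0).any(axis=0)  # (L, *shape)
    scores = np.where(candidate, scores, -1.0)
    winner_j = scores.argmax(axis=0)  # first max -> smallest label
    best = np.take_along_axis(scores, winner_j[None], axis=0)[0]
    labels_arr = np.asarray(state.labels_all, dtype=np.int32)
    return state.parcellation.like(labels_arr[winner_j]), best


def update_transforms(
    state: FusionState,
    atlases: Sequence[AtlasPair],
    fields: Sequence[DeformationField],
    cfg: FusionConfig,
) -> None:
    """Step 4: re-optimise every (atlas, structure) local affine against
    the new parcellation and refresh cached priors and Dice factors.

    Structures whose parcellation mask is unchanged since their last
    optimisation are skipped — the search is deterministic in its inputs,
    so the cached transform is exact, not approximate.
    """
    import hashlib

    changed: list[tuple[int, int]] = []
    for lab in state.labels_all:
        if lab == 0:
            continue  # background keeps the global field alone
        mask_hash = hashlib.sha1(
            np.ascontiguousarray(state.parcellation.data == lab)
        ).digest()
        for a, (atlas, field) in enumerate(zip(atlases, fields)):
            if state._opt_target_hash.get((a, lab)) == mask_hash:
                continue
            old = state.affines.get((a, lab))
            new = optimize_local_affine(
                lab, atlas.labels, field, state.parcellation, cfg.affine_prior
            )
            state.affines[(a, lab)] = new
            state._opt_target_hash[(a, lab)] = mask_hash
            if old is None:
                if not new.is_identity:
                    changed.append((a, lab))
            elif not (
                np.array_equal(old.params, new.params)
                and np.array_equal(old.center, new.center)
            ):
                changed.append((a, lab))
    # refresh only the prior slices whose transform actually changed
    if changed:
        from scipy.ndimage import map_coordinates

        labels_arr = list(state.labels_all)
        shape = state.parcellation.shape
        base_pts = _grid_points(shape).reshape(3, -1).T
        for a, lab in changed:
            j = labels_arr.index(lab)
            mapped = compose_transform_points(
                fields[a], state.affines.get((a, lab)), base_pts
            ).T
            ind = (atlases[a].labels.data == lab).astype(np.float64)
            state.label_priors[a, j] = map_coordinates(
                ind, mapped, order=1, mode="constant", cval=0.0
            ).reshape(shape)
    state.structure_dice = structure_dice_factors(
        state.parcellation, state.label_priors, state.labels_all, cfg.dice_floor
    )


def run(
    atlases: Sequence[AtlasPair],
    subject: MultiContrastImage,
    signatures: Sequence[AtlasSignature],
    fields: Sequence[DeformationField],
    cfg: FusionConfig | None = None,
    verbose: bool = False,
) -> tuple[LabelMap, FusionState]:
    """The full EM loop (Steps 2-5 repeated from the Step-1 initialisation).

    Stops when the changed-voxel fraction drops below
    ``cfg.stop_tolerance`` or after ``cfg.max_iterations`` iterations; a
    changed-voxel fraction that increases for 5 consecutive iterations
    sets the ``diverged`` flag and stops.  The logged surrogate objective
    is the per-voxel log of the winning fused score, summed over voxels.
    """
    cfg = cfg if cfg is not None else FusionConfig()
    if len(signatures) != len(atlases):
        raise ValueError("one signature per atlas required")
    import hashlib

    state = initialize(atlases, subject, fields, cfg)
    lik_cube = compute_likelihood_cube(subject, signatures, state.labels_all, cfg.channel_mask)
    diffeo_w = diffeo_weights(fields)
    n_vox = float(np.prod(subject.shape))
    n_increasing = 0
    prev_changed = np.inf
    seen_states: set[bytes] = set()
    for it in range(1, cfg.max_iterations + 1):
        t0 = time.time()
        state.selector = compute_selector(state, lik_cube, diffeo_w, cfg)
        new_parc, best_scores = update_parcellation(state, lik_cube, cfg)
        changed = float((new_parc.data != state.parcellation.data).sum()) / n_vox
        objective = float(np.log(np.maximum(best_scores, 1e-300)).sum())
        state.parcellation = new_parc
        state.iteration = it
        state.history.append(
            {
                "iteration": it,
                "changed_fraction": changed,
                "objective": objective,
                "seconds": time.time() - t0,
            }
        )
        if verbose:
            log.info(
                "iter %d: changed %.5f, objective %.2f", it, changed, objective
            )
        if changed < cfg.stop_tolerance:
            break
        digest = hashlib.sha1(np.ascontiguousarray(new_parc.data)).digest()
        if digest in seen_states:
            # deterministic loop revisiting a previous parcellation: a
            # limit cycle that would repeat until the iteration cap
            state.cycled = True
            log.info("parcellation cycle detected at iteration %d; stopping", it)
            break
        seen_states.add(digest)
        if changed > prev_changed:
            n_increasing += 1
            if n_increasing >= 5:
                state.diverged = True
                log.warning("changed-voxel fraction increased 5 times in a row; stopping")
                break
        else:
            n_increasing = 0
        prev_changed = changed
        if it < cfg.max_iterations and cfg.optimize_affines:
            update_transforms(state, atlases, fields, cfg)
            state.structure_dice = np.maximum(state.structure_dice, cfg.dice_floor)
    return state.parcellation, state


# -- model / results surface -------------------------------------------------


class MultiAtlasFusion:
    """Multi-contrast multi-atlas likelihood-fusion model for one subject.

    Parameters
    ----------
    subject : MultiContrastImage
        The 5-channel image to parcellate.
    atlases : sequence of AtlasPair
        The atlas library (image + labels on commensurate grids).
    config : FusionConfig, optional
    fields : sequence of DeformationField, optional
        Pre-computed atlas-to-subject registrations; computed from the
        FA and MD channels when omitted.
    signatures : sequence of AtlasSignature, optional
        Pre-fitted intensity signatures; fitted from the atlases when
        omitted.

    Examples
    --------
    >>> model = MultiAtlasFusion(subject, atlases)      # doctest: +SKIP
    >>> res = model.fit()                               # doctest: +SKIP
    >>> print(res.summary())                            # doctest: +SKIP
    """

    def __init__(
        self,
        subject: MultiContrastImage,
        atlases: Sequence[AtlasPair],
        config: FusionConfig | None = None,
        fields: Sequence[DeformationField] | None = None,
        signatures: Sequence[AtlasSignature] | None = None,
        seed: int = 0,
    ) -> None:
        if not atlases:
            raise ValueError("empty atlas list")
        self.subject = subject
        self.atlases = list(atlases)
        self.config = config if config is not None else FusionConfig()
        self.fields = list(fields) if fields is not None else None
        self.signatures = list(signatures) if signatures is not None else None
        self.seed = int(seed)

    @classmethod
    def from_directory(
        cls,
        subject_stem: str,
        atlas_dir: str,
        config: FusionConfig | None = None,
        seed: int = 0,
    ) -> "MultiAtlasFusion":
        """Build a model from NIfTI files on disk.

        ``atlas_dir`` must contain, per atlas stem, the five channel files
        and a ``<stem>_labels`` volume.
        """
        from pathlib import Path

        from .volumes import read_labelmap, read_multicontrast

        subject = read_multicontrast(subject_stem)
        adir = Path(atlas_dir)
        stems = sorted(
            {p.name.rsplit("_labels", 1)[0] for p in adir.glob("*_labels.nii*")}
        )
        if not stems:
            raise FileNotFoundError(f"no atlas label volumes in {atlas_dir}")
        atlases = [
            AtlasPair(
                read_multicontrast(adir / s),
                read_labelmap(adir / (s + "_labels.nii.gz")),
                name=s,
            )
            for s in stems
        ]
        return cls(subject, atlases, config=config, seed=seed)

    def register(self, verbose: bool = False) -> list[DeformationField]:
        """Two-channel (FA, MD) global registration of each atlas."""
        fields = []
        for a in self.atlases:
            if verbose:
                log.info("registering atlas %s", a.name)
            fields.append(
                register_two_channel(
                    [a.image.fa, a.image.md], [self.subject.fa, self.subject.md]
                )
            )
        self.fields = fields
        return fields

    def fit_signatures(self) -> list[AtlasSignature]:
        sigs = [
            fit_atlas_signature(
                a.image, a.labels, seed=self.seed + 17 * i, atlas_id=a.name or str(i)
            )
            for i, a in enumerate(self.atlases)
        ]
        self.signatures = sigs
        return sigs

    def fit(self, verbose: bool = False) -> "FusionResults":
        """Register (if needed), fit signatures (if needed), run the EM
        loop, and package the results."""
        if self.fields is None:
            self.register(verbose=verbose)
        if self.signatures is None:
            self.fit_signatures()
        labels, state = run(
            self.atlases, self.subject, self.signatures, self.fields, self.config,
            verbose=verbose,
        )
        return FusionResults(self, labels, state)


class FusionResults:
    """Fitted parcellation plus diagnostics.

    Attributes
    ----------
    labels : LabelMap
        The fused parcellation.
    state : FusionState
        Final EM state (selector, affines, Dice factors, history).
    """

    def __init__(self, model: MultiAtlasFusion, labels: LabelMap, state: FusionState) -> None:
        self.model = model
        self.labels = labels
        self.state = state

    @property
    def history(self) -> pd.DataFrame:
        return self.state.history_frame()

    @property
    def n_iterations(self) -> int:
        return self.state.iteration

    @property
    def converged(self) -> bool:
        if not self.state.history:
            return False
        return (
            self.state.history[-1]["changed_fraction"] < self.model.config.stop_tolerance
            and not self.state.diverged
        )

    def roi_stats(self, exclude: Iterable[int] = ()) -> pd.DataFrame:
        from .quantify import roi_stats

        return roi_stats(self.labels, self.model.subject, exclude=exclude)

    def dice_vs(self, reference: LabelMap) -> pd.DataFrame:
        """Per-structure Dice against a reference parcellation."""
        from .quantify import dice

        rows = []
        for lab in sorted(set(self.labels.label_set) | set(reference.label_set)):
            rows.append(
                {"structure": lab, "dice": dice(self.labels.mask(lab), reference.mask(lab))}
            )
        return pd.DataFrame(rows).set_index("structure")

    def summary(self) -> str:
        """Human-readable report: convergence, iteration log, ROI table."""
        lines = [
            "Multi-contrast multi-atlas likelihood fusion",
            "=" * 52,
            f"atlases:            {len(self.model.atlases)}",
            f"structures:         {len(self.labels.label_set)}",
            f"channel mask:       {self.model.config.channel_mask}",
            f"iterations:         {self.n_iterations} (cap {self.model.config.max_iterations})",
            f"converged:          {self.converged}",
        ]
        if self.state.history:
            lines.append("")
            lines.append("iter  changed_fraction      objective")
            for h in self.state.history:
                lines.append(
                    f"{h['iteration']:>4d}  {h['changed_fraction']:>16.6f}  {h['objective']:>13.1f}"
                )
        stats = self.roi_stats()
        lines.append("")
        lines.append(stats.to_string())
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Changed-voxel fraction and objective per iteration (matplotlib)."""
        import matplotlib.pyplot as plt

        h = self.history
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(h["iteration"], h["changed_fraction"], "o-", label="changed fraction")
        ax.set_xlabel("iteration")
        ax.set_ylabel("changed-voxel fraction")
        ax2 = ax.twinx()
        ax2.plot(h["iteration"], h["objective"], "s--", color="tab:red", label="objective")
        ax2.set_ylabel("surrogate objective")
        return ax

    def save(self, stem: str) -> None:
        from .volumes import write_labelmap

        write_labelmap(self.labels, stem)
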