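"""Grid-aware volume containers, NIfTI I/O and interpolation primitives.

The whole pipeline works on three containers:

``ScalarVolume``
    one real-valued 3-D image on a regular grid with voxel spacing in mm
    and a grid-to-world affine,

``MultiContrastImage``
    the 5-channel DTI feature field (FA, MD in mm²/s, and the absolute
    components of the primary eigenvector) sharing one grid,

``LabelMap``
    an integer parcellation with label 0 reserved for the unlabeled
    background.

Coordinate convention: voxel-centred, 0-based indices.  Spatial transforms
throughout the package map *subject* voxel coordinates to *atlas* voxel
coordinates (pull-back / resampling convention).  Outside the grid, label
probability mass belongs to the background (label 0) and channel
intensities fill with 0.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

log = logging.getLogger(__name__)

#: canonical channel order of a MultiContrastImage
CHANNEL_NAMES: tuple[str, ...] = ("fa", "md", "evx", "evy", "evz")

#: file-name suffix per channel, e.g. ``subject01_fa.nii.gz``
CHANNEL_SUFFIXES: dict[str, str] = {c: f"_{c}" for c in CHANNEL_NAMES}
LABEL_SUFFIX = "_labels"


class GridMismatchError(ValueError):
    """Raised when volumes expected to share a grid do not."""


def _default_affine(spacing: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclasses.dataclass
class ScalarVolume:
    """A real-valued image on a regular 3-D grid.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values.
    spacing : tuple of float
        Voxel size per axis in mm; strictly positive.
    affine : ndarray (4, 4), optional
        Grid-to-world map.  Defaults to ``diag(spacing)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3-D data, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "ScalarVolume | LabelMap") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.affine, other.affine)
        )

    def like(self, data: np.ndarray) -> "ScalarVolume":
        """New volume with the same grid geometry but different data."""
        return ScalarVolume(data, self.spacing, self.affine.copy())

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.float64), self.affine)
        img.header.set_zooms(self.spacing)
        nib.save(img, str(path))

    @classmethod
    def load(cls, path: str | Path) -> "ScalarVolume":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(str(path))
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        if data.ndim == 4 and data.shape[3] == 1:
            data = data[..., 0]
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(data, spacing, np.asarray(img.affine))


@dataclasses.dataclass
class LabelMap:
    """Integer parcellation volume; 0 is unlabeled background."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if not np.issubdtype(arr.dtype, np.integer):
            rounded = np.rint(arr)
            if not np.allclose(arr, rounded):
                raise ValueError("label data must be integer-valued")
            arr = rounded
        if arr.ndim != 3:
            raise ValueError(f"expected 3-D labels, got shape {arr.shape}")
        if arr.min() < 0:
            raise ValueError("labels must be non-negative")
        self.data = arr.astype(np.int32)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def label_set(self) -> tuple[int, ...]:
        """Structure indices present, excluding background."""
        labels = np.unique(self.data)
        return tuple(int(v) for v in labels if v != 0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "ScalarVolume | LabelMap") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.affine, other.affine)
        )

    def mask(self, label: int) -> np.ndarray:
        return self.data == label

    def volume_mm3(self, label: int) -> float:
        return float(np.count_nonzero(self.data == label)) * self.voxel_volume_mm3

    def like(self, data: np.ndarray) -> "LabelMap":
        return LabelMap(data, self.spacing, self.affine.copy())

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.uint16), self.affine)
        img.header.set_zooms(self.spacing)
        nib.save(img, str(path))

    @classmethod
    def load(cls, path: str | Path) -> "LabelMap":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(str(path))
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.rint(data).astype(np.int32), spacing, np.asarray(img.affine))


class MultiContrastImage:
    """The 5-channel DTI feature field (FA, MD, |EVx|, |EVy|, |EVz|).

    All channels share one grid.  Invariants enforced at construction
    (``validate='raise'``) or repaired (``validate='clamp'``):

    * FA in [0, 1] per voxel,
    * MD >= 0 (mm²/s),
    * each |EV| component in [0, 1],
    * the EV triple has unit norm (±1e-3) wherever FA > 0.
    """

    def __init__(
        self,
        channels: Sequence[ScalarVolume],
        validate: str = "raise",
    ) -> None:
        if len(channels) != 5:
            raise ValueError("MultiContrastImage needs exactly 5 channels (fa, md, evx, evy, evz)")
        ref = channels[0]
        for name, ch in zip(CHANNEL_NAMES[1:], channels[1:]):
            if not ref.same_grid(ch):
                raise GridMismatchError(f"channel '{name}' grid differs from 'fa'")
        self._channels = tuple(channels)
        self._validate(mode=validate)

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        fa: np.ndarray,
        md: np.ndarray,
        evx: np.ndarray,
        evy: np.ndarray,
        evz: np.ndarray,
        spacing: Sequence[float] = (1.0, 1.0, 1.0),
        affine: np.ndarray | None = None,
        validate: str = "raise",
    ) -> "MultiContrastImage":
        vols = [ScalarVolume(a, tuple(spacing), affine) for a in (fa, md, evx, evy, evz)]
        return cls(vols, validate=validate)

    def _validate(self, mode: str = "raise") -> None:
        if mode not in ("raise", "clamp", "none"):
            raise ValueError(f"unknown validation mode {mode!r}")
        if mode == "none":
            return
        fa, md = self.fa.data, self.md.data
        evs = [self._channels[i].data for i in (2, 3, 4)]
        for name, arr in zip(CHANNEL_NAMES, (fa, md, *evs)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel '{name}' contains non-finite voxels")
        problems = []
        if fa.min() < -1e-9 or fa.max() > 1 + 1e-9:
            problems.append(("fa", "FA outside [0, 1]"))
        if md.min() < -1e-12:
            problems.append(("md", "MD negative"))
        for i, ev in enumerate(evs):
            if ev.min() < -1e-9 or ev.max() > 1 + 1e-9:
                problems.append((CHANNEL_NAMES[2 + i], "|EV| outside [0, 1]"))
        if problems:
            if mode == "raise":
                raise ValueError("; ".join(msg for _, msg in problems))
            np.clip(fa, 0.0, 1.0, out=fa)
            np.clip(md, 0.0, None, out=md)
            for ev in evs:
                np.clip(ev, 0.0, 1.0, out=ev)
            log.warning("clamped out-of-range voxels in channels: %s", [n for n, _ in problems])
        norm2 = evs[0] ** 2 + evs[1] ** 2 + evs[2] ** 2
        gate = fa > 0
        bad = gate & (np.abs(np.sqrt(np.maximum(norm2, 0.0)) - 1.0) > 1e-3)
        if bad.any():
            if mode == "raise":
                raise ValueError(
                    f"{int(bad.sum())} voxels with FA > 0 have non-unit primary eigenvector"
                )
            nrm = np.sqrt(np.maximum(norm2, 1e-300))
            for ev in evs:
                ev[bad] = ev[bad] / nrm[bad]
            log.warning("renormalized %d non-unit eigenvector voxels", int(bad.sum()))

    # -- accessors -----------------------------------------------------------

    @property
    def channels(self) -> tuple[ScalarVolume, ...]:
        return self._channels

    @property
    def fa(self) -> ScalarVolume:
        return self._channels[0]

    @property
    def md(self) -> ScalarVolume:
        return self._channels[1]

    def channel(self, idx: int) -> ScalarVolume:
        return self._channels[idx]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self._channels[0].shape

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self._channels[0].spacing

    @property
    def affine(self) -> np.ndarray:
        return self._channels[0].affine

    @property
    def voxel_volume_mm3(self) -> float:
        return self._channels[0].voxel_volume_mm3

    def stacked(self) -> np.ndarray:
        """Channel-first array of shape (5, nx, ny, nz)."""
        return np.stack([c.data for c in self._channels])

    def same_grid(self, other: "ScalarVolume | LabelMap | MultiContrastImage") -> bool:
        if isinstance(other, MultiContrastImage):
            other = other.fa
        return self._channels[0].same_grid(other)


# -- NIfTI layout ------------------------------------------------------------


def channel_paths(stem: str | Path) -> dict[str, Path]:
    """Expected file paths for the 5 channels of a subject/atlas stem."""
    stem = Path(stem)
    out = {}
    for name, suf in CHANNEL_SUFFIXES.items():
        for ext in (".nii.gz", ".nii"):
            p = stem.parent / (stem.name + suf + ext)
            if p.exists():
                out[name] = p
                break
        else:
            out[name] = stem.parent / (stem.name + suf + ".nii.gz")
    return out


def read_multicontrast(
    stem_or_paths: str | Path | Mapping[str, str | Path] | Sequence[str | Path],
    validate: str = "raise",
) -> MultiContrastImage:
    """Read the 5 contrast channels.

    ``stem_or_paths`` may be a path stem (channels found as
    ``<stem>_fa.nii.gz`` etc.), a mapping ``{channel: path}``, or an
    ordered sequence of 5 paths in canonical channel order.
    """
    if isinstance(stem_or_paths, (str, Path)):
        paths = channel_paths(stem_or_paths)
        ordered = [paths[c] for c in CHANNEL_NAMES]
    elif isinstance(stem_or_paths, Mapping):
        ordered = [Path(stem_or_paths[c]) for c in CHANNEL_NAMES]
    else:
        ordered = [Path(p) for p in stem_or_paths]
        if len(ordered) != 5:
            raise ValueError("expected 5 channel paths")
    vols = [ScalarVolume.load(p) for p in ordered]
    return MultiContrastImage(vols, validate=validate)


def write_multicontrast(img: MultiContrastImage, stem: str | Path) -> list[Path]:
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    written = []
    for name, ch in zip(CHANNEL_NAMES, img.channels):
        p = stem.parent / (stem.name + CHANNEL_SUFFIXES[name] + ".nii.gz")
        ch.save(p)
        written.append(p)
    return written


def read_labelmap(stem_or_path: str | Path) -> LabelMap:
    p = Path(stem_or_path)
    if p.suffix in (".nii", ".gz") or p.exists():
        return LabelMap.load(p)
    for ext in (".nii.gz", ".nii"):
        cand = p.parent / (p.name + LABEL_SUFFIX + ext)
        if cand.exists():
            return LabelMap.load(cand)
    raise FileNotFoundError(f"no label volume for stem {p}")


def write_labelmap(labels: LabelMap, stem: str | Path) -> Path:
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    p = stem.parent / (stem.name + LABEL_SUFFIX + ".nii.gz")
    labels.save(p)
    return p


# -- interpolation primitives ------------------------------------------------


def interpolate_scalar(
    vol: ScalarVolume | np.ndarray,
    points: np.ndarray,
    mode: str = "trilinear",
    fill: float = 0.0,
) -> np.ndarray:
    """Sample a scalar volume at fractional voxel coordinates.

    Parameters
    ----------
    points : ndarray (N, 3)
        Query positions in the volume's 0-based voxel frame.
    mode : {"trilinear", "nearest"}
    fill : float
        Value returned outside the grid.
    """
    data = vol.data if isinstance(vol, ScalarVolume) else np.asarray(vol, float)
    pts = np.asarray(points, dtype=np.float64)
    if pts.size == 0:
        return np.empty((0,), dtype=np.float64)
    if pts.ndim == 1:
        pts = pts[None, :]
    order = {"trilinear": 1, "nearest": 0}.get(mode)
    if order is None:
        raise ValueError(f"unknown interpolation mode {mode!r}")
    return map_coordinates(data, pts.T, order=order, mode="constant", cval=fill)


def interpolate_label_probability(
    labels: LabelMap,
    points: np.ndarray,
    label: int,
) -> np.ndarray:
    """Trilinear probability of ``label`` at fractional voxel coordinates.

    The indicator volume of the label is interpolated trilinearly; outside
    the grid all probability mass belongs to the background (label 0), so
    summing over all labels including background gives 1 everywhere.
    An unknown label yields the zero field.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.size == 0:
        return np.empty((0,), dtype=np.float64)
    indicator = (labels.data == label).astype(np.float64)
    fill = 1.0 if label == 0 else 0.0
    return interpolate_scalar(indicator, pts, mode="trilinear", fill=fill)
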