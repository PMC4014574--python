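"""DTI-derived contrasts and the threshold-based peripheral decomposition.

``tensor_to_contrasts`` turns a 6-component diffusion-tensor volume into
the five contrasts the fusion stage consumes: fractional anisotropy (FA),
mean diffusivity (MD, mm²/s) and the componentwise absolute values of the
unit primary eigenvector.  ``decompose_peripheral`` splits surface-adjacent
structures into CSF / cortex / peripheral-white-matter sublabels by the
standard MD and FA thresholds (0.0015 mm²/s and 0.2).
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .volumes import LabelMap, MultiContrastImage, ScalarVolume

log = logging.getLogger(__name__)

#: default MD threshold separating CSF from tissue (mm²/s)
MD_CSF_THRESHOLD = 0.0015
#: default FA threshold separating cortex from white matter
FA_WM_THRESHOLD = 0.2

#: upper-triangular row order of the stored tensor components
TENSOR_COMPONENTS = ("dxx", "dxy", "dxz", "dyy", "dyz", "dzz")


@dataclasses.dataclass
class TensorVolume:
    """Symmetric diffusion tensor field, components in mm²/s.

    ``components`` has shape (6, nx, ny, nz) in upper-triangular row order
    (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz).
    """

    components: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=np.float64)
        if self.components.ndim != 4 or self.components.shape[0] != 6:
            raise ValueError(
                f"expected (6, nx, ny, nz) tensor components, got {self.components.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.components.shape[1:]  # type: ignore[return-value]

    def as_matrices(self) -> np.ndarray:
        """Dense symmetric matrices of shape (nx, ny, nz, 3, 3)."""
        dxx, dxy, dxz, dyy, dyz, dzz = self.components
        mats = np.empty(self.shape + (3, 3), dtype=np.float64)
        mats[..., 0, 0] = dxx
        mats[..., 1, 1] = dyy
        mats[..., 2, 2] = dzz
        mats[..., 0, 1] = mats[..., 1, 0] = dxy
        mats[..., 0, 2] = mats[..., 2, 0] = dxz
        mats[..., 1, 2] = mats[..., 2, 1] = dyz
        return mats

    @classmethod
    def load(cls, path: str | Path) -> "TensorVolume":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        if data.ndim != 4 or data.shape[3] != 6:
            raise ValueError(f"expected a 4-D NIfTI with 6 tensor volumes, got {data.shape}")
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.moveaxis(data, 3, 0), spacing, np.asarray(img.affine))

    def save(self, path: str | Path) -> None:
        import nibabel as nib

        aff = self.affine
        if aff is None:
            aff = np.diag(list(self.spacing) + [1.0])
        img = nib.Nifti1Image(np.moveaxis(self.components, 0, 3), aff)
        img.header.set_zooms(tuple(self.spacing) + (1.0,))
        nib.save(img, str(path))


def tensor_to_contrasts(tensor: TensorVolume) -> MultiContrastImage:
    """Compute FA, MD and |primary eigenvector| from a tensor field.

    Eigenvalues are sorted ascending by ``numpy.linalg.eigh``; negative
    eigenvalues (noise) are clamped to 0 before FA/MD and the clamp count
    is logged.  Per voxel::

        MD = (λ1 + λ2 + λ3) / 3
        FA = sqrt(3/2) * ||λ - MD|| / ||λ||

    All-zero tensors get FA = 0, MD = 0 and EV = (0, 0, 0); such voxels are
    exempt from the unit-eigenvector invariant because FA = 0 gates it.
    """
    mats = tensor.as_matrices()
    eigvals, eigvecs = np.linalg.eigh(mats)

    n_clamped = int(np.count_nonzero(eigvals < 0))
    if n_clamped:
        log.info("clamped %d negative eigenvalues to 0 before FA/MD", n_clamped)
    eigvals = np.maximum(eigvals, 0.0)

    md = eigvals.mean(axis=-1)
    dev = eigvals - md[..., None]
    norm_l = np.sqrt((eigvals**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.sqrt((dev**2).sum(axis=-1)) / norm_l
    zero = norm_l <= 0
    fa = np.where(zero, 0.0, fa)
    fa = np.clip(fa, 0.0, 1.0)

    ev = np.abs(eigvecs[..., :, 2])  # eigenvector of the largest eigenvalue
    ev = np.where(zero[..., None], 0.0, ev)

    return MultiContrastImage.from_arrays(
        fa, md, ev[..., 0], ev[..., 1], ev[..., 2],
        spacing=tensor.spacing, affine=tensor.affine,
    )


# -- peripheral decomposition ------------------------------------------------

#: deterministic sublabel scheme: parent*100 + offset
CSF_OFFSET, WM_OFFSET, CORTEX_OFFSET = 1, 2, 3


@dataclasses.dataclass
class PeripheralDecomposition:
    """Result of splitting peripheral structures by MD/FA thresholds.

    ``sublabels[s]`` maps a peripheral parent label ``s`` to its
    (csf, white-matter, cortex) sublabel ids; CSF sublabels are listed in
    ``excluded`` and are dropped from downstream ROI statistics.
    """

    labels: LabelMap
    sublabels: dict[int, tuple[int, int, int]]
    excluded: frozenset[int]


def sublabel_ids(parent: int) -> tuple[int, int, int]:
    """(csf, wm, cortex) sublabel ids for a peripheral parent label."""
    base = parent * 100
    return base + CSF_OFFSET, base + WM_OFFSET, base + CORTEX_OFFSET


def decompose_peripheral(
    labels: LabelMap,
    img: MultiContrastImage,
    peripheral_ids: Iterable[int],
    md_csf_threshold: float = MD_CSF_THRESHOLD,
    fa_wm_threshold: float = FA_WM_THRESHOLD,
) -> PeripheralDecomposition:
    """Split each peripheral structure into CSF / WM / cortex sublabels.

    Per voxel of a peripheral structure: MD >= ``md_csf_threshold`` puts it
    in the CSF sublabel (excluded from analysis); otherwise FA >
    ``fa_wm_threshold`` puts it in the peripheral-white-matter sublabel,
    and the remainder is cortex.  The boundary is inclusive on the CSF side
    for MD and on the cortex side for FA.  Non-peripheral labels are
    untouched; a peripheral id absent from the volume is a warned no-op.
    """
    if not labels.same_grid(img.fa):
        raise ValueError("label and image grids differ")
    peripheral = sorted(set(int(p) for p in peripheral_ids))
    present = set(labels.label_set)
    missing = [p for p in peripheral if p not in present]
    for p in missing:
        log.warning("peripheral structure %d absent from label map; skipped", p)
    peripheral = [p for p in peripheral if p in present]

    existing = set(np.unique(labels.data).tolist())
    out = labels.data.copy()
    submap: dict[int, tuple[int, int, int]] = {}
    excluded: set[int] = set()
    md, fa = img.md.data, img.fa.data
    for p in peripheral:
        csf_id, wm_id, ctx_id = sublabel_ids(p)
        clash = {csf_id, wm_id, ctx_id} & existing
        if clash:
            raise ValueError(f"sublabel ids {sorted(clash)} collide with existing labels")
        sel = labels.data == p
        is_csf = sel & (md >= md_csf_threshold)
        is_wm = sel & ~is_csf & (fa > fa_wm_threshold)
        is_ctx = sel & ~is_csf & ~is_wm
        out[is_csf] = csf_id
        out[is_wm] = wm_id
        out[is_ctx] = ctx_id
        submap[p] = (csf_id, wm_id, ctx_id)
        excluded.add(csf_id)
    return PeripheralDecomposition(labels.like(out), submap, frozenset(excluded))
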