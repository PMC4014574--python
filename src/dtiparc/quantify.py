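"""ROI statistics and evaluation metrics.

Volumes are voxel counts times voxel volume; ROI-specific FA and MD are
voxel averages.  Evaluation metrics: Dice overlap, symmetric volume
difference percent, scan-rescan percent differences, and cross-subject
variability (std/mean per structure and measure).
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .volumes import LabelMap, MultiContrastImage

log = logging.getLogger(__name__)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|) of two binary masks.

    Two empty masks are defined as Dice 1 (with a warning); mismatched
    grids raise.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        log.warning("Dice of two empty masks defined as 1.0")
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def roi_stats(
    labels: LabelMap,
    img: MultiContrastImage,
    exclude: Iterable[int] = (),
) -> pd.DataFrame:
    """Per-structure volume (mm³), mean FA and mean MD.

    One row per non-background structure not in ``exclude`` (CSF sublabels
    flagged excluded-from-analysis belong there); empty structures are
    absent rather than zero rows.
    """
    if not labels.same_grid(img.fa):
        raise ValueError("label and image grids differ")
    excluded = set(int(e) for e in exclude)
    voxvol = labels.voxel_volume_mm3
    fa, md = img.fa.data, img.md.data
    rows = []
    for lab in labels.label_set:
        if lab in excluded:
            continue
        sel = labels.data == lab
        n = int(sel.sum())
        rows.append(
            {
                "structure": lab,
                "n_voxels": n,
                "volume_mm3": n * voxvol,
                "mean_fa": float(fa[sel].mean()),
                "mean_md": float(md[sel].mean()),
            }
        )
    frame = pd.DataFrame(rows, columns=["structure", "n_voxels", "volume_mm3", "mean_fa", "mean_md"])
    return frame.set_index("structure")


def volume_diff_percent(v1: float, v2: float, denominator: str = "mean") -> float:
    """Percent volume difference between two measurements.

    Default is the symmetric form 100·|v1 − v2| / ((v1 + v2)/2), standard
    for scan-rescan studies; ``denominator='first'`` divides by v1
    instead.  Both volumes zero is undefined and raises.
    """
    if v1 < 0 or v2 < 0:
        raise ValueError("volumes must be non-negative")
    if v1 == 0 and v2 == 0:
        raise ValueError("volume difference undefined for two empty structures")
    if denominator == "mean":
        return 100.0 * abs(v1 - v2) / ((v1 + v2) / 2.0)
    if denominator == "first":
        if v1 == 0:
            raise ValueError("first-scan denominator is zero")
        return 100.0 * abs(v1 - v2) / v1
    raise ValueError(f"unknown denominator {denominator!r}")


def cross_subject_variability(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Per-structure std/mean (sample std, n−1) across subjects for
    volume, mean FA and mean MD.

    Structures absent in some subjects are computed over the subjects in
    which they are present; the count is reported in ``n_subjects``.
    Requires at least 2 subjects per structure.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 subjects")
    all_structs = sorted({s for t in tables for s in t.index})
    rows = []
    for s in all_structs:
        vals = {m: [] for m in ("volume_mm3", "mean_fa", "mean_md")}
        for t in tables:
            if s in t.index:
                for m in vals:
                    vals[m].append(float(t.loc[s, m]))
        n = len(vals["volume_mm3"])
        if n < 2:
            log.warning("structure %s present in <2 subjects; skipped", s)
            continue
        row = {"structure": s, "n_subjects": n}
        for m, key in (("volume_mm3", "volume"), ("mean_fa", "fa"), ("mean_md", "md")):
            arr = np.asarray(vals[m])
            mean = arr.mean()
            row[f"cv_{key}"] = float(arr.std(ddof=1) / mean) if mean != 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("structure")


def scan_rescan_report(
    run1: pd.DataFrame,
    run2: pd.DataFrame,
    small_structure_cutoff_mm3: float = 1000.0,
) -> dict:
    """Scan-rescan reproducibility of volume, mean FA and mean MD.

    Per matched structure, the absolute percent difference with the
    symmetric (mean-of-two) denominator; the summary reports the mean per
    measure over all structures and again excluding structures whose
    scan-1 volume is below ``small_structure_cutoff_mm3`` (the
    poorly-reproducible small gray-matter ROIs).  Unmatched structures are
    reported and excluded.
    """
    common = sorted(set(run1.index) & set(run2.index))
    unmatched = sorted(set(run1.index) ^ set(run2.index))
    if unmatched:
        log.warning("structures present in only one run (excluded): %s", unmatched)
    rows = []
    for s in common:
        r = {"structure": s}
        for m, key in (("volume_mm3", "volume"), ("mean_fa", "fa"), ("mean_md", "md")):
            v1, v2 = float(run1.loc[s, m]), float(run2.loc[s, m])
            if v1 == 0 and v2 == 0:
                r[f"pct_diff_{key}"] = np.nan
            else:
                r[f"pct_diff_{key}"] = 100.0 * abs(v1 - v2) / ((v1 + v2) / 2.0)
        r["small"] = float(run1.loc[s, "volume_mm3"]) < small_structure_cutoff_mm3
        rows.append(r)
    table = pd.DataFrame(rows).set_index("structure") if rows else pd.DataFrame()

    def _means(t: pd.DataFrame) -> dict:
        if t.empty:
            return {"volume": np.nan, "fa": np.nan, "md": np.nan}
        return {
            key: float(t[f"pct_diff_{key}"].mean()) for key in ("volume", "fa", "md")
        }

    return {
        "per_structure": table,
        "mean_pct_diff": _means(table),
        "mean_pct_diff_excluding_small": _means(table[~table["small"]]) if not table.empty else _means(table),
        "n_structures": len(common),
        "n_excluded_small": int(table["small"].sum()) if not table.empty else 0,
        "unmatched": unmatched,
    }
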