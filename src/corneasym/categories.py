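"""Bilateral normality categories and interocular scalar-index differences.

The device labels each scan with a quality specification (QS: OK or
error codes 1/2) and each eye with a keratoconus score (KKS: normal,
possible, stages 1-4).  Cases with a QS error in either eye are
excluded; the remaining cases are recoded into four bilateral
categories by the worse eye's KKS: bilateral-normal, KS-abnormal
(possible keratoconus), KCN stage 1-2, and KCN stage 3-4.

Scalar per-eye indices (apical / minimum thickness, maximum / mean
keratometry, corneal astigmatism) are compared between fellow eyes via
their absolute interocular difference; an astigmatism difference of
1.0 D or more flags anisoastigmatism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np
import pandas as pd

from .io import KKS, QS, Eye, EyeMetadata


class BilateralCategory(str, Enum):
    BILATERAL_NORMAL_QSOK = "Bilateral-normal QS-OK"
    KS_ABNORMAL_QSOK = "KS-abnormal QS-OK"
    KCN_1_2_QSOK = "KCN-1-2 QS-OK"
    KCN_3_4_QSOK = "KCN-3-4 QS-OK"
    EXCLUDED_QS_ERROR = "Excluded (QS error)"


_KKS_SEVERITY = {
    KKS.NORMAL: 0,
    KKS.POSSIBLE: 1,
    KKS.STAGE1: 2,
    KKS.STAGE2: 3,
    KKS.STAGE3: 4,
    KKS.STAGE4: 5,
}


def recode_bilateral(meta_od: EyeMetadata, meta_os: EyeMetadata) -> BilateralCategory:
    """Recode a case's two per-eye QS/KKS labels into one bilateral category.

    The rule is symmetric in its arguments and monotone: worsening
    either eye's KKS never yields a less severe category.
    """
    if meta_od.qs is not QS.OK or meta_os.qs is not QS.OK:
        return BilateralCategory.EXCLUDED_QS_ERROR
    worse = max(_KKS_SEVERITY[meta_od.kks], _KKS_SEVERITY[meta_os.kks])
    if worse == 0:
        return BilateralCategory.BILATERAL_NORMAL_QSOK
    if worse == 1:
        return BilateralCategory.KS_ABNORMAL_QSOK
    if worse in (2, 3):
        return BilateralCategory.KCN_1_2_QSOK
    return BilateralCategory.KCN_3_4_QSOK


#: scalar indices compared between fellow eyes, with units
SCALAR_INDICES = (
    "apical_thickness_um",
    "min_thickness_um",
    "max_keratometry_D",
    "mean_keratometry_D",
    "astigmatism_D",
)

ANISOASTIGMATISM_THRESHOLD_D = 1.0


@dataclass
class ScalarIndexPair:
    """Per-eye scalar indices and their absolute interocular differences."""

    case_id: str
    od: dict[str, float]
    os: dict[str, float]
    i_diff: dict[str, float] = field(default_factory=dict)
    anisoastigmatism: bool | None = None

    def __post_init__(self) -> None:
        for k, v in self.i_diff.items():
            if np.isfinite(v) and v < 0:
                raise ValueError(f"i_diff[{k!r}] must be non-negative")


def interocular_scalar_diffs(
    case_id: str,
    od_indices: Mapping[str, float],
    os_indices: Mapping[str, float],
    indices: tuple[str, ...] = SCALAR_INDICES,
) -> ScalarIndexPair:
    """Absolute fellow-eye difference for each scalar index.

    A missing or non-finite index in either eye flags that i_diff as NaN
    while the other indices are still computed.
    """
    i_diff: dict[str, float] = {}
    for name in indices:
        a = od_indices.get(name, np.nan)
        b = os_indices.get(name, np.nan)
        if a is None or b is None or not (np.isfinite(a) and np.isfinite(b)):
            i_diff[name] = float("nan")
        else:
            i_diff[name] = abs(float(a) - float(b))
    aniso = None
    ast = i_diff.get("astigmatism_D", float("nan"))
    if np.isfinite(ast):
        aniso = ast >= ANISOASTIGMATISM_THRESHOLD_D
    return ScalarIndexPair(
        case_id=case_id,
        od=dict(od_indices),
        os=dict(os_indices),
        i_diff=i_diff,
        anisoastigmatism=aniso,
    )


def categorize_cohort(
    metadata: Mapping[tuple[str, Eye], EyeMetadata]
) -> pd.DataFrame:
    """Bilateral category per case from a per-eye metadata mapping."""
    cases = sorted({cid for cid, _ in metadata})
    rows = []
    for cid in cases:
        od = metadata.get((cid, Eye.OD))
        os_ = metadata.get((cid, Eye.OS))
        if od is None or os_ is None:
            continue
        rows.append({"case_id": cid, "category": recode_bilateral(od, os_).value})
    return pd.DataFrame(rows).set_index("case_id")


def category_frequency_report(categories: pd.DataFrame) -> str:
    """Frequency table of bilateral categories (excluded cases listed last)."""
    counts = categories["category"].value_counts()
    order = [c.value for c in BilateralCategory]
    n_total = int(counts.sum())
    lines = ["Bilateral category\tn\t%"]
    for name in order:
        n = int(counts.get(name, 0))
        lines.append(f"{name}\t{n}\t{100.0 * n / n_total:.1f}" if n_total else f"{name}\t0\t0.0")
    return "\n".join(lines)
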