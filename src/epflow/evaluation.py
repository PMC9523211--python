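"""Observer-agreement and repeatability statistics.

Method comparison for wave counts and direction labels: per-clip percent
agreement, intraclass correlation (two-way random effects, absolute
agreement, single measure by default) with the conventional interpretation
bands (poor ≤ 0.20, fair ≤ 0.40, moderate ≤ 0.60, good ≤ 0.80, excellent
above), and paired comparison of count distributions (Shapiro–Wilk
normality of the differences plus the Wilcoxon signed-rank test).
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

__all__ = [
    "percent_agreement",
    "icc_agreement",
    "icc_band",
    "compare_counts",
    "PairedComparison",
    "round_half_up",
]


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), the convention used for
    reported agreement fractions."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(value)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def percent_agreement(labels_a: Sequence, labels_b: Sequence) -> float:
    """Fraction of positions where the two raters assigned the same label."""
    if len(labels_a) != len(labels_b):
        raise ValueError("label lists must have equal length")
    if len(labels_a) == 0:
        raise ValueError("label lists must be non-empty")
    matches = sum(a == b for a, b in zip(labels_a, labels_b))
    return matches / len(labels_a)


_BANDS = (
    (0.20, "poor"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "good"),
    (1.00, "excellent"),
)


def icc_band(icc: float) -> str:
    """Interpretation band for an ICC value (≤0.20 poor … >0.80 excellent)."""
    for upper, label in _BANDS:
        if icc <= upper + 1e-12:
            return label
    return "excellent"


def icc_agreement(
    table: pd.DataFrame | np.ndarray, model: str = "ICC2"
) -> tuple[float, str]:
    """Intraclass correlation of a complete subjects x raters table.

    Parameters
    ----------
    table : DataFrame or 2-D array
        One row per subject (clip), one column per rater/method; no
        missing cells.
    model : str
        Which ICC form to report: ``ICC1``, ``ICC2`` (two-way random,
        absolute agreement, single measure — the default for method
        comparison), ``ICC3``, or the average-measure variants
        ``ICC1k``/``ICC2k``/``ICC3k``.

    Returns
    -------
    (icc, band) : the coefficient and its interpretation label.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("ICC needs at least 2 subjects and 2 raters")
    if np.isnan(arr).any():
        raise ValueError("ICC requires a complete table (no missing cells)")

    n_subj, n_raters = arr.shape
    if np.allclose(arr, arr[:, [0]]):
        # raters identical: perfect agreement whenever subjects differ at all
        icc = 1.0 if np.ptp(arr[:, 0]) > 0 else 0.0
        return icc, icc_band(icc)

    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n_subj), n_raters),
            "rater": np.tile(np.arange(n_raters), n_subj),
            "rating": arr.ravel(),
        }
    )
    res = pg.intraclass_corr(
        data=long, targets="subject", raters="rater", ratings="rating"
    )
    # pingouin orders the six forms single-measure first: one-way, two-way
    # random absolute agreement, two-way mixed consistency, then the
    # average-measure variants in the same order
    order = {"ICC1": 0, "ICC2": 1, "ICC3": 2, "ICC1k": 3, "ICC2k": 4, "ICC3k": 5}
    if model not in order:
        raise ValueError(f"unknown ICC model {model!r}")
    icc = float(res["ICC"].iloc[order[model]])
    return icc, icc_band(icc)


@dataclass(frozen=True)
class PairedComparison:
    n: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    shapiro_stat: float
    shapiro_p: float
    wilcoxon_stat: float  # min(R+, R-) over non-zero differences
    rank_sum_positive: float  # R+: signed-rank sum of positive differences
    p_value: float
    degenerate: bool  # all paired differences are zero

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def compare_counts(a: Sequence[float], b: Sequence[float]) -> PairedComparison:
    """Paired comparison of two count series from the same clips.

    Reports mean ± SD of each series, Shapiro–Wilk on the paired
    differences, and the Wilcoxon signed-rank test (zero differences
    dropped, average ranks on ties).  When every difference is zero the
    test is undefined and the result is flagged degenerate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("count lists must be 1-D and of equal length")
    if a.size < 5:
        raise ValueError("need at least 5 paired counts")

    diff = a - b
    nonzero = diff[diff != 0]
    degenerate = nonzero.size == 0

    if np.ptp(diff) > 0:
        sh_stat, sh_p = stats.shapiro(diff)
    else:
        sh_stat, sh_p = float("nan"), float("nan")

    if degenerate:
        w_stat, p_val, r_plus = float("nan"), float("nan"), 0.0
    else:
        res = stats.wilcoxon(a, b, zero_method="wilcox", method="auto")
        w_stat, p_val = float(res.statistic), float(res.pvalue)
        ranks = stats.rankdata(np.abs(nonzero))
        r_plus = float(ranks[nonzero > 0].sum())

    return PairedComparison(
        n=int(a.size),
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        shapiro_stat=float(sh_stat),
        shapiro_p=float(sh_p),
        wilcoxon_stat=w_stat,
        rank_sum_positive=r_plus,
        p_value=p_val,
        degenerate=degenerate,
    )
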