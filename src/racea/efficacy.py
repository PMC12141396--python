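"""Disease-activity scoring, ACR responder derivation and comparison statistics.

The DAS28-ESR composite and the ACR20/50/70 responder criteria are the two
workhorse definitions of this module.  The ACR rule implemented here requires
the usual ≥X% improvement in *both* 28-joint counts, plus ≥X% improvement in
at least three of the four auxiliary core-set measures recorded in this study
design (pain VAS, HAQ, ESR, CRP); physician/patient global assessments are not
collected, so the canonical "3 of 5" majority maps onto "3 of the available 4".
An auxiliary measure with a zero baseline cannot show percentage improvement
and is treated as non-assessable.  A joint count of zero at baseline is
treated as satisfied provided it does not worsen; if both joint counts are
zero, response is not assessable and NONE is returned.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, DomainError
from .records import ACRLevel, AUX_MEASURES, CoreSet

__all__ = [
    "das28_esr",
    "acr_response",
    "response_rates",
    "compare_proportions",
    "compare_continuous",
    "ArmComparison",
    "RateTable",
]

#: thresholds checked in descending order; highest achieved level wins
_ACR_THRESHOLDS = ((ACRLevel.ACR70, 0.70), (ACRLevel.ACR50, 0.50), (ACRLevel.ACR20, 0.20))


def das28_esr(tjc28: float, sjc28: float, esr: float, gh: float) -> float:
    """DAS28 using the erythrocyte sedimentation rate.

    Parameters
    ----------
    tjc28, sjc28 : tender/swollen counts over 28 joints, in [0, 28].
    esr : ESR in mm/h, must be ≥ 1 so the logarithm is defined.
    gh : patient global health on a 0–100 scale (10 × the 0–10 pain VAS when
        a dedicated global assessment is not collected).
    """
    if not (0 <= tjc28 <= 28) or not (0 <= sjc28 <= 28):
        raise DomainError(f"joint counts out of [0, 28]: tjc={tjc28}, sjc={sjc28}")
    if esr < 1.0:
        raise DomainError(f"esr must be >= 1 mm/h, got {esr}")
    if not (0.0 <= gh <= 100.0):
        raise DomainError(f"global health out of [0, 100]: {gh}")
    return (
        0.56 * math.sqrt(tjc28)
        + 0.28 * math.sqrt(sjc28)
        + 0.70 * math.log(esr)
        + 0.014 * gh
    )


def _improvement(baseline: float, followup: float) -> float:
    return (baseline - followup) / baseline


def _joint_ok(baseline: int, followup: int, threshold: float) -> bool:
    if baseline == 0:
        # no measurable disease in this domain at baseline: satisfied unless worse
        return followup == 0
    return _improvement(baseline, followup) >= threshold


def acr_response(baseline: CoreSet, month6: CoreSet) -> ACRLevel:
    """Best ACR response level achieved between the two visits.

    Returns :attr:`ACRLevel.NONE` when both baseline joint counts are zero
    (response not assessable) or when no threshold is met.
    """
    for cs in (baseline, month6):
        if min(cs.sjc28, cs.tjc28, cs.vas, cs.haq, cs.crp, cs.rf) < 0 or cs.esr < 1:
            raise DomainError("core-set measures must be non-negative (esr >= 1)")
    if baseline.tjc28 == 0 and baseline.sjc28 == 0:
        return ACRLevel.NONE

    aux_pairs = [
        (getattr(baseline, m), getattr(month6, m))
        for m in AUX_MEASURES
        if getattr(baseline, m) > 0  # zero baseline: non-assessable
    ]
    for level, thr in _ACR_THRESHOLDS:
        joints = _joint_ok(baseline.tjc28, month6.tjc28, thr) and _joint_ok(
            baseline.sjc28, month6.sjc28, thr
        )
        if not joints:
            continue
        n_aux = sum(1 for b, f in aux_pairs if _improvement(b, f) >= thr)
        if n_aux >= 3:
            return level
    return ACRLevel.NONE


@dataclass(frozen=True)
class RateTable:
    """Cumulative responder proportions for one arm."""

    n: int
    counts: dict  # level name -> responders at-or-above that level
    rates: dict  # level name -> percentage

    def rate(self, level: ACRLevel) -> float:
        return self.rates[level.name]


def response_rates(levels: Sequence[ACRLevel]) -> RateTable:
    """Cumulative ACR20/50/70 proportions from per-patient best levels."""
    n = len(levels)
    if n == 0:
        raise DegenerateDataError("empty arm: no classified patients")
    counts = {}
    rates = {}
    for lv in (ACRLevel.ACR20, ACRLevel.ACR50, ACRLevel.ACR70):
        c = sum(1 for x in levels if x >= lv)
        counts[lv.name] = c
        rates[lv.name] = 100.0 * c / n
    return RateTable(n=n, counts=counts, rates=rates)


def compare_proportions(
    x1: int, n1: int, x2: int, n2: int, correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square test on a 2×2 table of responders.

    Returns ``(statistic, p_value)``.  With ``correction`` the Yates
    continuity correction is applied.  If any expected cell count falls below
    one, a warning recommends :func:`scipy.stats.fisher_exact` instead.
    """
    if not (0 <= x1 <= n1) or not (0 <= x2 <= n2) or n1 == 0 or n2 == 0:
        raise DomainError("need 0 <= x <= n and n > 0 in both groups")
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    if (expected == 0).any():
        # a zero margin: no variation in outcome, statistic is 0 by convention
        return 0.0, 1.0
    if (expected < 1).any():
        warnings.warn(
            "expected cell count below 1; consider scipy.stats.fisher_exact",
            stacklevel=2,
        )
    diff = np.abs(table - expected)
    if correction:
        diff = np.maximum(diff - 0.5, 0.0)
    chi2 = float((diff**2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


@dataclass(frozen=True)
class ArmComparison:
    """Result of a two-group (or paired) comparison of one measure."""

    measure: str
    test: str
    statistic: float
    p_value: float
    summary_a: str
    summary_b: str


def _summarise(x: np.ndarray, normal: bool) -> str:
    if normal:
        return f"{np.mean(x):.2f} ± {np.std(x, ddof=1):.2f}"
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.2f} ({q1:.2f}–{q3:.2f})"


def compare_continuous(
    a: Sequence[float],
    b: Sequence[float],
    paired: bool = False,
    measure: str = "",
    alpha_normality: float = 0.05,
) -> ArmComparison:
    """Compare two samples, choosing a t-test or a rank test by normality.

    Shapiro–Wilk at ``alpha_normality`` screens each sample (the differences,
    when paired); if both pass, Welch's/paired t is used, otherwise
    Mann–Whitney (unpaired) or Wilcoxon signed-rank (paired).
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DegenerateDataError("need at least two observations per group")
    if paired and len(x) != len(y):
        raise DomainError("paired comparison requires equal-length samples")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        if np.array_equal(x, y) or (paired and np.ptp(x - y) == 0 and x[0] == y[0]):
            raise DegenerateDataError("all observations constant; nothing to test")
        raise DegenerateDataError("all observations constant; nothing to test")

    def _normal(v: np.ndarray) -> bool:
        if np.ptp(v) == 0:
            return False
        return stats.shapiro(v).pvalue > alpha_normality

    if paired:
        d = x - y
        normal = _normal(d)
        if normal:
            res = stats.ttest_rel(x, y)
            test = "paired t"
        else:
            if np.all(d == 0):
                return ArmComparison(measure, "wilcoxon", 0.0, 1.0,
                                     _summarise(x, False), _summarise(y, False))
            res = stats.wilcoxon(x, y)
            test = "wilcoxon"
    else:
        normal = _normal(x) and _normal(y)
        if normal:
            res = stats.ttest_ind(x, y, equal_var=False)
            test = "welch t"
        else:
            if np.array_equal(np.sort(x), np.sort(y)):
                # identical samples: U statistic at its null midpoint, p = 1
                return ArmComparison(measure, "mann-whitney",
                                     len(x) * len(y) / 2.0, 1.0,
                                     _summarise(x, False), _summarise(y, False))
            res = stats.mannwhitneyu(x, y, alternative="two-sided")
            test = "mann-whitney"
    return ArmComparison(
        measure=measure,
        test=test,
        statistic=float(res.statistic),
        p_value=float(min(1.0, res.pvalue)),
        summary_a=_summarise(x, normal),
        summary_b=_summarise(y, normal),
    )
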