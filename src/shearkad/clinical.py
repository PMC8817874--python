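"""Treatment-effectiveness arithmetic for stone-outcome counts.

A treatment course is scored per patient as stone *disappeared*, *reduced*,
or *unchanged*; the total effective rate is the share of patients in the
first two categories.  Two groups are compared on effective vs. not-effective
with a chi-square test with continuity correction, falling back to Fisher's
exact test whenever an expected cell count drops below 5.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

from scipy import stats


@dataclass(frozen=True)
class OutcomeTable:
    """Per-group outcome counts after treatment."""

    disappeared: int
    reduced: int
    unchanged: int

    def __post_init__(self) -> None:
        for name in ("disappeared", "reduced", "unchanged"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} count must be >= 0")
        if self.total == 0:
            raise ValueError("outcome table must contain at least one patient")

    @property
    def total(self) -> int:
        return self.disappeared + self.reduced + self.unchanged

    @property
    def effective(self) -> int:
        return self.disappeared + self.reduced


@dataclass(frozen=True)
class RateComparison:
    """Result of a two-group effective-rate comparison."""

    statistic: float
    p_value: float
    significant: bool
    test: str  # "chi2" or "fisher"
    alpha: float


def effective_rate(table: OutcomeTable) -> float:
    """Total effective rate in percent, rounded half-up to 2 decimals.

    100 * (disappeared + reduced) / total.
    """
    raw = Decimal(100 * table.effective) / Decimal(table.total)
    return float(raw.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def compare_rates(
    a: OutcomeTable, b: OutcomeTable, alpha: float = 0.05
) -> RateComparison:
    """Two-group comparison of effective vs. not-effective proportions.

    Chi-square with Yates continuity correction on the 2x2 table; Fisher's
    exact test when any expected cell count is below 5.  Symmetric in its
    two arguments.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    contingency = [
        [a.effective, a.total - a.effective],
        [b.effective, b.total - b.effective],
    ]
    expected = stats.contingency.expected_freq(contingency)
    if expected.min() < 5:
        res = stats.fisher_exact(contingency)
        stat, p, test = float(res.statistic), float(res.pvalue), "fisher"
    else:
        res = stats.chi2_contingency(contingency, correction=True)
        stat, p, test = float(res.statistic), float(res.pvalue), "chi2"
    p = min(p, 1.0)
    return RateComparison(
        statistic=stat, p_value=p, significant=p < alpha, test=test, alpha=alpha
    )
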