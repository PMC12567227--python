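"""Disproportionality statistics on 2x2 contingency tables.

For a drug of interest and an adverse-event term set, the report universe is
partitioned into the classic pharmacovigilance 2x2 table::

                       event match   no match
    drug of interest        a            b
    all other drugs         c            d

with N = a+b+c+d the total number of deduplicated reports. Three
disproportionality measures are computed with 95% intervals:

* ROR, the reporting odds ratio (a*d)/(b*c), with a Wald interval on the log
  scale, exp(ln ROR +/- 1.96*sqrt(1/a + 1/b + 1/c + 1/d));
* PRR, the proportional reporting ratio [a/(a+b)] / [c/(c+d)], interval
  exp(ln PRR +/- 1.96*sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)));
* IC, the Bayesian information component log2((a+0.5)/(E+0.5)) with expected
  count E = (a+b)(a+c)/N; the +0.5 shrinkage pulls sparse estimates toward
  zero, and the 95% credibility bounds use the standard series approximation
  IC - 3.3*(a+0.5)^-1/2 - 2*(a+0.5)^-3/2 and
  IC + 2.4*(a+0.5)^-1/2 - 0.5*(a+0.5)^-3/2.

A signal is flagged when the ROR/PRR interval excludes 1.0, or when the IC
lower bound is above zero. Significance is also assessed with Fisher's exact
test and the chi-square test with and without Yates' continuity correction.

Zero cells make the ratio estimators undefined; under the default
``haldane`` policy the Haldane-Anscombe correction adds 0.5 to every cell,
only when some cell is zero. The ``strict`` policy raises instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

from scipy import stats as sps

from .errors import ConfigurationError, UndefinedEstimateError
from .filters import DrugQuery, TermSet, count_term_matches, select_drug_reports
from .model import ReportUniverse

__all__ = [
    "ContingencyTable",
    "MetricEstimate",
    "SignalResult",
    "build_table",
    "ror_with_ci",
    "prr_with_ci",
    "ic_with_ci",
    "fisher_exact",
    "chi_square",
    "classify_significance",
    "compute_signal",
]

Z95 = 1.96  # fixed: all intervals are 95%


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    """Cells of one drug x term-set 2x2 table over a report universe."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for cell in ("a", "b", "c", "d"):
            v = getattr(self, cell)
            if v < 0:
                raise ValueError(f"cell {cell} is negative: {v}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def degenerate(self) -> bool:
        """True when one margin is empty (no drug reports, or only drug reports)."""
        return self.a + self.b == 0 or self.c + self.d == 0

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


class MetricEstimate(NamedTuple):
    point: float
    low: float
    high: float


def build_table(
    universe: ReportUniverse, query: DrugQuery, term_set: TermSet
) -> ContingencyTable:
    """Partition a deduplicated universe into the 2x2 cells.

    Cells use unique-report counting (each report contributes exactly once),
    so a+b+c+d equals the universe total. The drug margin (a+b) is the
    windowed drug selection; c and d come from all remaining reports.
    """
    selected = select_drug_reports(universe, query)
    selected_ids = {r.primary_id for r in selected}
    a = count_term_matches(selected, term_set, mode="unique_reports").total
    b = len(selected.reports) - a
    rest = ReportUniverse(reports=[r for r in universe if r.primary_id not in selected_ids])
    c = count_term_matches(rest, term_set, mode="unique_reports").total
    d = len(rest.reports) - c
    return ContingencyTable(a=a, b=b, c=c, d=d)


def _corrected_cells(t: ContingencyTable, zero_policy: str) -> tuple[float, float, float, float]:
    if zero_policy not in ("haldane", "strict"):
        raise ConfigurationError(f"unknown zero policy {zero_policy!r}")
    cells = t.cells()
    if 0 in cells:
        if zero_policy == "strict":
            name = "abcd"[cells.index(0)]
            raise UndefinedEstimateError(
                f"cell {name} is zero; estimate undefined under strict policy"
            )
        return tuple(x + 0.5 for x in cells)  # Haldane-Anscombe
    return tuple(float(x) for x in cells)


def ror_with_ci(t: ContingencyTable, zero_policy: str = "haldane") -> MetricEstimate:
    """Reporting odds ratio with its 95% Wald interval."""
    a, b, c, d = _corrected_cells(t, zero_policy)
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return MetricEstimate(ror, ror * math.exp(-Z95 * se), ror * math.exp(Z95 * se))


def prr_with_ci(t: ContingencyTable, zero_policy: str = "haldane") -> MetricEstimate:
    """Proportional reporting ratio with its 95% Wald interval."""
    a, b, c, d = _corrected_cells(t, zero_policy)
    prr = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    return MetricEstimate(prr, prr * math.exp(-Z95 * se), prr * math.exp(Z95 * se))


def ic_with_ci(t: ContingencyTable) -> MetricEstimate:
    """Information component (log2 observed/expected, shrunk) with 95% bounds."""
    if t.n == 0:
        raise UndefinedEstimateError("IC undefined on an empty table (n=0)")
    expected = (t.a + t.b) * (t.a + t.c) / t.n
    return ic_from_observed_expected(t.a, expected)


def ic_from_observed_expected(a: float, expected: float) -> MetricEstimate:
    """IC from an observed count and its expectation (shared with tests/tools)."""
    ic = math.log2((a + 0.5) / (expected + 0.5))
    s = a + 0.5
    low = ic - 3.3 * s ** -0.5 - 2.0 * s ** -1.5
    high = ic + 2.4 * s ** -0.5 - 0.5 * s ** -1.5
    return MetricEstimate(ic, low, high)


def fisher_exact(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p: the hypergeometric probability mass of all
    tables with the observed margins no more probable than the observed one."""
    return float(sps.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided").pvalue)


class ChiSquareResult(NamedTuple):
    statistic: float
    pvalue: float


def chi_square(t: ContingencyTable, yates: bool = False) -> ChiSquareResult:
    """Pearson chi-square on the 2x2 table, 1 degree of freedom.

    With ``yates=True`` the continuity correction subtracts 0.5 from each
    |O - E| (capped at |O - E| so the correction never overshoots).
    """
    if t.n == 0:
        raise UndefinedEstimateError("chi-square undefined on an empty table (n=0)")
    try:
        res = sps.chi2_contingency([[t.a, t.b], [t.c, t.d]], correction=yates)
    except ValueError as exc:
        raise UndefinedEstimateError(f"chi-square undefined: {exc}") from exc
    return ChiSquareResult(float(res.statistic), float(res.pvalue))


@dataclass(slots=True)
class SignalResult:
    """All disproportionality metrics for one drug x term-set table."""

    table: ContingencyTable
    ror: float
    ror_low: float
    ror_high: float
    prr: float
    prr_low: float
    prr_high: float
    ic: float
    ic_low: float
    ic_high: float
    fisher_p: float
    chi2: float
    chi2_p: float
    chi2_yates: float
    chi2_yates_p: float
    significant_ror: bool = False
    significant_prr: bool = False
    significant_ic: bool = False


def classify_significance(result: SignalResult) -> SignalResult:
    """Set significance flags from the interval bounds (pure function of bounds).

    ROR/PRR are significant at alpha=0.05 when the 95% CI excludes 1.0; the
    IC is significant when its lower credibility bound is above zero.
    """
    result.significant_ror = result.ror_low > 1.0 or result.ror_high < 1.0
    result.significant_prr = result.prr_low > 1.0 or result.prr_high < 1.0
    result.significant_ic = result.ic_low > 0.0
    return result


def compute_signal(t: ContingencyTable, zero_policy: str = "haldane") -> SignalResult:
    """Compute ROR, PRR, IC, and the significance tests for one table."""
    ror = ror_with_ci(t, zero_policy)
    prr = prr_with_ci(t, zero_policy)
    ic = ic_with_ci(t)
    chi = chi_square(t, yates=False)
    chi_y = chi_square(t, yates=True)
    result = SignalResult(
        table=t,
        ror=ror.point, ror_low=ror.low, ror_high=ror.high,
        prr=prr.point, prr_low=prr.low, prr_high=prr.high,
        ic=ic.point, ic_low=ic.low, ic_high=ic.high,
        fisher_p=fisher_exact(t),
        chi2=chi.statistic, chi2_p=chi.pvalue,
        chi2_yates=chi_y.statistic, chi2_yates_p=chi_y.pvalue,
    )
    return classify_significance(result)
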