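"""Reporting-odds-ratio disproportionality analysis over a cleaned case series.

For each (drug, event) pair the deduplicated reports are cross-classified
into a 2x2 contingency table

    =============  =========  ===========
                   event      no event
    =============  =========  ===========
    target drug    a          b
    other drugs    c          d
    =============  =========  ===========

and the reporting odds ratio ROR = (a*d)/(b*c) is estimated with a Woolf
(log-normal) 95% confidence interval:

    SE(ln ROR) = sqrt(1/a + 1/b + 1/c + 1/d)
    CI         = exp(ln ROR +/- z * SE),  z = 1.959964

The interval is symmetric on the log scale, so the point estimate is the
geometric mean of its bounds — a property the package also exploits to
audit published results (:func:`implied_ror_from_ci`).  A pair is flagged
as a signal when ROR > 2.00, the lower CI bound > 1.00, and at least ten
reports carry the pair; an ROR above 1 suggests disproportionate
reporting, never causality.

Tables containing a zero cell get the Haldane–Anscombe correction (+0.5 to
every cell) before estimation, flagged in the result.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cleaning import CaseSeries, DrugSynonymMap, match_drug, match_event

__all__ = [
    "Z_95",
    "ContingencyTable",
    "SignalCriteria",
    "DisproportionalityResult",
    "DegenerateTableError",
    "build_contingency",
    "compute_ror",
    "classify_signal",
    "implied_ror_from_ci",
    "run_analysis",
]

#: Two-sided 95% normal quantile used throughout.
Z_95 = 1.959964


class DegenerateTableError(ValueError):
    """All four contingency cells are zero; the odds ratio is undefined."""


@dataclass(frozen=True)
class ContingencyTable:
    """Report counts for one (drug, event) pair against all other drugs."""

    a: int  # drug & event
    b: int  # drug, no event
    c: int  # no drug, event
    d: int  # no drug, no event

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def has_zero_cell(self) -> bool:
        return 0 in (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class SignalCriteria:
    """The tri-criteria signal rule: ROR, lower CI bound and report count.

    The ROR and CI thresholds are strict inequalities ("exceeding 2.00",
    "above 1.00"); the report-count threshold is inclusive ("at least ten").
    """

    min_ror: float = 2.00
    min_ci_low: float = 1.00
    min_reports: int = 10
    z_quantile: float = Z_95

    def __post_init__(self) -> None:
        if min(self.min_ror, self.min_ci_low, self.min_reports, self.z_quantile) <= 0:
            raise ValueError("all signal thresholds must be strictly positive")


@dataclass(frozen=True)
class DisproportionalityResult:
    ror: float
    se_log: float
    ci_low: float
    ci_high: float
    n_reports: int  # cell a of the (uncorrected) table
    corrected: bool
    is_signal: bool


def build_contingency(
    series: CaseSeries,
    drug: DrugSynonymMap,
    event_terms: Iterable[str],
    require_primary_suspect: bool = True,
) -> ContingencyTable:
    """Count each report into exactly one cell of the 2x2 table.

    The background (cells c, d) is every cleaned report not matching the
    target drug — all other drugs, kinase inhibitors included.  The series
    is expected to be deduplicated so the counting unit is the case.
    """
    event_terms = list(event_terms)
    a = b = c = d = 0
    for report in series.reports:
        drug_hit = match_drug(report, drug, require_primary_suspect)
        event_hit = match_event(report, event_terms)
        if drug_hit:
            if event_hit:
                a += 1
            else:
                b += 1
        elif event_hit:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def compute_ror(
    table: ContingencyTable, criteria: SignalCriteria | None = None
) -> DisproportionalityResult:
    """Estimate the ROR with its Woolf 95% CI and apply the signal rule."""
    criteria = criteria or SignalCriteria()
    if table.total == 0:
        raise DegenerateTableError("all contingency cells are zero")
    corrected = table.has_zero_cell
    a, b, c, d = (
        (table.a + 0.5, table.b + 0.5, table.c + 0.5, table.d + 0.5)
        if corrected
        else (table.a, table.b, table.c, table.d)
    )
    ror = (a * d) / (b * c)
    se_log = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    half_width = criteria.z_quantile * se_log
    log_ror = math.log(ror)
    result = DisproportionalityResult(
        ror=ror,
        se_log=se_log,
        ci_low=math.exp(log_ror - half_width),
        ci_high=math.exp(log_ror + half_width),
        n_reports=table.a,
        corrected=corrected,
        is_signal=False,
    )
    return dataclasses.replace(result, is_signal=classify_signal(result, criteria))


def classify_signal(
    result: DisproportionalityResult, criteria: SignalCriteria | None = None
) -> bool:
    """True iff ROR > min_ror AND ci_low > min_ci_low AND n_reports >= min_reports."""
    criteria = criteria or SignalCriteria()
    return (
        result.ror > criteria.min_ror
        and result.ci_low > criteria.min_ci_low
        and result.n_reports >= criteria.min_reports
    )


def implied_ror_from_ci(ci_low: float, ci_high: float) -> float:
    """Invert the Woolf log-symmetry: the point estimate implied by a 95% CI.

    Because the interval is symmetric in log space, the estimate is the
    geometric mean sqrt(ci_low * ci_high).  Useful for auditing published
    ROR tables that print only two decimals.
    """
    if ci_low <= 0 or ci_high <= 0:
        raise ValueError("confidence bounds must be positive")
    if ci_low > ci_high:
        raise ValueError("ci_low must not exceed ci_high")
    return math.sqrt(ci_low * ci_high)


RESULT_COLUMNS = [
    "drug",
    "event",
    "ror",
    "ci_low",
    "ci_high",
    "n_reports",
    "is_signal",
    "corrected",
    "error",
]


def run_analysis(
    series: CaseSeries,
    drugs: Sequence[DrugSynonymMap],
    event_term_sets: Mapping[str, Iterable[str]],
    criteria: SignalCriteria | None = None,
    require_primary_suspect: bool = True,
) -> pd.DataFrame:
    """One result row per (drug, event-set) pair, in the given order.

    Statistical failures (all-zero tables) are reported in the ``error``
    column of the affected row; other rows are unaffected.
    """
    criteria = criteria or SignalCriteria()
    rows = []
    for drug in drugs:
        for event_name, terms in event_term_sets.items():
            table = build_contingency(series, drug, terms, require_primary_suspect)
            row: dict = {"drug": drug.canonical_name, "event": event_name}
            try:
                res = compute_ror(table, criteria)
                row.update(
                    ror=res.ror,
                    ci_low=res.ci_low,
                    ci_high=res.ci_high,
                    n_reports=res.n_reports,
                    is_signal=res.is_signal,
                    corrected=res.corrected,
                    error="",
                )
            except DegenerateTableError as exc:
                row.update(
                    ror=float("nan"),
                    ci_low=float("nan"),
                    ci_high=float("nan"),
                    n_reports=table.a,
                    is_signal=False,
                    corrected=False,
                    error=str(exc),
                )
            rows.append(row)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)
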