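"""Case-series cleaning: deduplication, name standardization, matching, windowing.

Spontaneous-report databases accumulate multiple versions of the same case
(follow-up submissions) and wildly inconsistent verbatim drug names
("Xalkori (crizotinib) 250mg", "CRIZOTINIB.", ...).  Before any counting,
the series is reduced to one report per case — the latest version — and
drug names are normalized so brand/generic synonym lists can match them.
Every stage records a provenance triple (stage, reports in, reports out)
so report attrition is fully auditable.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .faers_io import SafetyReport

__all__ = [
    "DrugSynonymMap",
    "AnalysisWindow",
    "ProvenanceStage",
    "CaseSeries",
    "DEFAULT_SYNONYM_MAPS",
    "DEFAULT_EVENT_SETS",
    "normalize_drug_name",
    "deduplicate",
    "match_drug",
    "match_event",
    "apply_window",
    "clean_pipeline",
]

_NON_WORD = re.compile(r"[^A-Z0-9\- ]+")
_SPACES = re.compile(r"\s+")


@lru_cache(maxsize=1 << 16)
def normalize_drug_name(verbatim: str) -> str:
    """Standardize a verbatim drug name.

    Uppercase, trim, collapse internal whitespace, and drop punctuation
    except hyphens.  Deterministic, idempotent and case-insensitive.

    >>> normalize_drug_name("  Xalkori (crizotinib) 250mg")
    'XALKORI CRIZOTINIB 250MG'
    """
    text = _NON_WORD.sub(" ", verbatim.upper())
    return _SPACES.sub(" ", text).strip()


@dataclass(frozen=True)
class DrugSynonymMap:
    """A canonical drug name plus its normalized synonyms (brand, generic, salt).

    Matching is by token containment: a synonym matches a verbatim name if
    its tokens appear as a contiguous run among the normalized name's
    tokens, so "XALKORI CRIZOTINIB 250MG" matches canonical CRIZOTINIB via
    either the brand or the generic token.
    """

    canonical_name: str
    synonyms: frozenset[str]

    @classmethod
    def build(cls, canonical_name: str, synonyms: Iterable[str] = ()) -> "DrugSynonymMap":
        canon = normalize_drug_name(canonical_name)
        syns = {canon} | {normalize_drug_name(s) for s in synonyms}
        syns.discard("")
        return cls(canonical_name=canon, synonyms=frozenset(syns))

    def matches(self, text: str | None) -> bool:
        if not text:
            return False
        tokens = normalize_drug_name(text).split()
        for syn in self.synonyms:
            syn_tokens = syn.split()
            k = len(syn_tokens)
            if k == 1:
                if syn_tokens[0] in tokens:
                    return True
            else:
                for i in range(len(tokens) - k + 1):
                    if tokens[i : i + k] == syn_tokens:
                        return True
        return False


def validate_synonym_maps(maps: Sequence[DrugSynonymMap]) -> None:
    """Synonym sets of different canonical drugs must be disjoint."""
    seen: dict[str, str] = {}
    for m in maps:
        for s in m.synonyms:
            if s in seen and seen[s] != m.canonical_name:
                raise ValueError(
                    f"synonym {s!r} claimed by both {seen[s]!r} and {m.canonical_name!r}"
                )
            seen[s] = m.canonical_name


#: The five ALK inhibitors analyzed by default, with their US/EU brand names.
DEFAULT_SYNONYM_MAPS: tuple[DrugSynonymMap, ...] = (
    DrugSynonymMap.build("CRIZOTINIB", ["XALKORI"]),
    DrugSynonymMap.build("CERITINIB", ["ZYKADIA"]),
    DrugSynonymMap.build("ALECTINIB", ["ALECENSA"]),
    DrugSynonymMap.build("BRIGATINIB", ["ALUNBRIG"]),
    DrugSynonymMap.build("LORLATINIB", ["LORBRENA", "LORVIQUA"]),
)

#: Default target adverse events, as MedDRA preferred-term strings.
DEFAULT_EVENT_SETS: dict[str, frozenset[str]] = {
    "Pleural effusion": frozenset({"Pleural effusion"}),
    "Pericardial effusion": frozenset({"Pericardial effusion"}),
}


@dataclass(frozen=True)
class AnalysisWindow:
    """Inclusive receipt-date window for the analysis."""

    start: dt.date
    end: dt.date

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("window start must not be after end")

    def contains(self, date: dt.date | None) -> bool:
        return date is not None and self.start <= date <= self.end


#: The default window: the eleven calendar years the reference analysis covers.
DEFAULT_WINDOW = AnalysisWindow(dt.date(2013, 1, 1), dt.date(2023, 12, 31))


@dataclass(frozen=True)
class ProvenanceStage:
    stage: str
    reports_in: int
    reports_out: int

    @property
    def dropped(self) -> int:
        return self.reports_in - self.reports_out


@dataclass
class CaseSeries:
    """A cleaned collection of reports plus the attrition history that made it."""

    reports: list[SafetyReport]
    provenance: list[ProvenanceStage] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reports)

    def with_stage(self, stage: str, reports_in: int, reports: list[SafetyReport]) -> "CaseSeries":
        if len(reports) > reports_in:
            raise ValueError("a cleaning stage cannot add reports")
        return CaseSeries(
            reports=reports,
            provenance=self.provenance + [ProvenanceStage(stage, reports_in, len(reports))],
        )

    def provenance_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.stage, s.reports_in, s.reports_out, s.dropped) for s in self.provenance],
            columns=["stage", "reports_in", "reports_out", "dropped"],
        )


def _dedup_key(report: SafetyReport) -> tuple[int, dt.date, str]:
    # Highest version wins; ties broken by latest receipt date, then by
    # lexicographically greatest primary_id.  Missing dates sort earliest.
    return (
        report.case_version,
        report.receipt_date or dt.date.min,
        report.primary_id,
    )


def deduplicate(reports: Iterable[SafetyReport]) -> CaseSeries:
    """Keep exactly one report per case: the latest version.

    Idempotent; output order follows first appearance of each case.
    """
    reports = list(reports)
    best: dict[str, SafetyReport] = {}
    for r in reports:
        cur = best.get(r.case_id)
        if cur is None or _dedup_key(r) > _dedup_key(cur):
            best[r.case_id] = r
    kept = list(best.values())
    series = CaseSeries(reports=kept)
    series.provenance.append(ProvenanceStage("deduplicate", len(reports), len(kept)))
    return series


def match_drug(
    report: SafetyReport,
    synonym_map: DrugSynonymMap,
    require_primary_suspect: bool = True,
) -> bool:
    """True iff some drug entry names the target drug.

    An entry matches when its verbatim name or active ingredient contains a
    synonym of the map; with ``require_primary_suspect`` the matching entry
    must additionally carry role code PS.  A report counts once no matter
    how many entries match.
    """
    for entry in report.drugs:
        if synonym_map.matches(entry.verbatim_name) or synonym_map.matches(
            entry.active_ingredient
        ):
            if not require_primary_suspect or entry.role_code == "PS":
                return True
    return False


def match_event(report: SafetyReport, preferred_terms: Iterable[str]) -> bool:
    """True iff any reaction equals a target preferred term (case-insensitive, trimmed)."""
    targets = {t.strip().casefold() for t in preferred_terms}
    return any(r.strip().casefold() in targets for r in report.reactions)


def apply_window(series: CaseSeries, window: AnalysisWindow) -> CaseSeries:
    """Keep reports whose receipt date lies in the inclusive window.

    Reports with unparseable/missing dates are dropped here (and show up in
    the stage's attrition count): a report that cannot be placed in time
    cannot be attributed to the analysis window.
    """
    kept = [r for r in series.reports if window.contains(r.receipt_date)]
    return series.with_stage("window", len(series.reports), kept)


def clean_pipeline(
    reports: Iterable[SafetyReport],
    window: AnalysisWindow = DEFAULT_WINDOW,
) -> CaseSeries:
    """read -> deduplicate -> window, with a provenance row per stage."""
    reports = list(reports)
    series = CaseSeries(reports=reports, provenance=[ProvenanceStage("read", len(reports), len(reports))])
    deduped = deduplicate(reports)
    series = series.with_stage("deduplicate", len(reports), deduped.reports)
    return apply_window(series, window)


def event_sets_from_config(raw: Mapping[str, Iterable[str]]) -> dict[str, frozenset[str]]:
    """Build named preferred-term sets from a plain mapping (e.g. parsed YAML)."""
    return {name: frozenset(str(t) for t in terms) for name, terms in raw.items()}
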