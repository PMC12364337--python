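"""Reading and writing FAERS-style quarterly ASCII files.

The FDA Adverse Event Reporting System (FAERS) publishes quarterly
``$``-delimited ASCII tables.  Report-level disproportionality analysis
needs three of them: DEMO (one row per report version), DRUG (one row per
drug mention, with a role code) and REAC (one row per reaction preferred
term).  This module parses those tables into :class:`SafetyReport` records
and writes the same dialect back out, so synthetic datasets round-trip
through the exact code path real quarters would take.

Only the primaryid-era schema (2012Q4 onward) is supported; the legacy
ISR-keyed layout predates the analysis windows this package targets.
Files are decoded as Latin-1 — public FAERS extracts contain non-UTF-8
bytes — and every rejected row is counted with a reason, never silently
dropped.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ROLE_CODES",
    "DrugEntry",
    "SafetyReport",
    "FileParseStats",
    "QuarterBundle",
    "MissingColumnError",
    "parse_fda_date",
    "read_quarter",
    "write_quarter",
    "write_series_csv",
    "read_series_csv",
]

#: FAERS drug role codes: primary suspect, secondary suspect, concomitant,
#: interacting.  The primary-suspect restriction of the analysis keys on "PS".
ROLE_CODES = frozenset({"PS", "SS", "C", "I"})

ENCODING = "latin-1"
DELIMITER = "$"

DEMO_COLUMNS = ("primaryid", "caseid", "caseversion", "fda_dt")
DRUG_COLUMNS = ("primaryid", "drug_seq", "role_cod", "drugname", "prod_ai")
REAC_COLUMNS = ("primaryid", "pt")


class MissingColumnError(ValueError):
    """A required column is absent from a file header."""


@dataclass(slots=True)
class DrugEntry:
    """One drug mention on a report (a DRUG table row)."""

    report_id: str
    seq: int
    role_code: str  # one of ROLE_CODES
    verbatim_name: str
    active_ingredient: str | None = None

    def __post_init__(self) -> None:
        if self.role_code not in ROLE_CODES:
            raise ValueError(f"invalid role code {self.role_code!r}")
        if self.seq <= 0:
            raise ValueError("drug_seq must be positive")


@dataclass(slots=True)
class SafetyReport:
    """One spontaneous report version (a DEMO table row with its children).

    ``primary_id`` is unique per report *version*; ``case_id`` is shared by
    all versions of one case and is the deduplication key.  ``receipt_date``
    is the FDA receipt date (``fda_dt``); ``None`` means the date could not
    be parsed, and such reports are excluded from date-windowed analyses.
    """

    primary_id: str
    case_id: str
    case_version: int
    receipt_date: dt.date | None
    drugs: list[DrugEntry] = field(default_factory=list)
    reactions: list[str] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)


@dataclass
class FileParseStats:
    rows_read: int = 0
    rows_kept: int = 0
    rows_rejected: int = 0
    reject_reasons: Counter = field(default_factory=Counter)

    def reject(self, reason: str) -> None:
        self.rows_rejected += 1
        self.reject_reasons[reason] += 1

    def check(self) -> None:
        assert self.rows_read == self.rows_kept + self.rows_rejected


@dataclass
class QuarterBundle:
    """Locations of one quarter's DEMO/DRUG/REAC files plus parse accounting."""

    demo_path: Path
    drug_path: Path
    reac_path: Path
    quarter_label: str
    parse_stats: dict[str, FileParseStats] = field(default_factory=dict)

    @property
    def total_rejected(self) -> int:
        return sum(s.rows_rejected for s in self.parse_stats.values())


def parse_fda_date(raw: str) -> dt.date | None:
    """Parse a FAERS date string (YYYYMMDD, or truncated YYYYMM / YYYY).

    Truncated forms resolve to the first day of the period; anything else
    (including impossible calendar dates) returns ``None``.
    """
    raw = raw.strip()
    if not raw.isdigit():
        return None
    try:
        if len(raw) == 8:
            return dt.date(int(raw[:4]), int(raw[4:6]), int(raw[6:8]))
        if len(raw) == 6:
            return dt.date(int(raw[:4]), int(raw[4:6]), 1)
        if len(raw) == 4:
            return dt.date(int(raw), 1, 1)
    except ValueError:
        return None
    return None


def _read_table(
    path: Path, required: Sequence[str]
) -> tuple[list[dict[str, str]], FileParseStats]:
    """Read one ``$``-delimited table, validating the header and counting rejects."""
    stats = FileParseStats()
    rows: list[dict[str, str]] = []
    with open(path, encoding=ENCODING, newline="") as fh:
        reader = csv.reader(fh, delimiter=DELIMITER, quoting=csv.QUOTE_NONE)
        try:
            header = [h.strip().lower() for h in next(reader)]
        except StopIteration:
            raise MissingColumnError(f"{path}: file is empty, no header line")
        for col in required:
            if col not in header:
                raise MissingColumnError(f"{path}: required column {col!r} missing from header")
        ncol = len(header)
        for record in reader:
            stats.rows_read += 1
            if len(record) != ncol:
                stats.reject("field_count_mismatch")
                continue
            rows.append(dict(zip(header, record)))
            stats.rows_kept += 1
    stats.check()
    return rows, stats


def _dedupe_reactions(terms: Iterable[str]) -> list[str]:
    """Drop duplicate preferred terms (case-insensitive, trimmed), keeping order."""
    seen: set[str] = set()
    out: list[str] = []
    for t in terms:
        t = t.strip()
        key = t.casefold()
        if t and key not in seen:
            seen.add(key)
            out.append(t)
    return out


def read_quarter(bundle: QuarterBundle) -> list[SafetyReport]:
    """Parse one quarter bundle into SafetyReports joined on ``primaryid``.

    One report per kept DEMO row.  Reports lacking any drug or any reaction
    row are retained and flagged (``no_drugs`` / ``no_reactions``), as are
    reports whose receipt date could not be parsed (``missing_date``).
    Malformed rows in any file are rejected, counted by reason in
    ``bundle.parse_stats``, and never silently dropped.
    """
    for p in (bundle.demo_path, bundle.drug_path, bundle.reac_path):
        if not Path(p).exists():
            raise FileNotFoundError(p)

    demo_rows, demo_stats = _read_table(Path(bundle.demo_path), DEMO_COLUMNS)
    drug_rows, drug_stats = _read_table(Path(bundle.drug_path), DRUG_COLUMNS)
    reac_rows, reac_stats = _read_table(Path(bundle.reac_path), REAC_COLUMNS)

    drugs_by_report: dict[str, list[DrugEntry]] = {}
    seen_seq: set[tuple[str, int]] = set()
    for row in list(drug_rows):
        pid = row["primaryid"].strip()
        if not pid:
            drug_stats.rows_kept -= 1
            drug_stats.reject("empty_primaryid")
            continue
        try:
            seq = int(row["drug_seq"].strip())
            if seq <= 0:
                raise ValueError
        except ValueError:
            drug_stats.rows_kept -= 1
            drug_stats.reject("bad_drug_seq")
            continue
        role = row["role_cod"].strip().upper()
        if role not in ROLE_CODES:
            drug_stats.rows_kept -= 1
            drug_stats.reject("bad_role_cod")
            continue
        if (pid, seq) in seen_seq:
            drug_stats.rows_kept -= 1
            drug_stats.reject("duplicate_drug_seq")
            continue
        seen_seq.add((pid, seq))
        ai = row.get("prod_ai", "").strip()
        drugs_by_report.setdefault(pid, []).append(
            DrugEntry(
                report_id=pid,
                seq=seq,
                role_code=role,
                verbatim_name=row["drugname"].strip(),
                active_ingredient=ai or None,
            )
        )

    reac_by_report: dict[str, list[str]] = {}
    for row in list(reac_rows):
        pid = row["primaryid"].strip()
        pt = row["pt"].strip()
        if not pid or not pt:
            reac_stats.rows_kept -= 1
            reac_stats.reject("empty_primaryid" if not pid else "empty_pt")
            continue
        reac_by_report.setdefault(pid, []).append(pt)

    reports: list[SafetyReport] = []
    seen_pid: set[str] = set()
    for row in demo_rows:
        pid = row["primaryid"].strip()
        if not pid:
            demo_stats.rows_kept -= 1
            demo_stats.reject("empty_primaryid")
            continue
        if pid in seen_pid:
            demo_stats.rows_kept -= 1
            demo_stats.reject("duplicate_primaryid")
            continue
        seen_pid.add(pid)
        raw_version = row["caseversion"].strip()
        if not raw_version:
            version = 0
        else:
            try:
                version = int(raw_version)
                if version < 0:
                    raise ValueError
            except ValueError:
                demo_stats.rows_kept -= 1
                demo_stats.reject("bad_caseversion")
                continue
        date = parse_fda_date(row["fda_dt"])
        report = SafetyReport(
            primary_id=pid,
            case_id=row["caseid"].strip() or pid,
            case_version=version,
            receipt_date=date,
            drugs=sorted(drugs_by_report.get(pid, []), key=lambda d: d.seq),
            reactions=_dedupe_reactions(reac_by_report.get(pid, [])),
        )
        if date is None:
            report.flags.add("missing_date")
        if not report.drugs:
            report.flags.add("no_drugs")
        if not report.reactions:
            report.flags.add("no_reactions")
        reports.append(report)

    for s in (demo_stats, drug_stats, reac_stats):
        s.check()
    bundle.parse_stats = {"demo": demo_stats, "drug": drug_stats, "reac": reac_stats}
    return reports


def _sanitize(value: str) -> str:
    # The dialect has no quoting convention: delimiter and newline characters
    # cannot be represented and are stripped on write.
    return value.replace(DELIMITER, "").replace("\n", " ").replace("\r", " ")


def _date_out(date: dt.date | None) -> str:
    return date.strftime("%Y%m%d") if date is not None else ""


def write_quarter(
    reports: Iterable[SafetyReport], out_dir: Path | str, quarter_label: str
) -> QuarterBundle:
    """Emit DEMO/DRUG/REAC files in the FAERS dialect for one quarter.

    ``read_quarter(write_quarter(x))`` reproduces ``x`` up to field ordering.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    demo_path = out_dir / f"DEMO{quarter_label}.txt"
    drug_path = out_dir / f"DRUG{quarter_label}.txt"
    reac_path = out_dir / f"REAC{quarter_label}.txt"

    with open(demo_path, "w", encoding=ENCODING, newline="") as fd, open(
        drug_path, "w", encoding=ENCODING, newline=""
    ) as fg, open(reac_path, "w", encoding=ENCODING, newline="") as fr:
        fd.write(DELIMITER.join(DEMO_COLUMNS) + "\n")
        fg.write(DELIMITER.join(DRUG_COLUMNS) + "\n")
        fr.write(DELIMITER.join(REAC_COLUMNS) + "\n")
        for r in reports:
            fd.write(
                DELIMITER.join(
                    (
                        _sanitize(r.primary_id),
                        _sanitize(r.case_id),
                        str(r.case_version),
                        _date_out(r.receipt_date),
                    )
                )
                + "\n"
            )
            for d in r.drugs:
                fg.write(
                    DELIMITER.join(
                        (
                            _sanitize(r.primary_id),
                            str(d.seq),
                            d.role_code,
                            _sanitize(d.verbatim_name),
                            _sanitize(d.active_ingredient or ""),
                        )
                    )
                    + "\n"
                )
            for pt in r.reactions:
                fr.write(DELIMITER.join((_sanitize(r.primary_id), _sanitize(pt))) + "\n")

    return QuarterBundle(
        demo_path=demo_path,
        drug_path=drug_path,
        reac_path=reac_path,
        quarter_label=quarter_label,
    )


# ---------------------------------------------------------------------------
# Cleaned-series interchange CSV.  Nested drug / reaction lists are JSON-encoded
# per cell so the file stays plain CSV with a fixed, documented column order.

SERIES_COLUMNS = (
    "primary_id",
    "case_id",
    "case_version",
    "receipt_date",
    "drugs",
    "reactions",
    "flags",
)


def write_series_csv(reports: Iterable[SafetyReport], path: Path | str) -> None:
    records = []
    for r in reports:
        records.append(
            {
                "primary_id": r.primary_id,
                "case_id": r.case_id,
                "case_version": r.case_version,
                "receipt_date": r.receipt_date.isoformat() if r.receipt_date else "",
                "drugs": json.dumps(
                    [[d.seq, d.role_code, d.verbatim_name, d.active_ingredient] for d in r.drugs]
                ),
                "reactions": json.dumps(r.reactions),
                "flags": json.dumps(sorted(r.flags)),
            }
        )
    frame = pd.DataFrame(records, columns=list(SERIES_COLUMNS))
    frame.to_csv(path, index=False)


def read_series_csv(path: Path | str) -> list[SafetyReport]:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in SERIES_COLUMNS:
        if col not in frame.columns:
            raise MissingColumnError(f"{path}: required column {col!r} missing")
    reports = []
    for row in frame.itertuples(index=False):
        pid = row.primary_id
        reports.append(
            SafetyReport(
                primary_id=pid,
                case_id=row.case_id,
                case_version=int(row.case_version),
                receipt_date=dt.date.fromisoformat(row.receipt_date) if row.receipt_date else None,
                drugs=[
                    DrugEntry(pid, int(seq), role, name, ai if ai else None)
                    for seq, role, name, ai in json.loads(row.drugs)
                ],
                reactions=list(json.loads(row.reactions)),
                flags=set(json.loads(row.flags)),
            )
        )
    return reports
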