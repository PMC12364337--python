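"""Synthetic spontaneous-report generator with known ground truth.

Real FAERS snapshots are large, versioned and messy; validating a
disproportionality pipeline against them proves nothing because the true
drug–event odds ratios are unknown.  This generator emits FAERS-shaped
datasets where they *are* known: per-report drug exposures drawn from
marginal probabilities, reaction preferred terms drawn from background
rates, and selected (drug, event) pairs injected at a specified odds
ratio via the inverse-odds construction

    p1 = OR * p0 / (1 - p0 + OR * p0)

so that odds(p1)/odds(p0) equals the target OR exactly.  It also emulates
the database artifacts the cleaning stage exists for: versioned duplicate
cases, secondary-suspect/concomitant role codes on target-drug mentions,
and verbatim drug-name noise (brand names, dose strings, case changes).

Two views of the same draw are exposed: :func:`sample_population` returns
boolean exposure/event/role matrices (fast path for large simulation
studies), and :func:`generate` materializes full :class:`SafetyReport`
objects from the identical sample, so counts agree exactly between them.
Drug exposures are independent across drugs — no co-prescription
correlation — which is sufficient for exercising counting and statistics.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .cleaning import AnalysisWindow, DEFAULT_WINDOW
from .disproportionality import ContingencyTable
from .faers_io import DrugEntry, QuarterBundle, SafetyReport, write_quarter
from .reference import REFERENCE_ROWS

__all__ = [
    "SyntheticConfig",
    "PopulationArrays",
    "default_config",
    "event_prob_given_exposure",
    "sample_population",
    "contingency_from_population",
    "generate",
    "emit_quarters",
]

#: Reaction given to reports that drew no event, so every report has >= 1
#: preferred term like real submissions do.  Never use it as a target event.
FILLER_REACTION = "Drug ineffective"

#: Drug entry given to reports that drew no exposure.
FILLER_DRUG = "OTHER MEDICATION"

_BRANDS: dict[str, tuple[str, ...]] = {
    "CRIZOTINIB": ("XALKORI",),
    "CERITINIB": ("ZYKADIA",),
    "ALECTINIB": ("ALECENSA",),
    "BRIGATINIB": ("ALUNBRIG",),
    "LORLATINIB": ("LORBRENA", "LORVIQUA"),
}

_DOSE_SUFFIXES = (" 250MG", " 100 MG", " TABLET", " CAPSULES")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; the defaults of :func:`default_config` define
    the simulated study design."""

    n_reports: int
    drug_vocab: tuple[tuple[str, float], ...]
    event_vocab: tuple[tuple[str, float], ...]
    injected_signals: tuple[tuple[str, str, float], ...] = ()
    duplicate_rate: float = 0.0
    secondary_role_rate: float = 0.0
    date_range: AnalysisWindow = DEFAULT_WINDOW
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        drug_names = [n for n, _ in self.drug_vocab]
        event_terms = [t for t, _ in self.event_vocab]
        if len(set(drug_names)) != len(drug_names):
            raise ValueError("duplicate drug names in vocabulary")
        if len(set(event_terms)) != len(event_terms):
            raise ValueError("duplicate event terms in vocabulary")
        for name, p in list(self.drug_vocab) + list(self.event_vocab):
            if not 0.0 < p < 1.0:
                raise ValueError(f"probability for {name!r} must be in (0, 1), got {p}")
        for drug, event, odds_ratio in self.injected_signals:
            if drug not in drug_names:
                raise ValueError(f"injected drug {drug!r} not in drug vocabulary")
            if event not in event_terms:
                raise ValueError(f"injected event {event!r} not in event vocabulary")
            if odds_ratio <= 0:
                raise ValueError("target odds ratio must be positive")
        for rate in (self.duplicate_rate, self.secondary_role_rate):
            if not 0.0 <= rate < 1.0:
                raise ValueError("rates must lie in [0, 1)")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


def default_config(n_reports: int = 100_000, seed: int = 0) -> SyntheticConfig:
    """The default simulated study: five ALK inhibitors against a background
    of common co-reported drugs, with effusion signals injected at the
    published odds-ratio regime.

    Exposure and background-event probabilities are scaled so that at the
    default population size every injected pair is expected to clear (or
    sit near) the ten-report signal floor, mimicking the rare-event counts
    of the real analysis at desk scale.
    """
    drug_vocab = (
        ("CRIZOTINIB", 0.010),
        ("CERITINIB", 0.004),
        ("ALECTINIB", 0.010),
        ("BRIGATINIB", 0.005),
        ("LORLATINIB", 0.006),
        ("ASPIRIN", 0.050),
        ("METFORMIN", 0.040),
        ("LISINOPRIL", 0.030),
        ("ATORVASTATIN", 0.040),
        ("IBUPROFEN", 0.030),
        ("OSIMERTINIB", 0.006),
        ("IMATINIB", 0.008),
        ("PEMBROLIZUMAB", 0.010),
    )
    event_vocab = (
        ("Pleural effusion", 0.006),
        ("Pericardial effusion", 0.003),
        ("Nausea", 0.050),
        ("Dyspnoea", 0.030),
        ("Fatigue", 0.040),
        ("Headache", 0.030),
        ("Diarrhoea", 0.030),
    )
    injected = tuple((drug, event, ror) for drug, event, ror, _, _, _ in REFERENCE_ROWS)
    return SyntheticConfig(
        n_reports=n_reports,
        drug_vocab=drug_vocab,
        event_vocab=event_vocab,
        injected_signals=injected,
        duplicate_rate=0.08,
        secondary_role_rate=0.15,
        date_range=DEFAULT_WINDOW,
        seed=seed,
    )


def event_prob_given_exposure(target_or: float, p0: float) -> float:
    """Event probability among exposed reports yielding exactly the target OR.

    Inverts the odds ratio: with background probability ``p0`` the exposed
    probability ``p1 = OR*p0 / (1 - p0 + OR*p0)`` satisfies
    odds(p1)/odds(p0) == OR.
    """
    if not 0.0 < p0 < 1.0:
        raise ValueError("background probability must be in (0, 1)")
    if target_or <= 0:
        raise ValueError("target odds ratio must be positive")
    return (target_or * p0) / (1.0 - p0 + target_or * p0)


@dataclass
class PopulationArrays:
    """Boolean matrices of one sampled population (cases, pre-duplication).

    ``exposure[i, j]`` — report i mentions drug j; ``demoted[i, j]`` — that
    mention carries a secondary (SS/C) role instead of PS; ``events[i, k]``
    — report i lists event term k.
    """

    drug_names: tuple[str, ...]
    event_terms: tuple[str, ...]
    exposure: np.ndarray
    demoted: np.ndarray
    events: np.ndarray


def sample_population(config: SyntheticConfig, rng: np.random.Generator) -> PopulationArrays:
    """Draw the exposure/role/event matrices for ``config.n_reports`` cases."""
    n = config.n_reports
    drug_names = tuple(name for name, _ in config.drug_vocab)
    event_terms = tuple(term for term, _ in config.event_vocab)
    p_drug = np.array([p for _, p in config.drug_vocab])
    p_event = np.array([p for _, p in config.event_vocab])

    exposure = rng.random((n, len(drug_names))) < p_drug
    demoted = rng.random((n, len(drug_names))) < config.secondary_role_rate

    prob = np.broadcast_to(p_event, (n, len(event_terms))).copy()
    for drug, event, target_or in config.injected_signals:
        j = drug_names.index(drug)
        k = event_terms.index(event)
        p1 = event_prob_given_exposure(target_or, p_event[k])
        # A report exposed to several injected drugs for one event takes the
        # largest elevated probability.
        prob[:, k] = np.where(exposure[:, j], np.maximum(prob[:, k], p1), prob[:, k])
    events = rng.random((n, len(event_terms))) < prob

    return PopulationArrays(drug_names, event_terms, exposure, demoted, events)


def contingency_from_population(
    pop: PopulationArrays,
    drug: str,
    event: str,
    require_primary_suspect: bool = True,
) -> ContingencyTable:
    """2x2 counts straight from the population matrices (fast simulation path)."""
    j = pop.drug_names.index(drug)
    k = pop.event_terms.index(event)
    exposed = pop.exposure[:, j].copy()
    if require_primary_suspect:
        exposed &= ~pop.demoted[:, j]
    ev = pop.events[:, k]
    a = int(np.sum(exposed & ev))
    b = int(np.sum(exposed & ~ev))
    c = int(np.sum(~exposed & ev))
    d = int(np.sum(~exposed & ~ev))
    return ContingencyTable(a, b, c, d)


def _verbatim_name(
    canonical: str, brand_u: float, dose_u: float, case_u: float
) -> str:
    name = canonical
    brands = _BRANDS.get(canonical)
    if brands and brand_u < 0.25:
        name = brands[int(brand_u / 0.25 * len(brands))]
    if dose_u < 0.2:
        name = name + _DOSE_SUFFIXES[int(dose_u / 0.2 * len(_DOSE_SUFFIXES))]
    if case_u < 0.3:
        name = name.lower()
    return name


def generate(config: SyntheticConfig) -> list[SafetyReport]:
    """Materialize the sampled population as SafetyReports.

    Deterministic for a fixed config (seed included).  Base cases get
    ``case_version`` 1; a ``duplicate_rate`` fraction are re-emitted as a
    version-2 follow-up that differs only in ``case_version`` and
    ``receipt_date``, so deduplication must restore exactly one report per
    case.  Target-drug mentions default to role PS and are demoted to
    SS or C at ``secondary_role_rate``.
    """
    rng = np.random.default_rng(config.seed)
    pop = sample_population(config, rng)
    n = config.n_reports
    n_drugs = len(pop.drug_names)

    start = config.date_range.start
    span_days = (config.date_range.end - start).days
    date_offsets = rng.integers(0, span_days + 1, size=n)
    dup_mask = rng.random(n) < config.duplicate_rate
    dup_offsets = rng.integers(0, span_days + 1, size=n)
    role_u = rng.random((n, n_drugs))  # SS vs C choice for demoted mentions
    brand_u = rng.random((n, n_drugs))
    dose_u = rng.random((n, n_drugs))
    case_u = rng.random((n, n_drugs))
    ai_u = rng.random((n, n_drugs))

    reports: list[SafetyReport] = []
    for i in range(n):
        case_id = f"SC{i:08d}"
        primary_id = f"{case_id}.1"
        drugs: list[DrugEntry] = []
        seq = 0
        for j in np.flatnonzero(pop.exposure[i]):
            seq += 1
            canonical = pop.drug_names[j]
            if pop.demoted[i, j]:
                role = "SS" if role_u[i, j] < 0.5 else "C"
            else:
                role = "PS"
            drugs.append(
                DrugEntry(
                    report_id=primary_id,
                    seq=seq,
                    role_code=role,
                    verbatim_name=_verbatim_name(
                        canonical, brand_u[i, j], dose_u[i, j], case_u[i, j]
                    ),
                    active_ingredient=canonical if ai_u[i, j] < 0.7 else None,
                )
            )
        if not drugs:
            drugs.append(DrugEntry(primary_id, 1, "PS", FILLER_DRUG))
        reactions = [pop.event_terms[k] for k in np.flatnonzero(pop.events[i])]
        if not reactions:
            reactions = [FILLER_REACTION]
        reports.append(
            SafetyReport(
                primary_id=primary_id,
                case_id=case_id,
                case_version=1,
                receipt_date=start + dt.timedelta(days=int(date_offsets[i])),
                drugs=drugs,
                reactions=reactions,
            )
        )

    # Follow-up versions: identical content, new version number and date.
    for i in np.flatnonzero(dup_mask):
        base = reports[i]
        primary_id = f"{base.case_id}.2"
        reports.append(
            SafetyReport(
                primary_id=primary_id,
                case_id=base.case_id,
                case_version=2,
                receipt_date=start + dt.timedelta(days=int(dup_offsets[i])),
                drugs=[replace(d, report_id=primary_id) for d in base.drugs],
                reactions=list(base.reactions),
            )
        )
    return reports


def emit_quarters(
    reports: list[SafetyReport],
    out_dir: Path | str,
    n_quarters: int = 1,
    label_prefix: str = "SYN",
) -> list[QuarterBundle]:
    """Partition reports by receipt date into FAERS-dialect file bundles.

    Reports are split over ``n_quarters`` equal date spans (undated reports
    go to the first bundle) and written sorted by (date, primary_id) so
    output files are byte-stable for a fixed input.
    """
    if n_quarters < 1:
        raise ValueError("n_quarters must be >= 1")
    dated = [r.receipt_date for r in reports if r.receipt_date is not None]
    if not dated or n_quarters == 1:
        bins = [list(reports)]
    else:
        lo, hi = min(dated), max(dated)
        span = (hi - lo).days + 1
        bins = [[] for _ in range(n_quarters)]
        for r in reports:
            if r.receipt_date is None:
                bins[0].append(r)
            else:
                idx = min(((r.receipt_date - lo).days * n_quarters) // span, n_quarters - 1)
                bins[idx].append(r)
    bundles = []
    for q, chunk in enumerate(bins, start=1):
        chunk.sort(key=lambda r: (r.receipt_date or dt.date.min, r.primary_id))
        bundles.append(write_quarter(chunk, out_dir, f"{label_prefix}{q:02d}"))
    return bundles
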