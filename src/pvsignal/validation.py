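"""Validation studies: estimator calibration, recovery, and consistency audits.

These are the package's own evidence that the estimator and the counting
machinery behave: a log-symmetry audit of published reference intervals,
Monte-Carlo coverage of the Woolf 95% CI, type-I behaviour of the
tri-criteria signal rule under the null, recovery of an injected odds
ratio through the generator, and an equivalence check between the
object-level counting path and the vectorized population path.

Problem sizes are module defaults chosen to put expected exposed-case
counts in the regime the signal rule operates in (tens of reports per
pair); every study takes an explicit seed.
"""

from __future__ import annotations

import math
import statistics

import numpy as np
import pandas as pd

from .cleaning import DrugSynonymMap, deduplicate
from .disproportionality import (
    ContingencyTable,
    SignalCriteria,
    build_contingency,
    compute_ror,
    implied_ror_from_ci,
)
from .reference import published_estimates
from .synthetic import (
    SyntheticConfig,
    contingency_from_population,
    event_prob_given_exposure,
    generate,
    sample_population,
)

__all__ = [
    "woolf_audit",
    "ci_calibration",
    "null_signal_rate",
    "recovery_study",
    "counting_equivalence_mismatches",
]


def woolf_audit() -> pd.DataFrame:
    """Audit published (ROR, CI, n) rows for Woolf log-symmetry and SE plausibility.

    Adds, per row: the ROR implied by the geometric mean of the CI bounds,
    its absolute difference from the printed ROR after two-decimal
    rounding, whether the rounding reproduces the printed value exactly,
    and whether the implied SE(ln ROR) = (ln hi - ln lo) / (2 * 1.96)
    satisfies SE^2 > 1/n — forced by SE^2 = 1/a + 1/b + 1/c + 1/d with
    a = n, so any published row violating it cannot come from a Woolf
    interval on a real table.
    """
    frame = published_estimates().copy()
    implied = [implied_ror_from_ci(lo, hi) for lo, hi in zip(frame.ci_low, frame.ci_high)]
    frame["implied_ror"] = implied
    frame["abs_diff"] = [abs(round(i, 2) - r) for i, r in zip(implied, frame.ror)]
    frame["exact"] = [round(i, 2) == r for i, r in zip(implied, frame.ror)]
    se = [
        (math.log(hi) - math.log(lo)) / (2 * 1.96)
        for lo, hi in zip(frame.ci_low, frame.ci_high)
    ]
    frame["implied_se_log"] = se
    frame["se_plausible"] = [s * s > 1.0 / n for s, n in zip(se, frame.n_reports)]
    return frame


def _cell_probs(true_or: float, p_exposure: float, p0: float) -> np.ndarray:
    p1 = event_prob_given_exposure(true_or, p0)
    return np.array(
        [
            p_exposure * p1,
            p_exposure * (1 - p1),
            (1 - p_exposure) * p0,
            (1 - p_exposure) * (1 - p0),
        ]
    )


def ci_calibration(
    true_or: float = 3.0,
    p_exposure: float = 0.01,
    p0: float = 0.05,
    n: int = 25_000,
    n_sims: int = 10_000,
    seed: int = 0,
) -> float:
    """Empirical coverage of the Woolf 95% CI over multinomial 2x2 tables.

    Defaults put the expected drug-and-event cell near 34 reports, well
    above the asymptotic floor where the log-normal interval is trusted.
    """
    rng = np.random.default_rng(seed)
    tables = rng.multinomial(n, _cell_probs(true_or, p_exposure, p0), size=n_sims)
    covered = 0
    for a, b, c, d in tables:
        res = compute_ror(ContingencyTable(int(a), int(b), int(c), int(d)))
        covered += res.ci_low <= true_or <= res.ci_high
    return covered / n_sims


def null_signal_rate(
    p_exposure: float = 0.01,
    p0: float = 0.10,
    n: int = 15_000,
    n_sims: int = 10_000,
    seed: int = 0,
    criteria: SignalCriteria | None = None,
) -> float:
    """Fraction of null tables (true OR = 1) flagged by the tri-criteria rule.

    Defaults give an expected drug-and-event cell of 15 reports, above the
    ten-report floor so the count criterion alone does not mask the rate.
    """
    rng = np.random.default_rng(seed)
    tables = rng.multinomial(n, _cell_probs(1.0, p_exposure, p0), size=n_sims)
    flagged = 0
    for a, b, c, d in tables:
        res = compute_ror(ContingencyTable(int(a), int(b), int(c), int(d)), criteria)
        flagged += res.is_signal
    return flagged / n_sims


def _recovery_config(seed: int, n_reports: int, target_or: float) -> SyntheticConfig:
    return SyntheticConfig(
        n_reports=n_reports,
        drug_vocab=(("CRIZOTINIB", 0.01), ("ASPIRIN", 0.05)),
        event_vocab=(("Pleural effusion", 0.01), ("Nausea", 0.05)),
        injected_signals=(("CRIZOTINIB", "Pleural effusion", target_or),),
        duplicate_rate=0.0,
        secondary_role_rate=0.15,
        seed=seed,
    )


def recovery_study(
    target_or: float = 8.0,
    n_reports: int = 100_000,
    n_seeds: int = 200,
    base_seed: int = 0,
) -> dict[str, float]:
    """Recover an injected odds ratio across seeded generator replicates.

    For each seed the population is sampled, the primary-suspect-restricted
    2x2 table is built for the injected pair, and the ROR estimated.
    Returns the median estimate, its relative error against the target,
    and the fraction of replicates whose 95% CI contains the target.
    """
    rors: list[float] = []
    covered = 0
    for k in range(n_seeds):
        config = _recovery_config(base_seed + k, n_reports, target_or)
        pop = sample_population(config, np.random.default_rng(config.seed))
        table = contingency_from_population(pop, "CRIZOTINIB", "Pleural effusion")
        res = compute_ror(table)
        rors.append(res.ror)
        covered += res.ci_low <= target_or <= res.ci_high
    median = statistics.median(rors)
    return {
        "median_ror": median,
        "relative_error": abs(median - target_or) / target_or,
        "ci_coverage": covered / n_seeds,
        "n_seeds": n_seeds,
    }


def counting_equivalence_mismatches(
    n_series: int = 100, max_reports: int = 1_000, seed: int = 0
) -> int:
    """Compare object-pipeline counting against the vectorized population path.

    Generates randomized small populations (varying probabilities, injected
    odds ratios, role demotion and duplication), materializes reports, runs
    generate -> deduplicate -> build_contingency, and checks the 2x2 cells
    against counts taken directly off the population matrices.  Returns the
    number of mismatching tables (0 expected).
    """
    rng = np.random.default_rng(seed)
    mismatches = 0
    drug_map = DrugSynonymMap.build("CRIZOTINIB", ["XALKORI"])
    for _ in range(n_series):
        n = int(rng.integers(50, max_reports + 1))
        config = SyntheticConfig(
            n_reports=n,
            drug_vocab=(
                ("CRIZOTINIB", float(rng.uniform(0.02, 0.2))),
                ("ASPIRIN", float(rng.uniform(0.05, 0.3))),
            ),
            event_vocab=(
                ("Pleural effusion", float(rng.uniform(0.02, 0.2))),
                ("Nausea", float(rng.uniform(0.05, 0.3))),
            ),
            injected_signals=(
                ("CRIZOTINIB", "Pleural effusion", float(rng.uniform(0.5, 10.0))),
            ),
            duplicate_rate=float(rng.uniform(0.0, 0.3)),
            secondary_role_rate=float(rng.uniform(0.0, 0.4)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        pop = sample_population(config, np.random.default_rng(config.seed))
        series = deduplicate(generate(config))
        for require_ps in (True, False):
            expected = contingency_from_population(
                pop, "CRIZOTINIB", "Pleural effusion", require_ps
            )
            got = build_contingency(series, drug_map, ["Pleural effusion"], require_ps)
            if got != expected:
                mismatches += 1
    return mismatches
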