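# Methods

## The statistical model

The counting unit throughout is the deduplicated spontaneous report (one
case = one report). For a target drug D and target event set E over a
cleaned case series, reports are cross-classified into the 2×2 table
(a, b, c, d): a = reports matching D and E, b = matching D only,
c = matching E only, d = neither. The background (c, d) is *all* other
reports in the series, kinase inhibitors included; no reports are removed
from the comparator.

The reporting odds ratio and its confidence interval use the Woolf
(log-normal) construction:

    ROR        = (a·d) / (b·c)
    SE(ln ROR) = sqrt(1/a + 1/b + 1/c + 1/d)
    95% CI     = exp(ln ROR ± z·SE),  z = 1.959964

The interval is symmetric on the log scale, so `sqrt(ci_low·ci_high)`
recovers the point estimate — the property `implied_ror_from_ci` uses to
audit published result tables, and the reason the Woolf form was adopted
here: the geometric mean of every reference CI in
`pvsignal.reference` reproduces its printed ROR to two-decimal rounding
(eight of ten rows exactly, the other two within 0.01). A second audit
uses SE² = 1/a + 1/b + 1/c + 1/d ≥ 1/a: with the printed report count
n = a, any row with implied SE² ≤ 1/n could not have come from a Woolf
interval on a real table. All ten reference rows pass.

**Signal rule.** A pair is a signal iff ROR > 2.00 *and* ci_low > 1.00
*and* a ≥ 10. The ROR and CI thresholds are strict inequalities, the
count threshold inclusive, matching the usual phrasing of these criteria
("exceeding 2.00", "above 1.00", "at least ten"). No multiple-testing
correction is applied; the tri-criteria rule itself is the guard against
false positives, and its realized type-I behaviour is measured (below).

**Degenerate tables.** Any zero cell triggers the Haldane–Anscombe
correction (+0.5 to all four cells), flagged as `corrected` in results;
`n_reports` always reports the uncorrected a. An all-zero table raises
`DegenerateTableError` rather than returning NaN; `run_analysis` converts
per-row failures into an `error` column without aborting other rows.

## Cleaning

The cleaning stage implements three documented, testable operations
rather than emulating any specific web tool byte-for-byte:

* **Deduplication** — one report per `case_id`: highest `case_version`
  wins, ties broken by latest receipt date, then by lexicographically
  greatest `primary_id`. Idempotent by construction.
* **Name standardization** — `normalize_drug_name` uppercases, trims,
  collapses whitespace and strips punctuation except hyphens; synonym
  matching is by whole-token containment (multi-token synonyms must
  appear as a contiguous run), so "Xalkori (crizotinib) 250mg" matches
  canonical CRIZOTINIB while "CRIZOTINIBX" does not. Matching consults
  both the verbatim name and the active-ingredient field. With the
  primary-suspect restriction, the *matching entry* must carry role PS.
* **Windowing** — inclusive receipt-date bounds on `fda_dt`, the FDA
  receipt date, parsed as YYYYMMDD with truncated forms (YYYYMM, YYYY)
  resolved to the first day of the period. Which date field a given
  public query tool filters on is not generally documented; receipt date
  was chosen because it is always populated by the regulator rather than
  the reporter, and the choice is isolated in `apply_window`. Reports
  with unparseable dates are dropped by the window stage and appear in
  its attrition count.

Every stage appends a (stage, reports_in, reports_out) provenance triple;
the chain telescopes and is exported as CSV by the CLI. The default
window is 2013-01-01..2023-12-31, the eleven calendar years of the
reference analysis; it is fully configurable.

## The synthetic generator

`pvsignal.synthetic` emulates the statistical structure the analysis
assumes — report-level drug exposure and event occurrence — plus the
database artifacts the cleaning stage exists for:

* Drug exposures are independent Bernoulli draws per drug from marginal
  probabilities (no co-prescription correlation; a deliberate
  simplification — sufficient for exercising counting and estimation,
  not a model of real polypharmacy).
* Event occurrence uses the background probability p0, overridden for
  injected (drug, event, OR) pairs by the inverse-odds construction
  p1 = OR·p0/(1 − p0 + OR·p0), which makes the population odds ratio
  equal the target exactly. A report exposed to several injected drugs
  for one event takes the largest elevated probability.
* A `duplicate_rate` fraction of cases is re-emitted as a version-2
  follow-up differing only in `case_version` and receipt date, so
  deduplication correctness is checkable by exact count.
* Target-drug mentions default to role PS and are demoted to SS or C at
  `secondary_role_rate`, exercising the primary-suspect restriction (and
  introducing the mild real-world attenuation that misclassified roles
  cause).
* Verbatim names mix canonical names, brand names, dose strings and case
  changes; the active-ingredient field is populated 70% of the time.
* Receipt dates are uniform over the configured window; all randomness
  comes from one seeded NumPy generator, so output is reproducible and
  the emitted quarter files are byte-stable.

Two views of one draw exist: `sample_population` (boolean
exposure/role/event matrices; the fast path for simulation studies) and
`generate` (full `SafetyReport` objects from the identical sample). Their
contingency counts are proven equal by test on shared seeds, so large
seed sweeps may use the matrix path without a separate trust argument.

The default configuration is the simulated analogue of the motivating
study: five ALK inhibitors (exposure probabilities 0.004–0.010) over a
background of common co-reported drugs, pleural/pericardial effusion at
background probabilities 0.006/0.003 among background reaction terms, the
ten drug–event pairs injected at the published odds-ratio regime
(4.76–12.57), duplicate rate 0.08, secondary-role rate 0.15, 100,000
reports. These rates are scaled so the rare-event report counts per pair
land in the tens — the regime the signal rule operates in — at a desk-
scale population; real FAERS probabilities are an order of magnitude
smaller against a population an order of magnitude larger.

What passing tests on synthetic data do **not** show: robustness to
correlated co-prescription, reporting biases (severity-driven submission,
stimulated reporting), masking by competing signals, or real verbatim
chaos beyond the modelled noise. The generator validates the machinery,
not the epidemiology.

## Validation studies (`pvsignal.validation`)

Problem sizes are package defaults chosen to put the expected
drug-and-event cell in the tens of reports; all studies take explicit
seeds, and `scripts/acceptance.py` recomputes them end to end.

* **Woolf audit** — the published-interval consistency checks described
  above.
* **CI calibration** — 10,000 multinomial 2×2 tables at true OR = 3
  (exposure 0.01, background event probability 0.05, n = 25,000;
  expected a ≈ 34): empirical 95% CI coverage falls in [0.94, 0.96].
* **Null signal rate** — 10,000 tables at true OR = 1 (expected a = 15):
  the tri-criteria rule flags ≪ 2.5% of replicates (measured ≈ 0.1%,
  since the rule requires ROR > 2 *and* ci_low > 1 jointly).
* **Recovery** — injected OR = 8 (exposure 0.01, background 0.01,
  n = 100,000, secondary-role rate 0.15), 200 seeds: the median estimate
  sits within 5% of 8 (measured ≈ 1–2.5% below, the expected attenuation
  from PS-role misclassification pushing elevated-rate reports into the
  background), and the 95% CI covers the truth at its nominal rate
  within binomial tolerance.
* **Counting equivalence** — 100 randomized series of ≤ 1,000 reports
  with varying probabilities, injected ORs, duplication and demotion:
  the object pipeline (generate → deduplicate → build_contingency) and
  the population-matrix counts agree exactly; the test suite additionally
  compares against an independently written brute-force double loop.
* **Pipeline determinism** — fixed-seed simulate → ingest → analyze run
  twice is byte-identical, with zero rejected rows.

## Numerical and design choices

* z is fixed at 1.959964 rather than recomputed, so results are
  reproducible to the printed digit across SciPy versions.
* The FAERS dialect has no quoting convention; `$` and newlines are
  stripped from field values on write, and round-trips are exact under
  that documented policy.
* Files are decoded as Latin-1 (public extracts contain non-UTF-8
  bytes); parsing rejects are counted per file with reasons, and
  conservation (rows_read = rows_kept + rows_rejected) is an invariant.
* Only the primaryid-era schema (2012Q4+) is parsed; analysis windows
  here never reach the legacy ISR-keyed layout.
* The cleaned-series interchange CSV JSON-encodes the nested drug and
  reaction lists per cell, keeping the file plain text with a fixed
  column order.
* CLI: machine-readable results only in files; logs on stderr; exit code
  2 for configuration errors, 3 for input errors. The report view rounds
  to two decimals while the CSV keeps full precision.

## Known limitations

MedDRA is treated as plain strings — no LLT→PT mapping or SOC rollups;
no probabilistic record linkage across manufacturers' duplicate
submissions (only version-chain deduplication); no PRR, chi-square or
Bayesian shrinkage estimators (IC/EBGM); no time-to-onset or demographic
stratification. The published reference rows are consistency anchors
only: reproducing their absolute values would require the specific
database snapshot they were computed from.
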