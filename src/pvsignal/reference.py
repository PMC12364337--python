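"""Published ALK-inhibitor effusion disproportionality estimates.

Reference rows from a published FAERS disproportionality analysis of the
five ALK inhibitors and pleural/pericardial effusion (reporting odds
ratio, 95% CI, report count per pair).  The package uses them two ways:

* as internal-consistency anchors — every Woolf interval is symmetric on
  the log scale, so the geometric mean of the printed bounds must
  reproduce the printed ROR to rounding precision, and the implied
  SE(ln ROR) must exceed 1/sqrt(n) because SE^2 = 1/a + 1/b + 1/c + 1/d
  with a = n;
* as the default effect sizes injected by the synthetic-report generator,
  so simulated datasets live in the same odds-ratio regime.

They are anchors for auditing, not values the pipeline reproduces: the
underlying counts come from a dated FAERS snapshot that is not shipped.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["published_estimates", "REFERENCE_ROWS"]

#: (drug, event, ror, ci_low, ci_high, n_reports)
REFERENCE_ROWS: tuple[tuple[str, str, float, float, float, int], ...] = (
    ("CRIZOTINIB", "Pleural effusion", 7.76, 6.60, 9.12, 150),
    ("CRIZOTINIB", "Pericardial effusion", 9.00, 7.10, 11.41, 69),
    ("CERITINIB", "Pleural effusion", 7.36, 5.16, 10.50, 31),
    ("CERITINIB", "Pericardial effusion", 10.80, 6.79, 17.19, 18),
    ("ALECTINIB", "Pleural effusion", 4.76, 3.80, 5.97, 76),
    ("ALECTINIB", "Pericardial effusion", 6.67, 4.92, 9.04, 42),
    ("BRIGATINIB", "Pleural effusion", 8.70, 6.58, 11.52, 50),
    ("BRIGATINIB", "Pericardial effusion", 7.87, 4.95, 12.51, 18),
    ("LORLATINIB", "Pleural effusion", 8.61, 6.72, 11.02, 64),
    ("LORLATINIB", "Pericardial effusion", 12.57, 9.08, 17.38, 37),
)


def published_estimates() -> pd.DataFrame:
    """The reference rows as a DataFrame (drug, event, ror, ci_low, ci_high, n_reports)."""
    return pd.DataFrame(
        REFERENCE_ROWS,
        columns=["drug", "event", "ror", "ci_low", "ci_high", "n_reports"],
    )
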