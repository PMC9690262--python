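"""Published clinical reference data bundled with the package.

The GMFM-88 (Gross Motor Function Measure, 88 items) scores of the
eight children with cerebral palsy who completed the one-month
robot-assisted gait-training program, as published: score before (T0)
and after (T2) training, together with the GMFCS severity level at both
time points and the published change columns.  These values serve as a
worked example for the clinical-statistics workflow (all eight children
improved, giving the extreme exact signed-rank p of 2/2⁸).
"""

from __future__ import annotations

import pandas as pd

_ROWS = [
    # subject, gmfcs_t0, gmfcs_t2, t0, t2, published delta, published delta%
    ("1", "III", "III", 32.10, 42.00, 9.9, 30.8),
    ("2", "IV", "IV", 11.10, 16.10, 3.0, 45.0),
    ("3", "I", "I", 47.20, 49.20, 2.0, 4.1),
    ("4", "IV", "III", 17.20, 25.50, 8.3, 48.3),
    ("5", "IV", "III", 30.00, 36.30, 6.3, 21.0),
    ("6", "IV", "III", 16.00, 24.30, 8.3, 51.9),
    ("7", "V", "IV", 15.50, 22.40, 6.9, 44.5),
    ("8", "IV", "III", 12.40, 16.30, 3.9, 31.4),
]


def gmfm88_cohort() -> pd.DataFrame:
    """The published GMFM-88 pre/post scores of the eight-child cohort.

    Columns: subject, gmfcs_t0, gmfcs_t2, t0, t2, published_delta,
    published_delta_pct.  Note the published change columns contain
    printing inconsistencies in some rows (they do not all reproduce
    from the scores at 1-decimal rounding); recompute with
    :func:`thermoengage.stats.clinical_deltas` for consistent values.
    """
    return pd.DataFrame(
        _ROWS,
        columns=["subject", "gmfcs_t0", "gmfcs_t2", "t0", "t2",
                 "published_delta", "published_delta_pct"],
    )
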