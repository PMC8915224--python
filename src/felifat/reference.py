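"""Reconstruction of the published 54-cat validation cohort.

The published study reports visual fat-category counts (14 obese, 20
overweight, 11 normal weight, 9 underweight) and lists the FFR of every
cat whose FFR-based class disagreed with the visual call (4.8, 3.8, 3.3,
1.8, 1.6, 1.1).  Those facts pin down the full 2x2 confusion tables for
both the obesity and the overweight test, so a synthetic per-cat table
can be reconstructed exactly: concordant cats receive a representative
FFR inside their concordant band, discrepant cats the listed values.

The per-cat FFRs other than the six listed ones are stand-ins; only the
class of each cat (not its exact FFR) enters the diagnostics.
"""

from __future__ import annotations

import pandas as pd

# (visual_fc, ffr, n_cats); FFR bands: not_overweight < 1.6,
# overweight [1.6, 3.5), obese >= 3.5.
_COHORT_PLAN = [
    # concordant cats at representative in-band FFRs
    ("obese", 4.9, 13),
    ("overweight", 2.3, 17),
    ("normal", 1.0, 9),
    ("underweight", 0.6, 9),
    # discrepant cats with their individually listed FFRs
    ("overweight", 4.8, 1),  # visually overweight, FFR says obese
    ("overweight", 3.8, 1),  # visually overweight, FFR says obese
    ("obese", 3.3, 1),  # visually obese, FFR says overweight
    ("normal", 1.8, 1),  # visually normal, FFR says overweight
    ("normal", 1.6, 1),  # borderline: FFR exactly at the overweight cutoff
    ("overweight", 1.1, 1),  # visually overweight, FFR says not overweight
]


def reconstructed_cohort() -> pd.DataFrame:
    """Per-cat (cat_id, visual_fc, ffr) table; 54 rows."""
    rows = []
    i = 0
    for fc, ffr, n in _COHORT_PLAN:
        for _ in range(n):
            rows.append({"cat_id": f"ref{i:02d}", "visual_fc": fc, "ffr": ffr})
            i += 1
    return pd.DataFrame(rows)
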