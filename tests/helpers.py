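"""Small builders shared across test modules."""
from __future__ import annotations

import numpy as np
import pandas as pd


def make_cohort(rows: list[dict]) -> pd.DataFrame:
    """Build a cohort frame from sparse row dicts, filling defaults."""
    out = []
    for i, row in enumerate(rows):
        base = {
            "id": f"T{i:04d}",
            "onset_hours": 5.0,
            "nstemi": 0,
        }
        base.update(row)
        out.append(base)
    return pd.DataFrame(out)


def repeat_rows(spec_rows: list[tuple[int, dict]]) -> pd.DataFrame:
    """``spec_rows`` is [(count, row_dict), ...]."""
    rows = []
    for count, row in spec_rows:
        rows.extend([dict(row) for _ in range(count)])
    return make_cohort(rows)
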