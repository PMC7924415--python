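"""Association statistics between demographics and classification outcomes.

Builds per-class contingency tables of resolved outcomes (true/false
positives, true/false negatives, late, "I don't know"), tests row/class
independence with Pearson's chi-square, and measures rank association
between per-volunteer accuracy and each demographic variable with
Kendall's tau-b.
"""

from __future__ import annotations

from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from crowdprior.dataset import ResponseTable
from crowdprior.studydata import OUTCOME_COLUMNS


def outcome_table(
    table: ResponseTable, classes: Mapping[str, Hashable]
) -> pd.DataFrame:
    """Count resolved outcomes per reliability class.

    Columns, in fixed order: true positives (answer 1 on a threat
    image), false positives (answer 1 on a non-threat image), true
    negatives, false negatives, late (code 0, either truth), don't-know
    (code 3, either truth).  The grand total equals volunteers x images
    because every cell of the grid contributes exactly once.
    """
    rows: dict[Hashable, np.ndarray] = {}
    threat = table.truth == 1
    for vi, vid in enumerate(table.volunteer_ids):
        if vid not in classes:
            continue
        out = table.outcomes[vi]
        counts = rows.setdefault(classes[vid], np.zeros(6, dtype=np.int64))
        counts[0] += int(((out == 1) & threat).sum())
        counts[1] += int(((out == 1) & ~threat).sum())
        counts[2] += int(((out == 2) & ~threat).sum())
        counts[3] += int(((out == 2) & threat).sum())
        counts[4] += int((out == 0).sum())
        counts[5] += int((out == 3).sum())
    index = sorted(rows)
    return pd.DataFrame(
        [rows[c] for c in index], index=pd.Index(index, name="class"),
        columns=list(OUTCOME_COLUMNS),
    )


def chi2_independence(counts) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a 2-D count table.

    Returns (statistic, degrees of freedom, upper-tail p-value); no
    continuity correction.  Rows or columns with a zero marginal must
    be dropped by the caller first.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 2 or min(arr.shape) < 2:
        raise ValueError("need a table with at least 2 rows and 2 columns")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise ValueError("zero row or column marginal; drop empty strata first")
    stat, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return float(stat), int(df), float(p)


def kendall_tau(u: Sequence[float], v: Sequence[float]) -> float:
    """Kendall's tau-b (tie-corrected) rank correlation."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1 or len(u) < 2:
        raise ValueError("need two equal-length 1-D sequences of length >= 2")
    if np.ptp(u) == 0 or np.ptp(v) == 0:
        raise ValueError("rank correlation undefined for a constant sequence")
    return float(stats.kendalltau(u, v, variant="b").statistic)


def volunteer_accuracy(table: ResponseTable) -> pd.Series:
    """Fraction of images each volunteer resolved correctly.

    Correct means answering 1 on a threat image or 2 on a non-threat
    image; late and don't-know responses count as not correct.
    """
    correct = (table.outcomes == table.truth[None, :]).mean(axis=1)
    return pd.Series(correct, index=table.volunteer_ids, name="accuracy")
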