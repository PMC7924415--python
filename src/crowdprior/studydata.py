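"""Published summary tables from the source citizen-science study.

The raw 88-volunteer x 31-image response matrix of the canal-monitoring
project was never deposited, but the study's printed summary tables are
public and serve two purposes here: they seed the default synthetic
population, and the preliminary-analysis statistics can be recomputed
from them directly.

Outcome-count rows follow the fixed column order
(true positives, false positives, true negatives, false negatives,
late responses, "I don't know"); a true/false positive is a "threat"
answer on a threat/non-threat image and a true/false negative a
"no threat" answer on a non-threat/threat image.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

N_IMAGES = 31
N_VOLUNTEERS_KEPT = 88  # filled out the demographic questionnaire
N_VOLUNTEERS_RECRUITED = 91

OUTCOME_COLUMNS = (
    "true_positives",
    "false_positives",
    "true_negatives",
    "false_negatives",
    "late",
    "dont_know",
)

# Outcome counts by interest level (rows: interest 1..5), all 88 kept volunteers.
INTEREST_OUTCOME_COUNTS = pd.DataFrame(
    [
        [85, 118, 110, 124, 24, 35],
        [8, 16, 14, 18, 1, 5],
        [92, 244, 178, 261, 56, 130],
        [103, 256, 205, 236, 41, 89],
        [77, 63, 56, 42, 12, 29],
    ],
    index=pd.Index([1, 2, 3, 4, 5], name="interest"),
    columns=list(OUTCOME_COLUMNS),
)

# Outcome counts by education level (rows: education 2..4; no kept volunteer
# reported level 1 or declined to answer).
EDUCATION_OUTCOME_COUNTS = pd.DataFrame(
    [
        [25, 26, 13, 33, 8, 19],
        [29, 86, 79, 90, 23, 34],
        [311, 585, 471, 558, 103, 235],
    ],
    index=pd.Index([2, 3, 4], name="education"),
    columns=list(OUTCOME_COLUMNS),
)

# Demographic composition of all 91 recruited participants:
# rows = education level (2, 3, 4, non-valid), columns = interest level
# (1..5, non-valid).  The 88 analyzed volunteers are those with valid
# values on both variables.
DEMOGRAPHIC_COMPOSITION = pd.DataFrame(
    [
        [1, 0, 2, 0, 1, 0],
        [2, 0, 3, 4, 2, 0],
        [13, 2, 26, 26, 6, 1],
        [0, 0, 0, 0, 0, 2],
    ],
    index=pd.Index(["2", "3", "4", "NA"], name="education"),
    columns=pd.Index(["1", "2", "3", "4", "5", "NA"], name="interest"),
)


def interest_class_sizes() -> pd.Series:
    """Kept-volunteer counts per interest level, recovered from the outcome
    counts (each volunteer contributes exactly one outcome per image)."""
    sizes = INTEREST_OUTCOME_COUNTS.sum(axis=1) // N_IMAGES
    return sizes.astype(int)


def education_class_sizes() -> pd.Series:
    sizes = EDUCATION_OUTCOME_COUNTS.sum(axis=1) // N_IMAGES
    return sizes.astype(int)


def kept_education_distribution() -> np.ndarray:
    """Probability vector over education levels 1..5 among kept volunteers."""
    probs = np.zeros(5)
    sizes = education_class_sizes()
    for level, n in sizes.items():
        probs[level - 1] = n / sizes.sum()
    return probs
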