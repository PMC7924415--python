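"""Domain types and plumbing for volunteer response data.

Outcome codes follow the study convention for a timed binary image
classification: 0 = no answer within the time limit, 1 = "threat",
2 = "no threat", 3 = "I don't know".  Ground-truth labels are 1 (the
image contains a threat) and 2 (it does not).  Demographic attributes
are two ordinal variables on 1..5: interest toward the environment
(1 = not at all, 5 = very much) and education level (1 = high school
or less .. 4 = graduate/professional degree, 5 = prefers not to answer).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

OUTCOME_CODES = (0, 1, 2, 3)
TRUTH_LABELS = (1, 2)
DEMOGRAPHIC_RANGE = (1, 2, 3, 4, 5)


class DatasetError(ValueError):
    """Raised for malformed or inconsistent input files."""


class Explanatory(str, Enum):
    """Which demographic variable(s) define the reliability classes."""

    INTEREST = "interest"
    EDUCATION = "education"
    BOTH = "both"


@dataclass(frozen=True)
class DemographicProfile:
    """Validated demographic record of one volunteer.

    Education code 5 ("prefer not to answer") is a legitimate class of
    its own, not a missing value.
    """

    interest: int
    education: int

    def __post_init__(self) -> None:
        if self.interest not in DEMOGRAPHIC_RANGE:
            raise DatasetError(f"interest {self.interest!r} outside 1..5")
        if self.education not in DEMOGRAPHIC_RANGE:
            raise DatasetError(f"education {self.education!r} outside 1..5")


@dataclass(frozen=True)
class PoolSplit:
    """Disjoint partition of the volunteer pool into training and test sets."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise DatasetError("train and test pools overlap")


@dataclass
class ResponseTable:
    """Complete volunteer x image grid of outcome codes plus ground truth.

    The grid has no missing cells: a volunteer who gave no answer for an
    image is recorded with outcome code 0, so every (volunteer, image)
    pair carries exactly one code.
    """

    volunteer_ids: list[str]
    image_ids: list[str]
    outcomes: np.ndarray  # shape (n_volunteers, n_images), dtype int
    truth: np.ndarray  # shape (n_images,), values in {1, 2}

    def __post_init__(self) -> None:
        self.outcomes = np.asarray(self.outcomes, dtype=np.int64)
        self.truth = np.asarray(self.truth, dtype=np.int64)
        n_v, n_i = len(self.volunteer_ids), len(self.image_ids)
        if self.outcomes.shape != (n_v, n_i):
            raise DatasetError(
                f"outcome grid shape {self.outcomes.shape} does not match "
                f"{n_v} volunteers x {n_i} images"
            )
        if self.truth.shape != (n_i,):
            raise DatasetError("one ground-truth label per image required")
        if not np.isin(self.outcomes, OUTCOME_CODES).all():
            bad = sorted(set(self.outcomes.ravel()) - set(OUTCOME_CODES))
            raise DatasetError(f"outcome codes outside {{0,1,2,3}}: {bad}")
        if not np.isin(self.truth, TRUTH_LABELS).all():
            bad = sorted(set(self.truth.ravel()) - set(TRUTH_LABELS))
            raise DatasetError(f"truth labels outside {{1,2}}: {bad}")
        if len(set(self.volunteer_ids)) != n_v:
            raise DatasetError("duplicate volunteer ids")
        if len(set(self.image_ids)) != n_i:
            raise DatasetError("duplicate image ids")

    @property
    def n_volunteers(self) -> int:
        return len(self.volunteer_ids)

    @property
    def n_images(self) -> int:
        return len(self.image_ids)

    def volunteer_index(self, volunteer_id: str) -> int:
        return self.volunteer_ids.index(volunteer_id)

    def outcomes_for_image(self, image_index: int) -> dict[str, int]:
        """Map volunteer id -> outcome code for one image column."""
        col = self.outcomes[:, image_index]
        return {v: int(col[k]) for k, v in enumerate(self.volunteer_ids)}


def read_responses(responses_path: str | Path, truth_path: str | Path) -> ResponseTable:
    """Read the long-form responses CSV and the per-image truth CSV.

    ``responses.csv`` has header ``volunteer_id,image_id,outcome`` with one
    row per (volunteer, image) pair; ``truth.csv`` has ``image_id,label``.
    The grid must be complete and free of duplicates; any violation raises
    :class:`DatasetError` naming the offending row.
    """
    resp = pd.read_csv(responses_path, dtype={"volunteer_id": str, "image_id": str})
    truth = pd.read_csv(truth_path, dtype={"image_id": str})
    for col in ("volunteer_id", "image_id", "outcome"):
        if col not in resp.columns:
            raise DatasetError(f"{responses_path}: missing column {col!r}")
    for col in ("image_id", "label"):
        if col not in truth.columns:
            raise DatasetError(f"{truth_path}: missing column {col!r}")

    dup = resp.duplicated(subset=["volunteer_id", "image_id"])
    if dup.any():
        row = resp[dup].iloc[0]
        raise DatasetError(
            f"{responses_path}: duplicate row for volunteer "
            f"{row.volunteer_id!r}, image {row.image_id!r}"
        )
    bad = ~resp["outcome"].isin(OUTCOME_CODES)
    if bad.any():
        row = resp[bad].iloc[0]
        raise DatasetError(
            f"{responses_path}: unknown outcome code {row.outcome!r} "
            f"(volunteer {row.volunteer_id!r}, image {row.image_id!r})"
        )
    bad = ~truth["label"].isin(TRUTH_LABELS)
    if bad.any():
        row = truth[bad].iloc[0]
        raise DatasetError(f"{truth_path}: label {row.label!r} outside {{1,2}} for image {row.image_id!r}")
    if truth["image_id"].duplicated().any():
        raise DatasetError(f"{truth_path}: duplicate image id")

    volunteer_ids = sorted(resp["volunteer_id"].unique())
    image_ids = list(truth["image_id"])
    if set(resp["image_id"]) != set(image_ids):
        missing = sorted(set(resp["image_id"]) ^ set(image_ids))
        raise DatasetError(f"image id mismatch between responses and truth: {missing}")

    wide = resp.pivot(index="volunteer_id", columns="image_id", values="outcome")
    wide = wide.reindex(index=volunteer_ids, columns=image_ids)
    if wide.isna().any().any():
        v, i = next(
            (v, i) for v in volunteer_ids for i in image_ids if pd.isna(wide.at[v, i])
        )
        raise DatasetError(f"missing cell: volunteer {v!r} has no outcome for image {i!r}")

    return ResponseTable(
        volunteer_ids=volunteer_ids,
        image_ids=image_ids,
        outcomes=wide.to_numpy(dtype=np.int64),
        truth=truth.set_index("image_id").loc[image_ids, "label"].to_numpy(),
    )


def write_responses(
    table: ResponseTable, responses_path: str | Path, truth_path: str | Path
) -> None:
    """Write a ResponseTable back to the two-file CSV layout."""
    rows = [
        (v, i, int(table.outcomes[vi, ii]))
        for vi, v in enumerate(table.volunteer_ids)
        for ii, i in enumerate(table.image_ids)
    ]
    pd.DataFrame(rows, columns=["volunteer_id", "image_id", "outcome"]).to_csv(
        responses_path, index=False
    )
    pd.DataFrame(
        {"image_id": table.image_ids, "label": table.truth}
    ).to_csv(truth_path, index=False)


def read_demographics(
    path: str | Path, known_ids: Sequence[str]
) -> tuple[dict[str, DemographicProfile], list[str]]:
    """Read ``demographics.csv`` and validate each volunteer's record.

    Returns a (profiles, excluded_ids) pair.  Volunteers whose interest
    or education value cannot be parsed or falls outside 1..5 are placed
    on the excluded list rather than raising, mirroring the usual
    questionnaire-cleaning step that drops participants with non-valid
    answers before analysis.  An id absent from ``known_ids`` is an error.
    """
    df = pd.read_csv(path, dtype={"volunteer_id": str})
    for col in ("volunteer_id", "interest", "education"):
        if col not in df.columns:
            raise DatasetError(f"{path}: missing column {col!r}")
    known = set(known_ids)
    profiles: dict[str, DemographicProfile] = {}
    excluded: list[str] = []
    for _, row in df.iterrows():
        vid = row["volunteer_id"]
        if vid not in known:
            raise DatasetError(f"{path}: unknown volunteer id {vid!r}")
        try:
            profiles[vid] = DemographicProfile(int(row["interest"]), int(row["education"]))
        except (DatasetError, ValueError, TypeError):
            excluded.append(vid)
    return profiles, excluded


def write_demographics(profiles: Mapping[str, DemographicProfile], path: str | Path) -> None:
    pd.DataFrame(
        [(v, p.interest, p.education) for v, p in profiles.items()],
        columns=["volunteer_id", "interest", "education"],
    ).to_csv(path, index=False)


def assign_classes(
    profiles: Mapping[str, DemographicProfile], spec: Explanatory
) -> dict[str, object]:
    """Map each volunteer to a reliability-class index.

    The index is a stable injective encoding of the selected explanatory
    variable(s): the plain integer level for a single variable, and the
    ordered ``(interest, education)`` pair when both are used (up to 25
    classes, of which only the demographically occupied ones appear).
    """
    spec = Explanatory(spec)
    if spec is Explanatory.INTEREST:
        return {v: p.interest for v, p in profiles.items()}
    if spec is Explanatory.EDUCATION:
        return {v: p.education for v, p in profiles.items()}
    return {v: (p.interest, p.education) for v, p in profiles.items()}


def subset_volunteers(table: ResponseTable, keep_ids: Sequence[str]) -> ResponseTable:
    """Restrict a ResponseTable to the given volunteers (order preserved).

    Used to drop volunteers without a valid demographic record before
    any pools are formed.
    """
    keep = set(keep_ids)
    idx = [k for k, v in enumerate(table.volunteer_ids) if v in keep]
    if not idx:
        raise DatasetError("no volunteers left after subsetting")
    return ResponseTable(
        volunteer_ids=[table.volunteer_ids[k] for k in idx],
        image_ids=list(table.image_ids),
        outcomes=table.outcomes[idx, :],
        truth=table.truth.copy(),
    )


def split_pool(
    volunteer_ids: Sequence[str], train_size: int, rng: np.random.Generator
) -> PoolSplit:
    """Draw a uniformly random training subset of exactly ``train_size`` ids.

    The complement becomes the classification (test) pool.  Deterministic
    given the generator state.
    """
    ids = list(volunteer_ids)
    if not 0 < train_size < len(ids):
        raise DatasetError(
            f"train_size {train_size} must lie strictly between 0 and {len(ids)}"
        )
    chosen = rng.choice(len(ids), size=train_size, replace=False)
    chosen_set = set(int(k) for k in chosen)
    train = tuple(ids[k] for k in sorted(chosen_set))
    test = tuple(ids[k] for k in range(len(ids)) if k not in chosen_set)
    return PoolSplit(train_ids=train, test_ids=test)
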