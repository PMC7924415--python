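"""Matched-budget majority-voting baseline.

The baseline votes over exactly the volunteers the Bayesian run
consumed for each image (same sequence, same budget).  Outcome codes
0 (late) and 3 ("I don't know") carry no directional vote and are
discarded — unlike the Bayesian method, which extracts likelihood
information from them.  That asymmetry is deliberate: it is the point
of comparing the two aggregators.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from crowdprior.dataset import ResponseTable
from crowdprior.sequential import ImageClassification


def majority_vote(
    outcomes: Sequence[int],
    rng: np.random.Generator,
    tie_policy: str = "random",
) -> tuple[int, bool]:
    """Plurality vote over binary answers with abstentions dropped.

    Counts codes 1 ("threat") against codes 2 ("no threat"); an equal
    count — including the all-abstain case — is a tie, resolved either
    uniformly at random (``tie_policy="random"``) or deterministically
    as label 2 (``tie_policy="label2"``, for sensitivity checks).
    """
    arr = np.asarray(list(outcomes), dtype=int)
    n1 = int((arr == 1).sum())
    n2 = int((arr == 2).sum())
    if n1 > n2:
        return 1, False
    if n2 > n1:
        return 2, False
    if tie_policy == "label2":
        return 2, True
    return int(rng.integers(1, 3)), True


def matched_majority(
    table: ResponseTable,
    sequence: Sequence[str],
    bayes_results: Sequence[ImageClassification],
    rng: np.random.Generator,
    tie_policy: str = "random",
) -> tuple[list[int], list[bool], float]:
    """Majority vote each image over the Bayesian run's budget.

    For image i the vote is over the first ``n_i`` volunteers of the
    same sequence, where ``n_i`` is the number the Bayesian run
    consumed.  Returns per-image labels, tie flags and the fraction of
    images labeled correctly.
    """
    if len(bayes_results) != table.n_images:
        raise ValueError("one Bayesian result per image required")
    seq_idx = [table.volunteer_index(v) for v in sequence]
    labels: list[int] = []
    ties: list[bool] = []
    for ii, res in enumerate(bayes_results):
        if res.n_used > len(sequence):
            raise ValueError(
                f"image {table.image_ids[ii]!r}: budget {res.n_used} exceeds "
                f"sequence length {len(sequence)}"
            )
        votes = table.outcomes[seq_idx[: res.n_used], ii]
        label, tie = majority_vote(votes, rng, tie_policy=tie_policy)
        labels.append(label)
        ties.append(tie)
    chi_mv = float(np.mean(np.array(labels) == table.truth))
    return labels, ties, chi_mv
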