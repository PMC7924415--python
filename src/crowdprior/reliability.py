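"""Class-conditional response-distribution estimation.

For each reliability class ``c`` the model is the 2x4 table
``P(y = alpha | theta = beta, c)`` over the four outcome codes
(alpha in {0 late, 1 threat, 2 no-threat, 3 don't-know}) for each true
label (beta in {1, 2}).  Responses are pooled over images within a
class because per-image difficulty is assumed away; abstention codes
0 and 3 are counted inside their image's beta stratum, so they carry
likelihood information just like directional answers.

Estimates are smoothed with an additive pseudocount (Laplace by
default) so that a posterior update never divides by zero even when a
(class, beta, alpha) cell was unobserved in a small training pool.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Mapping

import numpy as np

from crowdprior.dataset import PoolSplit, ResponseTable

N_OUTCOMES = 4
N_LABELS = 2


class EstimationError(ValueError):
    """Raised when a probability row cannot be formed from the counts."""


def _probs_from_counts(counts: np.ndarray, pseudocount: float) -> np.ndarray:
    """(counts + eps) / (row total + 4 eps), rows indexed by beta."""
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    if pseudocount == 0 and (totals == 0).any():
        raise EstimationError(
            "a (class, truth-label) stratum has zero observations and "
            "pseudocount is 0; use smoothing or the pooled fallback"
        )
    return (counts + pseudocount) / (totals + N_OUTCOMES * pseudocount)


@dataclass
class ConditionalProbabilityTable:
    """Per-class 2x4 outcome distributions with their raw counts.

    ``counts[c]`` is an integer array of shape (2, 4) indexed by
    (beta - 1, alpha); ``probs(c)`` is the smoothed normalized version.
    """

    counts: dict[Hashable, np.ndarray]
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.pseudocount < 0:
            raise EstimationError("pseudocount must be non-negative")
        clean: dict[Hashable, np.ndarray] = {}
        for cls, grid in self.counts.items():
            grid = np.asarray(grid)
            if grid.shape != (N_LABELS, N_OUTCOMES):
                raise EstimationError(f"class {cls!r}: counts must be 2x4")
            if (grid < 0).any():
                raise EstimationError(f"class {cls!r}: negative counts")
            clean[cls] = grid.astype(np.int64)
        self.counts = clean

    @property
    def classes(self) -> list[Hashable]:
        return list(self.counts)

    def probs(self, cls: Hashable) -> np.ndarray:
        return _probs_from_counts(self.counts[cls], self.pseudocount)

    def pooled_counts(self) -> np.ndarray:
        if not self.counts:
            return np.zeros((N_LABELS, N_OUTCOMES), dtype=np.int64)
        return np.sum([g for g in self.counts.values()], axis=0)

    def pooled_probs(self) -> np.ndarray:
        pooled = self.pooled_counts()
        if pooled.sum() == 0 and self.pseudocount > 0:
            return np.full((N_LABELS, N_OUTCOMES), 1.0 / N_OUTCOMES)
        return _probs_from_counts(pooled, self.pseudocount)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "pseudocount": self.pseudocount,
            "classes": {
                str(cls): {
                    "beta1": self.probs(cls)[0].tolist(),
                    "beta2": self.probs(cls)[1].tolist(),
                    "counts": self.counts[cls].tolist(),
                }
                for cls in self.counts
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def cpt_from_grids(
    grids: Mapping[Hashable, np.ndarray], scale: int = 10**9
) -> ConditionalProbabilityTable:
    """Build a table whose probabilities match given 2x4 grids.

    Intended for the fully-specified-model regime (e.g. supplying a
    synthetic population's true grids to the classifier).  The grids
    are represented as integer counts at a large common denominator, so
    the returned probabilities agree with the inputs to ~1/scale.
    """
    counts = {}
    for cls, grid in grids.items():
        grid = np.asarray(grid, dtype=float)
        if grid.shape != (N_LABELS, N_OUTCOMES):
            raise EstimationError(f"class {cls!r}: grid must be 2x4")
        counts[cls] = np.round(grid * scale).astype(np.int64)
    return ConditionalProbabilityTable(counts=counts, pseudocount=0.0)


def estimate_cpt(
    table: ResponseTable,
    classes: Mapping[str, Hashable],
    split: PoolSplit,
    pseudocount: float = 1.0,
) -> ConditionalProbabilityTable:
    """Estimate the conditional probability table on the training pool.

    Counts every (volunteer, image) outcome of training volunteers into
    the (class, beta, alpha) cell given by the volunteer's class and the
    image's ground truth, then normalizes each (class, beta) row with the
    additive pseudocount.  With ``pseudocount=0`` and a fully observed
    stratum the estimates equal the empirical frequencies exactly.
    """
    if not split.train_ids:
        raise EstimationError("empty training pool")
    missing = [v for v in split.train_ids if v not in classes]
    if missing:
        raise EstimationError(f"no class assignment for training volunteers {missing}")

    counts: dict[Hashable, np.ndarray] = {}
    beta_idx = table.truth - 1  # per-image 0/1
    for vid in split.train_ids:
        cls = classes[vid]
        grid = counts.setdefault(cls, np.zeros((N_LABELS, N_OUTCOMES), dtype=np.int64))
        row = table.outcomes[table.volunteer_index(vid)]
        np.add.at(grid, (beta_idx, row), 1)

    cpt = ConditionalProbabilityTable(counts=counts, pseudocount=pseudocount)
    if pseudocount == 0:
        for cls in cpt.classes:
            cpt.probs(cls)  # raises EstimationError on an empty stratum
    return cpt


def resolve_class_row(
    cpt: ConditionalProbabilityTable, cls: Hashable
) -> tuple[np.ndarray, bool]:
    """Return the 2x4 probability grid for ``cls``, falling back to pooling.

    A class never seen in training (possible under random pool splits when
    a demographic cell has very few members) gets the grid estimated from
    the summed counts of all trained classes; the second element reports
    whether that fallback occurred.
    """
    if cls in cpt.counts:
        return cpt.probs(cls), False
    return cpt.pooled_probs(), True
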