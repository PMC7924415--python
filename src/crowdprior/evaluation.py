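"""Resampling evaluation protocol: accuracy/effort sweep over thresholds.

A *trial* is one (training-set draw, test-sequence permutation) pair:
the conditional probability table is estimated on the training pool,
every image is classified sequentially by the permuted test pool at
threshold sigma, and majority voting is evaluated on exactly the same
sequence and per-image budget.  The sweep averages chi (accuracy) and
nu (volunteers consumed) over m training draws x p permutations for
each sigma and each explanatory-variable choice, and additionally
reports the win-rate pi (percentage of trials where the Bayesian
accuracy strictly exceeds majority voting) and a pooled one-point
ROC/AUC per sigma.

``run_trial`` is the plain per-image reference implementation; the
sweep uses an algebraically identical vectorized path that evaluates
all thresholds at once from the cumulative log-likelihood-ratio matrix
(the posterior crosses sigma exactly when the absolute cumulative
log-odds crosses logit(sigma), since the prior is 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd

from crowdprior.dataset import (
    DemographicProfile,
    Explanatory,
    PoolSplit,
    ResponseTable,
    assign_classes,
    split_pool,
)
from crowdprior.majority import matched_majority
from crowdprior.reliability import ConditionalProbabilityTable, estimate_cpt, resolve_class_row
from crowdprior.sequential import ImageClassification, classify_all


def default_sigma_grid(step: float = 0.02) -> tuple[float, ...]:
    """Thresholds strictly inside (0.5, 1): 0.52, 0.54, ..., 0.98."""
    grid = np.round(np.arange(0.5 + step, 1.0 - 1e-12, step), 10)
    return tuple(float(s) for s in grid if 0.5 < s < 1.0)


@dataclass
class SweepConfig:
    sigma_grid: tuple[float, ...] = field(default_factory=default_sigma_grid)
    m: int = 100  # training-set draws
    p: int = 10  # sequence permutations per draw
    train_size: int = 45
    specs: tuple[Explanatory, ...] = (
        Explanatory.INTEREST,
        Explanatory.EDUCATION,
        Explanatory.BOTH,
    )
    seed: int = 0
    pseudocount: float = 1.0
    tie_policy: str = "random"

    def __post_init__(self) -> None:
        self.sigma_grid = tuple(float(s) for s in self.sigma_grid)
        if any(not 0.5 < s < 1.0 for s in self.sigma_grid):
            raise ValueError("sigma values must lie strictly inside (0.5, 1)")
        if list(self.sigma_grid) != sorted(self.sigma_grid):
            raise ValueError("sigma grid must be sorted ascending")
        if self.m < 1 or self.p < 1:
            raise ValueError("m and p must be positive")
        self.specs = tuple(Explanatory(s) for s in self.specs)


@dataclass
class TrialResult:
    chi_bayes: float
    chi_mv: float
    nu: float
    bayes_results: list[ImageClassification]
    mv_labels: list[int]
    mv_ties: list[bool]


@dataclass
class SweepSummary:
    """Per-(spec, sigma) aggregates as a tidy DataFrame."""

    frame: pd.DataFrame

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def run_trial(
    table: ResponseTable,
    classes: Mapping[str, Hashable],
    split: PoolSplit,
    permutation: Sequence[str],
    sigma: float,
    pseudocount: float,
    rng: np.random.Generator,
    tie_policy: str = "random",
) -> TrialResult:
    """One full trial at a single threshold (reference implementation)."""
    if set(permutation) != set(split.test_ids):
        raise ValueError("permutation must reorder exactly the test pool")
    cpt = estimate_cpt(table, classes, split, pseudocount)
    results, chi_b, nu = classify_all(table, permutation, classes, cpt, sigma, rng)
    mv_labels, mv_ties, chi_mv = matched_majority(
        table, permutation, results, rng, tie_policy=tie_policy
    )
    return TrialResult(
        chi_bayes=chi_b,
        chi_mv=chi_mv,
        nu=nu,
        bayes_results=results,
        mv_labels=mv_labels,
        mv_ties=mv_ties,
    )


def trial_curves(
    table: ResponseTable,
    classes: Mapping[str, Hashable],
    cpt: ConditionalProbabilityTable,
    permutation: Sequence[str],
    sigmas: Sequence[float],
    rng: np.random.Generator,
    tie_policy: str = "random",
) -> dict[str, np.ndarray]:
    """Evaluate one trial at every threshold simultaneously.

    Requires strictly positive likelihoods (any positive pseudocount
    guarantees this), so the cumulative log-likelihood ratio is finite
    and the stopping time at threshold sigma is the first step where
    its absolute value strictly exceeds logit(sigma).
    """
    sigmas = np.asarray(sigmas, dtype=float)
    seq_idx = np.array([table.volunteer_index(v) for v in permutation])
    A = table.outcomes[seq_idx, :]  # (T, I)
    T, I = A.shape
    grids = np.stack([resolve_class_row(cpt, classes[v])[0] for v in permutation])
    if (grids <= 0).any():
        raise ValueError("trial_curves requires strictly positive likelihoods")
    t_ix = np.arange(T)[:, None]
    log_ratio = np.log(grids[t_ix, 0, A]) - np.log(grids[t_ix, 1, A])
    C = np.cumsum(log_ratio, axis=0)  # (T, I) cumulative log odds
    thr = np.log(sigmas / (1.0 - sigmas))  # logit(sigma)

    crossed = np.abs(C)[:, :, None] > thr[None, None, :]  # (T, I, S)
    any_cross = crossed.any(axis=0)  # (I, S)
    n_used = np.where(any_cross, crossed.argmax(axis=0) + 1, T)
    i_ix = np.arange(I)[:, None]
    C_final = C[n_used - 1, i_ix]  # (I, S)
    labels = np.where(C_final > 0, 1, 2)
    bayes_tie = ~any_cross & (C_final == 0)
    if bayes_tie.any():
        labels[bayes_tie] = rng.integers(1, 3, size=int(bayes_tie.sum()))

    votes = np.where(A == 1, 1, np.where(A == 2, -1, 0))
    M = np.cumsum(votes, axis=0)
    M_final = M[n_used - 1, i_ix]
    mv_labels = np.where(M_final > 0, 1, 2)
    mv_tie = M_final == 0
    if mv_tie.any():
        if tie_policy == "label2":
            mv_labels[mv_tie] = 2
        else:
            mv_labels[mv_tie] = rng.integers(1, 3, size=int(mv_tie.sum()))

    truth = table.truth[:, None]
    return {
        "sigmas": sigmas,
        "n_used": n_used,  # (I, S)
        "labels": labels,  # (I, S)
        "mv_labels": mv_labels,
        "chi_bayes": (labels == truth).mean(axis=0),
        "chi_mv": (mv_labels == truth).mean(axis=0),
        "nu": n_used.mean(axis=0).astype(float),
    }


def roc_point(labels: Sequence[int], truth: Sequence[int]) -> tuple[float, float]:
    """Pooled (FPR, TPR) of hard decisions, positive = label 1 (threat)."""
    labels = np.asarray(labels)
    truth = np.asarray(truth)
    pos = truth == 1
    neg = truth == 2
    if not pos.any() or not neg.any():
        raise ValueError("need at least one positive and one negative image")
    tpr = float((labels[pos] == 1).mean())
    fpr = float((labels[neg] == 1).mean())
    return fpr, tpr


def auc_from_point(fpr: float, tpr: float) -> float:
    """Area under the one-point ROC polyline (0,0)-(fpr,tpr)-(1,1)."""
    if not (0.0 <= fpr <= 1.0 and 0.0 <= tpr <= 1.0):
        raise ValueError("fpr and tpr must lie in [0, 1]")
    return (1.0 + tpr - fpr) / 2.0


def run_sweep(
    table: ResponseTable,
    profiles: Mapping[str, DemographicProfile],
    config: SweepConfig,
    true_cpts: Mapping[Explanatory, ConditionalProbabilityTable] | None = None,
) -> SweepSummary:
    """The full m x p resampling experiment over the sigma grid.

    For each explanatory-variable choice: draw m training sets, p test
    permutations each, evaluate every sigma, and average.  All
    randomness derives from ``config.seed`` through a hierarchical
    seed-sequence split (spec -> draw -> permutation), so identical
    configs give bit-identical summaries.  Supplying ``true_cpts``
    skips estimation and uses the given table for every trial (the
    fully-specified-model regime).
    """
    pool_ids = [v for v in table.volunteer_ids if v in profiles]
    sigmas = np.asarray(config.sigma_grid)
    S = len(sigmas)
    rows = []
    root = np.random.SeedSequence(config.seed)
    spec_seeds = root.spawn(len(config.specs))
    for spec, spec_ss in zip(config.specs, spec_seeds):
        classes = assign_classes(
            {v: profiles[v] for v in pool_ids}, spec
        )
        chi_sum = np.zeros(S)
        chi_mv_sum = np.zeros(S)
        nu_sum = np.zeros(S)
        wins = np.zeros(S, dtype=np.int64)
        ties = np.zeros(S, dtype=np.int64)
        conf = np.zeros((S, 4), dtype=np.int64)  # TP, FN, FP, TN pooled
        n_trials = config.m * config.p
        draw_seeds = spec_ss.spawn(config.m)
        for draw_ss in draw_seeds:
            children = draw_ss.spawn(config.p + 1)
            split = split_pool(
                pool_ids, config.train_size, np.random.default_rng(children[0])
            )
            if true_cpts is not None:
                cpt = true_cpts[spec]
            else:
                cpt = estimate_cpt(table, classes, split, config.pseudocount)
            for perm_ss in children[1:]:
                rng = np.random.default_rng(perm_ss)
                perm = [split.test_ids[k] for k in rng.permutation(len(split.test_ids))]
                cur = trial_curves(
                    table, classes, cpt, perm, sigmas, rng, tie_policy=config.tie_policy
                )
                chi_sum += cur["chi_bayes"]
                chi_mv_sum += cur["chi_mv"]
                nu_sum += cur["nu"]
                wins += cur["chi_bayes"] > cur["chi_mv"]
                ties += cur["chi_bayes"] == cur["chi_mv"]
                truth = table.truth[:, None]
                lab = cur["labels"]
                conf[:, 0] += ((lab == 1) & (truth == 1)).sum(axis=0)
                conf[:, 1] += ((lab == 2) & (truth == 1)).sum(axis=0)
                conf[:, 2] += ((lab == 1) & (truth == 2)).sum(axis=0)
                conf[:, 3] += ((lab == 2) & (truth == 2)).sum(axis=0)
        tp, fn, fp, tn = conf.T
        tpr = tp / np.maximum(tp + fn, 1)
        fpr = fp / np.maximum(fp + tn, 1)
        for s in range(S):
            rows.append(
                {
                    "spec": spec.value,
                    "sigma": float(sigmas[s]),
                    "chi_bar": chi_sum[s] / n_trials,
                    "nu_bar": nu_sum[s] / n_trials,
                    "chi_mv_bar": chi_mv_sum[s] / n_trials,
                    "pi_pct": 100.0 * wins[s] / n_trials,
                    "tie_pct": 100.0 * ties[s] / n_trials,
                    "fpr": float(fpr[s]),
                    "tpr": float(tpr[s]),
                    "auc": auc_from_point(float(fpr[s]), float(tpr[s])),
                }
            )
    return SweepSummary(frame=pd.DataFrame(rows))
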