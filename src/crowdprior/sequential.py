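"""Sequential Bayesian classification of one image by a volunteer queue.

Starting from the uninformative prior P(theta = 1) = 0.5, each consumed
volunteer's outcome multiplies the posterior odds by the likelihood
ratio P(alpha | theta=1, class) / P(alpha | theta=2, class) taken from
the class-conditional table.  Classification stops at the first step
where either posterior strictly exceeds the confidence threshold sigma,
or when the volunteer pool is exhausted; the final label is the argmax
of the posterior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Hashable, Mapping, Sequence

import numpy as np

from crowdprior.dataset import ResponseTable
from crowdprior.reliability import ConditionalProbabilityTable, resolve_class_row


class Termination(str, Enum):
    THRESHOLD = "threshold"
    EXHAUSTED = "exhausted"
    EXHAUSTED_TIE = "exhausted_tie"


@dataclass
class PosteriorTrace:
    """Posterior path P_j(theta = 1) with the volunteers that produced it.

    ``p1_values[0]`` is the step-0 prior 0.5; element j is the posterior
    after consuming ``volunteer_sequence[j - 1]``.
    """

    p1_values: list[float]
    volunteer_sequence: list[str]


@dataclass
class ImageClassification:
    label: int  # in {1, 2}
    n_used: int
    final_p1: float
    termination: Termination
    trace: PosteriorTrace


def bayes_update(prior_p1: float, lik_threat: float, lik_no_threat: float) -> float:
    """One Bayes-rule step on P(theta = 1).

    ``lik_threat``/``lik_no_threat`` are P(alpha | theta = 1) and
    P(alpha | theta = 2) for the observed outcome.  A zero denominator
    (outcome impossible under both hypotheses, or an absorbing 0/1
    prior meeting a zero likelihood) leaves the prior unchanged.
    """
    num = lik_threat * prior_p1
    den = num + lik_no_threat * (1.0 - prior_p1)
    if den == 0.0:
        return prior_p1
    return num / den


def batch_posterior(
    likelihood_pairs: Sequence[tuple[float, float]], prior_p1: float = 0.5
) -> float:
    """Closed-form posterior after a whole batch of outcomes, in log space.

    Equals the iterated one-step update because the updates commute:
    the posterior is proportional to prior x product of likelihoods.
    Returns the prior when both products vanish.
    """
    if not likelihood_pairs:
        return prior_p1
    log1 = log2 = 0.0
    for l1, l2 in likelihood_pairs:
        log1 += math.log(l1) if l1 > 0 else -math.inf
        log2 += math.log(l2) if l2 > 0 else -math.inf
    if log1 == -math.inf and log2 == -math.inf:
        return prior_p1
    if prior_p1 == 0.0:
        return 0.0 if log2 > -math.inf else prior_p1
    if prior_p1 == 1.0:
        return 1.0 if log1 > -math.inf else prior_p1
    a = math.log(prior_p1) + log1
    b = math.log(1.0 - prior_p1) + log2
    if a == -math.inf:
        return 0.0
    if b == -math.inf:
        return 1.0
    # p1 = e^a / (e^a + e^b), stabilized
    m = max(a, b)
    ea, eb = math.exp(a - m), math.exp(b - m)
    return ea / (ea + eb)


def classify_image(
    outcomes: Mapping[str, int],
    sequence: Sequence[str],
    classes: Mapping[str, Hashable],
    cpt: ConditionalProbabilityTable,
    sigma: float,
    rng: np.random.Generator,
) -> ImageClassification:
    """Run the sequential update for a single image.

    Volunteers are consumed in ``sequence`` order without replacement;
    the stopping test ``max(p1, 1 - p1) > sigma`` is strict.  If the
    pool is exhausted with the posterior exactly at 0.5 the label is
    drawn uniformly with ``rng`` and recorded as an exhaustion tie.
    """
    if not sequence:
        raise ValueError("empty volunteer sequence")
    if not 0.5 < sigma < 1.0:
        raise ValueError(f"sigma {sigma} must lie in (0.5, 1)")
    p1 = 0.5
    trace = PosteriorTrace(p1_values=[p1], volunteer_sequence=[])
    for vid in sequence:
        if vid not in classes:
            raise KeyError(f"volunteer {vid!r} has no class assignment")
        alpha = outcomes[vid]
        grid, _ = resolve_class_row(cpt, classes[vid])
        p1 = bayes_update(p1, grid[0, alpha], grid[1, alpha])
        trace.p1_values.append(p1)
        trace.volunteer_sequence.append(vid)
        if max(p1, 1.0 - p1) > sigma:
            return ImageClassification(
                label=1 if p1 > 0.5 else 2,
                n_used=len(trace.volunteer_sequence),
                final_p1=p1,
                termination=Termination.THRESHOLD,
                trace=trace,
            )
    if p1 == 0.5:
        return ImageClassification(
            label=int(rng.integers(1, 3)),
            n_used=len(trace.volunteer_sequence),
            final_p1=p1,
            termination=Termination.EXHAUSTED_TIE,
            trace=trace,
        )
    return ImageClassification(
        label=1 if p1 > 0.5 else 2,
        n_used=len(trace.volunteer_sequence),
        final_p1=p1,
        termination=Termination.EXHAUSTED,
        trace=trace,
    )


def classify_all(
    table: ResponseTable,
    sequence: Sequence[str],
    classes: Mapping[str, Hashable],
    cpt: ConditionalProbabilityTable,
    sigma: float,
    rng: np.random.Generator,
) -> tuple[list[ImageClassification], float, float]:
    """Classify every image with the same volunteer sequence.

    The sequence restarts from its first element for each image (each
    image sees the full pool), so a volunteer typically serves many
    images.  Returns the per-image results together with the fraction
    of correctly labeled images (chi) and the mean number of volunteers
    consumed per image (nu).
    """
    results = [
        classify_image(table.outcomes_for_image(ii), sequence, classes, cpt, sigma, rng)
        for ii in range(table.n_images)
    ]
    labels = np.array([r.label for r in results])
    chi = float(np.mean(labels == table.truth))
    nu = float(np.mean([r.n_used for r in results]))
    return results, chi, nu


def results_to_csv(results: Sequence[ImageClassification], image_ids: Sequence[str], path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "image_id": list(image_ids),
            "label": [r.label for r in results],
            "n_used": [r.n_used for r in results],
            "final_p1": [r.final_p1 for r in results],
            "termination": [r.termination.value for r in results],
        }
    ).to_csv(path, index=False)
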