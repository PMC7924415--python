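"""Synthetic volunteer populations with class-conditional response behavior.

The generator draws exactly the data-generating process the classifier
assumes: image truths are i.i.d. Bernoulli(threat_prevalence) mapped to
{1, 2}; each volunteer belongs to a reliability class drawn from the
class proportions; every outcome is drawn independently from the
volunteer's class-conditional 2x4 outcome grid given the image's truth.
Outcomes are exchangeable across images given class and truth — there
is no per-image difficulty, learning, or fatigue.

The default population is seeded from the published outcome-count
tables of the 88-volunteer canal-image study: five interest classes
with the study's class proportions and per-class grids derived from
the printed counts.  The printed tables do not split late and
"don't know" counts by the image's truth, so those columns are divided
across the two truth values proportionally to the threat prevalence —
an explicit modeling assumption, not a published figure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable

import numpy as np
import yaml

from crowdprior.dataset import DemographicProfile, ResponseTable
from crowdprior.studydata import (
    INTEREST_OUTCOME_COUNTS,
    N_IMAGES,
    N_VOLUNTEERS_KEPT,
    interest_class_sizes,
    kept_education_distribution,
)


@dataclass
class PopulationSpec:
    """Parameters of a synthetic volunteer population.

    ``class_grids[c]`` is the true 2x4 table P(alpha | beta, c) with
    rows indexed by beta - 1 and columns by the outcome code alpha.
    Class labels that are integers 1..5 double as the interest level of
    the generated demographic profile; education is drawn independently
    from ``education_probs`` (levels 1..5), defaulting to the study's
    skewed distribution.
    """

    class_labels: list[Hashable]
    class_proportions: list[float]
    class_grids: dict[Hashable, np.ndarray]
    n_volunteers: int = N_VOLUNTEERS_KEPT
    n_images: int = N_IMAGES
    threat_prevalence: float = 0.5
    education_probs: np.ndarray = field(default_factory=kept_education_distribution)
    seed: int = 0

    def __post_init__(self) -> None:
        self.class_proportions = [float(p) for p in self.class_proportions]
        if len(self.class_labels) != len(self.class_proportions):
            raise ValueError("one proportion per class label required")
        if abs(sum(self.class_proportions) - 1.0) > 1e-12:
            raise ValueError("class proportions must sum to 1")
        if min(self.class_proportions) < 0:
            raise ValueError("class proportions must be non-negative")
        if not 0.0 < self.threat_prevalence < 1.0:
            raise ValueError("threat_prevalence must lie in (0, 1)")
        if self.n_volunteers < 1 or self.n_images < 1:
            raise ValueError("need at least one volunteer and one image")
        grids = {}
        for cls in self.class_labels:
            grid = np.asarray(self.class_grids[cls], dtype=float)
            if grid.shape != (2, 4):
                raise ValueError(f"class {cls!r}: grid must be 2x4")
            if (grid < 0).any() or np.abs(grid.sum(axis=1) - 1.0).max() > 1e-12:
                raise ValueError(f"class {cls!r}: grid rows must be distributions")
            grids[cls] = grid
        self.class_grids = grids
        self.education_probs = np.asarray(self.education_probs, dtype=float)
        if self.education_probs.shape != (5,) or abs(self.education_probs.sum() - 1) > 1e-9:
            raise ValueError("education_probs must be a length-5 distribution")


def generate(
    spec: PopulationSpec,
) -> tuple[ResponseTable, dict[str, DemographicProfile], dict[str, Hashable]]:
    """Draw one synthetic dataset: responses, demographics, class map.

    Fully determined by ``spec.seed``.  Returns the complete response
    table (with ground truth), a demographic profile per volunteer, and
    the true class assignment used to generate each volunteer (for
    oracle checks; real analyses recover classes from demographics).
    """
    rng = np.random.default_rng(spec.seed)
    n_v, n_i = spec.n_volunteers, spec.n_images
    width = max(3, len(str(n_v)))
    volunteer_ids = [f"v{k:0{width}d}" for k in range(n_v)]
    image_ids = [f"img{k:03d}" for k in range(n_i)]

    truth = np.where(rng.random(n_i) < spec.threat_prevalence, 1, 2)
    class_idx = rng.choice(len(spec.class_labels), size=n_v, p=spec.class_proportions)
    class_of = {v: spec.class_labels[k] for v, k in zip(volunteer_ids, class_idx)}

    # probs[v, i, :] = grid of volunteer v's class, row selected by truth of i
    grid_stack = np.stack([spec.class_grids[c] for c in spec.class_labels])  # (C,2,4)
    probs = grid_stack[class_idx[:, None], (truth - 1)[None, :], :]  # (V,I,4)
    u = rng.random((n_v, n_i))
    outcomes = (u[:, :, None] >= np.cumsum(probs, axis=2)).sum(axis=2)

    table = ResponseTable(
        volunteer_ids=volunteer_ids,
        image_ids=image_ids,
        outcomes=outcomes,
        truth=truth,
    )
    educations = rng.choice(5, size=n_v, p=spec.education_probs) + 1
    profiles = {}
    for v, k, edu in zip(volunteer_ids, class_idx, educations):
        label = spec.class_labels[k]
        interest = int(label) if isinstance(label, (int, np.integer)) else k + 1
        profiles[v] = DemographicProfile(interest=interest, education=int(edu))
    return table, profiles, class_of


def grids_from_outcome_counts(
    counts, threat_prevalence: float = 0.5
) -> dict[Hashable, np.ndarray]:
    """Turn per-class outcome counts into class-conditional grids.

    ``counts`` is a DataFrame in the fixed column order (TP, FP, TN,
    FN, late, don't-know) with one row per class.  Directional answers
    identify their truth stratum; late and don't-know counts are split
    across the two truth values proportionally to the threat
    prevalence, because each volunteer's exposure to threat images is
    that fraction of the pool.
    """
    q = threat_prevalence
    grids: dict[Hashable, np.ndarray] = {}
    for cls, row in counts.iterrows():
        tp, fp, tn, fn, late, idk = (float(row[c]) for c in counts.columns)
        beta1 = np.array([late * q, tp, fn, idk * q])
        beta2 = np.array([late * (1 - q), fp, tn, idk * (1 - q)])
        grid = np.stack([beta1 / beta1.sum(), beta2 / beta2.sum()])
        grids[cls] = grid
    return grids


def default_population_from_tables(
    threat_prevalence: float = 0.5, seed: int = 0
) -> PopulationSpec:
    """The study-shaped default population: 88 volunteers, 31 images.

    Five interest classes with proportions 16/88, 2/88, 31/88, 30/88,
    9/88 and grids derived from the published per-class outcome counts.
    """
    sizes = interest_class_sizes()
    labels = [int(c) for c in sizes.index]
    proportions = (sizes / sizes.sum()).tolist()
    grids = grids_from_outcome_counts(INTEREST_OUTCOME_COUNTS, threat_prevalence)
    return PopulationSpec(
        class_labels=labels,
        class_proportions=proportions,
        class_grids={int(c): g for c, g in grids.items()},
        n_volunteers=int(sizes.sum()),
        n_images=N_IMAGES,
        threat_prevalence=threat_prevalence,
        seed=seed,
    )


def spec_to_config(spec: PopulationSpec) -> dict:
    """JSON/YAML-serializable form of a PopulationSpec."""
    return {
        "class_labels": [str(c) for c in spec.class_labels],
        "class_proportions": list(spec.class_proportions),
        "class_grids": {
            str(c): spec.class_grids[c].tolist() for c in spec.class_labels
        },
        "n_volunteers": spec.n_volunteers,
        "n_images": spec.n_images,
        "threat_prevalence": spec.threat_prevalence,
        "education_probs": spec.education_probs.tolist(),
        "seed": spec.seed,
    }


def spec_from_config(config: dict) -> PopulationSpec:
    labels: list[Hashable] = []
    for c in config["class_labels"]:
        try:
            labels.append(int(c))
        except (TypeError, ValueError):
            labels.append(str(c))
    grids = {
        lab: np.asarray(config["class_grids"][str(lab)], dtype=float) for lab in labels
    }
    kwargs = {}
    for key in ("n_volunteers", "n_images", "threat_prevalence", "seed"):
        if key in config:
            kwargs[key] = config[key]
    if "education_probs" in config:
        kwargs["education_probs"] = np.asarray(config["education_probs"], dtype=float)
    return PopulationSpec(
        class_labels=labels,
        class_proportions=config["class_proportions"],
        class_grids=grids,
        **kwargs,
    )


def spec_to_yaml(spec: PopulationSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_config(spec), fh, sort_keys=False)


def spec_from_yaml(path) -> PopulationSpec:
    with open(path) as fh:
        return spec_from_config(yaml.safe_load(fh))
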