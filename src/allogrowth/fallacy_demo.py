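"""Bootstrap demonstration of the ecological fallacy on a scalar trait.

Group means can be sharply distinct while individuals overlap heavily, so
classifying a sample as all-one-group by its mean trait needs a minimum
sample size N — and the required N grows when the hypothesis space widens
(e.g. allowing a 50/50 mixed group as well as the two pure groups).  The
motivating example is adult human body mass, where the male and female
means differ by ~11 kg against within-group spreads of ~15-20 kg.

The procedure: resample n values from the true distribution, classify the
sample by which hypothesis mean is nearest the sample mean, and find the
smallest n for which every hypothesis is correctly recovered in at least a
``confidence`` fraction of replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "TraitDistribution",
    "ScenarioSpec",
    "classify_sample",
    "classification_accuracy",
    "minimal_group_size",
]


@dataclass
class TraitDistribution:
    """A labelled trait distribution: empirical sample or normal(mean, sd)."""

    label: str
    mean: Optional[float] = None
    sd: Optional[float] = None
    values: Optional[np.ndarray] = None
    #: mixture of other distributions with equal per-draw probability
    components: Optional[Sequence["TraitDistribution"]] = None

    def __post_init__(self) -> None:
        if self.components is not None:
            return
        if self.values is not None:
            self.values = np.asarray(self.values, dtype=float)
            if len(self.values) == 0:
                raise ValueError(f"{self.label}: empirical sample is empty")
        elif self.mean is None or self.sd is None or self.sd <= 0:
            raise ValueError(f"{self.label}: need values or normal(mean, sd>0)")

    @property
    def expected_mean(self) -> float:
        if self.components is not None:
            return float(np.mean([c.expected_mean for c in self.components]))
        if self.values is not None:
            return float(np.mean(self.values))
        return float(self.mean)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.components is not None:
            # each value's source component drawn independently
            idx = rng.integers(len(self.components), size=n)
            out = np.empty(n)
            for i, comp in enumerate(self.components):
                mask = idx == i
                out[mask] = comp.sample(int(mask.sum()), rng)
            return out
        if self.values is not None:
            return rng.choice(self.values, size=n, replace=True)
        return rng.normal(self.mean, self.sd, size=n)

    def support_range(self) -> tuple[float, float]:
        """Effective support, used only for the disjoint-distribution shortcut."""
        if self.components is not None:
            ranges = [c.support_range() for c in self.components]
            return min(r[0] for r in ranges), max(r[1] for r in ranges)
        if self.values is not None:
            return float(self.values.min()), float(self.values.max())
        return self.mean - 6 * self.sd, self.mean + 6 * self.sd


@dataclass
class ScenarioSpec:
    """Bootstrap scenario: which hypotheses compete, at what confidence."""

    scenario: str = "two_pure_groups"  # or "pure_or_mixed"
    confidence: float = 0.95
    replicates: int = 10_000
    seed: int = 0
    max_n: int = 100_000

    def __post_init__(self) -> None:
        if not (0.5 < self.confidence < 1.0):
            raise ValueError("confidence must lie in (0.5, 1)")
        if self.replicates < 1:
            raise ValueError("replicates must be positive")


def classify_sample(
    sample: np.ndarray, hypotheses: Sequence[TraitDistribution]
) -> str:
    """Assign the hypothesis whose expected mean is nearest the sample mean.

    Ties go to the lowest-index hypothesis.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.size == 0:
        raise ValueError("sample is empty")
    m = float(np.mean(sample))
    dists = [abs(m - h.expected_mean) for h in hypotheses]
    return hypotheses[int(np.argmin(dists))].label


def _hypotheses(dists: Sequence[TraitDistribution], scenario: str
                ) -> list[TraitDistribution]:
    hyps = list(dists)
    if scenario == "pure_or_mixed":
        hyps.append(TraitDistribution(label="mixed", components=list(dists)))
    elif scenario != "two_pure_groups":
        raise ValueError(f"unknown scenario {scenario!r}")
    return hyps


def classification_accuracy(
    n: int,
    hypotheses: Sequence[TraitDistribution],
    replicates: int,
    rng: np.random.Generator,
) -> float:
    """Minimum over hypotheses of the correct-classification rate at size n."""
    worst = 1.0
    means = np.array([h.expected_mean for h in hypotheses])
    for i, truth in enumerate(hypotheses):
        draws = truth.sample((replicates, n) if n > 1 else (replicates, 1), rng)
        sample_means = draws.mean(axis=1)
        # nearest hypothesis mean, ties to lowest index
        d = np.abs(sample_means[:, None] - means[None, :])
        assigned = np.argmin(d, axis=1)
        worst = min(worst, float(np.mean(assigned == i)))
    return worst


def minimal_group_size(
    dists: Sequence[TraitDistribution], scenario: ScenarioSpec
) -> dict:
    """Smallest N at which an all-one-group sample is classified correctly
    at the requested confidence, for every competing hypothesis.

    Search doubles N until the accuracy criterion holds, then bisects.
    Returns ``{"N": int | None, "curve": list[(n, accuracy)], "attainable":
    bool}``; N is None when accuracy plateaus below the confidence level
    (the unknown-composition regime, where classification is effectively
    impossible).
    """
    hyps = _hypotheses(dists, scenario.scenario)
    rng = np.random.default_rng(scenario.seed)

    # disjoint supports: a single observation suffices
    ranges = [d.support_range() for d in dists]
    disjoint = all(
        ranges[i][1] < ranges[j][0] or ranges[j][1] < ranges[i][0]
        for i in range(len(dists))
        for j in range(i + 1, len(dists))
    )
    if disjoint and scenario.scenario == "two_pure_groups":
        acc = classification_accuracy(1, hyps, scenario.replicates, rng)
        if acc >= scenario.confidence:
            return {"N": 1, "curve": [(1, acc)], "attainable": True}

    curve: list[tuple[int, float]] = []

    def ok(n: int) -> bool:
        acc = classification_accuracy(n, hyps, scenario.replicates, rng)
        curve.append((n, acc))
        return acc >= scenario.confidence

    n = 1
    while not ok(n):
        n *= 2
        if n > scenario.max_n:
            return {"N": None, "curve": curve, "attainable": False}
    if n == 1:
        return {"N": 1, "curve": curve, "attainable": True}
    lo, hi = n // 2, n  # lo failed, hi passed
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if ok(mid):
            hi = mid
        else:
            lo = mid
    return {"N": hi, "curve": sorted(curve), "attainable": True}
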