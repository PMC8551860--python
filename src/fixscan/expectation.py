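"""Analytic selfing expectations and pooled-sampling bias simulation.

Two questions are answered here without touching any genotype data:

1. What genotype-class proportions does repeated selfing produce? Under
   selfing, the heterozygote fraction halves every generation and each
   homozygous class gains a quarter of it, so a locus that is heterozygous
   in the BC1 generation reaches (0.71875, 0.0625, 0.21875) after three
   selfings and a pure heterozygote reaches (0.484375, 0.03125, 0.484375)
   after five.

2. How often does pooling a finite number of plants for one DNA sample
   yield a spurious homozygous call? With ``pool_n`` plants drawn
   independently, each belonging to one homozygous class with probability
   ``p_seg``, a homozygous call is triggered when at least ``k_threshold``
   of them fall in that class. The probability is a binomial upper tail;
   the Monte-Carlo estimator here mirrors the pooled-sampling experiment
   and is cross-checked against the closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SegregationTriple",
    "SamplingBiasResult",
    "selfing_segregation",
    "sampling_bias_closed_form",
    "sampling_bias_probability",
    "sampling_bias_grid",
    "BC1_TRIPLE",
    "F1_TRIPLE",
]

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class SegregationTriple:
    """Genotype-class probabilities (elite hom, het, wild hom) at one locus."""

    p_hom_elite: float
    p_het: float
    p_hom_wild: float

    def __post_init__(self) -> None:
        for name, p in zip(("p_hom_elite", "p_het", "p_hom_wild"), self.as_tuple()):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if abs(sum(self.as_tuple()) - 1.0) > _SUM_TOL:
            raise ValueError(f"components sum to {sum(self.as_tuple())}, not 1")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_hom_elite, self.p_het, self.p_hom_wild)

    def as_array(self) -> np.ndarray:
        return np.array(self.as_tuple(), dtype=float)


#: distribution after one backcross to the elite parent (F1 × elite)
BC1_TRIPLE = SegregationTriple(0.5, 0.5, 0.0)
#: fully heterozygous F1 locus
F1_TRIPLE = SegregationTriple(0.0, 1.0, 0.0)


def selfing_segregation(start: SegregationTriple, n_selfings: int) -> SegregationTriple:
    """Genotype-class proportions after ``n_selfings`` generations of selfing.

    Per generation the heterozygote fraction halves and a quarter of it is
    fixed in each homozygous class; homozygotes breed true. The closed form
    after n generations is

    .. math::

        p_{het} = h_0 2^{-n}, \\qquad
        p_{hom} = p_{hom,0} + h_0 (1 - 2^{-n}) / 2

    for each homozygous class.
    """
    if not isinstance(n_selfings, (int, np.integer)):
        raise TypeError("n_selfings must be an integer")
    if n_selfings < 0:
        raise ValueError("n_selfings must be non-negative")
    shrink = 0.5 ** n_selfings
    gain = start.p_het * (1.0 - shrink) / 2.0
    return SegregationTriple(
        p_hom_elite=start.p_hom_elite + gain,
        p_het=start.p_het * shrink,
        p_hom_wild=start.p_hom_wild + gain,
    )


@dataclass(frozen=True)
class SamplingBiasResult:
    """Monte-Carlo estimate of a spurious homozygous pooled call.

    ``estimate`` is P(at least ``k_threshold`` of ``pool_n`` pooled plants
    belong to one fixed homozygous class) when that class segregates at
    per-plant probability ``p_seg``; ``closed_form`` is the exact binomial
    upper tail for the same event.
    """

    p_seg: float
    pool_n: int
    k_threshold: int
    estimate: float
    n_trials: int
    std_error: float
    closed_form: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.estimate <= 1.0:
            raise ValueError("estimate outside [0, 1]")
        if self.std_error < 0:
            raise ValueError("negative standard error")
        if self.pool_n < 1:
            raise ValueError("pool_n must be >= 1")
        if not 1 <= self.k_threshold <= self.pool_n:
            raise ValueError("k_threshold must lie in [1, pool_n]")


def sampling_bias_closed_form(p_seg: float, pool_n: int, k_threshold: int) -> float:
    """Exact P(Binomial(pool_n, p_seg) >= k_threshold)."""
    if not 0.0 <= p_seg <= 1.0:
        raise ValueError("p_seg must lie in [0, 1]")
    if k_threshold > pool_n:
        raise ValueError("k_threshold exceeds pool_n")
    return float(stats.binom.sf(k_threshold - 1, pool_n, p_seg))


def sampling_bias_probability(
    p_seg: float,
    pool_n: int = 12,
    k_threshold: int = 12,
    n_trials: int = 1_000_000,
    seed: int | np.random.SeedSequence | None = None,
) -> SamplingBiasResult:
    """Estimate the spurious-homozygous-call probability by simulation.

    Each trial draws ``pool_n`` plants independently, each belonging to the
    focal homozygous class with probability ``p_seg``, and scores a success
    when at least ``k_threshold`` of them do. One class is reported; by
    symmetry the other class is obtained with ``1 - p_seg - p_het`` (callers
    symmetrise, which avoids double counting when ``p_seg`` != 0.5).
    """
    if not 0.0 <= p_seg <= 1.0:
        raise ValueError("p_seg must lie in [0, 1]")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if pool_n < 1:
        raise ValueError("pool_n must be >= 1")
    if not 1 <= k_threshold <= pool_n:
        raise ValueError("k_threshold must lie in [1, pool_n]")
    rng = np.random.default_rng(seed)
    counts = rng.binomial(pool_n, p_seg, size=n_trials)
    estimate = float(np.mean(counts >= k_threshold))
    std_error = math.sqrt(estimate * (1.0 - estimate) / n_trials)
    return SamplingBiasResult(
        p_seg=p_seg,
        pool_n=pool_n,
        k_threshold=k_threshold,
        estimate=estimate,
        n_trials=n_trials,
        std_error=std_error,
        closed_form=sampling_bias_closed_form(p_seg, pool_n, k_threshold),
    )


def sampling_bias_grid(
    p_min: float = 0.05,
    p_max: float = 0.95,
    step: float = 0.05,
    pool_n: int = 12,
    k_thresholds: tuple[int, ...] = (12, 9),
    n_trials: int = 1_000_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Sampling-bias estimates over a grid of simulated allele segregations.

    Returns one row per (p_seg, k_threshold) combination with columns
    ``p_seg``, ``k_threshold``, ``estimate``, ``std_error``, ``closed_form``.
    """
    if not 0.0 < step <= 0.9:
        raise ValueError("step must lie in (0, 0.9]")
    n_points = int(round((p_max - p_min) / step)) + 1
    p_values = np.round(p_min + step * np.arange(n_points), 12)
    p_values = p_values[(p_values >= 0.0) & (p_values <= 1.0) & (p_values <= p_max + 1e-12)]
    if len(p_values) == 0 or len(k_thresholds) == 0:
        raise ValueError("empty sampling-bias grid")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(p_values) * len(k_thresholds))
    rows = []
    i = 0
    for p in p_values:
        for k in k_thresholds:
            res = sampling_bias_probability(
                float(p), pool_n=pool_n, k_threshold=int(k),
                n_trials=n_trials, seed=children[i],
            )
            i += 1
            rows.append(
                {
                    "p_seg": res.p_seg,
                    "k_threshold": res.k_threshold,
                    "estimate": res.estimate,
                    "std_error": res.std_error,
                    "closed_form": res.closed_form,
                }
            )
    return pd.DataFrame(rows)
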