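"""Mutation-rate bound arithmetic for the switching-mutation screens.

Three simple calculations bracket the rate at which mating-type switching
(re-)arises:

* A *negative screen* of N spores with zero switchers gives a binomial
  zero-class upper limit: the largest rate still compatible with seeing
  nothing, μ_max = 1 − α^(1/N) (exact root of (1−μ)^N = α), with the Poisson
  approximation −ln(α)/N reported alongside.
* Observed fixation events give a *lower bound*:
  events / (generations × populations × opportunities per generation).
* A new genotype arising just before a bottleneck can be lost outright; with
  loss probability q, the observed event rate understates the true rate by
  (1 − q), hence rate / (1 − q).
* The screen's effective sample size is the number of distinct *asci*
  represented among the sampled spores (four spores per ascus are not
  independent); this is a without-replacement occupancy problem solved both
  in closed (hypergeometric) form and by Monte Carlo.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np

__all__ = [
    "ScreenInputs",
    "FixationInputs",
    "AscusSamplingInputs",
    "RateBound",
    "LossProbability",
    "AscusEstimate",
    "binomial_upper_limit",
    "rate_lower_bound",
    "loss_corrected_rate",
    "subsample_loss_probability",
    "independent_asci",
    "plating_density",
    "STUDY_SCENARIOS",
]


@dataclass(frozen=True)
class ScreenInputs:
    """A mutant screen: ``n_screened`` spores examined, ``n_events`` mutant
    colonies found, ``alpha`` the significance level of the bound."""

    n_screened: int
    n_events: int = 0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_screened < 1:
            raise ValueError("n_screened must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")


@dataclass(frozen=True)
class FixationInputs:
    """Fixation events observed across an evolution experiment."""

    n_fixation_events: int
    n_sexual_generations: int
    n_populations: int
    n_opportunities_per_generation: float
    loss_probability: float = 0.0

    def __post_init__(self) -> None:
        if min(self.n_sexual_generations, self.n_populations) < 1:
            raise ValueError("generation and population counts must be positive")
        if self.n_opportunities_per_generation <= 0:
            raise ValueError("n_opportunities_per_generation must be positive")
        if not 0.0 <= self.loss_probability < 1.0:
            raise ValueError("loss_probability must be in [0, 1)")
        if self.n_fixation_events < 0:
            raise ValueError("n_fixation_events must be >= 0")


@dataclass(frozen=True)
class AscusSamplingInputs:
    """Sampling spores from pooled asci."""

    n_asci: int
    n_spores_sampled: int
    spores_per_ascus: int = 4
    n_replicates: int = 1000
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if min(self.n_asci, self.n_spores_sampled, self.spores_per_ascus) < 1:
            raise ValueError("counts must be positive")
        if self.n_spores_sampled > self.n_asci * self.spores_per_ascus:
            raise ValueError(
                f"cannot sample {self.n_spores_sampled} spores from "
                f"{self.n_asci * self.spores_per_ascus} pooled"
            )
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


class RateBound(NamedTuple):
    """Zero-class upper limit: exact binomial root and Poisson approximation."""

    exact: float
    poisson: float
    inputs: ScreenInputs


class LossProbability(NamedTuple):
    """Chance a genotype at frequency f leaves zero copies in a sample of n:
    exact (1−f)^n and Poisson exp(−n·f)."""

    exact: float
    poisson: float
    n_sampled: float
    frequency: float


class AscusEstimate(NamedTuple):
    mc_mean: float
    mc_sd: float
    closed_form: float
    inputs: AscusSamplingInputs


def binomial_upper_limit(inputs: ScreenInputs) -> RateBound:
    """Upper limit on the mutation rate from a screen with zero events.

    The smallest μ whose zero-class probability (1−μ)^N drops to α, i.e.
    μ = 1 − α^(1/N); for N = 10⁶ spores at α = 0.05 this is ≈ 3 × 10⁻⁶.
    """
    if inputs.n_events > 0:
        raise ValueError(
            "the zero-class bound applies only to a negative screen; with observed "
            "events use a likelihood-based rate estimator instead"
        )
    n = inputs.n_screened
    exact = -math.expm1(math.log(inputs.alpha) / n)  # 1 - alpha**(1/n), stably
    poisson = -math.log(inputs.alpha) / n
    return RateBound(exact=exact, poisson=poisson, inputs=inputs)


def rate_lower_bound(inputs: FixationInputs) -> float:
    """Event-count lower bound on the rate per opportunity per sexual
    generation.  E.g. 9 fixations over 25 generations × 20 populations ×
    2.5 × 10⁶ crossover opportunities is 7.2 × 10⁻⁹."""
    if inputs.n_fixation_events == 0:
        warnings.warn(
            "zero fixation events: the result is 0 and is not a lower bound",
            stacklevel=2,
        )
        return 0.0
    denom = (
        inputs.n_sexual_generations
        * inputs.n_populations
        * inputs.n_opportunities_per_generation
    )
    return inputs.n_fixation_events / denom


def loss_corrected_rate(rate: float, loss_probability: float) -> float:
    """Correct an event-count rate for genotypes lost in the subsampling
    bottleneck before they could be observed: rate / (1 − loss)."""
    if not 0.0 <= loss_probability < 1.0:
        raise ValueError(f"loss_probability must be in [0, 1), got {loss_probability}")
    return rate / (1.0 - loss_probability)


def subsample_loss_probability(n_sampled: float, mutant_frequency: float) -> LossProbability:
    """Probability that a genotype at frequency f contributes zero cells to a
    subsample of n: exact (1−f)^n with Poisson approximation exp(−n·f).
    At n·f = 1 both are ≈ 0.37."""
    if n_sampled < 1:
        raise ValueError("n_sampled must be >= 1")
    if not 0.0 <= mutant_frequency < 1.0:
        raise ValueError("mutant_frequency must be in [0, 1)")
    exact = (1.0 - mutant_frequency) ** n_sampled
    poisson = math.exp(-n_sampled * mutant_frequency)
    return LossProbability(
        exact=exact, poisson=poisson, n_sampled=n_sampled, frequency=mutant_frequency
    )


def expected_distinct_asci(n_asci: int, spores_per_ascus: int, n_sampled: int) -> float:
    """Closed-form expectation of the number of asci with at least one spore
    in a without-replacement sample of ``n_sampled`` from the pool:
    n_asci × [1 − C(T−a, k)/C(T, k)] with T total spores, a spores/ascus."""
    total = n_asci * spores_per_ascus
    # C(T-a, k)/C(T, k) = prod_{m=0..a-1} (T-k-m)/(T-m)
    p_missed = 1.0
    for m in range(spores_per_ascus):
        p_missed *= (total - n_sampled - m) / (total - m)
    return n_asci * (1.0 - p_missed)


def independent_asci(
    inputs: AscusSamplingInputs, rng: Optional[np.random.Generator] = None
) -> AscusEstimate:
    """Monte-Carlo estimate of the number of distinct asci represented in a
    spore sample, with the hypergeometric closed form alongside.

    Each replicate draws ``n_spores_sampled`` spores without replacement from
    the pool (spores are physical objects; a spore cannot be sampled twice)
    and counts asci hit at least once.
    """
    if rng is None:
        rng = np.random.default_rng(inputs.seed)
    colors = np.full(inputs.n_asci, inputs.spores_per_ascus, dtype=np.int64)
    hits = np.empty(inputs.n_replicates, dtype=np.int64)
    for r in range(inputs.n_replicates):
        sample = rng.multivariate_hypergeometric(
            colors, inputs.n_spores_sampled, method="count"
        )
        hits[r] = int(np.count_nonzero(sample))
    closed = expected_distinct_asci(
        inputs.n_asci, inputs.spores_per_ascus, inputs.n_spores_sampled
    )
    sd = float(hits.std(ddof=1)) if inputs.n_replicates > 1 else 0.0
    return AscusEstimate(
        mc_mean=float(hits.mean()), mc_sd=sd, closed_form=closed, inputs=inputs
    )


def plating_density(n_cells: float, plate_diameter_cm: float) -> float:
    """Cells per mm² when ``n_cells`` spread over a circular plate of the
    given diameter; 5 × 10⁶ cells on a 4.5 cm plate is ≈ 3.1 × 10³ mm⁻²."""
    if n_cells <= 0 or plate_diameter_cm <= 0:
        raise ValueError("n_cells and plate_diameter_cm must be positive")
    radius_mm = plate_diameter_cm * 10.0 / 2.0
    return n_cells / (math.pi * radius_mm**2)


#: Named scenarios for the study's in-print calculations, runnable from the
#: CLI (`matesim rates`).  Values are the published experiment's inputs.
STUDY_SCENARIOS = {
    "upper_limit": {
        "description": "binomial zero-class upper limit from screening 1e6 spores",
        "inputs": {"n_screened": 1_000_000, "n_events": 0, "alpha": 0.05},
    },
    "lower_bound": {
        "description": "fixation-event lower bound: 9 events / (25 gen x 20 pops x 2.5e6)",
        "inputs": {
            "n_fixation_events": 9,
            "n_sexual_generations": 25,
            "n_populations": 20,
            "n_opportunities_per_generation": 2.5e6,
        },
    },
    "loss_corrected": {
        "description": "lower bound corrected for 0.37 bottleneck loss",
        "inputs": {"loss_probability": 0.37},
    },
    "independent_asci": {
        "description": "distinct asci represented when sampling 1e6 of 1e7 pooled spores",
        "inputs": {
            "n_asci": 2_500_000,
            "spores_per_ascus": 4,
            "n_spores_sampled": 1_000_000,
            "n_replicates": 1000,
        },
    },
    "plating_density": {
        "description": "5e6 cells spread on a 4.5 cm plate",
        "inputs": {"n_cells": 5e6, "plate_diameter_cm": 4.5},
    },
}
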