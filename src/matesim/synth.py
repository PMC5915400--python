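"""Synthetic competition-assay data with known ground truth.

The generator emulates a flow-cytometry competition experiment: two strains
are mixed, grown (or mated), and a fixed number of cells is classified by
fluorescence before and after.  The latent strain frequency evolves
deterministically — effects compose additively on the log-fitness scale, the
same additivity the marker correction assumes — and the only noise is
multinomial counting at the configured sampling depth.  Because the true
selection coefficient and marker effect are inputs, every estimator can be
validated as a round trip: generate → estimate → compare with truth.

A small catalog of hand-constructed lattice states (single clone,
checkerboard, two-clone frontier) with enumerable mating outcomes is bundled
for unit-testing the lattice model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from matesim.fitness import RECORD_COLUMNS, generations
from matesim.lattice import (
    M,
    NONSWITCHER,
    P,
    SWITCHER,
    WILL_SWITCH,
    WONT_SWITCH,
    Grid,
)

__all__ = ["GeneratorSpec", "generate_asexual", "generate_sexual", "fixture_grids"]

_EPS = 1e-12


@dataclass(frozen=True)
class GeneratorSpec:
    """Ground-truth parameterization of a synthetic competition.

    ``true_s`` is the per-generation selection coefficient of the focal
    strain i over its competitor j on the log-fitness scale (positive: i
    wins).  ``marker_effect`` is the per-generation cost borne by whichever
    strain carries the fluorescent label.  ``sampling_depth`` is the number
    of cells classified per measurement; ``None`` disables counting noise
    entirely (the deterministic limit).  ``replicate_jitter`` adds optional
    Gaussian between-replicate variation to ``true_s`` (default 0: the
    assay's biological replicate variance is not an observable here).
    """

    true_s: float
    marker_effect: float = 0.0
    marker_on: str = "i"
    transfers: int = 5
    fold_growth: float = 100.0
    sampling_depth: Optional[int] = 100_000
    n_replicates: int = 8
    initial_freq_i: float = 0.5
    seed: Optional[int] = None
    regime: str = "asexual_saturated"
    replicate_jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.sampling_depth is not None and self.sampling_depth < 100:
            raise ValueError("sampling_depth must be >= 100 (or None for no noise)")
        if not 0.0 < self.initial_freq_i < 1.0:
            raise ValueError("initial_freq_i must be in (0, 1)")
        if self.marker_on not in ("i", "j"):
            raise ValueError("marker_on must be 'i' or 'j'")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.replicate_jitter < 0:
            raise ValueError("replicate_jitter must be >= 0")


def _propagate(freq: float, log_drift: float) -> float:
    """Advance a frequency by a log-odds increment; error out if the latent
    frequency degenerates numerically."""
    logit = math.log(freq / (1.0 - freq)) + log_drift
    after = 1.0 / (1.0 + math.exp(-logit))
    if not _EPS < after < 1.0 - _EPS:
        raise ValueError(
            f"latent frequency left (0, 1) (drift {log_drift:.3g} from {freq:.3g}); "
            "reduce effect sizes, transfers or fold growth"
        )
    return after


def _observe(freq: float, depth: Optional[int], rng: np.random.Generator) -> tuple:
    if depth is None:
        return freq, 1.0 - freq
    ci, cj = rng.multinomial(depth, [freq, 1.0 - freq])
    return float(ci), float(cj)


def generate_asexual(
    spec: GeneratorSpec,
    rng: Optional[np.random.Generator] = None,
    marker_swap: bool = True,
) -> pd.DataFrame:
    """Generate asexual competition records plus isogenic marker controls.

    For each replicate the latent log-odds of strain i advance by
    ``t * (true_s ± marker_effect)`` over ``t = transfers × log2(fold)``
    generations (the sign depends on which strain carries the label), and
    the marker control advances by the marker term alone.  With
    ``marker_swap`` (default) a reciprocally labelled pair of record sets is
    produced, enabling the marker-symmetry check.

    Returns a long table following :data:`matesim.fitness.RECORD_COLUMNS`.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    t = generations(spec.transfers, spec.fold_growth)
    sides = ("i", "j") if marker_swap else (spec.marker_on,)
    rows = []
    for rep in range(spec.n_replicates):
        s_rep = spec.true_s
        if spec.replicate_jitter > 0:
            s_rep += rng.normal(0.0, spec.replicate_jitter)
        for marker_on in sides:
            sign = -1.0 if marker_on == "i" else 1.0
            for kind, drift in (
                ("competition", t * (s_rep + sign * spec.marker_effect)),
                ("marker_control", t * sign * spec.marker_effect),
            ):
                p_before = spec.initial_freq_i if kind == "competition" else 0.5
                p_after = _propagate(p_before, drift)
                ib, jb = _observe(p_before, spec.sampling_depth, rng)
                ia, ja = _observe(p_after, spec.sampling_depth, rng)
                rows.append(
                    {
                        "replicate": rep,
                        "kind": kind,
                        "regime": spec.regime,
                        "marker_on": marker_on,
                        "transfers": spec.transfers,
                        "fold_growth": spec.fold_growth,
                        "count_i_before": ib,
                        "count_j_before": jb,
                        "count_i_after": ia,
                        "count_j_after": ja,
                    }
                )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


AdvantageMap = Mapping[float, Union[float, Callable[[float], float]]]


def generate_sexual(
    spec: GeneratorSpec,
    mating_advantage: AdvantageMap,
    rng: Optional[np.random.Generator] = None,
    initial_freqs: Optional[Sequence[float]] = None,
    marker_swap: bool = True,
) -> pd.DataFrame:
    """Generate sexual competition records across density treatments.

    ``mating_advantage`` maps each density to the relative fitness w of
    strain i over one sexual episode (w = 0.163 means i ends the episode
    with s = 1 − w = 0.837 against it); a value may also be a callable of
    the before-frequency of i, allowing frequency-dependent advantage.
    ``initial_freqs`` reproduces ratio treatments (e.g. 0.9, 0.5, 0.1 for
    9:1, 1:1, 1:9); defaults to the spec's single initial frequency.  The
    marker multiplies w by exp(±marker_effect) for the labelled side, and
    marker-control records carry the marker effect alone.

    Returns a long record table with an extra ``density`` column.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if initial_freqs is None:
        initial_freqs = [spec.initial_freq_i]
    sides = ("i", "j") if marker_swap else (spec.marker_on,)
    rows = []
    for density, adv in mating_advantage.items():
        for rep in range(spec.n_replicates):
            for p0 in initial_freqs:
                w = adv(p0) if callable(adv) else float(adv)
                if w <= 0:
                    raise ValueError(f"mating advantage must be positive, got {w} at {density}")
                for marker_on in sides:
                    sign = -1.0 if marker_on == "i" else 1.0
                    for kind, drift in (
                        ("competition", math.log(w) + sign * spec.marker_effect),
                        ("marker_control", sign * spec.marker_effect),
                    ):
                        p_before = p0 if kind == "competition" else 0.5
                        p_after = _propagate(p_before, drift)
                        ib, jb = _observe(p_before, spec.sampling_depth, rng)
                        ia, ja = _observe(p_after, spec.sampling_depth, rng)
                        rows.append(
                            {
                                "replicate": rep,
                                "kind": kind,
                                "regime": "sexual",
                                "marker_on": marker_on,
                                "transfers": 1,
                                "fold_growth": 2.0,
                                "count_i_before": ib,
                                "count_j_before": jb,
                                "count_i_after": ia,
                                "count_j_after": ja,
                                "density": density,
                                "initial_freq_i": p0,
                            }
                        )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS + ["density", "initial_freq_i"])


def _full_grid(side: int) -> Grid:
    g = Grid.empty(side)
    g.clone_id[:] = 0
    return g


def _fixture_single_clone_5x5() -> Grid:
    """One non-switcher clone filling the grid: zero possible zygotes."""
    g = _full_grid(5)
    g.mating_type[:] = P
    g.strategy[:] = NONSWITCHER
    return g


def _fixture_all_p_3x3() -> Grid:
    """Distinct founders, all mating type P: zero possible zygotes."""
    g = _full_grid(3)
    g.mating_type[:] = P
    g.strategy[:] = NONSWITCHER
    g.clone_id[:] = np.arange(9)
    return g


def _fixture_checkerboard_4x4() -> Grid:
    """P/M checkerboard of 16 distinct non-switcher founders: every cell has
    an opposite-type neighbour, and a perfect matching (8 zygotes) exists."""
    g = _full_grid(4)
    idx = np.arange(16)
    parity = (idx // 4 + idx % 4) % 2
    g.mating_type[:] = np.where(parity == 0, P, M).astype(np.int8)
    g.strategy[:] = NONSWITCHER
    g.clone_id[:] = idx
    return g


def _fixture_two_clone_10x10() -> Grid:
    """Two non-switcher clones split left (P) / right (M): mating is possible
    only across the vertical contact zone (columns 4 and 5)."""
    g = _full_grid(10)
    col = np.arange(100) % 10
    left = col < 5
    g.mating_type[:] = np.where(left, P, M).astype(np.int8)
    g.strategy[:] = NONSWITCHER
    g.clone_id[:] = np.where(left, 0, 1)
    return g


def _fixture_two_clone_10x10_switchers() -> Grid:
    """Switcher variant of the two-clone frontier: each patch holds both
    mating types (as a grown switcher clone would), so every cell can mate
    within its own clone."""
    g = _full_grid(10)
    idx = np.arange(100)
    col = idx % 10
    parity = (idx // 10 + col) % 2
    g.mating_type[:] = np.where(parity == 0, P, M).astype(np.int8)
    g.strategy[:] = SWITCHER
    g.phase[:] = np.where(parity == 0, WILL_SWITCH, WONT_SWITCH).astype(np.int8)
    g.clone_id[:] = np.where(col < 5, 0, 1)
    return g


_CATALOG = {
    "single_clone_5x5": _fixture_single_clone_5x5,
    "all_P_3x3": _fixture_all_p_3x3,
    "checkerboard_4x4": _fixture_checkerboard_4x4,
    "two_clone_10x10": _fixture_two_clone_10x10,
    "two_clone_10x10_switchers": _fixture_two_clone_10x10_switchers,
}


def fixture_grids(catalog_name: str) -> Grid:
    """Return a hand-constructed small lattice state by name.

    These synthetic fixtures have enumerable mating outcomes and exist for
    unit tests and demonstrations; ``fixture_grids("?")`` raises with the
    catalog listing.
    """
    try:
        return _CATALOG[catalog_name]()
    except KeyError:
        raise KeyError(
            f"unknown fixture {catalog_name!r}; available: {sorted(_CATALOG)}"
        ) from None
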