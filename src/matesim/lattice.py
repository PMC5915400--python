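"""Cellular-automaton core for switcher/non-switcher competition.

The model lives on a square lattice.  Each occupied site holds a haploid cell
with a mating type (P or M), a mating strategy (switcher or non-switcher), a
switching-competence phase for switchers, the clone identity of the founder it
descends from in the current growth phase, a flag recording whether that
founder arose from an intraclonal (within-clone) zygote, and a mated flag.

One sexual cycle (a "transfer") is: seed founders at a target density →
asexual growth rounds until the grid is full → one mating pass (Moore
neighbourhood or global mass action) → Mendelian gamete accounting over the
zygotes, which yields the switcher frequency used to seed the next cycle.

Mating-type inheritance follows the fission-yeast switching pedigree: when a
competent ("will switch") switcher divides, exactly one of the two products
carries the opposite mating type and is not yet re-competent; the other keeps
the type and remains competent.  When a non-competent switcher divides, one
product gains competence.  Non-switcher lineages never change type — after
local growth a non-switcher clone is a patch of identical mating type that can
only find compatible partners at its edges, while a switcher clone is
internally self-compatible.  That contrast is the object of study.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np

from matesim import _kernels
from matesim._kernels import (
    EMPTY,
    P,
    M,
    NO_STRATEGY,
    SWITCHER,
    NONSWITCHER,
    PHASE_NA,
    WILL_SWITCH,
    WONT_SWITCH,
)

__all__ = [
    "EMPTY",
    "P",
    "M",
    "SWITCHER",
    "NONSWITCHER",
    "PHASE_NA",
    "WILL_SWITCH",
    "WONT_SWITCH",
    "LatticeConfig",
    "SimParams",
    "Grid",
    "MatingOutcome",
    "FounderPool",
    "ExtinctionError",
    "ConfigurationError",
    "seed_grid",
    "growth_round",
    "run_growth",
    "mating_round",
    "next_founder_pool",
    "mated_fraction_by_strategy",
]

#: safety factor for the growth-round cap (rounds = cap_factor * side**2)
_ROUND_CAP_FACTOR = 1000


class ConfigurationError(ValueError):
    """Invalid lattice or simulation configuration."""


class ExtinctionError(RuntimeError):
    """Raised when a mating round yields zero zygotes: no sexual offspring
    exist to seed the next cycle, so the population is extinct."""


@dataclass(frozen=True)
class LatticeConfig:
    """Geometry and seeding density of the lattice.

    Parameters
    ----------
    side_length:
        Edge length of the square grid (default 200, i.e. 40,000 sites).
    boundary:
        ``"bounded"`` (hard edges) or ``"torus"`` (wrap-around).
    density:
        Fraction of sites occupied at seeding, in (0, 1].  The number of
        founders is ``round(density * side_length**2)`` and must be >= 2.
    """

    side_length: int = 200
    boundary: str = "bounded"
    density: float = 1.0

    def __post_init__(self) -> None:
        if self.side_length < 4:
            raise ConfigurationError(f"side_length must be >= 4, got {self.side_length}")
        if self.boundary not in ("bounded", "torus"):
            raise ConfigurationError(f"boundary must be 'bounded' or 'torus', got {self.boundary!r}")
        if not 0.0 < self.density <= 1.0:
            raise ConfigurationError(f"density must be in (0, 1], got {self.density}")
        if self.n_founders < 2:
            raise ConfigurationError(
                f"density {self.density} on a {self.side_length}x{self.side_length} grid "
                f"seeds {self.n_founders} founders; at least 2 are required"
            )

    @property
    def n_sites(self) -> int:
        return self.side_length * self.side_length

    @property
    def n_founders(self) -> int:
        return int(round(self.density * self.n_sites))


@dataclass(frozen=True)
class SimParams:
    """Full parameterization of one simulation.

    Parameters
    ----------
    lattice:
        Grid geometry and seeding density.
    growth_chance:
        Per-round division probability R of a cell with an empty neighbour
        (default 0.5).
    switching_cost:
        Selection coefficient s in [0, 0.5] against switchers during asexual
        growth; a switcher divides with probability R*(1-s).
    intraclonal_cost:
        Multiplicative factor c in (0, 1] applied to the division chance of
        founders derived from intraclonal zygotes, for one growth phase.
    mating_mode:
        ``"moore"`` (8-neighbourhood) or ``"global"`` (mass action).
    max_transfers:
        Cap on the number of sexual cycles (default 500).
    initial_switcher_freq:
        Switcher frequency used at the first seeding.
    seed:
        Integer seed for the single RNG stream driving the run.
    max_growth_rounds:
        Optional cap on asexual rounds per transfer.  ``None`` (default)
        grows until the grid is full; a finite cap shortens the asexual
        phase, i.e. makes sexual reproduction more frequent per mitotic
        generation, and relaxes the full-grid precondition of mating.
    phase_rule:
        ``"pedigree"`` (default, deterministic competence alternation) or
        ``"bernoulli"`` (phases re-drawn fair-coin at each division), the
        latter for sensitivity checks.
    """

    lattice: LatticeConfig = field(default_factory=LatticeConfig)
    growth_chance: float = 0.5
    switching_cost: float = 0.0
    intraclonal_cost: float = 1.0
    mating_mode: str = "moore"
    max_transfers: int = 500
    initial_switcher_freq: float = 0.5
    seed: Optional[int] = None
    max_growth_rounds: Optional[int] = None
    phase_rule: str = "pedigree"

    def __post_init__(self) -> None:
        if not 0.0 < self.growth_chance <= 1.0:
            raise ConfigurationError(f"growth_chance must be in (0, 1], got {self.growth_chance}")
        if not 0.0 <= self.switching_cost <= 0.5:
            raise ConfigurationError(
                f"switching_cost must be in [0, 0.5], got {self.switching_cost}"
            )
        if not 0.0 < self.intraclonal_cost <= 1.0:
            raise ConfigurationError(
                f"intraclonal_cost must be in (0, 1], got {self.intraclonal_cost}"
            )
        if self.mating_mode not in ("moore", "global"):
            raise ConfigurationError(
                f"mating_mode must be 'moore' or 'global', got {self.mating_mode!r}"
            )
        if self.max_transfers < 1:
            raise ConfigurationError(f"max_transfers must be >= 1, got {self.max_transfers}")
        if not 0.0 <= self.initial_switcher_freq <= 1.0:
            raise ConfigurationError(
                f"initial_switcher_freq must be in [0, 1], got {self.initial_switcher_freq}"
            )
        if self.max_growth_rounds is not None and self.max_growth_rounds < 1:
            raise ConfigurationError("max_growth_rounds must be >= 1 or None")
        if self.phase_rule not in ("pedigree", "bernoulli"):
            raise ConfigurationError(
                f"phase_rule must be 'pedigree' or 'bernoulli', got {self.phase_rule!r}"
            )

    def with_(self, **kwargs) -> "SimParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class Grid:
    """Lattice state as flat (side**2,) arrays, C row-major order.

    ``mating_type``: 0 empty, 1 P, 2 M.  ``strategy``: 0 none, 1 switcher,
    2 non-switcher.  ``phase``: 0 n/a, 1 will-switch, 2 won't-switch.
    ``clone_id`` is -1 on empty sites.
    """

    side: int
    torus: bool
    mating_type: np.ndarray
    strategy: np.ndarray
    phase: np.ndarray
    clone_id: np.ndarray
    intraclonal: np.ndarray
    mated: np.ndarray

    @classmethod
    def empty(cls, side: int, torus: bool = False) -> "Grid":
        n = side * side
        return cls(
            side=side,
            torus=torus,
            mating_type=np.zeros(n, dtype=np.int8),
            strategy=np.zeros(n, dtype=np.int8),
            phase=np.zeros(n, dtype=np.int8),
            clone_id=np.full(n, -1, dtype=np.int64),
            intraclonal=np.zeros(n, dtype=np.bool_),
            mated=np.zeros(n, dtype=np.bool_),
        )

    @property
    def n_sites(self) -> int:
        return self.side * self.side

    @property
    def occupied(self) -> np.ndarray:
        """Flat indices of occupied sites."""
        return np.flatnonzero(self.mating_type != EMPTY)

    @property
    def n_occupied(self) -> int:
        return int((self.mating_type != EMPTY).sum())

    @property
    def n_empty(self) -> int:
        return self.n_sites - self.n_occupied

    def copy(self) -> "Grid":
        return Grid(
            side=self.side,
            torus=self.torus,
            mating_type=self.mating_type.copy(),
            strategy=self.strategy.copy(),
            phase=self.phase.copy(),
            clone_id=self.clone_id.copy(),
            intraclonal=self.intraclonal.copy(),
            mated=self.mated.copy(),
        )

    def to_coded_matrix(self) -> np.ndarray:
        """2-D snapshot coded 0 empty, 1 P-switcher, 2 M-switcher,
        3 P-non-switcher, 4 M-non-switcher."""
        code = np.zeros(self.n_sites, dtype=np.int8)
        sw = self.strategy == SWITCHER
        ns = self.strategy == NONSWITCHER
        code[sw & (self.mating_type == P)] = 1
        code[sw & (self.mating_type == M)] = 2
        code[ns & (self.mating_type == P)] = 3
        code[ns & (self.mating_type == M)] = 4
        return code.reshape(self.side, self.side)

    def mated_matrix(self) -> np.ndarray:
        return self.mated.astype(np.int8).reshape(self.side, self.side)


@dataclass
class MatingOutcome:
    """Result of one mating pass: the zygote list.

    Per zygote: the two site indices, parent strategies, parent clone ids and
    the intraclonal flag (equal clone ids, i.e. haploid selfing within one
    clone — exactly what the switching strategy enables inside a patch).
    """

    site_a: np.ndarray
    site_b: np.ndarray
    strategy_a: np.ndarray
    strategy_b: np.ndarray
    clone_a: np.ndarray
    clone_b: np.ndarray

    @property
    def n_zygotes(self) -> int:
        return len(self.site_a)

    @property
    def intraclonal(self) -> np.ndarray:
        return self.clone_a == self.clone_b

    @property
    def n_switcher_x_switcher(self) -> int:
        return int(((self.strategy_a == SWITCHER) & (self.strategy_b == SWITCHER)).sum())

    @property
    def n_nonswitcher_x_nonswitcher(self) -> int:
        return int(
            ((self.strategy_a == NONSWITCHER) & (self.strategy_b == NONSWITCHER)).sum()
        )

    @property
    def n_mixed(self) -> int:
        return self.n_zygotes - self.n_switcher_x_switcher - self.n_nonswitcher_x_nonswitcher


@dataclass(frozen=True)
class FounderPool:
    """Gamete-frequency summary of a mating round, used to seed the next
    growth phase."""

    switcher_freq: float
    intraclonal_fracs: Mapping[int, float]
    n_zygotes: int


def seed_grid(
    params: SimParams,
    switcher_freq: Optional[float] = None,
    intraclonal_fracs: Optional[Mapping[int, float]] = None,
    rng: Optional[np.random.Generator] = None,
) -> Grid:
    """Populate an empty grid with founders.

    ``round(density * side**2)`` sites are occupied at uniformly random
    positions.  Each founder is independently a switcher with probability
    ``switcher_freq`` (spore sampling — Bernoulli, not deterministic
    rounding, so fixation and loss are genuinely reachable), is P with
    probability 1/2 (Mendelian segregation at the mating-type locus), and a
    switcher founder is competent ("will switch") with probability 1/2.
    Founders get distinct clone ids 0..n-1; intraclonal-origin flags are
    drawn per strategy from ``intraclonal_fracs``.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if switcher_freq is None:
        switcher_freq = params.initial_switcher_freq
    if not 0.0 <= switcher_freq <= 1.0:
        raise ConfigurationError(f"switcher_freq must be in [0, 1], got {switcher_freq}")
    cfg = params.lattice
    grid = Grid.empty(cfg.side_length, torus=cfg.boundary == "torus")
    n = cfg.n_founders  # validated >= 2 by LatticeConfig

    sites = rng.choice(cfg.n_sites, size=n, replace=False)
    is_switcher = rng.random(n) < switcher_freq
    is_p = rng.random(n) < 0.5
    will_switch = rng.random(n) < 0.5
    u_intra = rng.random(n)

    frac_sw = frac_ns = 0.0
    if intraclonal_fracs:
        frac_sw = float(intraclonal_fracs.get(SWITCHER, 0.0))
        frac_ns = float(intraclonal_fracs.get(NONSWITCHER, 0.0))

    grid.mating_type[sites] = np.where(is_p, P, M).astype(np.int8)
    grid.strategy[sites] = np.where(is_switcher, SWITCHER, NONSWITCHER).astype(np.int8)
    grid.phase[sites] = np.where(
        is_switcher, np.where(will_switch, WILL_SWITCH, WONT_SWITCH), PHASE_NA
    ).astype(np.int8)
    grid.clone_id[sites] = np.arange(n, dtype=np.int64)
    grid.intraclonal[sites] = np.where(is_switcher, u_intra < frac_sw, u_intra < frac_ns)
    return grid


def growth_round(grid: Grid, params: SimParams, rng: np.random.Generator) -> int:
    """One asexual round over a fresh random order of currently occupied
    cells; returns the number of divisions.  Cells placed during the round do
    not divide until the next round; occupancy updates immediately."""
    occ = grid.occupied
    if len(occ) == 0:
        raise ConfigurationError("growth_round requires at least one occupied site")
    order = rng.permutation(occ)
    n = len(order)
    u_div = rng.random(n)
    u_tgt = rng.random(n)
    u_mig = rng.random(n)
    u_phase = rng.random(n)
    mode = _kernels.PEDIGREE if params.phase_rule == "pedigree" else _kernels.BERNOULLI
    return int(
        _kernels.growth_round_kernel(
            grid.mating_type,
            grid.strategy,
            grid.phase,
            grid.clone_id,
            grid.intraclonal,
            grid.side,
            grid.torus,
            params.growth_chance,
            params.switching_cost,
            params.intraclonal_cost,
            order,
            u_div,
            u_tgt,
            u_mig,
            u_phase,
            mode,
        )
    )


def run_growth(grid: Grid, params: SimParams, rng: np.random.Generator) -> int:
    """Iterate growth rounds until every site is occupied (or until the
    optional ``max_growth_rounds`` cap); returns the number of rounds run.

    A hard safeguard of ``1000 * side**2`` rounds guards against degenerate
    parameters (effective division chance zero) that could never fill the
    grid.
    """
    cap = params.max_growth_rounds
    hard_cap = _ROUND_CAP_FACTOR * grid.n_sites
    rounds = 0
    while grid.n_empty > 0:
        if cap is not None and rounds >= cap:
            break
        if rounds >= hard_cap:
            raise RuntimeError(
                f"grid not filled after {rounds} growth rounds; effective division "
                "chance R*(1-s)*c is degenerate"
            )
        growth_round(grid, params, rng)
        rounds += 1
    return rounds


def mating_round(
    grid: Grid,
    params: SimParams,
    rng: np.random.Generator,
    require_full: bool = True,
) -> MatingOutcome:
    """One mating pass; marks paired cells as mated and returns the zygotes.

    Unmated cells are visited in a fresh uniformly random order; each pairs
    with a uniformly chosen eligible partner (Moore mode: unmated
    opposite-type neighbour; global mode: any unmated opposite-type cell).
    One greedy pass leaves no eligible pair unmated.  Eligibility ignores
    strategy and clone identity — within-clone mating is allowed, and is
    exactly what switcher patches (mixed mating types) can do while
    non-switcher patches (one mating type) cannot.
    """
    if require_full and grid.n_empty > 0:
        raise ConfigurationError(
            f"mating_round requires a fully occupied grid ({grid.n_empty} empty sites); "
            "pass require_full=False to mate a partially filled grid"
        )
    occ = grid.occupied
    order = rng.permutation(occ)
    u_pick = rng.random(len(order))
    out_a = np.empty(len(order) // 2 + 1, dtype=np.int64)
    out_b = np.empty(len(order) // 2 + 1, dtype=np.int64)
    if params.mating_mode == "moore":
        nz = _kernels.mating_moore_kernel(
            grid.mating_type, grid.mated, grid.side, grid.torus, order, u_pick, out_a, out_b
        )
    else:
        nz = _kernels.mating_global_kernel(
            grid.mating_type, grid.mated, order, u_pick, out_a, out_b
        )
    a = out_a[:nz].copy()
    b = out_b[:nz].copy()
    return MatingOutcome(
        site_a=a,
        site_b=b,
        strategy_a=grid.strategy[a].copy(),
        strategy_b=grid.strategy[b].copy(),
        clone_a=grid.clone_id[a].copy(),
        clone_b=grid.clone_id[b].copy(),
    )


def next_founder_pool(outcome: MatingOutcome) -> FounderPool:
    """Mendelian gamete accounting over the zygotes.

    The switching strategy segregates 1:1 from heterozygous (switcher x
    non-switcher) zygotes, so the expected switcher gamete frequency is
    ``(2*n_SWxSW + n_SWxNS) / (2*n_zygotes)``.  Intraclonal-origin fractions
    are computed per strategy with heterozygous zygotes weighted half to each
    strategy.  Raises :class:`ExtinctionError` on zero zygotes.
    """
    nz = outcome.n_zygotes
    if nz == 0:
        raise ExtinctionError("mating produced zero zygotes; population is extinct")
    sw_a = (outcome.strategy_a == SWITCHER).astype(float)
    sw_b = (outcome.strategy_b == SWITCHER).astype(float)
    # per-zygote gamete weight for each strategy (each zygote yields 2 gametes)
    w_sw = (sw_a + sw_b) / 2.0
    w_ns = 1.0 - w_sw
    switcher_freq = float(w_sw.sum() / nz)
    intra = outcome.intraclonal.astype(float)
    fracs = {}
    for key, w in ((SWITCHER, w_sw), (NONSWITCHER, w_ns)):
        tot = w.sum()
        fracs[key] = float((w * intra).sum() / tot) if tot > 0 else 0.0
    return FounderPool(switcher_freq=switcher_freq, intraclonal_fracs=fracs, n_zygotes=nz)


def mated_fraction_by_strategy(grid: Grid) -> Mapping[int, float]:
    """Fraction of cells of each strategy that mated in the last pass."""
    out = {}
    for key in (SWITCHER, NONSWITCHER):
        mask = grid.strategy == key
        n = int(mask.sum())
        out[key] = float(grid.mated[mask].sum() / n) if n else float("nan")
    return out
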