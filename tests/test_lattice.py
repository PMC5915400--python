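"""Unit and property tests for the cellular-automaton core."""

import numpy as np
import pytest

import matesim
from matesim import lattice
from matesim.lattice import (
    EMPTY,
    M,
    NONSWITCHER,
    P,
    PHASE_NA,
    SWITCHER,
    WILL_SWITCH,
    WONT_SWITCH,
    ConfigurationError,
    ExtinctionError,
    Grid,
    LatticeConfig,
    MatingOutcome,
    SimParams,
    growth_round,
    mating_round,
    next_founder_pool,
    run_growth,
    seed_grid,
)


def _place(grid, site, mating_type, strategy=NONSWITCHER, phase=PHASE_NA, clone=0):
    grid.mating_type[site] = mating_type
    grid.strategy[site] = strategy
    grid.phase[site] = phase
    grid.clone_id[site] = clone


class TestSeedGrid:
    def test_founder_count_and_distinct_clones(self, rng):
        params = SimParams(lattice=LatticeConfig(side_length=50, density=0.01))
        grid = seed_grid(params, 0.5, None, rng)
        occ = grid.occupied
        assert len(occ) == 25  # round(0.01 * 2500)
        assert len(np.unique(grid.clone_id[occ])) == 25

    def test_full_density_occupies_every_site(self, rng):
        params = SimParams(lattice=LatticeConfig(side_length=20, density=1.0))
        grid = seed_grid(params, 0.5, None, rng)
        assert grid.n_occupied == 400
        assert grid.n_empty == 0

    def test_degenerate_switcher_freq_zero(self, rng):
        params = SimParams(lattice=LatticeConfig(side_length=20, density=0.5))
        grid = seed_grid(params, 0.0, None, rng)
        occ = grid.occupied
        assert (grid.strategy[occ] == NONSWITCHER).all()
        assert (grid.phase[occ] == PHASE_NA).all()
        # both mating types present at coin-flip assignment
        assert {P, M} <= set(grid.mating_type[occ].tolist())

    def test_intraclonal_fracs_extremes(self, rng):
        params = SimParams(lattice=LatticeConfig(side_length=20, density=0.5))
        grid = seed_grid(params, 0.5, {SWITCHER: 1.0, NONSWITCHER: 0.0}, rng)
        occ = grid.occupied
        sw = occ[grid.strategy[occ] == SWITCHER]
        ns = occ[grid.strategy[occ] == NONSWITCHER]
        assert grid.intraclonal[sw].all()
        assert not grid.intraclonal[ns].any()

    def test_too_few_founders_rejected(self):
        with pytest.raises(ConfigurationError, match="at least 2"):
            LatticeConfig(side_length=10, density=0.005)

    def test_tiny_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            LatticeConfig(side_length=3)


class TestGrowthPedigree:
    """Mating-type inheritance at division follows the switching pedigree."""

    def _divide_single(self, strategy, phase, seed=0):
        params = SimParams(
            lattice=LatticeConfig(side_length=4, density=0.5), growth_chance=1.0
        )
        rng = np.random.default_rng(seed)
        grid = Grid.empty(4)
        _place(grid, 5, P, strategy, phase)
        n = growth_round(grid, params, rng)
        assert n == 1
        occ = grid.occupied
        assert len(occ) == 2
        return grid, occ

    def test_nonswitcher_conserves_type(self):
        grid, occ = self._divide_single(NONSWITCHER, PHASE_NA)
        assert (grid.mating_type[occ] == P).all()
        assert (grid.clone_id[occ] == 0).all()

    def test_competent_switcher_yields_one_switched_noncompetent(self):
        grid, occ = self._divide_single(SWITCHER, WILL_SWITCH)
        types = sorted(grid.mating_type[occ].tolist())
        assert types == [P, M]
        # the switched product is not yet re-competent; the other stays competent
        switched = occ[grid.mating_type[occ] == M][0]
        kept = occ[grid.mating_type[occ] == P][0]
        assert grid.phase[switched] == WONT_SWITCH
        assert grid.phase[kept] == WILL_SWITCH

    def test_noncompetent_switcher_conserves_type_one_gains_competence(self):
        grid, occ = self._divide_single(SWITCHER, WONT_SWITCH)
        assert (grid.mating_type[occ] == P).all()
        assert sorted(grid.phase[occ].tolist()) == [WILL_SWITCH, WONT_SWITCH]

    def test_full_grid_is_noop(self):
        grid = matesim.fixture_grids("single_clone_5x5")
        before = grid.mating_type.copy()
        params = SimParams(lattice=LatticeConfig(side_length=5, density=1.0))
        assert growth_round(grid, params, np.random.default_rng(0)) == 0
        np.testing.assert_array_equal(grid.mating_type, before)

    def test_bernoulli_phase_variant_still_switches_types(self):
        params = SimParams(
            lattice=LatticeConfig(side_length=10, density=0.02), phase_rule="bernoulli"
        )
        rng = np.random.default_rng(8)
        grid = Grid.empty(10)
        _place(grid, 0, P, SWITCHER, WILL_SWITCH, clone=0)
        _place(grid, 99, P, SWITCHER, WILL_SWITCH, clone=1)
        run_growth(grid, params, rng)
        occ = grid.occupied
        assert {P, M} <= set(grid.mating_type[occ].tolist())
        assert set(grid.phase[occ].tolist()) <= {WILL_SWITCH, WONT_SWITCH}

    def test_nonswitcher_lineages_never_change_type(self, rng):
        params = SimParams(lattice=LatticeConfig(side_length=20, density=0.05))
        grid = seed_grid(params, 0.5, None, rng)
        occ = grid.occupied
        founder_type = dict(zip(grid.clone_id[occ].tolist(), grid.mating_type[occ].tolist()))
        founder_strat = dict(zip(grid.clone_id[occ].tolist(), grid.strategy[occ].tolist()))
        run_growth(grid, params, rng)
        occ = grid.occupied
        for site in occ:
            cid = grid.clone_id[site]
            assert grid.strategy[site] == founder_strat[cid]
            if grid.strategy[site] == NONSWITCHER:
                assert grid.mating_type[site] == founder_type[cid]


class TestRunGrowth:
    def test_single_founder_fills_grid_one_clone(self):
        params = SimParams(lattice=LatticeConfig(side_length=10, density=0.02))
        rng = np.random.default_rng(3)
        grid = Grid.empty(10)
        _place(grid, 0, P, NONSWITCHER, PHASE_NA, clone=42)
        rounds = run_growth(grid, params, rng)
        assert grid.n_occupied == 100
        assert rounds > 0
        assert (grid.clone_id == 42).all()
        assert (grid.mating_type == P).all()

    def test_occupancy_nondecreasing(self, small_params, rng):
        grid = seed_grid(small_params, 0.5, None, rng)
        prev = grid.n_occupied
        while grid.n_empty:
            growth_round(grid, small_params, rng)
            assert grid.n_occupied >= prev
            prev = grid.n_occupied

    def test_round_cap_safeguard(self, monkeypatch):
        monkeypatch.setattr(lattice, "_ROUND_CAP_FACTOR", 0)
        params = SimParams(lattice=LatticeConfig(side_length=10, density=0.02))
        grid = seed_grid(params, 0.5, None, np.random.default_rng(0))
        with pytest.raises(RuntimeError, match="growth rounds"):
            run_growth(grid, params, np.random.default_rng(0))

    def _two_founder_patch_diff(self, switching_cost, n_seeds=200):
        """Patch-size difference (switcher minus non-switcher clone) when two
        founders race to fill a 10x10 grid."""
        params = SimParams(
            lattice=LatticeConfig(side_length=10, density=0.02),
            switching_cost=switching_cost,
        )
        diffs = []
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            grid = Grid.empty(10)
            _place(grid, 22, P, NONSWITCHER, PHASE_NA, clone=0)
            _place(grid, 77, P, SWITCHER, WILL_SWITCH, clone=1)
            run_growth(grid, params, rng)
            diffs.append(int((grid.clone_id == 1).sum()) - int((grid.clone_id == 0).sum()))
        d = np.asarray(diffs, dtype=float)
        return d.mean(), 3 * d.std(ddof=1) / np.sqrt(len(d))

    def test_two_founders_neutral_patches_symmetric(self):
        mean, three_se = self._two_founder_patch_diff(0.0)
        assert abs(mean) < three_se

    def test_costly_switcher_patch_smaller(self):
        mean, three_se = self._two_founder_patch_diff(0.5)
        assert mean < -three_se


class TestMating:
    def test_forced_pair(self):
        grid = Grid.empty(4)
        _place(grid, 0, P, clone=0)
        _place(grid, 1, M, clone=1)
        params = SimParams(lattice=LatticeConfig(side_length=4, density=0.5))
        out = mating_round(grid, params, np.random.default_rng(0), require_full=False)
        assert out.n_zygotes == 1
        assert grid.mated.sum() == 2

    def test_incompatible_monotype_grid_yields_zero_zygotes(self):
        grid = matesim.fixture_grids("all_P_3x3")
        params = SimParams(lattice=LatticeConfig(side_length=4, density=0.5))
        out = mating_round(grid, params, np.random.default_rng(0))
        assert out.n_zygotes == 0
        with pytest.raises(ExtinctionError):
            next_founder_pool(out)

    def test_requires_full_grid_by_default(self):
        grid = Grid.empty(4)
        _place(grid, 0, P)
        params = SimParams(lattice=LatticeConfig(side_length=4, density=0.5))
        with pytest.raises(ConfigurationError, match="fully occupied"):
            mating_round(grid, params, np.random.default_rng(0))

    @pytest.mark.parametrize("k", [1, 2, 4, 8])
    def test_global_mode_pairs_min_of_types(self, k):
        # oracle: mass-action maximal matching has exactly min(#P, #M) pairs
        grid = Grid.empty(4)
        sites = np.arange(16)
        for s in sites[:k]:
            _place(grid, s, P, clone=int(s))
        for s in sites[k : 2 * k]:
            _place(grid, s, M, clone=int(s))
        for s in sites[2 * k :]:
            _place(grid, s, P, clone=int(s))  # surplus P, can never all mate
        params = SimParams(lattice=LatticeConfig(side_length=4, density=1.0), mating_mode="global")
        for seed in range(5):
            g = grid.copy()
            out = mating_round(g, params, np.random.default_rng(seed))
            assert out.n_zygotes == k

    def test_zygotes_have_opposite_types_and_reciprocal_mated(self, small_params, rng):
        grid = seed_grid(small_params, 0.5, None, rng)
        run_growth(grid, small_params, rng)
        occupancy_before = grid.n_occupied
        out = mating_round(grid, small_params, rng)
        assert grid.n_occupied == occupancy_before  # mating changes no occupancy
        assert int(grid.mated.sum()) == 2 * out.n_zygotes
        ta = grid.mating_type[out.site_a]
        tb = grid.mating_type[out.site_b]
        assert ((ta == P) & (tb == M) | (ta == M) & (tb == P)).all()
        # no cell appears in two zygotes
        all_sites = np.concatenate([out.site_a, out.site_b])
        assert len(np.unique(all_sites)) == len(all_sites)

    def test_moore_pass_is_maximal(self, rng):
        grid = matesim.fixture_grids("checkerboard_4x4")
        params = SimParams(lattice=LatticeConfig(side_length=4, density=1.0))
        mating_round(grid, params, rng)
        # maximality: no unmated opposite-type Moore neighbours remain
        side = grid.side
        for site in grid.occupied:
            if grid.mated[site]:
                continue
            r, c = divmod(int(site), side)
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < side and 0 <= cc < side:
                        j = rr * side + cc
                        if not grid.mated[j]:
                            assert grid.mating_type[j] == grid.mating_type[site]


class TestFounderPool:
    def _outcome(self, pairs):
        a, b, ca, cb = [], [], [], []
        for i, (sa, sb, same_clone) in enumerate(pairs):
            a.append(sa)
            b.append(sb)
            ca.append(i)
            cb.append(i if same_clone else 1000 + i)
        return MatingOutcome(
            site_a=np.arange(len(pairs)),
            site_b=np.arange(len(pairs)) + 100,
            strategy_a=np.array(a, dtype=np.int8),
            strategy_b=np.array(b, dtype=np.int8),
            clone_a=np.array(ca),
            clone_b=np.array(cb),
        )

    def test_all_switcher_zygotes(self):
        pool = next_founder_pool(self._outcome([(SWITCHER, SWITCHER, False)] * 3))
        assert pool.switcher_freq == 1.0

    def test_heterozygote_segregates_half(self):
        pool = next_founder_pool(self._outcome([(SWITCHER, NONSWITCHER, False)]))
        assert pool.switcher_freq == 0.5

    def test_mendelian_mixture(self):
        pairs = [(SWITCHER, SWITCHER, False)] * 3 + [(NONSWITCHER, NONSWITCHER, False)]
        pool = next_founder_pool(self._outcome(pairs))
        assert pool.switcher_freq == 0.75  # (2*3 + 0) / (2*4)

    def test_intraclonal_fraction_weights_heterozygotes_half(self):
        # one intraclonal SWxSW zygote + one outcrossed SWxNS zygote:
        # switcher gametes: 1 (intra) + 0.5 (out) -> frac 1/1.5
        pairs = [(SWITCHER, SWITCHER, True), (SWITCHER, NONSWITCHER, False)]
        pool = next_founder_pool(self._outcome(pairs))
        assert pool.intraclonal_fracs[SWITCHER] == pytest.approx(1 / 1.5)
        assert pool.intraclonal_fracs[NONSWITCHER] == 0.0


class TestBoundaryModes:
    @pytest.mark.parametrize("boundary", ["bounded", "torus"])
    def test_switchers_fix_without_cost_under_both_boundaries(self, boundary):
        # matched sweeps: no qualitative boundary effect on invasion outcome
        wins = 0
        for seed in range(10):
            params = SimParams(
                lattice=LatticeConfig(side_length=30, density=0.2, boundary=boundary),
                switching_cost=0.0,
                max_transfers=100,
                seed=seed,
            )
            traj = matesim.run_simulation(params)
            wins += traj.termination == "fixed_switcher"
        assert wins >= 8
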