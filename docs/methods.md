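# Methods

## The lattice model

The simulation tracks haploid fission-yeast cells on a square grid of
`side_length²` sites (default 200 × 200 = 40,000). Each occupied site stores
a mating type (P or M), a strategy (switcher or non-switcher), a switching
phase for switchers (competent "will switch" / non-competent "won't
switch"), the clone id of its founder in the current growth phase, an
intraclonal-origin flag, and a mated flag. One *transfer* (sexual cycle) is:

1. **Seeding.** `round(density × side²)` founders are placed at uniformly
   random sites. Strategy is drawn i.i.d. Bernoulli(switcher frequency) —
   spore sampling, not deterministic rounding, so fixation and loss are
   genuine absorbing events. Mating type is a fair coin (Mendelian
   segregation at the mating-type locus) and switcher founders are competent
   with probability 1/2.
2. **Asexual growth.** Rounds iterate until no empty site remains. Within a
   round, the cells occupied at the round's start are visited once each in a
   fresh random order (random-sequential update; occupancy changes take
   effect immediately, avoiding the write conflicts of a synchronous
   update). A visited cell with at least one empty Moore neighbour divides
   with probability `R · (1−s if switcher) · (c if intraclonal-origin)`,
   the target chosen uniformly among its empty neighbours; a fair coin
   decides which product migrates. Growth uses the same Moore neighbourhood
   as mating.
3. **Switching pedigree.** A non-switcher's daughters keep her type, always.
   When a *competent* switcher divides, exactly one product carries the
   opposite type and starts non-competent; the other keeps the type and
   stays competent. When a *non-competent* switcher divides, one product
   becomes competent. This reproduces the canonical one-daughter-switches /
   competence-after-one-division lineage pattern with a two-state phase.
   A `phase_rule="bernoulli"` variant re-draws both phases fair-coin at each
   division for sensitivity checks.
4. **Mating.** Unmated cells are visited in random order; each pairs with a
   uniformly chosen unmated opposite-type partner — a Moore neighbour
   (`mating_mode="moore"`) or any cell (`"global"`). Eligibility ignores
   strategy and clone identity: intraclonal mating is allowed, and is
   precisely what a mixed-type switcher patch can do that a monotype
   non-switcher patch cannot. One greedy pass yields a maximal matching (a
   cell left unpaired at its visit can never gain a partner later, since
   partners are only ever consumed); in global mode the pass pairs exactly
   `min(#P, #M)` cells.
5. **Reseeding.** The zygotes define the next founder pool. The switching
   locus segregates 1:1 from heterozygous zygotes, so the expected switcher
   gamete frequency is `(2·n_SW×SW + n_SW×NS) / (2·n_zygotes)`. Intraclonal
   fractions per strategy are carried the same way (heterozygous zygotes
   weighted half to each strategy) and expressed as the multiplicative
   division-chance factor `c` for one growth phase, cleared at the next
   reseeding — the minimal reading of a one-generation inbreeding cost.

A run terminates on fixation of either strategy (at reseeding sampling or in
the gamete pool), on extinction (a mating round with zero zygotes — an
outcome, not an exception), or at `max_transfers` (default 500). Boundaries
are hard by default; a torus option exists and gives no qualitative
difference in invasion outcomes. `max_growth_rounds` optionally truncates
the asexual phase, making sex more frequent per mitotic generation; mating
then operates on the partially filled grid.

### Parameters

| name | default | meaning |
|---|---|---|
| `side_length` | 200 | grid edge (sites) |
| `density` | 1.0 | fraction of sites seeded, (0, 1] |
| `growth_chance` R | 0.5 | per-round division probability |
| `switching_cost` s | 0.0 | asexual cost of switching, in [0, 0.5]; switcher divides at R(1−s) |
| `intraclonal_cost` c | 1.0 | division-chance factor for intraclonal-origin founders, (0, 1] |
| `mating_mode` | moore | neighbourhood vs mass-action mating |
| `max_transfers` | 500 | sexual-cycle cap |
| `initial_switcher_freq` | 0.5 | founder switcher frequency at cycle 1 |

The `s ≤ 0.5` cap keeps the switcher division probability in [R/2, R]; the
parameterization R(1−s) versus R is first-order equivalent to any other
relative-fitness convention at these magnitudes.

All randomness in a run flows from a single seeded numpy `Generator`;
the compiled inner loops consume pre-drawn uniforms, so trajectories are
bit-reproducible from `(params, seed)`. Sweep replicates derive their seeds
from `SeedSequence([master, density_index, cost_index, replicate])`,
recorded in the output, making sweep cells independent of execution order.

## Fitness estimation

For competing strains *i*, *j* with frequencies *p* measured before and
after a competition, the total selection coefficient is the natural-log
ratio change `s_ij = log(p_i/p_j)|after − log(p_i/p_j)|before` —
antisymmetric under strain swap and invariant to count rescaling. Dividing
by `t = transfers × log₂(fold growth per transfer)` (five transfers at
100-fold ≈ 33 generations; at 500-fold ≈ 45) gives the per-mitotic-
generation coefficient. The fluorescent marker's own cost is removed under
log-additivity: `s = s_total − s_marker`, with the marker effect measured in
isogenic label-only control competitions of the same regime (enforced).
Correction precedes per-generation scaling; both spans share *t*, so the
order is a determinism convention only. Sexual competitions report
`s = 1 − w` with `w = exp(Δ log-ratio)` per sexual episode; no attempt is
made to decompose *w* into pre-mating growth, mating success and post-mating
growth. Zero counts raise by default; an optional Haldane 0.5 pseudocount is
available and flagged. Replicate summaries report mean and SE of the mean
(SE undefined below two replicates).

## Mutation-rate bounds

* Negative screen of N spores: the exact zero-class root
  `μ_max = 1 − α^(1/N)` (computed via `expm1` for stability) with the
  Poisson companion `−ln α / N`; both are reported because they agree to
  <1 % for N ≥ 10⁴ and the printed headline value is their common rounding.
  A screen with observed events is rejected — that calls for a
  likelihood-based estimator, which is outside this package's scope.
* Event-count lower bound: `events / (generations × populations ×
  opportunities per generation)`; zero events return 0 with a warning that
  the result is then not a bound.
* Bottleneck-loss correction: `rate / (1 − q)`. The loss probability
  utility returns both the exact `(1−f)^n` and Poisson `exp(−nf)` forms.
  Note the two published numbers it connects are mutually inconsistent: a
  5 × 10⁸-cell subsample at frequency 5 × 10⁻⁸ gives e⁻²⁵, while the quoted
  0.37 corresponds to n·f = 1 (e⁻¹). The package evaluates whichever
  configuration it is given and reconciles nothing silently.
* Independent asci: sampling k spores without replacement from a asci × 4
  pooled spores, the expected number of asci hit is
  `n_asci · [1 − C(T−4, k)/C(T, k)]`; the Monte Carlo draws the per-ascus
  sample counts from the multivariate hypergeometric distribution and
  counts non-zero asci. Without-replacement is the physical choice — a
  spore cannot be picked twice.

## The synthetic-data generator

`GeneratorSpec` fixes a true per-generation coefficient, a marker effect,
the transfer schedule and a sampling depth. The latent frequency advances
deterministically on the log-odds scale by `t · (true_s ± marker_effect)`
(sign by labelled side) — the same additivity the correction assumes — and
the only noise is multinomial counting at fixed depth, emulating a flow
cytometer classifying a fixed number of events. `sampling_depth=None` gives
the deterministic limit (estimators recover truth to machine precision);
an optional Gaussian between-replicate jitter (default 0) stands in for
biological replicate variance, which is not observable from the published
summaries. Reciprocally labelled record sets enable the marker-swap
symmetry check. Sexual records assign a relative fitness *w* per density
(optionally as a function of the before-frequency, for frequency
dependence).

What the generator deliberately does **not** emulate: gating noise and
debris in real cytometry, germination and killing efficiency, shared-flask
covariance between replicates, and any density dependence it is not told
about. Passing round-trip tests therefore demonstrates estimator
correctness under the stated noise model, not robustness to those
artefacts.

## Problem sizes and test conditions

* **One-cycle neutrality** (no cost, no intraclonal penalty): 200 replicate
  cycles on a 30 × 30 grid at density 1.0, where mating success is
  independent of strategy and the strategy labels are exchangeable, so the
  expected frequency change is exactly zero. At lower densities with
  neighbourhood mating the expectation is *not* zero even at s = 0 — the
  mating advantage of switchers is the phenomenon itself. Growth-phase
  symmetry at s = 0 is checked separately through the two-founder
  patch-size race.
* **Invasion sweep**: 50 × 50 grid, densities {0.1, 0.5, 0.9} × costs
  {0, 0.25, 0.5}, 10 replicates per cell, 50:50 start, run to the
  500-transfer / fixation / extinction endpoint — the endpoint at which the
  heat map's claims are stated. At a 100-transfer truncation the
  highest-density cells are still mid-flight (per-transfer selection there
  is ~0.015 logit units), which ends runs at intermediate frequencies that
  reflect truncation, not stable polymorphism.
* **Structured-mating advantage**: one growth-plus-mating cycle on a
  100 × 100 grid at density 0.005 (50 founders → ~200-cell patches),
  10 replicates.
* **Estimator recovery**: depth 10⁵, 8 replicates, marker effect
  0.005/generation (a small insertion cost; the controls' measured value is
  not published), at the two study regimes — exponential (5 transfers ×
  500-fold, t ≈ 45, s = 0.016) and saturated (5 × 100-fold, t ≈ 33,
  s = 0.035) — plus a sexual competition at w = 0.163 (s = 0.837).
* **Ascus sampling**: 20 Monte-Carlo replicates at full scale (2.5 × 10⁶
  asci, 10⁶ spores sampled); the per-replicate SD is ≈ 280 on a mean of
  ≈ 8.6 × 10⁵, so 20 replicates pin the mean far below the 0.5 % comparison
  band.

## Numerical and degenerate-input conventions

Ties everywhere break by uniform draws from the run's single RNG stream.
Seeding below two founders, non-positive growth chances, costs outside
their ranges and oversampling are configuration errors raised before any
work. `run_growth` guards non-terminating configurations with a
1000 × side² round cap. Mating on a non-full grid is an error unless the
growth phase was explicitly truncated. Extinct sweep replicates are
excluded from cell means and reported as a separate count.

## Known limitations

No diploid vegetative growth, haploid sporulation, pheromone diffusion or
nutrient dynamics; the growth neighbourhood is fixed to Moore; the
intraclonal cost persists exactly one growth phase; sexual-fitness
estimates fold growth and mating success into a single *w*; and the
fixation-time arithmetic for a non-switching mutant under pure asexual
growth is out of scope.
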