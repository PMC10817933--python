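# Methods

## Model

The simulator couples two stochastic processes on a fixed undirected
network of `N` individuals.

**Opinion dynamics (bounded confidence).**  Each node `i` holds an opinion
`x_i ∈ [0, 1]`, initialised i.i.d. Uniform[0, 1].  When the tie `(i, j)`
activates at time `t`, the pair attempts an exchange:

    if |x_i − x_j| < d:        (strict inequality)
        x_i ← x_i + μ (x_j − x_i)
        x_j ← x_j + μ (x_i − x_j)

with both assignments using pre-update values.  `d ∈ (0, 1]` is the
confidence level (tolerance), `μ ∈ [0, 1]` the influence parameter.  A
successful exchange conserves `x_i + x_j` exactly and contracts the pair
difference by `|1 − 2μ|`; updates are convex combinations, so opinions can
never leave `[0, 1]`.  Default `μ = 0.5` (the canonical midpoint rule, which
changes the speed but not the attractor structure of the dynamics).

**Link activation (renewal clocks).**  Every tie carries an independent
renewal process: after firing at `t` it re-arms at `t + Δt` with `Δt` drawn
from the tie's inter-event distribution.  Supported families:

* exponential, rate `b` (mean `1/b`): memoryless, the homogeneous baseline;
* log-normal, `ln Δt ~ Normal(ν, σ²)`: right-skewed; `σ` sweeps the
  activation pattern from nearly periodic (`σ ≪ 1`, the distribution
  approaches a point mass at `e^ν`) to extremely bursty (`σ ≫ 1`, nearly
  power-law over many decades).

The first activation of each tie is drawn from
`Normal(init_mean, init_mean/4)` truncated to positive values, with
`init_mean` defaulting to the distribution's (effective) mean — a
scale-matched start whose influence is removed by the burn-in.  Before
opinions attach, a transient of 10 events per link (10 × |E| activations)
is discarded so that the event stream is close to its stationary renewal
state.  Events are delivered in global chronological order; simultaneous
events are ordered by link index.

**Truncation of the heavy tail.**  The log-normal mean
`exp(ν + σ²/2)` is astronomically large for σ ≳ 6 (at σ = 20 it is
~7·10⁸⁶), so untruncated draws produce arbitrarily long dead periods, the
renewal process has no usable stationary regime, and stabilisation times
explode beyond any physically interpretable scale.  Inter-event draws are
therefore resampled until `Δt ≤ dt_max`, with `dt_max = 10⁶` time units by
default; i.e. the working distribution is the log-normal conditioned on
`Δt ≤ dt_max`.  At this truncation point the effective means are ~1.005
(σ=0.1), 1.649 (σ=1), 38.0 (σ=2.7) and ~2.1·10⁴ (σ=20) — for σ ≤ 1 the
truncation is numerically invisible.  `InterEventModel.analytic_mean`
reports the closed form (∞ if it overflows the floating range) and
`effective_mean` the truncated mean used for comparator matching; the
`mean_exceeds_truncation` flag marks the heavy-tail regime in which only
the effective mean is meaningful.

**Homogeneous comparators.**  Every log-normal pattern is compared against
an exponential process with the same effective mean inter-event time
(`ActivationSpec("exponential-matched", sigma=...)`).  Because the
exponential dynamics is invariant under time rescaling, cluster statistics
of the plain `rate=1` exponential and of any matched comparator agree; the
matching matters only for time-valued observables such as `T_f`.

**Stopping rule.**  The run ends when a window of `stop_window`
consecutive activations passes without a successful exchange
(default `stop_window = N`); the stabilisation time `T_f` is the continuous
time of the last successful exchange, and an `events_to_stable` counter is
reported alongside so either convention can be analysed.  A window in
continuous time (`stop_time_window`) is also available but off by default:
under bursty clocks a time window races against the heavy tail of the
quiet periods and produces a zero-inflated, high-variance mixture of
half-frozen and fully coarsened outcomes, whereas the event-count window
yields a clean, unimodal stationary state.  A `max_events` hard cap
(default 10⁸) guarantees termination and is reported as a distinct
termination reason, as is exhaustion of a finite schedule horizon.

**Numerical quiescence.**  With μ = 0.5 an updated pair becomes exactly
equal, after which further activations of that pair pass the confidence
gate but change nothing; counting them as "successful" would prevent the
stopping window from ever closing at consensus.  An exchange therefore
counts as successful only if it moves at least one opinion by more than a
tolerance, `quiescence_atol = 10⁻⁶` — two decades below the cluster
resolution ε = 10⁻⁴, so the rule cannot alter detected cluster structure
(verified: cluster counts at d ∈ {0.05, 0.1} are identical for tolerances
0, 10⁻¹², 10⁻⁹ and 10⁻⁶, while run length shrinks ~6×).  Setting
`quiescence_atol = 0` recovers exact floating-point quiescence.

The N-event window can close while a handful of exchange-capable pairs
remain (a given link fires on average `N/|E|` times per window), so a
stopped run may admit a sub-percent trickle of further exchanges if
continued; this never changes the cluster summary (tested).

## Cluster detection

Final opinions are sorted; a new cluster opens at every consecutive gap
≥ ε = 10⁻⁴ (equivalent to one-dimensional single-linkage clustering at
threshold ε, which the tests verify by brute force).  A cluster counts
only if it holds at least `ceil(0.01 N)` members (inclusive reading of
"at least 1%"); smaller groups — typically poorly connected individuals
stranded between clusters — are reported as `unclustered`.  A cluster's
position is the arithmetic mean of its members (members differ by less
than ε each, so any representative is equivalent at reporting precision);
profiles report relative size `Ω = S/N` against offset `Δx = position − 0.5`,
aggregated across runs in Δx bins of width 0.05 by default.

## Substrates

* **Erdős–Rényi** `G(N, p)` with `p = ⟨k⟩/(N−1)`; defaults N = 1000,
  ⟨k⟩ = 20.
* **Watts–Strogatz**: ring lattice with `k_nn` nearest neighbours (default
  6), each edge rewired with probability `q`.  At `q = 0` the clustering
  coefficient is exactly `3(k_nn−2)/(4(k_nn−1)) = 0.6`; `q ≈ 0.33`
  reproduces ⟨cc⟩ ≈ 0.18 via `cc(q) ≈ 0.6 (1−q)³`.
* **Attribute-fitness growth**: nodes carry `θ ~ Uniform[0,1]`; growth
  starts from a complete graph on `m` nodes (giving ⟨k⟩ = 5.988 for
  N = 1000, m = 3) and each arrival attaches to `m` distinct nodes drawn
  without replacement with probability ∝ `k_i · exp(−β |θ_J − θ_i|)`,
  weights renormalised after each draw so the graph stays simple.  β = 0
  is pure preferential attachment (power-law degree tail `P(k) ∝ k⁻³`);
  large β trades hubs for attribute homophily, raising clustering and
  modularity.
* **Configuration null**: degree-preserving double edge swaps
  `((a,b),(c,d)) → ((a,d),(c,b))`, proposals creating loops or duplicates
  rejected; default 10·|E| accepted swaps, with a proposal budget so that
  rigid graphs (e.g. a triangle) terminate with a warning.

Structural statistics: ⟨k⟩ = 2|E|/N exactly; mean clustering with
`cc_i = 0` for degree < 2; normalised shortest-path betweenness with
endpoints excluded; degree assortativity as the Pearson correlation over
both edge orientations (None for regular graphs); modularity `Q` of either
a Louvain partition (default), a greedy CNM partition, or the fixed
partition of nodes into attribute quintiles.  The attribute partition is
the only reading under which unstructured substrates (β = 0, rewired
nulls) score Q ≈ 0 — a modularity maximiser finds Q ≈ 0.4 on any sparse
random graph — so it is the natural yardstick for attribute homophily;
its value at β = 100 depends mildly on bin count (0.72–0.78 for 3–10
bins; quintiles are the default).

## Replicate design

The canonical experiment generates 15 substrates per condition and runs
20 simulations per substrate (300 replicates per cell), sweeping d over
{0.05, …, 0.5} and the activation patterns {exponential; log-normal
σ ∈ {0.1, 1, 2.7, 20}}.  Cell statistics are the replicate mean and the
standard error `sd/√m` over all pooled replicates.  All randomness derives
from one master seed through stable spawn keys (cell, substrate, run), so
each replicate is individually reproducible and execution order is
irrelevant.  Scaled-down designs used by the test-suite and the
reproduction script (5 substrates × 6 runs, or 5 × 2 per sweep cell) keep
the same structure.

## What the generator does and does not emulate

Synthetic substrates and renewal clocks capture the degree mixing,
triangles/modularity, and inter-event dispersion that the model studies;
they do not emulate degree–activity correlations, circadian or weekly
rhythms, cross-link correlation of activity (all clocks are independent),
or co-evolution of ties with opinions.  Conclusions from passing tests
therefore concern the model's mechanics, not the fidelity of any real
communication dataset.

## Known limitations

* With truncation-consistent sampling (`dt_max = 10⁶`, the only sampling
  scheme consistent with the quoted effective means at σ = 2.7 and σ = 20)
  and any quiescence-style stopping rule, the stationary cluster count on
  ER substrates is essentially independent of burstiness: σ = 20 coarsens
  to the same ~4–5 clusters at d = 0.1 as the homogeneous process, rather
  than freezing at ~9.  States with ~9–12 clusters do occur, but only as a
  mid-coarsening transient with large unclustered fractions; no window
  length (10³–10⁶ events, or 10²–10³ time units) stops there reliably.
  The burstiness slowdown itself is robust: stabilisation at σ = 20 takes
  ~5–6× longer (and ~3–4× at σ = 2.7) than the matched exponential.
* The σ = 20 regime inherits every choice made about the untamable
  log-normal tail; results there should be read as conditional on the
  truncation convention.
* Structural effects are robust and large: at d = 0.1 under exponential
  activation the mean cluster count grows from ~4.8 (β = 0) to ~11
  (β = 100), Watts–Strogatz substrates sit in between, and moderate
  burstiness amplifies the clustered-substrate effect (~16 clusters at
  σ = 2.7 on β = 100).
* Exact betweenness is O(N·|E|) and dominates `compute_stats` on large
  substrates; it can be skipped with `include_betweenness=False`.
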