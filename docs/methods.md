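# Methods

## The game

Two individuals drawn at random from a large population each choose an
effort `e ≥ 0` toward a common good. A player of ability `a ∈ [0, 1]`
expending `e` against a partner expending `e'` receives

    W(a; e, e') = B(e + e') − K(a, e),
    B(t) = 2t − t²  (t < 1),  B(t) = 1  (t ≥ 1),
    K(a, e) = (2 − a) e^p,   p > 1.

The benefit saturates (diminishing returns) and the cost accelerates, so
each player's best response declines as the partner works more, but by less
than one-for-one: players *partially compensate* for a lazy partner.  The
compensation slope is `−2 / (2 + (2 − a) p (p − 1) r^{p−2})` at an interior
best response `r`, always in (−1, 0); its magnitude grows as `p ↓ 1`.  That
compensation is the engine of every result here: a low-ability player's
partner picks up part of the slack, so low ability can pay.

## Nash efforts

Within a pair, efforts are assumed to be in Nash equilibrium.  Both
first-order conditions share the total effort `s = e₁ + e₂`, and each
inverts in closed form:

    e_i(s) = ( 2(1 − s) / ((2 − a_i) p) )^{1/(p−1)}.

Each `e_i(s)` is strictly decreasing, so `φ(s) = e₁(s) + e₂(s) − s` is
strictly decreasing with `φ(0) > 0` and `φ(1) = −1`: the equilibrium total
is the unique root of a guaranteed sign change on (0, 1).  The scalar
solver uses Brent's method (`xtol` 1e−15); the batch solver used by the
simulation bisects the same residual elementwise (80 halvings).  This
reduction was chosen over damped best-response iteration because the
bracket is unconditional (no contraction argument needed, no damping
schedule) and it vectorises trivially; best-response iteration is retained
in the test suite as an independent oracle, alongside the exact linear-FOC
closed form available at `p = 2`.  Solutions always satisfy `s < 1`, so the
kink of `B` at 1 (where the right derivative 0 is used by convention) never
binds.  Both first-order-condition residuals are checked against a 1e−10
tolerance and reported in the solution object.  Cost exponents within 1e−6
of 1 are rejected: the exponent `1/(p−1)` blows up and the game approaches
the degenerate linear-cost limit.

## Adaptive dynamics

A rare mutant `ã` in an `a`-monomorphic population has invasion fitness
`V(ã, a)`, its equilibrium payoff against a resident partner.  Numerics:

* selection gradient `∂V/∂ã` at `ã = a`: central difference, step 1e−5
  (second-order one-sided at the bounds).  The Nash solver is accurate to
  ~1e−12, leaving ample headroom; against the closed-form `p = 2` gradient
  the error is ~1e−11.
* attractor scan: gradient on a uniform grid (default 201 points); interior
  sign changes refined by bisection until `|gradient| < 1e−8`; a trait
  bound is a boundary attractor when the gradient there points into it.
* classification: convergence stability from the gradient's sign change
  across the point (offset 1e−3 in the *resident* direction);
  evolutionary stability from `∂²V/∂ã²` (central stencil, step 1e−4,
  *mutant* direction).  These are different sections of the same surface;
  a convergence-stable point with positive mutant-direction curvature is a
  branching point — selection drives the population to it, then favours
  divergence.

For `p = 1.25` the gradient is negative throughout, so `a = 0` attracts;
for `p = 2.0` it is positive throughout, so `a = 1` attracts; for `p = 1.5`
there is a single interior attractor, located numerically at `a* = 2/3`
(to 1e−10; pinned in the tests as a regression value at 1e−6), with
positive invasion curvature: a branching point.  Pairwise invasibility
plots are computed with the batch solver (default 201 × 201 grids); the
diagonal is identically zero by construction.

One caution on reading the mutant-sweep table (resident 0.5, `p = 1.25`):
the mutant's payoff is maximal at ability 0 and falls over most of the
range, but it has a shallow interior minimum near ability 0.8 and turns up
slightly toward 1 (the envelope-theorem slope `e^p + B'·∂e_partner/∂ã`
changes sign once the direct cost saving outweighs the partner's
disengagement).  Even at ability 1 the mutant stays strictly below the
resident payoff, so the invasion analysis is unaffected.

## Evolutionary simulation

The agent-based layer makes the minimal set of additional assumptions, all
of which are package choices rather than properties of the game, and all
overridable in `SimConfig`:

* **Pairing**: one uniformly random perfect matching per generation; each
  individual plays exactly one game.
* **Fitness**: the raw game payoff, which is provably ≥ 0 (zero effort
  always secures the partner-provided benefit).  Parents are sampled with
  probability proportional to payoff, with replacement; if every payoff is
  zero (unreachable in this game, but possible for degenerate inputs) the
  step falls back to uniform sampling with a warning.
* **Sexual inheritance** (infinitesimal model): offspring = midparent mean
  of two independently sampled parents + Normal(0, `segregation_sd`),
  clipped to [0, 1].  `segregation_sd = 0.05` by default — about 5% of the
  trait range, a conventional quantitative-genetics scale that keeps the
  standing ability SD near 0.07.  Clipping (not reflection) is used because
  the trait bounds are hard by definition.
* **Asexual inheritance**: clonal copy of one sampled parent; with
  probability `mutation_prob = 0.01` a Normal(0, `mutation_sd = 0.05`)
  perturbation, clipped.  At the default population size this supplies ~10
  mutants per 1000 offspring — enough variation to resolve branching within
  ~10⁴ generations without swamping selection.
* **Scale**: `n_individuals = 1000`, `n_generations = 10001` by default;
  the test suite runs at N = 500 and 2000 generations, which reproduces
  the qualitative outcomes in minutes.
* **Reproducibility**: one `numpy` generator seeded per run; draws occur in
  a fixed order (pairing permutation, parent indices, inheritance noise),
  so equal seeds give bit-identical results.

What the simulation shows, at the scales the test suite runs: sexual
populations move toward the adaptive-dynamics attractor and remain
unimodal throughout; at `p = 1.5` they settle around the interior
attractor; asexual populations started at the `p = 1.5` branching point
split into a bimodal distribution in most seeds.  The asexual branching
runs are initialized *at* the singular point: started from a trait bound,
most of a short run is spent in the slow mutation-limited approach to
`a*`, which tests approach speed rather than disruptive selection.

Two quantitative caveats, visible in the suite's own measurements.  First,
payoff-proportionate selection in this game is weak — across the entire
trait range relative payoff differences are only a few percent for
`p = 2.0` — so trait medians approach a boundary attractor asymptotically
and stop a small distance short of it, where the per-generation selection
response balances the upward (resp. downward) bias that clipping induces
once the population presses against a bound.  At the reduced test scale
the `p = 1.25` sexual runs end with medians near 0.1 and the `p = 2.0`
runs near 0.6–0.9, approaching but not reaching the bounds themselves.
Second, finite-population drift spreads the 5-seed endpoint distribution
noticeably at N = 500; endpoint checks therefore aggregate across seeds.

## Bimodality statistic

`bimodality_index` is a fixed valley-depth statistic: histogram on 20 equal
bins over [0, 1]; candidate modes are local maxima of the count vector
reaching at least 10% of the tallest bin (so a stray individual in a tail
bin cannot pose as a mode); take the tallest candidate and the tallest
other candidate at least two bins away; the index is
`1 − valley / min(peaks)` with `valley` the minimum count strictly between
them, and 0 when no such pair exists.  Calibration by Monte Carlo: uniform
samples of n = 1000 score below 0.5 in ~98% of seeds (95th percentile
≈ 0.45); well-separated two-cluster mixtures score ≈ 1; tight unimodal
clusters score 0.  The decision threshold is pinned at 0.5.

## Known limitations

* Only the two-player game; no partner choice, no repeated interactions,
  no co-evolution of the effort rule itself.
* Efforts are equilibrium values, not a mechanistic negotiation process.
* The inheritance models are the two textbook extremes (infinitesimal
  sexual, clonal asexual); real genetic architectures sit in between, and
  the evolved trait *distribution* (unlike the attractor location) depends
  strongly on that choice.
* The simulation omits any fitness consequences of ability outside the
  focal game; adding a residual benefit of ability would shift attractors
  upward.
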