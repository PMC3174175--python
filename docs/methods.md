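# Methods

This note records the model assumptions, parameter choices, numerical
decisions and known limitations behind `etmc`, at the level of detail a
user needs to judge what the package's results do and do not show.

## Model and assumptions

The chain's states are slope-change events (`product:sign`), not
qualitative levels; this compresses the dynamics of an asynchronous
logical model (hundreds of qualitative domains) into a graph of a dozen
nodes, which is what makes eigenvalue-based inference tractable. The
ETG derivation from a state transition graph creates an edge for every
length-2 path `s1 → s2 → s3`: the event of the first transition may be
succeeded by the event of the second. Self-successions (`x:+ → x:+`)
are kept when the state graph produces them. Transitions that change
zero or several variables violate the asynchronous convention and are
rejected.

Modelling a *population*: transition probabilities are the mean fraction
of cells whose trajectory crosses a given transition, and the stationary
law of the chain (the *permanent regime*) describes fixed proportions of
rising/falling transcripts across the population — not a biological
steady state. Unsynchronized cells motivate the uniform initial event
distribution used throughout.

Key assumptions inherited by every downstream number:

* protein concentration changes are **multiplicative** per event
  transition (appropriate for prokaryotic burst-like translation, and
  what makes exponential time-series segments the natural observable);
* gene activity and protein production are linearly related
  (prokaryotes; no post-transcriptional layer);
* the chain is **minimal** (irreducible and aperiodic) under every
  condition analyzed — oscillatory systems are out of scope, and
  dead-end events are a hard error rather than silently absorbed.

## The equilibrium rule and its two calibrations

The impact scales are `s` (into `p:+`), `d = 1/s` (into `p:-`) and `ρ`
(elsewhere, default 0.95 — a free parameter meaning 5% passive decay per
transition; configurable per protein). `d` is fixed so that, in the
absence of information (uniform transition probabilities), the expected
concentration stays constant. Two readings of "constant" are
implemented:

* **spectral** (default): the Perron eigenvalue of the uniform-chain
  elementary cost matrix is exactly 1, so the asymptotic mean
  concentration is flat. Solved by bracketed 1-D root finding in `d`
  (Brent, `xtol = 1e-14`), seeded by the stationary calibration below.
* **stationary**: the one-step expected factor under the stationary law
  equals 1: with stationary masses `m₊`, `m₋` of the two active events,
  `m₋ d² + ((1 − m₊ − m₋)ρ − 1) d + m₊ = 0`, taking the unique root in
  (0, 1]. This degree-two equation is the closed form of the rule; its
  root slightly *undershoots* λ = 1 (a multiplicative Jensen gap — the
  mean of a product is not the product of means), so the spectral
  calibration is preferred and is what all fixtures use.

The spectral equation has no solution on graphs where every cycle
through `p:+` also crosses `p:-`: there `s` and `d` cancel along each
cycle and no scale keeps the mean flat (sup over `d` of λ stays below
1). Real regulatory ETGs — and both packaged fixtures — do not have this
degeneracy, because a gene's rise and fall are reachable through
independent regulatory routes. The random-graph generator used in
property tests rejection-samples until the rule is well-posed for every
gene, mirroring that structure. With `ρ = 1` and symmetric masses the
rule degenerates to `d = 1` (all impacts trivial); this is flagged, not
an error.

## Accumulation statistics

`exact_mean` is the matrix-power formula `v₀ᵀ C(s)ⁿ 𝟙` (`s = 1` mean,
`s = 2` second moment); it is tested against exhaustive path enumeration
at `≤ 1e-12` on small instances. The asymptotic constants are
`a = (v₀·r₁)(l₁·𝟙)` and `b = (v₀·r₂)(l₂·𝟙)` with `l·r = 1`,
`Σr = 1`; the closed-form variance `b λ₂ⁿ − a² λ₁²ⁿ` can dip negative
at small `n` from neglected error terms, in which case the exact second
moment is substituted. The spectral-gap ratio `ε` is reported as a
convergence diagnostic; the error-term *constants* of the underlying
limit law are not computed, only the qualitative `εⁿ` decay is checked.

Dominant eigenpairs come from a dense solver up to 64 events (power
iteration beyond); a dominant eigenvalue that is complex or not simple
(within `1e-10` relative) raises a minimality error — this is how
periodic chains surface at analysis time.

Monte-Carlo simulation draws the initial event from `v₀` and steps by
inverse-CDF lookup on cumulative row distributions (bit-reproducible for
a fixed seed across platforms); log-impacts are accumulated to avoid
overflow. Two statistical caveats, both properties of the *diagnostics*
rather than the simulator: (i) accumulated log-costs live on the 2-D
lattice spanned by `log s` and `log ρ`, so their Kolmogorov–Smirnov
distance to a continuous normal has an `O(1/√n)` floor (≈ 0.02 at
`n = 200`) — the normality check therefore uses 2000 replicates, whose
1% critical value (≈ 0.036) sits above the lattice floor while still
rejecting clearly non-normal laws; (ii) the "mean within 3 standard
errors" agreement band is itself a CLT statement and under-covers for
strongly skewed costs, so the agreement test runs at moderate impact
scales (`s = 1.2`) where its nominal coverage holds.

## Time series and the transition duration

Curves are successions of exponentials `c(t) = K_i g_i^(t−t_i)` between
user-supplied cutpoints (no automatic change-point detection; the basal
concentration is taken as 0, which keeps the fit linear in log space —
a nonzero basal is accepted but fitted iteratively). Segments with more
than two points are fitted by least squares on `log c`; two-point
segments reduce to the endpoint ratio. The per-transition objective is
`λ = g^δ`, with `δ` from the N-end rule: one passive step multiplies by
`ρ`, so a half-life `τ` spans `ln(1/2)/ln ρ` steps and
`δ = τ ln(1/ρ)/ln 2` minutes. For the *E. coli* case the packaged value
is `δ = 7/20 = 0.35` min, taken directly from the model's
20-iterations-per-7-minutes correspondence. Interval objectives default
to ±5% around the point estimate when no width is supplied.

## Inference

The score of a candidate matrix is the Euclidean distance between the
achieved Perron eigenvalues and the objectives. Optionally an objective
also pins the initial-condition constant `a` of its accumulation law
(the intercept of the fitted exponential under uniform initial events):
when a specification provides two measured points — slope *and*
intercept — fitting `λ` alone leaves `a` free across the solution set
and the realized fold-change scatters by a few percent; the two-gene
tutorial therefore fits `(λ, a)` with `a_target = 1`. Interval
feasibility always applies to `λ` only.

The optimizer is a seeded two-stage local search over one free
parameter per ETG edge with per-row renormalization: (1) exploration by
multi-start (default 8; uniform chain first, then Dirichlet rows)
stochastic descent, each move scaling one edge by `exp(±step)` with the
step growing 1.3× on success and halving after 30 rejections; (2) a
Powell direction-set polish in log-parameter space on the best point,
which follows the narrow curved valleys of the implicit eigenvalue
score far better than single-coordinate moves. Both stages share one
evaluation budget (default 20 000) and one RNG, so results are
deterministic given the seed. Non-convergence is a flag on the returned
point, never an exception.

Phases: objectives tagged with a condition evaluate on the
condition-filtered subgraph with the shared probabilities restricted
and renormalized there — one chain drives every phase.

Solution-set geometry follows the polyhedral picture: a source point is
searched against interval midpoints; boundary points are found by
bisection (tolerance `1e-6`) along random directions projected onto the
row-sum-zero tangent space, stopping when an interval endpoint or a
simplex face becomes active; the volume is a Monte-Carlo hit ratio over
the bounding box of the collected points in free coordinates (each
row's last edge eliminated by the sum constraint), with a binomial
standard error. Monte-Carlo was chosen over exact polyhedral
computation, which does not scale beyond a few genes. Interior samples
for prediction are Dirichlet convex combinations of source and boundary
points, re-checked for feasibility at the boundary tolerance.

Sensitivity multiplies one edge probability by 1.01, renormalizes the
row, and reports `100·|ΔF|/F`; at a (near-)exact optimum (`F ≤ 1e-9`)
raw `|ΔF|` is ranked instead, since the relative form is undefined at
zero. Note that the two edges of a two-edge row have exactly collinear
perturbation directions, hence tied first-order sensitivities — rankings
are meaningful up to such ties.

## Fixtures: what is printed, what is reconstructed

* **Two-gene tutorial** — the published transition matrix is graphical;
  the packaged graph (4 events, 8 edges, out-degree 2 everywhere,
  symmetric under the simultaneous swap x↔y, +↔−, non-bipartite hence
  aperiodic, uniform stationary law) is a reconstruction exposing the
  tutorial's two free parameters via `two_gene_matrix(p, q)`. The
  tutorial's passive rate (the one yielding `d = 0.882`) is not in the
  main text; `ρ` stays configurable with default 0.95.
* **Carbon starvation** — printed facts honored and self-checked at
  build time: 11 nodes, 22 edges, exactly 2 edges absent under
  starvation, minimal uniform chain under both conditions, Fis
  repression of *crp* (`fis:+ → crp:-`), supercoiling couplings among
  *fis*/*gyrAB*/*topA*, and the starvation signal feeding the
  cAMP·CRP complexation partners. Everything else about the edge list
  is reconstruction; the data file is plain TSV so users can substitute
  the true graph. `crp` and `cya` are built as exact structural twins
  (a graph automorphism swaps them), which makes their predicted growth
  behavior identical *in law* over the solution set; a single
  source-anchored sample retains a residual asymmetry of a few percent
  between their sampled means.
* **Fis series** — only the ×10-in-80-minutes stationary rise and the
  subsequent exponential-phase decline are printed; the sampling grid,
  initial level and decay rate are synthetic and labeled as such.

## Problem sizes and determinism

Property tests run on random well-posed ETGs of 4–12 events; path-
enumeration oracles use ≤ 5 events and horizons ≤ 7; hidden-chain
recovery uses 20 instances of 6–10 events with 1–3 objectives; the
Monte-Carlo checks use 2 000–50 000 replicates. Every stochastic
component (generator, search, simulation, sampling) takes an explicit
seed and is reproducible bit-for-bit given it.

## Limitations

* The synthetic generator produces ideal piecewise-exponential data
  with independent log-normal noise; real protein assays have
  correlated errors, baseline drift and nonzero basal levels, so
  passing tests demonstrate correctness of the machinery, not
  robustness to instrument systematics.
* Only the eigenvalue vector is identifiable from growth data; the
  matrix itself is not (the solution set has positive dimension), which
  is precisely why the polytope, not a point estimate, is the primary
  inference object.
* Additive accumulation rules, time-varying impacts, continuous-time
  chains and oscillatory (periodic) dynamics are out of scope.
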