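# Methods

This note documents the model, the numerical choices, and the scope of
the validation suite, in the order a reader would meet them.

## Model

Let *V* be the nodes of an ARG and *E* its logical edges (all genomic
segments shared by one parent–child pair, merged; the model depends
only on per-pair totals).  Sample nodes have known age 0; internal node
ages *t* are latent.  Each logical edge *ij* with span *s* (bp) and
mutation count *y* contributes a Poisson likelihood

    p(y | t_i - t_j) = (mu s)^y / y! * (t_i - t_j)^y exp(-mu s (t_i - t_j)),

valid on *t_j < t_i* and zero otherwise.  Ultimate roots (internal
nodes with children but no parents) carry an exponential prior
exp(-eta t); all other internal nodes carry an improper flat prior, so
their marginals are shaped purely by the data.  The posterior is
approximated by independent Gamma marginals fitted by expectation
propagation (EP).

### EP mechanics

Marginals are stored in natural coordinates: a factor (a, b) has density
t^a e^(-bt).  A node's marginal is exactly the sum of its prior factor
and the factors of its incident edges — a bookkeeping identity asserted
in tests.  One edge update:

1. cavity = node marginals minus this edge's factors;
2. surrogate = cavity × exact Poisson factor;
3. surrogate first/second moments for parent and child in closed form
   (below);
4. moment-matched Gammas replace the two marginals; factor differences
   are stored back.

Moments, not (mean, E log t), are matched: matching E t and E t² is
markedly more stable and near-equivalent in fit.  A sweep runs over all
edges ordered leaves-to-roots and back (deterministic order: edges
sorted by child topological rank, parent rank, child id, parent id,
with ranks from Kahn's algorithm, smallest id first).  After each sweep
the root-prior rate is refit by EM:

    eta' = (#roots) / sum_r (alpha_r / beta_r),

the reciprocal mean of the current root-age posteriors; its fixed point
is verified exactly in tests.  Convergence is declared when no node's
natural parameters move more than `tol` (default 1e-6) in a sweep;
default cap 25 sweeps.

### Surrogate moments

With cavity Gammas (ai, bi) for the parent and (aj, bj) for the child,
the surrogate density is

    t_i^(ai-1) t_j^(aj-1) (t_i - t_j)^y exp(-bi t_i - bj t_j - mu s (t_i - t_j)).

Writing T = ai + aj + y, d = mu s + bi and z = (mu s - bj)/d, the child
moments are products of Pochhammer ratios with the Gauss-hypergeometric
ratios F_n/F_0, F_n = 2F1(aj+n, T+n; aj+y+n+1; z); the parent moments
follow by the linear recursions

    E t_i  = z E t_j + T/d,
    E t_i² = z² E t_j² + (T+1)/d (2 E t_i - T/d).

When the child is a contemporary sample the surrogate collapses to
Gamma(ai + y, d) and the moments are immediate.  All four formulas were
fixed against an adaptive 2-D quadrature oracle before the engine was
built, and the validation suite re-checks them on a 200-point parameter
grid to 1e-6 relative error.

### Hypergeometric evaluation

F_n/F_0 is needed for arbitrary z < 1 and shapes ranging over many
orders of magnitude, where a naive 2F1 overflows (the ratio stays
moderate).  The primary route is a log-scaled power series: for
0 ≤ z < 1 the series terms are positive and are summed in linear space
with periodic rescaling; for z < 0 a Pfaff transform on the second
parameter maps the argument to z/(z-1) ∈ (0,1) with transformed
parameters (y+1, T+n) — again all positive, so no cancellation is
possible.  The inner loop is numba-compiled.  When the series would
need more than 4000 terms, evaluation falls back to tanh-sinh
(double-exponential) quadrature of the Euler integral

    I_n = ∫₀¹ x^(aj+n-1) (1-x)^y (1-zx)^(-(T+n)) dx

computed entirely in log space (the substitution x = sigma(pi sinh t)
keeps both endpoints accurate), refined over a three-level ladder
(h = 1/24, 1/48, 1/96) until two consecutive levels agree to 1e-10.
scipy's hyp2f1 is used only as an independent cross-check in tests; on
extreme parameter sets the two in-house routes agree with each other
where scipy's implementation loses accuracy.

### Feasibility projection and damping

A proposed update is applied as a line search: the largest step
fraction lambda ∈ [0,1] such that every affected node marginal keeps
shape ≥ 1e-3 and rate ≥ 1e-12 (normalizability with a small margin).
lambda = 0 skips the edge; infeasible cavities (e.g. a flat parent and
flat child early in the first sweep) are skipped and counted.  Damping
is off by default — EP converges fast here without it — but an edge
whose updates are repeatedly projected has its personal damping halved
as a safety valve.  On simulator output, projections are absent or
rare (counted in every result's metadata).

### Output point times

Posterior means are topologically unconstrained; for output tables and
tree-sequence round trips each node is lifted leaves-to-roots to at
least 1e-9 generations above its oldest child.

## Timescale calibration

EP is local; the Poisson model's global consequence — mutations per
unit time proportional to mu — is enforced afterwards by a
piecewise-linear strictly monotone map g of EP time with g(0)=0.  The
grid comes from equally spaced quantiles of provisional mutation ages;
within each cell the slope is (observed mutation mass)/(mu × expected
opportunity).  Two conventions are shipped:

* **path rescaling** (default): both sides are computed *per sample* —
  each mutation weighted by its carrier fraction, each edge's area
  weighted by the fraction of samples below it.  This measures average
  root-to-leaf mutational distance and is insensitive to spurious
  polytomies.
* **area rescaling**: raw totals, the convention of MCMC-based daters.
  Collapsing unmutated branches into polytomies *inflates* total edge
  area (children re-attach across the removed branch's duration), so
  area rescaling acquires a strong systematic bias where path rescaling
  does not — the validation suite reproduces this contrast.

Mutation mass is spread uniformly over each edge's extent between the
posterior mean child and parent ages (consistent with the mutation-age
model); carrier counts come from one pass over marginal trees (via
tskit).  Cells without signal are merged into their successor.
Posteriors are transformed by mapping their 2.5% and 97.5% quantiles
through g and refitting the Gamma that reproduces the transformed pair
— a bisection on the shape (the quantile ratio is scale-free and
strictly decreasing in shape) plus one rate solve.  A single-slope map
therefore transforms Gamma(a, b) to Gamma(a, b/slope) exactly.  The
quantile pair is configurable; wide quantiles stabilize tail behaviour.

## Mutation ages

A mutation is equally likely anywhere on its edge: with independent
parent and child age posteriors, E m = (E t_i + E t_j)/2 and
E m² = (E t_i² + E t_i E t_j + E t_j²)/3, moment-matched to a Gamma.
Independence is inherited from the factorized variational posterior and
is an approximation.  Credible intervals are central Gamma quantiles
(default 95%).  Age z-scores within derived-allele-count bins use
log10 ages and the population (divisor n) standard deviation — bins can
be tiny, so the convention is fixed and stated; bins with fewer than
two usable members, or zero spread, yield missing values.

## Singletons with unknown phase

A singleton in a diploid individual could sit on either of the two
terminal edges above the individual's two sample nodes at that
position.  Terminal edges are first split so every individual has at
most two immediate ancestors over the span of every attached edge.
Strategies:

* **shortest edge**: place the mutation on the candidate with the
  smaller logical span (ties to the lower sample id) — the longer-lived
  parent haplotype is the likelier carrier.
* **phase-agnostic EP** (default): each singleton contributes
  fractional counts (w, 1-w) to its two candidate edges (initialized to
  the span ratio, favouring the shorter edge).  After every sweep w is
  refreshed to the posterior probability of the first phase: the ratio
  of marginal Poisson evidences with the singleton moved to either
  edge, all other counts fixed, under the parents' current cavity
  Gammas — for a sample-child edge, log Z(y+1) - log Z(y) =
  log(mu s) - log(y+1) + log(a+y) - log(mu s + b).  The responsibility
  scheme (an EM-within-EP approximation chosen here; per-sweep rather
  than continuous updating) conserves counts exactly, is invariant to
  relabeling the two haplotypes, returns w = 1/2 under exact symmetry,
  and with all phases forced to 0/1 reduces bit-for-bit to the plain
  engine.  The singleton's age posterior is the w-mixture of the two
  per-edge age posteriors, moment-matched to a Gamma.
* **random** assignment is kept as the worst-case baseline for
  benchmarking.

## Synthetic data and oracles

The simulator wraps msprime's coalescent with recombination (so true
node times are exact) and drops mutations by hand as Poisson counts per
edge segment, recording each mutation's true age uniform on its branch
interval.  Defaults — 200 haploid samples, 1 Mb, N = 1e4, mutation and
recombination rates 1e-8 — are a neutral human-like setting that yields
roughly a thousand internal nodes and mutations per replicate; the
calibration check pools three replicates to exceed 2000 internal nodes.
Diploid simulations (ploidy 2) provide individuals for the singleton
machinery.  What the generator does *not* emulate: topology error from
real inference, demographic structure, selection, recombination-rate
variation, sequencing error.  Passing tests therefore demonstrate
correctness of the dating machinery given the topology, not robustness
to misinference; the polytomy experiment (collapsing branches without
mutational support) probes one specific, well-defined form of topology
degradation.

Two independent brute-force oracles validate EP on small graphs:
vectorized rejection sampling (roots proposed from the exponential
prior, other internal nodes uniform below their parents oldest-first,
with the proposal-density correction in the acceptance weight and a
pilot-estimated cap) and nested adaptive quadrature over the ordering
polytope (≤ 3 internal nodes; times nondimensionalized by 1/eta so the
integrator sees O(1) variables).  The two oracles agree within
Monte-Carlo error on shared instances, and EP matches them to well
under the 2% (means) / 10% (sds) bands — on pure chains EP is exact to
machine precision.

## Parameters that matter

| parameter | default | units | notes |
|---|---|---|---|
| mutation_rate | required | /bp/generation | the molecular clock |
| tol | 1e-6 | natural-parameter change | convergence criterion |
| max_iter | 25 | sweeps | EP converges in a handful |
| damping | 1.0 | — | off; per-edge auto-halving on projection |
| root_prior | em | — | or fixed:<rate> |
| rescale | path | — | path / area / none |
| rescale_intervals | 100 | quantile cells | merged when empty |
| q_lo, q_hi | 0.025, 0.975 | quantiles | posterior transform pair |
| alpha_min, beta_min | 1e-3, 1e-12 | shape/rate floors | projection bounds |

## Known limitations

* Contemporary samples only; tables with nonzero sample ages are
  rejected explicitly.
* The factorized posterior underestimates dependence between adjacent
  node ages; mutation-age posteriors inherit the independence
  approximation.
* Root-age regularization is a single exponential (adequate when recent
  ages are the target; a heavy-tailed mixture would serve deep roots
  better).
* The phase-agnostic responsibility scheme is an approximation to full
  phase marginalization; its contract is the set of invariances listed
  above plus the simulation benchmark, not exactness.
* No time-varying or per-region mutation rates.
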