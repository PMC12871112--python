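# vgdate

Variational-Gamma dating of ancestral recombination graphs (ARGs):
approximate Gamma posteriors for the ages of every internal node and
mutation of an ARG with contemporary samples, computed by expectation
propagation (EP) and calibrated against the molecular clock.

## The problem

An ARG records the inheritance relationships among a set of sampled
genomes: *nodes* are ancestral haplotypes, *edges* transmit a genomic
segment from an older parent node to a younger child node, and the graph
induces a genealogical tree at every position along the sequence.  Many
ARG-inference tools recover the *topology* of this graph but not the
*ages* of its nodes — and mutation ages (allele ages) are what link
genealogy to population history, selection and variant interpretation.
vgdate assigns calibrated, uncertainty-aware ages to all nodes and
mutations of a given topology, scaling to graphs far beyond the reach of
MCMC samplers.

## The model

For an edge from parent *i* to child *j* with genomic span *s<sub>ij</sub>*
bp carrying *y<sub>ij</sub>* mutations, the mutation count is Poisson:

```
y_ij | t_i, t_j  ~  Poisson( mu * s_ij * (t_i - t_j) ),    t_j < t_i,
```

with *mu* the per-base per-generation mutation rate.  Parentless
("ultimate root") nodes carry an exponential prior with rate *eta*,
refitted by EM each sweep.  The exact posterior over node ages is
intractable (a high-dimensional integral over an ordering polytope), so
vgdate fits a product of Gamma marginals by expectation propagation:
each edge's contribution to its two node marginals is iteratively
refined by removing it (the *cavity*), multiplying the cavity by the
exact Poisson factor (the *surrogate*), and moment-matching new Gamma
marginals to the surrogate's first two moments, which are available in
closed form through Gauss hypergeometric ratios.  A sweep visits all
edges leaves-to-roots and back; convergence typically takes a handful of
sweeps regardless of graph size.

After EP, a piecewise-linear monotone rescaling of time enforces the
molecular clock on the *per-sample* mutation count (path rescaling),
which is robust to polytomies that encode topology uncertainty;
posteriors are moved through the map by quantile matching.  Mutation-age
posteriors place each mutation uniformly along its edge and integrate
over the parent and child ages.  Unphased singleton variants in diploid
individuals can be dated phase-agnostically: EP marginalizes over the
two candidate haplotypes and reports a phase probability per singleton.

## Worked example

Simulate a small ARG with known truth, date it, and inspect the fit
(library API; the same is available as `vgdate simulate` / `vgdate date`
on the command line):

```python
from vgdate import ArgDatingModel
from vgdate.synthcoal import SimConfig, simulate_arg, drop_mutations

cfg = SimConfig(n_samples=50, sequence_length=2e5, seed=11)   # mu = 1e-8
sim = drop_mutations(simulate_arg(cfg), cfg.mutation_rate, seed=12)

res = ArgDatingModel(sim.tables, cfg.mutation_rate, seed=1).fit()
print(res.summary())
```

```
Variational-Gamma ARG dating results
====================================================
nodes: 202 (152 dated internal)
mutations dated: 167 of 167
mutation rate: 1.000e-08 /bp/gen
converged: True (20 sweeps, final delta 6.11e-07)
root prior rate eta: 2.69406e-05 (em)
rescaling: path (97 intervals)
projected/skipped updates: 0/0 of 20080
node age quartiles (generations): 356.3 / 2030 / 8595
mutation age quartiles (generations): 1049 / 3440 / 8837
```

Each internal node gets a Gamma posterior (`res.node_posteriors`:
shape, rate, mean, variance and an order-consistent point time); each
mutation gets a Gamma posterior with 95% credible bounds, derived allele
count/frequency, and — for unphased singletons — a phase probability
(`res.mutation_posteriors`).  Against the simulation truth this fit
recovers node ages with Spearman rho ≈ 0.98 and its central 80% credible
intervals cover the true ages at ≈ 0.80, i.e. the reported uncertainty
is well calibrated on true topologies.

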