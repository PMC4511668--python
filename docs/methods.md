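# Methods

## The model

`micronull` simulates the joint dynamics of a host population and the
microbial communities it carries, under the simplest assumptions possible:
every process is neutral.

**Hosts.** A constant population of N asexual hosts reproduces in discrete,
non-overlapping generations under a Wright-Fisher process: each offspring
draws its parent uniformly at random, with replacement, from the previous
generation. Lineages therefore drift and die; the whole population traces
back to a single common ancestor after about 2N generations, and
`mrca_generation` measures exactly this depth on the recorded genealogy.

**Microbiomes.** Each host carries a fixed capacity of n microbe "slots".
An offspring fills its n slots by sampling taxa with replacement: each slot
is, independently, *parental* with probability x (drawn from the parent's
relative taxon abundances) and *environmental* otherwise (drawn from the
current environmental pool). x = 0 is pure environmental acquisition, x = 1
pure parental acquisition. Finite capacity is the only interaction between
microbes — indirect competition for space — and no taxon has any intrinsic
advantage in the host or the environment.

**Environment.** The pool offered to a generation is the convex combination
`y * pooled + (1 - y) * fixed`, where *pooled* is the renormalized sum of all
previous-generation microbiomes and *fixed* is a constant distribution over
all m taxa (uniform by default, matching the uniform seeding of generation
0). y = 0 is the fixed environment, y = 1 the fully pooled one. The pooled
component is always computed from the generation just completed and offered
to the next, including the very first step (the generation-0 hosts pool into
the environment offered to generation 1); the fixed component never changes.

**What is deliberately absent.** No microbial mutation or speciation, no
selection on hosts or microbes, no host population structure, no sexual
reproduction, and no within-lifespan event modeling: a host's microbiome is
an aggregate over the single generation it exists. Taxa can only be lost by
drift — or re-enter through the fixed environmental component.

### Expected behavior at the boundaries

* x = 1 (or y = 1): the environment contributes nothing new, so taxa are
  lost irreversibly; both regimes end with a single taxon occupying every
  slot of every host, and between-host Bray-Curtis dissimilarity is then
  exactly 0. With x = 1 the environmental model is irrelevant: FE, ME and PE
  give the same offspring law.
* y = 0 with x < 1: every generation re-offers all m taxa, so the
  population-wide taxon set is maintained essentially forever, even when the
  per-host environmental fraction (1 - x) is as small as 10^-3.

## Implementation of the sampling step

Per-slot Bernoulli choices are never simulated individually. The number of
parental slots is drawn as k ~ Binomial(n, x), followed by one multinomial
draw of size k from the parent's abundances and one of size n - k from the
environment — distributionally identical and fully vectorizable across
hosts (numpy's batched multinomial over a matrix of per-parent probability
rows). Counts are stored as an N x m integer matrix rather than as agent
objects; the model law is unchanged and a full-scale run (N = 500, n = 1000,
m = 150) advances about 150 generations per second on one CPU core.

At x = 0 and x = 1 the corresponding draw is skipped entirely. This changes
which random numbers are consumed (not any distribution), so runs at
different parameters are never bitwise comparable — only runs with identical
configurations are, and those are bitwise reproducible.

All randomness flows through one `numpy.random.Generator` seeded from the
config. Sweep replicates derive their seeds from
`SeedSequence([base_seed, cell_index, replicate])`, so grid cells can be
computed in any order, or singly, with identical results.

## Diversity statistics

* Scaled Shannon-Wiener index `H = -sum p_i ln p_i / ln R`, with 0 ln 0 := 0
  and H := 0 when R <= 1 (the raw expression is 0/0 there). R is either the
  number of taxa observed in the community or a fixed global richness; the
  two conventions disagree exactly when taxa are absent from a sample.
  Simulation trajectories default to the **global** convention (R = m), which
  keeps values comparable along a run as taxa are lost; empirical sample
  tables default to **observed**, since a global genus count is not
  well-defined for real profiles. Both are exposed everywhere.
* Alpha is the across-community mean of per-community H (spread reported as
  the sample standard deviation, ddof = 1; a flag-level choice since
  standard error is trivially derived); gamma is H of the pooled community.
* Beta is the mean over all unordered pairs of the Bray-Curtis
  dissimilarity `sum_k |p_ik - p_jk| / 2`, computed as half the city-block
  distance on row-normalized abundances. Fewer than two communities is an
  error, not 0: a lone community has no between-community dissimilarity.

**Stabilization.** Long runs are halted when the recorded gamma trajectory
flattens: the means of the last two non-overlapping windows (default 500
recorded points) differ relatively by less than a tolerance (default 1e-4),
never before a configurable minimum number of generations. This
operationalizes by-eye plateau inspection; window and tolerance trade halt
time against sensitivity to slow drift, and runs in absorbing regimes may
instead stop exactly at absorption (single taxon remaining).

## Abundance-distribution fits

`fit_lognormal` is the closed-form MLE on log-abundances and requires
strictly positive input — zero abundances are excluded upstream, since the
histograms being summarized are of taxa present in the population.

`fit_dirichlet_multinomial` maximizes the DM likelihood over the
concentration vector with Minka's fixed-point iteration (digamma terms),
initialized from method-of-moments estimates (mean proportions scaled by a
moments precision). The update provably does not decrease the likelihood;
convergence is declared when the largest concentration change drops below
1e-8 (at most 10^4 iterations), and non-convergence or a degenerate table
(no between-sample variation, or a single taxon) is flagged on the result
and warned, never silent. Taxa absent from every sample are pinned at a
concentration floor of 1e-10 and listed on the fit. The reported
overdispersion is `theta = 1 / (1 + sum(alpha))`.

`reconstruct_diversities_from_dm` re-simulates sample tables from a fit
(Dirichlet draw per sample, then a multinomial at a chosen depth) and
returns replicate-averaged alpha/beta/gamma — the self-consistency check
that a fitted DM reproduces the diversities of the data it was fitted to
(observed to within a fraction of a percent at 300 samples x depth 800;
asserted at 5% in the tests). Fits of population-level abundance vectors use
`population_abundance_distribution` (normalized column sums), the natural
population-wide summary.

## Empirical community profiles

The reader handles the shotgun-metagenomics community-profile dialect:
tab-delimited, lineage strings (rank-prefixed components joined by `|` or
`;`, auto-detected) in the first column, per-sample relative abundances in
the rest. Such tables are usually *hierarchical* — rows at every rank, each
rank summing to 1 per sample — so collapsing to a rank takes rows already at
that rank as-is, truncates-and-sums deeper rows not covered by a parent row,
skips shallower rows that have descendant rows (cumulative aggregates), and
pools shallower rows *without* descendants into an explicit "unclassified"
bucket (droppable by flag, since keeping it changes observed richness).
Columns are renormalized afterwards. Subject deduplication keeps the first
sample per subject in stable column order — the selection rule is otherwise
arbitrary, and determinism matters more than the particular choice.

The synthetic profile generator emulates this dialect: each body site gets
its own disjoint genus set under its own phylum, each sample is an
independent draw from a symmetric Dirichlet over the site's genera, and rows
are emitted at kingdom, phylum and genus rank. The default concentration of
0.5 per genus produces skewed, uneven communities of the kind real body-site
profiles show. What the fixture does **not** emulate: shared genera between
sites, within-subject correlation of replicate samples (replicates are
independent draws), sequencing noise or compositional zeros from detection
limits, and realistic taxon-name structure. Pipeline tests on the fixture
therefore demonstrate correctness of the computation, not ecological realism
of any particular summary value.

## Sweep runner

`run_grid` crosses x and y value lists, runs independent replicates per
cell (10 by default in the CLI, matching standard practice for this kind of
study), and aggregates *end-of-run* alpha/beta/gamma means and standard
deviations — end-of-run rather than time-averaged values, since runs are
halted at stabilization. Three axis presets are shipped: `linear`
(0, 0.1, ..., 1), `power_small` ({0} with 0.5^j, j = 10..0, probing the
near-zero end) and `power_large` (1 - 0.5^j, j = 0..20, probing the
near-one end where the interesting transitions happen). Outputs label axes
with literal parameter values.

## Problem sizes in the tests and acceptance script

Absorption, trend and coalescence checks run at a reduced scale of N = 100
hosts, n = 200 slots and m = 20-30 taxa with runs of up to a few thousand
generations (absorbing regimes stop at absorption), which preserves every
qualitative regime of the model while keeping a full check run in minutes.
The fixed-environment retention check runs at the full scale (N = 500,
n = 1000, m = 150, 10^4 generations). Coalescence uses N = 20 over 500
replicate genealogies, where the Monte-Carlo error of the mean TMRCA is
about 1 generation. The trend assertions use a 0.02 absolute slack on
replicate-mean alpha/gamma comparisons to absorb Monte-Carlo noise at three
replicates per cell.

## Known limitations

* Observed-mode alpha at full scale barely differs from global mode (with
  n >> m every host carries nearly every taxon); the conventions diverge
  mainly for sparse empirical samples.
* The DM fixed-point iteration is reliable but first-order; extremely
  overdispersed tables (many near-zero concentrations) converge slowly and
  may hit the iteration cap, which is reported on the fit.
* The stabilization detector compares window means only; a gamma trajectory
  declining more slowly than the tolerance per window is declared stable.
* Bitwise reproducibility is guaranteed per configuration and numpy
  generation (PCG64 stream stability), not across different parameter values
  or numpy major versions.
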