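# Methods

This note documents the models, defaults and design decisions behind
`sololens`, in the order the pipeline runs them.

## Single-subject dysregulation model

**Normalization.** With a single pair of libraries there is nothing to fit:
the method must be a robust per-library scale. The default upper-quartile
factor (75th percentile of nonzero counts, both libraries rescaled to the
mean of the two factors) removes a global library-size imbalance exactly
and ignores the zero-inflated lower tail; `total_count` and `none` are
selectable. An all-zero library is an error, not a silent pass.

**Fold changes.** lfc_signed = log₂((T + c)/(U + c)) with pseudocount
c = 0.5 (configurable, must be > 0) so every gene is finite. The sign
convention is log₂(T/U): positive = higher under treatment = "up". The
magnitude |log₂FC| — the mixture's input — is identical under either
orientation of the ratio, so only the up/down labelling depends on it.

**Mixture clustering.** Genes are clustered into unaltered vs
dysregulated with a two-component Gaussian mixture on |log₂FC|, fit by EM:

- initialization: component means at the 50th and 95th percentiles of the
  data, both sds at the overall sd (floored at 1e-3), weights ½/½;
- convergence: log-likelihood gain < 1e-8 or 1000 iterations; the
  trace is non-decreasing by construction and asserted in tests;
- labelling: the larger-mean component is "dysregulated";
- degeneracy: a component sd below 1e-6, a weight below 1e-4, or fewer
  distinct values than components falls back to an all-unaltered call
  with a logged warning rather than a numerically meaningless fit.

Three output groups (up / down / unaltered) come from one decision
boundary: posterior of the dysregulated component > 0.5, then the sign of
lfc_signed splits up from down. A gene with lfc_signed exactly 0 stays
unaltered whatever the posterior (tie rule). The magnitude distribution
of unaltered genes is half-normal-like rather than Gaussian; the Gaussian
component absorbs this well enough that, on a planted
0.9·|N(0, 0.2)| + 0.1·|N(2.5, 0.4)| mixture, the recovered weight and
mean of the dysregulated component land within the test tolerances and
classification F1 exceeds 0.9.

**Pathway test.** Per set: one-sided (greater) Fisher exact test on
(dysregulated = up ∪ down vs unaltered) × (in-set vs out-of-set), i.e. the
hypergeometric right tail; odds ratio as the sample estimate ad/bc (+inf
when bc = 0 with ad > 0, 0 when ad = 0 with bc > 0). Up and down are
counted together ("bidirectional" enrichment); per-direction counts are
reported per set so a caller can still inspect direction balance. The
universe defaults to the measured genes (the whole profile); an
`annotated` policy restricting it to GMT-annotated genes is available.
Sets with fewer than 5 measured members are skipped. p values are
BY-adjusted in one batch per profile (per time point), since overlapping
sets make the tests dependent in an uncontrolled way.

**DEG selection.** Defaults |log₂FC| > 1 and adjusted p < 0.05 for
external cohort tables; for SSA output the rule is class ∈ {up, down} and
|log₂FC| > 1. SSA-derived DEG tables carry p_adj = 1 − posterior so the
table schema stays uniform.

## Network stage

**Construction.** Edges with combined confidence score strictly > 700
are retained (strict, deliberately, matching the "score > 700"
convention); an optional evidence-channel filter additionally requires a
positive score in at least one named channel (e.g. `experiments`,
`database`). The default `first_shell` policy includes the seeds plus
their direct interactors and every retained edge among included nodes —
a seeds-only network of a few hundred DEGs would be nearly edgeless at
this confidence threshold, which is why first-shell recruitment is the
default. Seeds absent from every retained edge are kept as isolated
nodes and listed in the metadata; an empty interaction table yields the
isolated-seed network, while a non-empty table containing none of the
seeds is an error listing the misses.

**Hubs.** k = ⌈fraction·n⌉ with fraction 0.10, ranked by unweighted
degree descending with node-id ascending as the deterministic tie-break.
The choice of ⌈·⌉ and id tie-breaking is ours; degree is unweighted
because hub-ness is about the number of interaction partners, not their
confidence.

**Cohesiveness clustering.** The module score is
f(V) = w_in / (w_in + w_bound + p·|V|), where w_in sums weights of edges
inside V, w_bound sums weights of edges crossing the boundary, and the
penalty term p·|V| (default p = 2) models unobserved interactions.
Growth is greedy and deterministic: seeds are taken in
(degree descending, id ascending) order among nodes not yet in any
cluster; from the current set the single move — adding a boundary vertex
or removing an internal non-seed vertex — with the largest strict
cohesiveness increase is applied until a local maximum. Clusters may
overlap because growth can re-enter nodes already used by earlier
clusters. Clusters below 3 nodes or below 0.5 unweighted edge density are
discarded; near-duplicates with overlap score ω(A,B) = |A∩B|²/(|A||B|)
above 0.8 are transitively merged (union, score recomputed). Incremental
w_in/w_bound bookkeeping during growth is checked against full
recomputation in the tests (1e-12).

**Cluster significance.** One-sided Mann–Whitney U comparing, over the
cluster's vertices, internal weight sums against boundary weight sums
(alternative: internal > boundary), exact U distribution up to group
size 20 and normal approximation with tie correction beyond; p < 0.05
flags a cluster significant. Note the exact test's granularity: a size-3
cluster's best attainable p is 1/C(6,3) = 0.05, so size-3 clusters can
never be significant — a property, not a bug. A cluster of size < 2 gets
p = 1 with a warning.

**Functional enrichment** of hubs and cluster members reuses the same
hypergeometric core (identical 2×2 tables give bit-identical p values
across stages). The default significance rule is uncorrected p < 0.05 —
the conventional term-scan threshold — with BH/BY behind a flag because
uncorrected scans are anticonservative. The universe defaults to the
genes annotated in the GMT collection, not the network; network-as-universe
is a caller choice.

## Synthetic data

The generator emulates the paired single-subject design: per-gene
baseline means log-uniform on [e³, e⁸] (≈20–3000 counts), untreated
counts NB(μ, α) with variance μ + αμ² and shared dispersion α = 0.05,
treated counts NB(μ·2^δ·r, α) with a global library-size ratio r = 1.3
(so normalization is doing real work), and δ = ±|N(2.5, 0.4)| for
dysregulated genes (sign up with probability 0.5), δ = 0 otherwise.
Pathways are 100 random sets of 30–50 genes; 10 implanted pathways have
50% of members dysregulated against a 5% background rate. These defaults
are the reference condition of the whole test suite; every output is a
pure function of the config including the seed.

The interactome generator plants `n_communities` consecutive blocks of
`community_size` labels as dense modules (edge probability p_in, scores
uniform on 701–999) in a sparse background (p_out, scores 150–400), so
that a 700-score threshold separates planted structure from noise.

What the generator does **not** emulate: real expression distributions
of any particular tissue or organism, gene-length effects, correlated
counts within pathways beyond the shared dysregulation indicator,
overlapping true modules, or degree-dependent interaction confidence.
Passing recovery tests therefore demonstrates correctness of the
algorithms under the stated generative model, not performance on any
particular real dataset.

## Pipeline orchestration

`run_pipeline` chains simulate → ssa → select_degs → network → enrich
under one YAML config and one global seed; per-stage seeds are fixed
offsets from it, so stages stay individually reproducible and a stage
re-run standalone matches the orchestrated run exactly. The interactome
fixture is built during the simulate stage with node labels drawn from
implanted-pathway genes (which form the planted communities) plus random
background genes: implanted genes are strongly enriched for
dysregulation, so the later DEG seed list is guaranteed substantial
overlap with the interaction table without the simulator depending on
SSA output. The manifest records the config snapshot, seed, package
version and a SHA-256 digest per output file; determinism is defined as
digest equality between runs (timestamps live in the manifest but not in
the digests).

Problem sizes used by the test suite and the acceptance script — 5,000
genes, 100 pathways, a 50-node planted-partition interactome, an
exhaustive exact-test sweep up to a 30-gene universe, and 2,000 random
p-vectors for the FDR check — were chosen as the smallest scales at which
every property is informative; all run in seconds.

## Known limitations

- The two-component Gaussian mixture can misestimate the unaltered
  component when counts are very low (heavy |log₂FC| noise tails);
  the pseudocount and upper-quartile normalization mitigate but do not
  remove this.
- Uncorrected p < 0.05 for hub/cluster term enrichment is
  anticonservative by design (it mirrors common practice); use
  `correction=bh|by` for calibrated scans.
- Greedy cohesiveness growth finds local maxima; on graphs with weak or
  overlapping modular structure the recovered clusters depend on the
  deterministic seed order.
- Identifier namespaces are the caller's problem: the alias map is a
  plain TSV, and no web-service mapping is attempted.
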