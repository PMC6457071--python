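# Methods

`metanet` infers species–species co-occurrence networks from taxon-by-sample
abundance tables and analyses them (clusters, hubs, topological comparison).
This note records the statistical model behind each stage, the defaults and
why they are what they are, and the choices made where the design was
genuinely open.

## Co-occurrence gating and correlation networks

A taxon is *present* in a sample when its abundance exceeds the detection
limit (default 0). The co-occurrence probability of a pair is the fraction
of samples in which both are present. Two constructions are provided:

* **strict** — a correlation is computed only for pairs present together in
  *every* sample. In sparse 16S data this is ruinous: a handful of
  detection zeros removes almost every pair.
* **loose** — pairs are evaluated when their co-occurrence probability is at
  least a gate (default 0.8, boundary inclusive). The gate also suppresses a
  specific noise mode: pairs seen together in only a few samples can show
  spuriously perfect correlations.

Once a pair passes the gate, the coefficient (Pearson by default, Spearman
selectable) is computed, by default **on the co-present samples only**. The
alternative (`all_samples`) is provided mainly because at a gate of 1.0 it
makes the loose construction reproduce the strict one edge-for-edge, which
the test suite verifies; including joint absences in the correlation would
otherwise manufacture association out of shared zeros. Edges require
|r| ≥ 0.5 at genus level (0.7 at OTU level) and a two-sided p ≤ 0.01 from
the standard correlation null. No multiple-testing correction is applied by
default; a Benjamini–Hochberg option (`fdr_bh=True`, via
`scipy.stats.false_discovery_control`) is available. Pairs with fewer than
3 co-present samples, or with a constant abundance vector, are skipped with
a logged warning.

## FS-Weight

FS-Weight scores a pair by neighborhood overlap in the *topology* of the
correlation network:

    S(u,v) = [2n_uv / (n_u\v + 2n_uv + λ_u)] · [2n_uv / (n_v\u + 2n_uv + λ_v)]

with `n_uv = |N_u ∩ N_v|`, `n_u\v = |N_u \ N_v|`, `N_x` the neighbor set of
x (including x itself by default), and `λ_x = max(0, n_avg − |N_x|)` a
pseudocount penalising nodes with fewer neighbors than the network average
(on by default; both toggles exposed). S is symmetric and lies in [0, 1].
Correlation weights gate which edges exist but do not enter S — the score
is deliberately structural, measuring shared interaction partners.

Rebuilding the network keeps direct edges with S ≥ threshold (0.5 genus /
0.7 OTU), adds *indirect* edges between non-adjacent pairs that share at
least one neighbor and score at or above the threshold, and drops direct
edges scoring below it. Indirect edges carry the score as weight and no
sign (signs belong to correlation-derived edges only). One pass is applied;
the augmented network is not re-scored.

## Part mutual information and path-consistency pruning

For abundance variables x, y and a conditioning vector z,

    PMI(x,y|z) = Σ p(x,y,z) · log [ p(x,y|z) / (p*(x|z) p*(y|z)) ]

where the partially marginalised conditionals are

    p*(y|z) = Σ_x p(y|z,x) p(x),    p*(x|z) = Σ_y p(x|z,y) p(y).

With an empty conditioning set PMI reduces exactly to mutual information;
the test suite asserts this to 1e-12, and the discrete core is checked
against an independently written literal triple sum.

**Estimators.** The `binned` estimator discretises each variable into
`⌈√C⌉` equal-frequency bins from average ranks (ties share a bin, so zero
inflation collapses into one cell instead of smearing into artificial
structure; strictly monotone transforms leave the value unchanged, exactly)
and evaluates the sums above on the empirical joint table. It is the
literal implementation of the definition and the one oracle checks target,
but as a plug-in estimator it is biased upward on continuous data by
roughly (B−1)²/2C nats — about 0.25 at B=23, C=500 — which dwarfs the
0.02-nat edge threshold. The `gaussian` estimator is the closed form
−½·log(1−ρ²) on the (partial) correlation, i.e. the value PMI takes for
Gaussian variables, where partial dependence is summarised by the partial
correlation ρ given the conditioning set. The network stage therefore
defaults to `gaussian`: the 0.02 default threshold is only meaningful for a
statistic whose null value is near zero at realistic sample sizes.

**Preprocessing for compositional, zero-inflated data** (Gaussian path of
`pca_pmi_network` only; the public `mutual_information` keeps its plain
contract):

1. log-transform positive entries;
2. centre each sample by the **median** log-abundance of its detected taxa.
   Relative abundances couple every pair through the sample total; the
   median is a robust stand-in for that per-sample scale factor and is
   insensitive to how many taxa dropped out of the sample;
3. map each taxon to rank normal scores over its *observed* entries, with
   zeros treated as missing. Detection-limit zeros carry no rank
   information, and encoding them as tied low values measurably dilutes
   every correlation (on the synthetic recovery conditions, planted |r|
   fell from ≈0.67 to ≈0.26 at 20% dropout);
4. compute correlations and partial correlations on pairwise /
   conditionally complete samples, requiring at least 8 complete
   observations (fewer returns 0, i.e. "no evidence of dependence").

**Pruning loop.** Order 0 connects every pair whose statistic strictly
exceeds the threshold. At order L ≥ 1, each surviving edge is tested
against every size-L subset of the pair's common neighbors; if any subset
drops the PMI to ≤ threshold, the edge is removed and the subset recorded
as its separating set (all removals are logged and collected in
`G.graph["removals"]`). Orders increase until one changes no edges;
`max_order` defaults to 3, with `None` reproducing the iterate-until-stable
behaviour. Common neighborhoods are taken from an adjacency snapshot made
at the start of each order (the "stable" variant of the path-consistency
algorithm): without the snapshot, a separator can be pruned moments before
the pair it separates is tested, and edge recovery on the synthetic
benchmark collapses (precision ≈0.55 → ≈0.88 with the snapshot). Surviving
edges carry the minimum statistic observed across all their tests.

## Clusters and hubs

**MCODE-style clustering** proceeds in three stages. (1) Each vertex is
weighted by the density of the k-core (k = 2 by default) of its closed
neighborhood times that core's highest core number. (2) Seeds are taken in
decreasing weight order (ties by label); a cluster is the seed plus its
unassigned neighbors whose weight is within `node_score_cutoff` (default
0.2) of the seed's. Expansion is deliberately limited to the seed's own
neighborhood: with recursive frontier expansion, two equally dense modules
joined by a single bridge edge merge into one cluster (all their vertices
carry identical weights, so the admission rule cannot stop at the bridge),
whereas module boundaries are exactly what the clustering is for. In the
dense modules this method targets, the seed is near the module centre and
one hop covers it. (3) Haircut iteratively strips members with fewer than
two in-cluster edges; fluff (off by default) adds unassigned neighbors
whose closed-neighborhood density exceeds `fluff_density`. Clusters must
have ≥ 3 members and a connected induced subgraph, are mutually disjoint,
and are scored by density × size.

**Hubs.** Candidates are the most connected nodes (default pool:
max(5, 5% of nodes)). For each candidate the degree sequence of all
*other* nodes before deletion is compared with the same nodes' degrees
after deletion by a Kruskal–Wallis rank test — the two samples differ only
through the candidate's incident edges, which makes the comparison
well-posed. Degree is the default node-level metric; any
`callable(graph) -> {node: value}` can be substituted (e.g. closeness) since
"how a deletion perturbs the network's distribution" admits more than one
reading. A node is a hub when p ≤ α (default 0.05). Identical sequences
short-circuit to p = 1.

## Network comparison

All comparison operations assume networks over a shared taxon namespace, so
alignment uses the identity mapping on shared labels (restricted to the
source's mapped nodes); a mapping search would add nothing when node
identity is known. With conserved = source edges whose endpoints are
adjacent in the target and induced = target edges among image nodes:
EC = conserved/|E_a|, ICS = conserved/induced, S3 = conserved/(|E_a| +
induced − conserved). Degenerate cases (no source edges, no induced edges)
score 1 with a warning rather than erroring.

Similarity trees use average linkage on 1 − Jaccard (node sets or edge
sets, both exposed since either reading is defensible) and are emitted as
newick with branch lengths equal to merge-height differences. Global
properties report density, mean local clustering, and the average shortest
path length of the largest connected component (inferred networks are
routinely disconnected; a path length over all pairs would be undefined).
Local properties are coreness, degree, eigenvector centrality (scaled to
max 1), per-component eccentricity, raw betweenness path counts, and
degree centrality.

The motif census enumerates connected 4-node induced subgraphs with the
ESU algorithm (verified against brute-force enumeration over all
quadruples), classifies them into the six undirected classes by induced
degree sequence, and computes z-scores against `n_random` (default 100)
degree-preserving rewired replicates (10·|E| double edge swaps each,
seeded; replicates keep every node's degree exactly). The sample standard
deviation is used; a zero-variance ensemble yields z = 0.

## The synthetic community generator

The generator emulates what an amplicon pipeline hands to network
inference: a zero-inflated relative-abundance table over a few hundred
samples with planted dependencies and a known ground-truth network.

Model. Each taxon has a log-scale baseline (dominant taxa at 0, rare taxa
at −7, enough to hold them below 0.1% mean relative abundance at realistic
richness) plus unit normal variation. A planted dependency replaces the
target's row with `strength`·(standardised parent signal) + Gaussian noise
(σ = `noise_sigma`); parent signals are standardised by their analytic
variance so dependency chains do not accumulate variance with depth.
Quadratic and sinusoidal forms use variance-matched transforms of the
parent. Chains x→z→y are realised as two such steps with no x–y coupling,
giving x ⊥ y | z. The log-scale field is scaled by `log_sigma`, dropout
zeros entries independently, and columns are closed to sum 1.

Defaults, with units and rationale:

| parameter | default | meaning / why |
|---|---|---|
| `chain_strength` / edge strength | 0.8 | per-edge coupling; one-parent log-scale correlation ≈ 0.73 |
| `noise_sigma` | 0.75 | per-target intrinsic noise (log units). Keeps planted edges above the 0.5 genus-level correlation gate at n = 500 while avoiding near-deterministic couplings — at σ = 0.25 the per-edge correlation is 0.95, multi-hop relatives stay at r ≈ 0.9, and the planted block dominates the sample total, flooding the relative abundances with closure correlations up to \|r\| ≈ 0.7 that no conditioning can remove |
| `log_sigma` | 0.5 | overall log dispersion (CV ≈ 53%); correlations are invariant to it, closure noise is not |
| `dropout` | 0 (0.2 in the recovery benchmark) | independent per-entry detection failure, applied after dependency generation so sparsity attenuates but does not redefine the planted structure |
| degree caps | ≤ 2 parents, ≤ 2 children | a k-parent target splits its variance k ways; a many-child source spawns a near-collinear sibling block |
| parent-pair uniqueness | enforced | two targets with the same parent pair are statistical near-duplicates and explain each other's true edges away under conditioning |

`random_spec` draws a structure of the requested size: chains take
node-disjoint triples, nonlinear pairs take further fresh taxa, and direct
edges form a random DAG over the remaining pool under the constraints
above (targets may take a second parent, so more edges than pool nodes are
possible).

What the generator does *not* emulate: phylogenetic correlation between
related taxa, read-count sampling noise, sequencing error,
abundance-dependent detection (dropout here is missing-completely-at-
random, which is exactly the assumption the pairwise-complete estimator
relies on), or ecological dynamics. Passing the recovery benchmark
therefore shows that the inference machinery is correct under its own
assumptions — not that those assumptions hold in any particular real
dataset, where detection is abundance-dependent and compositional effects
can be stronger.

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale, chosen to make
every stochastic check decisive in seconds: chain pruning on 10-taxon
communities at n = 500 over 20 seeds; edge recovery on 30-taxon communities
(20 direct edges, 5 chains, 20% dropout) at n = 1000 over 10 seeds, where
mean precision and recall are ≈ 0.85–0.92; a four-method comparison
community of 30 prevalent taxa at n = 500 with 5% dropout, where the strict
network is empty (no pair survives joint presence in all 500 samples) while
the loose, FS-Weight and PMI networks recover the planted structure. All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; regenerating with the same spec is bit-identical
and the CLI's run report is byte-identical across runs.

## Known limitations

* Compositionality is mitigated (median-log centring, rank scores), not
  solved; no SparCC/CCLasso-style estimation is attempted, and strongly
  correlated blocks that dominate the community total can still induce
  spurious dependence.
* Path consistency assumes the relevant confounders are observed taxa; a
  latent environmental driver leaves its signature as unremovable edges.
* Edges are undirected; no orientation rules are applied.
* The motif census is fixed at size 4; alignment uses identity mapping
  only; FS-Weight is single-pass.
* The Kruskal–Wallis hub test compares degree sequences that are not fully
  independent samples; its p-values are a ranking device more than exact
  error rates.
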