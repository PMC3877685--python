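# Methods

## Model and assumptions

The classifier assumes that phenotype differences are carried by *groups* of
closely interacting molecules rather than by single genes, and that the
expression pattern of such a group — possibly heterogeneous, with some probes
up- and others down-regulated — separates samples of the two phenotypes into
distinct clusters. Scoring a subnetwork by the class purity of its expression
clusters (rather than by a sum or mean of its expression values) is what lets
the method reward mixed-sign subnetworks that aggregation scores miss.

Two structural assumptions matter in practice:

* the interaction network is treated as an undirected, unweighted simple
  graph; edge weights, directions and interaction types are ignored;
* a node carries one or more molecules and a molecule may sit in several
  nodes, so the molecule sets of two subnetworks may overlap even though the
  node partition is disjoint. The probe map implicitly filters molecules with
  no measured probes (chemical compounds, unmapped genes).

## Network partition

Connected components at or below `max_range` nodes are emitted whole; smaller
ones are kept too, since their probe count may still suffice (they are
filtered later, by probe count, not node count). Larger components are
agglomerated greedily: starting from singletons, the adjacent pair of groups
whose merge maximises the modularity gain ΔQ = e_ij − 2·a_i·a_j is merged
until one group remains, recording Q = Σᵢ(eᵢᵢ − aᵢ²) after every merge. Ties
are broken on the lexicographically smallest pair of smallest member
identifiers, which makes the dendrogram — and everything downstream —
deterministic. The dendrogram is then cut from the top: in-range groups
become communities, oversized groups are split at their top merge, undersized
branches are dissolved.

Dissolved (discarded) nodes are re-attached in waves: a node with a 1-hop
neighbour inside some community joins the community with the most members
within h hops, escalating h = 1, 2, … and restricting to the tied leaders;
a tie surviving at h_max = 5 is broken uniformly at random with the run's
seed. Nodes with no path to any community are assigned at random among all
communities (with a warning) so the procedure always terminates. A community
pushed back above `max_range` by re-attachment is re-induced from the current
component and re-partitioned; if it reproduces itself unchanged (a star hub
with its leaves is the canonical case — no modularity cut yields in-range
parts) it is emitted as an oversized subnetwork. Both the hop cap and the
fixed-point stopping rule are this package's choices; they bound the
recursion without affecting well-behaved topologies.

## Feature selection

Differential expression is scored with a variance-offset Welch statistic

    t = (mean_pos − mean_neg) / sqrt(var_pos/M_pos + var_neg/M_neg + s0²)

with unbiased per-class variances. The offset s0 (default 5% of the median
per-probe standard error of the training set, recomputed per fit) keeps the
statistic finite for near-constant probes and shrinks the rank inflation of
low-variance noise probes; s0 = 0 recovers the classical Welch statistic, and
the policy is configurable (`"median"`, `"none"`, or an explicit value).

An MIS needs at least R unique mapped probes (R = 5 by default, the same
value as the probeset size — a single threshold keeps the size-R contract
uniform downstream); the R probes with the largest |t| form its
representative probeset, ties broken by probe identifier. Probesets
overlapping by ≥ `overlap_threshold` (default 0.6, i.e. 3 of 5 probes — the
smallest strict majority) are merged greedily, highest overlap first, the
merged probeset recomputed from the molecule union so every surviving MIS
still has exactly R probes. Each merge reduces the MIS count by one, so
merging terminates with all pairwise overlaps below the threshold.

## Normalisation, clustering and the entropy score

Quantile normalisation is fitted on the training matrix only: the reference
profile is the mean of the sorted per-sample vectors, and any vector
(training or new) is transformed by mapping its within-sample ranks onto that
reference (average ranks for ties, linear interpolation between grid points —
the standard out-of-sample extension). Per-probe z-scoring follows, with
means/sds computed after the quantile step; constant probes get their sd
floored at 1e-8 with a warning rather than erroring.

Samples are clustered per MIS with Ward's minimum-variance linkage on
Euclidean distances over the R probeset dimensions, cut into
k = round(√(M/2)) clusters (floored at 2). Cluster centroids are
coordinate-wise medians, which resist outlying samples. With per-cluster
positive/negative counts normalised by the class totals (p′ᵢ, n′ᵢ), the MIS
score is

    H(MIS) = Σᵢ wᵢ · h(p′ᵢ/(p′ᵢ+n′ᵢ)),   wᵢ = (p′ᵢ + n′ᵢ)/2,

where h is the binary entropy (0·log 0 ≡ 0). The weighting wᵢ is the unique
convex combination of the normalised counts for which the score is 0 exactly
when every nonempty cluster is class-pure and 1 exactly when every cluster
holds equal class proportions; empty clusters are skipped. MISs are ranked by
increasing entropy, ties broken by identifier.

## Voting and tie policy

A new sample, normalised with the training model, is assigned per MIS to the
nearest median centroid (ties to the lowest cluster index). The top G ranked
MISs vote with weights (w₊, w₋) = (p′꜀, n′꜀)/(p′꜀+n′꜀), so W₊ + W₋ = G
always. On an exact weighted tie, binary voting gives each MIS a whole vote
for the strictly dominant class of its nearest cluster (nothing on an
internally tied cluster); odd G with no tied clusters guarantees a strict
winner. If the binary vote also ties (possible only with tied clusters or
even G), the positive class is predicted deterministically with a logged
warning. The default G is 15; the supported selection procedure is the
smallest G on an odd grid (1, 3, …, 25) maximising LOOCV accuracy
(`loocv_curve` evaluates the whole grid from one fit per fold, and
`choose_g` picks the minimum of the argmax).

## Cross-validation

The network partition depends only on the graph, so it is computed once and
shared across folds. Everything expression-dependent — s0, t-scores,
probesets, overlap merging, normalisation, clustering, ranking — is refit on
the M−1 training samples of every fold. Accuracy is the fraction of held-out
samples predicted correctly; AUC is the rank-based probability that a random
positive sample's vote margin W₊ − W₋ exceeds a random negative's (ties count
half), the margin being the only continuous output. Because the per-class
variances need two samples, every fold must retain ≥ 2 samples per class: the
smallest dataset LOOCV accepts is therefore 3+3.

## Synthetic benchmarks

The generator emulates the three pipeline inputs with known ground truth:
a planted-partition graph (n_communities × community_size nodes, edge
probabilities p_in within and p_out between communities), one molecule per
node (optionally duplicated across communities to emulate KEGG multiplicity)
with a fixed number of probes per molecule, and a class-conditional Gaussian
expression matrix: i.i.d. N(0, σ) background with the designated signal
community's probes mean-shifted by ±(effect_size)·σ in the positive class,
alternating sign across probes to exercise the mixed-sign case.
`signal_probe_fraction` < 1 leaves part of the signal community's probes at
null, for testing probe-level discrimination within a subnetwork.

Default conditions used by the tests and the acceptance script: community
size 10, p_in 0.8–0.9, p_out 0–0.02, effect sizes 3σ (recovery benchmarks)
and 5σ (classification benchmark), M = 40 samples for recovery and M = 20
for LOOCV, probes per molecule 2. These sizes make the planted structure
recoverable but not trivial, and keep every benchmark deterministic under
its seed.

What the generator does *not* emulate: microarray intensity distributions
(background is Gaussian, not log-normal — the pipeline z-scores everything,
so only relative structure matters), probe-level cross-hybridisation,
batch effects, and correlated co-expression within null communities. Passing
benchmarks therefore demonstrates that the algorithmic chain recovers planted
structure under clean noise, not that any specific biological dataset would
reach a given accuracy.

## Numerical choices and degenerate inputs

* Modularity is recorded exactly (recomputed values agree to 1e-9) and all
  dendrogram tie-breaks are lexicographic.
* Constant probes: sd floor 1e-8 after quantile normalisation; s0 keeps
  t-scores finite when s0 > 0.
* `fcluster(..., maxclust=k)` can return fewer than k clusters on degenerate
  (duplicated) data; the model records the clusters actually formed.
* k is capped at M; requesting k > M is an error.
* Writers emit floats with `%.17g` and readers parse with round-trip
  precision, so write∘read is the identity and equal seeds give byte-equal
  outputs.

## Known limitations

* Two-class contexts only; no probability calibration or abstention.
* Unweighted, undirected community detection only (no Louvain/Leiden
  alternatives, no overlapping communities).
* The greedy modularity agglomeration has the usual resolution bias; very
  small true modules inside a dense component may be absorbed before the cut
  reaches them. The hop-distance re-attachment can inflate a community past
  `max_range`, which triggers re-partition rather than a size guarantee.
* G, the ranges and the overlap threshold interact with network density; the
  defaults follow the sparse-network setting (range 5–15) and should be
  re-selected for dense networks (e.g. range 5–25).
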