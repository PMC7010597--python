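# Methods

`genecascade` measures the biological gap between genetically engineered
organoids and matched tumor samples and prioritizes *gene cascading paths*
— candidate orders in which further driver mutations could be introduced.
The pipeline has five computational stages; this note records the model
behind each stage, the parameters that matter, the numerical choices that
were genuinely open, and what the synthetic data can and cannot show.

## 1. Rank-based expression scores

Organoid microarrays and tumor RNA-seq are not directly comparable, so
both are reduced to within-sample ranks over the common gene universe
(size N after gene intersection). The gene ranked `i` (1 = highest
expressed) in sample `s` receives

    W_s(g_i) = exp(-i / N),

a strictly decreasing function of rank bounded in `[e^-1, e^(-1/N)]`.
Scores depend on expression only through its order, so any strictly
monotone per-sample transformation (log, quantile scaling, unit changes)
leaves the entire downstream analysis unchanged — this is the property
that makes cross-platform joint analysis legitimate.

*Ties.* Average ranks would break strict monotonicity, so ties are ordinal
with gene-symbol lexicographic order as the tie-break: deterministic and
platform-independent. Ties are measure-zero for continuous expression and
only matter for degenerate inputs.

## 2. Functional activity and dysregulation

The activity of a function (pathway gene set) in a sample is a normalized
centroid shift:

    FAS = mean score over the function's genes − mean score over all other genes,

bounded in (−1, 1), zero under exchangeability. The gap between an
organoid group S and its tumor group T is, per function,

    DFAS = | mean_S FAS − mean_T FAS |.

Group FAS is the average of per-sample FAS (not pooled samples), matching
the averaging of per-sample activities in the procedure this implements.

*Null model.* Gene labels are permuted within every sample's score vector,
independently per sample and permutation, and DFAS is recomputed. This
preserves each sample's exact score distribution and tests only the
assignment of genes to the set. Group-label permutation is impossible at
the study's group sizes (single-sample organoid types), which forced this
choice. Empirical p-values carry the add-one pseudocount
`p = (1 + #{null ≥ observed}) / (n_perm + 1)`, so `p > 0` always — required
downstream by Fisher's combination — at the cost of a floor of
`1/(n_perm + 1)`. Defaults: 1,000 permutations, Benjamini–Hochberg FDR at
0.01.

A practical consequence of the p-value floor: with `n_perm` permutations
and `m` functions, the smallest attainable BH q-value is roughly
`m / (r (n_perm + 1))` for `r` true signals; runs with few permutations
need a correspondingly relaxed FDR (the fast test configurations do this
explicitly).

## 3. Signature dynamics

Hallmark-style signature activity uses the weighted Kolmogorov–Smirnov
running-sum enrichment score (ES): walking down a ranked gene list, hits
add `|metric|^p` normalized over the set (default `p = 1`), misses
subtract `1/(N − |set|)`; the ES is the signed maximum deviation. When the
maximum positive and negative deviations tie exactly, the positive side is
taken (declared tie-break, mirrored by the brute-force oracle in the
tests). A normalized ES is deliberately *not* computed: significance comes
from the procedure's own permutation null, not from a rescaled statistic.

For a pair of organoid types the ranking metric is the per-gene difference
of group-mean rank scores (the type with more mutations minus the other) —
a signal-to-noise metric is unavailable at n = 1 per type. Activation and
inactivation are the two tails of the same gene-label permutation null,
each BH-corrected across signatures at FDR 0.05. Single-sample activity
uses each sample's own rank-score vector as the metric; group-level
similarity is Pearson correlation of mean activity vectors.

## 4. Subsequent key genes

Each dysregulated pathway contributes a random walk with restart on the
protein-interaction network:

    P_{t+1} = (1 − r) W P_t + r P_0,   r = 0.7,

with `W` the column-stochastic adjacency (degree-zero nodes get a unit
self-loop to keep columns stochastic — the standard RWR convention; the
source procedure says only "normalized transfer matrix") and `P_0` uniform
over the pathway's seeds: the top 10% of its genes by *within-pathway*
degree (ceil, minimum one; cutoff ties by gene symbol). Iteration stops
when `max|P_{t+1} − P_t| < 1e-8`; since the residual contracts by a factor
`(1 − r) = 0.3` per step, convergence takes ~16 iterations. The closed
form `P = r (I − (1−r)W)^{-1} P_0` is implemented as a cross-checkable
fast path (`method="solve"`); the two agree to well below 1e-6 and the
test suite verifies this against an independent dense solve.

Per-gene significance is empirical: 1,000 pseudo-seed sets of the same
size, drawn uniformly from the network (degree-matched sampling is
available but not the default — only the size is prescribed), each walked
to its own steady state; `p_j` is the pseudocounted fraction of pseudo
walks giving gene j at least its observed probability. The K per-pathway
p-values combine by Fisher's method, `χ² = −2 Σ ln p` against χ²(2K), with
BH across genes at FDR 0.05. Genes already mutated in the organoid are
reported with their statistics but never called key.

*Power at small K.* With the p-value floor `1/1001`, a gene must sit near
the floor in ~3 of K = 5 pathways before BH across several thousand genes
can call it. At the study's scale (K of order 50–100) key-gene calls are
plentiful; at the synthetic scale the ranking is informative (planted
genes concentrate at the top, rank-sum p < 10⁻³) while the absolute
FDR call may return zero genes. The pipeline therefore falls back to the
ten best-ranked non-driver genes as cascade-path candidates when no gene
clears the FDR line.

## 5. Coherence network and cascade paths

Pairwise functional coherence between driver and candidate genes defaults
to the cosine similarity of binary function-membership vectors,
`|A∩B| / sqrt(|A||B|)`. The measure used by the original source is cited
there to external work without a formula; cosine over the loaded
gene-set annotation is this package's declared, pluggable substitute
(`measure=` accepts any set-pair function). In the synthetic pipeline the
annotation is membership *or one-hop network adjacency* to a function's
genes — generated pathways are node-disjoint by design (see §6), so pure
membership would make cross-pathway coherence identically zero, which real
overlapping catalogs never are.

Edges require coherence ≥ 0.4 (inclusive). The network is sparsified by
keeping each gene's two highest-coherence incident edges (ties by weight
then neighbor symbol; the union over genes is kept, so a popular hub may
retain degree above two). Paths run on the sparsified network: each
candidate's distance is the shortest-path length from the mutant-gene set
(minimum over mutants), the endpoint maximizes this distance (ties →
smaller key-gene q, then gene symbol), and one shortest path is extracted
by multi-source BFS with alphabetical source and neighbor expansion —
fully deterministic. Intermediate nodes need not be candidates; the
emitted path labels every node as mutant / candidate / intermediate.

## 6. Synthetic data: what it emulates and what it does not

The generator replaces the original inputs (organoid microarrays, tumor
expression and somatic mutations, curated pathway graphs, a literature
protein-interaction network, hallmark signatures) with structures having
the same shape and a known ground truth:

- **Network** — preferential attachment: a clique on m+1 nodes, then each
  new node attaches m edges with probability proportional to degree.
  Connected by construction, scale-free-like degree tail, and exactly
  `m(n−m−1) + m(m+1)/2` edges (tested in closed form). Default n = 5,000
  genes, m = 3 (~15,000 interactions) — a scale-down of a 9,617-gene,
  39,240-interaction literature network that keeps the full analysis in
  seconds-to-minutes on one CPU.
- **Pathways** — 50 connected BFS-ball subgraphs of 10–30 genes grown
  over *mutually disjoint* node sets. Disjointness is deliberate: planting
  a shift on one pathway must not leak signal into another, or
  sensitivity/specificity against the planted truth is ill-defined. Real
  pathway catalogs overlap heavily; that realism is reintroduced where it
  matters (coherence annotation) rather than where it would corrupt the
  ground truth.
- **Expression** — gene baseline `μ_g ~ Normal(0,1)`, log-normal values
  with within-gene sd σ = 1; the tumor group gets +δ·σ (δ = 3) on the log
  scale on every gene of each dysregulated pathway (10% of pathways).
  Because the downstream statistics are rank-based, only the monotone
  displacement matters, not the distributional family.
- **Key genes** — planted structurally as non-seed network neighbors of
  dysregulated-pathway hubs, preferring genes bordering several planted
  pathways: propagation proximity is exactly what the method rewards, so
  recovery tests the propagation stage, not biology.
- **Mutations** — every group sample carries Missense records for its
  declared drivers, plus decoy Silent records (decoy probability 0.2) to
  exercise the mutation-type filter.

Not emulated: probe-level microarray structure, batch effects,
between-gene correlation, clinical covariates, and annotation bias.
Passing tests on this generator show the machinery is correct and
calibrated under exchangeable noise with additive planted signal; they do
not show robustness to correlated expression noise or annotation
incompleteness in real data.

A universe-composition caveat worth knowing: rank scores are relative, so
shifting a large fraction of the genome displaces every other gene's rank.
With ~10% of genes shifted at δ = 3 in a small universe (≤1,000 genes),
unshifted pathways acquire a systematic spurious DFAS. At the default
5,000-gene universe the shifted fraction (~2%) leaves unplanted pathways
comfortably inside the null. The same effect exists in real data whenever
a large transcriptional program moves; it is a property of rank
normalization, not a bug.

## 7. Determinism and problem sizes

Every stochastic operation requires an explicit seed. The pipeline derives
per-stage seeds from the master seed keyed by stage name
(`sha256(f"{seed}:{stage}")`), so adding a stage never perturbs earlier
stages, and permutation streams are spawned per-permutation from numpy
`SeedSequence`, so results do not depend on how the permutation loop is
chunked. Rerunning the pipeline with the same inputs and master seed is
byte-identical (the manifest's wall-clock timings aside).

Problem sizes used by the tests and the reproduction script — chosen as
comfortable desk-scale versions of the study conditions: 5,000-gene
universe, 10 samples per group, 50 pathways, 1,000 permutations and 1,000
pseudo-seed randomizations; null calibration uses 20 replicates × 200
random gene sets at 2,000 genes. The full reproduction run completes in
about two minutes on one CPU.

## Known limitations

- The coherence measure is a declared substitute, not a reconstruction of
  the externally cited one; conclusions about specific path choices can
  shift under a different measure (the plug-in point exists for this).
- Empirical p-values are bounded below by `1/(n_perm+1)`; all FDR
  thresholds must be read jointly with the permutation count.
- The organoid/tumor comparison assumes a shared gene universe after
  intersection; genes absent from either platform are silently outside
  the analysis.
- Cascade paths are graph objects on a similarity network; the package
  makes no claim about the temporal order of mutation acquisition beyond
  the distance-maximizing endpoint convention.
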