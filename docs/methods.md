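# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic data does and does
not emulate, and the numerical conventions.

## Differential expression without replicates

With one library per condition there is no within-condition variance, so
DE calling is a deterministic rule, not a test.

* **Low-count filter.** A gene is kept iff its summed raw count over all
  samples of the species is ≥ 50 (strictly `< 50` is discarded). The
  filter runs on raw counts, before normalization, and is idempotent.
* **Size factors.** Median-of-ratios (the DESeq estimator): for sample j,
  s_j = median over reference genes of k_ij / geomean_i. Reference genes
  are those with strictly positive counts in every sample; if none
  exists the estimator is undefined and the package raises rather than
  guessing. TMM is not implemented: with two unreplicated libraries the
  two estimators differ negligibly relative to the ±1 log₂ threshold,
  and offering both invites silent inconsistency.
* **Fold change.** log₂((m_T + c)/(m_C + c)) on normalized condition
  means with pseudocount c = 1. The pseudocount is the only stabilizer
  available without replicates; it is monotone, zero-safe, and biases
  |lfc| downward for genes whose normalized means are of order c (≈150
  counts gives < 1% bias). It also fixes the 0/0 case to lfc = 0.
* **DE call.** up iff lfc ≥ +1, down iff lfc ≤ −1, both inclusive. The
  threshold is a parameter (`lfc_threshold`) but 1.0 is the convention
  the rest of the pipeline assumes.
* **QC PCA** operates on log₂(normalized + 1) with genes centered across
  samples; variance fractions are singular values squared over their sum
  and therefore sum to exactly 1.

Label-swap antisymmetry (swapping condition labels negates every lfc and
exchanges up/down) holds exactly because the pseudocount enters both
numerator and denominator.

## Reciprocal best hits

Hit tables are BLAST tabular (outfmt 6); multiple HSPs per (query,
subject) collapse to the maximum bit-score first. Hits with bit-score
< 100 are removed (strict). A pair (a, b) enters the map iff b is a's
single best subject A→B and a is b's best subject B→A. Tie-breaking is
deterministic: higher bit-score, then longer subject sequence (alignment
length when sequence length is unavailable), then lexicographically
smaller id — this realizes "keep only the longest with the best score"
wherever a length can discriminate. `collapse_duplicates` applies the
same rule per subject for annotation deduplication. The output is
asserted to be one-to-one on every call, and mutual-best symmetry means
swapping the two input tables yields the transposed pair set.

## Merged pathway networks

Pathways enter as GMT membership plus SIF edges; edge endpoints must be
co-members of a pathway and self-loops are dropped at load. Because SIF
carries no pathway provenance, a re-loaded collection attaches each edge
to every pathway containing both endpoints; collection equality (and all
downstream statistics) is therefore defined on memberships plus the
deduplicated edge union, which determines the merged graph exactly.

Selection keeps pathways with ≥ 1 DE member. Merging takes the union of
nodes and deduplicated undirected edges; members without edges are
singletons, reported separately and excluded from degree statistics,
hub calls and ECDFs. Hubs are nodes with degree strictly > 20 (degree 20
is not a hub). Neighborhood connectivity is the mean degree of a node's
neighbors (0 for an isolated node, which cannot occur in the connected
part). Degree ECDFs are standard right-continuous step functions.
Overlap percentages between two species' networks are round-half-up
integers over connected (non-singleton) nodes. Edge types are collapsed:
all topology statistics use degree only, so directions and interaction
labels would not change any reported number.

`exclude_gene_module` exists for self-contained complexes (e.g. a block
of co-regulated ribosomal protein genes) whose internal density distorts
the degree distribution; removal recomputes degrees and hub flags, and
nodes orphaned by the removal move to the singleton set.

## Neighborhood permutation test

The statistic is the number of DE nodes at distance 1..r (default r = 2)
from any seed, seeds excluded — seeds are typically DE by selection and
would bias their own test. The label universe is the connected part of
the network (the same universe on which degrees are defined); seeds keep
their labels inside the universe. Each of n_perm (default 1,000)
permutations assigns the observed number of DE labels to a uniform
random node subset; the implementation draws subsets via per-row
argpartition of uniform keys, chunked to bound memory. Since a uniform
subset draw is sampling without replacement, the exact null is
Hypergeometric(N, K, n); the permutation estimate is used anyway because
it generalizes unchanged to the hub-restricted variant and mirrors the
procedure it models.

Reported quantities: null mean and sd (n−1 denominator),
z = (obs − mean)/sd, two-sided normal p = 2(1 − Φ(|z|)), and an add-one
empirical upper-tail p, (1 + #{null ≥ obs})/(n_perm + 1), doubled and
capped at 1. A zero-sd null (K = 0, K = N, or an empty neighborhood) is
flagged degenerate explicitly; z and p_normal are None, never NaN. The
hub-restricted variant confines the universe, the neighborhood and the
observed count to hub nodes, for the question "are the *hubs* around the
seeds unusually DE" as opposed to all genes.

Calibration (reproducible via `analysis/06_calibration_studies.py` and
`scripts/acceptance.py`): under a uniform-label null on unplanted
synthetic networks the test rejects at α = 0.05 at a measured rate of
≈ 0.055 over 400 replicates — mildly anti-conservative, as expected when
a normal tail is applied to a discrete hypergeometric count with
moments estimated from 1,000 permutations. The empirical p is the safer
choice for small neighborhoods; both are always reported.

## Synthetic data

The generator emulates the target study design: two species, one control
and one treated library each, 24 h hormone treatment, transcriptome-level
counts, a pathway collection, and cross-species similarity hits.

Defaults (one decision each, fixed before any tuning):

| parameter | default | rationale |
|---|---|---|
| n_genes | 2,000 | enough for stable pathway sampling, small enough for fast tests |
| n_samples_per_condition | 1 | the unreplicated design the pipeline targets |
| nb_mean_log_mu / sigma | 5.0 / 1.0 | log-normal gene means, median ≈ 150 counts — typical mid-depth RNA-seq after low-count filtering |
| nb_dispersion (shape k) | 20 | var = μ + μ²/k, i.e. φ = 0.05, the usual magnitude for genetically near-identical laboratory animals |
| de_fraction | 0.05 | ~5% responders, matching the scale of hormone-response experiments |
| de_lfc_magnitude | 1.5 | planted effects clear the ±1 threshold but remain fallible under NB noise |
| n_pathways / size range / edge density | 40 / 10–60 / 0.08 | merged networks of ~1,000 nodes with realistic sparse degree structure |
| seed_target_degree | 25 | comfortably above the hub threshold of 20 |
| neighborhood_enrich_prob | 0.8 | strong but not total planting, so recovery is non-trivial |
| decoy_hit_fraction | 0.2 | enough noise to exercise the bit-score filter and best-hit logic |

Counts are negative binomial; planted DE genes have treated mean
2^(±1.5) × control mean. Pathway modules are Erdős–Rényi internally —
no pathway-database topology statistics are emulated, only controllable
degree structure. Seed genes are wired into pathways edge by edge until
their merged degree reaches the target, then DE labels inside the seeds'
radius-2 neighborhood are re-drawn at the enrichment probability and the
species-A counts of re-labeled genes are re-drawn so truth and
expression agree end to end (planting is exact in the truth record, and
recoverable through the expression pipeline up to NB noise). Hit tables
give every true homolog pair mutual scores in [150, 400); decoys link
non-homologous genes strictly below both partners' true scores, spanning
the bit-score floor (one decoy is pinned at 99.0 so the boundary is
always exercised) — hence the planted map is recoverable with precision
1 whenever the filter and reciprocity rules are implemented correctly,
and recall is limited only by decoy collisions.

What the generator does **not** emulate: read-level sequencing, assembly
artifacts and chimerism, GC/length biases, correlated gene modules in
expression (counts are independent across genes given their means), true
pathway-database topology, paralogy (the planted homology is strictly
one-to-one). Passing tests therefore demonstrate correctness of the
*rules* and calibration of the *test statistics* under a clean generative
model, not robustness to real-data pathologies.

All generators are driven by a single integer seed through independent
seed-sequence streams per stage; identical configs give byte-identical
outputs, including the written files.

## Term-profile contrast

Annotation profiles (term → number of annotated genes in a DE list) are
compared per term with Fisher's exact test on the 2×2 table
(in-list vs not, list A vs list B), BH-adjusted across terms, plus a
global chi-square homogeneity test over the two count vectors with terms
of expected count < 1 pooled. The per-term log-ratio is
log₂ of relative frequencies with 0.5/1.0 continuity corrections,
positive = A-leaning. This is deliberately simple: term counts are not
multinomial (a gene carries several terms), so the global p is a
descriptive homogeneity index, not an exact test.

## Numerical conventions and problem sizes

* Thresholds: count filter ≥ 50 to keep, bit-score ≥ 100 to keep,
  |lfc| ≥ 1 to call, degree > 20 for hubs — the first three inclusive on
  the keep/call side, the hub rule strict, all as stated by their
  sources in the pipeline's conventions.
* Percentages round half up to integers.
* Report bundles contain no timestamps; the manifest carries the package
  version, the rng seed and a SHA-256 hash of the config (destination
  directory excluded), so reruns are byte-identical.
* The calibration studies run at n_genes = 800, n_pathways = 25
  (merged networks of ≈ 500–700 nodes): 40 networks × 10 label draws for
  the type-I study, 20 datasets × (1 true + 50 random seed pairs) for
  recovery, 10,000 permutations for the null-moment check. These sizes
  give Monte-Carlo errors well inside the decision margins while keeping
  the full suite around a minute.

## Known limitations

* No significance is attached to individual DE calls — the threshold
  rule is the model, and its false-positive rate is a function of the
  (unknowable, unreplicated) dispersion.
* TMM normalization, KGML pathway parsing, GO-DAG propagation and any
  graph layout are out of scope.
* The neighborhood test conditions on the observed network; it does not
  model uncertainty in network construction itself.
* The normal p is slightly anti-conservative for small neighborhoods
  (see calibration above); prefer the empirical p there.
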