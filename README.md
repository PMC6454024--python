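# netcontrast

Cross-species contrast of hormone-induced transcriptional responses
through merged pathway networks.

## The problem

Two related species can respond to the same endocrine stimulus — here,
thyroid hormone (T₃) driving amphibian post-embryonic development — with
largely different sets of regulated genes, yet end up mobilizing the same
biological pathways. With unreplicated RNA-seq per condition (one control
and one treated library per species, a common design for non-model
organisms with assembled transcriptomes) no variance-based test is
possible, so the analysis rests on a chain of simple, explicit rules:

1. **DE calling** (`netcontrast.expression`). Genes with total raw count
   < 50 are discarded; libraries are depth-equalized with median-of-ratios
   size factors s_j = median_i ( k_ij / (∏_j k_ij)^(1/m) ) over genes
   positive in every sample; a gene is *up* when
   log₂((treated + 1)/(control + 1)) ≥ 1 and *down* when ≤ −1
   (boundaries inclusive), on normalized means.
2. **Homology mapping** (`netcontrast.homology`). Cross-species similarity
   hits (BLAST tabular) below bit-score 100 are discarded; a gene pair
   (a, b) is accepted when each is the other's highest-scoring hit
   (reciprocal best hit), ties resolved by score → sequence length →
   identifier. The map is a bijection on its support.
3. **Network construction** (`netcontrast.pathnet`). Every pathway
   (GMT membership + SIF interaction edges) containing ≥ 1 DE gene is
   merged into one simple undirected graph. Hubs are nodes with degree
   > 20; neighborhood connectivity is the mean degree of a node's
   neighbors; degree ECDFs are computed separately for DE and non-DE
   nodes; singletons are reported but excluded from degree statistics.
4. **Neighborhood enrichment** (`netcontrast.neighborhood`). For a set of
   seed nodes, the statistic is the number of DE genes at graph distance
   1–2 (seeds excluded). Its null is estimated by shuffling the DE labels
   uniformly over the network's nodes (1,000 permutations by default):
   z = (observed − null mean)/null sd, with a two-sided normal p and an
   add-one empirical p. Because each shuffle is a uniform draw without
   replacement, the exact null is hypergeometric, which the permutation
   moments approach as permutations accumulate.

A synthetic-data generator (`netcontrast.syndata`) produces complete
two-species datasets with known ground truth — negative-binomial counts
with planted fold changes, random pathway modules with seed genes wired
as hubs and an enriched radius-2 neighborhood, and noisy reciprocal hit
tables — so every stage can be validated against planted truth without
any external download.

## Worked example

```
$ cd <workdir>
$ python <repo>/analysis/01_simulate_data.py --seed 0
dataset written to results/data
genes per species: 2000, pathways: 40
planted DE genes: 340 (A), 100 (B)
seed hubs: gA0000, gA0001; planted neighborhood: 312 nodes

$ python <repo>/analysis/02_differential_expression.py
species_a: 1911 genes pass the low-count filter; 362 DE (184 up, 178 down); 279/324 planted DE genes recovered
species_b: 1920 genes pass the low-count filter; 175 DE (87 up, 88 down); 80/94 planted DE genes recovered

$ python <repo>/analysis/03_homology_map.py
bit-score filter kept 2147/2195 forward and 2142/2205 reverse hits
reciprocal best hits: 1996 one-to-one pairs (1996 of 2000 true pairs, 0 spurious)
shared DE pairs: 25 (7 up/up, 3 down/down, 15 opposite); species-specific DE: 337 (A), 150 (B)

$ python <repo>/analysis/04_pathway_network.py
species_a: 1009 nodes, 2558 edges, 34 singletons, 4 hubs (40 pathways selected)
species_b: 960 nodes, 2422 edges, 30 singletons, 4 hubs (36 pathways selected)
overlap: 960 shared nodes (95% of A, 100% of B); 36 shared pathways

$ python <repo>/analysis/05_neighborhood_test.py
[all nodes] seeds=gA0000,gA0001 neighborhood=312 observed DE=205 null=88.52+/-6.56 z=17.762 p_normal=0.0000 p_empirical=0.0020
```

Reading the last line: of the 312 genes within two steps of the seed
hubs, 205 are DE, versus 88.5 ± 6.6 expected when DE labels are placed at
random — almost 18 standard deviations of enrichment, so the seeds sit in
a genuinely DE-dense subnetwork (which is exactly what the generator
planted). The same machinery is exposed as a CLI
(`netcontrast simulate | expression | homology | network | neighborhood |
run | report`) and as a one-call pipeline (`netcontrast.report.run_pipeline`)
that writes a deterministic, manifest-stamped report bundle including a
hub report partitioned into species-A-specific / shared /
species-B-specific DE hubs.

`analysis/06_calibration_studies.py` quantifies error rates under known
truth: permutation-null moments against the hypergeometric closed form,
the type-I error of the neighborhood test on unplanted networks, the
recovery rate of planted seeds against random seed pairs, and the
precision/recall of the homolog map.

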