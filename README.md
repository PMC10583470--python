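# ferronet

Analysis pipeline for time-course transcriptomics of iron-deficiency
(-Fe) response in root epidermal cells — and, more generally, for any
two-condition expression time course in which you want to (1) call and
organise differentially expressed genes (DEGs) over time, (2) cluster
their trajectories, (3) infer which co-expression clusters drive which
others using time-lagged mutual information, and (4) screen promoter
motifs for the transcription factors (TFs) most predictive of
differential expression — including TFs that never change expression
themselves and would be invisible to DE analysis alone.

## The method

**DEG sets and waves.** Genes are tested per time point (stand-in test:
Welch's t on log2(x+1), BH within time point) and flagged when FDR ≤ 0.05
and |log2FC| ≥ 0.75, against either the 0-h control only or the
matched-time control. Any-time DEG sets, their overlaps, the genes DE at
every time point, and TF response waves (first DE before 12 h / in
12–18 h / only after 30 h) reproduce the study's set logic.

**Inter-cluster network.** DE-gene trajectories are max-normalized,
N_t = (R_t − mean(R)) / max(R), and clustered (pluggable: external
assignments or built-in agglomerative clustering). For every cluster
pair, gene pairs are drawn by Latin hypercube sampling and mutual
information is estimated at lag 0 and at a one-step (6-h) lag, by default
with the Gaussian parametric form MI = −½·ln(1 − ρ²). The pair's
connection score α_ij is the 90th percentile of its MI distribution; a
global threshold α\* is set at the centre of the widest empty gap in the
histogram of all α values; edges with α ≥ α\* form the network, lag-0
edges undirected and lagged edges directed.

**Motif screen.** Binary promoter-motif features (1000-bp strand-aware
promoters scanned for IUPAC consensi, or an AME-style map ingested
directly) enter an L1-penalized logistic regression of DE (1) versus an
equal-sized sample of quiescent genes (max |log2FC| < 0.251, labelled 0).
The fit is repeated 20 times with fresh folds and negative draws; motifs
whose coefficient x satisfies e^x > 1 in **all** runs are the motifs of
interest. TFs bound to them but absent from the DEG set are reported as
candidate post-transcriptionally regulated regulators.

A fully seeded synthetic-data module generates expression courses with
planted DE genes, cluster archetypes, lagged inter-cluster dependencies
and motif effects, so every stage is testable by parameter recovery with
no downloads.

## Worked example

Run the end-to-end demo on synthetic data (2000 genes, 10 clusters, two
planted lag-1 edges, three causal motifs):

```bash
ferronet demo --seed 1 --outdir run1
```

or equivalently from Python:

```python
from ferronet.pipeline import PipelineConfig, run_stage
run_stage("demo", PipelineConfig({"seed": 1}), "run1")
```

`run1/network_summary.txt` then reads:

```
Inter-cluster MI network
========================================
clusters:            10
cluster pairs x lags:   135
samples per pair:    1000
estimator:           gaussian_parametric
alpha percentile:    0.90
alpha threshold:     1.4584
accepted edges:      2 (0 undirected, 2 directed)
connected clusters:  4
```

The 135 rows are 45 unordered cluster pairs at lag 0 plus 90 ordered
pairs at lag 1; the empty-bin rule put α\* at 1.458, and exactly the two
planted directed lag-1 edges cleared it. `run1/recovery_report.txt`
compares every stage with the planted truth:

```
de_recall: 0.9875
de_precision: 1.0
planted_edges_recovered_directed: 2
false_positive_cluster_pairs: 0
n_consistent_motifs: 3
causal_motifs_recovered: ['M001', 'M002', 'M003']
null_motifs_consistent: []
n_non_de_candidates_on_causal_motifs: 3
```

i.e. 395/400 planted DEGs were recalled with no false calls, both
planted cluster dependencies and all three planted motifs (log-odds
effects 2.0, 1.5, 1.0) were recovered with no false motifs, and the
flat-profile TFs bound to those motifs surfaced as non-DE candidate
regulators. Individual stages are available as subcommands
(`simulate`, `de`, `cluster`, `network`, `motifs`, `regress`, `report`)
sharing one YAML config, and as library calls
(`InterClusterNetwork(...).fit()`, `MotifScreen(...).fit()`, each
returning a results object with a `summary()`).

## Layout

- `src/ferronet/simulate.py` — synthetic data with planted ground truth
- `src/ferronet/de.py` — DE stand-in, DEG sets, waves
- `src/ferronet/trajectories.py` — max-normalization, clustering
- `src/ferronet/network.py` — LHS sampling, MI estimators, α, threshold,
  `InterClusterNetwork` model
- `src/ferronet/motifs.py` — promoters, motif features, enrichment
- `src/ferronet/regression.py` — `MotifScreen` LASSO ensemble, regulators
- `src/ferronet/reporting.py` — target enrichment, keyword filter
- `src/ferronet/pipeline.py`, `cli.py` — stages, manifest, CLI
- `docs/methods.md` — model assumptions, defaults, limitations
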