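# Methods

`ferronet` re-implements, as a self-contained and testable pipeline, a
time-course analysis of iron-deficiency (-Fe) response in root epidermal
cells: per-time-point differential expression and DEG set logic, trajectory
clustering of DE genes, a sampling-based time-lagged mutual-information
(MI) network between co-expression clusters, and an L1-regularized
logistic-regression screen that uses promoter-motif features to nominate
transcription factors — including ones that are *not* themselves
differentially expressed — as putative regulators. This note records the
model assumptions, the defaults and why they were chosen, and the places
where the design was genuinely open.

## Differential expression stand-in

Count-model DE testing (GLM quasi-likelihood machinery on read counts) is
deliberately out of scope: the pipeline operates on RPKM-like abundances
and uses a declared stand-in — Welch's t-test on `log2(x+1)`, with
Benjamini–Hochberg correction applied **within each time point** — so the
thresholding and set logic downstream can be tested without external
tooling. The flag rule is the study's: FDR ≤ 0.05 and |log2FC| ≥ 0.75.
`DETable.from_tsv` also ingests externally computed DE tables (e.g. from a
count-based pipeline) for real-data runs.

Two reference modes exist because the DEG sets are defined against
different baselines: `zero_hour_control` contrasts every stressed time
point against the 0-h control replicates; `per_time_control` contrasts
against the matched-time control. Set G (per-time controls) uses only the
post-0 time points, since 0 h has no within-time contrast.

Response waves for TFs follow first-flag timing: wave 1 before 12 h,
wave 2 in [12, 18] h, wave 3 flagged **only** after 30 h. TFs first
flagged at 24 or 30 h fall in a gap of the published definition and are
reported `unassigned` rather than guessed into a wave.

## Max-normalization

Trajectories are normalized before clustering and MI estimation as

    N_t = (R_t − mean_k R_k) / max_k R_k ,

i.e. centre by the series mean, scale by the series maximum. The printed
form of this equation in the source protocol carries a free index and a
partial sum inconsistent with its verbal description ("max normalized");
the reading above is the one consistent with that description, and is
scale-invariant (`normalize(c·R) = normalize(R)` for c > 0) with constant
trajectories mapping to zero. Normalization is applied to the
stress-condition replicate-mean trajectories; whether the original
analysis used stress samples only or both conditions is unstated, and the
choice is recorded in the cluster stage's output metadata.

## Trajectory clustering

The reference clustering (a Dirichlet-process Gaussian-process mixture)
is external and pluggable: assignments in its output format are ingested
and validated. The built-in default is agglomerative clustering with
correlation distance and average linkage at a user-supplied K — K has no
silent default because the appropriate number (50 in the original study)
is data-specific. The built-in method is deterministic.

## Inter-cluster MI network

For each cluster pair, gene pairs are drawn by Latin hypercube sampling:
each cluster's gene-index range is split into `n_samples` equal strata
(default 1000), one uniform draw per stratum, stratum order permuted
independently per cluster before pairing. When the cluster size divides
the sample count every gene is covered; smaller clusters repeat genes.

MI is estimated at lag 0 and lag 1 (one 6-h sampling step). The default
estimator is the Gaussian parametric form `MI = −½·ln(1 − ρ²)` in nats,
with ρ the sample Pearson correlation clipped to |ρ| ≤ 0.9999. With at
most seven time samples per gene, a density-based estimate is badly
under-determined, so the parametric form is the honest default; a KDE
estimator (product-Gaussian kernels, grid integration of the standard
integrand `f(x,y)·log[f(x,y)/(f(x)f(y))]`) is provided as an option and
agrees with the closed form on Gaussian data to within ~0.1 nats at
n = 500. Its bandwidth is a Silverman-type rule deliberately
undersmoothed (`h = 0.8·σ·n^(−1/5)`): the standard 2-D plug-in rate
flattens the ridge of strongly correlated samples and biases MI downward.
The printed MI integrand in the source protocol has the density ratio
inverted (which would make MI non-positive); the standard orientation is
implemented. Lag-0 MI uses all 7 aligned points; lag-1 uses the 6
overlapping points.

The connection strength of a cluster pair is α_ij, the 90th percentile
(linear interpolation) of its sampled MI distribution. The global
threshold α\* is chosen by the empty-bin gap rule: histogram all α values
(50 bins), find maximal runs of consecutive empty bins flanked by
occupied bins, and take the centre of the longest run, breaking ties
toward the lowest-valued run (a conservative, smaller threshold). If no
interior bin is empty the rule falls back to the 95th percentile of α
with a warning. Accepted lag-0 edges are undirected (duplicated
orientations keep the larger α); lagged edges are directed source →
target, mirroring the convention that only time-lagged MI carries an
arrow.

Whether the original sampling drew TFs only or all clustered genes is
ambiguous in the protocol; the model accepts an optional gene whitelist
(e.g. a TF list) and the pipeline exposes a `tf_only` flag.

## Promoters and motif features

Promoters are the 1000 bp upstream of the TSS: plus strand
`[TSS−1000, TSS−1]` in 1-based inclusive coordinates, minus strand
`[end+1, end+1000]` reverse-complemented, truncated at contig edges (a
TSS flush with the edge yields an empty promoter with a warning). With
multiple records per gene id, the 5'-most TSS on the gene's strand is
used. Motif presence is a binary feature per (gene, motif): IUPAC
consensus scanning on both strands by default, or direct ingestion of an
AME-style motif → gene map; presence is encoded 1 (the protocol's
Methods convention; its Results section inverts the coding in prose).
A one-sided hypergeometric per (motif, cluster) with BH correction
stands in for external motif-enrichment tooling in self-contained runs.

## LASSO motif screen

Positives are all DE genes pooled across clusters (label 1); negatives
are an equal-sized random sample of quiescent genes with
max-over-time |log2FC| < 0.251 (label 0). Binary features are not
standardized, so each coefficient x is the motif's log-odds contribution
and the selection rule e^x > 1 reads directly as "raises the odds of
differential expression".

The penalty is chosen by 10-fold cross-validated deviance over a grid of
21 inverse-penalty values (10⁻³…10²). The default selection rule is the
**1-SE rule** (strongest penalty within one standard error of the best
mean deviance) rather than the plain minimum: at the minimum the LASSO
retains weak chance associations, and in parameter-recovery experiments
null motifs then survive the all-runs consistency filter; at 1-SE the
planted causal motif is still selected in every run while null motifs are
not. The plain minimum remains available (`lambda_rule="min"`).

The fit is repeated 20 times; run-to-run stochasticity comes from fresh
CV fold assignments and (by default) a fresh negative-sample draw per
run, both seeded — the two plausible random elements behind run-to-run
coefficient variability. Motifs with a positive coefficient in **all**
runs are the consistent motifs of interest. TFs bound to a consistent
motif are putative regulators; those not in the per-time-control DEG set
are reported as candidate post-transcriptional regulators, and putative
targets (genes carrying the motif) are intersected with a user-supplied
known-gene list (e.g. iron-homeostasis genes).

Target-set functional enrichment is a one-sided hypergeometric per term
with BH correction within each regulator's term family, against the
feature-matrix gene universe (the screen's sampling frame, not the whole
genome); a keyword filter narrows significant terms by case-insensitive
substring match.

## Synthetic data: what it emulates, and what it does not

The generator produces the statistical structure the analysis assumes,
with planted ground truth for parameter recovery:

- **Design**: two conditions × 7 time points (0–36 h, 6-h steps) ×
  3 replicates, the uniform grid the lag machinery assumes (one sampling
  step = 6 h). Abundances are RPKM-like, `2^(log2-profile + noise)` with
  additive Gaussian replicate noise on log2 (default sd 0.2).
- **DE genes** (default 20% of 2000 genes) deviate from their flat
  control baseline by `amplitude × cluster archetype + smooth
  gene-specific perturbation`; amplitudes are ±Uniform(1.5, 2.5) log2
  units, and per-(gene, time) truth flags mark |deviation| ≥ 0.75,
  matching the pipeline's flag threshold.
- **Cluster archetypes** are onset-gated smooth curves (linear trend plus
  one short-period (10–16 h) and one long-period (20–40 h) sinusoid;
  logistic onset ramp drawn over 0–24 h, giving temporal waves).
  Independent archetypes are drawn with rejection so that no two exceed
  |Pearson r| = 0.6 across shifts of up to ±2 sampling steps: with only
  seven samples, unconstrained smooth curves frequently collide at
  |r| > 0.95, i.e. the generator would produce duplicate clusters that a
  trajectory clustering would have merged — a structure the network
  stage rightly cannot distinguish from a planted edge.
- **Planted edges** (i, j, lag) make cluster j's stress archetype an
  affine (monotone) transform of cluster i's archetype evaluated `lag`
  steps earlier, so the lagged correlation at the planted lag is maximal
  by construction.
- **Intra-cluster variation** (perturbation scale 0.4) is deliberately
  substantial — the cluster mean is not a good representation of its
  member genes — which keeps sampled MI distributions away from the
  correlation clip and makes the α distribution properly bimodal.
- **Motif features**: causal motifs are present with probability
  `logistic(b0 + effect)` in DE genes and `logistic(b0)` otherwise
  (b0 = 0, background presence 0.5); null motifs are independent of DE
  status. Each motif binds 1–3 TFs, about half drawn from the flat
  (non-DE) TF pool so the regulator report has planted non-DE candidates.

Not emulated: read counts and library-size effects, sequencing error,
cell-sorting contamination, unequal sampling grids, and any genuine
regulatory biochemistry — passing recovery tests shows the *inference
machinery* behaves as designed under its own assumptions, not that those
assumptions hold in real epidermal data.

## Problem sizes and scenarios

The default end-to-end scenario (also the `demo` subcommand) is 2000
genes, 10 clusters, 2 planted lag-1 edges, 3 causal motifs among 50, 20
regression runs. Recovery experiments use this scale: the network
recovery experiment runs 10 seeds of the default scenario; the screen
recovery experiment uses one causal motif (+2 log-odds) among 20 with
10 replicate experiments of the 20-run ensemble. At these sizes a full
demo completes in well under ten minutes on one CPU. False positives in
network recovery are counted at the cluster-pair level: a lag-0 edge
between clusters joined by a planted lag-1 edge reflects genuine
(autocorrelated) dependence and is not counted as spurious.

## Numerical choices and degenerate inputs

- Zero-variance vectors: MI estimators return 0 with a warning; Welch's
  test returns p = 1 for equal means and p = 0 for distinct means when
  both groups are constant.
- ρ is clipped at 0.9999 (MI ceiling ≈ 4.26 nats).
- Percentiles use linear interpolation between order statistics.
- Empty-bin threshold ties break toward the lower gap.
- All-zero trajectories are rejected as degenerate before normalization;
  degenerate archetypes are redrawn.
- Every random element (generator, LHS, negative sampling, CV folds) is
  seeded through a single per-run seed; liblinear's internal state is
  pinned; repeated runs are byte-identical.

## Known limitations

- The Welch stand-in ignores count overdispersion; its recall/precision
  on real count data would differ from a count-model pipeline.
- The parametric MI estimator measures only linear (Gaussian)
  dependence; with 7 samples this is a feature, but genuinely nonlinear
  lagged relationships would be under-scored.
- The empty-bin gap rule assumes a bimodal α distribution; on data
  without separation it falls back to a quantile cutoff and says so.
- The 1-SE penalty rule trades a small amount of power for the false
  positive control the consistency filter needs; very weak motif effects
  (log-odds ≲ 0.5) are often not selected in all runs at n = 2000.
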