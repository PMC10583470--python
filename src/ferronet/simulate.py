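"""Synthetic time-course expression data with planted structure.

Generates two-condition (control / iron-starved) expression time courses
with replicate noise, a configurable fraction of differentially expressed
genes organised into cluster-structured trajectory archetypes, planted
time-lagged dependencies between clusters, and a binary promoter-motif
feature matrix whose causal motifs shift the log-odds of differential
expression by known amounts.  Every downstream stage of the pipeline can
therefore be tested by parameter recovery against the returned ground
truth.

Values are RPKM-like abundances.  Replicate noise is additive Gaussian on
the log2 scale.  Cluster archetypes are smooth curves (a low-order
polynomial plus one sinusoid, gated by a logistic onset ramp); a planted
edge (i, j, lag) makes cluster j's stress-deviation archetype an affine
monotone transform of cluster i's archetype evaluated ``lag`` sampling
steps earlier.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .motifs import MotifFeatureMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ExpressionMatrix",
    "simulate_trajectories",
    "simulate_motif_matrix",
    "write_expression_tsv",
    "read_expression_tsv",
    "write_truth_json",
    "read_truth_json",
    "write_motif_tf_map_tsv",
]

CONTROL = "control"
STRESS = "stress"


@dataclass
class SimulationConfig:
    """Tunable knobs of the synthetic study.

    Defaults mirror the study design the pipeline targets: a 0-36 h
    sampling grid in 6-h steps, two conditions, three replicates.
    """

    n_genes: int = 2000
    n_tfs: int = 200
    time_points: tuple = (0, 6, 12, 18, 24, 30, 36)
    n_replicates: int = 3
    n_clusters: int = 10
    de_fraction: float = 0.2
    #: per-gene peak |log2FC| drawn uniformly from this range
    de_effect_range: tuple = (1.5, 2.5)
    #: per-(gene, time) DE ground-truth flag: |planted log2 deviation| >= this
    de_flag_threshold: float = 0.75
    #: planted (source cluster, target cluster, lag in sampling steps)
    planted_edges: tuple = ()
    #: cap on |Pearson r| between independent cluster archetypes across
    #: small shifts (clusterings do not emit near-duplicate clusters)
    max_archetype_corr: float = 0.6
    n_motifs: int = 50
    #: motif id -> planted log-odds effect on DE status
    motif_effects: dict = field(default_factory=dict)
    #: baseline presence log-odds (0.0 -> background presence rate 0.5)
    motif_presence_logit: float = 0.0
    tfs_per_motif: tuple = (1, 3)
    #: fraction of motif-bound TFs drawn from the flat (non-DE) TF pool
    flat_tf_fraction: float = 0.5
    noise_sd: float = 0.2
    #: scale of the smooth gene-specific perturbation around the archetype
    intra_cluster_sd: float = 0.4
    base_log2_range: tuple = (5.0, 8.0)
    seed: int = 0

    def __post_init__(self) -> None:
        tp = np.asarray(self.time_points, dtype=float)
        if len(tp) < 2 or not np.all(np.diff(tp) > 0):
            raise ValueError("time points must be strictly increasing")
        n_lag_slots = len(tp) - 1
        for edge in self.planted_edges:
            i, j, lag = edge
            if not (0 <= lag < n_lag_slots):
                raise ValueError(
                    f"planted edge {edge}: lag must be in [0, {n_lag_slots})"
                )
            if not (1 <= i <= self.n_clusters and 1 <= j <= self.n_clusters):
                raise ValueError(f"planted edge {edge}: cluster id out of range")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_clusters > self.n_genes:
            raise ValueError("n_clusters may not exceed n_genes")
        if not (0 < self.de_fraction <= 1):
            raise ValueError("de_fraction must be in (0, 1]")
        if self.n_tfs > self.n_genes:
            raise ValueError("n_tfs may not exceed n_genes")


@dataclass
class GroundTruth:
    """Planted truth accompanying a simulated dataset."""

    #: genes x time points, True where the planted |log2 deviation| crossed
    #: the flag threshold
    de_flags: pd.DataFrame
    #: gene id -> cluster id (1..K), every gene in exactly one cluster
    cluster_of: pd.Series
    #: set of (source cluster, target cluster, lag steps)
    true_edges: set
    #: motif ids with a non-zero planted effect
    causal_motifs: set
    #: gene ids designated transcription factors
    tf_genes: list
    #: clusters x time points stress-deviation archetypes (max-abs 1)
    archetypes: pd.DataFrame

    @property
    def de_genes(self) -> set:
        """Genes flagged at one or more time points."""
        return set(self.de_flags.index[self.de_flags.any(axis=1)])


@dataclass
class ExpressionMatrix:
    """Genes x (condition, time, replicate) abundance values."""

    data: pd.DataFrame  # columns: MultiIndex (condition, time, replicate)

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def time_points(self) -> list:
        return sorted({t for _, t, _ in self.data.columns})

    def conditions(self) -> list:
        return sorted({c for c, _, _ in self.data.columns})

    def samples(self, condition: str, time) -> pd.DataFrame:
        """Replicate columns for one (condition, time) cell."""
        cols = [c for c in self.data.columns if c[0] == condition and c[1] == time]
        return self.data[cols]

    def mean_trajectories(self, condition: str = STRESS) -> pd.DataFrame:
        """Genes x time matrix of replicate-mean abundances."""
        sub = self.data[condition]
        return sub.T.groupby(level=0).mean().T


# ---------------------------------------------------------------------------
# archetype machinery


class _Archetype:
    """Smooth deviation curve: onset-gated trend plus two sinusoids.

    Defined on all of t (hours) so it can be evaluated at shifted times for
    planted lagged dependencies.  One short- and one long-period component
    give clusters distinguishable fine structure on a 6-h sampling grid.
    """

    def __init__(self, rng: np.random.Generator, t_max: float):
        self.a1 = rng.normal(0, 0.7)
        self.amp1 = rng.uniform(0.3, 1.0)
        self.amp2 = rng.uniform(0.3, 1.0)
        self.period1 = rng.uniform(10.0, 16.0)
        self.period2 = rng.uniform(20.0, 40.0)
        self.phase1 = rng.uniform(0, 2 * math.pi)
        self.phase2 = rng.uniform(0, 2 * math.pi)
        self.onset = rng.uniform(0.0, 24.0)
        self.t_max = t_max

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        ramp = 1.0 / (1.0 + np.exp(-(t - self.onset) / 3.0))
        wave = self.amp1 * np.sin(2 * math.pi * t / self.period1 + self.phase1)
        wave += self.amp2 * np.sin(2 * math.pi * t / self.period2 + self.phase2)
        return ramp * (self.a1 * t / self.t_max + wave)


class _ShiftedArchetype:
    """Monotone (affine) transform of a source archetype at a time lag."""

    def __init__(self, source, lag_hours: float, scale: float):
        self.source = source
        self.lag_hours = lag_hours
        self.scale = scale

    def __call__(self, t):
        return self.scale * self.source(np.asarray(t, dtype=float) - self.lag_hours)


def _max_shifted_abs_corr(f, others, t: np.ndarray, dt: float, max_shift: int) -> float:
    """Largest |Pearson r| between f and any drawn archetype over small shifts."""
    worst = 0.0
    for g in others:
        for s in range(-max_shift, max_shift + 1):
            x, y = f(t), g(t - s * dt)
            if x.std() == 0 or y.std() == 0:
                continue
            worst = max(worst, abs(float(np.corrcoef(x, y)[0, 1])))
    return worst


def _draw_archetypes(config: SimulationConfig, rng: np.random.Generator):
    """One deviation archetype per cluster, honouring planted edges.

    Independent archetypes are drawn with rejection against a pairwise
    shifted-correlation cap: a trajectory clustering would never emit two
    near-identical clusters, so accidental duplicates among the null
    clusters would misrepresent the structure the network stage assumes.
    Planted targets are exempt — they are lagged copies by design.
    """
    t = np.asarray(config.time_points, dtype=float)
    dt = float(t[1] - t[0])
    max_lag = max([lag for _, _, lag in config.planted_edges] + [1])
    funcs: dict = {}
    targets = {j: (i, lag) for i, j, lag in config.planted_edges}
    for c in range(1, config.n_clusters + 1):
        if c in targets:
            continue
        best, best_corr = None, np.inf
        for attempt in range(200):
            f = _Archetype(rng, t_max=float(t[-1]))
            if np.max(np.abs(f(t))) <= 1e-6:
                continue  # degenerate: redraw
            worst = _max_shifted_abs_corr(f, funcs.values(), t, dt, max_lag + 1)
            if worst < best_corr:
                best, best_corr = f, worst
            if worst <= config.max_archetype_corr:
                break
        if best is None:
            raise RuntimeError(
                f"degenerate archetype for cluster {c} after repeated redraws"
            )
        funcs[c] = best
    for j, (i, lag) in targets.items():
        if i not in funcs:
            raise ValueError(f"planted edge source cluster {i} is itself a target")
        funcs[j] = _ShiftedArchetype(funcs[i], lag * dt, rng.uniform(0.7, 1.3))
    # normalise each archetype to max |value| 1 on the sampling grid
    grid = {}
    for c, f in funcs.items():
        vals = f(t)
        grid[c] = vals / np.max(np.abs(vals))
    return grid


# ---------------------------------------------------------------------------
# main generators


def simulate_trajectories(config: SimulationConfig):
    """Generate an :class:`ExpressionMatrix` and its :class:`GroundTruth`.

    Control trajectories are flat per-gene baselines; the stress condition
    deviates from control only for planted DE genes, by
    ``amplitude * cluster archetype + smooth gene-specific perturbation``
    on the log2 scale.  Replicate noise is additive Gaussian on log2.
    """
    rng = np.random.default_rng(config.seed)
    t = np.asarray(config.time_points, dtype=float)
    T = len(t)
    n, R = config.n_genes, config.n_replicates
    width = max(4, len(str(n)))
    genes = [f"G{k + 1:0{width}d}" for k in range(n)]

    archetypes = _draw_archetypes(config, rng)
    arch_mat = pd.DataFrame(
        {c: archetypes[c] for c in sorted(archetypes)}, index=t
    ).T  # clusters x times
    arch_mat.columns = list(config.time_points)

    cluster_of = pd.Series(
        rng.permutation(np.arange(n) % config.n_clusters + 1), index=genes, name="cluster"
    )

    n_de = int(round(n * config.de_fraction))
    de_gene_idx = rng.choice(n, size=n_de, replace=False)
    is_de = np.zeros(n, dtype=bool)
    is_de[de_gene_idx] = True

    lo, hi = config.de_effect_range
    amp = rng.uniform(lo, hi, size=n) * rng.choice([-1.0, 1.0], size=n)

    # smooth gene-specific perturbation: small polynomial + sinusoid
    z = t / t[-1]
    c1 = rng.normal(0, 1.0, size=n)
    c2 = rng.normal(0, 1.0, size=n)
    phase = rng.uniform(0, 2 * math.pi, size=n)
    period = rng.choice([12.0, 18.0, 24.0], size=n)
    pert = config.intra_cluster_sd * (
        c1[:, None] * z[None, :]
        + c2[:, None] * np.sin(2 * math.pi * t[None, :] / period[:, None] + phase[:, None])
    )

    arch_rows = arch_mat.to_numpy()[cluster_of.to_numpy() - 1]  # genes x T
    deviation = np.where(is_de[:, None], amp[:, None] * arch_rows + pert, 0.0)

    flag_mat = np.abs(deviation) >= config.de_flag_threshold
    de_flags = pd.DataFrame(flag_mat, index=genes, columns=list(config.time_points))

    base = rng.uniform(*config.base_log2_range, size=n)
    log2_control = np.repeat(base[:, None], T, axis=1)
    log2_stress = log2_control + deviation

    cols, blocks = [], []
    for cond, profile in ((CONTROL, log2_control), (STRESS, log2_stress)):
        noise = rng.normal(0.0, config.noise_sd, size=(n, T, R))
        vals = 2.0 ** (profile[:, :, None] + noise)
        for ti, tp in enumerate(config.time_points):
            for r in range(1, R + 1):
                cols.append((cond, tp, r))
                blocks.append(vals[:, ti, r - 1])
    data = pd.DataFrame(
        np.column_stack(blocks),
        index=genes,
        columns=pd.MultiIndex.from_tuples(cols, names=["condition", "time", "replicate"]),
    )

    truth = GroundTruth(
        de_flags=de_flags,
        cluster_of=cluster_of,
        true_edges={tuple(e) for e in config.planted_edges},
        causal_motifs={m for m, e in config.motif_effects.items() if e != 0},
        tf_genes=genes[: config.n_tfs],
        archetypes=arch_mat,
    )
    return ExpressionMatrix(data), truth


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_motif_matrix(config: SimulationConfig, truth: GroundTruth) -> MotifFeatureMatrix:
    """Binary gene x motif presence matrix with planted DE associations.

    Causal motifs are present with probability ``logistic(b0 + effect)`` in
    DE genes and ``logistic(b0)`` otherwise; null motifs are independent of
    DE status.  Each motif is bound by one or more TFs; a configurable
    fraction of bound TFs are drawn from the flat (non-DE) TF pool so that
    the regulator report has planted non-DE candidates to find.
    """
    rng = np.random.default_rng(config.seed + 1)
    width = max(3, len(str(config.n_motifs)))
    motif_ids = [f"M{k + 1:0{width}d}" for k in range(config.n_motifs)]
    unknown = set(config.motif_effects) - set(motif_ids)
    if unknown:
        raise ValueError(f"motif_effects reference unknown motifs: {sorted(unknown)}")

    genes = list(truth.de_flags.index)
    de_status = truth.de_flags.any(axis=1).to_numpy()
    b0 = config.motif_presence_logit

    probs = np.empty((len(genes), len(motif_ids)))
    for k, m in enumerate(motif_ids):
        eff = config.motif_effects.get(m, 0.0)
        probs[:, k] = _sigmoid(b0 + eff * de_status)
    matrix = pd.DataFrame(
        (rng.random(probs.shape) < probs).astype(np.int8), index=genes, columns=motif_ids
    )

    tf_de = truth.de_flags.loc[truth.tf_genes].any(axis=1)
    flat_pool = [g for g in truth.tf_genes if not tf_de[g]]
    de_pool = [g for g in truth.tf_genes if tf_de[g]]
    lo, hi = config.tfs_per_motif
    motif_tf: dict = {}
    for m in motif_ids:
        k = int(rng.integers(lo, hi + 1))
        chosen: list = []
        for _ in range(k):
            pool = flat_pool if (rng.random() < config.flat_tf_fraction and flat_pool) else (
                de_pool or flat_pool
            )
            chosen.append(pool[int(rng.integers(len(pool)))])
        motif_tf[m] = sorted(set(chosen))
    return MotifFeatureMatrix(matrix=matrix, motif_tf=motif_tf)


# ---------------------------------------------------------------------------
# plain-text I/O


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    long = expr.data.stack([0, 1, 2], future_stack=True).rename("value").reset_index()
    long.columns = ["gene", "condition", "time", "replicate", "value"]
    long.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_expression_tsv(path) -> ExpressionMatrix:
    long = pd.read_csv(path, sep="\t")
    wide = long.pivot_table(
        index="gene", columns=["condition", "time", "replicate"], values="value", sort=False
    )
    wide = wide.loc[pd.unique(long["gene"])]
    return ExpressionMatrix(wide)


def write_truth_json(truth: GroundTruth, path) -> None:
    payload = {
        "de_flags": {g: [int(v) for v in row] for g, row in truth.de_flags.iterrows()},
        "time_points": [float(c) for c in truth.de_flags.columns],
        "cluster_of": {g: int(c) for g, c in truth.cluster_of.items()},
        "true_edges": sorted([int(i), int(j), int(l)] for i, j, l in truth.true_edges),
        "causal_motifs": sorted(truth.causal_motifs),
        "tf_genes": list(truth.tf_genes),
        "archetypes": {int(c): [float(v) for v in row] for c, row in truth.archetypes.iterrows()},
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth_json(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    tp = payload["time_points"]
    tp = [int(t) if float(t).is_integer() else float(t) for t in tp]
    genes = list(payload["de_flags"])
    de_flags = pd.DataFrame(
        [payload["de_flags"][g] for g in genes], index=genes, columns=tp
    ).astype(bool)
    return GroundTruth(
        de_flags=de_flags,
        cluster_of=pd.Series(payload["cluster_of"], name="cluster"),
        true_edges={tuple(e) for e in payload["true_edges"]},
        causal_motifs=set(payload["causal_motifs"]),
        tf_genes=payload["tf_genes"],
        archetypes=pd.DataFrame(
            {int(c): v for c, v in payload["archetypes"].items()}, index=tp
        ).T.sort_index(),
    )


def write_motif_tf_map_tsv(features: MotifFeatureMatrix, path) -> None:
    """AME-style map: motif id, alt id, bound TF, comma-joined target genes."""
    rows = []
    for m in features.matrix.columns:
        targets = ",".join(features.motif_targets(m))
        for tf in features.motif_tf.get(m, []):
            rows.append({"motif_id": m, "motif_alt_id": m, "tf_name": tf, "gene_list": targets})
    pd.DataFrame(rows, columns=["motif_id", "motif_alt_id", "tf_name", "gene_list"]).to_csv(
        path, sep="\t", index=False
    )


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
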