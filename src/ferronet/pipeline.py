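"""Stage orchestration: config handling, artifacts, manifest, demo run.

Each stage reads its upstream artifacts from a run directory, writes its
outputs atomically (temp file + rename), and appends an entry to
``manifest.json`` recording the SHA-256 of every input and output along
with the seeds used, so a run can be audited and re-runs can detect
stale upstream artifacts by hash mismatch.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import de as de_mod
from . import motifs as motifs_mod
from . import network as net_mod
from . import regression as reg_mod
from . import reporting as rep_mod
from . import simulate as sim_mod
from . import trajectories as traj_mod

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ConfigError", "DataError", "run_stage", "STAGES"]


class ConfigError(ValueError):
    """Bad configuration (CLI exit code 2)."""


class DataError(RuntimeError):
    """Missing or inconsistent data artifacts (CLI exit code 3)."""


_SECTION_KEYS = {
    "simulate": {f.name for f in dc_fields(sim_mod.SimulationConfig)},
    "de": {"fdr_threshold", "lfc_threshold"},
    "cluster": {"k"},
    "network": {"n_samples", "lags", "estimator", "q", "bins", "tf_only",
                "min_cluster_size", "use_true_clusters"},
    "regress": {"n_runs", "folds", "negative_max_abs_lfc", "resample_negatives",
                "lambda_rule"},
    "report": {"keywords"},
}

_DEFAULTS = {
    "seed": 0,
    "simulate": {
        "n_genes": 2000,
        "n_tfs": 200,
        "n_clusters": 10,
        "de_fraction": 0.2,
        "planted_edges": [[1, 2, 1], [3, 4, 1]],
        "n_motifs": 50,
        "motif_effects": {"M001": 2.0, "M002": 1.5, "M003": 1.0},
        "noise_sd": 0.2,
    },
    "de": {"fdr_threshold": 0.05, "lfc_threshold": 0.75},
    "cluster": {"k": 10},
    "network": {"n_samples": 1000, "lags": [0, 1], "estimator": "gaussian_parametric",
                "q": 0.90, "bins": 50, "tf_only": False, "min_cluster_size": 2,
                "use_true_clusters": True},
    "regress": {"n_runs": 20, "folds": 10, "negative_max_abs_lfc": 0.251,
                "resample_negatives": True, "lambda_rule": "1se"},
    "report": {"keywords": []},
}


class PipelineConfig:
    """Validated per-stage settings with paper-anchored defaults."""

    def __init__(self, raw: dict | None = None):
        raw = dict(raw or {})
        unknown = set(raw) - set(_DEFAULTS)
        if unknown:
            raise ConfigError(f"unknown config sections: {sorted(unknown)}")
        self.seed = int(raw.pop("seed", _DEFAULTS["seed"]))
        self.sections = {}
        for name, defaults in _DEFAULTS.items():
            if name == "seed":
                continue
            section = dict(defaults)
            override = raw.get(name, {}) or {}
            bad = set(override) - _SECTION_KEYS[name]
            if bad:
                raise ConfigError(f"unknown keys in [{name}]: {sorted(bad)}")
            section.update(override)
            self.sections[name] = section

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config: {exc}") from exc
        return cls(raw)

    def __getitem__(self, name):
        return self.sections[name]

    def simulation_config(self) -> sim_mod.SimulationConfig:
        sec = dict(self.sections["simulate"])
        sec.setdefault("seed", self.seed)
        sec["planted_edges"] = tuple(tuple(e) for e in sec.get("planted_edges", ()))
        try:
            return sim_mod.SimulationConfig(**sec)
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc

    def to_dict(self) -> dict:
        return {"seed": self.seed, **self.sections}


# ---------------------------------------------------------------------------
# manifest and atomic writes


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _manifest_path(outdir: Path) -> Path:
    return outdir / "manifest.json"


def _load_manifest(outdir: Path) -> dict:
    p = _manifest_path(outdir)
    if p.exists():
        return json.loads(p.read_text())
    from . import __version__

    return {"ferronet_version": __version__, "stages": {}}


def _atomic_write_text(path: Path, text: str) -> None:
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def _record_stage(outdir: Path, stage: str, inputs, outputs, seed: int,
                  cfg: "PipelineConfig | None" = None) -> None:
    manifest = _load_manifest(outdir)
    if cfg is not None:
        manifest["config"] = cfg.to_dict()
    manifest["stages"][stage] = {
        "seed": seed,
        "inputs": {str(Path(p).name): _sha256(Path(p)) for p in inputs},
        "outputs": {str(Path(p).name): _sha256(Path(p)) for p in outputs},
    }
    _atomic_write_text(_manifest_path(outdir), json.dumps(manifest, indent=1, sort_keys=True))


def _require(outdir: Path, filename: str, produced_by: str) -> Path:
    p = outdir / filename
    if not p.exists():
        raise DataError(f"missing artifact {filename!r}: run the "
                        f"{produced_by!r} stage first")
    _check_stale(outdir, p)
    return p


def _check_stale(outdir: Path, path: Path) -> None:
    manifest = _load_manifest(outdir)
    for stage, entry in manifest["stages"].items():
        recorded = entry["outputs"].get(path.name)
        if recorded is not None and recorded != _sha256(path):
            log.warning("artifact %s changed since the %s stage wrote it "
                        "(hash mismatch); downstream results may be stale",
                        path.name, stage)


def _write_df(df: pd.DataFrame, path: Path, **kwargs) -> None:
    tmp = path.with_name(path.name + ".tmp")
    df.to_csv(tmp, sep="\t", float_format="%.6g", **kwargs)
    os.replace(tmp, path)


# ---------------------------------------------------------------------------
# stages


def run_simulate(cfg: PipelineConfig, outdir: Path) -> list:
    sim_cfg = cfg.simulation_config()
    expr, truth = sim_mod.simulate_trajectories(sim_cfg)
    features = sim_mod.simulate_motif_matrix(sim_cfg, truth)
    out = []
    p = outdir / "expression.tsv"
    sim_mod.write_expression_tsv(expr, p); out.append(p)
    p = outdir / "truth.json"
    sim_mod.write_truth_json(truth, p); out.append(p)
    p = outdir / "motif_matrix.tsv"
    features.to_tsv(p); out.append(p)
    p = outdir / "motif_tf_map.tsv"
    sim_mod.write_motif_tf_map_tsv(features, p); out.append(p)
    _record_stage(outdir, "simulate", [], out, sim_cfg.seed, cfg)
    return out


def run_de(cfg: PipelineConfig, outdir: Path) -> list:
    expr_path = _require(outdir, "expression.tsv", "simulate")
    expr = sim_mod.read_expression_tsv(expr_path)
    sec = cfg["de"]
    de_zero = de_mod.compute_de(expr, de_mod.ZERO_HOUR,
                                fdr_threshold=sec["fdr_threshold"],
                                lfc_threshold=sec["lfc_threshold"])
    de_per = de_mod.compute_de(expr, de_mod.PER_TIME,
                               fdr_threshold=sec["fdr_threshold"],
                               lfc_threshold=sec["lfc_threshold"])
    sets = de_mod.build_sets(de_zero, de_per)
    truth_path = outdir / "truth.json"
    tf_list = sim_mod.read_truth_json(truth_path).tf_genes if truth_path.exists() else []
    waves = de_mod.assign_waves(de_per, tf_list)

    out = []
    p = outdir / "de_zero_hour.tsv"; de_zero.to_tsv(p); out.append(p)
    p = outdir / "de_per_time.tsv"; de_per.to_tsv(p); out.append(p)
    membership = pd.DataFrame({
        name: pd.Series(1, index=sorted(genes))
        for name, genes in sets.sets.items()
    }).fillna(0).astype(int)
    p = outdir / "set_membership.tsv"
    _write_df(membership, p, index_label="gene"); out.append(p)
    p = outdir / "set_counts.tsv"
    _write_df(sets.pairwise_counts(), p, index=False); out.append(p)
    p = outdir / "per_time_counts.tsv"
    _write_df(sets.per_time_counts().to_frame(), p, index_label="time"); out.append(p)
    p = outdir / "waves.tsv"
    _write_df(waves.to_frame(), p, index_label="tf"); out.append(p)
    all_times = sorted(de_mod.genes_de_at_all_times(de_per))
    p = outdir / "de_at_all_times.tsv"
    _write_df(pd.DataFrame({"gene": all_times}), p, index=False); out.append(p)
    _record_stage(outdir, "de", [expr_path], out, cfg.seed)
    return out


def _normalized_de_trajectories(outdir: Path):
    expr = sim_mod.read_expression_tsv(_require(outdir, "expression.tsv", "simulate"))
    de_per = de_mod.DETable.from_tsv(_require(outdir, "de_per_time.tsv", "de"),
                                     de_mod.PER_TIME)
    de_genes = sorted(de_per.de_genes(times=de_mod.post_zero_times(de_per)))
    traj = expr.mean_trajectories(sim_mod.STRESS).loc[de_genes]
    return traj_mod.max_normalize_frame(traj), de_genes


def run_cluster(cfg: PipelineConfig, outdir: Path) -> list:
    normalized, de_genes = _normalized_de_trajectories(outdir)
    assignment = traj_mod.cluster_trajectories(normalized, k=cfg["cluster"]["k"])
    out = []
    p = outdir / "clusters.tsv"; assignment.to_tsv(p); out.append(p)
    meta = {"method": assignment.method, "k": assignment.n_clusters,
            "n_genes": len(de_genes),
            "normalization": "stress-condition replicate-mean trajectories, "
                             "mean-centred, divided by series max"}
    truth_path = outdir / "truth.json"
    if truth_path.exists():
        from sklearn.metrics import adjusted_rand_score

        truth = sim_mod.read_truth_json(truth_path)
        true_labels = truth.cluster_of.loc[assignment.assignment.index]
        meta["adjusted_rand_vs_truth"] = round(
            float(adjusted_rand_score(true_labels, assignment.assignment)), 6)
    p = outdir / "cluster_meta.json"
    _atomic_write_text(p, json.dumps(meta, indent=1, sort_keys=True)); out.append(p)
    _record_stage(outdir, "cluster", [outdir / "expression.tsv",
                                      outdir / "de_per_time.tsv"], out, cfg.seed)
    return out


def run_network(cfg: PipelineConfig, outdir: Path) -> list:
    normalized, _ = _normalized_de_trajectories(outdir)
    sec = cfg["network"]
    truth_path = outdir / "truth.json"
    if sec["use_true_clusters"] and truth_path.exists():
        truth = sim_mod.read_truth_json(truth_path)
        clusters = truth.cluster_of[truth.cluster_of.index.isin(normalized.index)]
    else:
        clusters = traj_mod.ClusterAssignment.from_tsv(
            _require(outdir, "clusters.tsv", "cluster")).assignment
    genes = None
    if sec["tf_only"] and truth_path.exists():
        genes = sim_mod.read_truth_json(truth_path).tf_genes
    model = net_mod.InterClusterNetwork(
        normalized, clusters, genes=genes,
        n_samples=sec["n_samples"], lags=tuple(sec["lags"]),
        estimator=sec["estimator"], q=sec["q"], bins=sec["bins"],
        min_cluster_size=sec["min_cluster_size"],
    )
    res = model.fit(seed=cfg.seed)
    out = []
    p = outdir / "alpha_table.tsv"; _write_df(res.alpha_table, p, index=False); out.append(p)
    p = outdir / "edges.tsv"; _write_df(res.edges, p, index=False); out.append(p)
    p = outdir / "edges.sif"; res.to_sif(p); out.append(p)
    p = outdir / "network_summary.txt"
    _atomic_write_text(p, res.summary() + "\n"); out.append(p)
    _record_stage(outdir, "network", [outdir / "expression.tsv",
                                      outdir / "de_per_time.tsv"], out, cfg.seed)
    return out


def run_motifs(cfg: PipelineConfig, outdir: Path) -> list:
    features = motifs_mod.MotifFeatureMatrix.from_tsv(
        _require(outdir, "motif_matrix.tsv", "simulate"))
    truth = sim_mod.read_truth_json(_require(outdir, "truth.json", "simulate"))
    de_genes = truth.de_genes
    clusters = truth.cluster_of[truth.cluster_of.index.isin(de_genes)]
    enr = motifs_mod.cluster_motif_enrichment(features, clusters)
    out = []
    p = outdir / "motif_enrichment.tsv"; _write_df(enr, p, index=False); out.append(p)
    kept = motifs_mod.enriched_motifs(enr)
    p = outdir / "enriched_motifs.tsv"
    _write_df(pd.DataFrame({"motif": kept}), p, index=False); out.append(p)
    _record_stage(outdir, "motifs", [outdir / "motif_matrix.tsv",
                                     outdir / "truth.json"], out, cfg.seed)
    return out


def run_regress(cfg: PipelineConfig, outdir: Path) -> list:
    features = motifs_mod.MotifFeatureMatrix.from_tsv(
        _require(outdir, "motif_matrix.tsv", "simulate"))
    _, motif_tf = motifs_mod.read_ame_tsv(_require(outdir, "motif_tf_map.tsv", "simulate"))
    features.motif_tf = motif_tf
    de_per = de_mod.DETable.from_tsv(_require(outdir, "de_per_time.tsv", "de"),
                                     de_mod.PER_TIME)
    sec = cfg["regress"]
    de_genes = de_per.de_genes(times=de_mod.post_zero_times(de_per))
    screen = reg_mod.MotifScreen(
        features, de_per, n_runs=sec["n_runs"], folds=sec["folds"],
        negative_max_abs_lfc=sec["negative_max_abs_lfc"],
        resample_negatives=sec["resample_negatives"],
        lambda_rule=sec["lambda_rule"], de_genes=de_genes,
    )
    res = screen.fit(seed=cfg.seed)
    report = res.map_regulators(motif_tf, de_genes)
    out = []
    p = outdir / "lasso_coefficients.tsv"; _write_df(res.coefs, p, index_label="run"); out.append(p)
    p = outdir / "consistent_motifs.tsv"
    _write_df(pd.DataFrame({"motif": res.consistent_motifs()}), p, index=False); out.append(p)
    p = outdir / "regulator_report.tsv"; _write_df(report, p, index=False); out.append(p)
    p = outdir / "screen_summary.txt"
    _atomic_write_text(p, res.summary() + "\n"); out.append(p)
    _record_stage(outdir, "regress", [outdir / "motif_matrix.tsv",
                                      outdir / "de_per_time.tsv"], out, cfg.seed)
    return out


def run_report(cfg: PipelineConfig, outdir: Path) -> list:
    """Planted-truth recovery report tying all stages together."""
    truth = sim_mod.read_truth_json(_require(outdir, "truth.json", "simulate"))
    de_per = de_mod.DETable.from_tsv(_require(outdir, "de_per_time.tsv", "de"),
                                     de_mod.PER_TIME)
    edges = pd.read_csv(_require(outdir, "edges.tsv", "network"), sep="\t")
    moi = list(pd.read_csv(_require(outdir, "consistent_motifs.tsv", "regress"),
                           sep="\t")["motif"])
    regulators = pd.read_csv(_require(outdir, "regulator_report.tsv", "regress"),
                             sep="\t", keep_default_na=False)

    called = de_per.de_genes(times=de_mod.post_zero_times(de_per))
    planted = truth.de_genes
    recall = len(called & planted) / len(planted) if planted else float("nan")
    precision = len(called & planted) / len(called) if called else float("nan")

    true_pairs = {frozenset((i, j)) for i, j, _ in truth.true_edges}
    accepted_pairs = {frozenset((s, t)) for s, t in zip(edges["source"], edges["target"])}
    planted_dir_hits = sum(
        ((edges["source"] == i) & (edges["target"] == j) & (edges["lag"] == l)).any()
        for i, j, l in truth.true_edges
    )
    fp_pairs = accepted_pairs - true_pairs

    causal_found = sorted(set(moi) & truth.causal_motifs)
    null_consistent = sorted(set(moi) - truth.causal_motifs)
    cand = regulators[regulators["non_de_candidate"].astype(bool)]
    causal_candidates = cand[cand["motif"].isin(truth.causal_motifs)]

    summary = {
        "de_recall": round(recall, 4),
        "de_precision": round(precision, 4),
        "n_planted_de_genes": len(planted),
        "n_called_de_genes": len(called),
        "n_planted_edges": len(truth.true_edges),
        "planted_edges_recovered_directed": int(planted_dir_hits),
        "planted_pairs_recovered": len(true_pairs & accepted_pairs),
        "false_positive_cluster_pairs": len(fp_pairs),
        "n_consistent_motifs": len(moi),
        "causal_motifs_recovered": causal_found,
        "null_motifs_consistent": null_consistent,
        "n_non_de_candidate_regulators": int(cand["tf"].nunique()),
        "n_non_de_candidates_on_causal_motifs": int(causal_candidates["tf"].nunique()),
    }
    out = []
    p = outdir / "recovery_report.json"
    _atomic_write_text(p, json.dumps(summary, indent=1, sort_keys=True)); out.append(p)
    lines = ["Planted-truth recovery report", "=" * 40]
    lines += [f"{k}: {v}" for k, v in summary.items()]
    p = outdir / "recovery_report.txt"
    _atomic_write_text(p, "\n".join(lines) + "\n"); out.append(p)
    _record_stage(outdir, "report", [outdir / "truth.json", outdir / "edges.tsv"],
                  out, cfg.seed)
    return out


STAGES = {
    "simulate": run_simulate,
    "de": run_de,
    "cluster": run_cluster,
    "network": run_network,
    "motifs": run_motifs,
    "regress": run_regress,
    "report": run_report,
}

DEMO_ORDER = ["simulate", "de", "cluster", "network", "motifs", "regress", "report"]


def run_stage(stage: str, cfg: PipelineConfig, outdir) -> list:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if stage == "demo":
        written = []
        for name in DEMO_ORDER:
            written += STAGES[name](cfg, outdir)
        return written
    if stage not in STAGES:
        raise ConfigError(f"unknown stage {stage!r}")
    return STAGES[stage](cfg, outdir)
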