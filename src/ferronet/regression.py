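"""L1-regularized logistic-regression screen for regulatory motifs.

Differentially expressed genes (label 1) are matched by an equal-sized
random sample of quiescent genes (label 0; max over time |log2FC| <
0.251), and an L1-penalized logistic regression on binary promoter-motif
features is fitted with the penalty chosen by k-fold cross-validated
deviance.  Because the LASSO path and the negative sample are stochastic,
the fit is repeated (20 runs by default, each with fresh CV folds and,
optionally, a fresh negative draw) and only motifs whose coefficient x
satisfies e^x > 1 — i.e. raises the odds of differential expression — in
every run are kept as motifs of interest.  TFs known to bind a consistent
motif but not themselves differentially expressed are reported as
candidate post-transcriptional regulators.

Binary features are not standardized, so coefficients stay on the
per-motif log-odds scale that the e^x > 1 rule assumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import KFold

log = logging.getLogger(__name__)

__all__ = [
    "LabeledDesign",
    "build_design",
    "fit_lasso_logistic",
    "consistent_motifs",
    "MotifScreen",
    "MotifScreenResults",
    "map_regulators",
]

NEGATIVE_MAX_ABS_LFC = 0.251
DEFAULT_CS = np.logspace(-3, 2, 21)


@dataclass
class LabeledDesign:
    """Class-balanced gene x motif design with DE labels."""

    X: pd.DataFrame  # rows: genes, columns: motifs, values 0/1
    y: pd.Series  # 1 = differentially expressed, 0 = quiescent

    def __post_init__(self):
        if (self.y == 1).sum() != (self.y == 0).sum():
            raise ValueError("design must be class-balanced")


def eligible_negatives(de_table, threshold: float = NEGATIVE_MAX_ABS_LFC) -> set:
    """Genes whose |log2FC| stays below ``threshold`` at every time point."""
    max_abs = de_table.max_abs_log2fc()
    return set(max_abs.index[max_abs < threshold]) - de_table.de_genes()


def build_design(
    features,
    de_table,
    seed: int = 0,
    negative_max_abs_lfc: float = NEGATIVE_MAX_ABS_LFC,
    de_genes=None,
) -> LabeledDesign:
    """Positives = DE genes; negatives = equal-size random quiescent sample."""
    matrix = features.matrix if hasattr(features, "matrix") else features
    universe = set(matrix.index)
    if de_genes is None:
        de_genes = de_table.de_genes()
    positives = sorted(universe & set(de_genes))
    pool = sorted(universe & eligible_negatives(de_table, negative_max_abs_lfc))
    if len(pool) < len(positives):
        raise ValueError(
            f"only {len(pool)} eligible negatives for {len(positives)} positives "
            f"(shortfall {len(positives) - len(pool)})"
        )
    rng = np.random.default_rng(seed)
    negatives = sorted(rng.choice(pool, size=len(positives), replace=False))
    rows = positives + negatives
    y = pd.Series([1] * len(positives) + [0] * len(negatives), index=rows, name="label")
    return LabeledDesign(X=matrix.loc[rows].astype(float), y=y)


def fit_lasso_logistic(
    design: LabeledDesign,
    folds: int = 10,
    seed: int = 0,
    Cs=None,
    lambda_rule: str = "1se",
    max_iter: int = 2000,
) -> dict:
    """One LASSO logistic fit with CV-chosen penalty.

    Cross-validated mean deviance (log loss) over a grid of inverse
    penalties selects the strongest penalty within one standard error of
    the best (``lambda_rule='1se'``, the default: at the plain minimum the
    LASSO retains weak chance associations that defeat the consistency
    filter) or the minimum itself (``'min'``).  Returns the refit
    coefficient vector on the log-odds scale.
    """
    Cs = DEFAULT_CS if Cs is None else np.asarray(Cs, dtype=float)
    X = design.X.to_numpy(dtype=float)
    y = design.y.to_numpy(dtype=int)
    variable = X.std(axis=0) > 0
    if not variable.any() or variable.sum() < 2:
        raise ValueError("need >= 2 features with variation")
    if not variable.all():
        log.warning("dropping %d constant feature(s)", int((~variable).sum()))
    Xv = X[:, variable]

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(Xv))
    losses = np.empty((len(Cs), folds))
    for ci, C in enumerate(Cs):
        for fi, (tr, te) in enumerate(splits):
            clf = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                                     max_iter=max_iter, random_state=0)
            clf.fit(Xv[tr], y[tr])
            p = clf.predict_proba(Xv[te])[:, 1]
            losses[ci, fi] = log_loss(y[te], p, labels=[0, 1])
    mean = losses.mean(axis=1)
    se = losses.std(axis=1, ddof=1) / np.sqrt(folds)
    best = int(np.argmin(mean))
    if lambda_rule == "min":
        chosen = best
    elif lambda_rule == "1se":
        ok = mean <= mean[best] + se[best]
        chosen = int(np.nonzero(ok)[0][0])  # Cs ascending: smallest C = strongest penalty
    else:
        raise ValueError(f"unknown lambda_rule {lambda_rule!r}")

    clf = LogisticRegression(l1_ratio=1.0, C=Cs[chosen], solver="liblinear",
                             max_iter=max_iter, random_state=0)
    clf.fit(Xv, y)
    coef = pd.Series(0.0, index=design.X.columns)
    coef[design.X.columns[variable]] = clf.coef_.ravel()
    return {
        "coef": coef,
        "intercept": float(clf.intercept_[0]),
        "C": float(Cs[chosen]),
        "cv_mean_deviance": mean,
        "Cs": Cs,
    }


def consistent_motifs(coef_runs: pd.DataFrame, n_runs: int | None = None) -> list:
    """Motifs with e^x > 1 (x > 0) in every run of the ensemble."""
    if n_runs is not None and len(coef_runs) != n_runs:
        raise ValueError(f"expected {n_runs} runs, got {len(coef_runs)}")
    positive_all = (coef_runs > 0).all(axis=0)
    return sorted(coef_runs.columns[positive_all])


class MotifScreen:
    """Model: repeated LASSO logistic screen of motif features against DE.

    Parameters
    ----------
    features : MotifFeatureMatrix or DataFrame
        Binary gene x motif matrix.
    de_table : DETable
        Source of positive labels and of the quiescent-negative rule.
    """

    def __init__(self, features, de_table, n_runs: int = 20, folds: int = 10,
                 negative_max_abs_lfc: float = NEGATIVE_MAX_ABS_LFC,
                 resample_negatives: bool = True, Cs=None,
                 lambda_rule: str = "1se", de_genes=None):
        self.features = features
        self.de_table = de_table
        self.n_runs = n_runs
        self.folds = folds
        self.negative_max_abs_lfc = negative_max_abs_lfc
        self.resample_negatives = resample_negatives
        self.Cs = Cs
        self.lambda_rule = lambda_rule
        self.de_genes = de_genes

    def fit(self, seed: int = 0) -> "MotifScreenResults":
        child = np.random.SeedSequence(seed).generate_state(2 * self.n_runs + 1)
        base_design = build_design(
            self.features, self.de_table, seed=int(child[0] % 2**31),
            negative_max_abs_lfc=self.negative_max_abs_lfc, de_genes=self.de_genes,
        )
        coef_rows, meta = [], []
        for r in range(self.n_runs):
            design_seed = int(child[2 * r + 1] % 2**31)
            cv_seed = int(child[2 * r + 2] % 2**31)
            design = (
                build_design(self.features, self.de_table, seed=design_seed,
                             negative_max_abs_lfc=self.negative_max_abs_lfc,
                             de_genes=self.de_genes)
                if self.resample_negatives else base_design
            )
            fitres = fit_lasso_logistic(design, folds=self.folds, seed=cv_seed,
                                        Cs=self.Cs, lambda_rule=self.lambda_rule)
            coef_rows.append(fitres["coef"])
            meta.append({"run": r + 1, "C": fitres["C"],
                         "intercept": fitres["intercept"],
                         "design_seed": design_seed, "cv_seed": cv_seed})
        coefs = pd.DataFrame(coef_rows, index=pd.RangeIndex(1, self.n_runs + 1, name="run"))
        return MotifScreenResults(model=self, coefs=coefs,
                                  run_info=pd.DataFrame(meta), seed=seed)


@dataclass
class MotifScreenResults:
    """Coefficient ensemble of the repeated LASSO screen."""

    model: MotifScreen
    coefs: pd.DataFrame  # runs x motifs, log-odds scale
    run_info: pd.DataFrame
    seed: int = 0

    @property
    def n_runs(self) -> int:
        return len(self.coefs)

    def selection_counts(self) -> pd.Series:
        """Per motif: number of runs with a positive (odds-raising) coefficient."""
        return (self.coefs > 0).sum(axis=0).rename("runs_positive")

    def consistent_motifs(self) -> list:
        return consistent_motifs(self.coefs)

    def summary(self, top: int = 15) -> str:
        counts = self.selection_counts().sort_values(ascending=False)
        mean_coef = self.coefs.mean(axis=0)
        moi = set(self.consistent_motifs())
        lines = [
            "LASSO logistic motif screen",
            "=" * 52,
            f"runs: {self.n_runs}   folds: {self.model.folds}   "
            f"features: {self.coefs.shape[1]}",
            f"consistent motifs (e^x > 1 in all runs): {len(moi)}",
            "",
            f"{'motif':<12}{'runs e^x>1':>11}{'mean coef':>12}{'consistent':>12}",
        ]
        for m in counts.index[:top]:
            lines.append(
                f"{m:<12}{counts[m]:>11d}{mean_coef[m]:>12.3f}"
                f"{'yes' if m in moi else 'no':>12}"
            )
        return "\n".join(lines)

    def map_regulators(self, motif_tf: dict, de_genes, motif_targets=None,
                       known_genes=None) -> pd.DataFrame:
        return map_regulators(self.consistent_motifs(), motif_tf,
                              self._targets_map(motif_targets), de_genes, known_genes)

    def _targets_map(self, motif_targets):
        if motif_targets is not None:
            return motif_targets
        feats = self.model.features
        if hasattr(feats, "motif_targets"):
            return {m: feats.motif_targets(m) for m in self.consistent_motifs()}
        return {m: list(feats.index[feats[m] == 1]) for m in self.consistent_motifs()}


def map_regulators(motifs, motif_tf: dict, motif_targets: dict, de_genes,
                   known_genes=None) -> pd.DataFrame:
    """Per-motif regulator report.

    A bound TF is a candidate post-transcriptional regulator iff it binds
    a consistent motif and is not itself differentially expressed.
    Motifs missing from the TF map are reported with no TFs, not fatal.
    """
    de_genes = set(de_genes)
    known = set(known_genes or ())
    rows = []
    for m in sorted(motifs):
        tfs = motif_tf.get(m)
        if tfs is None:
            log.warning("motif %s missing from TF map", m)
            tfs = []
        targets = list(motif_targets.get(m, ()))
        for tf in tfs or [None]:
            rows.append({
                "motif": m,
                "tf": tf if tf is not None else "",
                "tf_is_de": bool(tf in de_genes) if tf is not None else False,
                "non_de_candidate": bool(tf is not None and tf not in de_genes),
                "n_targets": len(targets),
                "n_known_gene_targets": len(known & set(targets)),
                "targets": ",".join(targets),
            })
    return pd.DataFrame(rows, columns=["motif", "tf", "tf_is_de", "non_de_candidate",
                                       "n_targets", "n_known_gene_targets", "targets"])
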