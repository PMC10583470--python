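"""Per-time-point differential expression and DEG set logic.

The test is a declared stand-in for a count-based GLM pipeline: Welch's
t-test on log2(x+1)-transformed abundances, per-time-point
Benjamini-Hochberg correction, and the study thresholds FDR <= 0.05 and
|log2FC| >= 0.75.  The schema also accepts externally computed DE tables
(e.g. from edgeR) for real-data runs.

Two reference modes mirror the study's set definitions: contrasts against
the 0-h control only (``zero_hour_control``) or against the matched-time
control (``per_time_control``).  On top of the flags sit the set
comparisons (any-time DEG sets, pairwise overlaps), the
all-time-points intersection, and the assignment of transcription
factors to temporal response waves.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import ExpressionMatrix, CONTROL, STRESS

log = logging.getLogger(__name__)

__all__ = [
    "DETable",
    "GeneSets",
    "compute_de",
    "build_sets",
    "assign_waves",
    "genes_de_at_all_times",
]

ZERO_HOUR = "zero_hour_control"
PER_TIME = "per_time_control"

FDR_THRESHOLD = 0.05
LFC_THRESHOLD = 0.75


@dataclass
class DETable:
    """Tidy per-(gene, time) DE results with threshold flags."""

    table: pd.DataFrame  # columns: gene, time, log2FC, p_value, fdr, de_flag
    reference_mode: str
    fdr_threshold: float = FDR_THRESHOLD
    lfc_threshold: float = LFC_THRESHOLD

    @property
    def genes(self) -> pd.Index:
        return pd.Index(pd.unique(self.table["gene"]))

    @property
    def times(self) -> list:
        return sorted(self.table["time"].unique())

    def flags_wide(self) -> pd.DataFrame:
        return self.table.pivot(index="gene", columns="time", values="de_flag").fillna(
            False
        ).astype(bool)

    def de_genes(self, times=None) -> set:
        """Genes flagged at any of the given time points (default: all)."""
        sub = self.table
        if times is not None:
            sub = sub[sub["time"].isin(times)]
        return set(sub.loc[sub["de_flag"], "gene"])

    def de_genes_at(self, time) -> set:
        return self.de_genes(times=[time])

    def max_abs_log2fc(self) -> pd.Series:
        return self.table.groupby("gene", sort=False)["log2FC"].apply(
            lambda v: float(np.max(np.abs(v)))
        )

    def reflag(self, fdr_threshold=None, lfc_threshold=None) -> "DETable":
        """Recompute flags under different thresholds (same statistics)."""
        fdr_t = self.fdr_threshold if fdr_threshold is None else fdr_threshold
        lfc_t = self.lfc_threshold if lfc_threshold is None else lfc_threshold
        tab = self.table.copy()
        tab["de_flag"] = (tab["fdr"] <= fdr_t) & (tab["log2FC"].abs() >= lfc_t)
        return DETable(tab, self.reference_mode, fdr_t, lfc_t)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path, reference_mode: str,
                 fdr_threshold: float = FDR_THRESHOLD,
                 lfc_threshold: float = LFC_THRESHOLD) -> "DETable":
        tab = pd.read_csv(path, sep="\t")
        required = {"gene", "time", "log2FC"}
        missing = required - set(tab.columns)
        if missing:
            raise ValueError(f"DE table missing columns: {sorted(missing)}")
        if "fdr" not in tab.columns:
            if "p_value" not in tab.columns:
                raise ValueError("DE table needs fdr or p_value")
            tab["fdr"] = np.concatenate([
                multipletests(g["p_value"], method="fdr_bh")[1]
                for _, g in tab.groupby("time", sort=False)
            ])
        if "de_flag" not in tab.columns:
            tab["de_flag"] = (tab["fdr"] <= fdr_threshold) & (
                tab["log2FC"].abs() >= lfc_threshold
            )
        tab["de_flag"] = tab["de_flag"].astype(bool)
        return cls(tab, reference_mode, fdr_threshold, lfc_threshold)


def _welch(a: np.ndarray, b: np.ndarray):
    """Row-wise Welch's t p-values with a zero-variance escape hatch."""
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
    p[degenerate & equal_means] = 1.0
    p[degenerate & ~equal_means] = 0.0
    p[np.isnan(p)] = 1.0
    return p


def compute_de(
    expr: ExpressionMatrix,
    reference_mode: str = PER_TIME,
    fdr_threshold: float = FDR_THRESHOLD,
    lfc_threshold: float = LFC_THRESHOLD,
    stress: str = STRESS,
    control: str = CONTROL,
) -> DETable:
    """Stand-in DE test on an expression matrix.

    log2FC is the difference of replicate means of log2(value+1); p-values
    come from Welch's t-test on the same transform; BH adjustment is
    applied within each time point.
    """
    if reference_mode not in (ZERO_HOUR, PER_TIME):
        raise ValueError(f"unknown reference_mode {reference_mode!r}")
    times = expr.time_points
    rows = []
    for t in times:
        s = expr.samples(stress, t)
        ref_time = times[0] if reference_mode == ZERO_HOUR else t
        c = expr.samples(control, ref_time)
        if s.shape[1] < 2 or c.shape[1] < 2:
            raise ValueError(
                f"time point {t}: need >=2 replicates per group "
                f"(reference at {ref_time} under {reference_mode})"
            )
        ls = np.log2(s.to_numpy() + 1.0)
        lc = np.log2(c.to_numpy() + 1.0)
        lfc = ls.mean(axis=1) - lc.mean(axis=1)
        p = _welch(ls, lc)
        fdr = multipletests(p, method="fdr_bh")[1]
        rows.append(pd.DataFrame({
            "gene": expr.genes, "time": t, "log2FC": lfc, "p_value": p, "fdr": fdr,
        }))
    tab = pd.concat(rows, ignore_index=True)
    tab["de_flag"] = (tab["fdr"] <= fdr_threshold) & (tab["log2FC"].abs() >= lfc_threshold)
    return DETable(tab, reference_mode, fdr_threshold, lfc_threshold)


# ---------------------------------------------------------------------------
# set logic


@dataclass
class GeneSets:
    """Named any-time DEG sets plus per-time sets and their overlaps."""

    sets: dict  # name -> set of gene ids (e.g. "B", "G", optionally "R")
    per_time_sets: dict = field(default_factory=dict)  # time -> set (per-time table)

    def pairwise_counts(self) -> pd.DataFrame:
        """Sizes, intersections and differences for every pair of named sets."""
        rows = []
        for a, b in itertools.combinations(sorted(self.sets), 2):
            sa, sb = self.sets[a], self.sets[b]
            rows.append({
                "set_a": a, "set_b": b, "size_a": len(sa), "size_b": len(sb),
                "intersection": len(sa & sb),
                "only_a": len(sa - sb), "only_b": len(sb - sa),
                "union": len(sa | sb),
            })
        return pd.DataFrame(rows)

    def per_time_counts(self) -> pd.Series:
        return pd.Series({t: len(s) for t, s in sorted(self.per_time_sets.items())},
                         name="n_de_genes")


def post_zero_times(de: DETable) -> list:
    return [t for t in de.times if t != min(de.times)]


def build_sets(
    de_zero_hour: DETable,
    de_per_time: DETable,
    de_zero_hour_organ: DETable | None = None,
) -> GeneSets:
    """Assemble the study's DEG sets from flag tables.

    ``B`` = any-time DEGs of the cell-specific data vs. the 0-h control;
    ``G`` = any-time DEGs vs. matched-time controls (post-0 time points);
    ``R`` (optional) = any-time DEGs of an organ-level dataset vs. its 0-h
    control.  Membership is derived from the flags alone.
    """
    if set(de_zero_hour.genes) != set(de_per_time.genes):
        raise ValueError("DE tables must share a gene universe")
    sets = {
        "B": de_zero_hour.de_genes(),
        "G": de_per_time.de_genes(times=post_zero_times(de_per_time)),
    }
    if de_zero_hour_organ is not None:
        sets["R"] = de_zero_hour_organ.de_genes()
    per_time = {t: de_per_time.de_genes_at(t) for t in post_zero_times(de_per_time)}
    return GeneSets(sets=sets, per_time_sets=per_time)


def assign_waves(de_per_time: DETable, tf_list) -> pd.Series:
    """Group TFs into temporal response waves by first/only flag timing.

    wave1: first flagged before 12 h; wave2: first flagged in [12, 18] h;
    wave3: flagged only after 30 h; anything else (e.g. first flagged at
    24 or 30 h) is left unassigned rather than guessed.
    """
    flags = de_per_time.flags_wide()
    times = [t for t in flags.columns if t != min(de_per_time.times)]
    out = {}
    for tf in tf_list:
        if tf not in flags.index:
            log.warning("TF %s absent from DE table; skipped", tf)
            continue
        hit_times = [t for t in times if flags.at[tf, t]]
        if not hit_times:
            out[tf] = "unassigned"
        elif hit_times[0] < 12:
            out[tf] = "wave1"
        elif 12 <= hit_times[0] <= 18:
            out[tf] = "wave2"
        elif all(t > 30 for t in hit_times):
            out[tf] = "wave3"
        else:
            out[tf] = "unassigned"
    return pd.Series(out, name="wave", dtype=object)


def genes_de_at_all_times(de_per_time: DETable) -> set:
    """Genes flagged at every post-0 time point."""
    times = post_zero_times(de_per_time)
    sets = [de_per_time.de_genes_at(t) for t in times]
    if not sets:
        return set()
    return set.intersection(*sets)
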