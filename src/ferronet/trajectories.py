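"""Trajectory max-normalization and pluggable co-expression clustering.

Before clustering, each gene's time course is centred by its mean and
scaled by its maximum abundance:

    N_t = (R_t - mean_k R_k) / max_k R_k

so a constant trajectory maps to zero and the output is invariant to
positive rescaling of the input.  Cluster assignment is pluggable: either
ingest an external assignment file (e.g. from a Dirichlet-process GP
mixture run) or use the built-in default, agglomerative clustering with
correlation distance and average linkage at a user-chosen K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering

__all__ = [
    "ClusterAssignment",
    "max_normalize",
    "max_normalize_frame",
    "cluster_trajectories",
]


@dataclass
class ClusterAssignment:
    """gene -> cluster id (contiguous 1..K) plus the method that made it."""

    assignment: pd.Series
    method: str  # "external" | "default"

    def __post_init__(self):
        self.assignment = self.assignment.rename("cluster").rename_axis("gene")

    @property
    def n_clusters(self) -> int:
        return int(self.assignment.nunique())

    def members(self, cluster_id) -> list:
        a = self.assignment
        return list(a.index[a == cluster_id])

    def to_tsv(self, path) -> None:
        self.assignment.rename("cluster").to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path, method: str = "external") -> "ClusterAssignment":
        df = pd.read_csv(path, sep="\t")
        if "gene" not in df.columns or "cluster" not in df.columns:
            raise ValueError("cluster file needs 'gene' and 'cluster' columns")
        # DPGP-style files carry an ignored assignment-probability column
        s = df.set_index("gene")["cluster"].astype(int)
        return cls(assignment=s, method=method)


def max_normalize(trajectory) -> np.ndarray:
    """Normalize one per-time abundance vector: subtract mean, divide by max."""
    r = np.asarray(trajectory, dtype=float)
    if r.ndim != 1 or len(r) < 2:
        raise ValueError("trajectory must be 1-D with at least 2 time samples")
    if not np.all(np.isfinite(r)):
        raise ValueError("trajectory contains non-finite values")
    m = r.max()
    if m <= 0:
        raise ValueError("degenerate trajectory: maximum must be positive")
    return (r - r.mean()) / m


def max_normalize_frame(traj: pd.DataFrame) -> pd.DataFrame:
    """Row-wise :func:`max_normalize` over a genes x times matrix."""
    arr = traj.to_numpy(dtype=float)
    maxes = arr.max(axis=1)
    if np.any(maxes <= 0):
        bad = list(traj.index[maxes <= 0][:5])
        raise ValueError(f"degenerate trajectory (non-positive max), e.g. {bad}")
    out = (arr - arr.mean(axis=1, keepdims=True)) / maxes[:, None]
    return pd.DataFrame(out, index=traj.index, columns=traj.columns)


def _correlation_distance(arr: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(arr)
    corr = np.nan_to_num(corr, nan=0.0)  # zero-variance rows: no correlation
    np.fill_diagonal(corr, 1.0)
    return 1.0 - corr


def _relabel_contiguous(labels: np.ndarray) -> np.ndarray:
    """Map labels to 1..K in order of first appearance (deterministic)."""
    mapping: dict = {}
    out = np.empty(len(labels), dtype=int)
    for k, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[k] = mapping[lab]
    return out


def cluster_trajectories(
    normalized: pd.DataFrame,
    k: int | None = None,
    external=None,
) -> ClusterAssignment:
    """Assign co-expression clusters to normalized trajectories.

    ``external`` may be a path to a (gene, cluster) TSV, a Series, or a
    :class:`ClusterAssignment`; it is validated against the trajectory
    gene universe and passed through.  Otherwise the built-in default is
    run at the user-supplied ``k`` (no silent default, the right K is
    data-specific).
    """
    if external is not None:
        if isinstance(external, ClusterAssignment):
            assign = external.assignment
        elif isinstance(external, pd.Series):
            assign = external.astype(int)
        else:
            assign = ClusterAssignment.from_tsv(external).assignment
        unknown = sorted(set(assign.index) - set(normalized.index))
        if unknown:
            raise ValueError(f"external assignment references unknown genes: {unknown}")
        labels = _relabel_contiguous(assign.to_numpy())
        return ClusterAssignment(
            assignment=pd.Series(labels, index=assign.index, name="cluster"),
            method="external",
        )
    if k is None:
        raise ValueError("k is required for the built-in clusterer")
    lengths = {len(row.dropna()) for _, row in normalized.iterrows()}
    if len(lengths) > 1:
        raise ValueError("all trajectories must have the same length")
    if k == 1:
        labels = np.ones(len(normalized), dtype=int)
    else:
        dist = _correlation_distance(normalized.to_numpy(dtype=float))
        model = AgglomerativeClustering(
            n_clusters=k, metric="precomputed", linkage="average"
        )
        labels = _relabel_contiguous(model.fit_predict(dist))
    return ClusterAssignment(
        assignment=pd.Series(labels, index=normalized.index, name="cluster"),
        method="default",
    )
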