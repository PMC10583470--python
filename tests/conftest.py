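import numpy as np
import pandas as pd
import pytest

from ferronet import (
    SimulationConfig,
    simulate_trajectories,
    simulate_motif_matrix,
    compute_de,
)
from ferronet.simulate import ExpressionMatrix


@pytest.fixture(scope="session")
def small_sim():
    """Small planted scenario shared across tests (read-only)."""
    cfg = SimulationConfig(
        n_genes=300, n_tfs=60, n_clusters=5, planted_edges=((1, 2, 1),), seed=42,
        n_motifs=12, motif_effects={"M001": 2.0},
    )
    expr, truth = simulate_trajectories(cfg)
    features = simulate_motif_matrix(cfg, truth)
    return cfg, expr, truth, features


@pytest.fixture(scope="session")
def small_de(small_sim):
    _, expr, _, _ = small_sim
    return compute_de(expr, "per_time_control")


def make_expression(values: dict, genes, times, n_reps) -> ExpressionMatrix:
    """Build an ExpressionMatrix from {(condition, time): per-gene replicate rows}."""
    cols, blocks = [], []
    for (cond, t), mat in values.items():
        mat = np.asarray(mat, dtype=float)
        for r in range(n_reps):
            cols.append((cond, t, r + 1))
            blocks.append(mat[:, r])
    data = pd.DataFrame(
        np.column_stack(blocks), index=genes,
        columns=pd.MultiIndex.from_tuples(cols, names=["condition", "time", "replicate"]),
    )
    return ExpressionMatrix(data)
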