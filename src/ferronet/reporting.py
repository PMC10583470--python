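"""Functional enrichment of putative target sets and keyword reports.

A one-sided hypergeometric test per annotation term with BH correction
inside each target set stands in for DAG-aware GO machinery; the keyword
filter mirrors the practice of narrowing significant terms to those
naming a process of interest (e.g. "iron", "root", "epidermis").
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["enrich_targets", "keyword_filter"]

ENRICH_COLUMNS = ["term_id", "term_name", "hits", "term_size", "target_size",
                  "universe_size", "fold_enrichment", "p_value", "fdr", "significant"]


def enrich_targets(targets, annotation: pd.DataFrame, universe,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric term enrichment of a target set against a universe.

    ``annotation`` is a tidy (term_id, term_name, gene) table.  Terms
    annotating zero universe genes are skipped; BH correction is applied
    across the terms tested for this target set.
    """
    universe = set(universe)
    targets = set(targets) & universe
    if not universe >= targets:
        raise ValueError("universe must contain all targets")
    out = pd.DataFrame(columns=ENRICH_COLUMNS)
    if not targets:
        return out
    M, N = len(universe), len(targets)
    rows = []
    for (tid, tname), grp in annotation.groupby(["term_id", "term_name"], sort=True):
        term_genes = set(grp["gene"]) & universe
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & targets)
        p = float(hypergeom.sf(k - 1, M, K, N))
        expected = K * N / M
        rows.append({"term_id": tid, "term_name": tname, "hits": k, "term_size": K,
                     "target_size": N, "universe_size": M,
                     "fold_enrichment": (k / expected) if expected > 0 else 0.0,
                     "p_value": p})
    if not rows:
        return out
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["significant"] = out["fdr"] < alpha
    return out[ENRICH_COLUMNS]


def keyword_filter(enrichment: pd.DataFrame, keywords) -> pd.DataFrame:
    """Keep terms whose name contains any keyword (case-insensitive).

    An empty keyword list passes everything through unchanged.
    """
    keywords = [k.lower() for k in keywords]
    if not keywords:
        return enrichment.copy()
    names = enrichment["term_name"].str.lower()
    mask = names.apply(lambda s: any(k in s for k in keywords))
    return enrichment[mask].reset_index(drop=True)
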