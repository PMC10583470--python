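"""Promoter extraction and binary cis-regulatory motif features.

Promoters are the 1000 bp upstream of each gene's transcription start
site, taken strand-aware from a genome FASTA plus GFF3 annotation and
truncated at contig boundaries.  Motif presence/absence over promoters
yields the binary gene x motif feature matrix consumed by the regression
screen; alternatively an AME-style motif-to-gene map is ingested directly.
A per-cluster hypergeometric enrichment scan (BH-corrected) stands in for
an external motif-enrichment tool in self-contained runs.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "Promoter",
    "MotifFeatureMatrix",
    "extract_promoters",
    "write_promoters_fasta",
    "build_feature_matrix",
    "cluster_motif_enrichment",
    "read_ame_tsv",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]",
    "B": "[CGT]", "D": "[AGT]", "H": "[ACT]", "V": "[ACG]",
    "N": "[ACGT]",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Promoter:
    """1-based inclusive genomic interval plus its (strand-oriented) sequence."""

    gene: str
    contig: str
    start: int  # 1-based inclusive; start > end encodes a zero-length promoter
    end: int
    strand: str
    sequence: str


@dataclass
class MotifFeatureMatrix:
    """Binary gene x motif presence matrix with motif-to-TF bindings."""

    matrix: pd.DataFrame  # genes x motifs, 0/1
    motif_tf: dict = field(default_factory=dict)  # motif id -> list of TF ids

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    @property
    def motifs(self) -> pd.Index:
        return self.matrix.columns

    def motif_targets(self, motif: str) -> list:
        """Genes whose promoter carries the motif."""
        col = self.matrix[motif]
        return list(col.index[col == 1])

    def uninformative_motifs(self) -> list:
        """All-0 or all-1 columns: useless as classification features."""
        col_sums = self.matrix.sum(axis=0)
        n = len(self.matrix)
        return list(self.matrix.columns[(col_sums == 0) | (col_sums == n)])

    def to_tsv(self, path) -> None:
        self.matrix.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path, motif_tf: dict | None = None) -> "MotifFeatureMatrix":
        mat = pd.read_csv(path, sep="\t", index_col="gene").astype(np.int8)
        return cls(matrix=mat, motif_tf=motif_tf or {})


# ---------------------------------------------------------------------------
# promoter extraction


def _gene_records(gff3_path):
    import gffutils

    db = gffutils.create_db(
        str(gff3_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    by_gene: dict = {}
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        by_gene.setdefault(gid, []).append(feat)
    return by_gene


def extract_promoters(gff3_path, fasta_path, length: int = 1000) -> dict:
    """Extract upstream promoters for every gene in a GFF3.

    Plus strand: the ``length`` bases ending just before the TSS
    (``[TSS-length, TSS-1]`` 1-based).  Minus strand: the ``length`` bases
    just after the annotated end, reverse-complemented.  Intervals are
    truncated at contig boundaries; a TSS flush against the edge yields a
    zero-length promoter with a warning.  With multiple records per gene
    id the 5'-most TSS on the gene's strand is used.
    """
    from pyfaidx import Fasta

    fasta = Fasta(str(fasta_path), sequence_always_upper=True)
    promoters: dict = {}
    for gid, feats in _gene_records(gff3_path).items():
        strand = feats[0].strand
        contig = feats[0].seqid
        if contig not in fasta:
            raise ValueError(f"gene {gid}: contig {contig!r} not in FASTA")
        contig_len = len(fasta[contig])
        if strand == "-":
            tss = max(f.end for f in feats)
            start, end = tss + 1, min(contig_len, tss + length)
        else:
            tss = min(f.start for f in feats)
            start, end = max(1, tss - length), tss - 1
        if end < start:
            log.warning("gene %s: TSS at contig edge, zero-length promoter", gid)
            seq = ""
            start, end = tss, tss - 1  # canonical empty interval
        else:
            seq = str(fasta.get_seq(contig, start, end, rc=(strand == "-")))
        promoters[gid] = Promoter(gid, contig, start, end, strand, seq)
    return promoters


def write_promoters_fasta(promoters: dict, path) -> None:
    with open(path, "w") as fh:
        for p in promoters.values():
            fh.write(f">{p.gene} {p.contig}:{p.start}-{p.end}({p.strand})\n")
            for k in range(0, len(p.sequence), 70):
                fh.write(p.sequence[k:k + 70] + "\n")


# ---------------------------------------------------------------------------
# feature matrix


def _motif_regex(consensus: str) -> re.Pattern:
    bad = set(consensus.upper()) - set(IUPAC)
    if bad:
        raise ValueError(f"motif {consensus!r}: illegal characters {sorted(bad)}")
    return re.compile("".join(IUPAC[b] for b in consensus.upper()))


def build_feature_matrix(
    source,
    motifs,
    genes=None,
    both_strands: bool = True,
    motif_tf: dict | None = None,
) -> MotifFeatureMatrix:
    """Build the binary presence matrix.

    ``source`` is either a promoter dict (gene -> :class:`Promoter` or raw
    sequence string), in which case ``motifs`` maps motif id to an IUPAC
    consensus that is scanned on both strands by default; or a
    motif -> iterable-of-genes map (AME-style), in which case ``motifs``
    lists the motif ids to keep and ``genes`` fixes the gene universe.
    """
    if source and all(
        not isinstance(v, (Promoter, str)) for v in source.values()
    ):
        # pass-through: motif -> gene list
        if genes is None:
            raise ValueError("gene universe required for a motif->gene map")
        genes = list(genes)
        motif_ids = list(motifs)
        mat = pd.DataFrame(0, index=genes, columns=motif_ids, dtype=np.int8)
        gene_set = set(genes)
        for m in motif_ids:
            hits = set(source.get(m, ())) & gene_set
            mat.loc[sorted(hits), m] = 1
        return MotifFeatureMatrix(matrix=mat, motif_tf=motif_tf or {})

    seqs = {
        g: (p.sequence if isinstance(p, Promoter) else str(p))
        for g, p in source.items()
    }
    motif_ids = list(motifs)
    patterns = {m: _motif_regex(motifs[m]) for m in motif_ids}
    mat = pd.DataFrame(0, index=list(seqs), columns=motif_ids, dtype=np.int8)
    for g, seq in seqs.items():
        seq_u = seq.upper()
        rc = reverse_complement(seq_u) if both_strands else None
        for m, pat in patterns.items():
            if pat.search(seq_u) or (rc is not None and pat.search(rc)):
                mat.at[g, m] = 1
    return MotifFeatureMatrix(matrix=mat, motif_tf=motif_tf or {})


def read_ame_tsv(path):
    """Read an AME-style map (motif_id, motif_alt_id, tf_name, gene_list).

    Returns ``(motif -> sorted gene list, motif -> sorted TF list)``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    motif_genes: dict = {}
    motif_tf: dict = {}
    for _, row in df.iterrows():
        m = row["motif_id"]
        motif_tf.setdefault(m, set()).add(row["tf_name"])
        gl = [g for g in str(row["gene_list"]).split(",") if g]
        motif_genes.setdefault(m, set()).update(gl)
    return (
        {m: sorted(v) for m, v in motif_genes.items()},
        {m: sorted(v) for m, v in motif_tf.items()},
    )


# ---------------------------------------------------------------------------
# enrichment stand-in


def cluster_motif_enrichment(
    features: MotifFeatureMatrix,
    clusters: pd.Series,
    background=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric motif enrichment per (motif, cluster).

    For each cluster and motif, tests whether the motif is present in the
    cluster's promoters more often than expected from the background gene
    universe (default: all genes in the matrix); BH correction across all
    tests.  Returns a tidy table with an ``enriched`` flag at FDR ``alpha``.
    """
    if background is None:
        background = list(features.genes)
    background = [g for g in background if g in set(features.genes)]
    M = len(background)
    present = features.matrix.loc[background]
    rows = []
    gene_set = set(features.genes)
    bg_set = set(background)
    for cl in sorted(clusters.unique()):
        cluster_genes = [g for g in clusters.index[clusters == cl] if g in gene_set]
        if len(cluster_genes) > M:
            raise ValueError(f"cluster {cl} larger than background universe")
        members = [g for g in cluster_genes if g in bg_set]
        Ncl = len(members)
        if Ncl == 0:
            continue
        sub = features.matrix.loc[members]
        for m in features.motifs:
            K = int(present[m].sum())
            k = int(sub[m].sum())
            p = float(hypergeom.sf(k - 1, M, K, Ncl))
            rows.append({"cluster": cl, "motif": m, "hits": k, "cluster_size": Ncl,
                         "background_hits": K, "background_size": M, "p_value": p})
    out = pd.DataFrame(rows)
    if out.empty:
        out["fdr"] = []
        out["enriched"] = []
        return out
    out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["enriched"] = out["fdr"] <= alpha
    return out


def enriched_motifs(enrichment: pd.DataFrame) -> list:
    """Motifs enriched in at least one cluster (feature-selection rule)."""
    if enrichment.empty:
        return []
    return sorted(enrichment.loc[enrichment["enriched"], "motif"].unique())


def clusters_without_motifs(enrichment: pd.DataFrame) -> list:
    """Clusters with no enriched motif, dropped from downstream feature work."""
    if enrichment.empty:
        return []
    keep = enrichment.groupby("cluster")["enriched"].any()
    return sorted(keep.index[~keep])
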