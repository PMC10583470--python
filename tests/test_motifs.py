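"""Promoter extraction, motif scanning, and the enrichment stand-in."""

import numpy as np
import pandas as pd
import pytest

from ferronet import build_feature_matrix, cluster_motif_enrichment, extract_promoters
from ferronet.motifs import (
    MotifFeatureMatrix,
    read_ame_tsv,
    reverse_complement,
    write_promoters_fasta,
)
from ferronet.simulate import write_motif_tf_map_tsv


CONTIG_LEN = 5000


@pytest.fixture(scope="module")
def toy_genome(tmp_path_factory):
    """5-kb contig with genes exercising strand, truncation, and edge cases."""
    root = tmp_path_factory.mktemp("genome")
    rng = np.random.default_rng(13)
    seq = "".join(rng.choice(list("ACGT"), size=CONTIG_LEN))
    fasta = root / "genome.fa"
    fasta.write_text(">chr1\n" + "\n".join(seq[k:k + 80] for k in range(0, CONTIG_LEN, 80)) + "\n")
    genes = [
        # gid, start, end, strand
        ("plus_mid", 2000, 2500, "+"),
        ("minus_mid", 1200, 1800, "-"),
        ("plus_trunc", 500, 900, "+"),
        ("plus_edge", 1, 300, "+"),
        ("minus_edge", 4700, CONTIG_LEN, "-"),
    ]
    gff_lines = ["##gff-version 3"]
    for gid, s, e, strand in genes:
        gff_lines.append(
            f"chr1\ttest\tgene\t{s}\t{e}\t.\t{strand}\t.\tID={gid}"
        )
    gff = root / "genes.gff3"
    gff.write_text("\n".join(gff_lines) + "\n")
    return seq, fasta, gff


def test_plus_strand_promoter_coordinates(toy_genome):
    seq, fasta, gff = toy_genome
    proms = extract_promoters(gff, fasta)
    p = proms["plus_mid"]
    # TSS at 2000: 1-based positions 1000..1999
    assert (p.start, p.end) == (1000, 1999)
    assert p.sequence == seq[999:1999]
    assert len(p.sequence) == 1000


def test_minus_strand_promoter_reverse_complemented(toy_genome):
    seq, fasta, gff = toy_genome
    p = extract_promoters(gff, fasta)["minus_mid"]
    # TSS at 1800 on minus strand: genomic 1801..2800, reverse-complemented
    assert (p.start, p.end) == (1801, 2800)
    assert p.sequence == reverse_complement(seq[1800:2800])


def test_truncation_at_contig_start(toy_genome):
    seq, fasta, gff = toy_genome
    p = extract_promoters(gff, fasta)["plus_trunc"]
    # TSS at 500: only 499 bases upstream exist
    assert (p.start, p.end) == (1, 499)
    assert len(p.sequence) == 499
    assert p.sequence == seq[0:499]


def test_zero_length_promoter_warned(toy_genome, caplog):
    import logging

    _, fasta, gff = toy_genome
    with caplog.at_level(logging.WARNING):
        proms = extract_promoters(gff, fasta)
    assert proms["plus_edge"].sequence == ""
    assert any("plus_edge" in r.message for r in caplog.records)


def test_minus_strand_truncation_at_contig_end(toy_genome):
    seq, fasta, gff = toy_genome
    p = extract_promoters(gff, fasta)["minus_edge"]
    assert p.sequence == ""  # TSS flush with the contig end


def test_promoter_fasta_roundtrip(toy_genome, tmp_path):
    from Bio import SeqIO

    _, fasta, gff = toy_genome
    proms = extract_promoters(gff, fasta)
    out = tmp_path / "promoters.fa"
    write_promoters_fasta({g: p for g, p in proms.items() if p.sequence}, out)
    back = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(out), "fasta")}
    for gid, seq in back.items():
        assert seq == proms[gid].sequence


def test_strand_flip_mirror_property(toy_genome, tmp_path):
    """Reverse-complementing the genome and flipping strands preserves promoters."""
    seq, fasta, gff = toy_genome
    rc = reverse_complement(seq)
    fasta2 = tmp_path / "rc.fa"
    fasta2.write_text(">chr1\n" + rc + "\n")
    flip = {"+": "-", "-": "+"}
    lines = ["##gff-version 3"]
    for gid, s, e, strand in [("plus_mid", 2000, 2500, "+"), ("minus_mid", 1200, 1800, "-")]:
        s2, e2 = CONTIG_LEN + 1 - e, CONTIG_LEN + 1 - s
        lines.append(f"chr1\ttest\tgene\t{s2}\t{e2}\t.\t{flip[strand]}\t.\tID={gid}")
    gff2 = tmp_path / "rc.gff3"
    gff2.write_text("\n".join(lines) + "\n")
    orig = extract_promoters(gff, fasta)
    mirrored = extract_promoters(gff2, fasta2)
    for gid in ("plus_mid", "minus_mid"):
        assert mirrored[gid].sequence == orig[gid].sequence


def test_unknown_contig_rejected(toy_genome, tmp_path):
    _, fasta, _ = toy_genome
    gff = tmp_path / "bad.gff3"
    gff.write_text("##gff-version 3\nchrX\ttest\tgene\t100\t200\t.\t+\t.\tID=g1\n")
    with pytest.raises(ValueError, match="chrX"):
        extract_promoters(gff, fasta)


# ---------------------------------------------------------------------------
# motif scanning


def test_literal_motif_found():
    mat = build_feature_matrix({"g1": "CCTATACC"}, {"m": "TATA"})
    assert mat.matrix.at["g1", "m"] == 1


def test_absent_motif_scores_zero():
    mat = build_feature_matrix({"g1": "CCCCCCCC"}, {"m": "TATA"})
    assert mat.matrix.at["g1", "m"] == 0


def test_iupac_ebox_match():
    mat = build_feature_matrix({"g1": "GCACGTGC"}, {"ebox": "CANNTG"})
    assert mat.matrix.at["g1", "ebox"] == 1


def test_reverse_strand_hit_counts():
    # motif AAGGG only present as reverse complement (CCCTT) in the promoter
    mat = build_feature_matrix({"g1": "TTCCCTTTT"}, {"m": "AAGGG"})
    assert mat.matrix.at["g1", "m"] == 1
    fwd_only = build_feature_matrix({"g1": "TTCCCTTTT"}, {"m": "AAGGG"},
                                    both_strands=False)
    assert fwd_only.matrix.at["g1", "m"] == 0


def test_illegal_motif_alphabet_rejected():
    with pytest.raises(ValueError, match="illegal"):
        build_feature_matrix({"g1": "ACGT"}, {"m": "AXGT"})


def test_passthrough_motif_gene_map():
    mat = build_feature_matrix(
        {"m1": ["g1", "g3"], "m2": ["g2"]}, ["m1", "m2"], genes=["g1", "g2", "g3"]
    )
    assert mat.matrix.loc["g1", "m1"] == 1
    assert mat.matrix.loc["g2", "m1"] == 0
    assert mat.motif_targets("m2") == ["g2"]


def test_uninformative_columns_flagged():
    mat = MotifFeatureMatrix(pd.DataFrame(
        {"all0": [0, 0, 0], "all1": [1, 1, 1], "mixed": [0, 1, 0]},
        index=["g1", "g2", "g3"],
    ))
    assert set(mat.uninformative_motifs()) == {"all0", "all1"}


def test_ame_map_roundtrip(tmp_path, small_sim):
    _, _, _, features = small_sim
    path = tmp_path / "ame.tsv"
    write_motif_tf_map_tsv(features, path)
    motif_genes, motif_tf = read_ame_tsv(path)
    m = features.motifs[0]
    assert motif_tf[m] == sorted(features.motif_tf[m])
    assert motif_genes[m] == sorted(features.motif_targets(m))


# ---------------------------------------------------------------------------
# enrichment stand-in


def _enrichment_fixture():
    genes = [f"g{k}" for k in range(100)]
    mat = pd.DataFrame(0, index=genes, columns=["hot", "flat"], dtype=np.int8)
    cluster_genes = genes[:10]
    mat.loc[cluster_genes, "hot"] = 1  # 10/10 inside the cluster
    mat.loc[genes[50:55], "flat"] = 1  # background-rate motif
    clusters = pd.Series(1, index=cluster_genes)
    return MotifFeatureMatrix(mat), clusters


def test_strong_enrichment_detected():
    features, clusters = _enrichment_fixture()
    enr = cluster_motif_enrichment(features, clusters)
    hot = enr[enr["motif"] == "hot"].iloc[0]
    assert hot["p_value"] < 1e-6
    assert bool(hot["enriched"])
    flat = enr[enr["motif"] == "flat"].iloc[0]
    assert not bool(flat["enriched"])


def test_background_smaller_than_cluster_rejected():
    features, clusters = _enrichment_fixture()
    with pytest.raises(ValueError, match="larger than"):
        cluster_motif_enrichment(features, clusters, background=list(features.genes[:5]))


def test_hypergeometric_matches_permutation_null():
    """Exact tail probability agrees with a label-shuffle Monte Carlo."""
    rng = np.random.default_rng(21)
    genes = [f"g{k}" for k in range(200)]
    presence = np.zeros(200, dtype=int)
    presence[rng.choice(200, 60, replace=False)] = 1
    mat = MotifFeatureMatrix(pd.DataFrame({"m": presence}, index=genes))
    members = [g for g in genes[:30]]
    clusters = pd.Series(1, index=members)
    enr = cluster_motif_enrichment(mat, clusters)
    p_exact = enr.iloc[0]["p_value"]
    k_obs = enr.iloc[0]["hits"]
    draws = np.array([
        presence[rng.choice(200, 30, replace=False)].sum() for _ in range(10000)
    ])
    p_mc = (draws >= k_obs).mean()
    assert p_exact == pytest.approx(p_mc, abs=3 * np.sqrt(p_mc * (1 - p_mc) / 10000) + 1e-3)
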