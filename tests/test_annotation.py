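"""Annotation DB construction, motif classification, and gene overlap."""

import re

import numpy as np
import pytest
from Bio import SeqIO

from splicescape.annotation import (
    GeneInterval,
    JunctionAnnotationDB,
    build_annotation_db,
    classify_motif,
    is_annotated,
    overlaps_gene,
    revcomp,
)
from splicescape.junctions import (
    AT_AC,
    GC_AG,
    GT_AG,
    Junction,
    JunctionKey,
    MINUS,
    NON_CANONICAL,
    PLUS,
    UNDEFINED,
)
from splicescape.synthetic import write_fasta


def _gtf_exon(chrom, start, end, strand, gid, tid, num):
    return (
        f"{chrom}\ttest\texon\t{start}\t{end}\t.\t{strand}\t.\t"
        f'gene_id "{gid}"; transcript_id "{tid}"; exon_number "{num}";\n'
    )


def test_exon_walk_yields_one_junction_per_consecutive_exon_pair(tmp_path):
    gtf = tmp_path / "t.gtf"
    gtf.write_text(
        _gtf_exon("chr1", 101, 200, "+", "G1", "T1", 1)
        + _gtf_exon("chr1", 301, 400, "+", "G1", "T1", 2)
        + _gtf_exon("chr1", 501, 600, "+", "G1", "T1", 3)
        + _gtf_exon("chr1", 701, 800, "+", "G2", "T2", 1)  # single exon
    )
    db = build_annotation_db(gtf)
    assert set(db.annotated) == {
        JunctionKey("chr1", 201, 300),
        JunctionKey("chr1", 401, 500),
    }
    assert db.genes["G1"].start == 101 and db.genes["G1"].end == 600


def test_overlapping_exons_skip_transcript_with_warning(tmp_path):
    gtf = tmp_path / "t.gtf"
    gtf.write_text(
        _gtf_exon("chr1", 101, 250, "+", "G1", "T1", 1)
        + _gtf_exon("chr1", 200, 400, "+", "G1", "T1", 2)
        + _gtf_exon("chr1", 501, 600, "+", "G2", "T2", 1)
        + _gtf_exon("chr1", 701, 800, "+", "G2", "T2", 2)
    )
    with pytest.warns(UserWarning, match="T1"):
        db = build_annotation_db(gtf)
    assert set(db.annotated) == {JunctionKey("chr1", 601, 700)}


def test_gtf_without_exons_is_an_error(tmp_path):
    gtf = tmp_path / "t.gtf"
    gtf.write_text('chr1\ttest\tgene\t1\t100\t.\t+\t.\tgene_id "G1";\n')
    with pytest.raises(ValueError, match="no exon features"):
        build_annotation_db(gtf)


def test_annotation_db_matches_exon_pair_oracle(tmp_path):
    """DB keys equal an independently scripted walk over a random GTF

    (20 genes x 3 transcripts with 2-5 exons each, seed 7)."""
    rng = np.random.default_rng(7)
    lines = []
    for g in range(20):
        gid = f"G{g:03d}"
        chrom = f"chr{1 + g % 3}"
        base = 1_000 + g * 50_000
        for t in range(3):
            tid = f"{gid}.T{t}"
            pos = base + int(rng.integers(0, 500))
            n_exons = int(rng.integers(2, 6))
            for num in range(n_exons):
                length = int(rng.integers(50, 300))
                lines.append(_gtf_exon(chrom, pos, pos + length, "+", gid, tid, num + 1))
                pos += length + int(rng.integers(60, 400))
    gtf = tmp_path / "rand.gtf"
    gtf.write_text("".join(lines))

    # oracle: regex-parse the text, group by transcript, walk exon pairs
    exons: dict[str, list[tuple[str, int, int]]] = {}
    for line in lines:
        f = line.split("\t")
        tid = re.search(r'transcript_id "([^"]+)"', f[8]).group(1)
        exons.setdefault(tid, []).append((f[0], int(f[3]), int(f[4])))
    expected = set()
    for tid, ex in exons.items():
        ex.sort(key=lambda e: e[1])
        for (chrom, _, up_end), (_, down_start, _) in zip(ex, ex[1:]):
            expected.add(JunctionKey(chrom, up_end + 1, down_start - 1))

    db = build_annotation_db(gtf)
    assert set(db.annotated) == expected


@pytest.fixture()
def toy_genome(tmp_path):
    #                 1-based:  123456789...
    # chr1: introns planted at fixed offsets below
    seq = "CCCCC" + "GT" + "AAAAAA" + "AG" + "CCCCC"  # GT..AG at 6..15
    seq += "CT" + "TTTTTT" + "AC"  # CT..AC (minus GT/AG) at 21..30
    seq += "GC" + "GGGGGG" + "AG"  # GC..AG at 31..40
    seq += "AT" + "CCCCCC" + "AC"  # AT..AC at 41..50
    seq += "AA" + "GGGGGG" + "TT"  # non-canonical at 51..60
    seq += "C" * 20
    path = tmp_path / "toy.fa"
    write_fasta({"chr1": seq}, path)
    return path


@pytest.mark.parametrize(
    "start, end, motif, strand",
    [
        (6, 15, GT_AG, PLUS),
        (21, 30, GT_AG, MINUS),
        (31, 40, GC_AG, PLUS),
        (41, 50, AT_AC, PLUS),
        (51, 60, NON_CANONICAL, UNDEFINED),
    ],
)
def test_classify_motif_cases(toy_genome, start, end, motif, strand):
    call = classify_motif(Junction("chr1", start, end), toy_genome)
    assert (call.motif, call.resolved_strand) == (motif, strand)


def test_classify_non_canonical_keeps_carried_strand(toy_genome):
    call = classify_motif(Junction("chr1", 51, 60, strand=MINUS), toy_genome)
    assert (call.motif, call.resolved_strand) == (NON_CANONICAL, MINUS)


def test_classify_motif_bounds_and_degenerate_errors(toy_genome):
    with pytest.raises(IndexError):
        classify_motif(Junction("chr1", 70, 5000), toy_genome)
    with pytest.raises(KeyError):
        classify_motif(Junction("chrZ", 6, 15), toy_genome)
    with pytest.raises(ValueError, match="4 bp"):
        classify_motif(Junction("chr1", 6, 8), toy_genome)


def test_n_containing_dinucleotide_is_non_canonical(tmp_path):
    path = tmp_path / "n.fa"
    write_fasta({"c": "AAAAA" + "NT" + "CCCC" + "AG" + "AAAAA"}, path)
    call = classify_motif(Junction("c", 6, 13), path)
    assert call.motif == NON_CANONICAL
    assert "N" in call.donor_dinuc


def test_classification_recovers_planted_motifs_and_matches_slicing_oracle(
    mini_dataset, mini_genome
):
    """Every generated junction classifies to its planted motif, and the
    classification agrees with an independent second-reader oracle."""
    seqs = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(mini_dataset.fasta_path), "fasta")
    }
    canonical = {("GT", "AG"): GT_AG, ("GC", "AG"): GC_AG, ("AT", "AC"): AT_AC}
    truth = mini_dataset.truth
    rng = np.random.default_rng(0)
    idx = rng.choice(len(truth), size=min(1000, len(truth)), replace=False)
    for _, row in truth.iloc[idx].iterrows():
        call = classify_motif(
            Junction(row.chrom, row.intron_start, row.intron_end), mini_genome
        )
        assert call.motif == row.motif
        # oracle: plain string slicing on an independently parsed FASTA
        seq = seqs[row.chrom]
        left = seq[row.intron_start - 1 : row.intron_start + 1]
        right = seq[row.intron_end - 2 : row.intron_end]
        if (left, right) in canonical:
            expected = (canonical[(left, right)], PLUS)
        elif (revcomp(right), revcomp(left)) in canonical:
            expected = (canonical[(revcomp(right), revcomp(left))], MINUS)
        else:
            expected = (NON_CANONICAL, call.resolved_strand)
        assert (call.motif, call.resolved_strand) == expected


def test_classification_is_strand_consistent_under_genome_mirroring(
    mini_dataset, mini_genome, tmp_path
):
    """Reverse-complementing the genome and mirroring coordinates flips the
    resolved strand but preserves the motif class."""
    chrom = mini_dataset.truth.chrom.iloc[0]
    seq = str(mini_genome[chrom][:]).upper()
    L = len(seq)
    mirrored = tmp_path / "mirror.fa"
    write_fasta({chrom: revcomp(seq)}, mirrored)
    flip = {PLUS: MINUS, MINUS: PLUS, UNDEFINED: UNDEFINED}
    sub = mini_dataset.truth[mini_dataset.truth.chrom == chrom].head(50)
    for _, row in sub.iterrows():
        fwd = classify_motif(Junction(chrom, row.intron_start, row.intron_end), mini_genome)
        rev = classify_motif(
            Junction(chrom, L - row.intron_end + 1, L - row.intron_start + 1), mirrored
        )
        assert rev.motif == fwd.motif
        if fwd.motif != NON_CANONICAL:
            assert rev.resolved_strand == flip[fwd.resolved_strand]


def test_is_annotated_requires_exact_coordinates(mini_db):
    key = next(iter(mini_db.annotated))
    assert is_annotated(key, mini_db)
    off = JunctionKey(key.chrom, key.intron_start + 1, key.intron_end)
    assert not is_annotated(off, mini_db)


def _db_with_genes(genes):
    db = JunctionAnnotationDB()
    for gid, chrom, start, end, strand in genes:
        db.genes[gid] = GeneInterval(gid, chrom, start, end, strand)
    db.build_index()
    return db


def test_gene_overlap_strand_rules():
    db = _db_with_genes([("Gplus", "chr1", 100, 1000, "+")])
    inside = Junction("chr1", 200, 300, strand=PLUS)
    assert overlaps_gene(inside, db) == "Gplus"
    assert overlaps_gene(Junction("chr1", 200, 300, strand=MINUS), db) is None
    # strand test waived when the junction strand is unknown
    db_minus = _db_with_genes([("Gminus", "chr1", 100, 1000, "-")])
    assert overlaps_gene(Junction("chr1", 200, 300), db_minus) == "Gminus"


def test_gene_overlap_tie_break_is_deterministic():
    genes = [
        ("B", "chr1", 100, 500, "+"),   # overlap 101 bp with 200-300
        ("A", "chr1", 250, 2000, "+"),  # overlap 51 bp
        ("C", "chr1", 100, 500, "+"),   # duplicate span of B -> tie on overlap
    ]
    j = Junction("chr1", 200, 300, strand=PLUS)
    for order in (genes, genes[::-1], genes[1:] + genes[:1]):
        assert overlaps_gene(j, _db_with_genes(order)) == "B"


def test_generator_annotated_fraction_is_half_of_true_junctions(mini_dataset):
    truth = mini_dataset.truth
    true_j = truth[truth.origin != "noise"]
    frac = true_j.annotated.mean()
    assert abs(frac - mini_dataset.spec.annotated_fraction) < 0.02
    assert not truth[truth.origin == "noise"].annotated.any()
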