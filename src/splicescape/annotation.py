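"""Annotated-junction database and splice-site motif classification.

Two reference resources back the pipeline:

* a database of annotated intron coordinates plus gene intervals, derived
  from an Ensembl-dialect GTF (every consecutive exon pair of every
  transcript defines one annotated junction), and
* the genome FASTA, from which each junction's donor/acceptor
  dinucleotides are read to classify its splice-site motif (GT/AG, GC/AG,
  AT/AC on either strand; everything else non-canonical).

Annotation matching is coordinate-exact and strand-lenient: a junction
whose intron coordinates equal an annotated intron counts as annotated even
if its (often motif-inferred) strand disagrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import gffutils
from intervaltree import IntervalTree
from pyfaidx import Fasta

from .junctions import (
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

# plus-strand (donor, acceptor) dinucleotides of the canonical motif classes
_CANONICAL_PAIRS = {
    ("GT", "AG"): GT_AG,
    ("GC", "AG"): GC_AG,
    ("AT", "AC"): AT_AC,
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, slots=True)
class MotifCall:
    """Genome-derived splice-site classification of one junction."""

    motif: str
    resolved_strand: str
    donor_dinuc: str
    acceptor_dinuc: str


@dataclass
class GeneInterval:
    gene_id: str
    chrom: str
    start: int  # 1-based closed, min over the gene's exons
    end: int
    strand: str


@dataclass
class JunctionAnnotationDB:
    """Annotated intron coordinates and gene intervals from one GTF."""

    annotated: dict[JunctionKey, str] = field(default_factory=dict)  # key -> strand
    genes: dict[str, GeneInterval] = field(default_factory=dict)
    source: str = ""
    _gene_trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def build_index(self) -> None:
        self._gene_trees = {}
        for gene in self.genes.values():
            tree = self._gene_trees.setdefault(gene.chrom, IntervalTree())
            # interval tree is half-open; store [start, end+1)
            tree.addi(gene.start, gene.end + 1, gene.gene_id)

    def genes_overlapping(self, chrom: str, start: int, end: int) -> list[GeneInterval]:
        tree = self._gene_trees.get(chrom)
        if tree is None:
            return []
        return [self.genes[iv.data] for iv in tree.overlap(start, end + 1)]

    def save(self, directory: str | Path) -> None:
        """Persist as a sorted junction-key TSV plus a gene BED for inspection."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "annotated_junctions.tsv", "wt") as fh:
            fh.write("chrom\tintron_start\tintron_end\tstrand\n")
            for key in sorted(self.annotated):
                fh.write(
                    f"{key.chrom}\t{key.intron_start}\t{key.intron_end}\t"
                    f"{self.annotated[key]}\n"
                )
        with open(directory / "genes.bed", "wt") as fh:
            for gid in sorted(self.genes):
                g = self.genes[gid]
                fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{gid}\t0\t{g.strand}\n")


def build_annotation_db(gtf_path: str | Path, source: str = "") -> JunctionAnnotationDB:
    """Derive the annotated-junction DB and gene index from an Ensembl GTF.

    For every transcript with k >= 2 exons, the k-1 introns between
    consecutive exons become annotated junction keys
    (``intron_start = upstream exon end + 1``,
    ``intron_end = downstream exon start - 1``).  Gene intervals are the
    min/max span of each gene's exons.  Transcripts with overlapping exons
    are skipped with a warning.
    """
    gdb = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    db = JunctionAnnotationDB(source=source or str(gtf_path))
    by_transcript: dict[str, list] = {}
    n_exons = 0
    for exon in gdb.features_of_type("exon"):
        n_exons += 1
        tid = exon.attributes["transcript_id"][0]
        by_transcript.setdefault(tid, []).append(exon)
        gid = exon.attributes["gene_id"][0]
        gene = db.genes.get(gid)
        if gene is None:
            db.genes[gid] = GeneInterval(gid, exon.seqid, exon.start, exon.end, exon.strand)
        else:
            gene.start = min(gene.start, exon.start)
            gene.end = max(gene.end, exon.end)
    if n_exons == 0:
        raise ValueError(f"{gtf_path}: no exon features; cannot build annotation DB")
    for tid, exons in by_transcript.items():
        exons.sort(key=lambda e: (e.start, e.end))
        overlapping = any(
            b.start <= a.end for a, b in zip(exons, exons[1:])
        )
        if overlapping:
            warnings.warn(f"transcript {tid} has overlapping exons; skipped")
            continue
        for up, down in zip(exons, exons[1:]):
            key = JunctionKey(up.seqid, up.end + 1, down.start - 1)
            db.annotated.setdefault(key, up.strand if up.strand in (PLUS, MINUS) else UNDEFINED)
    db.build_index()
    return db


def open_genome(genome: str | Path | Fasta) -> Fasta:
    if isinstance(genome, Fasta):
        return genome
    return Fasta(str(genome))


def classify_motif(junction: Junction | JunctionKey, genome: Fasta | str | Path) -> MotifCall:
    """Classify a junction's splice-site motif from the genome sequence.

    Reads the first two and last two intronic bases on the plus strand.  If
    they match a canonical (donor, acceptor) pair the junction is that motif
    on the plus strand; if their reverse complements (swapped) match, it is
    that motif on the minus strand; otherwise it is non-canonical and the
    strand stays as carried by the junction record.
    """
    fasta = open_genome(genome)
    chrom, start, end = junction.chrom, junction.intron_start, junction.intron_end
    if end - start + 1 < 4:
        raise ValueError(
            f"degenerate junction {chrom}:{start}-{end}: intron shorter than 4 bp"
        )
    if chrom not in fasta:
        raise KeyError(f"chromosome {chrom!r} not in genome FASTA")
    chrom_len = len(fasta[chrom])
    if start < 1 or end > chrom_len:
        raise IndexError(
            f"junction {chrom}:{start}-{end} outside chromosome (length {chrom_len})"
        )
    left = str(fasta[chrom][start - 1 : start + 1]).upper()
    right = str(fasta[chrom][end - 2 : end]).upper()
    if "N" not in left + right:
        if (left, right) in _CANONICAL_PAIRS:
            return MotifCall(_CANONICAL_PAIRS[(left, right)], PLUS, left, right)
        flipped = (revcomp(right), revcomp(left))
        if flipped in _CANONICAL_PAIRS:
            return MotifCall(_CANONICAL_PAIRS[flipped], MINUS, left, right)
    carried = getattr(junction, "strand", UNDEFINED)
    if carried not in (PLUS, MINUS):
        carried = UNDEFINED
    return MotifCall(NON_CANONICAL, carried, left, right)


def is_annotated(key: JunctionKey, db: JunctionAnnotationDB) -> bool:
    """Exact-coordinate annotation lookup (strand not required to match)."""
    return key in db.annotated


def overlaps_gene(
    junction: Junction | JunctionKey,
    db: JunctionAnnotationDB,
    strand: Optional[str] = None,
) -> Optional[str]:
    """Gene whose span intersects the intron interval, or None.

    Strand agreement is required only when the junction's resolved strand is
    defined.  Ties (several overlapping genes) are broken by the longest
    overlap, then lexicographic gene id, so the result is independent of
    gene input order.
    """
    if strand is None:
        strand = getattr(junction, "strand", UNDEFINED)
    start, end = junction.intron_start, junction.intron_end
    candidates = []
    for gene in db.genes_overlapping(junction.chrom, start, end):
        if strand in (PLUS, MINUS) and gene.strand in (PLUS, MINUS) and gene.strand != strand:
            continue
        overlap = min(end, gene.end) - max(start, gene.start) + 1
        candidates.append((-overlap, gene.gene_id))
    if not candidates:
        return None
    return min(candidates)[1]
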