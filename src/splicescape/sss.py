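"""Strain-specific splicing (SSS) calling.

A junction is a *potential* SSS event when it is detected in exactly one
strain of the panel.  A potential event is promoted to *high confidence*
when it additionally (1) has unique-read coverage at or above a floor
(default 10) in its strain and (2) is defined by a canonical splice-site
motif (GT/AG, GC/AG or AT/AC, either strand).  The motif used for the
filter is re-derived from the genome sequence by default, so the call does
not depend on the aligner's motif column; a config flag allows trusting the
table code instead.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import JunctionAnnotationDB, classify_motif, is_annotated, open_genome, overlaps_gene
from .conservation import ConservationProfile
from .junctions import (
    CANONICAL_MOTIFS,
    Junction,
    JunctionKey,
    MOTIF_CLASSES,
    StrainJunctionSet,
    UNDEFINED,
    UNKNOWN,
)

POTENTIAL = "potential"
HIGH_CONFIDENCE = "high_confidence"


@dataclass(frozen=True)
class SSSConfig:
    """Thresholds of the high-confidence protocol.

    ``min_coverage`` is the Step-2 coverage floor; ``canonical_set`` the
    motif classes accepted at Step 3; ``require_absent_reads`` the maximum
    unique-read count tolerated in every *other* strain for the junction to
    count as strain-specific (0 = strict absence).
    """

    min_coverage: int = 10
    canonical_set: frozenset[str] = frozenset(CANONICAL_MOTIFS)
    require_absent_reads: int = 0
    trust_table_motif: bool = False

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")


@dataclass(slots=True)
class SSSCall:
    """One strain-specific junction with provenance fields."""

    key: JunctionKey
    strain: str
    coverage: int
    motif: str = UNKNOWN
    resolved_strand: str = UNDEFINED
    annotated: Optional[bool] = None
    gene: Optional[str] = None
    tier: str = POTENTIAL
    region: Optional[str] = None


def find_potential_sss(
    profiles: Sequence[ConservationProfile],
    focal_min: int = 1,
    require_absent_reads: int = 0,
    sets: Optional[Sequence[StrainJunctionSet]] = None,
) -> list[SSSCall]:
    """Junctions detected in exactly one strain (Step 1).

    Emits one ``potential`` call per junction whose coverage is
    >= ``focal_min`` in exactly one strain and <= ``require_absent_reads``
    everywhere else.  When the original strain sets are supplied, the focal
    strain's table motif and strand are carried onto the call.
    """
    by_strain = {s.strain: s for s in sets} if sets is not None else {}
    calls: list[SSSCall] = []
    for p in profiles:
        above = p.coverage >= focal_min
        if int(above.sum()) != 1:
            continue
        focal = int(np.argmax(above))
        others = np.delete(p.coverage, focal)
        if others.size and int(others.max()) > require_absent_reads:
            continue
        call = SSSCall(p.key, p.strains[focal], int(p.coverage[focal]))
        src = by_strain.get(call.strain)
        if src is not None and p.key in src.junctions:
            j = src.junctions[p.key]
            call.motif = j.motif
            call.resolved_strand = j.strand
        calls.append(call)
    return calls


def call_high_confidence(
    potentials: Iterable[SSSCall],
    config: SSSConfig = SSSConfig(),
    genome=None,
    db: Optional[JunctionAnnotationDB] = None,
) -> list[SSSCall]:
    """Apply the coverage and canonical-motif filters (Steps 2-3).

    Surviving calls are re-tiered ``high_confidence`` and decorated with
    annotation status and overlapping gene.  Unless
    ``config.trust_table_motif`` is set, the motif is re-classified from the
    genome FASTA, which must then be provided.
    """
    if db is None:
        raise ValueError("annotation DB required to decorate high-confidence calls")
    if not config.trust_table_motif:
        if genome is None:
            raise ValueError("genome FASTA required unless trust_table_motif is set")
        genome = open_genome(genome)
    calls = []
    for call in potentials:
        if call.coverage < config.min_coverage:
            continue
        if config.trust_table_motif:
            motif, strand = call.motif, call.resolved_strand
            if motif == UNKNOWN:
                raise ValueError(
                    f"call {call.key} carries no table motif; run without "
                    "trust_table_motif or supply source sets"
                )
        else:
            junction = Junction(
                call.key.chrom, call.key.intron_start, call.key.intron_end,
                strand=call.resolved_strand,
            )
            mc = classify_motif(junction, genome)
            motif, strand = mc.motif, mc.resolved_strand
        if motif not in config.canonical_set:
            continue
        calls.append(
            replace(
                call,
                motif=motif,
                resolved_strand=strand,
                annotated=is_annotated(call.key, db),
                gene=overlaps_gene(call.key, db, strand=strand),
                tier=HIGH_CONFIDENCE,
            )
        )
    return calls


def sss_summary(calls: Iterable[SSSCall]) -> pd.DataFrame:
    """Per-strain composition table plus a TOTAL row.

    Columns: total calls, annotated, each motif class, gene-overlapping —
    the standard per-strain summary of a strain-specific junction screen.
    """
    cols = ["total", "annotated", *MOTIF_CLASSES, "gene_overlap"]
    counts: dict[str, dict[str, int]] = {}
    for call in calls:
        row = counts.setdefault(call.strain, {c: 0 for c in cols})
        row["total"] += 1
        if call.annotated:
            row["annotated"] += 1
        if call.motif in MOTIF_CLASSES:
            row[call.motif] += 1
        if call.gene is not None:
            row["gene_overlap"] += 1
    df = pd.DataFrame.from_dict(counts, orient="index", dtype=np.int64)
    if df.empty:
        df = pd.DataFrame(columns=cols, dtype=np.int64)
    df = df.reindex(columns=cols, fill_value=0).sort_index()
    df.loc["TOTAL"] = df.sum(axis=0)
    df.index.name = "strain"
    return df


def _strain_rows(summary: pd.DataFrame, strains: Optional[Sequence[str]]) -> pd.DataFrame:
    rows = summary.drop(index="TOTAL", errors="ignore")
    if strains is not None:
        rows = rows.loc[list(strains)]
    return rows


def unannotated_percent(summary: pd.DataFrame, strains: Optional[Sequence[str]] = None) -> float:
    """Percentage of calls (over the selected strains) not previously annotated."""
    rows = _strain_rows(summary, strains)
    total = int(rows["total"].sum())
    if total == 0:
        return float("nan")
    return 100.0 * (total - int(rows["annotated"].sum())) / total


def gene_overlap_percent(summary: pd.DataFrame, strains: Optional[Sequence[str]] = None) -> float:
    """Percentage of calls whose intron overlaps an annotated gene."""
    rows = _strain_rows(summary, strains)
    total = int(rows["total"].sum())
    if total == 0:
        return float("nan")
    return 100.0 * int(rows["gene_overlap"].sum()) / total


def read_regions(path) -> list[tuple[str, int, int, str]]:
    """Read genomic regions from BED (0-based half-open) or 1-based TSV.

    BED is detected by a ``.bed`` suffix; anything else is parsed as
    ``chrom  start  end  [label]`` with 1-based closed coordinates.
    """
    from pathlib import Path

    path = Path(path)
    is_bed = path.suffix.lower() == ".bed"
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: region needs chrom, start, end")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer region bounds") from None
            if is_bed:
                start += 1  # convert to 1-based closed
            if start > end:
                raise ValueError(f"{path}:{lineno}: start > end")
            label = fields[3] if len(fields) > 3 else f"{chrom}:{start}-{end}"
            regions.append((chrom, start, end, label))
    return regions


def intersect_regions(
    calls: Iterable[SSSCall],
    regions: Sequence[tuple[str, int, int, str]],
) -> list[SSSCall]:
    """Calls whose intron interval intersects any region (1-based closed).

    Overlapping region labels are attached sorted and ';'-joined.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, label in regions:
        if start > end:
            raise ValueError(f"malformed region {label}: start > end")
        trees.setdefault(chrom, IntervalTree()).addi(start, end + 1, label)
    hits = []
    for call in calls:
        tree = trees.get(call.key.chrom)
        if tree is None:
            continue
        labels = sorted(iv.data for iv in tree.overlap(call.key.intron_start, call.key.intron_end + 1))
        if labels:
            hits.append(replace(call, region=";".join(labels)))
    return hits


def write_calls_tsv(calls: Iterable[SSSCall], path) -> None:
    header = (
        "chrom\tintron_start\tintron_end\tstrain\tcoverage\tmotif\t"
        "resolved_strand\tannotated\tgene\ttier\tregion\n"
    )
    with open(path, "wt") as fh:
        fh.write(header)
        for c in sorted(calls, key=lambda c: (c.key, c.strain)):
            annot = "" if c.annotated is None else str(int(c.annotated))
            fh.write(
                f"{c.key.chrom}\t{c.key.intron_start}\t{c.key.intron_end}\t"
                f"{c.strain}\t{c.coverage}\t{c.motif}\t{c.resolved_strand}\t"
                f"{annot}\t{c.gene or ''}\t{c.tier}\t{c.region or ''}\n"
            )


def write_calls_bed(calls: Iterable[SSSCall], path) -> None:
    with open(path, "wt") as fh:
        for c in sorted(calls, key=lambda c: (c.key, c.strain)):
            strand = c.resolved_strand if c.resolved_strand in ("+", "-") else "."
            fh.write(
                f"{c.key.chrom}\t{c.key.intron_start - 1}\t{c.key.intron_end}\t"
                f"{c.strain}|{c.motif}\t{min(c.coverage, 1000)}\t{strand}\n"
            )
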