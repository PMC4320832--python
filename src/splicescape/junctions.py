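"""Splice-junction table I/O.

Handles the tabular splice-junction dialect emitted by spliced aligners
(one row per exon-exon junction, nine whitespace-separated columns)::

    chrom  intron_start  intron_end  strand  motif  annotated  unique  multi  overhang

Coordinates are 1-based and closed on the *intron*: ``intron_start`` is the
first intronic base and ``intron_end`` the last.  Strand is encoded
``0`` (undefined), ``1`` (plus), ``2`` (minus).  The motif column encodes the
biological splice-site class together with the strand on which it was
observed: ``0`` non-canonical, ``1``/``2`` GT/AG (plus/minus), ``3``/``4``
GC/AG, ``5``/``6`` AT/AC.  Ingest is deliberately permissive: no row is ever
dropped for being unannotated or non-canonical.

Internally everything stays in the 1-based closed intron convention of the
dialect; exports (BED) convert at the boundary.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional

import numpy as np

# strand symbols used throughout the package
PLUS = "+"
MINUS = "-"
UNDEFINED = "."
CONFLICT = "conflict"  # only produced by cross-strain reconciliation

GT_AG = "GT/AG"
GC_AG = "GC/AG"
AT_AC = "AT/AC"
NON_CANONICAL = "non-canonical"
UNKNOWN = "unknown"  # motif not yet classified (never produced by the reader)

CANONICAL_MOTIFS = (GT_AG, GC_AG, AT_AC)
MOTIF_CLASSES = (GT_AG, GC_AG, AT_AC, NON_CANONICAL)

_STRAND_FROM_CODE = {0: UNDEFINED, 1: PLUS, 2: MINUS}
_CODE_FROM_STRAND = {UNDEFINED: 0, PLUS: 1, MINUS: 2}

# motif code -> (class, strand implied by the code itself)
_MOTIF_FROM_CODE = {
    0: (NON_CANONICAL, UNDEFINED),
    1: (GT_AG, PLUS),
    2: (GT_AG, MINUS),
    3: (GC_AG, PLUS),
    4: (GC_AG, MINUS),
    5: (AT_AC, PLUS),
    6: (AT_AC, MINUS),
}
_MOTIF_BASE_CODE = {GT_AG: 1, GC_AG: 3, AT_AC: 5}


class SJParseError(ValueError):
    """A malformed row in a splice-junction table."""


class JunctionIntegrityError(ValueError):
    """Structurally valid input that violates junction invariants."""


@dataclass(frozen=True, order=True, slots=True)
class JunctionKey:
    """Strand-less identity of a junction: its intron coordinates.

    Strand is deliberately not part of the key so that the same intron
    observed with an undefined strand in one strain and an explicit strand
    in another unifies during cross-strain comparison; strands are
    reconciled at merge time.
    """

    chrom: str
    intron_start: int
    intron_end: int


@dataclass(slots=True)
class Junction:
    """One exon-exon junction as observed in a single strain."""

    chrom: str
    intron_start: int
    intron_end: int
    strand: str = UNDEFINED
    motif: str = UNKNOWN
    annotated: Optional[bool] = None
    unique_reads: int = 0
    multi_reads: int = 0
    max_overhang: int = 0

    def __post_init__(self) -> None:
        if self.intron_start > self.intron_end:
            raise JunctionIntegrityError(
                f"intron_start > intron_end at {self.chrom}:"
                f"{self.intron_start}-{self.intron_end}"
            )
        if min(self.unique_reads, self.multi_reads, self.max_overhang) < 0:
            raise JunctionIntegrityError("read counts and overhang must be >= 0")

    @property
    def key(self) -> JunctionKey:
        return JunctionKey(self.chrom, self.intron_start, self.intron_end)

    @property
    def intron_length(self) -> int:
        return self.intron_end - self.intron_start + 1


@dataclass
class StrainJunctionSet:
    """All junctions observed in one strain, keyed for comparison."""

    strain: str
    junctions: dict[JunctionKey, Junction] = field(default_factory=dict)
    source_path: str = ""

    def __post_init__(self) -> None:
        if not self.strain:
            raise ValueError("strain label must be non-empty")

    def __len__(self) -> int:
        return len(self.junctions)

    def __iter__(self) -> Iterator[Junction]:
        return iter(self.junctions.values())

    def __contains__(self, key: JunctionKey) -> bool:
        return key in self.junctions

    def add(self, junction: Junction) -> None:
        key = junction.key
        if key in self.junctions:
            raise JunctionIntegrityError(f"duplicate junction key {key}")
        self.junctions[key] = junction


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _decode_row(fields: list[str], lineno: int) -> Junction:
    try:
        chrom = fields[0]
        start, end = int(fields[1]), int(fields[2])
        strand_code, motif_code, annot_code = (int(f) for f in fields[3:6])
        unique, multi, overhang = (int(f) for f in fields[6:9])
    except ValueError as exc:
        raise SJParseError(f"line {lineno}: non-numeric field ({exc})") from None
    if strand_code not in _STRAND_FROM_CODE:
        raise SJParseError(f"line {lineno}: strand code {strand_code} not in {{0,1,2}}")
    if motif_code not in _MOTIF_FROM_CODE:
        raise SJParseError(f"line {lineno}: motif code {motif_code} not in 0..6")
    if annot_code not in (0, 1):
        raise SJParseError(f"line {lineno}: annotated flag {annot_code} not in {{0,1}}")
    motif, implied_strand = _MOTIF_FROM_CODE[motif_code]
    strand = _STRAND_FROM_CODE[strand_code]
    # an explicit strand field wins; for strand code 0 a canonical motif code
    # still tells us the strand the motif was observed on
    if strand == UNDEFINED:
        strand = implied_strand
    try:
        return Junction(
            chrom, start, end, strand, motif,
            annotated=bool(annot_code),
            unique_reads=unique, multi_reads=multi, max_overhang=overhang,
        )
    except JunctionIntegrityError as exc:
        raise JunctionIntegrityError(f"line {lineno}: {exc}") from None


def read_sj_table(path: str | Path, strain: str) -> StrainJunctionSet:
    """Read one strain's splice-junction table (plain or gzipped).

    Every row becomes a :class:`Junction`; nothing is filtered by motif or
    annotation status.  Duplicate intron coordinates within one file are an
    integrity error (the message lists every offending line).
    """
    sjs = StrainJunctionSet(strain, source_path=str(path))
    first_line: dict[JunctionKey, int] = {}
    duplicates: list[str] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 9:
                raise SJParseError(
                    f"line {lineno}: expected >= 9 fields, got {len(fields)}"
                )
            junction = _decode_row(fields, lineno)
            key = junction.key
            if key in sjs.junctions:
                duplicates.append(
                    f"{key.chrom}:{key.intron_start}-{key.intron_end} "
                    f"(lines {first_line[key]} and {lineno})"
                )
                continue
            first_line[key] = lineno
            sjs.junctions[key] = junction
    if duplicates:
        raise JunctionIntegrityError(
            f"{path}: duplicate junction keys: " + "; ".join(duplicates)
        )
    return sjs


def _encode_motif(junction: Junction) -> int:
    if junction.motif == NON_CANONICAL:
        return 0
    if junction.motif not in _MOTIF_BASE_CODE:
        raise ValueError(
            f"cannot encode motif {junction.motif!r}; classify the junction first"
        )
    return _MOTIF_BASE_CODE[junction.motif] + (1 if junction.strand == MINUS else 0)


def write_sj_table(sjs: StrainJunctionSet, path: str | Path) -> None:
    """Write a junction set back out in the aligner tabular dialect."""
    with open(path, "wt") as fh:
        for j in sorted(sjs, key=lambda j: (j.chrom, j.intron_start, j.intron_end)):
            fh.write(
                f"{j.chrom}\t{j.intron_start}\t{j.intron_end}\t"
                f"{_CODE_FROM_STRAND.get(j.strand, 0)}\t{_encode_motif(j)}\t"
                f"{int(bool(j.annotated))}\t{j.unique_reads}\t{j.multi_reads}\t"
                f"{j.max_overhang}\n"
            )


def write_junction_tsv(sjs: StrainJunctionSet, path: str | Path) -> None:
    """Dump all junction fields as a headered TSV."""
    header = (
        "chrom\tintron_start\tintron_end\tstrand\tmotif\tannotated\t"
        "unique_reads\tmulti_reads\tmax_overhang\n"
    )
    with open(path, "wt") as fh:
        fh.write(header)
        for j in sorted(sjs, key=lambda j: (j.chrom, j.intron_start, j.intron_end)):
            annot = "" if j.annotated is None else str(int(j.annotated))
            fh.write(
                f"{j.chrom}\t{j.intron_start}\t{j.intron_end}\t{j.strand}\t"
                f"{j.motif}\t{annot}\t{j.unique_reads}\t{j.multi_reads}\t"
                f"{j.max_overhang}\n"
            )


def write_junction_bed(sjs: StrainJunctionSet, path: str | Path) -> None:
    """Export the intron intervals as BED6 (0-based half-open).

    ``bedStart = intron_start - 1``, ``bedEnd = intron_end``; name is the
    motif class, score is the unique-read count capped at 1000, strand is
    ``.`` when undefined.
    """
    with open(path, "wt") as fh:
        for j in sorted(sjs, key=lambda j: (j.chrom, j.intron_start, j.intron_end)):
            strand = j.strand if j.strand in (PLUS, MINUS) else UNDEFINED
            fh.write(
                f"{j.chrom}\t{j.intron_start - 1}\t{j.intron_end}\t{j.motif}\t"
                f"{min(j.unique_reads, 1000)}\t{strand}\n"
            )


def coverage_median(sets: Iterable[StrainJunctionSet]) -> float:
    """Median unique-read coverage pooled over every junction record.

    Each strain's record of a shared junction contributes one value, so a
    junction seen in all strains is counted once per strain.  The pooled
    median is the statistic used when choosing a coverage floor for
    strain-specific calls.
    """
    pooled = np.array(
        [j.unique_reads for sjs in sets for j in sjs], dtype=np.int64
    )
    if pooled.size == 0:
        raise ValueError("coverage median undefined: no junctions in any set")
    return float(np.median(pooled))
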