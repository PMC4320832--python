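"""Published worked-example input: founder-strain high-confidence SSS counts.

Per-strain composition of the high-confidence strain-specific splicing
calls reported for the eight Collaborative Cross founder strains in a deep
striatum RNA-seq survey (mm9 coordinates, Ensembl 66 annotation): total
calls, previously annotated calls, calls per canonical motif class, and
calls overlapping an annotated gene.  Only these marginal counts are
published, so :func:`founder_sss_calls` reconstructs a *synthetic* call
list matching the marginals (attribute co-occurrence is arbitrary); it is
suitable for summary statistics, not for per-call analysis.
"""

from __future__ import annotations

from .junctions import AT_AC, GC_AG, GT_AG, JunctionKey, PLUS
from .sss import HIGH_CONFIDENCE, SSSCall

#: strain -> (total, annotated, GT/AG, GC/AG, AT/AC, gene_overlap)
FOUNDER_SSS_COUNTS: dict[str, tuple[int, int, int, int, int, int]] = {
    "129": (51, 8, 47, 4, 0, 32),
    "AJ": (53, 6, 45, 7, 1, 40),
    "B6": (66, 24, 64, 2, 0, 55),
    "CAST": (651, 18, 545, 99, 7, 427),
    "NOD": (40, 2, 32, 7, 1, 22),
    "NZO": (42, 0, 38, 4, 0, 30),
    "PWK": (482, 23, 401, 73, 8, 318),
    "WSB": (124, 2, 109, 13, 2, 76),
}

REFERENCE_STRAIN = "B6"  # the strain the reads were aligned to


def founder_sss_calls() -> list[SSSCall]:
    """Synthetic call list whose per-strain marginals equal the published counts.

    Coordinates are placeholders on an unplaced contig; motif, annotation
    and gene-overlap attributes are assigned to the first calls of each
    strain independently, which preserves every marginal used by
    :func:`splicescape.sss.sss_summary`.
    """
    calls: list[SSSCall] = []
    for strain_idx, (strain, row) in enumerate(sorted(FOUNDER_SSS_COUNTS.items())):
        total, annotated, gt_ag, gc_ag, at_ac, gene_overlap = row
        if gt_ag + gc_ag + at_ac != total:
            raise AssertionError(f"{strain}: motif columns do not sum to total")
        for i in range(total):
            if i < gt_ag:
                motif = GT_AG
            elif i < gt_ag + gc_ag:
                motif = GC_AG
            else:
                motif = AT_AC
            start = strain_idx * 1_000_000 + i * 100 + 1
            calls.append(
                SSSCall(
                    key=JunctionKey("chrUn", start, start + 49),
                    strain=strain,
                    coverage=10,
                    motif=motif,
                    resolved_strand=PLUS,
                    annotated=i < annotated,
                    gene=f"G{strain}" if i < gene_overlap else None,
                    tier=HIGH_CONFIDENCE,
                )
            )
    return calls
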