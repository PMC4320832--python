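"""Paper-style summary tables and the one-shot pipeline run.

Produces the per-strain junction summary (counts, % annotated, motif
percentages, % gene overlap), the conservation summary, the sharing
matrix + splicing phylogeny, and the strain-specific-splicing summary,
each as a TSV with a provenance header (package version + config hash, no
timestamps, so identical configs give byte-identical files).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .annotation import build_annotation_db, is_annotated, open_genome, overlaps_gene
from .conservation import (
    conservation_summary,
    merge_strains,
    sharing_matrix,
    splicing_phylogeny,
)
from .junctions import MOTIF_CLASSES, StrainJunctionSet, read_sj_table
from .sss import (
    SSSConfig,
    call_high_confidence,
    find_potential_sss,
    sss_summary,
    write_calls_tsv,
)


def round_half_even(x: float, ndigits: int = 2) -> float:
    """Banker's rounding on the decimal representation (report convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_EVEN))


def fmt_pct(x: float) -> str:
    return f"{round_half_even(x, 2):.2f}"


@dataclass
class RunConfig:
    """Inputs and knobs of one summarize run."""

    sj_paths: dict[str, str]  # strain -> SJ table path
    fasta: str
    gtf: str
    outdir: str
    min_coverage: int = 10
    require_absent_reads: int = 0
    trust_table_motif: bool = False
    thresholds: tuple[int, ...] = (1, 3, 10)
    conservation_mode: str = "focal"
    linkage: str = "average"
    phylo_threshold: int = 1

    def digest(self) -> str:
        # provenance covers inputs and parameters; the output location is not
        # part of the analysis identity
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _header(config: RunConfig) -> str:
    return f"# splicescape {__version__}\n# config sha256/16 {config.digest()}\n"


def strain_table(
    sets: Sequence[StrainJunctionSet],
    db,
    genome=None,
    recompute_motif: bool = False,
) -> pd.DataFrame:
    """Per-strain junction summary: totals, % annotated, motif %, % gene overlap.

    By default motif percentages use the motif carried in the input tables;
    with ``recompute_motif`` each junction is re-classified from the genome.
    """
    from .annotation import classify_motif

    if recompute_motif:
        genome = open_genome(genome)
    rows = []
    for sjs in sets:
        total = len(sjs)
        n_annot = 0
        n_gene = 0
        motif_counts = {m: 0 for m in MOTIF_CLASSES}
        for j in sjs:
            if recompute_motif:
                mc = classify_motif(j, genome)
                motif, strand = mc.motif, mc.resolved_strand
            else:
                motif, strand = j.motif, j.strand
            if motif in motif_counts:
                motif_counts[motif] += 1
            if is_annotated(j.key, db):
                n_annot += 1
            if overlaps_gene(j.key, db, strand=strand) is not None:
                n_gene += 1
        row = {
            "strain": sjs.strain,
            "mapped_junctions": total,
            "pct_annotated": 100.0 * n_annot / total if total else float("nan"),
        }
        for m in MOTIF_CLASSES:
            row[f"pct_{m}"] = 100.0 * motif_counts[m] / total if total else float("nan")
        row["pct_gene_overlap"] = 100.0 * n_gene / total if total else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("strain")


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig, index: bool = True) -> None:
    pct_cols = [c for c in df.columns if str(c).startswith(("pct_", "frac_"))]
    out = df.copy()
    for c in pct_cols:
        out[c] = out[c].map(lambda x: fmt_pct(x) if pd.notna(x) else "NA")
    with open(path, "wt") as fh:
        fh.write(_header(config))
        out.to_csv(fh, sep="\t", index=index)


def summarize_run(config: RunConfig) -> dict[str, Path]:
    """Run the full pipeline and write the five summary outputs.

    Returns a name -> path mapping for: strain_summary, conservation,
    sharing_matrix, phylogeny (newick), sss_summary (plus the raw
    high-confidence calls TSV).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sets = [read_sj_table(path, strain) for strain, path in config.sj_paths.items()]
    db = build_annotation_db(config.gtf)
    genome = open_genome(config.fasta)

    outputs: dict[str, Path] = {}

    table3 = strain_table(sets, db)
    outputs["strain_summary"] = outdir / "strain_summary.tsv"
    _write_tsv(table3, outputs["strain_summary"], config)

    profiles = merge_strains(sets)
    cons = conservation_summary(profiles, config.thresholds, mode=config.conservation_mode)
    outputs["conservation"] = outdir / "conservation_summary.tsv"
    _write_tsv(cons, outputs["conservation"], config, index=False)

    matrix = sharing_matrix(profiles, t=config.phylo_threshold)
    outputs["sharing_matrix"] = outdir / "sharing_matrix.tsv"
    _write_tsv(matrix.to_frame(), outputs["sharing_matrix"], config)

    phylo = splicing_phylogeny(matrix, method=config.linkage)  # type: ignore[arg-type]
    outputs["phylogeny"] = outdir / "phylogeny.nwk"
    outputs["phylogeny"].write_text(phylo.newick + "\n")

    sss_config = SSSConfig(
        min_coverage=config.min_coverage,
        require_absent_reads=config.require_absent_reads,
        trust_table_motif=config.trust_table_motif,
    )
    potentials = find_potential_sss(
        profiles,
        focal_min=config.min_coverage,
        require_absent_reads=config.require_absent_reads,
        sets=sets,
    )
    calls = call_high_confidence(potentials, sss_config, genome=genome, db=db)
    outputs["sss_calls"] = outdir / "sss_calls.tsv"
    write_calls_tsv(calls, outputs["sss_calls"])
    table5 = sss_summary(calls)
    outputs["sss_summary"] = outdir / "sss_summary.tsv"
    _write_tsv(table5, outputs["sss_summary"], config)
    return outputs
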