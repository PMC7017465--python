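"""End-to-end pipeline: references + reads → variant CSV + annotated GenBank.

One call runs the whole workflow: load GenBank references, align reads
(built-in aligner for FASTQ, or ingest an external SAM), build
strand-aware pileups, apply the filter cascade, classify consequences,
attach advisory zygosity hints, and write the two canonical outputs — a
simplified ``variants.csv`` and one variant-annotated GenBank file per
gene — plus a machine-readable ``summary.json``.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from canseq.align import (
    DEFAULT_MAX_MISMATCHES,
    DEFAULT_SEED_LENGTH,
    align_builtin,
    build_pileup,
    parse_sam,
)
from canseq.calling import FilterConfig, VariantCall, call_variants, zygosity_hint
from canseq.consequence import Consequence, annotate
from canseq.design import PoolDesign
from canseq.errors import InputError
from canseq.reference import load_reference, write_annotated_genbank

logger = logging.getLogger("canseq")

_version = "0.1.0"


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    reference_paths: list[Union[str, Path]]
    out_dir: Union[str, Path]
    fastq: Optional[tuple[Union[str, Path], Union[str, Path]]] = None
    sam: Optional[Union[str, Path]] = None
    filters: FilterConfig = field(default_factory=FilterConfig)
    n_mutants: int = 23
    seed: int = 0
    seed_length: int = DEFAULT_SEED_LENGTH
    max_mismatches: int = DEFAULT_MAX_MISMATCHES
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.reference_paths:
            raise InputError("no reference files given")
        if (self.fastq is None) == (self.sam is None):
            raise InputError("exactly one of fastq or sam input is required")
        if self.n_mutants < 1:
            raise InputError("n_mutants must be >= 1")
        missing = [
            str(p)
            for p in list(self.reference_paths)
            + (list(self.fastq) if self.fastq else [self.sam])
            if not Path(p).exists()
        ]
        if missing:
            raise InputError(f"input file(s) not found: {', '.join(missing)}")


def run_pipeline(config: RunConfig) -> dict:
    """Run the full workflow; returns the run summary dict."""
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    refs = [load_reference(p) for p in config.reference_paths]
    logger.info("loaded %d reference(s)", len(refs))

    align_stats: dict = {}
    if config.fastq is not None:
        stream = align_builtin(
            list(config.fastq),
            refs,
            seed_length=config.seed_length,
            max_mismatches=config.max_mismatches,
            stats=align_stats,
        )
    else:
        stream = parse_sam(config.sam, refs)

    pileups = build_pileup(stream, refs)
    all_columns = [col for cols in pileups.values() for col in cols]
    logger.info("pileup over %d covered position(s)", len(all_columns))

    calls = call_variants(all_columns, refs, config.filters)
    pool = PoolDesign(
        n_mutants=config.n_mutants,
        threshold_percent=config.filters.min_freq_percent,
    )
    ref_by_id = {r.gene_id: r for r in refs}
    annotated: list[tuple[VariantCall, Consequence]] = []
    for call in calls:
        call.zygosity_hint = zygosity_hint(call, pool)
        annotated.append((call, annotate(call, ref_by_id[call.gene_id])))
    logger.info("%d variant call(s) passed all filters", len(calls))

    csv_path = out_dir / "variants.csv"
    write_variant_csv(annotated, csv_path)
    gb_paths = {}
    for ref in refs:
        gene_calls = [(c, q) for c, q in annotated if c.gene_id == ref.gene_id]
        gb_path = out_dir / f"{ref.gene_id}.gb"
        write_annotated_genbank(ref, gene_calls, gb_path)
        gb_paths[ref.gene_id] = str(gb_path)

    summary = {
        "version": _version,
        "references": {r.gene_id: r.length for r in refs},
        "input_mode": "fastq" if config.fastq is not None else "sam",
        "alignment_stats": align_stats,
        "filters": {
            "min_freq_percent": config.filters.min_freq_percent,
            "min_depth": config.filters.min_depth,
            "min_variant_reads": config.filters.min_variant_reads,
            "min_per_strand": config.filters.min_per_strand,
            "canonical_only": config.filters.canonical_only,
        },
        "pool": {
            "n_mutants": pool.n_mutants,
            "expected_hom_percent": pool.expected_hom_percent,
            "expected_het_percent": pool.expected_het_percent,
        },
        "n_covered_positions": len(all_columns),
        "n_calls": len(calls),
        "calls": [
            {
                "gene_id": c.gene_id,
                "pos": c.pos,
                "ref": c.ref_base,
                "alt": c.alt_base,
                "freq_percent": round(c.freq_percent, 4),
                "depth": c.depth,
                "consequence": q.kind,
                "protein_change": q.protein_change,
                "zygosity_hint": c.zygosity_hint,
            }
            for c, q in annotated
        ],
        "outputs": {"variants_csv": str(csv_path), "genbank": gb_paths},
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


CSV_COLUMNS = [
    "gene_id",
    "pos",
    "ref",
    "alt",
    "freq_percent",
    "depth",
    "variant_reads",
    "variant_fwd",
    "variant_rev",
    "consequence_kind",
    "protein_change",
    "intron_index",
    "zygosity_hint",
]


def write_variant_csv(
    annotated: list[tuple[VariantCall, Optional[Consequence]]],
    path: Union[str, Path],
) -> None:
    """Write the simplified variant CSV (fixed column order, LF endings)."""
    rows = sorted(annotated, key=lambda cq: (cq[0].gene_id, cq[0].pos,
                                             cq[0].alt_base))
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(CSV_COLUMNS)
        for call, cons in rows:
            writer.writerow(
                [
                    call.gene_id,
                    call.pos,
                    call.ref_base,
                    call.alt_base,
                    f"{call.freq_percent:.2f}",
                    call.depth,
                    call.variant_reads,
                    call.variant_fwd,
                    call.variant_rev,
                    cons.kind if cons else "",
                    cons.protein_change if cons else "",
                    cons.intron_index if cons and cons.intron_index else "",
                    call.zygosity_hint,
                ]
            )


def write_vcf(
    annotated: list[tuple[VariantCall, Optional[Consequence]]],
    refs,
    path: Union[str, Path],
) -> None:
    """Write calls as minimal VCF 4.2 (CHROM = gene_id)."""
    rows = sorted(annotated, key=lambda cq: (cq[0].gene_id, cq[0].pos,
                                             cq[0].alt_base))
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=canseq {_version}\n")
        for ref in refs:
            fh.write(f"##contig=<ID={ref.gene_id},length={ref.length}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write(
            '##INFO=<ID=VF,Number=1,Type=Float,Description='
            '"Variant frequency percent">\n'
        )
        fh.write(
            '##INFO=<ID=SC,Number=2,Type=Integer,Description='
            '"Variant strand counts fwd,rev">\n'
        )
        fh.write(
            '##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for call, cons in rows:
            info = (
                f"DP={call.depth};VF={call.freq_percent:.2f};"
                f"SC={call.variant_fwd},{call.variant_rev}"
            )
            if cons is not None:
                csq = cons.kind + (f"|{cons.protein_change}"
                                   if cons.protein_change else "")
                info += f";CSQ={csq}"
            fh.write(
                f"{call.gene_id}\t{call.pos}\t.\t{call.ref_base}\t"
                f"{call.alt_base}\t.\tPASS\t{info}\n"
            )
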