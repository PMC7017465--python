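"""The candidate-mutation filter cascade.

A pool of n mutants dilutes each mutation to ~1/n (homozygous) or ~1/(2n)
(heterozygous) of the reads at its position, so the caller must separate
sub-5% true variants from sequencing error. Five filters, all inclusive
(>=), are applied to every non-reference base at every pileup column:

1. canonical EMS transition (G→A or C→T, as written on the reference top
   strand) — unless ``canonical_only`` is off;
2. depth >= ``min_depth`` (default 200 reads covering the position);
3. variant reads >= ``min_variant_reads`` (default 30);
4. at least ``min_per_strand`` variant reads in each of the forward and
   reverse orientations (default 5) — rejects strand-specific errors;
5. variant frequency >= ``min_freq_percent`` (default 0.75%).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Optional, Union

from canseq.align import PileupColumn
from canseq.errors import InputError
from canseq.reference import AmpliconReference

if TYPE_CHECKING:  # pragma: no cover
    from canseq.design import PoolDesign

CANONICAL_PAIRS = {("G", "A"), ("C", "T")}


@dataclass
class FilterConfig:
    """Thresholds of the filter cascade; defaults follow the method."""

    min_freq_percent: float = 0.75
    min_depth: int = 200
    min_variant_reads: int = 30
    min_per_strand: int = 5
    canonical_only: bool = True

    def __post_init__(self) -> None:
        for name in ("min_freq_percent", "min_depth", "min_variant_reads",
                     "min_per_strand"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")
        if self.min_per_strand > self.min_variant_reads / 2:
            warnings.warn(
                "min_per_strand exceeds half of min_variant_reads; the "
                "per-strand filter dominates the variant-read filter",
                stacklevel=3,
            )

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "FilterConfig":
        """Load thresholds from a JSON config file (unknown keys rejected)."""
        with open(path) as fh:
            data = json.load(fh)
        known = {"min_freq_percent", "min_depth", "min_variant_reads",
                 "min_per_strand", "canonical_only"}
        bad = set(data) - known
        if bad:
            raise InputError(f"unknown filter config keys: {sorted(bad)}")
        return cls(**data)


@dataclass
class VariantCall:
    """A candidate EMS variant passing all filters."""

    gene_id: str
    pos: int  # 1-based
    ref_base: str
    alt_base: str
    depth: int
    variant_reads: int
    variant_fwd: int
    variant_rev: int
    zygosity_hint: str = "indeterminate"
    freq_percent: float = field(init=False)

    def __post_init__(self) -> None:
        if self.variant_fwd + self.variant_rev != self.variant_reads:
            raise InputError("strand counts do not sum to variant_reads")
        if self.variant_reads > self.depth:
            raise InputError("variant_reads exceeds depth")
        self.freq_percent = 100.0 * self.variant_reads / self.depth


def call_variants(
    columns: list[PileupColumn],
    refs: list[AmpliconReference],
    config: Optional[FilterConfig] = None,
) -> list[VariantCall]:
    """Apply the filter cascade to pileup columns.

    Every non-reference base at every column is tested against the five
    filters; output is sorted by (gene_id, pos, alt_base). Columns whose
    reference base is N are skipped with a warning.
    """
    if config is None:
        config = FilterConfig()
    ref_by_id = {r.gene_id: r for r in refs}
    calls = []
    for col in columns:
        ref = ref_by_id.get(col.gene_id)
        if ref is None:
            raise InputError(f"column references unknown gene {col.gene_id!r}")
        if not 1 <= col.pos <= ref.length:
            raise InputError(
                f"column position {col.pos} outside {col.gene_id} [1, {ref.length}]"
            )
        ref_base = ref.sequence[col.pos - 1]
        if ref_base == "N":
            warnings.warn(
                f"{col.gene_id}:{col.pos}: reference base N, column skipped",
                stacklevel=2,
            )
            continue
        depth = col.depth
        if depth == 0:
            continue
        for alt in "ACGT":
            if alt == ref_base:
                continue
            if config.canonical_only and (ref_base, alt) not in CANONICAL_PAIRS:
                continue
            fwd = col.count(alt, "forward")
            rev = col.count(alt, "reverse")
            n_var = fwd + rev
            if depth < config.min_depth:
                continue
            if n_var < config.min_variant_reads:
                continue
            if fwd < config.min_per_strand or rev < config.min_per_strand:
                continue
            if 100.0 * n_var / depth < config.min_freq_percent:
                continue
            calls.append(
                VariantCall(
                    gene_id=col.gene_id,
                    pos=col.pos,
                    ref_base=ref_base,
                    alt_base=alt,
                    depth=depth,
                    variant_reads=n_var,
                    variant_fwd=fwd,
                    variant_rev=rev,
                )
            )
    calls.sort(key=lambda c: (c.gene_id, c.pos, c.alt_base))
    return calls


def zygosity_hint(call: VariantCall, pool: "PoolDesign") -> str:
    """Advisory zygosity label from the pool-dilution model.

    In a pool of n mutants a homozygous mutation is expected at 100/n %
    of reads and a heterozygous one at 100/(2n) %. A call at or above the
    midpoint of those two expectations is ``homozygous-like``; at or
    above half the heterozygous expectation (but below the midpoint) it
    is ``heterozygous-like``; otherwise ``indeterminate``. Never used for
    filtering — true zygosity is established by genotyping individuals.
    """
    het = pool.expected_het_percent
    hom = pool.expected_hom_percent
    midpoint = (het + hom) / 2
    if call.freq_percent >= midpoint:
        return "homozygous-like"
    if call.freq_percent >= het / 2:
        return "heterozygous-like"
    return "indeterminate"
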