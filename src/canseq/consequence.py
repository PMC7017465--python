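"""Functional classification of called variants against the gene model.

CDS variants are classified by mutating the affected codon (strand-aware)
and translating with the standard nuclear genetic code: a new stop is
``nonsense``, an amino-acid change ``missense``, no change ``silent``
(``stop_codon_silent`` when the natural stop stays a stop). Intronic
variants in the two canonical intron-terminal dinucleotides (GT donor,
AG acceptor) are splice-site variants; other intronic positions are
``intron`` and positions outside the gene span are ``flank`` — reported
but never classified as protein-changing. Protein changes use the
conventional one-letter notation, e.g. ``W227*`` for Trp227→stop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from Bio.Seq import Seq

from canseq.calling import VariantCall
from canseq.errors import ConsistencyError, InputError
from canseq.reference import (
    AmpliconReference,
    CodonAddress,
    Region,
    genomic_to_codon,
    revcomp,
)

_AA_CODES = set("ACDEFGHIKLMNPQRSTVWY*X")

KINDS = (
    "nonsense",
    "missense",
    "silent",
    "splice_donor",
    "splice_acceptor",
    "intronic",
    "flank",
    "stop_codon_silent",
)


@dataclass(frozen=True)
class Consequence:
    """Functional class of a variant, with protein notation when coding."""

    kind: str
    protein_change: str = ""
    codon_number: Optional[int] = None
    intron_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise InputError(f"unknown consequence kind {self.kind!r}")


def notation(ref_aa: str, codon_number: int, alt_aa: str) -> str:
    """Protein-change notation: one-letter ref AA + codon number + alt AA."""
    for aa in (ref_aa, alt_aa):
        if aa not in _AA_CODES:
            raise InputError(f"invalid amino-acid code {aa!r}")
    if codon_number < 1:
        raise InputError("codon_number must be >= 1")
    return f"{ref_aa}{codon_number}{alt_aa}"


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def annotate(call: VariantCall, ref: AmpliconReference) -> Consequence:
    """Classify a variant call against the reference gene model."""
    if not 1 <= call.pos <= ref.length:
        raise InputError(f"position {call.pos} outside [1, {ref.length}]")
    if ref.sequence[call.pos - 1] != call.ref_base:
        raise ConsistencyError(
            f"{call.gene_id}:{call.pos}: call reference base {call.ref_base} "
            f"disagrees with sequence base {ref.sequence[call.pos - 1]}"
        )
    if ref.gene_model is None:
        return Consequence(kind="flank")

    address = genomic_to_codon(ref, call.pos)
    if isinstance(address, Region):
        if address.kind in ("splice_donor", "splice_acceptor", "intron"):
            kind = "intronic" if address.kind == "intron" else address.kind
            return Consequence(kind=kind, intron_index=address.intron_index)
        return Consequence(kind="flank")

    assert isinstance(address, CodonAddress)
    # Strand-normalize the alternative base into mRNA sense.
    if ref.gene_model.strand == "reverse":
        alt = revcomp(call.alt_base)
    else:
        alt = call.alt_base
    ref_codon = address.ref_codon
    i = address.position_in_codon - 1
    alt_codon = ref_codon[:i] + alt + ref_codon[i + 1 :]
    ref_aa = _translate(ref_codon)
    alt_aa = _translate(alt_codon)
    change = notation(ref_aa, address.codon_number, alt_aa)

    if ref_aa == alt_aa:
        kind = "stop_codon_silent" if ref_aa == "*" else "silent"
    elif alt_aa == "*":
        kind = "nonsense"
    else:
        if ref_aa == "*":
            # stop-loss: unreachable under canonical-only transitions
            import warnings

            warnings.warn(
                f"{call.gene_id}:{call.pos}: stop-loss variant reported as "
                "missense",
                stacklevel=2,
            )
        kind = "missense"
    return Consequence(
        kind=kind, protein_change=change, codon_number=address.codon_number
    )
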