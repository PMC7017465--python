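"""Candidate-gene reference models parsed from GenBank records.

A candidate-gene amplicon is a single GenBank record carrying the locus
sequence and (usually) a CDS feature describing the gene model. Internally
all coordinates are 0-based half-open; everything user-facing (function
arguments, reports, GenBank output) is 1-based inclusive, matching the
GenBank convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from canseq.errors import InputError, ModelValidationError, UnsupportedOperationError

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CodonAddress:
    """Location of a genomic position within the coding sequence.

    ``codon_number`` counts from the initiator Met (= 1);
    ``position_in_codon`` is 1, 2 or 3; ``ref_codon`` is the
    strand-normalized reference triplet at that codon.
    """

    codon_number: int
    position_in_codon: int
    ref_codon: str


@dataclass(frozen=True)
class Region:
    """Non-coding region label for a genomic position.

    ``kind`` is one of ``intron``, ``splice_donor``, ``splice_acceptor``,
    ``flank``; ``intron_index`` is the 1-based ordinal of the intron in
    transcription order (None for flank).
    """

    kind: str
    intron_index: Optional[int] = None


@dataclass
class GeneModel:
    """CDS structure of a candidate gene on its amplicon.

    ``cds_segments`` are 0-based half-open intervals on the reference,
    sorted by start and non-overlapping. ``strand`` is ``"forward"`` or
    ``"reverse"``. Intron segments are the gaps between consecutive CDS
    segments. The concatenated, strand-normalized CDS must be a whole
    number of codons; a missing ATG start or stop end only warns, so
    partial models remain usable for annotation.
    """

    cds_segments: list[tuple[int, int]]
    strand: str
    intron_segments: list[tuple[int, int]] = field(init=False)
    cds_length: int = field(init=False)

    def __post_init__(self) -> None:
        if self.strand not in ("forward", "reverse"):
            raise ModelValidationError(f"invalid strand {self.strand!r}")
        if not self.cds_segments:
            raise ModelValidationError("gene model requires at least one CDS segment")
        segs = sorted(self.cds_segments)
        for (s1, e1), (s2, _) in zip(segs, segs[1:]):
            if s2 < e1:
                raise ModelValidationError(
                    f"overlapping CDS segments ({s1 + 1}..{e1}) and starting at {s2 + 1}"
                )
        for s, e in segs:
            if e <= s:
                raise ModelValidationError(f"empty CDS segment at {s + 1}")
        self.cds_segments = segs
        self.intron_segments = [
            (e1, s2) for (_, e1), (s2, _) in zip(segs, segs[1:])
        ]
        self.cds_length = sum(e - s for s, e in segs)
        if self.cds_length % 3 != 0:
            raise ModelValidationError(
                f"CDS length {self.cds_length} is not a multiple of 3"
            )

    @property
    def span(self) -> tuple[int, int]:
        """0-based half-open interval from first CDS base to last."""
        return self.cds_segments[0][0], self.cds_segments[-1][1]

    def n_introns(self) -> int:
        return len(self.intron_segments)


@dataclass
class AmpliconReference:
    """A candidate-gene locus: sequence plus optional gene model.

    ``source_record`` keeps the original Bio.SeqRecord so the annotated
    GenBank output preserves every pre-existing feature.
    """

    gene_id: str
    sequence: str
    gene_model: Optional[GeneModel] = None
    source_record: Optional[SeqRecord] = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.gene_model is not None:
            lo, hi = self.gene_model.span
            if lo < 0 or hi > len(self.sequence):
                raise ModelValidationError(
                    f"{self.gene_id}: CDS interval {lo + 1}..{hi} outside "
                    f"sequence of length {len(self.sequence)}"
                )
            cds = self.cds_sequence()
            if not cds.startswith("ATG"):
                warnings.warn(
                    f"{self.gene_id}: CDS does not begin with ATG (partial model?)",
                    stacklevel=3,
                )
            if cds[-3:] not in ("TAA", "TAG", "TGA"):
                warnings.warn(
                    f"{self.gene_id}: CDS does not end with a stop codon "
                    "(partial model?)",
                    stacklevel=3,
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def cds_sequence(self) -> str:
        """Strand-normalized (5'→3' mRNA sense) concatenated CDS."""
        if self.gene_model is None:
            raise UnsupportedOperationError(f"{self.gene_id}: no gene model")
        cds = "".join(self.sequence[s:e] for s, e in self.gene_model.cds_segments)
        if self.gene_model.strand == "reverse":
            cds = revcomp(cds)
        return cds


def load_reference(genbank_path: Union[str, Path]) -> AmpliconReference:
    """Parse a single-record GenBank flat file into an AmpliconReference.

    The first CDS feature (if any) supplies the gene model; ``join()``
    multi-interval locations become multiple CDS segments and a
    ``complement()`` location sets the reverse strand. Records without a
    CDS feature load with ``gene_model=None`` (sequence-only use).
    """
    path = Path(genbank_path)
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read GenBank file {path}: {exc}") from exc
    if not records:
        raise InputError(f"no GenBank record found in {path}")
    if len(records) > 1:
        raise InputError(f"{path} contains {len(records)} records; expected 1")
    record = records[0]
    sequence = str(record.seq).upper()
    if not sequence:
        raise InputError(f"{path}: record {record.id} has an empty sequence")

    gene_model = None
    for feat in record.features:
        if feat.type != "CDS":
            continue
        segments = [(int(part.start), int(part.end)) for part in feat.location.parts]
        strand = "reverse" if feat.location.strand == -1 else "forward"
        for s, e in segments:
            if s < 0 or e > len(sequence):
                raise ModelValidationError(
                    f"{record.id}: CDS interval {s + 1}..{e} outside sequence "
                    f"of length {len(sequence)}"
                )
        gene_model = GeneModel(cds_segments=segments, strand=strand)
        break

    gene_id = record.name if record.name and record.name != "." else record.id
    return AmpliconReference(
        gene_id=gene_id,
        sequence=sequence,
        gene_model=gene_model,
        source_record=record,
    )


def _transcription_order_introns(model: GeneModel) -> list[tuple[int, int]]:
    """Introns ordered 5'→3' along the mRNA."""
    introns = model.intron_segments
    return introns if model.strand == "forward" else introns[::-1]


def genomic_to_codon(
    ref: AmpliconReference, pos: int
) -> Union[CodonAddress, Region]:
    """Map a 1-based genomic position to a codon address or region label.

    CDS positions return a :class:`CodonAddress` (strand-aware: on a
    reverse-strand gene the codon numbering runs against reference
    coordinates). The first two intronic bases in transcription order are
    ``splice_donor``, the last two ``splice_acceptor``; other intronic
    bases are ``intron``; positions outside the gene span are ``flank``.
    """
    if not 1 <= pos <= ref.length:
        raise InputError(f"position {pos} outside [1, {ref.length}]")
    model = ref.gene_model
    if model is None:
        raise UnsupportedOperationError(f"{ref.gene_id}: no gene model")
    p0 = pos - 1
    lo, hi = model.span
    if p0 < lo or p0 >= hi:
        return Region("flank")

    # CDS?
    offset = 0
    for s, e in model.cds_segments:
        if s <= p0 < e:
            fwd_offset = offset + (p0 - s)
            if model.strand == "reverse":
                cds_index = model.cds_length - 1 - fwd_offset
            else:
                cds_index = fwd_offset
            codon_number = cds_index // 3 + 1
            position_in_codon = cds_index % 3 + 1
            cds = ref.cds_sequence()
            ref_codon = cds[(codon_number - 1) * 3 : codon_number * 3]
            return CodonAddress(codon_number, position_in_codon, ref_codon)
        offset += e - s

    # intronic: locate the intron and its position relative to transcription
    ordered = _transcription_order_introns(model)
    for idx, (s, e) in enumerate(ordered, start=1):
        if s <= p0 < e:
            if model.strand == "forward":
                from_donor = p0 - s
                from_acceptor = e - 1 - p0
            else:
                from_donor = e - 1 - p0
                from_acceptor = p0 - s
            if from_donor < 2:
                return Region("splice_donor", intron_index=idx)
            if from_acceptor < 2:
                return Region("splice_acceptor", intron_index=idx)
            return Region("intron", intron_index=idx)
    raise AssertionError("position inside gene span but in no segment")  # pragma: no cover


def write_annotated_genbank(
    ref: AmpliconReference,
    annotated_calls: list,
    out_path: Union[str, Path],
) -> None:
    """Write the reference back to GenBank with one feature per variant.

    ``annotated_calls`` is a list of ``(VariantCall, Consequence)`` pairs
    (the Consequence may be None). Each variant becomes a ``variation``
    feature at its single base with qualifiers for ref/alt base, frequency
    percent, depth, strand counts, consequence class and protein notation.
    All original features are preserved.
    """
    if ref.source_record is not None:
        record = ref.source_record[:]  # slicing copies record + features
        record.name = ref.source_record.name
        record.id = ref.source_record.id
        record.description = ref.source_record.description
        record.annotations = dict(ref.source_record.annotations)
    else:
        record = SeqRecord(Seq(ref.sequence), id=ref.gene_id, name=ref.gene_id)
        if ref.gene_model is not None:
            strand = -1 if ref.gene_model.strand == "reverse" else 1
            parts = [
                SimpleLocation(s, e, strand=strand)
                for s, e in ref.gene_model.cds_segments
            ]
            if strand == -1:
                parts = parts[::-1]  # join() in transcription order
            location = parts[0] if len(parts) == 1 else sum(parts[1:], parts[0])
            record.features.append(SeqFeature(location, type="CDS"))
    record.annotations.setdefault("molecule_type", "DNA")

    for call, cons in sorted(annotated_calls, key=lambda vc: vc[0].pos):
        if not 1 <= call.pos <= ref.length:
            raise InputError(
                f"variant position {call.pos} outside [1, {ref.length}]"
            )
        qualifiers = {
            "replace": [f"{call.ref_base.lower()}->{call.alt_base.lower()}"],
            "ref_base": [call.ref_base],
            "alt_base": [call.alt_base],
            "frequency_percent": [f"{call.freq_percent:.2f}"],
            "depth": [str(call.depth)],
            "variant_reads": [str(call.variant_reads)],
            "variant_fwd": [str(call.variant_fwd)],
            "variant_rev": [str(call.variant_rev)],
        }
        if cons is not None:
            qualifiers["consequence"] = [cons.kind]
            if cons.protein_change:
                qualifiers["protein_change"] = [cons.protein_change]
            if cons.intron_index is not None:
                qualifiers["intron_index"] = [str(cons.intron_index)]
        if getattr(call, "zygosity_hint", None):
            qualifiers["zygosity_hint"] = [call.zygosity_hint]
        feature = SeqFeature(
            SimpleLocation(call.pos - 1, call.pos, strand=1),
            type="variation",
            qualifiers=qualifiers,
        )
        record.features.append(feature)

    try:
        with open(out_path, "w") as handle:
            SeqIO.write(record, handle, "genbank")
    except OSError as exc:
        raise InputError(f"cannot write {out_path}: {exc}") from exc


def write_fasta(refs: list[AmpliconReference], out_path: Union[str, Path]) -> None:
    """Export references as FASTA for use with external aligners."""
    with open(out_path, "w") as handle:
        for ref in refs:
            handle.write(f">{ref.gene_id}\n")
            for i in range(0, ref.length, 70):
                handle.write(ref.sequence[i : i + 70] + "\n")
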