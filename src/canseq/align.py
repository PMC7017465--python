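"""Strand-aware per-position base counting from amplicon alignments.

Two alignment sources feed the same pileup builder: an external SAM file
(e.g. from Bowtie 2 or bwa) parsed with pysam, or the built-in ungapped
aligner. The built-in aligner is substitution-only and end-to-end, which
matches the amplicon setting: reads derive from PCR products of the
references themselves, EMS induces substitutions, and the variant caller
only considers substitutions. Ambiguous placements are discarded rather
than randomly assigned, so cross-amplicon repeats cannot bleed reads into
another locus and distort sub-percent variant frequencies. Duplicate
reads are retained — amplicon libraries are duplicates by construction —
and base qualities are ignored by default (input reads are expected to be
quality-trimmed upstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

import numpy as np
import pysam

from canseq.errors import InputError
from canseq.reference import AmpliconReference, revcomp

BASES = "ACGT"
ORIENTATIONS = ("forward", "reverse")

DEFAULT_SEED_LENGTH = 31
DEFAULT_MAX_MISMATCHES = 3


@dataclass
class ReadAlignment:
    """Aligned base observations from one read.

    ``positions`` are 0-based reference coordinates, parallel to
    ``bases`` (uint8 ASCII). ``orientation`` reflects the strand the read
    aligned to.
    """

    gene_id: str
    positions: np.ndarray
    bases: np.ndarray
    orientation: str

    def observations(self) -> Iterator[tuple[str, int, str, str]]:
        """Yield (gene_id, 1-based pos, base, orientation) per base."""
        for p, b in zip(self.positions, self.bases):
            yield self.gene_id, int(p) + 1, chr(b), self.orientation


@dataclass
class PileupColumn:
    """Per-position, per-base, per-orientation aligned read counts.

    ``counts`` maps (base, orientation) to a non-negative count over
    A/C/G/T only; N and gap observations are excluded from both counts
    and depth.
    """

    gene_id: str
    pos: int  # 1-based
    counts: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return sum(self.counts.values())

    def count(self, base: str, orientation: Optional[str] = None) -> int:
        if orientation is not None:
            return self.counts.get((base, orientation), 0)
        return sum(self.counts.get((base, o), 0) for o in ORIENTATIONS)


def parse_sam(
    sam_path: Union[str, Path], refs: list[AmpliconReference]
) -> Iterator[ReadAlignment]:
    """Stream aligned base observations from a SAM/BAM file.

    Unmapped, secondary and supplementary records are skipped. Insertions
    contribute no reference-anchored observation; deleted reference bases
    are simply uncovered by the read.
    """
    known = {r.gene_id for r in refs}
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as sam:
        for read in sam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            rname = read.reference_name
            if rname not in known:
                raise InputError(
                    f"SAM reference {rname!r} not among loaded gene references"
                )
            seq = read.query_sequence
            if seq is None:
                continue
            pairs = [
                (q, r)
                for q, r in read.get_aligned_pairs()
                if q is not None and r is not None
            ]
            if not pairs:
                continue
            qpos, rpos = zip(*pairs)
            bases = np.frombuffer(seq.encode(), dtype=np.uint8)[list(qpos)]
            yield ReadAlignment(
                gene_id=rname,
                positions=np.asarray(rpos, dtype=np.int64),
                bases=bases,
                orientation="reverse" if read.is_reverse else "forward",
            )


class _KmerIndex:
    """Exact k-mer lookup over a set of reference sequences."""

    def __init__(self, refs: list[AmpliconReference], k: int):
        if not refs:
            raise InputError("empty reference set")
        self.k = k
        self.refs = refs
        self.arrays = [
            np.frombuffer(r.sequence.encode(), dtype=np.uint8) for r in refs
        ]
        self.index: dict[str, list[tuple[int, int]]] = {}
        for gi, r in enumerate(refs):
            seq = r.sequence
            for p in range(len(seq) - k + 1):
                self.index.setdefault(seq[p : p + k], []).append((gi, p))


def align_builtin(
    fastq_paths: Iterable[Union[str, Path]],
    refs: list[AmpliconReference],
    seed_length: int = DEFAULT_SEED_LENGTH,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    stats: Optional[dict] = None,
) -> Iterator[ReadAlignment]:
    """Ungapped end-to-end alignment of FASTQ reads against the amplicons.

    Candidate placements come from exact ``seed_length``-mer lookup of the
    read prefix and suffix, in both orientations; each candidate is
    extended end-to-end and accepted only if it is the unique placement
    with at most ``max_mismatches`` mismatches. Ties and unplaceable
    reads are discarded and counted in ``stats`` (keys: aligned,
    ambiguous, unaligned, too_short).
    """
    index = _KmerIndex(refs, seed_length)
    if stats is None:
        stats = {}
    for key in ("aligned", "ambiguous", "unaligned", "too_short"):
        stats.setdefault(key, 0)

    for path in fastq_paths:
        with pysam.FastxFile(str(path)) as fh:
            for entry in fh:
                seq = entry.sequence.upper()
                n = len(seq)
                if n < seed_length:
                    stats["too_short"] += 1
                    continue
                rc = revcomp(seq)
                candidates: set[tuple[int, int, str]] = set()
                for orient, s in (("forward", seq), ("reverse", rc)):
                    for seed, offset in ((s[:seed_length], 0),
                                         (s[-seed_length:], n - seed_length)):
                        for gi, p in index.index.get(seed, ()):
                            candidates.add((gi, p - offset, orient))
                accepted = []
                for gi, start, orient in candidates:
                    ref_arr = index.arrays[gi]
                    if start < 0 or start + n > ref_arr.shape[0]:
                        continue
                    s = seq if orient == "forward" else rc
                    read_arr = np.frombuffer(s.encode(), dtype=np.uint8)
                    mism = int(
                        np.count_nonzero(ref_arr[start : start + n] != read_arr)
                    )
                    if mism <= max_mismatches:
                        accepted.append((gi, start, orient, read_arr))
                if len(accepted) == 1:
                    gi, start, orient, read_arr = accepted[0]
                    stats["aligned"] += 1
                    yield ReadAlignment(
                        gene_id=refs[gi].gene_id,
                        positions=np.arange(start, start + n, dtype=np.int64),
                        bases=read_arr,
                        orientation=orient,
                    )
                elif len(accepted) > 1:
                    stats["ambiguous"] += 1
                else:
                    stats["unaligned"] += 1


def build_pileup(
    alignments: Iterable[ReadAlignment], refs: list[AmpliconReference]
) -> dict[str, list[PileupColumn]]:
    """Tally an alignment stream into per-gene pileup columns.

    Pure counting: one column per reference position with any A/C/G/T
    coverage, stratified by base and read orientation. Order-independent
    in the input stream.
    """
    ref_by_id = {r.gene_id: r for r in refs}
    # gene -> (L, 4 bases, 2 orientations) tally
    tallies: dict[str, np.ndarray] = {}
    base_index = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        base_index[b] = i

    for aln in alignments:
        ref = ref_by_id.get(aln.gene_id)
        if ref is None:
            raise InputError(f"alignment references unknown gene {aln.gene_id!r}")
        tally = tallies.setdefault(aln.gene_id, np.zeros((ref.length, 4, 2),
                                                         dtype=np.int64))
        oi = 0 if aln.orientation == "forward" else 1
        bi = base_index[aln.bases]
        keep = bi >= 0  # drop N / non-ACGT observations
        np.add.at(tally[:, :, oi], (aln.positions[keep], bi[keep]), 1)

    out: dict[str, list[PileupColumn]] = {}
    for gene_id, tally in tallies.items():
        cols = []
        covered = np.nonzero(tally.sum(axis=(1, 2)))[0]
        for p0 in covered:
            counts = {}
            for bi, base in enumerate(BASES):
                for oi, orient in enumerate(ORIENTATIONS):
                    c = int(tally[p0, bi, oi])
                    if c:
                        counts[(base, orient)] = c
            cols.append(PileupColumn(gene_id=gene_id, pos=int(p0) + 1,
                                     counts=counts))
        out[gene_id] = cols
    return out


def write_pileup_tsv(
    pileups: dict[str, list[PileupColumn]],
    refs: list[AmpliconReference],
    out_path: Union[str, Path],
) -> None:
    """Dump per-gene pileups as TSV for debugging."""
    ref_by_id = {r.gene_id: r for r in refs}
    header = ["gene_id", "pos", "ref"]
    header += [f"{b}_{o[:3]}" for b in BASES for o in ORIENTATIONS]
    header.append("depth")
    with open(out_path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for gene_id in sorted(pileups):
            ref = ref_by_id[gene_id]
            for col in pileups[gene_id]:
                row = [gene_id, str(col.pos), ref.sequence[col.pos - 1]]
                row += [
                    str(col.count(b, o)) for b in BASES for o in ORIENTATIONS
                ]
                row.append(str(col.depth))
                fh.write("\t".join(row) + "\n")
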