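"""Seeded simulator of EMS mutant pools and paired-end amplicon reads.

Emulates the pooled candidate-gene design: a pool of up to ~23
independently mutagenized individuals, each carrying canonical EMS
transitions (G→A, C→T) in homozygous or heterozygous state, is PCR
amplified per locus and sequenced as uniform-coverage 91 bp paired-end
reads. Reads are drawn from the pool of 2n haplotypes, so a homozygous
mutation in one individual appears on 2 of 2n haplotypes (fraction 1/n)
and a heterozygous one on 1 of 2n (fraction 1/(2n)). Sequencing error is
a uniform per-base substitution; coverage is uniform along the amplicon
(no PCR bias model) and qualities are constant — the caller ignores them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from canseq.errors import InputError
from canseq.reference import AmpliconReference, GeneModel, revcomp

CANONICAL = {"G": "A", "C": "T"}

_BASES = np.frombuffer(b"ACGT", dtype="S1")
# alternatives[i] = the three bases != _BASES[i]
_ALTERNATIVES = np.array(
    [[b for b in b"ACGT" if b != base] for base in b"ACGT"], dtype=np.uint8
)
_BASE_INDEX = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


@dataclass(frozen=True)
class SpikedMutation:
    """A canonical EMS transition seeded into one pool member."""

    gene_id: str
    pos: int  # 1-based
    ref_base: str
    alt_base: str
    zygosity: str = "homozygous"
    mutant_index: int = 1

    def __post_init__(self) -> None:
        if (self.ref_base, self.alt_base) not in (("G", "A"), ("C", "T")):
            raise InputError(
                f"non-canonical substitution {self.ref_base}->{self.alt_base} "
                f"at {self.gene_id}:{self.pos}"
            )
        if self.zygosity not in ("homozygous", "heterozygous"):
            raise InputError(f"invalid zygosity {self.zygosity!r}")
        if self.mutant_index < 1:
            raise InputError("mutant_index must be >= 1")


@dataclass
class PoolSpec:
    """Parameters of a simulated mutant pool and its sequencing run.

    ``coverage`` is the mean per-base read coverage of each amplicon.
    ``base_error_rate`` is the per-base substitution error probability
    (uniform over the three alternative bases).
    """

    n_mutants: int
    mutations: list[SpikedMutation] = field(default_factory=list)
    coverage: float = 5000.0
    read_length: int = 91
    fragment_length_mean: float = 250.0
    fragment_length_sd: float = 30.0
    base_error_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mutants < 1:
            raise InputError("n_mutants must be >= 1")
        if self.coverage <= 0:
            raise InputError("coverage must be > 0")
        if self.read_length > self.fragment_length_mean:
            raise InputError("read_length must not exceed fragment_length_mean")
        if not 0 <= self.base_error_rate:
            raise InputError("base_error_rate must be >= 0")
        if self.base_error_rate >= 0.01:
            warnings.warn(
                f"base_error_rate {self.base_error_rate} is unrealistically high",
                stacklevel=3,
            )
        for m in self.mutations:
            if m.mutant_index > self.n_mutants:
                raise InputError(
                    f"mutation at {m.gene_id}:{m.pos} assigned to mutant "
                    f"{m.mutant_index} > pool size {self.n_mutants}"
                )


_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def random_amplicon(
    seed: int,
    gene_id: str = "GENE1",
    n_codons: int = 120,
    n_exons: int = 3,
    intron_length: int = 80,
    flank_length: int = 200,
    strand: str = "forward",
) -> AmpliconReference:
    """Generate a random but structurally valid candidate-gene amplicon.

    The CDS starts with ATG, ends with a stop, contains no internal stop,
    and is split into ``n_exons`` exons separated by introns with
    canonical GT...AG boundaries. Flanks of ``flank_length`` bp surround
    the gene, mirroring amplicons that extend beyond the start and stop
    codons. Deterministic for a fixed seed.
    """
    if n_codons < max(3, n_exons):
        raise InputError("n_codons too small for the requested structure")
    rng = np.random.default_rng(seed)

    def rand_seq(n: int) -> str:
        return "".join(_BASES[i].decode() for i in rng.integers(0, 4, n))

    codons = ["ATG"]
    codons += [
        _NON_STOP_CODONS[i]
        for i in rng.integers(0, len(_NON_STOP_CODONS), n_codons - 2)
    ]
    codons.append(["TAA", "TAG", "TGA"][int(rng.integers(3))])
    cds = "".join(codons)

    # split CDS into n_exons non-empty pieces
    if n_exons > 1:
        cuts = sorted(rng.choice(np.arange(1, len(cds)), size=n_exons - 1,
                                 replace=False))
    else:
        cuts = []
    pieces = [cds[a:b] for a, b in zip([0] + list(cuts), list(cuts) + [len(cds)])]
    introns = [
        "GT" + rand_seq(max(0, intron_length - 4)) + "AG"
        for _ in range(n_exons - 1)
    ]

    parts = [rand_seq(flank_length)]
    segments = []
    offset = flank_length
    for i, piece in enumerate(pieces):
        segments.append((offset, offset + len(piece)))
        parts.append(piece)
        offset += len(piece)
        if i < len(introns):
            parts.append(introns[i])
            offset += len(introns[i])
    parts.append(rand_seq(flank_length))
    sequence = "".join(parts)

    if strand == "reverse":
        total = len(sequence)
        sequence = revcomp(sequence)
        segments = [(total - e, total - s) for s, e in reversed(segments)]
    return AmpliconReference(
        gene_id=gene_id,
        sequence=sequence,
        gene_model=GeneModel(cds_segments=segments, strand=strand),
    )


def mutagenize(
    sequence: str,
    rate: float,
    seed: int,
    gene_id: str = "",
    zygosity: str = "homozygous",
    mutant_index: int = 1,
) -> list[SpikedMutation]:
    """Apply the EMS substitution model to a sequence.

    Each G independently becomes A and each C becomes T with probability
    ``rate``; A, T and N are never touched. Deterministic for a fixed seed.
    """
    if not 0 <= rate <= 1:
        raise InputError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for i, base in enumerate(sequence.upper()):
        if base in CANONICAL and rng.random() < rate:
            out.append(
                SpikedMutation(
                    gene_id=gene_id,
                    pos=i + 1,
                    ref_base=base,
                    alt_base=CANONICAL[base],
                    zygosity=zygosity,
                    mutant_index=mutant_index,
                )
            )
    return out


def allele_fraction(spec: PoolSpec, m: SpikedMutation) -> float:
    """Expected fraction of reads carrying mutation ``m`` in the pool.

    1/n for a homozygous mutation, 1/(2n) for a heterozygous one, where n
    is the pool size.
    """
    n = spec.n_mutants
    return 1.0 / n if m.zygosity == "homozygous" else 1.0 / (2 * n)


def _haplotypes_carrying(m: SpikedMutation) -> tuple[int, ...]:
    """Indices (0-based, among 2n) of the haplotypes carrying ``m``."""
    h0 = 2 * (m.mutant_index - 1)
    return (h0, h0 + 1) if m.zygosity == "homozygous" else (h0,)


def _apply_errors(read: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    """In-place uniform substitution errors on a uint8 base array."""
    if rate <= 0:
        return
    hits = np.nonzero(rng.random(read.shape[0]) < rate)[0]
    for i in hits:
        idx = _BASE_INDEX[read[i]]
        if idx < 0:  # N — leave untouched
            continue
        read[i] = _ALTERNATIVES[idx][rng.integers(3)]


def simulate_reads(
    refs: list[AmpliconReference],
    spec: PoolSpec,
    out_dir: Union[str, Path],
    prefix: str = "pool",
) -> tuple[Path, Path, pd.DataFrame]:
    """Simulate paired-end amplicon reads from a mutant pool.

    Writes ``<prefix>_R1.fastq`` / ``<prefix>_R2.fastq`` and a
    ``<prefix>_truth.csv`` ground-truth table under ``out_dir``; returns
    the two FASTQ paths and the truth table. Byte-identical output for
    identical spec + seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    n_hap = 2 * spec.n_mutants
    rl = spec.read_length

    by_gene: dict[str, list[SpikedMutation]] = {}
    ref_by_id = {r.gene_id: r for r in refs}
    for m in spec.mutations:
        ref = ref_by_id.get(m.gene_id)
        if ref is None:
            raise InputError(f"mutation references unknown gene {m.gene_id!r}")
        if ref.sequence[m.pos - 1] != m.ref_base:
            raise InputError(
                f"{m.gene_id}:{m.pos} reference base is "
                f"{ref.sequence[m.pos - 1]}, mutation expects {m.ref_base}"
            )
        by_gene.setdefault(m.gene_id, []).append(m)

    r1_path = out_dir / f"{prefix}_R1.fastq"
    r2_path = out_dir / f"{prefix}_R2.fastq"
    qual = "I" * rl
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for ref in refs:
            length = ref.length
            if length < rl:
                raise InputError(
                    f"{ref.gene_id} is shorter ({length} bp) than the read length"
                )
            seq_arr = np.frombuffer(ref.sequence.encode(), dtype=np.uint8)
            # haplotype -> list of (0-based pos, alt byte)
            hap_muts: dict[int, list[tuple[int, int]]] = {}
            for m in by_gene.get(ref.gene_id, []):
                for h in _haplotypes_carrying(m):
                    hap_muts.setdefault(h, []).append(
                        (m.pos - 1, ord(m.alt_base))
                    )
            n_pairs = int(round(spec.coverage * length / (2 * rl)))
            for i in range(n_pairs):
                hap = int(rng.integers(n_hap))
                frag_len = int(
                    np.clip(
                        round(rng.normal(spec.fragment_length_mean,
                                         spec.fragment_length_sd)),
                        rl,
                        length,
                    )
                )
                start = int(rng.integers(0, length - frag_len + 1))
                frag = seq_arr[start : start + frag_len].copy()
                for p0, alt in hap_muts.get(hap, ()):
                    if start <= p0 < start + frag_len:
                        frag[p0 - start] = alt
                fwd = frag[:rl].copy()
                rev = np.frombuffer(
                    revcomp(frag.tobytes().decode()).encode(), dtype=np.uint8
                )[:rl].copy()
                if rng.random() < 0.5:
                    read1, read2 = fwd, rev
                else:
                    read1, read2 = rev, fwd
                _apply_errors(read1, spec.base_error_rate, rng)
                _apply_errors(read2, spec.base_error_rate, rng)
                name = f"{ref.gene_id}_{i}"
                f1.write(f"@{name}/1\n{read1.tobytes().decode()}\n+\n{qual}\n")
                f2.write(f"@{name}/2\n{read2.tobytes().decode()}\n+\n{qual}\n")

    truth = pd.DataFrame(
        [
            {
                "gene_id": m.gene_id,
                "pos": m.pos,
                "ref": m.ref_base,
                "alt": m.alt_base,
                "zygosity": m.zygosity,
                "mutant_index": m.mutant_index,
                "haplotype_fraction": len(_haplotypes_carrying(m)) / n_hap,
            }
            for m in spec.mutations
        ],
        columns=[
            "gene_id",
            "pos",
            "ref",
            "alt",
            "zygosity",
            "mutant_index",
            "haplotype_fraction",
        ],
    )
    truth.to_csv(out_dir / f"{prefix}_truth.csv", index=False)
    return r1_path, r2_path, truth
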