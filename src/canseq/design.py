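"""Pool-design arithmetic and complementation-test bookkeeping.

Classifying n independent recessive mutants into allelic groups by
pairwise complementation crosses alone requires n(n-1)/2 crosses — 780
for 40 mutants — which is what pooled candidate-gene sequencing avoids.
The pool dilution model gives the expected read share of a mutation
carried by one pool member: 100/n percent if homozygous, 100/(2n) if
heterozygous (each individual contributes two haplotypes).

Complementation logic is for recessive alleles: a wild-type F1 means the
two parents complement (different genes), so a single wild-type cross
rules a candidate out. Mutant F1s with independent partners mutated in
the same gene accumulate evidence: two or more such partners make the
candidate causative, exactly one makes it putative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from canseq.errors import ConsistencyError, InputError


@dataclass
class PoolDesign:
    """Pool size with derived expected read frequencies."""

    n_mutants: int
    threshold_percent: float = 0.75
    expected_hom_percent: float = field(init=False)
    expected_het_percent: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n_mutants < 1:
            raise InputError("n_mutants must be >= 1")
        self.expected_hom_percent = 100.0 / self.n_mutants
        self.expected_het_percent = 100.0 / (2 * self.n_mutants)
        if self.threshold_percent > self.expected_het_percent:
            warnings.warn(
                f"threshold {self.threshold_percent}% exceeds the expected "
                f"heterozygous share {self.expected_het_percent:.2f}% for a "
                f"pool of {self.n_mutants}; heterozygous mutations may be "
                "missed",
                stacklevel=3,
            )


@dataclass(frozen=True)
class CrossResult:
    """Scored F1 phenotype of one complementation cross."""

    mutant_a: str
    mutant_b: str
    gene_id: str
    f1_phenotype: str  # mutant | wildtype
    n_f1_scored: int = 3

    def __post_init__(self) -> None:
        if self.f1_phenotype not in ("mutant", "wildtype"):
            raise InputError(f"invalid f1_phenotype {self.f1_phenotype!r}")
        if self.n_f1_scored < 1:
            raise InputError("n_f1_scored must be >= 1")

    def pair(self) -> frozenset:
        return frozenset((self.mutant_a, self.mutant_b))


def crosses_required(n: int) -> int:
    """Pairwise crosses needed to classify n mutants into allelic groups."""
    if n < 2:
        raise InputError("n must be >= 2")
    return n * (n - 1) // 2


def expected_frequencies(n: int, threshold_percent: float = 0.75) -> PoolDesign:
    """Expected homozygous/heterozygous read shares for an n-mutant pool."""
    return PoolDesign(n_mutants=n, threshold_percent=threshold_percent)


def classify_complementation(
    candidate: tuple[str, str], crosses: list[CrossResult]
) -> str:
    """Classify a candidate mutation from its complementation crosses.

    ``candidate`` is (mutant id, gene_id); ``crosses`` should be the
    crosses involving that mutant against partners carrying homozygous
    mutations in the same gene. Any wild-type F1 means complementation
    and dominates → ``not_causative`` (with a consistency warning if
    mutant-F1 crosses coexist). Otherwise: >= 2 distinct mutant-F1
    partners → ``causative``; exactly 1 → ``putative``; no informative
    crosses → ``untested``.
    """
    mutant, gene_id = candidate
    seen: dict[frozenset, str] = {}
    wildtype_partners = []
    mutant_partners = []
    for cross in crosses:
        if cross.gene_id != gene_id:
            continue
        if mutant not in (cross.mutant_a, cross.mutant_b):
            continue
        partner = cross.mutant_b if cross.mutant_a == mutant else cross.mutant_a
        key = cross.pair()
        if key in seen and seen[key] != cross.f1_phenotype:
            raise ConsistencyError(
                f"conflicting duplicate records for cross {sorted(key)}"
            )
        seen[key] = cross.f1_phenotype
        if cross.f1_phenotype == "wildtype":
            wildtype_partners.append(partner)
        else:
            mutant_partners.append(partner)
    if wildtype_partners:
        if mutant_partners:
            warnings.warn(
                f"{mutant}/{gene_id}: both complementing and "
                "non-complementing crosses recorded; classifying as "
                "not_causative (wildtype F1 dominates) — check the data",
                stacklevel=2,
            )
        return "not_causative"
    n_partners = len(set(mutant_partners))
    if n_partners >= 2:
        return "causative"
    if n_partners == 1:
        return "putative"
    return "untested"
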