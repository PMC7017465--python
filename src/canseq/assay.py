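"""CAPS and dCAPS genotyping assay design for called variants.

A CAPS assay exists when the variant itself creates or destroys a
restriction site, so digesting a PCR product spanning the variant
distinguishes the two alleles. When no natural site difference exists, a
dCAPS assay engineers one: a PCR primer ending just 5' of the variant
carries one or more deliberate mismatches near its 3' end, so that the
amplified product completes an enzyme site together with one allele's
variant base but not the other's.

Primer thermodynamics (melting temperature, secondary structure,
specificity) are not modelled and must be checked at the bench; the
default primer length is 25 nt.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from pathlib import Path
from typing import Optional, Union

from canseq.calling import VariantCall
from canseq.errors import InputError
from canseq.reference import AmpliconReference, revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def iupac_revcomp(site: str) -> str:
    return site.translate(_IUPAC_COMPLEMENT)[::-1]


def iupac_match(seq: str, site: str) -> bool:
    """True if ``seq`` (ACGT, same length) matches the IUPAC ``site``."""
    if len(seq) != len(site):
        return False
    return all(b in IUPAC[s] for b, s in zip(seq, site))


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme's recognition site in IUPAC code."""

    name: str
    recognition_site: str

    def __post_init__(self) -> None:
        site = self.recognition_site.upper()
        if not site:
            raise InputError(f"{self.name}: empty recognition site")
        bad = set(site) - set(IUPAC)
        if bad:
            raise InputError(f"{self.name}: invalid IUPAC letters {sorted(bad)}")
        object.__setattr__(self, "recognition_site", site)

    @property
    def site_length(self) -> int:
        return len(self.recognition_site)


#: Common 6-cutters (palindromic and degenerate-site) for CAPS screening.
_BUILTIN = [
    ("EcoRI", "GAATTC"), ("HindIII", "AAGCTT"), ("BamHI", "GGATCC"),
    ("EcoRV", "GATATC"), ("XbaI", "TCTAGA"), ("SpeI", "ACTAGT"),
    ("PstI", "CTGCAG"), ("SalI", "GTCGAC"), ("XhoI", "CTCGAG"),
    ("KpnI", "GGTACC"), ("SacI", "GAGCTC"), ("SphI", "GCATGC"),
    ("NcoI", "CCATGG"), ("NdeI", "CATATG"), ("BglII", "AGATCT"),
    ("ClaI", "ATCGAT"), ("DraI", "TTTAAA"), ("SspI", "AATATT"),
    ("HpaI", "GTTAAC"), ("ScaI", "AGTACT"), ("HincII", "GTYRAC"),
    ("AflIII", "ACRYGT"),
]


def builtin_enzymes() -> list[EnzymeSpec]:
    """The built-in enzyme catalogue (users may supply their own TSV)."""
    return [EnzymeSpec(name, site) for name, site in _BUILTIN]


def load_enzyme_table(path: Union[str, Path]) -> list[EnzymeSpec]:
    """Load an enzyme table from TSV (columns: name, IUPAC site)."""
    enzymes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise InputError(f"malformed enzyme table line: {line!r}")
            enzymes.append(EnzymeSpec(parts[0], parts[1]))
    if not enzymes:
        raise InputError(f"no enzymes found in {path}")
    return enzymes


@dataclass(frozen=True)
class AssayDesign:
    """A genotyping assay distinguishing the two alleles of a variant.

    ``cut_allele`` names the allele whose sequence contains the enzyme
    site. ``primer`` and ``introduced_mismatches`` apply to dCAPS only;
    ``site_start`` is the 1-based start of the matched site window in the
    coordinate frame of ``strand`` ("forward" = reference top strand).
    """

    variant: VariantCall
    mode: str  # CAPS | dCAPS
    enzyme: EnzymeSpec
    cut_allele: str  # reference | mutant
    primer: str = ""
    introduced_mismatches: int = 0
    site_start: Optional[int] = None
    strand: str = "forward"


def _site_at(seq: str, start: int, enzyme: EnzymeSpec) -> bool:
    """Enzyme site present at 0-based ``start`` in either orientation?"""
    window = seq[start : start + enzyme.site_length]
    if len(window) < enzyme.site_length:
        return False
    return iupac_match(window, enzyme.recognition_site) or iupac_match(
        window, iupac_revcomp(enzyme.recognition_site)
    )


def find_caps(
    variant: VariantCall,
    ref: AmpliconReference,
    enzymes: Optional[list[EnzymeSpec]] = None,
) -> list[AssayDesign]:
    """Find natural CAPS assays for a variant.

    For each enzyme, every site-length window overlapping the variant is
    tested on both alleles (IUPAC matching, both orientations of the
    site); a design is emitted wherever exactly one allele matches.
    Deterministic order: enzyme list order, then window position.
    """
    if enzymes is None:
        enzymes = builtin_enzymes()
    p0 = variant.pos - 1
    if not 0 <= p0 < ref.length:
        raise InputError(f"variant position {variant.pos} outside reference")
    ref_seq = ref.sequence
    alt_seq = ref_seq[:p0] + variant.alt_base + ref_seq[p0 + 1 :]
    designs = []
    for enzyme in enzymes:
        L = enzyme.site_length
        windows = range(max(0, p0 - L + 1), min(p0 + 1, len(ref_seq) - L + 1))
        ref_hits = [s for s in windows if _site_at(ref_seq, s, enzyme)]
        alt_hits = [s for s in windows if _site_at(alt_seq, s, enzyme)]
        # exclusivity is molecule-level: the digest only distinguishes the
        # alleles when exactly one of them is cut anywhere over the variant
        if bool(ref_hits) == bool(alt_hits):
            continue
        cut_allele = "reference" if ref_hits else "mutant"
        for start in ref_hits or alt_hits:
            designs.append(
                AssayDesign(
                    variant=variant,
                    mode="CAPS",
                    enzyme=enzyme,
                    cut_allele=cut_allele,
                    site_start=start + 1,
                )
            )
    return designs


def design_dcaps(
    variant: VariantCall,
    ref: AmpliconReference,
    enzyme: EnzymeSpec,
    primer_length: int = 25,
    max_intro_mismatches: int = 1,
) -> Optional[AssayDesign]:
    """Search for a dCAPS primer creating an allele-specific enzyme site.

    Candidate primers end 1..site_length-1 bases 5' of the variant, on
    either strand, with up to ``max_intro_mismatches`` substitutions in
    the primer's 3' region (never at the 3'-terminal base, never at the
    variant). The first candidate whose rewritten amplicon completes the
    enzyme site on exactly one allele is returned; candidates are tried
    with fewer mismatches first, then smaller distance to the variant.
    Returns None when no design exists within these bounds.
    """
    if primer_length < enzyme.site_length + 4:
        raise InputError("primer_length must be >= site_length + 4")
    if max_intro_mismatches < 0:
        raise InputError("max_intro_mismatches must be >= 0")
    p0 = variant.pos - 1
    frames = [
        ("forward", ref.sequence, p0, variant.ref_base, variant.alt_base),
        (
            "reverse",
            revcomp(ref.sequence),
            ref.length - 1 - p0,
            revcomp(variant.ref_base),
            revcomp(variant.alt_base),
        ),
    ]
    L = enzyme.site_length
    for n_mm in range(max_intro_mismatches + 1):
        for d in range(1, L):
            for strand, seq, q0, rbase, abase in frames:
                design = _try_primer(
                    variant, enzyme, strand, seq, q0, rbase, abase,
                    d, primer_length, n_mm,
                )
                if design is not None:
                    return design
    return None


def _try_primer(
    variant: VariantCall,
    enzyme: EnzymeSpec,
    strand: str,
    seq: str,
    q0: int,
    ref_base: str,
    alt_base: str,
    d: int,
    primer_length: int,
    n_mm: int,
) -> Optional[AssayDesign]:
    """Try all ``n_mm``-mismatch primers ending ``d`` bases 5' of q0."""
    L = enzyme.site_length
    primer_end = q0 - d  # exclusive index of primer 3' end + 1
    primer_start = primer_end - primer_length
    if primer_start < 0 or primer_end > len(seq):
        return None
    # 3' region eligible for engineered mismatches: last site_length bases
    # of the primer minus the 3'-terminal base.
    region = range(max(primer_start, primer_end - L), primer_end - 1)
    for positions in combinations(region, n_mm):
        alt_choices = [
            [b for b in "ACGT" if b != seq[p]] for p in positions
        ]
        for bases in product(*alt_choices):
            rewritten = list(seq)
            for p, b in zip(positions, bases):
                rewritten[p] = b
            ref_allele = "".join(rewritten[:q0]) + ref_base + "".join(rewritten[q0 + 1 :])
            alt_allele = "".join(rewritten[:q0]) + alt_base + "".join(rewritten[q0 + 1 :])
            windows = range(max(0, q0 - L + 1), min(q0 + 1, len(seq) - L + 1))
            ref_hits = [s for s in windows if _site_at(ref_allele, s, enzyme)]
            alt_hits = [s for s in windows if _site_at(alt_allele, s, enzyme)]
            if bool(ref_hits) != bool(alt_hits):
                primer = "".join(rewritten[primer_start:primer_end])
                return AssayDesign(
                    variant=variant,
                    mode="dCAPS",
                    enzyme=enzyme,
                    cut_allele="reference" if ref_hits else "mutant",
                    primer=primer,
                    introduced_mismatches=n_mm,
                    site_start=(ref_hits or alt_hits)[0] + 1,
                    strand=strand,
                )
    return None


def rewritten_alleles(
    design: AssayDesign, ref: AmpliconReference
) -> tuple[str, str]:
    """Full (reference, mutant) amplicon sequences implied by a design.

    For CAPS these are the natural alleles; for dCAPS the primer region
    is replaced by the primer. Both are returned in the design's strand
    frame, for independent re-checking of allele-specific cutting.
    """
    variant = design.variant
    p0 = variant.pos - 1
    if design.strand == "reverse":
        seq = revcomp(ref.sequence)
        q0 = ref.length - 1 - p0
        rbase, abase = revcomp(variant.ref_base), revcomp(variant.alt_base)
    else:
        seq = ref.sequence
        q0 = p0
        rbase, abase = variant.ref_base, variant.alt_base
    if design.mode == "dCAPS" and design.primer:
        # locate the primer: it ends 1..site_length-1 bases 5' of the variant
        n = len(design.primer)
        placed = None
        for d in range(1, design.enzyme.site_length):
            start = q0 - d - n
            if start < 0:
                continue
            window = seq[start : start + n]
            if sum(a != b for a, b in zip(window, design.primer)) == \
                    design.introduced_mismatches:
                placed = start
                break
        if placed is None:
            raise InputError("primer does not place on the reference")
        seq = seq[:placed] + design.primer + seq[placed + n :]
    ref_allele = seq[:q0] + rbase + seq[q0 + 1 :]
    alt_allele = seq[:q0] + abase + seq[q0 + 1 :]
    return ref_allele, alt_allele
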