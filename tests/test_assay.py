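"""CAPS/dCAPS design: allele-exclusive cutting, checked independently."""

from itertools import combinations, product

import numpy as np
import pytest

from canseq.assay import (
    AssayDesign,
    EnzymeSpec,
    builtin_enzymes,
    design_dcaps,
    find_caps,
    iupac_revcomp,
    load_enzyme_table,
    rewritten_alleles,
)
from canseq.calling import VariantCall
from canseq.errors import InputError
from canseq.reference import AmpliconReference
from canseq.simulate import CANONICAL, random_amplicon

ECORI = EnzymeSpec("EcoRI", "GAATTC")

# Independent IUPAC matcher (kept deliberately separate from the package's)
_IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"}, "B": {"C", "G", "T"},
    "D": {"A", "G", "T"}, "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}


def _matches(window, site):
    return len(window) == len(site) and all(
        b in _IUPAC[s] for b, s in zip(window, site)
    )


def _cuts_near(seq, q0, enzyme):
    """Does any site window overlapping position q0 match either strand?"""
    L = len(enzyme.recognition_site)
    rc = iupac_revcomp(enzyme.recognition_site)
    for start in range(max(0, q0 - L + 1), min(q0 + 1, len(seq) - L + 1)):
        w = seq[start : start + L]
        if _matches(w, enzyme.recognition_site) or _matches(w, rc):
            return True
    return False


def _variant(ref, pos, alt):
    return VariantCall(
        gene_id=ref.gene_id, pos=pos, ref_base=ref.sequence[pos - 1],
        alt_base=alt, depth=1000, variant_reads=43, variant_fwd=20,
        variant_rev=23,
    )


class TestEnzymeSpec:
    def test_invalid_iupac_rejected(self):
        with pytest.raises(InputError):
            EnzymeSpec("Bad", "GAAXTC")
        with pytest.raises(InputError):
            EnzymeSpec("Empty", "")

    def test_builtin_table_is_valid(self):
        enzymes = builtin_enzymes()
        assert len(enzymes) >= 20
        assert {"EcoRI", "HindIII"} <= {e.name for e in enzymes}

    def test_load_tsv(self, tmp_path):
        path = tmp_path / "enzymes.tsv"
        path.write_text("# name\tsite\nEcoRI\tGAATTC\nHincII\tGTYRAC\n")
        enzymes = load_enzyme_table(path)
        assert [e.name for e in enzymes] == ["EcoRI", "HincII"]


class TestFindCaps:
    def test_site_gain_on_mutant_allele(self):
        # GAATCC -> C>T at base 5 gives GAATTC (EcoRI) on the mutant only
        ref = AmpliconReference("X", "TTTTGAATCCTTTT")
        variant = _variant(ref, 9, "T")
        designs = find_caps(variant, ref, [ECORI])
        assert designs and all(d.cut_allele == "mutant" for d in designs)
        assert designs[0].mode == "CAPS"

    def test_site_loss_on_reference_allele(self):
        # GAATTC with G>A at base 1 destroys the site on the mutant
        ref = AmpliconReference("X", "TTTTGAATTCTTTT")
        variant = _variant(ref, 5, "A")
        designs = find_caps(variant, ref, [ECORI])
        assert designs and all(d.cut_allele == "reference" for d in designs)

    def test_no_site_difference_gives_empty_list(self):
        ref = AmpliconReference("X", "TTTTTGTTTTTTT")
        variant = _variant(ref, 6, "A")
        assert find_caps(variant, ref, [ECORI]) == []

    def test_symmetry_under_allele_swap(self):
        # swapping ref/alt flips cut_allele
        gain = AmpliconReference("X", "TTTTGAATCCTTTT")
        loss = AmpliconReference("X", "TTTTGAATTCTTTT")
        d_gain = find_caps(_variant(gain, 9, "T"), gain, [ECORI])
        # C>T gain of site mirrors the T>C loss read from the other allele:
        # here exercised via the canonical pair G>A destroying the site
        d_loss = find_caps(_variant(loss, 5, "A"), loss, [ECORI])
        assert {d.cut_allele for d in d_gain} == {"mutant"}
        assert {d.cut_allele for d in d_loss} == {"reference"}


def _brute_force_dcaps_exists(seq, q0, ref_base, alt_base, enzyme,
                              primer_length, max_mm):
    """Exhaustive search over every primer placement/mismatch choice."""
    from canseq.reference import revcomp

    L = len(enzyme.recognition_site)
    frames = [
        (seq, q0, ref_base, alt_base),
        (revcomp(seq), len(seq) - 1 - q0, revcomp(ref_base),
         revcomp(alt_base)),
    ]
    for wseq, wq0, rbase, abase in frames:
        for d in range(1, L):
            end = wq0 - d
            start = end - primer_length
            if start < 0 or end > len(wseq):
                continue
            region = list(range(max(start, end - L), end - 1))
            for n_mm in range(0, max_mm + 1):
                for positions in combinations(region, n_mm):
                    choices = [[b for b in "ACGT" if b != wseq[p]]
                               for p in positions]
                    for bases in product(*choices):
                        rew = list(wseq)
                        for p, b in zip(positions, bases):
                            rew[p] = b
                        ra = "".join(rew[:wq0]) + rbase + "".join(rew[wq0 + 1:])
                        aa = "".join(rew[:wq0]) + abase + "".join(rew[wq0 + 1:])
                        if _cuts_near(ra, wq0, enzyme) != _cuts_near(
                            aa, wq0, enzyme
                        ):
                            return True
    return False


class TestDesignDcaps:
    def test_single_mismatch_completes_site_on_one_allele(self):
        # Around the variant G (pos 11): sequence ...GAAT C C...
        # ref GAATCC needs C->T one base 5' of nothing... construct:
        # we want primer mismatch + variant to complete GAATTC on ref allele
        # variant G>A at pos 11; upstream GAAT; site GAATTC would need
        # positions 7..12 = GAAT?G -> with primer rewriting base 11 is the
        # variant. Simpler: verified through the soundness re-check below.
        ref = AmpliconReference("X", "ACGTACGTACGTACGTACGATCGGACCTGCAGGT"
                                     "GAATCGTTACGATCAGT")
        # pos 40 base? find a canonical G or C with no natural CAPS
        seq = ref.sequence
        pos = 40
        assert seq[pos - 1] in CANONICAL
        variant = _variant(ref, pos, CANONICAL[seq[pos - 1]])
        design = design_dcaps(variant, ref, ECORI, primer_length=25,
                              max_intro_mismatches=2)
        if design is not None:
            assert design.mode == "dCAPS"
            assert 0 <= design.introduced_mismatches <= 2
            ra, aa = rewritten_alleles(design, ref)
            q0 = (pos - 1 if design.strand == "forward"
                  else ref.length - pos)
            assert _cuts_near(ra, q0, ECORI) != _cuts_near(aa, q0, ECORI)

    def test_zero_mismatches_reduces_to_caps_failure(self):
        ref = AmpliconReference("X", "T" * 30 + "G" + "T" * 30)
        variant = _variant(ref, 31, "A")
        assert find_caps(variant, ref, [ECORI]) == []
        assert design_dcaps(variant, ref, ECORI, primer_length=25,
                            max_intro_mismatches=0) is None

    def test_primer_length_precondition(self):
        ref = AmpliconReference("X", "T" * 61)
        variant = _variant(ref, 31, "A")  # T is not canonical; build G
        ref = AmpliconReference("X", "T" * 30 + "G" + "T" * 30)
        variant = _variant(ref, 31, "A")
        with pytest.raises(InputError):
            design_dcaps(variant, ref, ECORI, primer_length=8)

    def test_matches_brute_force_on_small_instances(self, no_stop_warning):
        """If exhaustive search finds any design, design_dcaps finds one."""
        rng = np.random.default_rng(17)
        ref = random_amplicon(seed=33, n_codons=40, n_exons=1,
                              flank_length=40)
        positions = [
            p + 1 for p in range(30, ref.length - 30)
            if ref.sequence[p] in CANONICAL
        ]
        for pos in rng.choice(positions, size=12, replace=False):
            pos = int(pos)
            variant = _variant(ref, pos, CANONICAL[ref.sequence[pos - 1]])
            got = design_dcaps(variant, ref, ECORI, primer_length=25,
                               max_intro_mismatches=1)
            expected = _brute_force_dcaps_exists(
                ref.sequence, pos - 1, variant.ref_base, variant.alt_base,
                ECORI, 25, 1,
            )
            assert (got is not None) == expected


class TestSoundness:
    """Every emitted design cuts exactly one allele under the
    independent matcher."""

    def test_caps_designs_on_random_variants(self, no_stop_warning):
        ref = random_amplicon(seed=50, n_codons=150, n_exons=2)
        rng = np.random.default_rng(5)
        enzymes = builtin_enzymes()
        positions = [p + 1 for p in range(ref.length)
                     if ref.sequence[p] in CANONICAL]
        n_designs = 0
        for pos in rng.choice(positions, size=80, replace=False):
            pos = int(pos)
            variant = _variant(ref, pos, CANONICAL[ref.sequence[pos - 1]])
            for design in find_caps(variant, ref, enzymes):
                n_designs += 1
                ra, aa = rewritten_alleles(design, ref)
                assert _cuts_near(ra, pos - 1, design.enzyme) != _cuts_near(
                    aa, pos - 1, design.enzyme
                )
                expected_cut = ra if design.cut_allele == "reference" else aa
                assert _cuts_near(expected_cut, pos - 1, design.enzyme)
        assert n_designs > 0  # the screen found at least some assays

    def test_dcaps_designs_on_random_variants(self, no_stop_warning):
        ref = random_amplicon(seed=51, n_codons=120, n_exons=1)
        rng = np.random.default_rng(6)
        positions = [p + 1 for p in range(30, ref.length - 30)
                     if ref.sequence[p] in CANONICAL]
        enzymes = builtin_enzymes()[:6]
        n_designs = 0
        for pos in rng.choice(positions, size=15, replace=False):
            pos = int(pos)
            variant = _variant(ref, pos, CANONICAL[ref.sequence[pos - 1]])
            for enzyme in enzymes:
                design = design_dcaps(variant, ref, enzyme,
                                      primer_length=25,
                                      max_intro_mismatches=1)
                if design is None:
                    continue
                n_designs += 1
                ra, aa = rewritten_alleles(design, ref)
                q0 = (pos - 1 if design.strand == "forward"
                      else ref.length - pos)
                cut_ra = _cuts_near(ra, q0, enzyme)
                cut_aa = _cuts_near(aa, q0, enzyme)
                assert cut_ra != cut_aa
                assert (design.cut_allele == "reference") == cut_ra
        assert n_designs > 0
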