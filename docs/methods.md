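# Methods

## Pool dilution model

A pool of n independently mutagenized individuals contributes 2n
haplotypes to the PCR template. A mutation that is homozygous in one
individual sits on 2 of the 2n haplotypes and is expected in 1/n of the
reads covering its position; a heterozygous mutation sits on 1 haplotype
and is expected in 1/(2n). For the reference pool size n = 23 this gives
~4.35% and ~2.17%. `PoolDesign` carries these expectations; a warning is
emitted when the configured detection threshold exceeds the heterozygous
expectation, since heterozygous mutations then become undetectable in
principle.

EMS chemistry is modelled as canonical transitions only: each G→A and
C→T independently, nothing else. `mutagenize` applies this per eligible
base with a configurable rate; `SpikedMutation` rejects non-canonical
pairs at construction.

## Coordinates and gene models

Internally all intervals are 0-based half-open; every user-facing
position (function arguments, CSV, VCF, GenBank features) is 1-based
inclusive, the GenBank convention. A gene model is the ordered list of
CDS segments from a single CDS feature (`join()` locations give multiple
segments, `complement()` sets the reverse strand). Validation: segments
sorted and non-overlapping, total CDS length a multiple of 3 (error),
CDS starting with ATG and ending with a stop (warning only, so partial
models remain usable for annotation). Introns are the gaps between
consecutive CDS segments; the first two intronic bases in transcription
order are the splice donor window, the last two the acceptor window —
the canonical GT/AG dinucleotides, the minimal defensible definition of
a splice-site variant. Positions outside the CDS span are `flank`; they
are reported but never classified as protein-changing.

Codon numbering starts at the annotated initiator Met = 1. On
reverse-strand genes, codon numbering runs against reference
coordinates and bases are complemented into mRNA sense before
translation (standard nuclear genetic code). A variant preserving the
natural stop codon is reported as `stop_codon_silent`; a stop-loss —
unreachable under canonical-only transitions — would be reported as
missense with a warning.

## Simulator

`simulate_reads` emulates equimolar pooled-amplicon sequencing: read
pairs are drawn uniformly along each amplicon (number of pairs =
coverage × length / (2 × read length)), each pair from a haplotype
chosen uniformly among the 2n, fragment lengths normal (mean 250 bp,
sd 30, clipped to [read length, amplicon length]), read length 91 bp,
strand of origin random. Sequencing error is a uniform per-base
substitution over the three alternative bases (default 1e-3, warning
above 1%); there are no indel errors, no PCR or coverage bias, no
chimeric artifacts, and base qualities are constant — the caller
ignores qualities, assuming reads were quality-trimmed upstream.
Output is byte-identical for identical spec and seed.

Consequently, passing tests demonstrate the pipeline's behaviour under
idealized uniform coverage and error; they do not probe adapter
contamination, quality degradation along the read, PCR jackpot
duplicates or coverage troughs that real libraries show. The defaults
(pool of 23, 5000× coverage, 91 bp pairs, 1e-3 error) reflect the
pooled-amplicon study design this package targets; per-amplicon coverage
in such experiments is a free parameter and is exposed as one.

`random_amplicon` builds structurally valid synthetic candidate genes
(ATG…stop CDS without internal stops, GT…AG introns, 200 bp flanks
mirroring amplicons that extend beyond the start/stop codons) for tests
and the acceptance script.

## Alignment and pileup

The built-in aligner is ungapped and end-to-end: exact 31-mer seeds
(read prefix and suffix, both orientations) against a k-mer index of the
references, candidates extended and accepted only when a unique
placement has ≤ 3 mismatches per 91 bp read. Ties are discarded, never
randomly assigned — at a 0.75% detection threshold, cross-amplicon
bleed-through from repeated sequence would be a direct false-positive
mechanism. Substitution-only alignment is sufficient because the
simulator and the EMS model emit substitutions only; gapped or local
alignment is out of scope, and externally aligned SAM/BAM (parsed with
pysam; unmapped/secondary/supplementary records skipped, insertions
contribute no reference-anchored observation) is the escape hatch for
anything richer. Read pairs are aligned independently (amplicon
geometry makes proper-pair constraints uninformative) and duplicates
are retained (amplicon libraries are duplicates by construction;
deduplication would destroy the frequency signal).

Pileup construction is a pure tally: per position, per base (A/C/G/T
only — N and gaps excluded from counts and depth), per read
orientation. It is order-independent and is property-tested against a
brute-force per-observation counter.

## Filter cascade

All five thresholds are inclusive (≥): canonical pair, depth ≥ 200,
variant reads ≥ 30, per-strand variant reads ≥ 5, frequency ≥ 0.75% of
column depth. The frequency denominator is the full column depth (all
counted A/C/G/T observations), the simplest defensible reading of
"percent of reads covering the position". The canonical test is applied
on the reference top strand only; multiple alternative bases at one
position are each evaluated (canonical-only admits at most one).
Zygosity hints compare the called frequency with the pool expectations:
at or above the midpoint of the homozygous and heterozygous
expectations → homozygous-like, at or above half the heterozygous
expectation → heterozygous-like, else indeterminate. Hints are advisory
and never gate filtering.

At the default error rate (1e-3 per base, spread over three alternative
bases) and 5000× depth, a specific substitution error accumulates ~1.7
reads on expectation — far below both the 30-read and 0.75% (≥ 37.5
reads at 5000×) requirements simultaneously, which is why an unmutated
pool yields zero calls across seeds (verified empirically in the
acceptance suite).

## Assay design

CAPS: for each enzyme, every recognition-site window overlapping the
variant is matched (IUPAC codes, both orientations of the site) on both
alleles; designs are emitted only when exactly one allele is cut
anywhere over the variant — exclusivity is molecule-level, since a
digest cannot distinguish which window cut. dCAPS: candidate primers
end 1..site_length−1 bases 5′ of the variant on either strand, with up
to a configurable number of engineered mismatches in the primer's 3′
region (the last site-length bases, never the 3′-terminal base, never
the variant); the first candidate whose rewritten amplicon completes
the site on exactly one allele wins, searching fewer mismatches first,
then smaller distance to the variant. The search is exhaustive within
these bounds (tested against brute-force enumeration). Primer melting
temperature, specificity and secondary structure are deliberately not
modelled — they are bench checks; the default primer length is 25 nt.
A built-in table of 22 common 6-cutters is included; users supply their
own as TSV (name, IUPAC site).

## Complementation classification

Recessive-allele logic over scored F1 phenotypes: any wild-type F1
(complementation) dominates and classifies the candidate mutation as
not_causative, with a consistency warning if non-complementing crosses
coexist; otherwise ≥ 2 distinct non-complementing partners carrying
homozygous mutations in the same gene → causative, exactly 1 →
putative, none → untested. Conflicting duplicate records for the same
pair raise an error rather than being resolved silently. There is no
"inconclusive" state: ambiguous rows must be resolved upstream or will
surface via the conflict warning.

## Numerical and I/O choices

- Randomness: a single `numpy.random.default_rng(seed)` per simulation;
  identical inputs, configuration and seed give byte-identical FASTQ,
  CSV and GenBank outputs.
- CSV frequencies are printed to two decimals; rows sorted by
  (gene_id, pos, alt). The CSV schema is a superset of the minimal
  location/abundance report: strand counts, consequence and zygosity
  hint ride along.
- The annotated GenBank output preserves the original record and its
  features, appending one `variation` feature per call; when a reference
  was constructed in memory, a CDS feature is synthesized so the gene
  model survives the round-trip.
- Degenerate inputs: zero-depth pileup columns are skipped; reference-N
  columns are skipped with a warning; a mutation spiked onto a
  non-matching reference base is an error.

## Problem sizes in the test and acceptance runs

The simulation-based checks use one ~1.1 kb two-exon amplicon, a pool
of 23, 5000× mean coverage (≈ 30k read pairs per replicate) and 10
seeded replicates, which reproduces the ~4% homozygous recovery band
comfortably while keeping a full run of suite plus acceptance script in
the low minutes on a single core. The oracle suites use ≥ 1000 random
pileup columns and ≥ 1000 random CDS variants per run.

## Known limitations

- No gapped alignment and no indel calling: EMS-scope only.
- The uniform-coverage, uniform-error simulator understates the tail
  risks of real libraries (see above).
- The dCAPS search optimizes digest feasibility only, not primer
  thermodynamics.
- Multi-record references for one gene (a locus amplified in pieces)
  are not merged; supply one record per locus.
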