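# canseq

Detection of EMS-induced point mutations in deep-sequenced candidate-gene
amplicons from pools of mutant individuals.

## The problem

In a forward genetic screen, many of the recovered mutants carry new
alleles of genes already known to affect the trait. Classifying n mutants
into allelic groups by pairwise complementation crosses alone needs
n(n−1)/2 crosses (780 for 40 mutants). A cheaper route is to pool genomic
DNA from up to ~23 independent mutants, PCR-amplify each known or
candidate gene from the pool, deep-sequence the amplicons, and look for
low-frequency variant nucleotides: a homozygous mutation carried by one
member of an n-mutant pool appears in ~1/n of the reads covering its
position (~4% for n = 23), a heterozygous one in ~1/(2n) (~2%).

Because EMS (ethyl methanesulfonate) almost exclusively induces G:C→A:T
transitions, the search space is restricted to canonical G→A and C→T
substitutions as written on the reference top strand (a bottom-strand
G→A reads as C→T on top, so both physical strands are covered). A filter
cascade separates these sub-5% true variants from sequencing error; by
default a variant is called when, at its position,

- depth ≥ 200 reads,
- variant reads ≥ 30,
- variant reads on each strand ≥ 5 (rejects strand-specific errors),
- variant frequency ≥ 0.75% of coverage,

all comparisons inclusive. Called variants are classified against the
gene model (nonsense / missense / silent / splice donor / splice
acceptor / intronic / flank, with protein notation such as `W227*`), and
CAPS/dCAPS restriction assays can be designed to genotype individual
pool members. A seeded simulator generates mutant pools and 91 bp
paired-end amplicon reads with ground truth, so the whole pipeline is
testable offline.

## Worked example

Simulate a 23-mutant pool in which mutant #1 is homozygous for a G→A
substitution at position 592 of a ~1.1 kb candidate-gene amplicon, then
run the full pipeline:

```sh
canseq simulate --refs refs --pool-size 23 --spike CAND1:592:homozygous \
    --coverage 5000 --out sim --seed 11
canseq call --refs refs --fastq sim/pool_R1.fastq sim/pool_R2.fastq \
    --pool-size 23 --out out
cat out/variants.csv
```

```
gene_id,pos,ref,alt,freq_percent,depth,variant_reads,variant_fwd,variant_rev,consequence_kind,protein_change,intron_index,zygosity_hint
CAND1,592,G,A,4.01,6905,277,148,129,nonsense,W131*,,homozygous-like
```

Exactly the spiked variant is recovered: a G→A at position 592, seen in
277 of 6905 reads (4.01%, close to the expected 1/23 ≈ 4.35%), balanced
across strands, creating a premature stop at codon 131 (`W131*`). The
frequency is consistent with a homozygous mutation in one pool member
(`homozygous-like`); true zygosity would be established by genotyping
individuals, e.g. with a restriction assay:

```sh
canseq assay --ref refs/CAND1.gb --pos 560 --alt A
# CAPS  ScaI  AGTACT  cut=reference  primer=-  mismatches=0
canseq design --pool-size 23
# {"n_mutants": 23, "expected_hom_percent": 4.3478,
#  "expected_het_percent": 2.1739, "threshold_percent": 0.75,
#  "crosses_required": 253}
```

`canseq call` also writes one variant-annotated GenBank file per gene
and a machine-readable `summary.json`. Other subcommands: `annotate`
(classify a single substitution) and `complement` (classify a candidate
mutation as causative / putative / not_causative from a table of
complementation-cross results).

## Library use

Every stage is available as a plain function:
`load_reference`, `simulate_reads`, `align_builtin` / `parse_sam`,
`build_pileup`, `call_variants`, `annotate`, `find_caps` /
`design_dcaps`, `expected_frequencies`, `classify_complementation`,
`run_pipeline`. See `docs/methods.md` for the model and all parameter
conventions.

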