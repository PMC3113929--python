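# Methods

## Scope and shape

`polytill` models a reverse-genetics mutation screen in an allotetraploid:
EMS mutagenesis of an M2 population, homeolog-specific nested PCR, CEL1
heteroduplex-cleavage detection with four-fold pooling, deconvolution and
zygosity calling, mutation-effect annotation, CAPS marker design, Southern
fragment-count prediction, and edge-corrected mutation-density estimation.
The library is organized as seven submodules (`genemodels`, `popsim`,
`insilico_pcr`, `celscreen`, `annotate`, `restriction`, `stats`) with a
Model/Results facade on top: `TillingScreen(population, genes, schemes)`
holds the experimental design, `fit()` executes the screen, and
`TillingScreenResults` carries the confirmed-mutation table, tallies,
density estimates and `summary()`.

## Coordinate conventions

All sequences are stored on the plus strand; reverse-strand genes must be
reverse-complemented at load time. Three 1-based coordinate systems are
mapped explicitly: locus (within the stored sequence), ATG-anchored
(mutation-table convention: +1 is the A of the start codon, −1 the base
5' of it, no zero), and concatenated-CDS. Anchored coordinates of
intron-bearing genes are intron-inclusive counts from the ATG; for
intronless genes they coincide with CDS coordinates. Intervals are closed.

## The EMS population model

Per M1 individual and locus of length L, the induced mutation count is
Poisson(ρ·L), with ρ the per-bp density (the benchmark regime is
ρ ≈ 1.4 × 10⁻⁶, giving a *retained* M2 density of about 1/966,000 bp —
roughly one mutation per 966 kb screened). A fraction
`canonical_fraction` (default 1.0) of lesions are G→A or C→T transitions
placed uniformly over G/C sites of the stored strand; the remainder are
random substitutions at any site. No local sequence-context model is used
beyond the G/C requirement, and M1 plants are treated as non-chimeric
single genotypes, so every lesion is heterozygous in M1 and transmits to
the single M2 descendant as hom : het : lost = 1 : 2 : 1. A site drawn
twice within one individual is re-drawn with a warning. Contaminant
alleles — pre-existing variants in the seed stock — are layered on
independently per individual at fixed frequencies, always heterozygous;
the benchmark provides a single-A insertion (2/3420) and an A→G
substitution (3/3420) as defaults via `seed_stock_contaminants()`.

What the simulator deliberately does not model: germination or lethality
dose response, chimeric M1 sectors, linkage between loci, and
mutagen-specific chemistry beyond the transition bias (a treatment that
induces nothing is simply ρ = 0).

## Amplification

Primer binding is exact ungapped matching by default; when mismatches are
allowed, the 3'-terminal 3 bases must still match exactly (polymerase
extension is 3'-anchored). Homeolog specificity therefore comes from
primers spanning discriminating indels or divergent regions, exactly as in
practice — no melting-temperature or dimer thermodynamics are modeled,
and cycling programs are metadata. Products are capped at 5 kb (all
realistic screen amplicons are under 2.3 kb). Nested amplification runs
the inner pair on the outer product and is verified to equal direct inner
amplification whenever the inner sites are unique.

## Detection and deconvolution

Heteroduplex formation and CEL1 kinetics are reduced to a set rule: a
pooled site is cleavable iff at least two distinct alleles are present
among the pooled haplotypes (hets contribute both alleles, homs only the
alt; mixing with wild type adds a reference haplotype). Cleavage at
amplicon offset d emits sizes d (700-channel, 5' label) and L − d
(800 channel); detection requires the two sizes to sum to L and
d to lie strictly inside (edge, L − edge) with edge = 100 bp, which is
the origin of the (L − 200) density correction. Fragment sizing is
noise-free by default; an optional Gaussian σ exists but every shipped
analysis uses σ = 0, because no sizing-error model is available to
calibrate against. Two variants at mirrored offsets d and L − d produce
co-migrating bands; both calls are emitted with a warning that the gel
pairing is ambiguous. Partial digestion and band intensities are not
modeled — detection is binary.

One genuine blind spot is modeled faithfully rather than patched: the
pooled primary screen contains no wild-type spike, so a pool whose every
member is homozygous for the same variant forms no heteroduplex and is
invisible. At realistic densities the probability is negligible, and the
individual verification step (alone + 1:1 wild-type mix) recovers
homozygotes whenever any pool-mate differs.

## Annotation

Substitutions are classified by translating the wild-type and mutant
codon: silent, missense, nonsense (with `truncated_length` = residues
strictly before the new stop, so a stop at codon 102 leaves 101 residues),
or start-loss when codon 1 no longer reads ATG (the note records whether
any in-frame downstream ATG could rescue translation). Indels of length
not divisible by 3 are frameshifts; the truncated length is found by
re-translating the shifted CDS to the first stop. Upstream and intron
positions are labeled as such and never scored against promoter or splice
motifs. Epitope overlap is closed-interval containment of the affected
codon in user-supplied protein coordinates; no signal-peptide renumbering
is applied. The spectrum summary counts G→A and C→T substitutions as
canonical EMS lesions and everything else as atypical.

## Restriction assays

Degenerate recognition sites are matched on the top strand only (the
built-in enzymes — EcoRI, HindIII, AseI, and the interrupted palindrome
BslI, CCNNNNN^NNGG with the cut after the seventh base — are all
self-reverse-complementary). CAPS design digests both alleles of an
amplicon and reports, per allele, the largest fragment size unique to it;
a destroyed site merges two adjacent wild-type fragments (the mutant
diagnostic is their sum), a created site splits one. Genotyping is
presence/absence of the two diagnostics. Southern counting digests a
two-copy genomic layout and counts fragments overlapping either
probe-homologous copy by ≥ 50 bp with size ≥ 100 bp (the detectability
floor is what hides a 40-bp inter-site fragment on a blot); fragments
within 5% relative size are flagged as co-migrating. Hybridization
chemistry and band intensity are out of scope.

## The benchmark fixtures

`popsim.benchmark_fixtures()` builds, deterministically and with a final
self-verification pass, three synthetic homeologous pairs engineered so
that a specific 27-row confirmed-mutation table is exactly consistent:

* an intronless 2S-albumin-like pair (amplicons 1278/1226 bp) carrying,
  among others, a Leu49 CTT codon, a start codon whose G3→A loss has no
  in-frame downstream rescue ATG, and two DPYSPS epitope motifs with an
  Arg codon just before the first and an Asp codon inside the second;
* an intron-bearing vicilin-like pair (2211/1666 bp); the B-subgenome
  copy's amplicon carries exactly six BslI sites, one of which spans the
  Arg102 CGA codon so that the C304→T nonsense change destroys it and
  merges adjacent 230- and 63-bp digest fragments into a 293-bp
  mutant-diagnostic CAPS band; the other copy totals 395 bp of intron
  ahead of its codon-333 region, making intron-inclusive anchored
  coordinates (C1392 → residue 333) come out;
* an intronless desaturase-like pair identical except for a 19-bp
  insertion ending 80 bp upstream of the A-copy start codon (the handle
  for copy-specific primers) and the Asn/Asp difference at codon 150.

The fixture sequences are engineered synthetic stand-ins, not database
records; background sequence is sampled under motif-exclusion constraints
(no stray six-cutter sites anywhere; no CC/GG dinucleotides in the
BslI-controlled amplicon outside the engineered sites) and the builder
asserts every designed property — amplicon lengths, primer specificity,
reference bases under all 27 mutations, restriction geometry — before
returning. A frozen checksum test pins bit-stability. Three table rows
whose stated coordinate and residue annotation are mutually
inconsistent under contiguous CDS numbering are carried with their stated
reference base but flagged `anomalous`, and their annotated effect is not
asserted.

A 22.6-kb Southern layout embeds the vicilin-like pair in ≥ 6 kb flanks
with genomic-background cut sites placed so that the no-cutter, one-cut-
per-copy, and adjacent-pair configurations yield 2 (co-migrating), 4 and
3 visible fragments respectively.

Because the fixtures are engineered and the generator is idealized,
passing tests demonstrate internal consistency of the screening logic and
arithmetic — not performance on real gels, where background bands,
incomplete digestion and sizing error would erode sensitivity.

## Statistics

kb/SNP = Σ(L_g − 200) · N / n, reported rounded to the nearest integer kb
with the exact bp value retained; zero mutations yields an explicit NA
rather than an exception. The only uncertainty quoted is the Poisson
sampling scatter of n (delta method); no confidence intervals or
between-treatment tests are offered, as group differences at these counts
are not meaningfully testable.

## Problem sizes and numerical choices

The shipped analyses run in seconds on one CPU: the transcribed screen is
3,420 individuals × 6 amplicons (855 pools), the parameter-recovery
simulation uses 2,000 individuals in the test suite (Poisson mean ≈ 16
confirmed mutations, checked within 3 standard errors) and 12,000 in the
acceptance script (mean ≈ 95, for a ~10% relative scatter on the
recovered kb/SNP). Property tests compare the site finder against a
brute-force IUPAC oracle on random 5-kb sequences and the classifier
against a full-CDS translate-and-diff oracle. All randomness flows through
explicit integer seeds; fixture construction retries deterministically if
a random/engineered junction would create a spurious motif, and the
first-success build is frozen by checksum.
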