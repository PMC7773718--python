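# Methods

This note documents the models, rules and defaults behind `minibarcode`,
the choices made where the design was genuinely open, and what the
synthetic-data generators do and do not emulate.

## Genome records and orthologs

Genomes are read with Biopython and normalized to 0-based half-open
coordinates internally; 1-based inclusive coordinates appear only at the
GenBank boundary and in human-readable names. Protein-coding genes are
spliced from their CDS segments and reverse-complemented to coding
orientation. Three normalizations matter downstream:

- **Inverted-repeat duplicates.** A gene annotated twice (same name,
  case-insensitive) keeps only the copy with the smaller start
  coordinate, so each gene contributes one sequence to diversity
  ranking. Which copy is kept is immaterial when the copies are
  identical, and deterministic when they are not.
- **Trans-spliced genes** (segments on both strands, e.g. *rps12*-like
  annotations) are excluded with a warning: their spliced sequence
  depends on annotation conventions, which would contaminate an
  ortholog comparison.
- **Gene names** are compared after whitespace stripping,
  case-insensitively; the first genome's spelling is reported.

Ambiguity codes are kept in sequences but treated as non-comparable in
every diversity computation.

## Pairwise alignment

Ortholog pairs are aligned with a Gotoh three-state affine-gap global
aligner (numba-compiled). Defaults follow a widely used DNA convention:
match +5, mismatch −4, gap open 10, gap extend 0.5, where a maximal gap
run of length k costs `open + k·extend`. Traceback is deterministic: on
score ties a diagonal step is preferred, then a gap in the second
sequence, then a gap in the first; inside a gap state, closing the gap
beats extending it, which beats switching gap types. Scores are exact
multiples of 0.5, so the 1e-9 float tolerance used during traceback
cannot misroute. The aligner is verified in the test suite against an
exhaustive enumeration oracle on short random pairs.

## Nucleotide diversity (π)

π uses *complete deletion*: any column containing a gap or a non-ACGT
code is excluded from the compared sites; π is the mean pairwise
proportion of differing compared columns (for two sequences, the
p-distance). Genes are ranked by π descending with alphabetical
tie-breaks; a gene with zero comparable columns is flagged undefined and
placed last rather than treated as π = 0. Reports round π to 5 decimals.
π values computed this way on real ortholog pairs depend slightly on the
alignment in their trailing decimals, which is why the verification
checks against the deposited *Senna* plastomes use a small absolute
tolerance rather than printed-digit equality.

Codon-aware alignment is deliberately not used; for the closely related
taxa this toolkit targets, indels in coding genes are rare and the
nucleotide-level alignment is stable.

## Primer design

Primers are enumerated exhaustively from conserved blocks (alignment
columns identical in both taxa, gap-free, unambiguous), so any returned
pair is perfectly conserved across the compared genomes by
construction. Screening defaults mirror common practice for short
barcodes: product 150–300 bp, primer 18–30 nt, Tm 40–70 °C, GC 30–70 %.

- **Melting temperature** is the nearest-neighbor thermodynamic Tm with
  the unified duplex parameter set, terminal initiation corrections,
  the entropic salt correction ΔS += 0.368 (N−1) ln[Na⁺] at 50 mM
  monovalent salt, and total strand concentration 250 nM (CT/4 term for
  a non-self-complementary duplex). The implementation is cross-checked
  in the tests against Biopython's independent NN implementation and a
  hand-summed oracle. The published Tm/GC values for the two *Senna*
  primer pairs are internally inconsistent with the published primer
  sequences (e.g. a 20-mer with 9 G/C listed as 33.3 %), so they are
  not used as reference values anywhere.
- **Hairpin rule**: reject when an intramolecular stem of ≥ 4
  Watson–Crick pairs can form around a loop of ≥ 3 unpaired bases
  (exhaustive stem enumeration). **Dimer rule**: scanning all ungapped
  antiparallel offsets of one primer against another (or itself),
  reject when a contiguous complementary run reaches 8 anywhere or 4
  anchored at either 3' terminus. Both thresholds are explicit,
  configurable heuristics standing in for folding-energy calculations,
  which are out of scope.
- **In-silico PCR** models annealing as ≤ 2 substitutions over the
  footprint with an exactly matching 3'-terminal trinucleotide (a
  polymerase cannot extend a mismatched 3' end); all plus/minus site
  combinations yielding a product ≤ 2,000 bp are reported. A candidate
  pair is *specific* only if it amplifies exactly one product per
  genome — presence alone is not enough, since a second product would
  corrupt both identification and quantification.
- Candidates are ranked by insert variable sites (descending), then
  insert length (ascending), then coordinate; at most 200 pairs per
  gene proceed to PCR validation (ranking makes the cutoff stable).
  Degenerate-base primers are not generated.

Only coding regions are searched: intergenic spacers of plastomes are
rich in indels and intra-specific variation, which breaks both primer
conservation and the quantitative interpretation of read counts.

## Quantification pipeline

- **Demultiplexing** requires an exact match of both tags of one sample
  (read 1 forward tag, read 2 reverse tag). Tags are short (≥ 6 nt), so
  allowing mismatches would re-admit exactly the tag-jump artifacts the
  dual-tag design guards against; any unrecognized combination goes to
  the unassigned pool. Reads lost to tag sequencing errors only shrink
  a sample's depth; they cannot bias its proportions.
- **Merging** reverse-complements mate 2 and picks the overlap (≥ 20 nt,
  mismatch fraction ≤ 0.1) with the most matching bases, preferring the
  longer overlap on ties; disagreements take the higher-quality base,
  mate 1 winning quality ties.
- **Primer trimming** allows ≤ 2 substitutions per footprint and no
  indels (amplicon reads essentially never shift within the footprint).
- **Dereplication** pools identical inserts per sample (ASVs at 100 %
  identity); inserts containing N are discarded and counted.
- **Denoising** replaces the full probabilistic error-model denoiser
  used in metabarcoding practice with an explicit abundance-based
  collapse, applied per sample: (1) ASVs with count < 2 are removed;
  (2) in descending abundance order, an ASV joins an existing cluster
  when it lies within Hamming distance 1 of *any* sequence already
  merged into that cluster and its count is at most 0.05 of the
  cluster's current total; cluster-level merges under the same rules
  are then iterated to a fixed point. Membership chaining is what makes
  the rule correct: a k-error read is Hamming-1 from a (k−1)-error
  variant, not from the true sequence, so a collapse keyed only to
  surviving top ASVs would strand multi-error variants (expected to
  occur in the hundreds-of-thousands-of-reads regime) as spurious
  low-count ASVs. Genuine biological ASVs are protected by the
  abundance-skew test, not by distance: a minority species at
  proportion p is safe whenever p > skew/(1+skew) ≈ 0.048 of a sample.
  This is the designed lower limit of detection; rarer components
  require lowering `skew` at the cost of error tolerance.
- **Assignment** aligns each ASV globally to every reference insert;
  identity = 100 × matching columns / alignment columns. 100 % →
  species; ≥ 97 % → near (reporting only); equal best scores → tie,
  unassigned. Global identity is appropriate because ASV and reference
  are the same short region; no local search heuristic is involved.
- **Proportions** are computed over species-assigned reads only, so
  they sum to 1 per sample; samples with no species-assigned reads are
  flagged rather than zero-filled. The optional regression is ordinary
  least squares of reads proportion on biomass proportion pooled over
  taxa and mixtures, with R² the squared Pearson correlation (a
  constant-y input returns slope 0, R² 0 with a warning instead of
  NaN).

Read conservation is enforced as an invariant at every stage: assigned +
unassigned = input; retained + rejected = merged input; table totals
equal retained inserts; denoising never increases a total.

## Synthetic generators

`simulate_genome_pair` emulates two congeneric organelle genomes:
random genes separated by spacers, genome B differing by independent
per-site substitutions (default 3 %, roughly the coding-gene divergence
of congeneric plastomes) except in conserved flanks (default 30 bp) at
gene ends. `simulate_barcode_refs` plants a mini-barcode: two amplicons
sharing primer footprints whose inserts differ at a chosen number of
sites (default 7 over a 164 bp insert, the geometry of the published
647F-847R barcode). `simulate_mixture_reads` draws read pairs from the
reference amplicons at the configured proportions, prepends sample
tags, and flips every base (tags included) to a uniformly random other
base with the configured error probability; qualities are constant and
consistent with that rate.

What the generators deliberately do **not** emulate: indels (planted
variable-site counts stay exact), position- or motif-dependent error
profiles, quality-score variation along reads, chimeras, length-variable
amplicons, and — most importantly — **primer amplification bias**, the
dominant real-world distortion of read-count quantification. Passing
the simulation-based tests therefore demonstrates that the pipeline
recovers proportions when amplification is unbiased; it says nothing
about primer bias in a wet experiment, which must be assessed with
mixtures of known composition, as the poor quantitative behavior of one
of the two published *Senna* barcodes illustrates.

## Problem sizes and determinism

The test suite and the acceptance script run simulations at four
mixtures × 20,000 read pairs (error 0.002, proportions 0.05–0.95) and a
single 50,000-pair mixture (error 0.001); these sizes give binomial
sampling noise well below the ±0.02 proportion tolerance being checked
while keeping a full run in the tens of seconds on one CPU. All
generators are pure functions of a single integer seed, and identical
inputs produce byte-identical reports.

## Verification against deposited records

The published plastome statistics (lengths 162,426/159,993 bp, GC
36.0/36.2 %, π ranking ycf1 > rpl23 > petL > matK with π(ycf1)=0.04363
and π(matK)=0.03206, amplicon sizes 200/151 bp, seven insert variable
sites per barcode) are checked by an optional job that requires the two
GenBank records to be fetched once over the network
(`scripts/fetch_accessions.py`, then `scripts/verify_accessions.py` or
the corresponding acceptance test). The published mixture read counts
and amplicon geometry need no download and are verified in every run.
The published R² of 0.9975 between read and biomass proportions cannot
be recomputed (raw reads and the biomass table were not deposited) and
is replaced by the simulation-based regression check.

## Known limitations

- Designed for *pairs* of genomes; multi-taxon panels would need a
  multiple alignment and a generalized variable-site count.
- The denoiser's detection floor (~5 % per sample at default skew) is a
  consequence of replacing an error model with an abundance rule.
- Tm assumes perfect-complement duplexes at fixed salt; annealing-site
  mismatches found by in-silico PCR are not thermodynamically weighted,
  only counted.
- Circular genomes are treated as linear strings; a gene spanning the
  origin would be missed unless the record is rotated first.
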