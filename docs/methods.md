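# Methods

This note documents the models, conventions and numerical choices behind
`coldlocus`, and what the synthetic-data generators do and do not emulate.

## Coordinates and gene models

Internal genomic coordinates are 0-based half-open; GFF3 and GenBank I/O
convert from/to 1-based inclusive at the boundary, which keeps all interval
arithmetic subtraction-only. A `GeneModel` stores exons in transcript order
(5'→3' along the mRNA); introns are the genomic gaps between genomically
adjacent exons, returned in transcript orientation. "Gene size" means the
genomic span from the first exon start to the last exon end. Published
per-component lengths (exons, introns, terminal segment) of the reference
gene do not sum exactly to its published total, so the package reports both
the span and the component sums and never forces agreement. Sequences may
contain N; N propagates to outputs, and any window statistic skips windows
with more than 10% N.

## CpG islands

The detector follows the sliding-window family of island finders: a 200-nt
window slides with step 1; windows with GC ≥ 0.50 and ObsCpG/ExpCpG ≥ 0.60
qualify (ObsCpG/ExpCpG = n(CpG)·L / (n(C)·n(G)), CpG pairs counted within
the window); overlapping/adjacent qualifying windows merge, and each merged
region is trimmed to its longest sub-interval that still qualifies as a
whole (leftmost on ties). All three thresholds are parameters. This is a
faithful detector of the same class as genome-browser island tracks, not a
byte-for-byte replication of any particular browser implementation.

## Poly(A) signals and motifs

The canonical poly(A) hexamer is AATAAA; the default non-canonical set is
the 11 common single-substitution variants (ATTAAA, TATAAA, AGTAAA, AATATA,
AATACA, CATAAA, GATAAA, AATGAA, TTTAAA, ACTAAA, AATAGA), configurable. A
signal is flagged disrupted when a sequence-variant position falls anywhere
inside its six bases. Motif scanning is a fixed-length Hamming scan (no
indels) of both strands; hits whose starts lie within motif-length +
`tandem_gap` (default 10 nt) of each other form a tandem group.

## Intron comparison

Per intron index the focal and comparison groups contribute min/max ranges;
an intron is "elongated" when the focal minimum strictly exceeds the
comparison maximum — a deliberately conservative, purely descriptive flag
(every focal gene longer than every comparison gene). No significance test
is attached to the flag; the paired expression module is where formal
testing lives.

## Protein features

Sequons are N-X-S/T with X ≠ P; overlapping sequons are all reported, and
in region reports a sequon belongs to the region containing its Asn. The
cysteine classifier takes the first and last cysteine of a domain as the
canonical intrachain bridge and reports a nested pair spaced exactly seven
residues separately; a canonical spacing of ≥ 55 residues classifies the
domain IgV-like (IgC/IgI folds are shorter-spaced). Net charge is a
Henderson–Hasselbalch sum over the termini and D, E, C, Y, H, K, R side
chains with Bjellqvist-style pKa values (N-term 7.5, C-term 3.55, K 10.0,
R 12.0, H 5.98, D 4.05, E 4.45, C 9.0, Y 10.0); the isoelectric point is
the bisection root of that monotone function to |charge| < 1e-4. The pKa
table is swappable. The charged-residue set for charge-change annotation is
K/R positive and D/E negative; histidine is excluded by default
(physiological-pH convention) and can be included by flag. The
transmembrane scan is a plain Kyte–Doolittle window (default 19 residues,
threshold 1.6 mean hydropathy) reporting maximal super-threshold runs —
a transparent stand-in for trained TM topology predictors, and it will also
fire on signal peptides, which are equally hydrophobic.

## Grouped-alignment screen

A column is focal-specific when every focal sequence covering it (non-gap)
carries one identical residue, focal coverage is at least
`min_focal_coverage` (default 1.0 — all focal sequences must cover; relax
to tolerate fragmentary sequences), and the residue occurs in no covering
non-focal sequence. Focal+sister shared columns are defined the same way
against the outgroup only. Columns where every non-focal sequence is gapped
are excluded as uninformative. Charge change compares the focal residue
with the majority residue among covering non-focal sequences (ties broken
lexicographically); sequon gain requires the private residue to be an Asn
forming a valid sequon in at least one focal sequence and none of the
others. Fragmentary sequences are handled by the per-column coverage rule
rather than global alignment trimming, so one short sequence does not
discard whole regions. Convergent sequon sites map each sequence's sequons
(detected on the ungapped sequence) back to alignment columns and merge
start columns within `cluster_span` (default 2), capturing alternative Asn
placements spaced by a single residue.

## Distances and trees

p-distance is the mismatch fraction over sites gap-free in both sequences.
Trees are Saitou–Nei neighbor joining on the p-distance matrix; taxa are
canonicalised to lexicographic id order before joining (making output
deterministic and input-order invariant) and negative branch lengths are
clamped to zero. NJ is exact on additive matrices, which the test suite
exercises against random additive trees; on real alignments the tree is a
distance summary, not a likelihood phylogeny.

## Relative expression

Technical replicates are averaged (arithmetic mean of Cq) per gene before
ΔCq = Cq_target − Cq_reference; ΔΔCq subtracts the same specimen's
calibrator-tissue ΔCq, and fold = 2^−ΔΔCq, so the calibrator fold is 1 by
construction for every specimen. Per-tissue summaries report both the mean
of per-specimen folds (with SD) and the fold of the mean ΔΔCq, because the
two differ on the linear scale. Hypothesis tests are two-tailed paired
Student's t on per-specimen ΔΔCq — the log2 scale, where replicate noise is
closest to Gaussian — Bonferroni-adjusted with m equal to the number of
comparisons actually performed. Pairs whose differences are identically
zero are flagged undefined and reported at p = 1.

## Synthetic data

All generators are pure functions of a spec plus a seed and log the exact
coordinates of every planted feature, so detector precision/recall can be
scored without re-deriving truth.

* **Locus.** An i.i.d. background at configurable GC (default 0.32) hosts
  the exon/intron layout, a planted CpG block (rejection-sampled until its
  ObsCpG/ExpCpG is within 0.05 of target, default 1.4), planted motif
  copies (default: an exact tandem pair on the plus strand and a
  one-mismatch copy on the minus strand inside the third intron) and a
  planted AATAAA inside the fourth intron. The background GC default was
  chosen from the binomial tail: at GC 0.32 a 200-nt window reaches 50% GC
  with probability ~1e-8, so the neutral background cannot satisfy the
  island criteria by chance, whereas at GC 0.40 spurious windows would be
  near-certain on a 10-kb scaffold. The background is therefore slightly
  more AT-rich than a typical teleost genome average and comparable to
  AT-rich intronic DNA. The planted block's realized GC runs higher
  (~0.7) than genomic islands because CpG pairs are injected on top of the
  base composition.
* **Alignment.** Background columns draw one consensus residue per column
  (never Asn or Cys, so sequon and cysteine features are controlled
  entirely by plants) and mutate cells i.i.d. at the background rate
  (default 0.02). Planted columns realize their definitions exactly:
  defaults are 20 focal-specific columns split 4/6/1/3/6 over
  D1/D2/EMPD/TM/CYT of a 317-column mature-protein layout, five of them
  charge-changing, two focal+sister shared columns, and one convergent
  sequon site in D2 whose 9 (of 12) focal carriers alternate the Asn
  between two columns spaced by one residue. This is a direct column
  generator, not a phylogenetic simulation: there is no tree, no rate
  heterogeneity and no indel process, so passing screens here demonstrate
  correctness of the column logic, not robustness to real evolutionary
  alignment error.
* **Cq tables.** Cq = reference level + true ΔCq + specimen offset +
  Gaussian replicate noise (default SD 0.2 cycles, 3 specimens, duplicate
  reactions — the published design). The specimen offset applies to both
  genes equally and cancels in ΔCq. Default tissue folds relative to the
  muscle calibrator encode the published expression pattern (gills highest;
  the middle intestine 2.7× and 3.9× below the anterior and posterior
  segments; liver 3.9× and head kidney 10× below gills).
* **Fixed reference.** `synthetic_pigr_cdna()` / `synthetic_pigr_locus()`
  build one deterministic transcript/locus pair whose design parameters
  are the published anatomy of the Antarctic *pIgR* gene: a 1414-nt cDNA
  (38-nt 5' UTR, 1017-nt CDS, 359-nt 3' UTR) with AATAAA at 1387 and
  ATTAAA at 1395; a 338-aa precursor with a 21-aa signal peptide, IgV-type
  D1 (108 aa, cysteines spaced 68 plus a nested pair spaced 7) and D2
  (95 aa, spaced 62 plus 7), a 39-aa EMPD with 7 prolines (17.9%) and a
  composition tuned at design time to a theoretical pI of ~11.0, a 20-aa
  TM with 6 leucines (30%) and one cysteine, a 51-aa basic tail, and
  exactly four valid sequons (D1, D2, the EMPD/TM boundary, CYT); and an
  eight-exon locus with the published intron lengths and an 8310-nt span.
  These are synthetic stand-ins constructed to the published numbers — not
  the real sequences — so checks against them validate that the feature
  extractors measure what the design encodes, not that the real accessions
  would yield those values. The published exon components sum to 2 nt more
  than the published gene total; the synthetic locus sizes its final exon
  (427 nt) to the total.

## Problem sizes

The default verification runs use 100 seeded alignments for screen error
rates, 100 random ≤2-kb sequences for the island-detector/oracle
equivalence, 50 seeded loci for island recall, 30 random additive trees of
up to 12 taxa for NJ recovery, and 500 seeded Cq tables for expression-bias
estimation; the full suite completes in well under a minute on one CPU.

## Known limitations

* The island detector is not a byte-level replication of any specific
  genome-browser track; threshold conventions differ slightly between
  published detectors.
* The hydropathy scan has no topology model and flags signal peptides.
* The screen's charge annotation uses a fixed two-class residue partition;
  histidine handling is a flag, not a pKa model.
* The MSA generator's lack of phylogenetic structure means group screens on
  real alignments face correlated noise the tests do not exercise.
* De-novo motif discovery, repeat/TE annotation, TFBS database scanning,
  splice-site scoring, signal-peptide/glycosylation prediction and
  structure modelling are out of scope; alignments are inputs, never built
  here.
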