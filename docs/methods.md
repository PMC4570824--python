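# Methods

## Scope and data model

The pipeline reproduces the computational arc of a two-condition plant
small-RNA + degradome study: one unreplicated small-RNA library and one
degradome library per condition ("wild" and "mutant"), a reference genome,
structural-RNA/repeat annotation, and a set of known mature miRNAs. All
internal coordinates are 0-based half-open; all emitted tables are 1-based
inclusive. Libraries are collapsed to (unique sequence → count) at parse
time; per-copy mean Phred scores are retained so the quality filter can act
after collapsing. Reads containing `N` survive parsing and are removed by
the quality filter, so the accounting sees every read.

## Read cleaning

"High quality" is not a standardized notion; the default here is *no `N`
bases and mean Phred ≥ 20*, both configurable. High-quality reads then
receive exactly one category in a fixed precedence order that mirrors the
conventional mutually exclusive data-set summary:

1. no detectable 3′ adapter → `adapter3_null`;
2. adapter at position 0 → `insert_null` (adapter dimer);
3. insert starting with ≥ 8 nt of the 5′ adapter → `adapter5_contaminant`;
4. trimmed insert < 18 nt → `shorter_than_min`;
5. insert ≥ 90 % adenine → `polyA`;
6. otherwise clean.

3′-adapter detection takes the longest adapter prefix (≥ 6 nt, ≤ 1
mismatch) found leftmost in the read — standard small-RNA trimming
behaviour with the parameters exposed. The accounting invariant
`high_quality = clean + Σ removed` is asserted at construction; the
percentage table uses high-quality reads as the 100 % denominator
(consistent with 10,107,814 / 10,789,735 = 93.68 %), downstream tables use
clean reads. Degradome libraries run through the same machinery — same
categories, only the adapter content differs and the polyA class is
typically empty.

## Mapping and annotation partition

Genome mapping is exact on both strands (a minus-strand hit stores the
locus where the read's reverse complement occurs). Exactness keeps a
brute-force scan usable as an oracle in the tests; the implementation uses
an 18-mer seed dictionary with full verification, so reported hits are
identical to the naive scan. Annotation categories are assigned per unique
sequence with the precedence miRNA > rRNA > tRNA > snRNA > snoRNA >
repeat > exon/intron > unannotated (the conventional small-RNA hierarchy;
configurable in code). Feature overlap is strand-agnostic, as is usual for
structural-RNA filtering. Multi-locus reads are classified once by their
best-precedence annotation over all loci; for locus-level counting their
count is divided equally among loci so totals are conserved. First-
nucleotide bias tables report counts and percentages of all four bases per
insert length (18–26 nt), with T printed as U.

## Hairpin folding

The folder maximizes nested base pairing (Watson–Crick plus G·U, minimum
loop 3) by Nussinov-style dynamic programming, breaking count ties toward
the larger weighted score with GC = 3, AU = 2, GU = 1, and a deterministic
traceback (unpaired case first, then smallest pairing partner). The DP is
exact: the suite checks equality of the pair count with an exhaustive
enumeration over all nested structures — a full alphabet sweep for lengths
≤ 6 and seeded random samples at 7–12 (the sweep breadth is a runtime
choice; the comparison itself is exact). Maximum-pairing is deliberately
simpler than thermodynamic partition-function folding: the discriminative
power for miRNA calling comes from the duplex-geometry criteria below, not
from free energies, and the exact DP admits a closed oracle.

## Novel miRNA calling

Clusters are built from unannotated mapped reads merged within 100 nt on
the same strand. A cluster becomes a candidate when, in order:

* cluster support ≥ 3 reads (a minimum-depth criterion in the spirit of
  MIREAP-class pipelines; without it every 20–22 nt sequencing straggler
  would trigger a fold of its ±150 nt window);
* the dominant read (highest count; ties to the lexicographically smallest
  sequence) is 20–22 nt;
* 5′-end specificity > 0.75, where the dominant group is all reads sharing
  the dominant 5′ end (3′ isomiRs count toward it, shifted 5′ ends count
  against);
* the genomic window mature ± 150 nt folds into a hairpin in which the
  mature sits wholly in one arm: its partners lie outside the mature on a
  single side in antiparallel order, ≤ 4 mature positions unpaired, no
  asymmetric bulge > 2 nt between adjacent duplex pairs, and the weighted
  pairing score of the window is ≥ 18.

These duplex tolerances follow conventional plant-miRNA annotation
criteria and are all configurable (`DiscoveryConfig`). The star is read
off the partner map with the canonical 2-nt 3′ overhangs: with the mature
at [a, b], the star spans [partner(b−2), partner(a)+2], extrapolating from
the nearest paired position within 2 nt when an anchor is unpaired;
`star_observed` records whether the star sequence itself was sequenced.
Accepted candidates must not overlap annotated structural RNA. Discovery
runs on the union of both libraries so condition-specific miRNAs are not
lost; per-condition candidate counts are the counts of the exact mature
sequence in each clean library.

## Degradome targets

Tags are truncated to 20 nt (tag lengths peak at 20–21) and matched
exactly, sense strand only, onto transcripts; each transcript's per-position
5′-end counts form its t-plot. Categories follow the widespread 0–4
convention: 0 = unique maximum (> 1 tag), 1 = shared maximum, 2 = above the
median, 3 = at/below the median, 4 = singleton; the median is taken over
positions with ≥ 1 tag only, so transcript length does not dilute it.

Duplex scoring penalizes mismatch 1.0, G·U 0.5, gap 2.0, doubled at miRNA
positions 2–13 from the 5′ end, minimized by a global alignment DP in
which the number of gap columns is an explicit state (≤ 1 by default) —
this prevents compensating gap pairs and makes the optimum identical to
direct enumeration over ≤ 1-gap alignments, which the tests exploit as an
oracle. A published E-value threshold from a pairing tool without public
scoring internals cannot be reproduced verbatim; this position-weighted
penalty with threshold ≤ 4.0 is a declared, configurable stand-in. A
target is reported when the score is ≤ 4 and a pile-up with ≥ 2 tags
(category ≤ 3) lies opposite miRNA positions 9–11 — the canonical slicing
position 10 with ±1 slack for imprecise processing (configurable to
exact-10). One call is made per (miRNA, transcript, position), preferring
position 10 on score ties. A fast gap-free upper bound screens windows
before the DP. A complementarity-only scan (no tag requirement) provides
the "predicted" counterpart to degradome-evidenced calls.

## Expression

RPM = count / clean-library total × 10⁶. Fold change is log2(wild/mutant)
on RPM; when either raw count is zero a pseudo-count of 1 raw read is added
to both sides before normalization (zero-free pairs are left untouched, so
the pseudo-count never biases them); if both are zero the record is
excluded from DE. Significance uses the Audic–Claverie exact test — the
standard choice for a count difference between two unreplicated libraries
of known sizes — under p(y|x) = (N_y/N_x)^y (x+y)! / (x! y! (1+N_y/N_x)^{x+y+1}),
with the two-sided value min(1, 2·min(P(Y≤y), P(Y≥y))) computed in log
space (gammaln + logsumexp; overflow-safe). A Fisher-exact option exists.
No multiple-testing correction is applied by default, matching the raw
P < 0.05 convention for this design; Benjamini–Hochberg is available.
"Specifically expressed" (not quantified in the source convention) defaults
to ≥ 10 reads in one library versus 0 in the other. The five calls
partition all records. Tests verify the test against an exact-rational
oracle on all x + y ≤ 50 and its null calibration (≈ 5 % of 1,000
equal-rate Poisson tags at α = 0.05).

## Synthetic study design

The generator is first-class code: its defaults *are* the study conditions
the test suite certifies.

* **Genome** — 4 chromosomes (~44 kb total) assembled from blocks: 20
  novel precursor loci and 30 known-miRNA loci (each flanked by 160 nt of
  random sequence), structural-RNA/repeat/exon/intron regions, and 5 kb of
  unannotated intergenic space per chromosome. Each planted hairpin is
  mature + 8-nt loop + complement arm carrying 1–2 mutations (≥ 1, so the
  mature cannot multimap onto its own star arm), and is rejection-sampled
  until the discovery module's own folder accepts its ±150 nt window — the
  manifest therefore guarantees every planted mature is recoverable in
  principle. Known loci are annotated as known-miRNA precursors; novel
  loci are unannotated.
* **Expression truth** — per-miRNA base means are log-uniform on
  [80, 800] reads; 20 % of each pool is up- and 20 % down-regulated at
  |log2 FC| = 2 (split symmetrically around the base mean), 10 % is
  condition-specific, the rest unchanged.
* **Small-RNA libraries** — miRNA read counts are Poisson around the
  manifest means (no overdispersion: the design has one library per
  condition; a negative-binomial mode is not pretended). Mature reads are
  accompanied by 12 % 3′ isomiRs, 5 % shifted-5′ reads and 8 % star reads.
  The remaining clean reads split into structural fragments (20 %),
  degradation fragments concentrated at 150 hotspot loci kept ≥ 300 nt
  away from planted matures (15 %), and unmappable random inserts (20 %),
  with insert lengths drawn from a bimodal 21/24 profile. Adapter
  contamination classes are added at fractions matching the magnitude of a
  typical data-set summary (e.g. 5 % short inserts, ~1 % 5′ contaminants);
  every emitted read is verified to classify into its intended category,
  so the generator's accounting is exact, not approximate. Qualities are
  constant Q35 except a 0.3 % Q10 low-quality class (only the mean-quality
  filter consumes them).
* **Degradome** — transcripts are 300-nt random sequences, 32 of which
  carry one embedded reverse-complement target site each (one per
  transcript, so the category-0 "unique maximum" property is well
  defined); the cleavage position sits opposite miRNA position 10. Signal
  pile-ups are emitted at their expected depth round(signal_to_noise ×
  background rate) — the pile-up is the modelled signal, sampling noise is
  left to the Poisson background (0.5 tags/position) — with tag lengths
  20–21 nt and 25 % unmappable tags.

All randomness flows from the single supplied seed through per-stream
`numpy` generators; identical (cfg, seed) reproduce identical manifests
and identical FASTQ files.

What the generator does **not** emulate: sequencing errors inside reads,
hexaploid homoeologous copies and large multi-gene families, expression
overdispersion across replicates, RNA-structure-dependent degradation
bias, and transcripts embedded in the genome (degradome mapping summaries
are computed against the transcript set). Passing tests therefore certify
the bookkeeping, the folding/duplex geometry, and the statistical
machinery under clean planted signal — not performance on real hexaploid
wheat data.

## Numerical and design choices

* Folding combines pair count and weighted score lexicographically in one
  integer DP (count × 4096 + weight), keeping the oracle comparison exact.
* The arm/loop annotation of a fold derives from the smallest-span stem
  pair; for the multi-branch structures random windows can adopt, the
  duplex-geometry test (not the arm labels) carries the decision weight.
* Dominant-read ties break lexicographically; traceback tie-breaks are
  fixed; report rows are sorted — reruns are byte-identical.
* Degradome target evaluation treats a call within ±1 nt of a planted
  cleavage site as correct, consistent with the ±1 calling window.
* The end-to-end suite runs the default study (≈ 45 k raw small-RNA reads
  and ≈ 10 k degradome tags per condition) once per session; problem sizes
  were chosen so the planted effects (≥ 80-read means, |log2 FC| = 2,
  signal-to-noise 20) are comfortably detectable by design, which is what
  a ground-truth recovery suite should certify.

## Known limitations

* Exact-match mapping: a single sequencing error unmaps a read; fine for
  synthetic data, lossy on real data.
* Maximum-pairing folding can overpair random windows; the stability
  threshold (≥ 18 weighted pairs) is consequently weak on its own and the
  duplex-geometry criteria do the filtering.
* The E-value of the original pairing tool is approximated by a score
  threshold; absolute target counts are therefore not comparable across
  tools, though rankings are.
* With one library per condition the Audic–Claverie test measures sampling
  noise only; biological variability is unmodelled, as in any
  unreplicated design.
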