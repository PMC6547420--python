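# Methods

## Model and coordinates

An IES form is a deletion interval in 0-based half-open MIC coordinates
[A, B), A being the 5′ (A-end) and B the 3′ (B-end) boundary in reference
orientation. Half-open intervals make "at least 1 bp overlap" exactly
`a1 < b2 and a2 < b1`, and touching intervals ([100,200) and [200,300))
distinct loci. 1-based inclusive coordinates appear only in human-readable
output, never internally.

### Junction normalization

Terminal direct repeats (junction microhomology) make a breakpoint
representation ambiguous: if the m bases starting at A equal the m bases
starting at B, any shift of the interval by up to m positions deletes the
same sequence. Forms are canonicalized by left-alignment — [A, B) is
shifted to [A−1, B−1) while `seq[A−1] == seq[B−1]` — which moves the
retained microhomology copy against the A-end. The rejoined MAC product
`seq[:A] + seq[B:]` is provably invariant under each shift, the operation
is idempotent, and the canonical form is the unique left-most
representation (tested on random sequences). `mh_len` is the maximal m
with `seq[A:A+m] == seq[B:B+m]` after shifting.

### Breakpoint refinement

Clipped-read pileups localize junctions at base resolution. For each
candidate end, positions within ±window/2 (window = 200 bp by default; the
symmetric reading of "a 200-bp window" — the interpretation is exposed as
a parameter because other readings are possible) are screened against a
threshold and the position with the highest clip count wins; ties go to
the position closest to the prediction, then to the smaller coordinate.
The threshold is the arithmetic mean of clip counts per position, computed
per (strain, contig) over positions with at least one clipped read — the
per-pair scope is robust to coverage differences between strains and
contigs, and a mean over *covered* positions is the only computable
default when pileups carry no explicit zeros (an include-zeros mode over
recorded positions exists). When several window positions tie for the
maximum, all of them are kept and every consistent (A, B) combination
with A < B becomes a call: equal clip maxima are exactly what alternative
intra-strain boundaries look like in pileup data. Junction re-verification
by spanning reads is approximated by requiring both ends to pass the
threshold independently.

### Variation statistic

For two forms, diff = |A₁ − A₂| + |B₁ − B₂|; a locus's maximum boundary
variation is the maximum of diff over all unordered pairs of distinct
intervals (0 for a single form). The statistic is a metric on (A, B)
pairs and is invariant to form order and duplicates. Reporting classes
are 0, 1–10, …, 91–100 (closed bins) and >100. Ratios and percentages in
report tables are rounded half-up at 2 decimals, matching the print
precision of the published tables this layout mirrors.

### Flank processing and IR/DR search

For a locus, distances are measured against a designated reference
strain's form (the lexicographically smallest (A, B) when that strain has
several); loci without the reference strain, or whose flank would cross a
contig end, are excluded and logged. The left flank is the W = 100 bases
ending at A; the right flank is the reverse complement of the W bases
starting at B. After this processing, a literal k-mer shared by the two
flank strings is an inverted repeat in genome coordinates; matching the
*un*-complemented downstream flank instead yields direct repeats.

Distances dA/dB run from the junction to the motif copy's IES-proximal
base (0 = abutting). The measuring point is a convention — any fixed
choice shifts all distances by a constant — and proximal-base is used
consistently everywhere, including PWM hits. Pairs are kept when
|dA − dB| ≤ 10 bp (inclusive; configurable). All qualifying pairs of a
locus feed the concentricity statistics; per-locus assignment instead
uses a single representative pair (minimal distance difference, then
smaller mean distance), which reconciles copy-level tallies with
per-locus presence. Both dA and dB distributions are computed and
reported rather than assuming the right side mirrors the left.

Concentricity is the interquartile range of a k-mer group's dA values,
with quantiles by linear interpolation on sorted values (the common
type-7 rule; configurable, as no single convention is canonical). A group
is selected when IQR ≤ 10 and count ≥ 3. Groups sharing a core sequence
can be pooled (`group_by_core`; N in the core is a wildcard), and the
pooled IQR is computed on the concatenated distance vector.

### Composition profiles

Per-position A/C/G/T fractions over −span…−1 (inside the IES, counting
back from the junction) and 0…span−1 (flank, counting outward), span
500 bp by default. With both ends pooled, the B-end window is
strand-complemented so both ends read in a common IES-to-flank
orientation; N bases are excluded from the denominator, and each row's
four fractions sum to 1.

### PWMs and FRS typing

Matrices are built from equal-length instances (or a plain-text
JASPAR-style count file) with pseudocount 1 per base per position and
log₂-odds against a uniform 0.25 background. Similarity is min–max
normalized, (score − s_min)/(s_max − s_min): unlike a fraction-of-maximum
score it is background-independent and attains both 0 and 1, making a
"75% similarity" threshold well defined; the comparison is inclusive (≥).
Although the genome is ~75% AT, the uniform background keeps the scale
reproducible; an AT-weighted background can be supplied by building the
matrix with explicit weights. Windows containing N are not scored.

Both processed flanks are scanned with the matrix and its reverse
complement. Same-orientation hits on the two sides within the distance
tolerance form an IR call: forward/forward is a G-rich IR, reverse/
reverse a C-rich IR (the downstream flank's prior reverse-complementation
maps a genomic IR onto same-orientation matches). When both types qualify
at a locus the one with the lesser distance difference is assigned, a tie
going to G-rich (logged); loci with neither but with a selected
concentric k-mer group are typed "other-IR", else "none".

The packaged matrix `data/g_rich_ir_synthetic.pfm` is a synthetic
A₅G₅-like polypurine count matrix (consensus `AAAAAGGGGG`) — a stand-in
for a Lia3p-type G-rich FRS used in examples and synthetic runs. Real
analyses should pass their own instance-derived matrix; the matrix is a
configurable input throughout.

### Mutant contrast

Only loci with at least one form in every wild-type and every mutant
strain are considered. A locus is flagged mutant-affected when the WT-only
maximum variation is ≤ 100 bp (a stringent ≤ 20 bp cap is available) and
pooling mutant forms raises the maximum by ≥ 100 bp. The increase
comparison defaults to ≥ with a strict > option, because the two readings
both occur in the literature this rule comes from. Enrichment tables
count G-IR/C-IR assignments per strain plus "at least one strain" and
"all strains" aggregations, with the background set being the considered
loci minus the flagged set; since assignment is exclusive, total = G + C.
Headline statistics (≤20-bp share, difference of >100-bp shares,
per-end ≤20-bp share) accept class-percentage mappings, so the same
arithmetic serves computed histograms and printed counts.

The multiple-FRS survey asks whether high variation reflects *controlled
alternative boundaries*: for each assigned locus with > 20 bp variation,
every distinct form is rescanned for a same-type IR pair, and the locus
is "multiple-FRS" when ≥ 2 forms each have their own pair within the
distance tolerance of the locus's modal (median) motif distance.

## The synthetic generator

The generator emulates the data regime the pipeline is designed for, not
sequencing itself: no reads, no quality values — evidence enters as
candidate intervals (a structural-variant caller's output) and clip-count
profiles.

- **Genome**: independent bases at 25% GC (the observed MIC AT-richness);
  IESs of 250–600 bp placed with clearance
  2·(ir_distance + motif length + 500) from contig ends and each other,
  so flank extraction and ±500-bp profiles never truncate and refinement
  windows never span two loci.
- **Motifs**: a planted hexamer (default `TACCGT`) at 45 ± 3 bp
  (uniform jitter) outside each boundary, the downstream copy
  reverse-complemented — the IR geometry of the known M-element FRS. A
  `motif_fraction` < 1 leaves some loci motif-free; those loci define the
  unaffected truth set for the mutant contrast.
- **Microhomology**: 0–6 bp, planted by copying the first m IES bases to
  the position after the B-end, so left- and right-aligned
  representations are both valid deletions; the truth interval is then
  forced canonical (base left of A ≠ base at B−1) so that truth equals
  the normalized representation.
- **Strains**: one substream per strain, derived by hashing (seed,
  strain) — adding a strain never changes another's draws. Boundary
  jitter is ±5 bp in wild type, ±150 bp in mutant strains *at motif
  loci only*; jitter shrinking a form below 100 bp is resampled. Each
  strain skips 2% of loci; 1% of loci get an intra-strain duplicate form
  offset by 160–240 bp (below the window-plus-displacement reach of 150
  bp, two equal clip maxima would land in one refinement window and the
  keep-all-ties rule would emit chimeric cross-pairs; the offset floor
  avoids that by construction, and default IES lengths ≥ 250 bp keep
  duplicates overlapping their primary form).
- **Evidence**: candidate ends displaced uniformly within ±50 bp
  (inside the ±100-bp refinement reach); a constant clip peak of 30
  reads at each true end — constant because the refinement threshold is
  the mean of covered positions, and in a zero-noise profile randomly
  varying peaks would put half the true junctions below their own mean —
  plus background noise at 5·10⁻⁴ sites/bp with counts 1 + Poisson(1).
  The noise model is a choice (real pileup noise is not characterized
  here) and is exposed in the config.

What the generator does **not** emulate: mapping artefacts, coverage
variation, chimeric reads, repeat-induced ambiguity, incomplete reference
(N runs), or allele-frequency structure in the polyploid macronucleus.
Passing tests therefore demonstrate the correctness of the analysis
logic under the stated evidence model, not robustness to every real-data
pathology.

## Problem sizes and numerical choices

The test-suite and acceptance-script runs use 2-contig genomes of 0.2–1
Mb with 30–500 planted IESs — large enough that concentricity, enrichment
and sensitivity/specificity estimates are stable at the reported
precision while a full run of suite plus script stays under a minute.
Deterministic seeding (numpy `default_rng` with blake2b-derived
substreams, all below 2³¹) makes every number reproducible.

Degenerate inputs: an all-zero clip profile is an explicit "no evidence"
error; an empty variation class prints an empty ratio cell rather than
dividing by zero; a zero-sized enrichment group yields empty percentages;
loci missing a contrast strain are excluded, not errored; flank-boundary
exclusions are logged with reasons.

## Known limitations

- The refinement window semantics ("within a 200-bp window" read as
  ±100 bp) and the inclusive ≤10-bp distance filter are documented
  interpretations of ambiguous prose; both are configurable.
- The N-filter width at junctions (5 bp inside each end plus 5 bp of
  flank) is a chosen guard; the source rule states no width.
- FRS assignment uses one representative pair per locus; loci with
  genuinely co-active FRS pairs are surfaced by the multiple-FRS survey
  rather than by multi-assignment.
- The shipped G-rich matrix is synthetic; conclusions about real strains
  require an instance-derived matrix.
- Genome-scale counts from the real strain panels (tens of thousands of
  deletions) require the deposited sequencing data and MIC assembly and
  are outside what the synthetic panels reproduce; the pipeline reports
  the same statistics at simulation scale.
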