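# Methods

## Measurement model

Direct-BSP sequences a *population* of PCR molecules. At a CpG, the
methylated fraction keeps its cytosine through bisulfite treatment while
the unmethylated fraction reads as thymine, so the basecalled chromatogram
shows two superimposed peaks whose analyzed-signal heights are taken as
proportional to the molecule fractions:

* forward read: `m = peakC / (peakC + peakT)`
* reverse read: `m = peakG / (peakG + peakA)`

No normalization of peak heights is applied: modern basecallers no longer
over-scale the minor base, and rescaling would bias the ratio. The same
formulas applied to a single clone yield values near 0 or 1, which is how
cloning-BSP reads are interpreted downstream. Cytosines of the amplified
strand *outside* CpG context must fully convert regardless of methylation;
their residual C (forward) or G (reverse) signal measures bisulfite
conversion efficiency and is the core per-read QC quantity.

## Coordinates and templates

Coordinates are 1-based and fully closed throughout: reference position
`p` has genomic coordinate `seq_start + p − 1`. Because bisulfite destroys
strand complementarity, only one strand is amplified; in-silico conversion
is applied to that strand (C→T outside CpG, C kept at CpG) giving the
*sense* template, and its reverse complement gives the *antisense*
template. When the minus strand is amplified, the reference is
reverse-complemented first and all outputs are reported in plus-strand
genomic coordinates (sense position `p` ↦ `seq_end − p + 1`). CpG sites
are numbered in ascending plus-frame position; a trailing C whose G falls
outside the region is not a site, and N never matches.

## Trimming

Two independent criteria, intersected:

* **Mott quality trimming** (M1, reset-to-zero running sum). Per base,
  score = `cutoff − 10^(−q/10)`; the kept window is the maximum-sum
  contiguous segment. Default cutoff 0.001, i.e. the Phred-30 anchor
  (`Q = −10·log10 P`).
* **Mixed-peak trimming**. A base is *non-mixed* when its primary peak
  ratio (max channel / channel sum) is strictly above 0.75; a ratio of
  exactly 0.75, or an all-zero base, is mixed. For each boundary width
  `n = 3..15` the candidate is the longest window opening and closing with
  `n` non-mixed bases; among candidates whose non-mixed fraction is
  ≥ 0.75, the smallest `n` is kept. The implementation uses run-length
  arrays (earliest valid start, latest valid end per `n`), which provably
  selects the longest window; the test suite checks it against exhaustive
  enumeration of every `(start, end, n)` triple.

The final window must satisfy length ≥ 30 bp, mean Phred ≥ 30 and
non-mixed fraction ≥ 0.75; failures are recorded as data, not raised. The
mean-Phred default of 30 reuses the workflow's only quality anchor (the
same Q30 that defines the Mott cutoff); at those defaults the gate is
nearly redundant with Mott trimming, which is intended.

Note that the *end-to-end* trimmed window length is not monotone in the
primary-ratio threshold: the fraction filter can reject a long
low-threshold window yet accept a shorter, denser one at a higher
threshold. Only the geometric window search itself is monotone.

## Alignment and position mapping

Smith–Waterman local alignment with affine gaps, scores +2 / −1 / −5 / −2
(match / mismatch / open / extend) — favoring the contiguous, high-identity
alignments expected of Sanger reads; all scores are exposed in the config.
Direction is auto-detected by aligning against both templates and keeping
the longer alignment (ties: higher score, then sense); if the best pairing
fails the validity gates the read is declared unalignable — random DNA
always produces some short spurious local hit, so a bare
"non-empty alignment" criterion would be meaningless.

The position map sends each aligned template position to its read
position; for ungapped alignments it is the closed form
`read = template − s_start + p_start`, and template positions falling in
read gaps map to nothing. Identity is matches over aligned columns,
excluding gap columns and excluding CpG columns: a read legitimately
carries C or T (forward; G/A reverse) at a CpG depending on methylation,
and counting those columns would let the methylation level itself degrade
alignment QC. N never counts as a match.

## QC gates

A read contributes methylation values only if aligned length ≥ 30 bp,
identity ≥ 75% and mean conversion rate ≥ 0.9. Comparisons are inclusive
(≥), so the printed defaults remain attainable exactly at threshold.
Control positions inside alignment gaps or with zero denominator carry no
evidence and are skipped, never scored as zero; the mean is unweighted
over scored sites. A read with no usable control site fails QC outright.

## Per-sample table and combination

Forward/reverse percentages at a CpG are combined as their mean; the
standard deviation uses the two-value sample (n−1) form, matching the
two-decimal rendering of the CSV output (values are kept at full precision
internally). A CpG covered by only one direction uses that direction
alone; uncovered CpGs yield missing records. The per-sample CSV schema is
frozen (16 columns, one row per CpG) and is the sole interface consumed by
the grouped stage.

## Grouped analysis

CpG ordinals are reset over the union of sites covered by at least one
sample, numbered in ascending genomic coordinate. Clone statuses:
≤ 20% unmethylated, ≥ 80% methylated, strictly between ⇒ partial
(reported not-available). A clone whose partial fraction strictly exceeds
20% is flagged a potential mix of clones and fully masked; CpGs that are
missing due to coverage (rather than partial methylation) do not count
toward that fraction. Group-level clone proportion =
methylated / (methylated + unmethylated), excluding not-available.

Statistics use per-sample mean methylation per CpG as observations
(cloning: masked statuses mapped to 0/100). The two-sample test is
Welch's t by default (a pooled-variance switch exists); Kruskal–Wallis
runs across all groups per CpG. Groups with fewer than two observations
are skipped (reported as missing). Zero-variance pairs are guarded: equal
means give p = 1, perfectly separated means give p = 0 — no infinite
statistics. Raw p-values are reported with the conventional symbols
(*, **, ***, **** at 0.05 / 0.01 / 0.001 / 0.0001);
Benjamini–Hochberg adjustment is available but off by default, matching
standard presentation of BSP panels.

Sample ordering in plots: by group, by descending mean methylation, or by
average-linkage hierarchical clustering on Euclidean distance (missing
values imputed with the column mean for the ordering only).

## Synthetic data generator

The generator emulates the measurement model directly: per called base a
dominant peak of height ~1000 (arbitrary signal units), CpG columns split
C/T (or G/A) in proportion to the simulated methylation, control columns
split T/C (or A/G) by the simulated conversion efficiency (default 0.99),
additive Gaussian noise with σ = 2% of the peak scale clipped at zero, and
15 degraded bases at each extremity (flat mixed peaks, Phred 8 vs 50 in
the clean interior). Base calls are the argmax channel. Reads are written
as genuine minimal ABIF files and the forward/reverse pair of a sample is
shuffled so direction auto-detection is actually exercised. Recovery tests
use a 400 bp reference with 6 CpGs placed ≥ 40 bp from the ends, so the
degraded extremities never overlap a CpG — ordinary amplicon design, and
small enough that the full suite runs in seconds.

Because peak height is linear in molecule fraction *by construction*,
passing recovery tests demonstrates that the pipeline inverts its own
measurement model correctly (trimming, direction detection, gap-corrected
position mapping, ratio arithmetic); they do not validate dye-specific
incorporation biases, mobility artifacts or baseline drift of real
chromatograms, which the quantification inherits as assumptions.

## Numerical and degenerate-input choices

* Mott: reset-to-zero (Kadane) variant; the first argmax of the running
  sum ends the window. Score ties between distinct windows are broken by
  the earlier end.
* Mixed-peak trimming: strict `>` for non-mixed, `≥` for the fraction
  filter, smallest qualifying boundary width wins.
* All-zero peak heights: mixed base (trimming), skipped site (QC),
  missing value (methylation).
* Both trace files detecting the same direction: the first is kept, the
  extra read is ignored with a warning.
* A sample whose reads all fail produces a complete table of missing
  records with the failure reasons attached — never an exception.

## Known limitations

* Only CpG context is analyzed (no CHG/CHH).
* One sequencing read per direction per sample; no read merging beyond
  the forward/reverse combination.
* The ABIF writer emits the minimal tag set the reader requires; it is a
  fixture/export format, not a full sequencer-file emulation.
* Clone-status thresholds (20/80) are heuristics inherited from standard
  practice; partially methylated clones are discarded rather than
  modeled.
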