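# bsptrace

Quantification and comparison of region-specific CpG DNA methylation from
Sanger **bisulfite sequencing PCR** (BSP) chromatograms.

Bisulfite treatment deaminates unmethylated cytosines to uracil (read as T
after PCR) while 5-methyl-cytosine stays C. After PCR amplification of a
region of interest and Sanger sequencing, the methylation level of each CpG
site is therefore encoded in the chromatogram's relative dye-peak heights:

* forward read:  `methylation % = peakC / (peakC + peakT) × 100`
* reverse read:  `methylation % = peakG / (peakG + peakA) × 100`

`bsptrace` automates the whole analysis for both flavors of BSP —
**direct-BSP** (sequencing the PCR product pool; mixed C/T peaks give a
quantitative level per CpG) and **cloning-BSP** (sequencing individual
clones; each gives binary statuses) — starting from raw ABIF (`.ab1`) trace
files. It is intended for biologists running locus-specific methylation
assays who today read peak heights off chromatogram viewers by hand.

## What the pipeline does

**Individual analysis** (per sample, 1–2 unlabeled trace files):

1. **ABIF parsing** — base calls, per-base Phred qualities, and the four
   analyzed dye channels sampled at each base call's peak location, with
   the channel order taken from the file's field-order record.
2. **In-silico bisulfite PCR** of the reference region — every non-CpG C of
   the amplified strand becomes T, producing the *sense* template and its
   reverse complement (*antisense*), plus the CpG and conversion-control
   coordinates.
3. **Trimming** — a modified Mott algorithm on error probabilities
   (cutoff 0.001 ≙ Phred 30) intersected with a mixed-peak window search
   (primary peak ratio > 0.75, boundary runs of 3–15 clean bases).
4. **Alignment** — Smith–Waterman local alignment against both templates;
   the longer alignment fixes the read direction; a gap-aware position map
   links template, read and genomic coordinates.
5. **QC** — bisulfite conversion rate measured at non-CpG cytosines
   (`peakT/(peakC+peakT)` forward, `peakA/(peakG+peakA)` reverse); a read
   is used only if aligned length ≥ 30 bp, identity ≥ 75% and mean
   conversion ≥ 0.9.
6. **Methylation table** — per-CpG percentages per direction, combined
   mean ± SD, written as a frozen-schema CSV plus a genomic control plot.

**Grouped analysis** gathers all per-sample CSVs of one sequence, renumbers
CpGs over the union of covered sites, calls clone statuses for cloning-BSP
(≤ 20% unmethylated, ≥ 80% methylated, > 20% partial CpGs ⇒ potential clone
mix), and compares groups: per-CpG pairwise Welch t-tests, per-CpG
Kruskal–Wallis, and t-tests on per-sample means — rendered as lollipop
plots, a methylation profile, boxplots and a heatmap.

A fully deterministic synthetic-chromatogram generator (Gaussian peaks,
controllable per-CpG methylation, conversion efficiency, degraded read
ends) makes every stage testable without sequencer data.

## Worked example

Simulate a two-group experiment (3 replicates each, 6 CpGs, true
methylation 5% vs 85%) and run the two analysis stages:

```python
from bsptrace import make_reference, simulate_experiment

ref = make_reference(name="demoRegion", length=400, n_cpg=6, seed=1)
simulate_experiment("input", ref,
                    {"ctrl": (5.0,)*6, "treated": (85.0,)*6},
                    n_replicates=3, seed=17)
```

```bash
bsptrace batch input/manifest.csv --outdir results
# 6/6 analyses succeeded; summary at results/batch_summary.csv
bsptrace grouped --results-dir results --sequence-name demoRegion --outdir grouped
```

The per-sample CSV holds one row per CpG:

```
sequence_name,collection,group,replicate_or_clone,experiment_type,cpg_index,c_coordinate,meth_fwd,meth_rev,meth_mean,meth_sd,n_reads,...
demoRegion,colA,ctrl,1,direct,1,6040,7.42,3.92,5.67,2.48,2,...
demoRegion,colA,ctrl,1,direct,2,6104,4.68,2.84,3.76,1.30,2,...
```

i.e. at the CpG whose cytosine sits at genomic coordinate 6040 the forward
read measures 7.42% methylation, the reverse read 3.92%, combined
5.67 ± 2.48% from both reads — close to the simulated 5%. The grouped
summary (`grouped/demoRegion_summary.json`) reports per-sample means of
≈5.3% (ctrl) vs ≈85% (treated) and a Kruskal–Wallis p-value of 0.0495 per
CpG (the floor attainable with 3 vs 3 samples), with the figure files
(`*_lollipop_samples.png`, `*_profile.png`, `*_boxplots.png`, …) alongside.

Single samples can also be run directly:

```bash
bsptrace individual --fasta ref.fasta --start 6000 --end 6399 --strand plus \
    --ab1 read1.ab1 --ab1 read2.ab1 --sequence-name demoRegion \
    --collection colA --group ctrl --replicate 1 --outdir results
```

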