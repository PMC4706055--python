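# windowdb

Window-based detection of **differential binding (DB)** in ChIP-seq data:
from filtered BAM alignments to region-level DB calls with false
discovery rate (FDR) control.

Instead of calling peaks and testing them (which re-uses the data twice),
`windowdb` counts directionally extended reads into sliding windows
tiling the genome, tests every window with a negative-binomial (NB)
quasi-likelihood (QL) F-test, and aggregates windows into regions whose
FDR is controlled with Simes combined p-values and Benjamini–Hochberg.
It is aimed at experiments with biological replicates in two or more
conditions — e.g. a histone mark changing between cell types, or a
transcription factor lost in a knock-out.

## Model

For window *g* and library *i* with count *y_gi*:

    y_gi ~ NB(mu_gi, phi_g),    log mu_gi = x_i' beta_g + o_gi

where *x_i* encodes the experimental design, *o_gi* are offsets carrying
library size and normalization (loess offsets for trended biases, or
binned TMM factors for composition biases), and *phi_g* follows an
abundance-dependent trend estimated by Cox–Reid adjusted profile
likelihood.  Window-level variability is captured by a QL dispersion
*s²_g* (residual deviance / residual df), shrunk towards its abundance
trend by empirical Bayes with estimated prior degrees of freedom *d0*:

    s²_post = (d0 s²_trend + df_res s²_raw) / (d0 + df_res)

A contrast *c* is tested per window with F = (deviance difference / r) /
s²_post against F(r, d0 + df_res).  Adjacent significant windows (< 100 bp
apart, clusters capped at 5 kbp) form regions; the region p-value is
Simes' min_i(m p_(i)/i) over member windows, and BH across regions
controls the region-level FDR.

## Worked example

Simulate a two-condition experiment with known truth, then run the full
pipeline with the histone preset (150 bp windows, loess normalization):

```bash
windowdb simulate --seed 7 --outdir sim/
cat > config.yaml <<EOF
bams: [sim/library_1.bam, sim/library_2.bam, sim/library_3.bam, sim/library_4.bam]
groups: [A, A, B, B]
contrast: B-A
preset: histone
outdir: results/
EOF
windowdb run config.yaml
```

which prints (log lines abridged):

```
INFO estimated fragment length: 149 bp
INFO library 1 (sim/library_1.bam): 45501 filtered reads
INFO abundance filter: kept 1079 / 19997 windows (background 6.714 log2-CPM)
INFO common NB dispersion: 0.0402 (BCV 0.200)
INFO QL prior df: median 44.86
INFO 258 regions, 54 at FDR <= 0.05
fragment length 149 bp; 1079 windows tested; 54 significant regions -> results/
```

Reading this: the strand cross-correlation peaks at 149 bp (the simulated
fragment length is 148); ~5% of windows survive the 3-fold background
filter; replicate variability corresponds to a biological coefficient of
variation of 20%; and 54 regions are significant at region-level FDR
0.05 — the simulation contains 50 truly differential sites, all of which
are recovered.  `results/regions.tsv` holds one row per region
(1-based coordinates) with columns `chrom, start, end, nWindows,
logFC.up, logFC.down, PValue, FDR, best.pos, best.logFC`;
`results/significant.bed` scores each significant region by
−10·log10(FDR), e.g. 13.01 at FDR = 0.05.

Every stage is also available as its own subcommand (`fraglen`, `count`,
`filter`, `normalize`, `test`, `regions`, `annotate`, `coverage`,
`export`), reading and writing plain TSV/BED/bedGraph so intermediate
results are inspectable and the expensive counting step is never
repeated.  For sharp transcription-factor binding use `preset: tf`
(10 bp windows, TMM normalization on 10 kbp bins).

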