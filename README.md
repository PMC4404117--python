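# splinewin

Smoothing-spline window boundaries for genome scans.

High-density genomic statistics — per-SNP FST from pooled sequencing being
the canonical case — are usually analyzed in windows of adjacent markers.
Fixed-size sliding or distinct windows force an arbitrary size choice, can
split a real signal across a boundary, and (for sliding windows) produce
thousands of correlated tests.  `splinewin` instead fits a penalized cubic
smoothing spline

    S(f) = Σᵢ {Yᵢ − f(tᵢ)}² + λ ∫ f″(x)² dx

to the per-SNP values of one chromosome, with λ chosen by generalized or
leave-one-out cross-validation, and uses the **inflection points of the
fitted spline** (sign changes of f̂″) as window boundaries.  Peaks of the
fit are concave-down, so every candidate signal falls inside a single
window, and window sizes adapt to the local signal-to-noise structure.
Windows of unequal size are compared with the t-like statistic

    W = (X̄ − μ) / √(s²/n),

where X̄ is the window mean, μ and s² are the mean and sample variance of
the statistic over the whole dataset, and n is the number of SNPs in the
window.  Outliers in W mark candidate selected regions.

The package is aimed at population geneticists running FST-style selection
scans (individual or Pool-seq data), and ships everything needed to
benchmark the approach: per-marker FST, a two-stage binomial Pool-seq
sampling model, fixed-window baselines, a Wright-Fisher truncation-selection
simulator, and a null-calibrated true/false-positive evaluation harness.

## Worked example

Generate a deterministic 200-marker fixture with one selection-style bump
at 500 kb, analyze it, and scan for outliers:

```sh
splinewin fixture --kind figure1 --seed 7 -o markers.tsv
splinewin analyze markers.tsv -o windows.tsv
```

`analyze` fits the spline (GCV), finds inflection points at 100-bp
resolution, and writes one row per window.  The fixture's bump sits at
500 kb, and the output shows exactly one strongly outlying window covering
it (27 windows total; excerpt):

```
 CHROM  WindowStart  WindowStop  SNPcount  MeanY   Wstat
     1       349484      452384        22 0.2118  1.1089
     1       452384      553384        24 0.5432 11.3057
     1       553384      698584        33 0.1718 -0.0783
```

The window [452384, 553384) holds 24 SNPs with mean FST 0.54 against a
dataset mean of ~0.12; W = 11.3 because that elevation is sustained over
24 markers — a small window with one noisy SNP at 0.54 would score far
lower.  Neighboring windows are near or below zero: spline boundaries keep
the outlying region cleanly separated instead of smearing it over
overlapping windows.

Per-marker FST from pre/post allele frequencies (or pooled read counts),
and simulated experiments, come from the other subcommands:

```sh
splinewin fst freqs.tsv -o fst.tsv          # CHROM POS FREQ_PRE FREQ_POST -> FST
splinewin simulate --seed 3 --outdir sims/  # Wright-Fisher selection replicate
splinewin benchmark --seed 1 -o table.tsv   # method comparison, null-calibrated
splinewin scan windows.tsv -o regions.tsv   # 99.9% outliers, 5-Mb merging
```

As a library: `splinewin.spline_analyze(series)` is the main entry point;
`read_marker_table`, `fst_table`, `run_benchmark`, and `scan` cover the
pipeline.  See `docs/methods.md` for the model, the founder-population
surrogate used by the simulator, and the numerical choices.

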