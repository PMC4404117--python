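# Methods

## The spline-window method

Per-SNP values of a noisy genomic statistic — here the two-population FST at
marker *i*, position *t_i* (bp) — are modeled as observations
*Y_i = f(t_i) + e_i* of a smooth underlying function *f* on one chromosome.
The estimate *f̂* is the cubic smoothing spline minimizing

    S(f) = Σ_i {Y_i − f(t_i)}² + λ ∫ f″(x)² dx,

a natural cubic spline with knots at the marker positions.  The smoothing
parameter λ is chosen to minimize either the generalized cross-validation
score GCV(λ) = n·RSS/(n − tr A)² (default) or the exact leave-one-out CV
score mean[{(Y_i − f̂_i)/(1 − A_ii)}²], where A(λ) is the smoother ("hat")
matrix.

Window boundaries are the inflection points of *f̂*: positions where *f̂″*
changes sign.  Since *f̂* is concave-down at every local maximum, any peak
lies strictly inside a window, never on a boundary; window sizes adapt to
the local roughness of the fit.  Windows are scored with

    W = (X̄ − μ) / sqrt(s²/n),

X̄ the window mean, μ and s² the mean and sample variance (n−1 denominator)
of the statistic over the analyzed dataset, n the SNPs in the window.  W is
*not* t-distributed (markers are autocorrelated under drift and
hitchhiking); it is a size-adjusted scale on which windows of unequal n can
be ranked and thresholded.

### Numerical implementation

The solver uses the Reinsch band form: with second-difference matrix Q
(n×(n−2)) and Gram matrix R, the fitted values are g = y − λQγ where
(R + λQᵀQ)γ = Qᵀy.  The pentadiagonal system is solved by banded Cholesky
after diagonal equilibration; if factorization still breaks down at extreme
λ (near-duplicate marker spacings), it is retried with a relative diagonal
ridge growing from 1e−12 — a perturbation far below statistical noise.
Exact GCV and leave-one-out scores come from the central five bands of
(R + λQᵀQ)⁻¹, obtained from the Cholesky factor by the Takahashi/
Erisman–Tinney backward recursion in O(n); no dense matrix is ever formed.
Tests cross-check fitted values, hat diagonal, and CV scores against
`scipy.interpolate.make_smoothing_spline` and against brute-force
leave-one-out refits.

λ is selected over ~50 log-spaced candidates spanning 16 orders of
magnitude anchored at (mean marker spacing)³ — the penalty competes with
the residual term at the h³ scale — followed by golden-section refinement
in log λ around the grid minimum.  CV/GCV profiles need not be convex; the
grid finds the basin, refinement only polishes it.

Inflection points are read off a uniform grid (default resolution 100 bp,
matching common practice: finer grids are slow and jittery, coarser ones
miss features).  A grid value of *f̂″* is treated as zero when its
magnitude is below max(1e−9·max|f̂″|, 1e−4·range(f̂)/span²); the absolute
floor keeps exactly-flat or linear fits (whose curvature is pure float
noise, ~1e−19 in double precision) from spraying spurious boundaries, while
sitting ~6 orders of magnitude below any curvature that visibly moves the
fit.  A strict sign change between nearest nonzero-sign grid points yields
one boundary at their midpoint; zero plateaus therefore emit at most one
boundary.

Bookkeeping conventions: input positions are 1-based bp; windows are
half-open [start, stop) with boundaries snapped to integer bp (ceil, so a
marker sitting exactly on a boundary opens the right-hand window); BED
export shifts to 0-based.  Boundary intervals containing no marker are
merged rightward so every reported window has n ≥ 1.  Duplicate positions
are rejected, never silently averaged.  μ and s² default to the analyzed
chromosome's own moments; callers running multi-chromosome scans can (and
should) pass genome-wide moments instead — both scopes are supported
because neither is uniquely implied by the method's definition.

## FST and Pool-seq sampling

Per-marker FST between two populations uses the r = 2 variance estimator
FST = s²/(p̄(1−p̄) + s²/r) with s² the between-population sample variance of
the allele frequency (r−1 denominator, so s² = (p1−p2)²/2).  The estimator
is bounded in [0,1], symmetric, and invariant to allele relabeling;
monomorphic markers (p̄ ∈ {0,1}) are dropped with a logged count, never
emitted as NaN.

Pooled sequencing of n diploid individuals at coverage c is modeled as two
nested binomial draws (2n gametes from the population, then c reads from
the sampled gametes).  The estimate is unbiased with variance
p(1−p)·(1/2n + (1 − 1/2n)/c); the default design (n = 100, c = 50X) gives
sampling noise comparable to an FST of ~0.025 between identical
populations.  Depth is fixed at exactly c reads per site; Poisson-varying
depth is deliberately out of scope of the default model.

## The selection simulator

`simulate.SimConfig` describes a truncation-selection experiment in the
style of livestock-genetics forward simulators: a diploid genome of
`n_chrom` chromosomes with a uniform genetic map (default 200 cM / 100 Mb
= 2 cM/Mb), biallelic markers placed uniformly at random, and `n_qtl_per_chrom`
biallelic QTL at fixed map positions (default 50/100/150 cM) with standard
normal effects resampled per replicate (the effect scale is immaterial:
the environmental variance is calibrated from it).  Selection runs
`n_generations` (default 30) discrete generations: phenotype = genotypic
value + N(0, Ve) with Ve fixed at generation 0 so Vg/(Vg+Ve) = h² (default
0.5); the top `n_sires` males and `n_dams` females by phenotype mate
randomly, each dam producing `litter_size` offspring; gametes recombine
with Poisson crossovers on the cM map, without interference.  Null
replicates are identical except parents are drawn at random.  Outputs are
pre-selection (generation-0) and final-generation allele frequencies at
every marker plus the QTL truth table.

### Founder population surrogate

The reference full-scale design establishes its base population with 5000
historical generations of 5000 random-mating individuals, starting every
biallelic locus at frequency 0.5, with recurrent mutation at 2.5e−5.
Re-running that burn-in is the dominant cost at full scale, so this package
substitutes a two-part surrogate:

1. Founder allele frequencies are drawn from the Balding–Nichols
   distribution Beta(α, α) with α = (1−F)/(2F), where
   F = 1 − (1 − 1/2N)^t ≈ 0.39 for t = 5000, N = 5000, i.e. α ≈ 0.77.
   This matches the mean and variance of the Wright–Fisher transition
   density from p0 = 0.5 after the historical phase (which is *not* the
   mutation–drift stationary U-shape: t/2N ≈ 0.5 is far from stationarity).
   QTL columns monomorphic in the sampled pool are redrawn before the
   burn-in — a locus with no variance could not carry a trait effect.
2. A short explicit random-mating Wright–Fisher burn-in (default 30
   generations, 1000 individuals) with recombination and recurrent
   mutation builds linkage disequilibrium on top of the
   linkage-equilibrium draw.  Mutation is off after the burn-in, mirroring
   the reference design's historical-only mutation.

What the surrogate does **not** reproduce: coalescent haplotype structure.
A drifted real population carries alleles on narrow haplotype clusters
(sweeps are "hard"); a Beta + short-burn-in population spreads alleles over
many backgrounds, so hitchhiking is weaker at a given selection response.
Passing simulation tests therefore demonstrate the machinery and the
direction and rough magnitude of hitchhiking, not field-realistic LD decay.

### Scaled benchmark design

The packaged benchmark (`SimConfig.scaled()`) keeps the full-scale
chromosome verbatim — 200 cM / 100 Mb, 3 QTL at 50/100/150 cM, 30
generations, 4% of the census selected as parents, Pool-seq at 100
individuals / 50X — and scales the counts around it: 2 chromosomes instead
of 10, 5000 markers per chromosome instead of 100 000, census 10 000
(200 + 200 parents) instead of 25 000, and 20 selected + 10 null
replicates instead of 100 + 20.  A replicate takes ~20 s on one core; the
full benchmark runs in ~12 minutes.

Two scale effects cannot be removed at desk scale and are visible in every
scaled run:

- Drift noise: neutral divergence grows like F ≈ t/2Ne.  With 400 parents
  Ne ≈ 533 and F ≈ 0.028, ~2.5× the full-scale design's ~0.011.  Null
  maxima are correspondingly higher, thresholds harsher, and the detected
  fraction of QTL lower than the 50–67% reported at full scale.
- Marker density: 50 vs 500 markers/cM.  Sweep windows contain ~10× fewer
  SNPs, so W peaks are smaller relative to their null distribution.

The detections-to-false-positives *ordering* of methods — spline windows
ahead of fixed windows, which pay for genome-wide drift with either high
thresholds (small windows) or many false positives (large windows) — is
stable under scaling and is what the benchmark asserts.  W's normalization
by the dataset's own μ and s² partially absorbs the genome-wide heating of
selected replicates (selection reduces Ne), which raw mean-FST thresholds
for fixed windows do not; this inflates fixed-window false positives at
desk scale beyond their full-scale values.

## Thresholding and evaluation

Significance thresholds are simulation-calibrated: the maximum window
statistic (W for spline windows, window mean FST for fixed windows) is
recorded in each unselected replicate, and the 95% quantile of those maxima
(linear interpolation between order statistics) is the genome-wide
threshold for that method.  With m null maxima the attained family-wise
level is systematically above the nominal 5% for small m — order-statistic
algebra gives ≈ 13% at m = 10 and ≈ 9% at m = 20, for any continuous maxima
distribution — approaching 5% only as m grows.  The quantile rule is a
config knob because at m = 10 the choice materially moves the threshold.

Significant windows are classified against the QTL truth table: a window is
a true positive when any point of its span lies within 5 cM of a QTL (a
conservative radius: selection perturbs a linked segment, not a point);
each QTL counts at most once per replicate, so detections are bounded by
the number of simulated QTL; every significant window near no QTL counts
one false positive — including each overlapping sliding window, which is
why sliding methods accumulate large false-positive counts.  Methods are
ranked by mean detections / mean false positives.

The empirical-scan protocol for real datasets flags windows with W above
the 99.9% empirical quantile and merges flagged windows closer than 5 Mb
into candidate regions (same-chromosome only, idempotent).

## Problem sizes used by the packaged checks

Unit and property tests run on hundreds of markers and tiny populations
(census 200–500, ≤ 20 generations) chosen so each check isolates one
mechanism; the acceptance benchmark uses the scaled design above.  The
family-wise calibration check uses a one-chromosome, 800-marker null
configuration so that 110 replicates fit in about a minute; the family-wise
rate is a property of the thresholding protocol, not of the genome size.

## Known limitations

- One λ per chromosome; no region-specific smoothing.
- Statistics computed across haplotypes (Tajima's D, EHH) are out of scope;
  the spline input must be a per-marker statistic.
- r = 2 populations only; no read-error model on top of binomial pooling.
- The founder surrogate underrepresents haplotype structure (above), and
  crossovers are interference-free.
- The W statistic's null distribution is empirical by construction; no
  parametric p-values are offered anywhere.
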