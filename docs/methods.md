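# Methods

This note documents the models, the synthetic-data generators, the numerical
choices and the known limitations of `samgwas`. Everything quantitative
stated here is computed by the test suite or by `scripts/acceptance.py`.

## Parabolic SAM model and microphenotypes

A near-median longitudinal section of the shoot apical meristem (SAM) is
modeled as a parabola with the apex at the origin, opening downward:

    y = h − (h/r²)·x²,  x ∈ [−r, r]

with height h (apex to the P1-notch base level) and radius r (half-width at
that level), both in µm. The standard-form shape coefficient a = h/r² is
scale-bearing (µm⁻¹) but shape-defining: a·r² = h holds identically.

`fit_parabola` resamples the traced contour by spline interpolation at 51
evenly spaced x stations (the trace density of hand-drawn contours is
irregular), fits the full quadratic y = c0 + c1·x + c2·x² by least squares,
and takes the vertex as the apex. Fitting the linear term too makes the
procedure robust to imperfect centering. The base level is defined as the
**mean of the two contour endpoint y values**. Under symmetric measurement
noise this estimate is unbiased, whereas the minimum of the two endpoints is
biased low by about σ/√π, which would propagate into a systematic ~1%
overestimate of h and break the estimated-vs-measured area equivalence
below. Contours whose fitted c2 is not negative (not concave-down) and
contours with fewer than 7 points are rejected as degenerate.

From (h, r) the microphenotype set is, in closed form:

| quantity | formula | units |
|---|---|---|
| ratio | h/r | — |
| diameter | 2r | µm |
| midsection area | (4/3)·h·r | µm² |
| volume | (π/2)·r²·h | µm³ |
| coefficient | h/r² | µm⁻¹ |
| lateral surface | (πr/6h²)·((r²+4h²)^{3/2} − r³) | µm² |
| arc length | √(r²+4h²) + (r²/2h)·asinh(2h/r) | µm |

These are the standard parabolic-segment / paraboloid-of-revolution results.
Each is verified against adaptive numeric integration to a relative 1e−8
over the grid h, r ∈ {0.5, 1, 2, 5, 10}². The surface area is lateral only
(no base disc). `estimate_vs_measured_area` contrasts the model area
(4/3)·h·r with the shoelace polygon area of the trace closed along its base
chord; a self-intersecting *trace* is an error, but closing-chord crossings
caused by noise at the base are tolerated (the shoelace sum is still the
natural area estimate there).

## BLUP phenotyping and repeatability

Replicated phenotypes are modeled as y_ij = μ + ρ_j + g_i + e_ij with the
growth-batch (replicate) effect ρ_j fixed — only 4 levels, so treating it as
random would rest on a 4-point variance estimate — and the genotype effect
g_i random i.i.d. N(0, σ²_g). REML estimation is profiled to a 1-D bounded
search over log λ, λ = σ²_e/σ²_g ∈ [e⁻¹⁰, e¹⁰], which is exact for a single
random effect; the spectral decomposition of ZZ' is computed once per fit.
Negative/zero variance estimates are clamped to 1e−12 with a warning.
Genotype values are reported in BLUP+intercept form. Entry-mean
repeatability is H² = σ²_g/(σ²_g + σ²_e/n̄) with n̄ the harmonic mean of
per-genotype replicate counts (the standard entry-mean formula for
unbalanced data). A `replicate_fixed=False` switch drops the batch term for
sensitivity analysis.

## SNP-matrix construction

Thresholds default to: base quality < 15 trimmed; overlapping 10-bp quality
windows; alignments kept when unique with ≤ 2 mismatches per started 36 bp
and < 5 unaligned tail bases per started 75 bp (ceiling proration); calls
need base quality ≥ 20 and ≥ 5 unique supporting reads after masking the 3
terminal aligned bases of each read; sites with MAF < 1% (non-missing calls)
or missingness > 60% (strict) are excluded.

Two readings of the window-trimming sentence are possible: truncate at the
first window whose mean quality fails, or keep through the last passing
window. The first is implemented; more importantly, a single
end-strip-then-window pass is not idempotent (truncation can expose a
low-quality 3' base that end-stripping would then remove), so the two
phases are **iterated to a fixed point**, making `trim_read` idempotent by
construction.

Homozygous calls additionally require a supporting-read fraction ≥ 0.9
("putative homozygous" needs a purity rule for an inbred panel; the value is
a parameter). "Unique reads" means distinct read ids. Coordinates are
0-based half-open internally; VCF output is 1-based. Consensus merging of
repeated runs keeps agreeing non-missing calls, scores conflicts missing,
and ignores missing entries when a concrete call exists; it is
order-invariant.

## Mixed-model GWAS

The scan is the EMMAX/P3D form of the unified mixed model: eigendecompose
the kinship once, estimate (σ²_g, σ²_e) by null-model REML (the same 1-D
profile), and with P3D (default) reuse those components for every SNP,
reducing each test to weighted least squares on the rotated data. Exact
per-SNP REML is available (`p3d=False`); on simulated panels the two differ
by < 0.2 −log₁₀p units. Wald t-tests use n − rank(X) − 1 degrees of
freedom. Missing genotypes are mean-imputed per site for testing only.

Kinship is the VanRaden centered-genotype matrix K = WW'/Σ2p_k(1−p_k). For
a fully homozygous panel the dosage variance is 4p(1−p), so K's diagonal
sits near 2 rather than 1; the scale is absorbed by σ²_g and does not
affect p-values. Structure covariates are genotype principal components;
the number (0..3) is chosen by BIC on the null-model restricted likelihood
(−2·logLik + k·log n, k counting fixed effects plus two variance
components). Compression — hierarchical clustering of individuals on
kinship with a group-mean K — is provided as an optional mode; the default
is no compression, which changes nothing at the panel sizes used here.

The genome-wide threshold is Bonferroni, T = −log₁₀(α/M), with M the number
of sites actually tested after filtering. Candidate genes are assigned to a
trait-associated SNP (TAS) when the gene interval expanded by the window
(default 100 kb) contains the SNP; containment in the unexpanded interval
sets the inside flag with distance 0. The ALT burden of an individual is
its count of homozygous-ALT calls over the TAS set (missing skipped),
correlated with the phenotype by Pearson r with Fisher-transformation
significance.

## Cytometry

Nuclei segmentation is a fixed deterministic pipeline: Gaussian smoothing
(σ = 1 px), background subtraction (σ = 10 px), Otsu threshold computed
within the SAM mask but applied on a 3-px dilation of it (so nuclei touching
the mask boundary keep their full shape), distance-transform watershed with
peak separation ≥ 4 px and a 4-px² minimum object area, and
intensity-weighted centroids (robust to asymmetric clipping). Objects whose
centroid falls outside the mask are dropped. The defaults suit the
generator's rendering scale (~1 µm/px, 1-px nuclei σ); all scales are
parameters.

The cell lattice is the pixel-wise Voronoi partition of the mask by nearest
centroid; distance ties break to the lowest centroid index for bit-exact
reproducibility. Cell areas therefore sum to the mask area identically, SCN
is the centroid count and ASCS = mask area / SCN. Cell size is defined on
the 2-D median section, not in 3-D. The SCN/ASCS model is a sequential
(Type-I) two-way ANOVA, response ~ genotype class + volume + interaction;
with Type-I ordering the genotype term is only interpretable when classes
are sampled balanced across the volume range, which is how the cytometry
stage and the tests construct their designs.

## Synthetic-data generators

All generators draw from independent substreams of one master seed and
record exact ground truth (never re-estimated) for the tests. Defaults
emulate the study conditions: 369 genotypes × 4 replicates, SAM sizes
log-normal with medians h = 100 µm, r = 80 µm and CV 0.15 (the panel's size
distribution is not fully constrained by published summaries; these medians
put volumes near 10⁶ µm³), contour noise SD 2 µm, batch-effect SD 2×10⁴ µm³,
5% germination dropout, ALT frequencies in (0.01, 0.09), 10%
missingness, and replicate-level polygenic heritability 0.5676 — the value
that makes entry-mean repeatability 0.84 at 4 replicates. `n_snps` defaults
to 5,000: a desk-scale stand-in for the combined 1.28-million-site matrix,
whose size enters only through the Bonferroni threshold (computed exactly at
the published M).

Genotypes: each site's ALT frequency p is drawn uniformly from
`alt_freq_range` and realized **exactly** — round(p·n) lines carry the ALT
allele — so realized common-allele frequencies stay inside the configured
band. (With i.i.d. Bernoulli carriers, binomial dispersion alone pushes
~7% of sites past the band edge at n = 400, and Balding–Nichols frequency
drift far more.) Population structure instead enters through *where* the
carriers sit: they are allocated across round-robin subpopulations with
Balding–Nichols weights at differentiation `fst` (default 0.1), which gives
the leading genotype PCs and the kinship matrix clear subpopulation
block structure while preserving site-level frequencies.

Phenotypes: y_ij = μ + Σ β_k·g_ik/2 + g_i + b_j + e_ij, with the polygenic
g ~ N(0, σ²_g K) drawn through a Cholesky factor of the VanRaden kinship.
Contours carry the same genetic signal when a genotype matrix is supplied:
the per-genotype volume is converted to (h, r) at a log-normally drawn
aspect ratio, and replicate volumes add batch plus biological residual
noise, so the signal flows genotype → image → fit → BLUP → GWAS.

Nuclei images: about (4/3)·h·r / mean_cell_area nuclei are placed by
hard-core sampling (minimum distance 0.75·√mean_cell_area — about half the
random-sequential-adsorption jamming density, so target counts remain
reachable while Voronoi cells stay well conditioned) and rendered as
Gaussian blobs.

Reads are error-free with exact tiled depth; qualities follow named
profiles ("uniform" Q40, "degraded_tail" with the last 10 bases far below
the trimming threshold). Features deliberately not emulated: linkage
disequilibrium beyond shared drift, heterozygosity, sequencing base errors,
indels, DIC optics, 3-D confocal stacks. Passing tests therefore validate
the analysis chain's contracts and calibration, not robustness to those
real-data complications.

## Problem sizes

The calibration suite uses 400 individuals × 5,000 SNPs with 200 null
replicates and 100 power replicates; BLUP recovery uses 20 genotypes × 4
replicates over 200 seeds; fit recovery uses 100 seeds at 200 contour
points; cytometry uses 25 image pairs. These sizes give the quoted
tolerances comfortable Monte-Carlo margins on a single CPU.

## Known limitations

* The MLM assumes a homoskedastic polygenic term; strong cryptic family
  structure beyond the simulated subpopulations is untested.
* The Type-I ANOVA genotype term is order-dependent by design; unbalanced
  observational designs need Type-II/III instead.
* `extract_contour` assumes a single bright dome; it is not a general
  segmenter for cluttered micrographs.
* Compression mode groups by average-linkage clustering only and is not
  likelihood-optimized per group count.
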