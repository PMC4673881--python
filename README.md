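# samgwas

**From microscope images of the shoot apical meristem to genotype–phenotype
associations.**

The maize shoot apical meristem (SAM) is a microscopic dome of stem cells
that builds every above-ground organ of the plant. Its median longitudinal
profile is closely approximated by a parabola, which turns a traced outline
into two numbers — height *h* and radius *r* — and from them a full set of
derived microphenotypes (volume, surface area, arc length, shape
coefficient *a = h/r²*). `samgwas` implements the complete quantitative
chain needed to map natural variation in such microphenotypes:

1. **morphometrics** — spline-resampled quadratic regression of SAM
   contours; microphenotypes from the closed-form paraboloid geometry
   (volume = (π/2)·r²·h, midsection area = (4/3)·h·r, lateral surface, arc
   length).
2. **blup** — replicate-batch mixed models (REML, profiled to a 1-D search)
   giving BLUP+intercept phenotypes and the entry-mean repeatability
   H² = σ²_g/(σ²_g + σ²_e/n̄).
3. **variants** — RNAseq-style SNP matrix construction: two-phase PHRED
   quality trimming, unique-alignment filters (≤2 mismatches/36 bp,
   <5 tail bases/75 bp), homozygous pileup calling (q ≥ 20, ≥5 unique
   reads, 3-bp end masking), consensus merging, MAF ≥ 1% and
   missingness ≤ 60% filters, VCF in/out.
4. **gwas** — unified mixed linear model y = Xβ + sα + u + e with
   u ~ N(0, σ²_g K): VanRaden kinship, BIC-selected principal-component
   covariates, spectral P3D scan, Bonferroni trait-associated-SNP (TAS)
   calling at −log₁₀(α/M), 100-kb candidate-gene mapping, and ALT-allele
   burden correlation (Pearson r, Fisher-transformation p).
5. **cytometry** — nuclei segmentation (Otsu + distance-transform
   watershed) and a pixel-exact Voronoi cell lattice giving SAM cell number
   (SCN) and average cell size (ASCS), with sequential two-way ANOVA.
6. **synthgen / pipeline** — seeded generators for every input (contours,
   genotype matrices with population structure and rare ALT alleles,
   replicate phenotype tables, reads + alignments, nuclei images) plus an
   end-to-end orchestrator with a checksummed run manifest.

The library is the interface: import the modules, or start from the
narrative scripts in `examples/`. A thin CLI (`samgwas simulate`,
`samgwas run`) covers the two shell-natural entry points.

## Worked example

```python
from samgwas.config import SimConfig
from samgwas.morphometrics import fit_parabola, derive_phenotypes
from samgwas.synthgen import gen_contours

cfg = SimConfig(seed=42, n_genotypes=1, n_replicates=1, noise_sd=2.0)
contours, truth = gen_contours(cfg, n_points=200)
fit = fit_parabola(contours[0], n_stations=200)
print(fit.h, fit.r, fit.a)
print(derive_phenotypes(fit.h, fit.r).volume)
```

prints (true h was 98.57 µm, true r 84.98 µm):

```
98.71 85.42 0.013528
1131317.46
```

i.e. the fit recovers the generating parabola to well under 1% despite 2 µm
point noise, and the SAM volume — the phenotype used for association — is
1.13 × 10⁶ µm³. Running `python examples/04_gwas_scan.py` continues the
chain on a simulated 300-line panel: the mixed model recovers both planted
causal SNPs as TAS (−log₁₀p ≈ 19.6 against a Bonferroni line of 5.60 for
M = 3,987 tested sites; at the full published matrix size of 1,281,000
sites the same rule gives 8.11), maps nearby candidate genes within 100 kb,
and reports an ALT-burden correlation with SAM volume of r = 0.7,
P < 2.22e−16.

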