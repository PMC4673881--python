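"""Seeded synthetic-data generators for every pipeline input.

The generators emulate the structure of the real study: a panel of inbred
genotypes grown in replicated batches, parabolic SAM profiles traced from
micrographs, a homozygous SNP matrix with population structure and rare ALT
alleles, short reads for RNAseq-style SNP calling, and stained-nuclei
section images inside a parabolic SAM mask. Every generator draws from an
independent substream of the master seed (:meth:`SimConfig.rng`), writes
exact ground truth into a :class:`SyntheticTruth` record for the tests, and
is byte-deterministic under a fixed config.

Real-data features deliberately not emulated: linkage disequilibrium beyond
shared subpopulation drift, heterozygosity, sequencing base errors, and
optical (DIC) artifacts.
"""

from __future__ import annotations

from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from samgwas.config import InvalidConfigError, SimConfig, SyntheticTruth
from samgwas.cytometry import SAMMask, parabola_mask
from samgwas.morphometrics import SAMContour
from samgwas.variants import MISSING, AlignmentRecord, GenotypeMatrix, ReadRecord
from samgwas.gwas import GeneAnnotation

__all__ = [
    "gen_contours",
    "gen_genotypes",
    "gen_phenotypes",
    "gen_nuclei_image",
    "gen_reads",
    "gen_genes",
    "genotype_ids",
    "replicate_ids",
]

N_CONTOUR_POINTS = 51


def genotype_ids(cfg: SimConfig) -> list[str]:
    width = max(3, len(str(cfg.n_genotypes)))
    return [f"Inb{i + 1:0{width}d}" for i in range(cfg.n_genotypes)]


def replicate_ids(cfg: SimConfig) -> list[str]:
    return [f"rep{j + 1}" for j in range(cfg.n_replicates)]


# ---------------------------------------------------------------------------
# SAM sizes and contours


def _genotype_sizes(cfg: SimConfig, rng: np.random.Generator, geno: GenotypeMatrix | None, truth: SyntheticTruth):
    """Per-genotype true (h, r) in µm, log-normal across the panel.

    With a genotype matrix supplied, the per-genotype SAM volume carries the
    causal-SNP and polygenic signal from :func:`_genetic_values`, and (h, r)
    are recovered from that volume at a log-normally drawn aspect ratio —
    so the genetic signal flows through the imaging chain.
    """
    n = cfg.n_genotypes
    sd_log = np.sqrt(np.log1p(cfg.size_cv**2))
    if geno is None:
        h = cfg.height_median * np.exp(rng.normal(0, sd_log, n))
        r = cfg.radius_median * np.exp(rng.normal(0, sd_log, n))
    else:
        gvals = _genetic_values(geno, cfg, rng, truth)
        volumes = np.maximum(cfg.pheno_mean + gvals, 0.05 * cfg.pheno_mean)
        ratio = (cfg.height_median / cfg.radius_median) * np.exp(rng.normal(0, sd_log / 2, n))
        r = (2.0 * volumes / (np.pi * ratio)) ** (1.0 / 3.0)
        h = ratio * r
    return h, r


def gen_contours(
    cfg: SimConfig,
    geno: GenotypeMatrix | None = None,
    n_points: int = N_CONTOUR_POINTS,
) -> tuple[list[SAMContour], SyntheticTruth]:
    """Parabolic SAM contours for every genotype × replicate.

    Points are sampled at evenly spaced x on y = h − (h/r²)x², x ∈ [−r, r],
    with i.i.d. Gaussian measurement noise of SD ``cfg.noise_sd`` on y.
    Replicate-level (h, r) are the genotype values shifted on the volume
    scale by an additive batch offset (SD ``cfg.batch_effect_sd``) plus a
    biological replicate residual with variance
    (1 − h2_polygenic)·pheno_sd², so entry-mean repeatability of volume
    lands in the regime the replicate count implies.
    """
    rng = cfg.rng("contours")
    truth = SyntheticTruth()
    h_g, r_g = _genotype_sizes(cfg, rng, geno, truth)
    gids, rids = genotype_ids(cfg), replicate_ids(cfg)
    batch = rng.normal(0, cfg.batch_effect_sd, cfg.n_replicates)
    truth.batch_effects = dict(zip(rids, batch.tolist()))
    contours: list[SAMContour] = []
    for i, gid in enumerate(gids):
        truth.true_h[gid] = float(h_g[i])
        truth.true_r[gid] = float(r_g[i])
        v_i = (np.pi / 2) * r_g[i] ** 2 * h_g[i]
        ratio = h_g[i] / r_g[i]
        for j, rid in enumerate(rids):
            e_ij = rng.normal(0, np.sqrt((1.0 - cfg.h2_polygenic)) * cfg.pheno_sd)
            v_ij = max(v_i + batch[j] + e_ij, 0.05 * v_i)
            r_ij = (2.0 * v_ij / (np.pi * ratio)) ** (1.0 / 3.0)
            h_ij = ratio * r_ij
            truth.replicate_h[(gid, rid)] = float(h_ij)
            truth.replicate_r[(gid, rid)] = float(r_ij)
            x = np.linspace(-r_ij, r_ij, n_points)
            y = h_ij - (h_ij / r_ij**2) * x**2
            y = y + rng.normal(0, cfg.noise_sd, n_points)
            contours.append(SAMContour(genotype=gid, replicate=rid, x=x, y=y))
    return contours, truth


# ---------------------------------------------------------------------------
# genotype matrix


def subpop_assignment(cfg: SimConfig) -> np.ndarray:
    """Deterministic round-robin subpopulation labels for the panel."""
    return np.arange(cfg.n_genotypes) % cfg.n_subpops


def gen_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Homozygous-inbred SNP matrix with subpopulation structure.

    Per site an ALT frequency p is drawn uniformly from
    ``cfg.alt_freq_range`` and realized exactly: round(p·n) lines carry the
    ALT allele homozygously, so site-level common-allele frequencies stay
    inside the configured band (above 0.91 with the default (0.01, 0.09)
    range). Population structure comes from allocating those carriers
    unevenly across round-robin subpopulations with Balding–Nichols weights
    at differentiation ``cfg.fst``; missingness is applied uniformly.
    """
    rng = cfg.rng("genotypes")
    n, m = cfg.n_genotypes, cfg.n_snps
    lo, hi = cfg.alt_freq_range
    p_site = rng.uniform(lo, hi, m)
    subpop = subpop_assignment(cfg)
    members = [np.flatnonzero(subpop == s) for s in range(cfg.n_subpops)]
    sizes = np.array([len(ix) for ix in members])
    calls = np.zeros((n, m), dtype=np.int8)
    f = cfg.fst
    for j in range(m):
        c = int(round(p_site[j] * n))
        if c == 0:
            continue
        if f > 0 and cfg.n_subpops > 1:
            p_s = rng.beta(p_site[j] * (1 - f) / f, (1 - p_site[j]) * (1 - f) / f, cfg.n_subpops)
        else:
            p_s = np.full(cfg.n_subpops, p_site[j])
        weights = sizes * p_s
        weights = weights / weights.sum()
        # allocate the fixed carrier total across subpops, respecting sizes
        c_s = rng.multinomial(c, weights)
        while (over := c_s - sizes).max() > 0:
            excess = np.clip(over, 0, None)
            c_s = np.minimum(c_s, sizes)
            room = sizes - c_s
            redist = room / room.sum()
            c_s = c_s + rng.multinomial(int(excess.sum()), redist)
        for s, ix in enumerate(members):
            if c_s[s]:
                chosen = rng.choice(ix, int(c_s[s]), replace=False)
                calls[chosen, j] = 2
    if cfg.missing_rate > 0:
        calls[rng.random((n, m)) < cfg.missing_rate] = MISSING
    # 10 chromosomes, positions spaced 1 kb apart
    n_chrom = 10
    chrom_of = np.arange(m) % n_chrom + 1
    pos = (np.arange(m) // n_chrom) * 1000 + 500
    bases = np.array(list("ACGT"))
    com = bases[rng.integers(0, 4, m)]
    alt = np.array([bases[(list(bases).index(c) + rng.integers(1, 4)) % 4] for c in com])
    sites = pd.DataFrame({"chrom": [f"chr{c}" for c in chrom_of], "pos": pos, "com": com, "alt": alt})
    return GenotypeMatrix(individuals=genotype_ids(cfg), sites=sites, calls=calls, source="genomic")


# ---------------------------------------------------------------------------
# phenotypes


def _genetic_values(
    geno: GenotypeMatrix, cfg: SimConfig, rng: np.random.Generator, truth: SyntheticTruth
) -> np.ndarray:
    """Causal-SNP plus kinship-structured polygenic values, variance-scaled.

    σ²_g = h2_polygenic · pheno_sd²; the polygenic part is N(0, σ²_g K)
    drawn through a jittered Cholesky factor of the VanRaden kinship.
    """
    from samgwas.gwas import kinship

    n = geno.n_individuals
    fixed = np.zeros(n)
    for idx, effect in cfg.causal_effects:
        dose = geno.calls[:, idx].astype(float)
        dose[geno.calls[:, idx] == MISSING] = 0.0
        fixed += effect * dose / 2.0
    sigma2_g = cfg.h2_polygenic * cfg.pheno_sd**2
    if sigma2_g > 0:
        k = kinship(geno).values + 1e-6 * np.eye(n)
        chol = np.linalg.cholesky(k)
        poly = np.sqrt(sigma2_g) * (chol @ rng.standard_normal(n))
        # normalize so the realized polygenic variance matches σ²_g on average
        poly *= 1.0 / max(np.sqrt(np.mean(np.diag(k))), 1e-6)
    else:
        poly = np.zeros(n)
    g = fixed + poly
    truth.causal_snps = list(cfg.causal_effects)
    truth.sigma2_g = float(sigma2_g)
    truth.genetic_values = dict(zip(geno.individuals, g.tolist()))
    return g


def gen_phenotypes(geno: GenotypeMatrix, cfg: SimConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Replicate-level phenotype table y_ij = μ + Σ_k β_k·g_ik/2 + g_i + b_j + e_ij.

    g_i is the kinship-structured polygenic value with variance
    h2_polygenic·pheno_sd², b_j an additive batch effect per replicate
    (SD batch_effect_sd) and e_ij residual noise with variance
    (1−h2_polygenic)·pheno_sd². A fraction ``germination_dropout`` of
    genotype×replicate cells is dropped to emulate failed germination.
    """
    rng = cfg.rng("phenotypes")
    truth = SyntheticTruth()
    g = _genetic_values(geno, cfg, rng, truth)
    sigma2_e = (1.0 - cfg.h2_polygenic) * cfg.pheno_sd**2
    truth.sigma2_e = float(sigma2_e)
    rids = replicate_ids(cfg)
    batch = rng.normal(0, cfg.batch_effect_sd, cfg.n_replicates)
    truth.batch_effects = dict(zip(rids, batch.tolist()))
    rows = []
    for i, gid in enumerate(geno.individuals):
        for j, rid in enumerate(rids):
            if rng.random() < cfg.germination_dropout:
                continue
            y = cfg.pheno_mean + g[i] + batch[j] + rng.normal(0, np.sqrt(sigma2_e))
            rows.append({"genotype": gid, "replicate": rid, "value": y})
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# nuclei images


def gen_nuclei_image(
    h: float,
    r: float,
    mean_cell_area: float,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    blob_sigma_px: float = 2.0,
    background_sd: float = 0.0,
) -> tuple[np.ndarray, SAMMask, np.ndarray]:
    """Render a stained-nuclei section image inside a parabolic SAM mask.

    About (parabolic-segment area)/(mean_cell_area) nuclei are placed by
    hard-core (minimum-distance) inhibition sampling, so the downstream
    Voronoi cells are well conditioned; each nucleus is a Gaussian blob.
    Returns (image, mask, true centroids in µm as (x, y)).
    """
    if mean_cell_area <= 0:
        raise InvalidConfigError("mean_cell_area must be positive")
    if rng is None:
        rng = cfg.rng("nuclei")
    mask = parabola_mask(h, r, pixel_scale=cfg.pixel_scale)
    area = (4.0 / 3.0) * h * r  # analytic segment area, µm²
    n_target = max(1, int(round(area / mean_cell_area)))
    d_min = 0.75 * np.sqrt(mean_cell_area)
    rows, cols = np.nonzero(mask.mask)
    H, W = mask.mask.shape
    placed: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = 400 * n_target
    while len(placed) < n_target and attempts < max_attempts:
        attempts += 1
        k = rng.integers(0, rows.size)
        x_um = cols[k] * cfg.pixel_scale
        y_um = (H - 1 - rows[k]) * cfg.pixel_scale
        if all((x_um - px) ** 2 + (y_um - py) ** 2 >= d_min**2 for px, py in placed):
            placed.append((x_um, y_um))
    centroids = np.array(sorted(placed))
    img = np.zeros((H, W), dtype=float)
    yy, xx = np.mgrid[0:H, 0:W]
    for x_um, y_um in centroids:
        cx = x_um / cfg.pixel_scale
        cy = (H - 1) - y_um / cfg.pixel_scale
        img += 1000.0 * np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * blob_sigma_px**2)))
    if background_sd > 0:
        img += rng.normal(0, background_sd, img.shape)
    return img, mask, centroids


def write_image_tiff(image: np.ndarray, path: str | Path) -> None:
    """Write a rendered section image as 16-bit grayscale TIFF."""
    import tifffile

    img = np.asarray(image, dtype=float)
    lo, hi = img.min(), img.max()
    scaled = np.zeros_like(img) if hi == lo else (img - lo) / (hi - lo)
    tifffile.imwrite(str(path), (scaled * 65535).astype(np.uint16))


def read_image(path: str | Path) -> np.ndarray:
    """Load a grayscale TIFF/PNG section image as a float array."""
    from skimage import io

    img = io.imread(str(path))
    if img.ndim == 3:
        img = img.mean(axis=2)
    return img.astype(float)


# ---------------------------------------------------------------------------
# reads and alignments


def _quality_uniform(length: int, rng: np.random.Generator) -> list[int]:
    return [40] * length

def _quality_degraded_tail(length: int, rng: np.random.Generator) -> list[int]:
    """High-quality body, last 10 bases degraded well below the q15 threshold."""
    q = np.full(length, 38, dtype=int)
    tail = min(10, length)
    q[length - tail :] = np.clip(np.round(rng.normal(10, 2, tail)), 2, 14).astype(int)
    return q.tolist()

QUALITY_PROFILES: dict[str, Callable[[int, np.random.Generator], list[int]]] = {
    "uniform": _quality_uniform,
    "degraded_tail": _quality_degraded_tail,
}


def gen_reads(
    reference: str,
    variant_sites: Sequence[tuple[int, str]],
    depth: int,
    quality_profile: str | Callable[[int, np.random.Generator], list[int]] = "uniform",
    seed: int = 0,
    read_length: int = 75,
    chrom: str = "chr1",
    sample: str = "sample",
) -> tuple[list[ReadRecord], list[AlignmentRecord]]:
    """Error-free reads for one homozygous sample, with exact tiling depth.

    ``variant_sites`` lists (0-based position, ALT base) pairs the sample
    carries homozygously; every read overlapping such a site reports the ALT
    base. Reads tile the reference in ``depth`` staggered layers so interior
    positions are covered exactly ``depth`` times. Per-base qualities follow
    the chosen profile ("uniform" = Q40 everywhere, "degraded_tail" = last
    10 bases far below the q15 trimming threshold).
    """
    if depth <= 0:
        raise InvalidConfigError("depth must be positive")
    rng = np.random.default_rng(seed)
    profile = QUALITY_PROFILES[quality_profile] if isinstance(quality_profile, str) else quality_profile
    alt_at = dict(variant_sites)
    sample_seq = list(reference)
    for pos, alt in alt_at.items():
        sample_seq[pos] = alt
    sample_seq = "".join(sample_seq)
    reads: list[ReadRecord] = []
    alns: list[AlignmentRecord] = []
    idx = 0
    for layer in range(depth):
        offset = round(layer * read_length / depth)
        for start in range(offset, len(reference) - read_length + 1, read_length):
            bases = sample_seq[start : start + read_length]
            quals = profile(read_length, rng)
            rid = f"{sample}:read{idx:06d}"
            idx += 1
            nm = sum(1 for p in alt_at if start <= p < start + read_length)
            reads.append(ReadRecord(id=rid, bases=bases, qualities=quals))
            alns.append(
                AlignmentRecord(
                    read_id=rid,
                    chrom=chrom,
                    pos=start,
                    length=read_length,
                    mismatches=nm,
                    tail=0,
                    unique=True,
                    bases=bases,
                    qualities=quals,
                )
            )
    return reads, alns


# ---------------------------------------------------------------------------
# gene annotations


def gen_genes(
    cfg: SimConfig,
    n_genes: int = 50,
    gene_length: int = 3000,
    chrom_length: int | None = None,
) -> list[GeneAnnotation]:
    """Random non-overlapping gene intervals over the simulated chromosomes.

    Positions land on the same 10-chromosome layout as
    :func:`gen_genotypes`, so candidate-gene mapping against a simulated
    scan is exercised end to end.
    """
    rng = cfg.rng("genes")
    n_chrom = 10
    if chrom_length is None:
        chrom_length = ((cfg.n_snps // n_chrom) + 1) * 1000
    genes: list[GeneAnnotation] = []
    starts_by_chrom: dict[str, list[int]] = {}
    attempts = 0
    while len(genes) < n_genes and attempts < 100 * n_genes:
        attempts += 1
        chrom = f"chr{rng.integers(1, n_chrom + 1)}"
        start = int(rng.integers(0, max(1, chrom_length - gene_length)))
        if any(abs(start - s) < gene_length for s in starts_by_chrom.get(chrom, [])):
            continue
        starts_by_chrom.setdefault(chrom, []).append(start)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneAnnotation(
                gene_id=f"GENE{len(genes) + 1:04d}",
                chrom=chrom,
                start=start,
                end=start + gene_length,
                strand=strand,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def write_genes_bed(genes: list[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_genes_bed(path: str | Path) -> list[GeneAnnotation]:
    genes = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            genes.append(
                GeneAnnotation(
                    gene_id=f[3] if len(f) > 3 else f"{f[0]}:{f[1]}",
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    strand=f[5] if len(f) > 5 else "+",
                )
            )
    return genes
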