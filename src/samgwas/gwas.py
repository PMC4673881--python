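"""Unified mixed-model genome-wide association.

The scan fits, for each SNP s,

    y = Xβ + s·α + u + e,   u ~ N(0, σ²_g K),   e ~ N(0, σ²_e I),

where y is the BLUP+intercept phenotype per individual, X holds an intercept
plus optional genotype principal components, and K is the VanRaden
centered-genotype kinship matrix. A single eigendecomposition of K rotates
the model to independent errors; the null-model variance components are
estimated once by profiled REML and, with P3D (population parameters
previously determined, the default), reused for every SNP test, which makes
million-site scans a sequence of weighted least-squares solves. Significance
uses a Wald t-test; trait-associated SNPs (TAS) are those exceeding the
Bonferroni threshold −log10(α/M) for M tested sites.

Compression — replacing individuals by kinship-derived groups — is available
as an optional mode; the default leaves every individual in its own group,
which changes no contract at panel scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from samgwas.variants import MISSING, GenotypeMatrix

__all__ = [
    "KinshipMatrix",
    "MLMResult",
    "TASRecord",
    "GeneAnnotation",
    "kinship",
    "genotype_pcs",
    "select_model",
    "mlm_scan",
    "bonferroni_threshold",
    "call_tas",
    "map_candidates",
    "alt_burden",
]


@dataclass
class KinshipMatrix:
    """Genomic relatedness among the panel's individuals."""

    values: np.ndarray
    individuals: list[str]
    method: str = "vanraden"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.individuals)
        if self.values.shape != (n, n):
            raise ValueError("kinship must be n×n for n individuals")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("kinship must be symmetric")


@dataclass
class MLMResult:
    """Per-SNP association statistics plus the model metadata of one scan."""

    table: pd.DataFrame  # chrom, pos, com, alt, effect, se, neglog10p
    n_pcs: int
    sigma2_g: float
    sigma2_e: float
    p3d: bool
    m_tested: int
    alpha: float
    threshold: float  # −log10(alpha / m_tested)


@dataclass
class TASRecord:
    """One trait-associated SNP and its candidate-gene assignments."""

    chrom: str
    pos: int
    com: str
    alt: str
    neglog10p: float
    genes: list[tuple[str, int, bool]] = field(default_factory=list)  # (gene id, distance bp, inside)
    alt_indicator: np.ndarray | None = None  # per-individual ALT-hom flag


@dataclass
class GeneAnnotation:
    """A gene interval in 0-based half-open coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("gene start must be < end")


# ---------------------------------------------------------------------------
# kinship and structure covariates


def _imputed_dosage(geno: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Calls as float dosages with per-site mean imputation; returns (G, p_alt)."""
    g = geno.calls.astype(float)
    g[geno.calls == MISSING] = np.nan
    p = np.nanmean(g, axis=0) / 2.0  # ALT allele frequency
    mu = 2.0 * p
    idx = np.where(np.isnan(g))
    g[idx] = mu[idx[1]]
    return g, p

def kinship(geno: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden centered-genotype kinship: K = WW' / Σ 2p_k(1−p_k).

    Missing genotypes are mean-imputed per site for this computation only.
    Monomorphic sites contribute nothing; an all-monomorphic matrix is an
    error.
    """
    g, p = _imputed_dosage(geno)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("matrix is monomorphic: kinship undefined")
    w = g[:, poly] - 2.0 * p[poly]
    denom = float(np.sum(2.0 * p[poly] * (1.0 - p[poly])))
    k = (w @ w.T) / denom
    return KinshipMatrix(values=k, individuals=list(geno.individuals))


def compress_kinship(K: KinshipMatrix, n_groups: int) -> tuple[KinshipMatrix, np.ndarray]:
    """Compressed-model grouping: cluster individuals on kinship similarity.

    Average-linkage hierarchical clustering on 1−K distance yields
    `n_groups` groups; the returned kinship is the group-mean K expanded
    back to individuals, and the group label per individual. With
    n_groups = n this is the identity operation (the default scan uses no
    compression).
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    n = len(K.individuals)
    if n_groups >= n:
        return K, np.arange(n)
    d = np.max(K.values) - K.values
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    labels = fcluster(linkage(squareform(d, checks=False), method="average"), n_groups, "maxclust") - 1
    grouped = np.zeros_like(K.values)
    for a in range(n_groups):
        ia = labels == a
        for b in range(n_groups):
            ib = labels == b
            grouped[np.ix_(ia, ib)] = K.values[np.ix_(ia, ib)].mean()
    return KinshipMatrix(values=grouped, individuals=list(K.individuals), method=K.method + "+compressed"), labels


def genotype_pcs(geno: GenotypeMatrix, n_pcs: int = 3) -> np.ndarray:
    """Leading principal components of the centered genotype matrix."""
    g, p = _imputed_dosage(geno)
    w = g - 2.0 * p
    # left singular vectors via the small n×n cross-product (m >> n)
    vals, vecs = np.linalg.eigh(w @ w.T)
    order = np.argsort(vals)[::-1]
    vals, vecs = np.clip(vals[order], 0, None), vecs[:, order]
    k = min(n_pcs, vals.size)
    pcs = vecs[:, :k] * np.sqrt(vals[:k])
    sd = pcs.std(axis=0)
    sd[sd == 0] = 1.0
    return pcs / sd


# ---------------------------------------------------------------------------
# REML machinery (spectral form)


def _null_reml(yt: np.ndarray, Xt: np.ndarray, eigvals: np.ndarray) -> tuple[float, float, float]:
    """Profiled REML for V = σ²_g·diag(eigvals) + σ²_e·I on rotated data.

    Returns (σ²_g, σ²_e, restricted log-likelihood). The criterion is
    profiled over δ = σ²_e/σ²_g and minimized on log δ ∈ [−10, 10].
    """
    n, p = Xt.shape

    def neg_reml(log_delta: float) -> float:
        delta = np.exp(log_delta)
        w = eigvals + delta
        Xw = Xt / w[:, None]
        XtVX = Xt.T @ Xw
        try:
            beta = np.linalg.solve(XtVX, Xw.T @ yt)
        except np.linalg.LinAlgError:
            return np.inf
        resid = yt - Xt @ beta
        quad = float(resid @ (resid / w))
        if quad <= 0:
            return np.inf
        sign, logdet_x = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return np.inf
        return 0.5 * (np.sum(np.log(w)) + logdet_x + (n - p) * np.log(quad))

    res = optimize.minimize_scalar(neg_reml, bounds=(-10.0, 10.0), method="bounded")
    delta = float(np.exp(res.x))
    w = eigvals + delta
    Xw = Xt / w[:, None]
    beta = np.linalg.solve(Xt.T @ Xw, Xw.T @ yt)
    resid = yt - Xt @ beta
    sigma2_g = float(resid @ (resid / w)) / (n - p)
    sigma2_e = delta * sigma2_g
    loglik = -float(res.fun) - 0.5 * (n - p) * (1.0 + np.log(2 * np.pi / (n - p)))
    return sigma2_g, sigma2_e, loglik


def _decompose_k(K: KinshipMatrix) -> tuple[np.ndarray, np.ndarray]:
    vals, vecs = np.linalg.eigh(K.values)
    if vals.min() < -1e-6:
        jitter = -vals.min() + 1e-8
        vals = vals + jitter
        if vals.min() < 0:
            raise ValueError("kinship not positive semi-definite after jitter")
    vals = np.clip(vals, 0.0, None)
    return vals, vecs


def select_model(
    y: np.ndarray, K: KinshipMatrix, pcs: np.ndarray, max_pcs: int = 3
) -> tuple[int, dict[int, float]]:
    """Choose the number of PC covariates (0..max_pcs) by null-model BIC.

    The null MLM (no SNP term) is fitted by REML for each candidate
    covariate set; BIC = −2·logLik + k·log(n) with k the fixed-effect count
    plus two variance components. Returns (chosen count, {count: BIC}).
    """
    y = np.asarray(y, float)
    n = y.size
    vals, vecs = _decompose_k(K)
    yt = vecs.T @ y
    bics: dict[int, float] = {}
    limit = min(max_pcs, pcs.shape[1] if pcs.ndim == 2 else 0)
    for q in range(0, limit + 1):
        X = np.column_stack([np.ones(n)] + [pcs[:, j] for j in range(q)])
        Xt = vecs.T @ X
        _, _, loglik = _null_reml(yt, Xt, vals)
        k = X.shape[1] + 2
        bics[q] = float(-2 * loglik + k * np.log(n))
    chosen = min(bics, key=bics.get)
    return chosen, bics


def mlm_scan(
    y: np.ndarray,
    geno: GenotypeMatrix,
    K: KinshipMatrix,
    covariates: np.ndarray | None = None,
    p3d: bool = True,
    alpha: float = 0.01,
) -> MLMResult:
    """Association scan of every site in `geno` against phenotype `y`.

    With P3D (default) the null-model variance components are estimated once
    and reused for all SNP tests; with ``p3d=False`` REML is re-run per SNP.
    Missing genotypes are mean-imputed per site for testing only. P-values
    are Wald t with n − rank(X) − 1 degrees of freedom.
    """
    y = np.asarray(y, float)
    n = y.size
    if n != geno.n_individuals:
        raise ValueError("phenotype and genotype individuals are misaligned")
    if np.ptp(y) == 0:
        raise ValueError("zero-variance phenotype")
    vals, vecs = _decompose_k(K)
    if covariates is None or covariates.size == 0:
        X = np.ones((n, 1))
    else:
        covariates = np.atleast_2d(np.asarray(covariates, float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        X = np.column_stack([np.ones(n), covariates])
    yt = vecs.T @ y
    Xt = vecs.T @ X
    sigma2_g, sigma2_e, _ = _null_reml(yt, Xt, vals)
    delta0 = sigma2_e / max(sigma2_g, 1e-12)

    g, _ = _imputed_dosage(geno)
    Gt = vecs.T @ g  # rotated SNP dosages, n × m
    p_fixed = X.shape[1]
    df = n - p_fixed - 1
    if df <= 0:
        raise ValueError("not enough individuals for the fixed design")

    def scan_with_delta(delta: float, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        w = vals + delta
        Xw = Xt / w[:, None]
        XtX = Xt.T @ Xw  # p×p
        Xty = Xw.T @ yt
        Gw = cols / w[:, None]
        XtG = Xt.T @ Gw  # p×m
        GtG = np.einsum("ij,ij->j", cols, Gw)  # m
        Gty = Gw.T @ yt  # m
        XtX_inv = np.linalg.inv(XtX)
        # block inversion of [[XtX, XtG],[GtX, GtG]] per SNP
        AinvB = XtX_inv @ XtG  # p×m
        schur = GtG - np.einsum("ij,ij->j", XtG, AinvB)  # m
        schur = np.maximum(schur, 1e-30)
        alpha_hat = (Gty - AinvB.T @ Xty) / schur
        beta0 = XtX_inv @ Xty
        # residual sum of squares under the weighted model, per SNP
        yty = float(yt @ (yt / w))
        rss0 = yty - float(Xty @ beta0)
        rss = rss0 - alpha_hat**2 * schur
        rss = np.maximum(rss, 1e-30)
        sigma2 = rss / df
        se = np.sqrt(sigma2 / schur)
        return alpha_hat, se

    m = geno.n_sites
    if p3d:
        effects, ses = scan_with_delta(delta0, Gt)
    else:
        effects = np.empty(m)
        ses = np.empty(m)
        for j in range(m):
            Xj = np.column_stack([Xt, Gt[:, j]])
            sg, se_var, _ = _null_reml(yt, Xj, vals)
            dj = se_var / max(sg, 1e-12)
            e_j, s_j = scan_with_delta(dj, Gt[:, j : j + 1])
            effects[j], ses[j] = e_j[0], s_j[0]

    tvals = effects / ses
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    table = pd.DataFrame(
        {
            "chrom": geno.sites["chrom"],
            "pos": geno.sites["pos"],
            "com": geno.sites["com"],
            "alt": geno.sites["alt"],
            "effect": effects,
            "se": ses,
            "neglog10p": -np.log10(pvals),
        }
    )
    n_pcs = X.shape[1] - 1
    return MLMResult(
        table=table,
        n_pcs=n_pcs,
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_e,
        p3d=p3d,
        m_tested=m,
        alpha=alpha,
        threshold=bonferroni_threshold(alpha, m),
    )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold on the −log10 p scale: T = −log10(α/M)."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("M must be at least 1")
    return float(-np.log10(alpha / m))


# ---------------------------------------------------------------------------
# TAS calling, candidate genes, burden


def call_tas(result: MLMResult, geno: GenotypeMatrix) -> list[TASRecord]:
    """Sites whose −log10 p exceeds the scan's Bonferroni threshold."""
    hits = result.table[result.table["neglog10p"] > result.threshold]
    out = []
    site_index = {(c, p): j for j, (c, p) in enumerate(zip(geno.sites["chrom"], geno.sites["pos"]))}
    for row in hits.itertuples(index=False):
        j = site_index[(row.chrom, row.pos)]
        out.append(
            TASRecord(
                chrom=row.chrom,
                pos=int(row.pos),
                com=row.com,
                alt=row.alt,
                neglog10p=float(row.neglog10p),
                alt_indicator=(geno.calls[:, j] == 2),
            )
        )
    return out


def map_candidates(
    tas: list[TASRecord], genes: list[GeneAnnotation], window: int = 100_000
) -> list[TASRecord]:
    """Assign each TAS every gene within `window` bp (100 kb by default).

    A gene is assigned when its interval expanded by the window contains the
    TAS position; the inside flag marks containment in the unexpanded
    interval, with distance 0. TAS on chromosomes absent from the annotation
    get an empty assignment (warning-level event).
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for gene in genes:
        trees.setdefault(gene.chrom, IntervalTree()).addi(
            gene.start - window, gene.end + window, gene
        )
    for rec in tas:
        rec.genes = []
        tree = trees.get(rec.chrom)
        if tree is None:
            continue
        for iv in sorted(tree[rec.pos], key=lambda iv: iv.data.gene_id):
            gene = iv.data
            inside = gene.start <= rec.pos < gene.end
            if inside:
                dist = 0
            elif rec.pos < gene.start:
                dist = gene.start - rec.pos
            else:
                dist = rec.pos - (gene.end - 1)
            rec.genes.append((gene.gene_id, int(dist), inside))
    return tas


def alt_burden(tas: list[TASRecord], geno: GenotypeMatrix, y: np.ndarray):
    """Per-individual ALT-allele burden over the TAS set and its correlation
    with the phenotype.

    The burden is the count of homozygous-ALT calls at TAS sites (missing
    calls skipped). Returns (counts, CorrelationResult) using the Pearson r /
    Fisher transformation machinery.
    """
    from samgwas.assoc_stats import UndefinedStatisticError, pearson_fisher

    if not tas:
        raise ValueError("TAS set is empty")
    site_index = {(c, p): j for j, (c, p) in enumerate(zip(geno.sites["chrom"], geno.sites["pos"]))}
    cols = [site_index[(t.chrom, t.pos)] for t in tas]
    counts = (geno.calls[:, cols] == 2).sum(axis=1).astype(float)
    if np.ptp(counts) == 0:
        raise UndefinedStatisticError(
            "all individuals carry identical ALT burden; correlation undefined"
        )
    return counts, pearson_fisher(counts, y)
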