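"""Per-genotype BLUPs across replicated batches and entry-mean repeatability.

Germination failures make the replicate table unbalanced, so genotype values
are estimated as best linear unbiased predictors under

    y_ij = μ + ρ_j + g_i + e_ij,
    g_i ~ N(0, σ²_g)  i.i.d.,   e_ij ~ N(0, σ²_e),

with replicate (growth batch) ρ_j a fixed effect. Variance components come
from REML, profiled to a one-dimensional bounded search over
λ = σ²_e/σ²_g, which is exact for a single i.i.d. random effect. Phenotypes
are reported in BLUP+intercept form (g̃_i + μ̂), and the entry-mean
repeatability (heritability on a genotype-mean basis) is

    H² = σ²_g / (σ²_g + σ²_e / n̄),

with n̄ the harmonic mean of per-genotype replicate counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = ["BLUPResult", "fit_blup", "repeatability"]

VAR_FLOOR = 1e-12  # negative/zero REML variance estimates are clamped here


@dataclass
class BLUPResult:
    """Fitted mixed model for one phenotype."""

    intercept: float
    blups: pd.Series  # genotype -> g̃_i
    replicate_effects: pd.Series  # replicate -> ρ̂_j (first level = 0)
    sigma2_g: float
    sigma2_e: float
    n_bar: float  # harmonic-mean replicate number

    @property
    def blup_plus_intercept(self) -> pd.Series:
        out = self.blups + self.intercept
        out.name = "blup_plus_intercept"
        return out

    @property
    def repeatability(self) -> float:
        denom = self.sigma2_g + self.sigma2_e / self.n_bar
        return 0.0 if denom == 0 else float(self.sigma2_g / denom)


def repeatability(result: BLUPResult) -> float:
    """Entry-mean repeatability H² = σ²_g/(σ²_g + σ²_e/n̄) of a fitted model."""
    return result.repeatability


def fit_blup(
    table: pd.DataFrame,
    value: str = "value",
    genotype: str = "genotype",
    replicate: str = "replicate",
    replicate_fixed: bool = True,
) -> BLUPResult:
    """Fit the replicate + genotype mixed model by profiled REML.

    Parameters
    ----------
    table:
        Long-format replicate table with genotype, replicate and value
        columns. Missing cells (failed germination) are simply absent rows.
    replicate_fixed:
        With False, the batch term is dropped from the fixed design and
        absorbed into the residual (a deliberately cruder model, exposed for
        sensitivity checks).

    Notes
    -----
    The REML criterion is profiled over λ = σ²_e/σ²_g and minimized by a
    bounded scalar search on log λ ∈ [−10, 10]. Boundary solutions map to
    the degenerate cases σ²_e → 0 (no shrinkage; BLUP+intercept equals the
    genotype mean) and σ²_g → 0 (full shrinkage). Estimated components below
    zero are clamped to a tiny floor with a warning.
    """
    df = table[[genotype, replicate, value]].dropna()
    if not np.issubdtype(df[value].dtype, np.number):
        raise ValueError("phenotype values must be numeric")
    geno_ids, gi = np.unique(df[genotype].astype(str), return_inverse=True)
    rep_ids, ri = np.unique(df[replicate].astype(str), return_inverse=True)
    y = df[value].to_numpy(float)
    n = y.size
    n_g = geno_ids.size
    if n_g < 2:
        raise ValueError("need at least 2 genotypes")
    counts = np.bincount(gi, minlength=n_g)
    if counts.max() < 2:
        raise ValueError("all genotypes are singletons: variance components unidentifiable")

    # fixed design: intercept + replicate dummies (first level reference)
    if replicate_fixed and rep_ids.size > 1:
        X = np.zeros((n, rep_ids.size))
        X[:, 0] = 1.0
        for j in range(1, rep_ids.size):
            X[ri == j, j] = 1.0
    else:
        X = np.ones((n, 1))
    p = np.linalg.matrix_rank(X)

    # Z Z' has the same eigenstructure per genotype block; dense eigh is fine
    # at panel scale (n ≤ a few thousand).
    Z = np.zeros((n, n_g))
    Z[np.arange(n), gi] = 1.0
    ZZt = Z @ Z.T
    d, U = np.linalg.eigh(ZZt)
    yt = U.T @ y
    Xt = U.T @ X

    def neg_reml(log_lam: float) -> float:
        lam = np.exp(log_lam)
        w = d + lam  # V*/σ²_g eigenvalues
        Xw = Xt / w[:, None]
        XtVX = Xt.T @ Xw
        beta = np.linalg.solve(XtVX, Xw.T @ yt)
        resid = yt - Xt @ beta
        quad = float(resid @ (resid / w))
        if quad <= 0:
            return np.inf
        logdet_v = float(np.sum(np.log(w)))
        sign, logdet_x = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return np.inf
        return 0.5 * (logdet_v + logdet_x + (n - p) * np.log(quad))

    res = optimize.minimize_scalar(neg_reml, bounds=(-10.0, 10.0), method="bounded")
    lam = float(np.exp(res.x))
    w = d + lam
    Xw = Xt / w[:, None]
    XtVX = Xt.T @ Xw
    beta = np.linalg.solve(XtVX, Xw.T @ yt)
    resid = yt - Xt @ beta
    sigma2_g = float(resid @ (resid / w)) / (n - p)
    sigma2_e = lam * sigma2_g
    if sigma2_g < VAR_FLOOR:
        warnings.warn("genetic variance estimated at or below zero; clamped", stacklevel=2)
        sigma2_g = VAR_FLOOR
    if sigma2_e < VAR_FLOOR:
        sigma2_e = VAR_FLOOR

    # BLUP: g̃ = σ²_g Z'V⁻¹(y − Xβ̂); V⁻¹ = U diag(1/(σ²_g w)) U'
    vinv_resid = U @ (resid / w)  # = V⁻¹(y−Xβ̂)·σ²_g
    blups = Z.T @ vinv_resid

    intercept = float(beta[0])
    rep_eff = np.zeros(rep_ids.size)
    if replicate_fixed and rep_ids.size > 1:
        rep_eff[1:] = beta[1:]
    n_bar = float(len(counts) / np.sum(1.0 / counts))
    return BLUPResult(
        intercept=intercept,
        blups=pd.Series(blups, index=pd.Index(geno_ids, name="genotype"), name="blup"),
        replicate_effects=pd.Series(rep_eff, index=pd.Index(rep_ids, name="replicate")),
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_e,
        n_bar=n_bar,
    )


def blup_table(
    table: pd.DataFrame,
    phenotypes: list[str],
    genotype: str = "genotype",
    replicate: str = "replicate",
) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Fit every phenotype column; return BLUP+intercept table and components.

    The components dict maps phenotype -> {sigma2_g, sigma2_e, repeatability,
    n_bar}, matching what the pipeline writes to JSON.
    """
    values = {}
    components = {}
    for ph in phenotypes:
        res = fit_blup(table, value=ph, genotype=genotype, replicate=replicate)
        values[ph] = res.blup_plus_intercept
        components[ph] = {
            "sigma2_g": res.sigma2_g,
            "sigma2_e": res.sigma2_e,
            "repeatability": res.repeatability,
            "n_bar": res.n_bar,
        }
    return pd.DataFrame(values), components
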