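"""Shared statistics: Pearson/Fisher correlation, Welch t, size classes.

These are the statistical primitives the association and cytometry stages
share. P-values smaller than machine epsilon (2.22e−16) are kept exact
internally and formatted as ``"<2.22e-16"`` in text output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "SizeClassTable",
    "pearson_fisher",
    "classify_sizes",
    "welch_t",
    "format_p",
    "UndefinedStatisticError",
]

P_FLOOR = 2.22e-16  # double-precision epsilon; printed as "<2.22e-16"


class UndefinedStatisticError(ValueError):
    """Raised when a statistic is undefined (e.g. zero-variance input)."""


def format_p(p: float) -> str:
    """Human-readable p-value: values below machine epsilon print as a bound."""
    return "<2.22e-16" if p < P_FLOOR else f"{p:.6g}"


@dataclass
class CorrelationResult:
    """Pearson product-moment r with Fisher-transformation significance."""

    r: float
    n: int
    z: float
    p: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"Pearson's r={self.r:.4g} (n={self.n}, Fisher transformation P{'' if self.p < P_FLOOR else '='}{format_p(self.p)})"


def pearson_fisher(x, y) -> CorrelationResult:
    """Pearson correlation with Fisher-z two-sided significance.

    z = atanh(r), se = 1/sqrt(n−3), p = 2·(1 − Φ(|z|·sqrt(n−3))). Pairs with a
    missing (NaN) member are dropped (pairwise-complete).

    Raises
    ------
    UndefinedStatisticError
        If fewer than 4 complete pairs remain or either variable has zero
        variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 4:
        raise UndefinedStatisticError("need at least 4 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("zero variance: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        return CorrelationResult(r=r, n=n, z=np.sign(r) * np.inf, p=0.0)
    z = float(np.arctanh(r))
    se = 1.0 / np.sqrt(n - 3)
    p = float(2.0 * stats.norm.sf(abs(z) / se))
    return CorrelationResult(r=r, n=n, z=z, p=p)


@dataclass
class SizeClassTable:
    """Quartile-based small/intermediate/large assignment of a panel."""

    classes: pd.Series  # genotype id -> {"small","intermediate","large"}
    q1: float
    q3: float

    def counts(self) -> dict[str, int]:
        return self.classes.value_counts().to_dict()


def classify_sizes(volumes: pd.Series) -> SizeClassTable:
    """Assign genotypes to SAM-size classes by volume quartiles.

    The lower quartile is "small", the upper quartile "large", the middle two
    "intermediate". Quartiles use linear-interpolation (type-7) quantiles;
    values exactly on a boundary go to the lower class. Ties spanning a
    boundary are resolved deterministically because assignment is by value
    against fixed thresholds (tied values land in the same class).
    """
    volumes = pd.Series(volumes).dropna()
    if len(volumes) < 4:
        raise ValueError("need at least 4 genotypes to form quartiles")
    q1, q3 = np.quantile(volumes.to_numpy(float), [0.25, 0.75])
    if q1 == q3:
        raise UndefinedStatisticError("degenerate quartiles: volumes are constant")
    cls = pd.Series(
        np.where(volumes <= q1, "small", np.where(volumes <= q3, "intermediate", "large")),
        index=volumes.index,
        name="size_class",
    )
    return SizeClassTable(classes=cls, q1=float(q1), q3=float(q3))


def welch_t(group_a, group_b, pooled: bool = False) -> tuple[float, float, float]:
    """Two-sample t-test, Welch's unequal-variance form by default.

    Returns (t, df, two-sided p). `pooled=True` restores the classic
    equal-variance Student form. Two identical zero-variance groups return
    (0, df, 1) by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            df = a.size + b.size - 2 if pooled else float(a.size + b.size - 2)
            return 0.0, float(df), 1.0
        raise UndefinedStatisticError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=pooled)
    if pooled:
        df = float(a.size + b.size - 2)
    else:
        va, vb = np.var(a, ddof=1) / a.size, np.var(b, ddof=1) / b.size
        df = float((va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1)))
    return float(res.statistic), df, float(res.pvalue)
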