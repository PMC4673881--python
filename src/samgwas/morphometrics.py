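"""Parabolic SAM morphometrics.

The shoot apical meristem in a median longitudinal section is closely
approximated by a parabola. With the apex at the origin and the dome opening
downward, the model is

    y = h − (h/r²)·x²,   x ∈ [−r, r],

where h is the dome height from the apex to the P1-notch base level and r is
the half-width (radius) at that level. The shape coefficient a = h/r² of the
standard-form parabola y = a·x² is the single scale-free model factor.

From (h, r) the full microphenotype set follows in closed form:

    ratio         = h / r
    diameter      = 2 r
    midsection_area = (4/3)·h·r              (parabolic-segment area)
    volume        = (π/2)·r²·h               (paraboloid of revolution)
    coefficient   = h / r²
    surface_area  = (π r / 6h²)·((r²+4h²)^{3/2} − r³)   (lateral surface)
    arc_length    = sqrt(r²+4h²) + (r²/2h)·asinh(2h/r)

Each closed form is validated against adaptive numeric integration in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import interpolate

__all__ = [
    "SAMContour",
    "ParabolicFit",
    "MicrophenotypeSet",
    "fit_parabola",
    "derive_phenotypes",
    "estimate_vs_measured_area",
    "extract_contour",
    "read_contours_tsv",
    "write_contours_tsv",
    "DegenerateContourError",
]

N_STATIONS = 51  # spline-resampling stations before the quadratic regression


class DegenerateContourError(ValueError):
    """Contour cannot be described by a downward-opening parabola."""


@dataclass
class SAMContour:
    """An ordered 2-D trace of one SAM outline, apex-up, in µm."""

    genotype: str
    replicate: str
    x: np.ndarray
    y: np.ndarray
    apex_up: bool = True

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if self.x.size < 7:
            raise DegenerateContourError("contour needs at least 7 points")
        if not self.apex_up:
            # y-down (image) coordinates: flip so the apex is the maximum
            self.y = -self.y
            self.apex_up = True
        apex_x = self.x[np.argmax(self.y)]
        if not (self.x.min() < apex_x < self.x.max()):
            raise DegenerateContourError("x must cover both sides of the apex")

    def __len__(self) -> int:
        return self.x.size


@dataclass
class ParabolicFit:
    """Least-squares parabola fitted to one contour."""

    a: float  # shape coefficient, µm⁻¹
    h: float  # height, µm
    r: float  # radius, µm
    rmse: float
    n_points: int

    def __post_init__(self) -> None:
        if self.a <= 0 or self.h <= 0 or self.r <= 0:
            raise DegenerateContourError("fit parameters must be positive")


@dataclass(frozen=True)
class MicrophenotypeSet:
    """The derived shape statistics of a single SAM."""

    height: float
    radius: float
    ratio: float
    diameter: float
    midsection_area: float
    volume: float
    coefficient: float
    surface_area: float
    arc_length: float

    def as_dict(self) -> dict[str, float]:
        return {
            "height": self.height,
            "radius": self.radius,
            "ratio": self.ratio,
            "diameter": self.diameter,
            "midsection_area": self.midsection_area,
            "volume": self.volume,
            "coefficient": self.coefficient,
            "surface_area": self.surface_area,
            "arc_length": self.arc_length,
        }


def _resample(contour: SAMContour, n_stations: int = N_STATIONS) -> tuple[np.ndarray, np.ndarray]:
    """Spline-interpolate the trace and resample at evenly spaced x stations."""
    order = np.argsort(contour.x, kind="stable")
    x, y = contour.x[order], contour.y[order]
    # collapse duplicate x (hand traces can double back slightly)
    ux, inv = np.unique(x, return_inverse=True)
    if ux.size < x.size:
        uy = np.zeros_like(ux)
        counts = np.bincount(inv)
        np.add.at(uy, inv, y)
        x, y = ux, uy / counts
    if x.size < 4:
        raise DegenerateContourError("too few distinct x positions for a spline")
    k = min(3, x.size - 1)
    spl = interpolate.make_interp_spline(x, y, k=k)
    xs = np.linspace(x[0], x[-1], n_stations)
    return xs, spl(xs)


def fit_parabola(contour: SAMContour, n_stations: int = N_STATIONS) -> ParabolicFit:
    """Fit y = c0 + c1·x + c2·x² to a spline-resampled contour.

    The full quadratic (with a linear term) is fitted and the vertex taken as
    the apex, which tolerates imperfect centering of the trace. The shape
    coefficient is a = −c2; the height h is the vertex y minus the base level
    — the mean of the two contour endpoint y values, an unbiased estimate of
    the P1-notch level under symmetric measurement noise; the radius solves
    y(±r) = base, i.e. r = sqrt(h/a).

    Raises
    ------
    DegenerateContourError
        If the fitted quadratic is not concave-down (c2 ≥ 0) or the contour
        has fewer than 7 points.
    """
    xs, ys = _resample(contour, n_stations)
    c2, c1, c0 = np.polyfit(xs, ys, 2)
    if c2 >= 0:
        raise DegenerateContourError("contour is not concave-down")
    a = -float(c2)
    vertex_y = float(c0 - c1**2 / (4 * c2))
    base = float((contour.y[0] + contour.y[-1]) / 2.0)
    h = vertex_y - base
    if h <= 0:
        raise DegenerateContourError("nonpositive fitted height")
    r = float(np.sqrt(h / a))
    resid = ys - np.polyval([c2, c1, c0], xs)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return ParabolicFit(a=a, h=h, r=r, rmse=rmse, n_points=xs.size)


def derive_phenotypes(h: float, r: float) -> MicrophenotypeSet:
    """Compute the full microphenotype set from height and radius (µm).

    Pure closed-form function; see the module docstring for the formulas.
    """
    if h <= 0 or r <= 0:
        raise ValueError("height and radius must be positive")
    h, r = float(h), float(r)
    surface = (np.pi * r / (6 * h**2)) * ((r**2 + 4 * h**2) ** 1.5 - r**3)
    arc = np.sqrt(r**2 + 4 * h**2) + (r**2 / (2 * h)) * np.arcsinh(2 * h / r)
    return MicrophenotypeSet(
        height=h,
        radius=r,
        ratio=h / r,
        diameter=2 * r,
        midsection_area=(4.0 / 3.0) * h * r,
        volume=(np.pi / 2.0) * r**2 * h,
        coefficient=h / r**2,
        surface_area=float(surface),
        arc_length=float(arc),
    )


def estimate_vs_measured_area(contour: SAMContour) -> tuple[float, float]:
    """Model-estimated vs directly measured midsection area (µm²).

    `estimated` is (4/3)·h·r from the parabolic fit; `measured` is the
    shoelace polygon area of the contour closed along its base chord.
    """
    from shapely.geometry import LineString

    fit = fit_parabola(contour)
    estimated = (4.0 / 3.0) * fit.h * fit.r
    if not LineString(zip(contour.x, contour.y)).is_simple:
        raise ValueError("contour polygon is self-intersecting")
    # shoelace area of the trace closed along the base chord
    x, y = contour.x, contour.y
    signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return float(estimated), float(abs(signed))


def extract_contour(
    image: np.ndarray,
    pixel_scale: float = 1.0,
    genotype: str = "",
    replicate: str = "",
    inverted: bool = False,
) -> SAMContour:
    """Trace the upper boundary of a bright dome on a dark background.

    Otsu threshold → largest connected component → topmost foreground pixel
    per column → µm coordinates (image y-down flipped to apex-up, apex at the
    component top).
    """
    from skimage import filters, measure

    img = np.asarray(image, dtype=float)
    if inverted:
        img = img.max() - img
    if img.max() == img.min():
        raise ValueError("no foreground component found")
    thr = filters.threshold_otsu(img)
    fg = img > thr
    labels = measure.label(fg)
    if labels.max() == 0:
        raise ValueError("no foreground component found")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    comp = labels == np.argmax(sizes)
    cols = np.flatnonzero(comp.any(axis=0))
    top = np.array([np.argmax(comp[:, c]) for c in cols], dtype=float)  # first True row
    x_um = cols * pixel_scale
    y_um = -top * pixel_scale  # flip y-down pixels to apex-up µm
    y_um -= y_um.min()
    x_um -= x_um[np.argmax(y_um)]
    return SAMContour(genotype=genotype, replicate=replicate, x=x_um, y=y_um)


def write_contours_tsv(contours: list[SAMContour], path: str | Path) -> None:
    rows = [
        {"genotype": c.genotype, "replicate": c.replicate, "x_um": xi, "y_um": yi}
        for c in contours
        for xi, yi in zip(c.x, c.y)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_contours_tsv(path: str | Path) -> list[SAMContour]:
    df = pd.read_csv(path, sep="\t", dtype={"genotype": str, "replicate": str})
    out = []
    for (g, rep), grp in df.groupby(["genotype", "replicate"], sort=True):
        out.append(SAMContour(genotype=g, replicate=rep, x=grp["x_um"].to_numpy(), y=grp["y_um"].to_numpy()))
    return out


def microphenotype_table(fits: dict[tuple[str, str], ParabolicFit]) -> pd.DataFrame:
    """One row of derived microphenotypes per genotype×replicate."""
    rows = []
    for (g, rep), fit in fits.items():
        row = {"genotype": g, "replicate": rep, "rmse": fit.rmse}
        row.update(derive_phenotypes(fit.h, fit.r).as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
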