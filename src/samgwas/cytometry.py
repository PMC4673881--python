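"""Nuclei-lattice cytometry of SAM sections.

Stained nuclei in a median optical section are segmented, and the space
between them inside the SAM mask is divided into a lattice of cells by a
pixel-wise Voronoi partition (nearest-centroid assignment). Two statistics
summarize the lattice: SCN, the SAM cell number (the centroid count), and
ASCS, the average SAM cell size (mask area / SCN, µm²). By construction the
per-cell polygon areas sum exactly to the mask area at pixel resolution.

Segmentation is a fixed, deterministic pipeline: Gaussian smoothing →
background subtraction → Otsu threshold within the mask → watershed split on
the distance transform → per-object centroid, with a minimum-area floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SAMMask", "CellLattice", "segment_nuclei", "tessellate", "scn_ascs_model", "parabola_mask"]


@dataclass
class SAMMask:
    """Binary SAM-region mask with its physical pixel scale (µm/pixel)."""

    mask: np.ndarray
    pixel_scale: float = 1.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")

    @property
    def area_um2(self) -> float:
        return float(self.mask.sum()) * self.pixel_scale**2


@dataclass
class CellLattice:
    """Voronoi partition of the SAM mask around nuclei centroids."""

    centroids_um: np.ndarray  # (n, 2) as (x, y) µm
    cell_areas_um2: np.ndarray  # per-centroid polygon area
    label_image: np.ndarray  # 0 background, 1..n per cell
    mask_area_um2: float

    @property
    def scn(self) -> int:
        """SAM cell number."""
        return int(len(self.centroids_um))

    @property
    def ascs(self) -> float:
        """Average SAM cell size, µm² (mask area / SCN)."""
        return self.mask_area_um2 / self.scn


def parabola_mask(h: float, r: float, pixel_scale: float = 1.0, pad: int = 4) -> SAMMask:
    """Binary mask of the parabolic SAM segment y ∈ [0, h − (h/r²)x²]."""
    if h <= 0 or r <= 0:
        raise ValueError("h and r must be positive")
    w_px = int(np.ceil(2 * r / pixel_scale)) + 2 * pad
    h_px = int(np.ceil(h / pixel_scale)) + 2 * pad
    yy, xx = np.mgrid[0:h_px, 0:w_px]
    x_um = (xx - w_px / 2) * pixel_scale
    y_um = (h_px - pad - yy) * pixel_scale  # row 0 is the image top
    inside = (y_um >= 0) & (y_um <= h - (h / r**2) * x_um**2)
    return SAMMask(mask=inside, pixel_scale=pixel_scale)


def segment_nuclei(
    image: np.ndarray,
    mask: SAMMask,
    sigma: float = 1.0,
    min_area_px: int = 4,
    min_distance_px: int = 4,
) -> np.ndarray:
    """Detect nuclei centroids inside the mask.

    Returns an (n, 2) array of (x, y) centroid coordinates in µm (x along
    columns, y upward from the image bottom row). A blank image yields an
    empty array (SCN = 0); an empty mask is an error.
    """
    from scipy import ndimage as ndi
    from skimage import feature, filters, measure, segmentation

    img = np.asarray(image, dtype=float)
    if img.shape != mask.mask.shape:
        raise ValueError("image and mask must have the same shape")
    if not mask.mask.any():
        raise ValueError("empty mask")
    smoothed = filters.gaussian(img, sigma=sigma, preserve_range=True)
    background = filters.gaussian(img, sigma=10 * sigma, preserve_range=True)
    enhanced = smoothed - background
    vals = enhanced[mask.mask]
    if np.ptp(vals) == 0:
        return np.empty((0, 2))
    thr = filters.threshold_otsu(vals)
    # threshold computed within the mask but applied on a small dilation, so
    # nuclei touching the mask boundary keep their full shape; objects whose
    # centroid falls outside the mask are dropped below
    halo_px = max(2, int(np.ceil(3 * sigma)))
    halo = ndi.binary_dilation(mask.mask, iterations=halo_px)
    fg = (enhanced > thr) & halo
    if not fg.any():
        return np.empty((0, 2))
    distance = ndi.distance_transform_edt(fg)
    peaks = feature.peak_local_max(
        distance, min_distance=min_distance_px, labels=fg, exclude_border=False
    )
    markers = np.zeros(fg.shape, dtype=int)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = segmentation.watershed(-distance, markers, mask=fg)
    centroids = []
    # intensity-weighted centroids: robust to asymmetric clipping of blobs
    # at the mask boundary
    weight = np.clip(enhanced, 0, None)
    for region in measure.regionprops(labels, intensity_image=weight):
        if region.area < min_area_px:
            continue
        row, col = region.centroid_weighted
        if not np.isfinite(row):
            row, col = region.centroid
        ri = int(np.clip(round(row), 0, mask.mask.shape[0] - 1))
        ci = int(np.clip(round(col), 0, mask.mask.shape[1] - 1))
        if not mask.mask[ri, ci]:
            continue
        x_um = col * mask.pixel_scale
        y_um = (mask.mask.shape[0] - 1 - row) * mask.pixel_scale
        centroids.append((x_um, y_um))
    return np.array(sorted(centroids)) if centroids else np.empty((0, 2))


def tessellate(centroids_um: np.ndarray, mask: SAMMask) -> CellLattice:
    """Partition the mask into Voronoi cells around the centroids.

    Every mask pixel is assigned to its nearest centroid (Euclidean;
    distance ties go to the lowest centroid index, which makes the label
    image bit-reproducible). Centroids outside the mask are warned about but
    still used.
    """
    import warnings

    centroids_um = np.atleast_2d(np.asarray(centroids_um, dtype=float))
    if centroids_um.size == 0:
        raise ValueError("need at least one centroid")
    rows, cols = np.nonzero(mask.mask)
    if rows.size == 0:
        raise ValueError("empty mask")
    x_px = centroids_um[:, 0] / mask.pixel_scale
    y_px = (mask.mask.shape[0] - 1) - centroids_um[:, 1] / mask.pixel_scale
    inside = mask.mask[
        np.clip(np.round(y_px).astype(int), 0, mask.mask.shape[0] - 1),
        np.clip(np.round(x_px).astype(int), 0, mask.mask.shape[1] - 1),
    ]
    if not inside.all():
        warnings.warn(f"{int((~inside).sum())} centroid(s) fall outside the mask", stacklevel=2)
    # squared distances pixel×centroid; argmin takes the lowest index on ties
    d2 = (cols[:, None] - x_px[None, :]) ** 2 + (rows[:, None] - y_px[None, :]) ** 2
    nearest = np.argmin(d2, axis=1)
    label_image = np.zeros(mask.mask.shape, dtype=int)
    label_image[rows, cols] = nearest + 1
    counts = np.bincount(nearest, minlength=len(centroids_um))
    areas = counts * mask.pixel_scale**2
    return CellLattice(
        centroids_um=centroids_um,
        cell_areas_um2=areas.astype(float),
        label_image=label_image,
        mask_area_um2=mask.area_um2,
    )


def scn_ascs_model(table: pd.DataFrame, response: str, genotype: str = "genotype_class", volume: str = "volume") -> pd.DataFrame:
    """Two-way ANOVA of SCN or ASCS on genotype class and SAM volume.

    Fits ``response ~ genotype + volume + genotype:volume`` and returns the
    sequential (Type-I) sums-of-squares table with F and p per term. The
    genotype class is categorical (e.g. COM vs ALT carriers); volume is a
    numeric covariate.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = table[[genotype, volume, response]].dropna().copy()
    classes = df[genotype].unique()
    if len(classes) < 2:
        raise ValueError("need at least 2 genotype classes")
    if df.groupby(genotype).size().min() < 3:
        raise ValueError("need at least 3 observations per genotype class")
    if np.ptp(df[response].to_numpy(float)) == 0:
        raise ValueError("zero-variance response")
    df = df.rename(columns={genotype: "G", volume: "V", response: "Y"})
    model = smf.ols("Y ~ C(G) + V + C(G):V", data=df).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError("rank-deficient design: genotype:volume interaction is aliased")
    anova = sm.stats.anova_lm(model, typ=1)
    anova.index = [i.replace("C(G)", "genotype").replace("V", "volume") for i in anova.index]
    return anova
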