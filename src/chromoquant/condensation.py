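"""Chromatin clustering statistics on nuclear dot patterns.

Two classical point-pattern summaries quantify the degree of condensation:

* the radial distribution function (pair-correlation) g(r), computed in rings
  of width Δr (default 0.2 μm) as

      g(r) = [S/(N−1)] · 1/(π(2rΔr + Δr²)) · (1/N) · n_pairs(r ≤ r_ij < r+Δr)

  with ordered-pair counting over the N points in a window of area S;
  g ≡ 1 under complete spatial randomness;

* Ripley's K and its linearized forms L(r) = sqrt(K/π) and H(r) = L(r) − r.
  K uses the unweighted estimator K(r) = S/(N(N−1)) · n_pairs(r_ij ≤ r)
  (ordered pairs). H peaks near the characteristic cluster radius; its peak
  location is the reported cluster scale.

No edge correction is applied — the window area S is the only geometry term,
so the estimators are negatively biased at radii approaching the window size;
``r_max`` beyond half the shorter window side triggers a warning.

Dot detection (thresholding + connected components) converts 8-bit images
into point patterns, with per-component equivalent diameters summarizing
cluster sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .datatypes import Image8, PointPattern, Window, warn

__all__ = [
    "RadialProfile",
    "KLProfile",
    "ClusterSummary",
    "RoiProfiles",
    "detect_dots",
    "compute_rdf",
    "compute_k_l",
    "cluster_scale",
    "summarize_rois",
]

DEFAULT_RING_WIDTH = 0.2  # μm


@dataclass
class RadialProfile:
    """g(r) sampled on rings [r, r+Δr); ``r_grid`` holds the ring left edges."""

    r_grid: np.ndarray
    ring_width: float
    g_values: np.ndarray

    def __post_init__(self) -> None:
        self.r_grid = np.asarray(self.r_grid, dtype=float)
        self.g_values = np.asarray(self.g_values, dtype=float)
        if self.ring_width <= 0:
            raise ValueError("ring_width: must be > 0")
        if np.any(np.diff(self.r_grid) <= 0) or np.any(self.r_grid < 0):
            raise ValueError("r_grid: must be non-negative and strictly increasing")
        if np.any(self.g_values < 0):
            raise ValueError("g_values: must be >= 0")


@dataclass
class KLProfile:
    """K, L = sqrt(K/π) and centered H = L − r on a common radius grid."""

    r_grid: np.ndarray
    k_values: np.ndarray
    l_values: np.ndarray
    h_values: np.ndarray
    peak_r: float | None

    def __post_init__(self) -> None:
        for name in ("r_grid", "k_values", "l_values", "h_values"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(np.diff(self.k_values) < 0):
            raise ValueError("k_values: K(r) must be non-decreasing")
        if np.any(self.k_values < 0):
            raise ValueError("k_values: must be >= 0")


@dataclass
class ClusterSummary:
    """Detected component count, equivalent diameters (μm) and covered area."""

    n_clusters: int
    equivalent_diameters: np.ndarray
    area_fraction: float

    def __post_init__(self) -> None:
        self.equivalent_diameters = np.asarray(self.equivalent_diameters, dtype=float)
        if np.any(self.equivalent_diameters <= 0):
            raise ValueError("equivalent_diameters: must be > 0")
        if not 0 <= self.area_fraction <= 1:
            raise ValueError("area_fraction: must lie in [0, 1]")


@dataclass
class RoiProfiles:
    """Per-ROI and pointwise-averaged profiles (mean ± SD across ROIs)."""

    rdf_profiles: list[RadialProfile]
    kl_profiles: list[KLProfile]
    mean_rdf: RadialProfile
    sd_g: np.ndarray
    mean_kl: KLProfile
    sd_h: np.ndarray


def _pair_distances(pattern: PointPattern) -> np.ndarray:
    if pattern.n < 2:
        raise ValueError("pattern: at least 2 points required")
    return pdist(pattern.points)


def compute_rdf(
    pattern: PointPattern,
    ring_width: float = DEFAULT_RING_WIDTH,
    r_max: float = 2.0,
) -> RadialProfile:
    """Radial distribution function g(r) with ordered-pair ring counts."""
    if ring_width <= 0:
        raise ValueError("ring_width: must be > 0")
    if r_max <= 0:
        raise ValueError("r_max: must be > 0")
    d = _pair_distances(pattern)
    w = pattern.window
    if r_max > min(w.width, w.height) / 2:
        warn(
            "compute_rdf: r_max exceeds half the shorter window side; "
            "uncorrected edge bias will depress g at large r"
        )
    n_rings = int(np.ceil(r_max / ring_width))
    edges = np.arange(n_rings + 1) * ring_width
    unordered, _ = np.histogram(d, bins=edges)
    ordered = 2.0 * unordered
    r = edges[:-1]
    S, N = pattern.area, pattern.n
    ring_area = np.pi * (2.0 * r * ring_width + ring_width**2)
    g = (S / (N - 1)) / ring_area * (ordered / N)
    return RadialProfile(r_grid=r, ring_width=ring_width, g_values=g)


def compute_k_l(pattern: PointPattern, r_grid: np.ndarray) -> KLProfile:
    """Ripley's K, L and centered H on the given radius grid."""
    r_grid = np.asarray(r_grid, dtype=float)
    if np.any(r_grid < 0) or np.any(np.diff(r_grid) <= 0):
        raise ValueError("r_grid: must be non-negative and strictly increasing")
    d = np.sort(_pair_distances(pattern))
    S, N = pattern.area, pattern.n
    ordered = 2.0 * np.searchsorted(d, r_grid, side="right")
    K = S / (N * (N - 1)) * ordered
    L = np.sqrt(K / np.pi)
    H = L - r_grid
    peak_r = _peak_of_h(r_grid, H)
    return KLProfile(r_grid=r_grid, k_values=K, l_values=L, h_values=H, peak_r=peak_r)


def _peak_of_h(r_grid: np.ndarray, h: np.ndarray) -> float | None:
    interior = r_grid > 0
    if not interior.any() or np.nanmax(h[interior]) <= 0:
        return None
    sub = np.where(interior, h, -np.inf)
    return float(r_grid[int(np.argmax(sub))])


def cluster_scale(profile: KLProfile) -> float | None:
    """Characteristic cluster radius: argmax of H(r), absent if H ≤ 0."""
    return _peak_of_h(profile.r_grid, profile.h_values)


def detect_dots(
    image: Image8,
    threshold: float | str = "auto",
    min_area: int = 4,
) -> tuple[PointPattern, ClusterSummary]:
    """Threshold + 8-connected components -> intensity-weighted centroids (μm).

    ``threshold="auto"`` uses Otsu's method. An all-zero image yields an empty
    pattern. Components smaller than ``min_area`` pixels are dropped.
    """
    px = image.pixels
    if px.size == 0:
        raise ValueError("image: empty raster")
    if threshold == "auto":
        thr = float(threshold_otsu(px)) if px.max() > px.min() else float(px.max()) + 1
    else:
        thr = float(threshold)
        if not 0 <= thr <= 255:
            raise ValueError("threshold: must lie in [0, 255]")
    mask = px >= thr
    labeled = label(mask, connectivity=2)
    props = regionprops(labeled, intensity_image=px.astype(float))
    centroids, areas = [], []
    for p in props:
        if p.area < min_area:
            continue
        row, col = p.centroid_weighted
        # pixel centers sit at (index + 0.5) · pixel_size
        centroids.append(((col + 0.5) * image.pixel_size, (row + 0.5) * image.pixel_size))
        areas.append(p.area)
    areas_um2 = np.asarray(areas, dtype=float) * image.pixel_size**2
    summary = ClusterSummary(
        n_clusters=len(areas),
        equivalent_diameters=2.0 * np.sqrt(areas_um2 / np.pi),
        area_fraction=float(areas_um2.sum() / image.window.area) if areas else 0.0,
    )
    pts = np.asarray(centroids, dtype=float).reshape(-1, 2)
    # weighted centroids can fall marginally outside the strict raster extent
    w = image.window
    if pts.size:
        pts[:, 0] = np.clip(pts[:, 0], w.x0, w.x1)
        pts[:, 1] = np.clip(pts[:, 1], w.y0, w.y1)
    return PointPattern(pts, w), summary


def _crop(image: Image8, roi: Window) -> Image8:
    ps = image.pixel_size
    c0, c1 = int(np.floor(roi.x0 / ps)), int(np.ceil(roi.x1 / ps))
    r0, r1 = int(np.floor(roi.y0 / ps)), int(np.ceil(roi.y1 / ps))
    nrow, ncol = image.pixels.shape
    if not (0 <= r0 < r1 <= nrow and 0 <= c0 < c1 <= ncol):
        raise ValueError("roi: sub-window must lie inside the image")
    return Image8(image.pixels[r0:r1, c0:c1], ps)


def summarize_rois(
    image: Image8,
    rois: list[Window],
    ring_width: float = DEFAULT_RING_WIDTH,
    r_max: float = 2.0,
    threshold: float | str = "auto",
    min_area: int = 4,
) -> RoiProfiles:
    """Per-ROI g(r) and K/L/H with ROI-local window area, then pointwise mean ± SD.

    ROIs with fewer than two detected dots are excluded with a warning; if all
    are excluded the call is rejected.
    """
    if not rois:
        raise ValueError("rois: at least one ROI required")
    r_grid = np.arange(1, int(np.ceil(r_max / ring_width)) + 1) * ring_width
    rdfs: list[RadialProfile] = []
    kls: list[KLProfile] = []
    for i, roi in enumerate(rois):
        sub = _crop(image, roi)
        pattern, _ = detect_dots(sub, threshold=threshold, min_area=min_area)
        if pattern.n < 2:
            warn(f"summarize_rois: ROI {i} has fewer than 2 dots; excluded")
            continue
        rdfs.append(compute_rdf(pattern, ring_width=ring_width, r_max=r_max))
        kls.append(compute_k_l(pattern, r_grid))
    if not rdfs:
        raise ValueError("rois: no ROI contains at least 2 detected dots")
    g_stack = np.vstack([p.g_values for p in rdfs])
    h_stack = np.vstack([p.h_values for p in kls])
    k_stack = np.vstack([p.k_values for p in kls])
    l_stack = np.vstack([p.l_values for p in kls])
    mean_k = k_stack.mean(axis=0)
    mean_l = l_stack.mean(axis=0)
    mean_h = h_stack.mean(axis=0)
    mean_kl = KLProfile(
        r_grid=r_grid,
        k_values=mean_k,
        l_values=mean_l,
        h_values=mean_h,
        peak_r=_peak_of_h(r_grid, mean_h),
    )
    mean_rdf = RadialProfile(
        r_grid=rdfs[0].r_grid,
        ring_width=ring_width,
        g_values=g_stack.mean(axis=0),
    )
    return RoiProfiles(
        rdf_profiles=rdfs,
        kl_profiles=kls,
        mean_rdf=mean_rdf,
        sd_g=g_stack.std(axis=0, ddof=0),
        mean_kl=mean_kl,
        sd_h=h_stack.std(axis=0, ddof=0),
    )
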