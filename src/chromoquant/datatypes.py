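"""Core data containers shared across the analysis stages.

Conventions
-----------
* Microscopy coordinates are in micrometers (μm); the observation window is an
  axis-aligned rectangle and its area ``S`` enters the spatial statistics.
* Genomic coordinates are 0-based, half-open base-pair intervals; contact
  matrices are per-chromosome, square and symmetric at a fixed bin size.
* FRAP traces carry a pre-bleach segment (``n_pre`` frames) followed by the
  post-bleach recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Window",
    "PointPattern",
    "Image8",
    "ContactMatrix",
    "FrapTrace",
]


@dataclass(frozen=True)
class Window:
    """Axis-aligned rectangular observation window, coordinates in μm."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError("window: x1 > x0 and y1 > y0 required")

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the (closed) window."""
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        return (
            (xy[:, 0] >= self.x0)
            & (xy[:, 0] <= self.x1)
            & (xy[:, 1] >= self.y0)
            & (xy[:, 1] <= self.y1)
        )


@dataclass
class PointPattern:
    """A 2D point set inside a rectangular window (the substrate of g(r)/K(r)).

    Attributes
    ----------
    points : (N, 2) float array of (x, y) in μm.
    window : observation window; its area ``S`` normalizes the statistics.
    parents : optional ground-truth cluster centers attached by simulators.
    """

    points: np.ndarray
    window: Window
    parents: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if self.points.size and not self.window.contains(self.points).all():
            raise ValueError("points: all points must lie inside the window")

    @property
    def n(self) -> int:
        return int(self.points.shape[0])

    @property
    def area(self) -> float:
        return self.window.area

    def translated(self, dx: float, dy: float) -> "PointPattern":
        """Rigidly translate the pattern together with its window."""
        w = self.window
        return PointPattern(
            self.points + np.array([dx, dy]),
            Window(w.x0 + dx, w.y0 + dy, w.x1 + dx, w.y1 + dy),
        )


@dataclass
class Image8:
    """8-bit grayscale raster with a physical pixel size (μm/pixel)."""

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size: must be > 0")
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("pixels: expected a 2D array")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("pixels: intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def window(self) -> Window:
        nrow, ncol = self.pixels.shape
        return Window(0.0, 0.0, ncol * self.pixel_size, nrow * self.pixel_size)


_SYMMETRY_RTOL = 1e-9


@dataclass
class ContactMatrix:
    """Symmetric per-chromosome Hi-C contact matrix at a fixed bin size.

    ``counts`` holds raw counts or, after balancing, corrected contact values
    with masked (low-coverage) bins set to NaN. ``bias`` is the per-bin
    correction weight (NaN where masked). Ground-truth annotations from the
    simulator ride along for recovery tests.
    """

    counts: np.ndarray
    bin_size: int = 10_000
    chrom: str = "chrS"
    balanced: bool = False
    bias: np.ndarray | None = None
    tad_boundaries: np.ndarray | None = None
    compartment_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.counts, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("counts: matrix must be square")
        if self.bin_size <= 0:
            raise ValueError("bin_size: must be > 0")
        finite = np.isfinite(m)
        if not (finite == finite.T).all():
            raise ValueError("counts: NaN mask must be symmetric")
        vals = np.where(finite, m, 0.0)
        scale = max(np.abs(vals).max(), 1.0)
        if not np.allclose(vals, vals.T, rtol=_SYMMETRY_RTOL, atol=_SYMMETRY_RTOL * scale):
            raise ValueError("counts: matrix must be symmetric")
        if (vals < 0).any():
            raise ValueError("counts: entries must be non-negative")
        self.counts = m

    @property
    def n_bins(self) -> int:
        return int(self.counts.shape[0])

    @property
    def valid_bins(self) -> np.ndarray:
        """Boolean mask of bins that are not masked out."""
        if self.bias is not None:
            return np.isfinite(self.bias)
        return ~np.all(~np.isfinite(self.counts) | (self.counts == 0), axis=0)


@dataclass
class FrapTrace:
    """Timed bleach/reference ROI intensities with a pre-bleach segment."""

    times: np.ndarray
    bleach_intensity: np.ndarray
    reference_intensity: np.ndarray
    n_pre: int
    truth: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.bleach_intensity = np.asarray(self.bleach_intensity, dtype=float)
        self.reference_intensity = np.asarray(self.reference_intensity, dtype=float)
        n = self.times.size
        if self.bleach_intensity.size != n or self.reference_intensity.size != n:
            raise ValueError("trace: times/bleach/reference lengths must match")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times: must be strictly increasing")
        if not (1 <= self.n_pre <= n - 2):
            raise ValueError("n_pre: need >= 1 pre-bleach and >= 2 post-bleach frames")
        if np.any(self.reference_intensity <= 0):
            raise ValueError("reference_intensity: must be strictly positive")


def warn(msg: str) -> None:
    """Uniform warning channel for recoverable data issues."""
    warnings.warn(msg, UserWarning, stacklevel=3)
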