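"""Synthetic data with known ground truth for every downstream stage.

Four generators cover the pipeline's inputs:

* complete spatial randomness (CSR) and Thomas-type clustered point patterns
  at nuclear scale — the null and the condensed alternative for the spatial
  statistics; the Thomas process is used because its K-function has a closed
  form, ``K(r) = πr² + (1/κ)(1 − exp(−r²/4σ²))``, giving an analytic oracle;
* dot-image rendering so image-based detection can be round-tripped;
* per-chromosome contact matrices with power-law distance decay, planted TAD
  blocks and a planted two-compartment checkerboard under Poisson sampling;
* FRAP traces with single-exponential recovery and multiplicative acquisition
  photobleaching.

All generators are deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import ContactMatrix, FrapTrace, Image8, PointPattern, Window, warn

__all__ = [
    "CsrSpec",
    "ThomasSpec",
    "HicSimSpec",
    "FrapSimSpec",
    "simulate_csr",
    "simulate_thomas",
    "render_dots_image",
    "simulate_hic",
    "simulate_frap",
    "thomas_k_theoretical",
]


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"{name}: {msg}")


@dataclass(frozen=True)
class CsrSpec:
    """Homogeneous Poisson (binomial, fixed-N) point pattern in a rectangle."""

    window_width: float = 100.0   # μm
    window_height: float = 100.0  # μm
    n_points: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.window_width > 0, "window_width", "must be > 0")
        _require(self.window_height > 0, "window_height", "must be > 0")
        _require(self.n_points >= 2, "n_points", "must be >= 2")


@dataclass(frozen=True)
class ThomasSpec:
    """Thomas cluster process: Poisson parents, Gaussian-scattered offspring.

    Defaults give ~2500 points in a 50×50 μm window with clusters at the
    sub-μm scale of condensed chromatin puncta.
    """

    window_width: float = 50.0      # μm
    window_height: float = 50.0     # μm
    parent_intensity: float = 0.02  # parents per μm² (κ)
    mean_offspring: float = 50.0    # offspring per parent (μ)
    cluster_sd: float = 0.15        # Gaussian scatter σ, μm
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.window_width > 0, "window_width", "must be > 0")
        _require(self.window_height > 0, "window_height", "must be > 0")
        _require(self.parent_intensity > 0, "parent_intensity", "must be > 0")
        _require(self.mean_offspring > 0, "mean_offspring", "must be > 0")
        _require(self.cluster_sd > 0, "cluster_sd", "must be > 0")


@dataclass(frozen=True)
class HicSimSpec:
    """Contact-matrix generative model.

    Expected counts for bins i ≠ j::

        λ_ij = depth · s^(−α) · τ^[i,j in same TAD] · (1 + A·e_i·e_j)

    with s = |i − j| in bins, so ``depth`` fixes the expected count at a
    one-bin separation. Counts are Poisson with C_ij = C_ji. The diagonal uses
    the one-bin scale (s clipped to 1).
    """

    n_bins: int = 500
    bin_size: int = 10_000
    decay_exponent: float = 1.0          # α
    tad_boundaries: tuple[int, ...] = () # strictly increasing, in (0, n_bins)
    tad_enrichment: float = 1.0          # τ ≥ 1, within-TAD fold
    compartment_labels: np.ndarray | None = None  # per-bin ±1
    compartment_amplitude: float = 0.0   # A in [0, 1)
    depth: float = 100.0                 # expected count at 1-bin separation
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_bins >= 2, "n_bins", "must be >= 2")
        _require(self.bin_size > 0, "bin_size", "must be > 0")
        _require(self.decay_exponent > 0, "decay_exponent", "must be > 0")
        _require(self.tad_enrichment >= 1, "tad_enrichment", "must be >= 1")
        _require(
            0 <= self.compartment_amplitude < 1,
            "compartment_amplitude",
            "must lie in [0, 1)",
        )
        _require(self.depth >= 0, "depth", "must be >= 0")
        b = np.asarray(self.tad_boundaries, dtype=int)
        if b.size:
            _require(
                bool(np.all(np.diff(b) > 0)),
                "tad_boundaries",
                "must be strictly increasing",
            )
            _require(
                bool(b[0] > 0 and b[-1] < self.n_bins),
                "tad_boundaries",
                "indices must lie strictly inside (0, n_bins)",
            )
        if self.compartment_labels is not None:
            e = np.asarray(self.compartment_labels)
            _require(
                e.shape == (self.n_bins,),
                "compartment_labels",
                "must have one label per bin",
            )
            _require(
                bool(np.isin(e, (-1, 1)).all()),
                "compartment_labels",
                "labels must be ±1",
            )


@dataclass(frozen=True)
class FrapSimSpec:
    """Single-exponential FRAP recovery with acquisition photobleaching.

    Bleach-ROI truth: 1 pre-bleach, then
    ``(1 − bleach_depth) + bleach_depth·M·(1 − exp(−t/τ))`` post-bleach;
    reference-ROI truth: constant 1. Both are multiplied by
    ``exp(−acquisition_decay_rate · t_abs)`` and Gaussian noise is added.
    """

    n_pre: int = 5
    n_post: int = 60
    frame_interval: float = 1.0        # s
    mobile_fraction: float = 0.6       # M in [0, 1]
    recovery_tau: float = 10.0         # s
    bleach_depth: float = 0.8          # fraction in (0, 1]
    acquisition_decay_rate: float = 0.0  # per second
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_pre >= 1, "n_pre", "must be >= 1")
        _require(self.n_post >= 2, "n_post", "must be >= 2")
        _require(self.frame_interval > 0, "frame_interval", "must be > 0")
        _require(0 <= self.mobile_fraction <= 1, "mobile_fraction", "must lie in [0, 1]")
        _require(self.recovery_tau > 0, "recovery_tau", "must be > 0")
        _require(0 < self.bleach_depth <= 1, "bleach_depth", "must lie in (0, 1]")
        _require(
            self.acquisition_decay_rate >= 0,
            "acquisition_decay_rate",
            "must be >= 0",
        )
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")


def simulate_csr(spec: CsrSpec) -> PointPattern:
    """Exactly ``n_points`` i.i.d. uniform points in the window."""
    rng = np.random.default_rng(spec.seed)
    xy = rng.uniform(
        low=(0.0, 0.0),
        high=(spec.window_width, spec.window_height),
        size=(spec.n_points, 2),
    )
    return PointPattern(xy, Window(0.0, 0.0, spec.window_width, spec.window_height))


def simulate_thomas(spec: ThomasSpec) -> PointPattern:
    """Thomas cluster process; offspring outside the window are discarded."""
    rng = np.random.default_rng(spec.seed)
    window = Window(0.0, 0.0, spec.window_width, spec.window_height)
    n_parents = rng.poisson(spec.parent_intensity * window.area)
    parents = rng.uniform(
        low=(0.0, 0.0),
        high=(spec.window_width, spec.window_height),
        size=(n_parents, 2),
    )
    counts = rng.poisson(spec.mean_offspring, size=n_parents)
    offspring = np.repeat(parents, counts, axis=0)
    offspring = offspring + rng.normal(0.0, spec.cluster_sd, size=offspring.shape)
    offspring = offspring[window.contains(offspring)]
    if offspring.shape[0] < 2:
        raise ValueError(
            "realized pattern has fewer than 2 points; increase "
            "parent_intensity × mean_offspring"
        )
    return PointPattern(offspring, window, parents=parents)


def thomas_k_theoretical(r: np.ndarray, kappa: float, sigma: float) -> np.ndarray:
    """Closed-form K-function of the Thomas process."""
    r = np.asarray(r, dtype=float)
    return np.pi * r**2 + (1.0 / kappa) * (1.0 - np.exp(-(r**2) / (4.0 * sigma**2)))


def render_dots_image(
    pattern: PointPattern,
    pixel_size: float,
    dot_radius: float,
    peak_value: int = 255,
) -> Image8:
    """Rasterize a point pattern as solid discs on a zero background."""
    if pixel_size <= 0:
        raise ValueError("pixel_size: must be > 0")
    if not (0 < peak_value <= 255):
        raise ValueError("peak_value: must lie in (0, 255]")
    w = pattern.window
    ncol = max(int(np.ceil(w.width / pixel_size)), 1)
    nrow = max(int(np.ceil(w.height / pixel_size)), 1)
    img = np.zeros((nrow, ncol), dtype=np.uint8)
    r_px = dot_radius / pixel_size
    half = int(np.ceil(r_px)) + 1
    clipped = 0
    for x, y in pattern.points:
        cc = (x - w.x0) / pixel_size - 0.5
        rr = (y - w.y0) / pixel_size - 0.5
        r0, r1 = int(np.floor(rr)) - half, int(np.floor(rr)) + half + 1
        c0, c1 = int(np.floor(cc)) - half, int(np.floor(cc)) + half + 1
        if r1 <= 0 or c1 <= 0 or r0 >= nrow or c0 >= ncol:
            clipped += 1
            continue
        cr0, cr1 = max(r0, 0), min(r1, nrow)
        cc0, cc1 = max(c0, 0), min(c1, ncol)
        if (cr0, cr1, cc0, cc1) != (r0, r1, c0, c1):
            clipped += 1
        gy, gx = np.mgrid[cr0:cr1, cc0:cc1]
        mask = (gy - rr) ** 2 + (gx - cc) ** 2 <= max(r_px, 0.5) ** 2
        img[cr0:cr1, cc0:cc1][mask] = peak_value
    if clipped:
        warn(f"render_dots_image: {clipped} dot(s) clipped at the raster edge")
    return Image8(img, pixel_size)


def _tad_segment_ids(n_bins: int, boundaries: np.ndarray) -> np.ndarray:
    # segment index per bin; boundary bin b starts a new segment
    return np.searchsorted(boundaries, np.arange(n_bins), side="right")


def simulate_hic(spec: HicSimSpec) -> ContactMatrix:
    """Poisson-sampled symmetric contact matrix with attached ground truth."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_bins
    idx = np.arange(n)
    s = np.abs(idx[:, None] - idx[None, :]).astype(float)
    np.maximum(s, 1.0, out=s)  # diagonal uses the one-bin scale
    lam = spec.depth * s ** (-spec.decay_exponent)

    boundaries = np.asarray(spec.tad_boundaries, dtype=int)
    if boundaries.size and spec.tad_enrichment != 1.0:
        seg = _tad_segment_ids(n, boundaries)
        same_tad = seg[:, None] == seg[None, :]
        lam = lam * np.where(same_tad, spec.tad_enrichment, 1.0)

    labels = None
    if spec.compartment_labels is not None and spec.compartment_amplitude > 0:
        labels = np.asarray(spec.compartment_labels, dtype=int)
        lam = lam * (1.0 + spec.compartment_amplitude * np.outer(labels, labels))
    elif spec.compartment_labels is not None:
        labels = np.asarray(spec.compartment_labels, dtype=int)

    upper = np.triu(rng.poisson(np.triu(lam)))
    counts = upper + np.triu(upper, 1).T
    return ContactMatrix(
        counts.astype(float),
        bin_size=spec.bin_size,
        chrom="chrS",
        tad_boundaries=boundaries if boundaries.size else None,
        compartment_labels=labels,
    )


def simulate_frap(spec: FrapSimSpec) -> FrapTrace:
    """Simulate a FRAP trace; ground-truth parameters ride along in ``truth``."""
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_pre + spec.n_post
    times = np.arange(n_total) * spec.frame_interval
    t_post = times[spec.n_pre:] - times[spec.n_pre]  # 0 at the first post frame

    bleach = np.ones(n_total)
    bleach[spec.n_pre:] = (1.0 - spec.bleach_depth) + spec.bleach_depth * (
        spec.mobile_fraction * (1.0 - np.exp(-t_post / spec.recovery_tau))
    )
    reference = np.ones(n_total)

    fade = np.exp(-spec.acquisition_decay_rate * times)
    bleach = bleach * fade
    reference = reference * fade
    if spec.noise_sd > 0:
        bleach = bleach + rng.normal(0.0, spec.noise_sd, n_total)
        reference = reference + rng.normal(0.0, spec.noise_sd, n_total)
        reference = np.maximum(reference, 1e-6)  # keep the reference positive

    return FrapTrace(
        times,
        bleach,
        reference,
        n_pre=spec.n_pre,
        truth={
            "mobile_fraction": spec.mobile_fraction,
            "recovery_tau": spec.recovery_tau,
            "bleach_depth": spec.bleach_depth,
        },
    )
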