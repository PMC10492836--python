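"""Conformational statistics on per-chromosome contact matrices.

The stages mirror a standard Hi-C downstream workflow:

* iterative-correction balancing with MAD-based masking of low-coverage bins;
* contact-probability decay P(s) in log-spaced separation bins, normalized to
  sum to one over the included separations;
* insulation scores: for each bin, the mean contact in a w×w diamond crossing
  it (w = window / bin_size, default 500 kb / 10 kb), as log2 of the diamond
  mean over its chromosome-wide mean — identically 0 on a uniform matrix,
  undefined within w bins of the chromosome edges;
* TAD boundaries at strict local minima of the insulation track, with
  strength defined as the prominence of the minimum (the smaller of the two
  rises to the nearest flanking local maxima); boundaries with strength above
  0.1 are high-confidence;
* boundary matching between conditions: each boundary bin is extended by
  50 kb on both sides into a 110 kb zone; zones that partially overlap are
  matched one-to-one (greedy, nearest centers first), so the shared/specific
  counts satisfy Venn arithmetic exactly;
* A/B compartments: first eigenvector of the Pearson correlation matrix of
  the observed/expected matrix, sign-oriented against a supplied covariate
  (planted labels for synthetic data, GC content for real data); A where
  e1 > 0, B where e1 < 0;
* compartment switch counts between two oriented tracks and compartment
  strength as mean observed/expected within AA, BB and AB bin pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import mannwhitneyu

from .datatypes import ContactMatrix, warn

__all__ = [
    "PsCurve",
    "InsulationTrack",
    "Boundary",
    "BoundarySet",
    "BoundaryComparison",
    "CompartmentTrack",
    "CompartmentStrength",
    "SwitchSummary",
    "balance_matrix",
    "ps_curve",
    "fit_ps_slope",
    "insulation",
    "call_boundaries",
    "compare_boundaries",
    "compartments",
    "compartment_switches",
    "compartment_strength",
    "aggregate_insulation_profiles",
    "expected_by_distance",
    "observed_over_expected",
    "compare_insulation_distributions",
]

DEFAULT_INSULATION_WINDOW = 500_000  # bp
DEFAULT_STRENGTH_THRESHOLD = 0.1
DEFAULT_ZONE_EXTENSION = 50_000  # bp
# minimum masking margin (dex below median coverage) when the MAD collapses
_MAD_SPAN_FLOOR = 0.5


@dataclass
class PsCurve:
    """Mean contact probability per log-spaced genomic-separation bin."""

    s_bins: np.ndarray   # bp, geometric centers of the separation bins
    probs: np.ndarray    # normalized to sum to 1 over included bins

    def __post_init__(self) -> None:
        self.s_bins = np.asarray(self.s_bins, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if np.any(np.diff(self.s_bins) <= 0):
            raise ValueError("s_bins: must be strictly increasing")
        if np.any(self.probs < 0):
            raise ValueError("probs: must be >= 0")


@dataclass
class InsulationTrack:
    """Per-bin log2 normalized insulation; NaN where undefined."""

    scores: np.ndarray
    window: int = DEFAULT_INSULATION_WINDOW
    bin_size: int = 10_000
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)


@dataclass(frozen=True)
class Boundary:
    """One called TAD boundary: its bin, bp interval, and prominence strength."""

    bin_index: int
    start: int
    end: int
    strength: float

    @property
    def center(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class BoundarySet:
    boundaries: list[Boundary]
    bin_size: int = 10_000
    chrom: str = "chrS"
    zone_extension: int = DEFAULT_ZONE_EXTENSION

    def __post_init__(self) -> None:
        self.boundaries = sorted(self.boundaries, key=lambda b: b.start)

    def __len__(self) -> int:
        return len(self.boundaries)

    def zones(self) -> np.ndarray:
        """Half-open [start − ext, end + ext) zones, one row per boundary."""
        ext = self.zone_extension
        return np.array([(b.start - ext, b.end + ext) for b in self.boundaries])


@dataclass
class BoundaryComparison:
    shared_pairs: list[tuple[Boundary, Boundary]]
    a_specific: list[Boundary]
    b_specific: list[Boundary]

    @property
    def n_shared(self) -> int:
        return len(self.shared_pairs)


@dataclass
class CompartmentTrack:
    """First-eigenvector values with A/B labels; NaN / None where masked."""

    e1: np.ndarray
    labels: np.ndarray  # 'A', 'B' or '' (unassigned)
    oriented: bool
    bin_size: int = 10_000
    chrom: str = "chrS"
    # ratio of the two largest eigenvalues; near 1 means no dominant
    # compartment signal and the A/B calls are unstable
    eigenvalue_ratio: float = float("nan")
    low_confidence: bool = False

    def __post_init__(self) -> None:
        self.e1 = np.asarray(self.e1, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        assigned = self.labels != ""
        if not np.all((self.e1[assigned] > 0) == (self.labels[assigned] == "A")):
            raise ValueError("labels: must equal A where e1 > 0 and B where e1 < 0")

    @property
    def assigned(self) -> np.ndarray:
        return self.labels != ""


@dataclass
class CompartmentStrength:
    """Mean observed/expected contact within AA, BB and across AB bin pairs."""

    aa: float
    bb: float
    ab: float


@dataclass
class SwitchSummary:
    """A/B switch counts between two oriented tracks over jointly assigned bins."""

    n_joint: int
    a_to_b: int
    b_to_a: int
    stable_a: int
    stable_b: int

    @property
    def pct_a_to_b(self) -> float:
        return 100.0 * self.a_to_b / self.n_joint

    @property
    def pct_b_to_a(self) -> float:
        return 100.0 * self.b_to_a / self.n_joint

    @property
    def pct_switched(self) -> float:
        return 100.0 * (self.a_to_b + self.b_to_a) / self.n_joint


# ---------------------------------------------------------------------------
# balancing


def balance_matrix(
    m: ContactMatrix,
    max_iter: int = 200,
    tol: float = 1e-5,
    mad_filter: float = 5.0,
) -> ContactMatrix:
    """Iterative correction: equalize marginals, mask low-coverage bins.

    Bins with zero coverage, or whose log10 marginal falls more than
    ``mad_filter`` MADs below the median, are masked (NaN in the output).
    The MAD criterion targets technical dropouts; when the coverage
    distribution is nearly uniform the MAD collapses and would mask healthy
    bins, so the cutoff is floored at 0.5 dex (~3-fold) below the median.
    Converges when the coefficient of variation of the unmasked marginals
    drops below ``tol``; the balanced matrix is scaled so unmasked rows sum
    to 1.
    """
    counts = np.array(m.counts, dtype=float)
    n = counts.shape[0]
    marg = counts.sum(axis=0)
    valid = marg > 0
    if valid.any() and mad_filter is not None:
        logm = np.log10(marg[valid])
        med = np.median(logm)
        mad = np.median(np.abs(logm - med))
        lo = med - max(mad_filter * mad, _MAD_SPAN_FLOOR)
        valid[valid] &= logm >= lo
    if not valid.any():
        raise ValueError("balance_matrix: all bins masked (no coverage)")

    w = counts[np.ix_(valid, valid)]
    bias_sub = np.ones(valid.sum())
    for _ in range(max_iter):
        s = w.sum(axis=0)
        s = s / s.mean()
        cv = s.std() / s.mean()
        if cv < tol:
            break
        w = w / np.outer(s, s)
        bias_sub *= s
    rowsum = w.sum(axis=0)
    scale = rowsum.mean()
    w = w / scale
    bias_sub = bias_sub * np.sqrt(scale)

    balanced = np.full((n, n), np.nan)
    balanced[np.ix_(valid, valid)] = w
    bias = np.full(n, np.nan)
    bias[valid] = bias_sub
    return ContactMatrix(
        balanced,
        bin_size=m.bin_size,
        chrom=m.chrom,
        balanced=True,
        bias=bias,
        tad_boundaries=m.tad_boundaries,
        compartment_labels=m.compartment_labels,
    )


# ---------------------------------------------------------------------------
# P(s)


def _per_separation_sums(m: ContactMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Sum and count of finite contact values at each bin separation >= 1."""
    c = m.counts
    n = m.n_bins
    sums = np.zeros(n)
    cnts = np.zeros(n)
    for s in range(1, n):
        diag = np.diagonal(c, offset=s)
        finite = np.isfinite(diag)
        sums[s] = diag[finite].sum()
        cnts[s] = finite.sum()
    return sums, cnts


def ps_curve(
    matrices: list[ContactMatrix] | ContactMatrix,
    bins_per_decade: int = 8,
) -> PsCurve:
    """Contact probability vs genomic separation, pooled across chromosomes."""
    if isinstance(matrices, ContactMatrix):
        matrices = [matrices]
    if not matrices:
        raise ValueError("matrices: at least one contact matrix required")
    bs = matrices[0].bin_size
    if any(m.bin_size != bs for m in matrices):
        raise ValueError("matrices: bin sizes must match")
    max_sep = max(m.n_bins for m in matrices) * bs
    # log-spaced edges from one bin to the chromosome span
    n_edges = max(int(np.ceil(np.log10(max_sep / bs) * bins_per_decade)) + 1, 2)
    edges = np.geomspace(bs, max_sep, n_edges)

    pooled_sum = np.zeros(edges.size - 1)
    pooled_cnt = np.zeros(edges.size - 1)
    for m in matrices:
        sums, cnts = _per_separation_sums(m)
        seps_bp = np.arange(m.n_bins) * bs
        which = np.clip(np.searchsorted(edges, seps_bp, side="right") - 1, 0, edges.size - 2)
        for s in range(1, m.n_bins):
            pooled_sum[which[s]] += sums[s]
            pooled_cnt[which[s]] += cnts[s]

    keep = pooled_cnt > 0
    if not keep.all():
        warn(f"ps_curve: dropping {int((~keep).sum())} empty separation bin(s)")
    mean_contact = pooled_sum[keep] / pooled_cnt[keep]
    centers = np.sqrt(edges[:-1] * edges[1:])[keep]
    total = mean_contact.sum()
    if total <= 0:
        raise ValueError("ps_curve: no contacts at any separation")
    return PsCurve(s_bins=centers, probs=mean_contact / total)


def fit_ps_slope(curve: PsCurve, s_min: float, s_max: float) -> float:
    """Log–log slope of P(s) over separations in [s_min, s_max]."""
    sel = (curve.s_bins >= s_min) & (curve.s_bins <= s_max) & (curve.probs > 0)
    if sel.sum() < 3:
        raise ValueError("fit_ps_slope: fewer than 3 usable separation bins")
    slope, _ = np.polyfit(np.log(curve.s_bins[sel]), np.log(curve.probs[sel]), 1)
    return float(slope)


# ---------------------------------------------------------------------------
# insulation & boundaries


def insulation(
    m: ContactMatrix,
    window: int = DEFAULT_INSULATION_WINDOW,
) -> InsulationTrack:
    """Diamond insulation score: log2 of the mean cross-bin contact in a
    window×window diamond over its chromosome-wide mean.

    Accepts balanced or raw matrices. Balance first when the matrix carries
    experimental coverage bias; simulated matrices with uniform detection
    efficiency are best scored raw, since iterative correction of a purely
    TAD-structured matrix redistributes counts and flattens the insulation
    valley floor around boundaries.
    """
    if window % m.bin_size != 0:
        raise ValueError("window: must be a multiple of bin_size")
    w = window // m.bin_size
    n = m.n_bins
    scores = np.full(n, np.nan)
    if n < 2 * w + 1:
        warn("insulation: chromosome shorter than 2 windows; all scores undefined")
        return InsulationTrack(scores, window=window, bin_size=m.bin_size, chrom=m.chrom)
    c = m.counts
    diamond = np.full(n, np.nan)
    for i in range(w, n - w):
        block = c[i - w : i, i + 1 : i + w + 1]
        finite = np.isfinite(block)
        if finite.any():
            diamond[i] = block[finite].mean()
    overall = np.nanmean(diamond) if np.isfinite(diamond).any() else np.nan
    if np.isfinite(overall) and overall > 0:
        with np.errstate(divide="ignore"):
            # a zero diamond (no cross-bin contact at all) scores -inf,
            # the perfectly insulating limit
            scores = np.log2(diamond / overall)
    return InsulationTrack(scores, window=window, bin_size=m.bin_size, chrom=m.chrom)


def call_boundaries(
    track: InsulationTrack,
    strength_threshold: float = DEFAULT_STRENGTH_THRESHOLD,
) -> BoundarySet:
    """Local minima of the insulation score, filtered by prominence.

    Strength is the topographic prominence of the minimum: the smaller of the
    two rises from the valley floor to the bounding maxima (key saddles) on
    each side, computed within the contiguous defined segment. On a clean
    V-shaped valley this equals min(left peak − minimum, right peak − minimum);
    with noise it is robust to small wiggles inside the valley.
    """
    s = track.scores
    boundaries: list[Boundary] = []
    idx = np.flatnonzero(~np.isnan(s))  # -inf (zero diamond) is a defined minimum
    if idx.size == 0:
        return BoundarySet([], bin_size=track.bin_size, chrom=track.chrom)
    # contiguous defined segments
    splits = np.flatnonzero(np.diff(idx) > 1)
    for seg in np.split(idx, splits + 1):
        if seg.size < 3:
            continue
        minima, props = find_peaks(-s[seg[0] : seg[-1] + 1], prominence=0.0)
        for local_i, strength in zip(minima, props["prominences"]):
            i = int(seg[0] + local_i)
            if strength > strength_threshold:
                boundaries.append(
                    Boundary(
                        bin_index=i,
                        start=i * track.bin_size,
                        end=(i + 1) * track.bin_size,
                        strength=float(strength),
                    )
                )
    return BoundarySet(boundaries, bin_size=track.bin_size, chrom=track.chrom)


def compare_boundaries(a: BoundarySet, b: BoundarySet) -> BoundaryComparison:
    """One-to-one matching of boundary zones that partially overlap.

    Candidate pairs (half-open zone intersection non-empty) are matched
    greedily by increasing center distance; leftovers are condition-specific.
    """
    if a.bin_size != b.bin_size:
        raise ValueError("compare_boundaries: bin sizes must match")
    if a.chrom != b.chrom:
        raise ValueError("compare_boundaries: chromosome labels must match")
    za = a.zones().reshape(-1, 2)
    zb = b.zones().reshape(-1, 2)
    candidates: list[tuple[float, int, int]] = []
    for i, ba in enumerate(a.boundaries):
        for j, bb in enumerate(b.boundaries):
            if za[i, 0] < zb[j, 1] and zb[j, 0] < za[i, 1]:
                candidates.append((abs(ba.center - bb.center), i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    shared: list[tuple[Boundary, Boundary]] = []
    for _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        shared.append((a.boundaries[i], b.boundaries[j]))
    a_specific = [bd for i, bd in enumerate(a.boundaries) if i not in used_a]
    b_specific = [bd for j, bd in enumerate(b.boundaries) if j not in used_b]
    return BoundaryComparison(shared, a_specific, b_specific)


# ---------------------------------------------------------------------------
# compartments


def expected_by_distance(m: ContactMatrix) -> np.ndarray:
    """Mean finite contact value at each bin separation (index = separation)."""
    sums, cnts = _per_separation_sums(m)
    diag = np.diagonal(m.counts)
    finite0 = np.isfinite(diag)
    sums[0] = diag[finite0].sum()
    cnts[0] = finite0.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)


def observed_over_expected(m: ContactMatrix) -> np.ndarray:
    """O/E matrix; NaN where the matrix is masked or expected is 0/undefined."""
    n = m.n_bins
    exp = expected_by_distance(m)
    i = np.arange(n)
    sep = np.abs(i[:, None] - i[None, :])
    e = exp[sep]
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(np.isfinite(e) & (e > 0), m.counts / e, np.nan)


def compartments(
    m: ContactMatrix,
    orientation_track: np.ndarray | None = None,
) -> CompartmentTrack:
    """First eigenvector of the Pearson correlation matrix of O/E columns.

    The eigenvector sign is oriented so its correlation with
    ``orientation_track`` is positive; without a covariate the sign is
    arbitrary and the output is flagged ``oriented=False``.
    """
    if not m.balanced:
        raise ValueError("compartments: matrix must be balanced first")
    valid = m.valid_bins
    if valid.sum() < 2:
        raise ValueError("compartments: fewer than 2 unmasked bins")
    oe = observed_over_expected(m)[np.ix_(valid, valid)]
    oe = np.where(np.isfinite(oe), oe, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(oe, rowvar=False)
    corr = np.where(np.isfinite(corr), corr, 0.0)
    if np.linalg.matrix_rank(corr) < 2:
        raise ValueError("compartments: degenerate correlation matrix (rank < 2)")
    eigvals, eigvecs = np.linalg.eigh(corr)
    v = eigvecs[:, -1]  # eigenvector of the largest eigenvalue
    ratio = float(eigvals[-1] / eigvals[-2]) if eigvals[-2] > 0 else float("inf")
    low_confidence = ratio < 2.0
    if low_confidence:
        warn(
            "compartments: leading eigenvalue is not dominant "
            f"(ratio {ratio:.2f}); A/B calls are low-confidence"
        )

    e1 = np.full(m.n_bins, np.nan)
    e1[valid] = v
    oriented = False
    if orientation_track is not None:
        ref = np.asarray(orientation_track, dtype=float)
        if ref.shape != (m.n_bins,):
            raise ValueError("orientation_track: one value per bin required")
        both = valid & np.isfinite(ref)
        c = np.corrcoef(e1[both], ref[both])[0, 1]
        if np.isfinite(c) and c < 0:
            e1 = -e1
        oriented = True
    else:
        warn("compartments: no orientation covariate; A/B sign is arbitrary")
    labels = np.where(e1 > 0, "A", np.where(e1 < 0, "B", "")).astype(object)
    labels[~np.isfinite(e1)] = ""
    return CompartmentTrack(
        e1=e1,
        labels=labels,
        oriented=oriented,
        bin_size=m.bin_size,
        chrom=m.chrom,
        eigenvalue_ratio=ratio,
        low_confidence=low_confidence,
    )


def compartment_switches(ctrl: CompartmentTrack, treated: CompartmentTrack) -> SwitchSummary:
    """Count A↔B switches over bins assigned in both oriented tracks."""
    if ctrl.bin_size != treated.bin_size or ctrl.e1.size != treated.e1.size:
        raise ValueError("compartment_switches: binning mismatch")
    if not (ctrl.oriented and treated.oriented):
        raise ValueError("compartment_switches: both tracks must be sign-oriented")
    joint = ctrl.assigned & treated.assigned
    la, lb = ctrl.labels[joint], treated.labels[joint]
    return SwitchSummary(
        n_joint=int(joint.sum()),
        a_to_b=int(((la == "A") & (lb == "B")).sum()),
        b_to_a=int(((la == "B") & (lb == "A")).sum()),
        stable_a=int(((la == "A") & (lb == "A")).sum()),
        stable_b=int(((la == "B") & (lb == "B")).sum()),
    )


def compartment_strength(
    m: ContactMatrix,
    track: CompartmentTrack,
    min_separation: int = 2,
) -> CompartmentStrength:
    """Mean O/E over AA, BB and AB bin pairs at |i − j| >= min_separation bins."""
    if not m.balanced:
        raise ValueError("compartment_strength: matrix must be balanced first")
    oe = observed_over_expected(m)
    n = m.n_bins
    i = np.arange(n)
    sep_ok = np.abs(i[:, None] - i[None, :]) >= min_separation
    assigned = track.assigned
    pair_ok = sep_ok & np.isfinite(oe) & np.outer(assigned, assigned)
    is_a = track.labels == "A"
    groups = {
        "aa": np.outer(is_a, is_a),
        "bb": np.outer(~is_a & assigned, ~is_a & assigned),
        "ab": np.outer(is_a, ~is_a & assigned) | np.outer(~is_a & assigned, is_a),
    }
    means = {}
    for name, gmask in groups.items():
        sel = gmask & pair_ok
        if sel.any():
            means[name] = float(oe[sel].mean())
        else:
            warn(f"compartment_strength: no usable {name.upper()} pairs")
            means[name] = float("nan")
    return CompartmentStrength(aa=means["aa"], bb=means["bb"], ab=means["ab"])


# ---------------------------------------------------------------------------
# averaged insulation profiles & distribution comparison


def aggregate_insulation_profiles(
    track: InsulationTrack,
    centers: np.ndarray,
    flank: int = DEFAULT_INSULATION_WINDOW,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Mean ± SD insulation profile around center bins.

    Returns (offsets_bp, mean, sd, n_used). Centers whose window includes any
    undefined score are dropped with a warning.
    """
    k = flank // track.bin_size
    offsets = np.arange(-k, k + 1) * track.bin_size
    rows = []
    dropped = 0
    for c in np.asarray(centers, dtype=int):
        if c - k < 0 or c + k >= track.scores.size:
            dropped += 1
            continue
        win = track.scores[c - k : c + k + 1]
        if not np.isfinite(win).all():
            dropped += 1
            continue
        rows.append(win)
    if dropped:
        warn(f"aggregate_insulation_profiles: dropped {dropped} center(s)")
    if not rows:
        raise ValueError("aggregate_insulation_profiles: no usable centers")
    stack = np.vstack(rows)
    return offsets, stack.mean(axis=0), stack.std(axis=0, ddof=0), stack.shape[0]


def compare_insulation_distributions(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    alternative: str = "less",
) -> tuple[float, float]:
    """One-tailed Mann–Whitney U comparison of two insulation score samples."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("compare_insulation_distributions: empty sample")
    stat, p = mannwhitneyu(a, b, alternative=alternative)
    return float(stat), float(p)
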