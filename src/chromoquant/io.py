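"""File formats: TSV point sets and dense matrices, BED/bedGraph tracks,
8-bit TIFF images, and FRAP traces.

Dialects
--------
* Point sets: TSV with header ``x_um\\ty_um`` plus a JSON sidecar
  (``<path>.window.json``) holding the window bounds.
* Contact matrices: dense TSV with the one-line header
  ``#bin_size=<bp>\\t#chrom=<name>`` followed by the square body.
* BED is 0-based, half-open; bedGraph is 4-column.
* FRAP traces: TSV ``time_s\\tbleach\\treference`` with an ``#n_pre=<k>``
  header comment.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .datatypes import ContactMatrix, FrapTrace, Image8, PointPattern, Window
from .hic import BoundarySet, CompartmentTrack, InsulationTrack
from .condensation import KLProfile, RadialProfile

__all__ = [
    "read_point_tsv",
    "write_point_tsv",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "write_bed",
    "write_bedgraph",
    "read_image",
    "write_image",
    "read_frap_tsv",
    "write_frap_tsv",
    "write_rdf_tsv",
    "write_kl_tsv",
    "write_boundaries_bed",
    "write_insulation_bedgraph",
    "write_e1_bedgraph",
]


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".window.json")


def write_point_tsv(path: str | Path, pattern: PointPattern) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("x_um\ty_um\n")
        for x, y in pattern.points:
            fh.write(f"{x:.12g}\t{y:.12g}\n")
    w = pattern.window
    _sidecar(path).write_text(
        json.dumps({"x0": w.x0, "y0": w.y0, "x1": w.x1, "y1": w.y1}) + "\n"
    )


def read_point_tsv(path: str | Path) -> PointPattern:
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise ValueError(f"{path}: window sidecar {side.name} is missing")
    meta = json.loads(side.read_text())
    window = Window(meta["x0"], meta["y0"], meta["x1"], meta["y1"])
    pts = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header.split("\t") != ["x_um", "y_um"]:
            raise ValueError(f"{path}, line 1: expected header 'x_um\\ty_um'")
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}, line {lineno}: expected 2 columns")
            try:
                pts.append((float(fields[0]), float(fields[1])))
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from None
    return PointPattern(np.asarray(pts, dtype=float).reshape(-1, 2), window)


def write_matrix_tsv(path: str | Path, m: ContactMatrix) -> None:
    with open(path, "w") as fh:
        fh.write(f"#bin_size={m.bin_size}\t#chrom={m.chrom}\n")
        for row in m.counts:
            fh.write("\t".join(f"{v:.12g}" for v in row) + "\n")


def read_matrix_tsv(path: str | Path) -> ContactMatrix:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        fields = dict(
            part.lstrip("#").split("=", 1)
            for part in header.split("\t")
            if part.startswith("#") and "=" in part
        )
        if "bin_size" not in fields:
            raise ValueError(f"{path}, line 1: missing '#bin_size=' header")
        bin_size = int(fields["bin_size"])
        chrom = fields.get("chrom", "chrS")
        rows = []
        width = None
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            vals = line.rstrip("\n").split("\t")
            if width is None:
                width = len(vals)
            elif len(vals) != width:
                raise ValueError(
                    f"{path}, line {lineno}: expected {width} columns, got {len(vals)}"
                )
            try:
                rows.append([float(v) for v in vals])
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from None
    body = np.asarray(rows, dtype=float)
    if body.ndim != 2 or body.shape[0] != body.shape[1]:
        raise ValueError(
            f"{path}, line {len(rows) + 1}: matrix body is {body.shape[0]}×"
            f"{body.shape[1]}, not square"
        )
    return ContactMatrix(body, bin_size=bin_size, chrom=chrom)


def write_bed(
    path: str | Path,
    intervals: list[tuple[str, int, int]] | list[tuple[str, int, int, str, float]],
) -> None:
    """0-based, half-open BED; optional name and score columns."""
    with open(path, "w") as fh:
        for rec in intervals:
            fh.write("\t".join(str(v) for v in rec) + "\n")


def write_bedgraph(
    path: str | Path,
    chrom: str,
    bin_size: int,
    values: np.ndarray,
) -> None:
    """Per-bin track as 4-column bedGraph; NaN bins are skipped."""
    values = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        for i, v in enumerate(values):
            if np.isfinite(v):
                fh.write(f"{chrom}\t{i * bin_size}\t{(i + 1) * bin_size}\t{v:.9g}\n")


def write_image(path: str | Path, image: Image8) -> None:
    tifffile.imwrite(str(path), image.pixels)


def read_image(path: str | Path, pixel_size: float) -> Image8:
    px = tifffile.imread(str(path))
    if px.dtype != np.uint8:
        raise ValueError(f"{path}: expected an 8-bit grayscale image")
    return Image8(px, pixel_size)


def write_frap_tsv(path: str | Path, trace: FrapTrace) -> None:
    with open(path, "w") as fh:
        fh.write(f"#n_pre={trace.n_pre}\n")
        fh.write("time_s\tbleach\treference\n")
        for t, b, r in zip(trace.times, trace.bleach_intensity, trace.reference_intensity):
            fh.write(f"{t:.12g}\t{b:.12g}\t{r:.12g}\n")


def read_frap_tsv(path: str | Path, n_pre: int | None = None) -> FrapTrace:
    path = Path(path)
    times, bleach, ref = [], [], []
    with open(path) as fh:
        lineno = 0
        for line in fh:
            lineno += 1
            line = line.rstrip("\n")
            if line.startswith("#n_pre="):
                if n_pre is None:
                    n_pre = int(line.split("=", 1)[1])
                continue
            if line.startswith("time_s"):
                continue
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}, line {lineno}: expected 3 columns")
            try:
                times.append(float(fields[0]))
                bleach.append(float(fields[1]))
                ref.append(float(fields[2]))
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from None
    if n_pre is None:
        raise ValueError(f"{path}: n_pre not given and no '#n_pre=' header found")
    return FrapTrace(np.array(times), np.array(bleach), np.array(ref), n_pre=n_pre)


def write_rdf_tsv(path: str | Path, profile: RadialProfile) -> None:
    with open(path, "w") as fh:
        fh.write("r\tg\n")
        for r, g in zip(profile.r_grid, profile.g_values):
            fh.write(f"{r:.9g}\t{g:.9g}\n")


def write_kl_tsv(path: str | Path, profile: KLProfile) -> None:
    with open(path, "w") as fh:
        fh.write("r\tK\tL\tH\n")
        for r, k, l, h in zip(
            profile.r_grid, profile.k_values, profile.l_values, profile.h_values
        ):
            fh.write(f"{r:.9g}\t{k:.9g}\t{l:.9g}\t{h:.9g}\n")


def write_boundaries_bed(path: str | Path, bs: BoundarySet) -> None:
    write_bed(
        path,
        [
            (bs.chrom, b.start, b.end, f"boundary_{b.bin_index}", round(b.strength, 6))
            for b in bs.boundaries
        ],
    )


def write_insulation_bedgraph(path: str | Path, track: InsulationTrack) -> None:
    write_bedgraph(path, track.chrom, track.bin_size, track.scores)


def write_e1_bedgraph(path: str | Path, track: CompartmentTrack) -> None:
    write_bedgraph(path, track.chrom, track.bin_size, track.e1)
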