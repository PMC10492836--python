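"""Config-driven multi-stage runs with a reproducibility manifest.

A run config is a mapping (usually loaded from YAML)::

    seed: 1
    outdir: runs/demo
    stages:
      - stage: simulate-hic
        n_bins: 500
        tad_boundaries: [100, 200, 300, 400]
        tad_enrichment: 3.0
      - stage: insulation
        window: 500000
      - stage: boundaries
        min_strength: 0.1

Stages communicate through files in ``outdir``; the manifest records the
parameters, the seed, the package version and a sha256 checksum of every
output, so identical config + seed yields identical checksums.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__, condensation, frap, hic, io, simulate

__all__ = ["run_pipeline"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _pick(params: dict, cls) -> dict:
    fields = cls.__dataclass_fields__
    return {k: v for k, v in params.items() if k in fields}


def run_pipeline(config: dict[str, Any]) -> dict[str, Any]:
    """Execute the configured stages; return (and write) the run manifest."""
    if "stages" not in config or not config["stages"]:
        raise ValueError("config: at least one stage required")
    seed = int(config.get("seed", 0))
    outdir = Path(config.get("outdir", "run"))
    outdir.mkdir(parents=True, exist_ok=True)

    state: dict[str, Any] = {}
    outputs: list[dict[str, str]] = []
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "stages": [],
        "success": False,
    }

    def emit(name: str, writer, obj) -> Path:
        path = outdir / name
        writer(path, obj)
        outputs.append({"path": str(path), "sha256": _sha256(path)})
        return path

    for spec in config["stages"]:
        params = dict(spec)
        stage = params.pop("stage")
        record: dict[str, Any] = {"stage": stage, "params": params}
        if stage == "simulate-points":
            kind = params.pop("kind", "csr")
            params.setdefault("seed", seed)
            if kind == "csr":
                pattern = simulate.simulate_csr(simulate.CsrSpec(**_pick(params, simulate.CsrSpec)))
            elif kind == "thomas":
                pattern = simulate.simulate_thomas(
                    simulate.ThomasSpec(**_pick(params, simulate.ThomasSpec))
                )
            else:
                raise ValueError(f"simulate-points: unknown kind {kind!r}")
            state["pattern"] = pattern
            emit("points.tsv", io.write_point_tsv, pattern)
        elif stage == "simulate-hic":
            params.setdefault("seed", seed)
            if "tad_boundaries" in params:
                params["tad_boundaries"] = tuple(params["tad_boundaries"])
            if params.get("compartment_labels") is not None:
                params["compartment_labels"] = np.asarray(params["compartment_labels"])
            matrix = simulate.simulate_hic(
                simulate.HicSimSpec(**_pick(params, simulate.HicSimSpec))
            )
            state["matrix"] = matrix
            emit("matrix.tsv", io.write_matrix_tsv, matrix)
        elif stage == "simulate-frap":
            params.setdefault("seed", seed)
            trace = simulate.simulate_frap(
                simulate.FrapSimSpec(**_pick(params, simulate.FrapSimSpec))
            )
            state["trace"] = trace
            emit("frap.tsv", io.write_frap_tsv, trace)
        elif stage == "load-matrix":
            state["matrix"] = io.read_matrix_tsv(params["path"])
        elif stage == "load-points":
            state["pattern"] = io.read_point_tsv(params["path"])
        elif stage == "rdf":
            profile = condensation.compute_rdf(
                state["pattern"],
                ring_width=params.get("ring_width", condensation.DEFAULT_RING_WIDTH),
                r_max=params.get("r_max", 2.0),
            )
            record["params"]["ring_width"] = profile.ring_width
            emit("rdf.tsv", io.write_rdf_tsv, profile)
        elif stage == "lfunction":
            ring = params.get("ring_width", condensation.DEFAULT_RING_WIDTH)
            r_max = params.get("r_max", 2.0)
            r_grid = np.arange(1, int(np.ceil(r_max / ring)) + 1) * ring
            profile = condensation.compute_k_l(state["pattern"], r_grid)
            emit("lfunction.tsv", io.write_kl_tsv, profile)
        elif stage == "balance":
            state["matrix"] = hic.balance_matrix(state["matrix"])
        elif stage == "insulation":
            m = state["matrix"]
            if params.get("balance", False) and not m.balanced:
                m = state["matrix"] = hic.balance_matrix(m)
            track = hic.insulation(m, window=params.get("window", hic.DEFAULT_INSULATION_WINDOW))
            state["insulation"] = track
            emit("insulation.bedgraph", io.write_insulation_bedgraph, track)
        elif stage == "boundaries":
            bset = hic.call_boundaries(
                state["insulation"],
                strength_threshold=params.get("min_strength", hic.DEFAULT_STRENGTH_THRESHOLD),
            )
            state["boundaries"] = bset
            emit("boundaries.bed", io.write_boundaries_bed, bset)
        elif stage == "compartments":
            m = state["matrix"]
            if not m.balanced:
                m = state["matrix"] = hic.balance_matrix(m)
            orient = m.compartment_labels
            track = hic.compartments(m, orientation_track=orient)
            state["compartments"] = track
            emit("e1.bedgraph", io.write_e1_bedgraph, track)
        elif stage == "ps-curve":
            m = state["matrix"]
            curve = hic.ps_curve([m], bins_per_decade=params.get("bins_per_decade", 8))
            def _write_ps(path, c):
                with open(path, "w") as fh:
                    fh.write("s_bp\tprob\n")
                    for s, p in zip(c.s_bins, c.probs):
                        fh.write(f"{s:.9g}\t{p:.9g}\n")
            emit("ps_curve.tsv", _write_ps, curve)
        elif stage == "frap-normalize":
            norm = frap.normalize_frap(state["trace"])
            def _write_norm(path, tr):
                with open(path, "w") as fh:
                    fh.write("time_s\tnormalized\n")
                    for t, v in zip(tr.times, tr.values):
                        fh.write(f"{t:.9g}\t{v:.9g}\n")
            emit("frap_normalized.tsv", _write_norm, norm)
            if params.get("fit"):
                mobile, half = frap.fit_recovery(norm)
                record["fit"] = {"mobile_fraction": mobile, "half_time": half}
        else:
            raise ValueError(f"unknown stage {stage!r}")
        manifest["stages"].append(record)

    manifest["outputs"] = outputs
    manifest["success"] = True
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
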