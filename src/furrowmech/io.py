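"""Config files, TIFF snapshots and tidy CSV outputs."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .embryo import GeometryConfig
from .sweep import FurrowTrace, RunConfig, SweepResult


def load_run_config(path) -> RunConfig:
    """Build a RunConfig from a YAML document.

    Recognised top-level keys: ``geometry`` (GeometryConfig fields),
    ``schedule`` (preset / myosin / params mapping) and any RunConfig
    field (n_mcs, snapshot_every, lam_V, lam_S, T, spring_scale,
    final_fraction, depth_metric).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return run_config_from_dict(doc)


def run_config_from_dict(doc: dict) -> RunConfig:
    doc = dict(doc)
    geom_kw = doc.pop("geometry", {}) or {}
    if "fractions" in geom_kw:
        geom_kw["fractions"] = tuple(geom_kw["fractions"])
    geometry = GeometryConfig(**geom_kw)
    schedule = doc.pop("schedule", {}) or {}
    fields = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(doc) - fields
    if unknown:
        raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
    return RunConfig(geometry=geometry, schedule=schedule, **doc)


def save_trace(trace: FurrowTrace, path) -> None:
    """Write a furrow trace as CSV (mcs, depth, energy, acceptance)."""
    frame = trace.frame.copy()
    frame["seed"] = str(trace.seed)
    frame["schedule"] = trace.schedule_id
    frame.to_csv(path, index=False)


def save_sweep(result: SweepResult, runs_path, summary_path=None) -> None:
    """Write sweep results: the long per-replicate table and, when a
    second path is given, the per-grid-point summary."""
    result.runs.to_csv(runs_path, index=False)
    if summary_path is not None:
        result.summary.to_csv(summary_path, index=False)


def write_label_snapshot(path, states) -> None:
    """Write one or more label lattices as a multi-page TIFF."""
    lattices = [np.asarray(s.lattice if hasattr(s, "lattice") else s)
                for s in (states if isinstance(states, (list, tuple)) else [states])]
    tifffile.imwrite(path, np.stack(lattices).astype(np.int32),
                     photometric="minisblack")


def write_shift_stack(path, stack) -> None:
    """Write a shift-map stack (GHz) as a float32 multi-page TIFF."""
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32),
                     photometric="minisblack")


def read_shift_stack(path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def write_mask_stack(path, stack) -> None:
    tifffile.imwrite(path, np.asarray(stack).astype(np.uint8),
                     photometric="minisblack")


def read_mask_stack(path) -> np.ndarray:
    return tifffile.imread(path) > 0


def write_metadata(path, **fields) -> None:
    """JSON sidecar (timestamps, reference-event index, pixel size...)."""
    def _clean(v):
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        return v
    Path(path).write_text(json.dumps({k: _clean(v) for k, v in fields.items()},
                                     indent=2))


def read_metadata(path) -> dict:
    return json.loads(Path(path).read_text())
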