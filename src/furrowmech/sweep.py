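"""Furrow-depth readout, single-run driver, and stiffness parameter sweeps.

Furrow depth is the inward displacement of the apical-most site of the
central mesodermal cell relative to the initial mesoderm apical
surface, in units of the initial apical-basal cell height h0, clamped
at 0. Sweeps run replicate simulations per grid point and aggregate
the final depth (mean of the last fraction of snapshots) as mean and
standard error.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from . import embryo, schedules
from .engine import LinkSet, SimState, VanishedCompartmentError, run_mcs
from .embryo import (COMPARTMENT_ORDER, GeometryConfig, build_initial_state,
                     build_links, grow_core2)


@dataclass
class RunConfig:
    """Configuration for one simulation run.

    `schedule` follows the mapping accepted by
    :func:`furrowmech.schedules.make_schedules`. `spring_scale`
    converts schedule stiffness units to lattice energy units.
    """

    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    schedule: dict = field(default_factory=dict)
    lam_V: float = 2.0
    lam_S: float = 0.05
    T: float = 6.0
    n_mcs: int = 2500
    snapshot_every: int = 25
    spring_scale: float = 1.0
    final_fraction: float = 0.05  # trailing window averaged into "final" depth
    depth_metric: str = "central_group"  # or "central_cell"

    def with_schedule_params(self, **params) -> "RunConfig":
        sched = dict(self.schedule)
        sched["params"] = {**sched.get("params", {}), **params}
        return replace(self, schedule=sched)


def reduced_config(**overrides) -> RunConfig:
    """A desk-scale configuration: smaller cells, same physics.

    Same 47-cell layout, schedules and energy parameters as the
    full-scale default, with w0=8, h0=32 (and the core2 growth rate
    scaled to the smaller compartment volume) so a single 2500-MCS run
    completes in a few seconds.
    """
    geom = GeometryConfig(w0=8, h0=32, growth_rate=0.024, growth_duration=500,
                          growth_factor=1.15)
    kw = dict(geometry=geom)
    kw.update(overrides)
    return RunConfig(**kw)


@dataclass
class FurrowTrace:
    """Depth/energy time series of one replicate."""

    frame: pd.DataFrame          # columns: mcs, depth, energy, acceptance
    seed: int | tuple
    schedule_id: str

    def final_depth(self, fraction: float = 0.05) -> float:
        n = max(1, int(np.ceil(fraction * len(self.frame))))
        return float(self.frame["depth"].iloc[-n:].mean())


@dataclass
class SweepResult:
    """Grid-aggregated furrow depths."""

    runs: pd.DataFrame           # long: axis columns + seed + final_depth
    summary: pd.DataFrame        # axis columns + mean_depth, se_depth, n
    axes: dict


_CONN8 = np.ones((3, 3), dtype=bool)


def _cell_apex(state: SimState, cell, inward: np.ndarray) -> float:
    """Apical-most inward coordinate of a cell's main connected body.

    The apex is the minimum of the inward coordinate over the cell's
    sites, restricted to the largest 8-connected component of the
    whole-cell mask so that stray detached fragments cannot dominate.
    """
    mask = np.isin(state.lattice, [cell.labels[c] for c in COMPARTMENT_ORDER])
    if not mask.any():
        raise VanishedCompartmentError(f"cell {cell.cell_id} has vanished")
    comp, n = ndimage.label(mask, structure=_CONN8)
    if n > 1:
        sizes = np.bincount(comp.ravel())[1:]
        mask = comp == (int(np.argmax(sizes)) + 1)
    return float(inward[mask].min())


def mesoderm_apical_surface(state: SimState, cells, inward: np.ndarray) -> float:
    """Apical-most inward coordinate over all mesodermal cells."""
    vals = []
    for cell in cells:
        if cell.is_mesodermal:
            sites = state.lattice == cell.labels["apical"]
            if sites.any():
                vals.append(float(inward[sites].min()))
    if not vals:
        raise VanishedCompartmentError("no mesodermal apical sites")
    return min(vals)


def furrow_depth(state: SimState, initial_state: SimState, cells, h0: float,
                 inward: np.ndarray | None = None) -> float:
    """Normalised inward displacement of the central cell's apex.

    depth = max(0, apex(t) - apex(0)) / h0, where apex is the
    apical-most inward coordinate of the central mesodermal cell and
    apex(0) its position at the initial mesoderm apical surface.
    `inward` is the per-site inward coordinate map
    (``GeometryConfig.inward_map``); when omitted, lattice rows are
    used (flat layout).
    """
    if inward is None:
        H, W = state.shape
        inward = np.broadcast_to(np.arange(H, dtype=float)[:, None], (H, W))
    central = next(c for c in cells if c.position == 0)
    apex = _cell_apex(state, central, inward)
    ref = _cell_apex(initial_state, central, inward)
    return max(0.0, apex - ref) / float(h0)


def furrow_depth_group(state: SimState, initial_state: SimState, cells,
                       h0: float, inward: np.ndarray | None = None) -> float:
    """Median apex displacement of the nine central mesodermal cells.

    Same displacement as :func:`furrow_depth` but aggregated over the
    whole central group, so a single cell squeezed out of the
    epithelium does not read as a furrow: the fold only scores when
    the central group invaginates collectively.
    """
    if inward is None:
        H, W = state.shape
        inward = np.broadcast_to(np.arange(H, dtype=float)[:, None], (H, W))
    disp = [max(0.0, _cell_apex(state, c, inward)
                - _cell_apex(initial_state, c, inward))
            for c in cells if c.population == embryo.MESODERM_CENTRAL]
    if not disp:
        raise VanishedCompartmentError("no central mesodermal cells")
    return float(np.median(disp)) / float(h0)


def run_simulation(config: RunConfig, seed) -> FurrowTrace:
    """Run one replicate and record the furrow-depth trace.

    Deterministic given (config, seed). Each MCS the core2 growth rule
    advances and the link set is rebuilt from the schedules before the
    Metropolis sweep.
    """
    rng = np.random.default_rng(seed)
    profile, sched = schedules.make_schedules(config.schedule)
    params = embryo.default_energy_params(lam_V=config.lam_V,
                                          lam_S=config.lam_S, T=config.T)
    state, cells = build_initial_state(config.geometry)
    initial = state.copy()
    h0 = config.geometry.h0
    inward = config.geometry.inward_map()
    if config.depth_metric == "central_group":
        metric = furrow_depth_group
    elif config.depth_metric == "central_cell":
        metric = furrow_depth
    else:
        raise ValueError(f"unknown depth metric {config.depth_metric!r}")

    rows = [(0, 0.0, _energy_snapshot(state, params, cells, sched, profile,
                                      0.0, config.spring_scale), 0.0)]
    n_active = len(state.active_sites())
    for t in range(config.n_mcs):
        grow_core2(state, cells, config.geometry, t)
        links = build_links(state, cells, sched, profile, float(t),
                            spring_scale=config.spring_scale)
        accepted = run_mcs(state, params, links, rng)
        if (t + 1) % config.snapshot_every == 0 or t + 1 == config.n_mcs:
            from .engine import total_energy
            depth = metric(state, initial, cells, h0, inward)
            rows.append((t + 1, depth, total_energy(state, params, links),
                         accepted / n_active))
    frame = pd.DataFrame(rows, columns=["mcs", "depth", "energy", "acceptance"])
    frame = frame.drop_duplicates(subset="mcs", keep="last").reset_index(drop=True)
    sched_id = config.schedule.get("preset") or "custom"
    return FurrowTrace(frame=frame, seed=seed, schedule_id=sched_id)


def _energy_snapshot(state, params, cells, sched, profile, t, spring_scale):
    from .engine import total_energy
    links = build_links(state, cells, sched, profile, t, spring_scale=spring_scale)
    return total_energy(state, params, links)


def run_grid(base_config: RunConfig, axes: dict, replicates: int = 5,
             base_seed: int = 0, progress=None) -> SweepResult:
    """Sweep schedule parameters over a grid with replicate runs.

    `axes` maps schedule parameter names (keys of the schedule preset's
    params) to value lists. Each grid point runs `replicates`
    simulations with independent seeds derived from `base_seed`;
    aggregation reports the mean and standard error (SD/sqrt(n)) of the
    final furrow depth.
    """
    names = list(axes)
    records = []
    for point_idx, values in enumerate(itertools.product(*(axes[n] for n in names))):
        cfg = base_config.with_schedule_params(**dict(zip(names, values)))
        for rep in range(replicates):
            seed = np.random.SeedSequence([base_seed, point_idx, rep])
            trace = run_simulation(cfg, seed)
            rec = dict(zip(names, values))
            rec["replicate"] = rep
            rec["final_depth"] = trace.final_depth(cfg.final_fraction)
            records.append(rec)
            if progress is not None:
                progress(rec)
    runs = pd.DataFrame(records)
    grouped = runs.groupby(names)["final_depth"]
    summary = grouped.agg(mean_depth="mean",
                          se_depth=lambda x: x.std(ddof=1) / np.sqrt(len(x)),
                          n="count").reset_index()
    return SweepResult(runs=runs, summary=summary, axes=axes)


def relative_change(dynamic_mean: float, control_mean: float) -> float:
    """Percent change of a dynamic-schedule mean depth over its control."""
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    return 100.0 * (dynamic_mean - control_mean) / control_mean
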