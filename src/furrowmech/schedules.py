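"""Time- and position-dependent contractility and stiffness schedules.

The apical-constriction (myosin) stiffness follows a separable profile
A * m(position) * r(t): a spatial weight peaked at the ventral midline
and decreasing outward across the mesoderm, and a smooth temporal ramp
standing in for the measured myosin accumulation curve. Longitudinal
stiffness (lambda_sa sub-apical, lambda_sb sub-basal) is scheduled per
cell population, either constant, grouped, or linearly ramped in time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .embryo import MESODERM_CENTRAL, MESODERM_PERIPHERAL, NEUROECTODERM

GROUPS = (MESODERM_CENTRAL, MESODERM_PERIPHERAL, NEUROECTODERM)
MESODERM_HALF_WIDTH = 9  # |position| <= 9 is mesodermal


def _smoothstep(x: float) -> float:
    x = min(1.0, max(0.0, x))
    return x * x * (3.0 - 2.0 * x)


@dataclass
class MyosinProfile:
    """Separable contractility profile A * m(position) * r(t).

    m is a Gaussian in the signed cell position (sigma in cells), so it
    is symmetric about the midline and non-increasing outward; r is a
    smoothstep ramp from 0 at `t_on` to 1 at `t_on + ramp`. Outside the
    mesoderm the profile is identically zero.

    `contraction` sets how much of the initial apical-apical gap the
    constriction links remove at full activation: their rest length is
    gap0 * (1 - contraction * m(position) * r(t)), so the apical chain
    shortens coherently instead of collapsing to a point.
    """

    amplitude: float = 300.0
    sigma_cells: float = 4.0
    t_on: float = 0.0
    ramp: float = 300.0
    contraction: float = 0.7

    def rest_fraction(self, position: float, t: float) -> float:
        """Fraction of the initial apical gap kept at (position, t)."""
        return 1.0 - self.contraction * self.spatial(position) * self.temporal(t)

    def spatial(self, position: float) -> float:
        if abs(position) > MESODERM_HALF_WIDTH:
            return 0.0
        if not np.isfinite(self.sigma_cells):
            return 1.0
        return float(np.exp(-0.5 * (position / self.sigma_cells) ** 2))

    def temporal(self, t: float) -> float:
        if self.ramp <= 0:
            return 1.0 if t >= self.t_on else 0.0
        return _smoothstep((t - self.t_on) / self.ramp)

    def __call__(self, position: float, t: float) -> float:
        return self.amplitude * self.spatial(position) * self.temporal(t)


def myosin_lambda(profile: MyosinProfile, position: float, t: float) -> float:
    """Apical-constriction stiffness at a mesoderm position and time."""
    return profile(position, t)


@dataclass
class GroupStiffness:
    """Per-group (start, final) sub-apical / sub-basal stiffness values."""

    sa_start: float
    sa_final: float
    sb_start: float
    sb_final: float


@dataclass
class StiffnessSchedule:
    """lambda_sa / lambda_sb per cell population, optionally ramped.

    mode 'uniform' and 'grouped' hold the start values at all times;
    'dynamic' interpolates linearly from start to final over
    [ramp_start, ramp_start + ramp_window] and is constant after.
    """

    mode: str = "grouped"
    groups: dict = field(default_factory=dict)   # population -> GroupStiffness
    ramp_start: float = 0.0
    ramp_window: float = 300.0

    def __post_init__(self) -> None:
        if self.mode not in ("uniform", "grouped", "dynamic"):
            raise ValueError(f"unknown schedule mode {self.mode!r}")
        for g, v in self.groups.items():
            if min(v.sa_start, v.sa_final, v.sb_start, v.sb_final) < 0:
                raise ValueError(f"negative stiffness for group {g}")

    def __call__(self, group: str, t: float):
        return stiffness_lambda(self, group, t)


def stiffness_lambda(schedule: StiffnessSchedule, group: str, t: float):
    """(lambda_sa, lambda_sb) for a cell population at time t."""
    if group not in schedule.groups:
        raise KeyError(f"unknown group {group!r}")
    g = schedule.groups[group]
    if schedule.mode in ("uniform", "grouped"):
        return g.sa_start, g.sb_start
    frac = 1.0 if schedule.ramp_window <= 0 else min(
        1.0, max(0.0, (t - schedule.ramp_start) / schedule.ramp_window))
    sa = g.sa_start + frac * (g.sa_final - g.sa_start)
    sb = g.sb_start + frac * (g.sb_final - g.sb_start)
    return sa, sb


def uniform_schedule(sa: float, sb: float) -> StiffnessSchedule:
    groups = {g: GroupStiffness(sa, sa, sb, sb) for g in GROUPS}
    return StiffnessSchedule(mode="uniform", groups=groups)


def grouped_schedule(sa_by_group: dict, sb_by_group: dict) -> StiffnessSchedule:
    groups = {g: GroupStiffness(sa_by_group[g], sa_by_group[g],
                                sb_by_group[g], sb_by_group[g]) for g in GROUPS}
    return StiffnessSchedule(mode="grouped", groups=groups)


def dynamic_schedule(start: float, final_central: float, final_peripheral: float,
                     sb: float, ramp_window: float, ramp_start: float = 0.0,
                     neuro_sa: float | None = None) -> StiffnessSchedule:
    """Time-ramped mesodermal sub-apical stiffness, constant sub-basal.

    Central cells ramp start -> final_central, peripheral cells
    start -> final_peripheral; the neuroectoderm holds `neuro_sa`
    (defaults to the start value).
    """
    neuro = start if neuro_sa is None else neuro_sa
    groups = {
        MESODERM_CENTRAL: GroupStiffness(start, final_central, sb, sb),
        MESODERM_PERIPHERAL: GroupStiffness(start, final_peripheral, sb, sb),
        NEUROECTODERM: GroupStiffness(neuro, neuro, sb, sb),
    }
    return StiffnessSchedule(mode="dynamic", groups=groups,
                             ramp_start=ramp_start, ramp_window=ramp_window)


# ----------------------------------------------------------------------
# presets for the stiffness-sweep experiment families


def make_schedules(config: dict):
    """Build (MyosinProfile, StiffnessSchedule) from a config mapping.

    Recognised presets (config['preset']):

    - 'fig5d'         uniform mesodermal (sa, sb) from config
    - 'fig5e'         grouped central/peripheral sa, shared sb
    - 'fig5f'         dynamic ramp: central up, peripheral down
    - 'fig5f_control' constant sa = 30 for all groups

    Myosin parameters may be overridden under config['myosin'].
    """
    cfg = dict(config or {})
    myo_kw = dict(cfg.get("myosin", {}))
    profile = MyosinProfile(**myo_kw)
    preset = cfg.get("preset")
    p = dict(cfg.get("params", {}))
    if preset == "fig5d":
        sched = uniform_schedule(sa=p.get("sa", 30.0), sb=p.get("sb", 30.0))
    elif preset == "fig5e":
        sb = p.get("sb", 30.0)
        sched = grouped_schedule(
            sa_by_group={MESODERM_CENTRAL: p.get("sa_central", 30.0),
                         MESODERM_PERIPHERAL: p.get("sa_peripheral", 30.0),
                         NEUROECTODERM: p.get("sa_neuro", 30.0)},
            sb_by_group={g: sb for g in GROUPS})
    elif preset == "fig5f":
        sched = dynamic_schedule(
            start=p.get("start", 30.0),
            final_central=p.get("final_central", 170.0),
            final_peripheral=p.get("final_peripheral", 18.0),
            sb=p.get("sb", 30.0),
            ramp_window=p.get("ramp_window", 300.0),
            ramp_start=p.get("ramp_start", 0.0))
    elif preset == "fig5f_control":
        sched = uniform_schedule(sa=p.get("start", 30.0), sb=p.get("sb", 30.0))
    elif preset is None:
        sched = uniform_schedule(sa=p.get("sa", 30.0), sb=p.get("sb", 30.0))
    else:
        raise ValueError(f"unknown schedule preset {preset!r}")
    return profile, sched
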