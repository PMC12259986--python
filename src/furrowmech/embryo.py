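"""Initial half-embryo geometry: cell row, compartments, links, growth.

The model is a 2D cross-section of the ventral half of the blastoderm:
47 columnar cells side by side (19 mesodermal flanked by 2 x 14
neuroectodermal), each split into four stacked compartments (apical,
core1, core2, basal), apical side against a frozen vitelline layer,
yolk filling the interior. The default layout is a semicircular arc —
cells are radial wedges, apical surfaces facing outward against a
curved vitelline shell, yolk inside — which is what lets the
contractile apical chain generate an inward (purse-string) pressure; a
flat-row layout is available behind ``GeometryConfig.arc``. The
lateral-most ends of the band are frozen spacers standing in for the
rest of the embryo.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import (APICAL, BASAL, CORE1, CORE2, LINK_APICAL_CONSTRICTION,
                     LINK_SUB_APICAL, LINK_SUB_BASAL, MEDIUM, N_KINDS,
                     VITELLINE, YOLK, EnergyParams, LinkSet, SimState,
                     VanishedCompartmentError)

MESODERM_CENTRAL = "mesoderm_central"
MESODERM_PERIPHERAL = "mesoderm_peripheral"
NEUROECTODERM = "neuroectoderm"

N_MESODERM = 19         # 9 central + 5 peripheral per side
N_NEUROECTODERM = 28    # 14 per side
N_CELLS = N_MESODERM + N_NEUROECTODERM

COMPARTMENT_ORDER = ("apical", "core1", "core2", "basal")
_COMP_KIND = {"apical": APICAL, "core1": CORE1, "core2": CORE2, "basal": BASAL}


@dataclass
class CellRecord:
    """One biological cell: population, signed position, compartment labels."""

    cell_id: int
    position: int                 # 0 at the ventral midline, +/- outward
    population: str
    labels: dict                  # compartment name -> lattice label
    d0_sub_apical: float = 0.0    # spring rest lengths frozen at build time
    d0_sub_basal: float = 0.0
    d0_apical_gap: float = 0.0    # gap to the right neighbour's apical centroid
    v0_core2: float = 0.0         # initial core2 target volume (growth cap base)
    s0_core2: float = 0.0         # initial core2 target surface

    @property
    def is_mesodermal(self) -> bool:
        return self.population in (MESODERM_CENTRAL, MESODERM_PERIPHERAL)


@dataclass
class GeometryConfig:
    """Lattice geometry and core2 growth rule.

    Lengths are in lattice sites; `fractions` split the initial cell
    height h0 over (apical, core1, core2, basal) and must sum to 1.
    With ``arc`` (the default) the 47 cells form a semicircular band of
    radial wedges whose apical arc width is w0; otherwise a flat row.
    `growth_rate` is the per-MCS increment of the mesodermal core2
    target volume, applied while t < `growth_duration` and capped at
    `growth_factor` times the initial core2 volume.
    """

    w0: int = 10
    h0: int = 40
    fractions: tuple = (0.15, 0.35, 0.35, 0.15)
    arc: bool = True
    yolk_depth: int = 100         # flat layout only
    medium_rows: int = 2          # flat layout only
    cap_rows: int = 2             # arc layout: frozen band closing the top
    margin: int = 2               # arc layout: medium beyond the vitelline
    vit_thickness: int = 2
    spacer_width: int = 3
    growth_rate: float = 0.042
    growth_duration: int = 500
    growth_factor: float = 1.15
    yolk_w_V: float = 0.0         # yolk as a passive fluid reservoir

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("compartment height fractions must sum to 1")
        if self.w0 < 4 or self.h0 < 4:
            raise ValueError("cells need w0, h0 >= 4 sites")

    @property
    def compartment_heights(self) -> tuple:
        """Integer per-compartment radial heights summing exactly to h0."""
        raw = [f * self.h0 for f in self.fractions]
        hs = [int(np.floor(x)) for x in raw]
        # largest-remainder rounding
        rem = sorted(range(4), key=lambda i: raw[i] - hs[i], reverse=True)
        for i in rem[: self.h0 - sum(hs)]:
            hs[i] += 1
        if min(hs) < 1:
            raise ValueError("h0 too small for the requested fractions")
        return tuple(hs)

    @property
    def outer_radius(self) -> float:
        """Apical-surface radius of the arc layout."""
        return (N_CELLS * self.w0 + 2 * self.spacer_width) / np.pi

    @property
    def lattice_shape(self) -> tuple:
        if self.arc:
            r = int(np.ceil(self.outer_radius)) + self.vit_thickness + self.margin
            return self.cap_rows + r + 1, 2 * r + 1
        height = self.medium_rows + self.vit_thickness + self.h0 + self.yolk_depth
        width = 2 * self.spacer_width + N_CELLS * self.w0
        return height, width

    def inward_map(self) -> np.ndarray:
        """Per-site inward coordinate, increasing away from the vitelline.

        Offset is arbitrary; furrow depth only uses differences.
        """
        H, W = self.lattice_shape
        if not self.arc:
            return np.broadcast_to(np.arange(H, dtype=float)[:, None], (H, W)).copy()
        rr, cc = np.indices((H, W), dtype=float)
        rho = np.hypot(rr - self.cap_rows, cc - W // 2)
        return self.outer_radius - rho


def default_contact_matrix() -> np.ndarray:
    """Inter-cell contact energies J(kind, kind) for the half-embryo model.

    Cell-cell interfaces are moderately cheap (cohesive epithelium) and
    much cheaper than cell-yolk, so yolk does not wet its way between
    cells; apical-apical contact between different cells is slightly
    dearer than other cell-cell contact, which keeps the contractile
    apical compartments from piling on top of one another; cell-medium
    is very expensive (cells never touch medium across the vitelline);
    apical surfaces adhere weakly to the vitelline while a bare
    (yolk-exposed) vitelline is very costly, so flanking cells spread
    to cover shell vacated by the invaginating mesoderm.
    """
    J = np.zeros((N_KINDS, N_KINDS))
    cells = (APICAL, CORE1, CORE2, BASAL)
    for a in cells:
        for b in cells:
            J[a, b] = 10.0
        J[a, MEDIUM] = J[MEDIUM, a] = 40.0
        J[a, YOLK] = J[YOLK, a] = 16.0
        J[a, VITELLINE] = J[VITELLINE, a] = 14.0
    J[APICAL, APICAL] = 12.0
    J[APICAL, VITELLINE] = J[VITELLINE, APICAL] = 4.0
    J[BASAL, YOLK] = J[YOLK, BASAL] = 8.0
    J[YOLK, MEDIUM] = J[MEDIUM, YOLK] = 40.0
    J[YOLK, VITELLINE] = J[VITELLINE, YOLK] = 30.0
    J[MEDIUM, VITELLINE] = J[VITELLINE, MEDIUM] = 1.0
    return J


def default_intra_contact_matrix() -> np.ndarray:
    """Contact energies between compartments of the same cell (cohesion)."""
    J = default_contact_matrix().copy()
    cells = (APICAL, CORE1, CORE2, BASAL)
    for a in cells:
        for b in cells:
            J[a, b] = 6.0
    return J


def default_energy_params(**overrides) -> EnergyParams:
    kw = dict(J=default_contact_matrix(), J_intra=default_intra_contact_matrix(),
              lam_V=2.0, lam_S=0.05, T=6.0)
    kw.update(overrides)
    return EnergyParams(**kw)


# label layout: 0 medium, 1 vitelline (incl. arc cap), 2 yolk,
# 3/4 lateral spacers, then 4 per cell in build order
LABEL_VITELLINE = 1
LABEL_YOLK = 2
LABEL_SPACER_L = 3
LABEL_SPACER_R = 4
FIRST_CELL_LABEL = 5


def positions() -> list:
    """Signed position indices for the 47 cells, midline outward."""
    return list(range(-(N_CELLS // 2), N_CELLS // 2 + 1))


def population_of(position: int) -> str:
    a = abs(position)
    if a <= 4:
        return MESODERM_CENTRAL
    if a <= 9:
        return MESODERM_PERIPHERAL
    if a <= 23:
        return NEUROECTODERM
    raise ValueError(f"position index {position} outside the 47-cell row")


def assign_groups(cells) -> dict:
    """Map population name -> list of CellRecord, validating counts."""
    if len(cells) != N_CELLS:
        raise ValueError(f"expected {N_CELLS} cells, got {len(cells)}")
    groups = {MESODERM_CENTRAL: [], MESODERM_PERIPHERAL: [], NEUROECTODERM: []}
    for cell in cells:
        groups[population_of(cell.position)].append(cell)
    sizes = {k: len(v) for k, v in groups.items()}
    if sizes != {MESODERM_CENTRAL: 9, MESODERM_PERIPHERAL: 10, NEUROECTODERM: 28}:
        raise ValueError(f"unexpected group sizes {sizes}")
    return groups


def _paint_flat(geom: GeometryConfig, lattice: np.ndarray) -> None:
    H, W = lattice.shape
    hs = geom.compartment_heights
    vit0 = geom.medium_rows
    apical_row = vit0 + geom.vit_thickness
    basal_end = apical_row + geom.h0
    lattice[vit0:apical_row, :] = LABEL_VITELLINE
    lattice[basal_end:, :] = LABEL_YOLK
    lattice[apical_row:basal_end, : geom.spacer_width] = LABEL_SPACER_L
    lattice[apical_row:basal_end, W - geom.spacer_width:] = LABEL_SPACER_R
    for i in range(N_CELLS):
        c0 = geom.spacer_width + i * geom.w0
        row = apical_row
        for comp_idx, h in enumerate(hs):
            lab = FIRST_CELL_LABEL + 4 * i + comp_idx
            lattice[row:row + h, c0:c0 + geom.w0] = lab
            row += h


def _paint_arc(geom: GeometryConfig, lattice: np.ndarray) -> None:
    H, W = lattice.shape
    hs = geom.compartment_heights
    R = geom.outer_radius
    rr, cc = np.indices((H, W), dtype=float)
    dy = rr - geom.cap_rows
    dx = cc - W // 2
    rho = np.hypot(dx, dy)
    phi = np.arctan2(np.maximum(dy, 0.0), dx)   # 0 at right end, pi at left
    s = phi * R                                  # arc-length coordinate

    lattice[: geom.cap_rows, :] = LABEL_VITELLINE
    lower = rr >= geom.cap_rows
    lattice[lower & (rho >= R) & (rho < R + geom.vit_thickness)] = LABEL_VITELLINE
    lattice[lower & (rho < R - geom.h0)] = LABEL_YOLK

    band = lower & (rho >= R - geom.h0) & (rho < R)
    lattice[band & (s < geom.spacer_width)] = LABEL_SPACER_R
    lattice[band & (s >= np.pi * R - geom.spacer_width)] = LABEL_SPACER_L
    cell_band = band & (s >= geom.spacer_width) & (s < np.pi * R - geom.spacer_width)
    k = np.clip(((s - geom.spacer_width) // geom.w0).astype(int), 0, N_CELLS - 1)
    # radial compartment bands, apical outermost
    edges = R - np.cumsum((0,) + hs)
    comp = np.zeros_like(lattice)
    for ci in range(4):
        sel = (rho < edges[ci]) & (rho >= (edges[ci + 1] if ci < 3 else -1.0))
        comp[sel] = ci
    comp[rho >= edges[0]] = 0
    comp[rho < edges[4]] = 3
    lattice[cell_band] = (FIRST_CELL_LABEL + 4 * k + comp)[cell_band]


def build_initial_state(geom: GeometryConfig | None = None):
    """Construct the initial SimState and cell registry.

    Returns (state, cells). All compartments start at their target
    volumes and surfaces; the vitelline shell (plus the arc layout's
    cap band) and the two lateral spacers are frozen.
    """
    geom = geom or GeometryConfig()
    H, W = geom.lattice_shape
    n_labels = FIRST_CELL_LABEL + 4 * N_CELLS

    lattice = np.zeros((H, W), dtype=np.int32)
    if geom.arc:
        _paint_arc(geom, lattice)
    else:
        _paint_flat(geom, lattice)

    kind = np.zeros(n_labels, dtype=np.int8)
    frozen = np.zeros(n_labels, dtype=bool)
    kind[LABEL_VITELLINE] = VITELLINE
    kind[LABEL_YOLK] = YOLK
    kind[LABEL_SPACER_L] = VITELLINE
    kind[LABEL_SPACER_R] = VITELLINE
    frozen[[LABEL_VITELLINE, LABEL_SPACER_L, LABEL_SPACER_R]] = True

    cells = []
    for i, pos in enumerate(positions()):
        labels = {}
        for comp_idx, comp in enumerate(COMPARTMENT_ORDER):
            lab = FIRST_CELL_LABEL + 4 * i + comp_idx
            kind[lab] = _COMP_KIND[comp]
            labels[comp] = lab
        cells.append(CellRecord(cell_id=i, position=pos,
                                population=population_of(pos), labels=labels))

    counts = np.bincount(lattice.ravel(), minlength=n_labels)
    if counts[FIRST_CELL_LABEL:].min() < 4:
        raise ValueError("lattice too small: a compartment has fewer than 4 sites")

    w_V = np.ones(n_labels)
    w_S = np.ones(n_labels)
    w_V[[0, LABEL_VITELLINE, LABEL_SPACER_L, LABEL_SPACER_R]] = 0.0
    w_S[[0, LABEL_VITELLINE, LABEL_SPACER_L, LABEL_SPACER_R]] = 0.0
    w_V[LABEL_YOLK] = geom.yolk_w_V
    w_S[LABEL_YOLK] = 0.0

    # compartments of one biological cell share a parent id (J_intra)
    parent = np.arange(n_labels, dtype=np.int64)
    for cell in range(N_CELLS):
        base = FIRST_CELL_LABEL + 4 * cell
        parent[base:base + 4] = n_labels + cell

    state = SimState.from_lattice(lattice, kind, frozen=frozen, w_V=w_V,
                                  w_S=w_S, parent=parent)

    # freeze spring rest lengths and growth baselines at the built geometry
    for cell in cells:
        cell.d0_sub_apical = _centroid_distance(state, cell.labels["apical"],
                                                cell.labels["core1"])
        cell.d0_sub_basal = _centroid_distance(state, cell.labels["core2"],
                                               cell.labels["basal"])
        cell.v0_core2 = float(state.target_V[cell.labels["core2"]])
        cell.s0_core2 = float(state.target_S[cell.labels["core2"]])
    ordered = sorted(cells, key=lambda c: c.position)
    for left, right in zip(ordered[:-1], ordered[1:]):
        left.d0_apical_gap = _centroid_distance(state, left.labels["apical"],
                                                right.labels["apical"])
    return state, cells


def _centroid_distance(state: SimState, a: int, b: int) -> float:
    va, vb = state.volume[a], state.volume[b]
    if va == 0 or vb == 0:
        raise VanishedCompartmentError("empty compartment in link construction")
    dr = state.sum_r[a] / va - state.sum_r[b] / vb
    dc = state.sum_c[a] / va - state.sum_c[b] / vb
    return float(np.hypot(dr, dc))


def build_links(state: SimState, cells, stiffness_schedule, myosin_profile,
                t: float, spring_scale: float = 1.0) -> LinkSet:
    """Assemble the link set for time t.

    (i) apical-constriction links between apical compartments of
    adjacent mesodermal cells, stiffness from the myosin profile at the
    midpoint position and rest length shrinking from the built gap
    according to the profile's contraction schedule; (ii) one
    sub-apical link apical<->core1 per cell; (iii) one sub-basal link
    core2<->basal per cell; rest lengths are the built-state centroid
    separations. `spring_scale` converts schedule stiffness units into
    lattice energy units.
    """
    recs = []
    ordered = sorted(cells, key=lambda cell: cell.position)
    for left, right in zip(ordered[:-1], ordered[1:]):
        if left.is_mesodermal and right.is_mesodermal:
            pos = 0.5 * (left.position + right.position)
            lam = myosin_profile(pos, t) * spring_scale
            d0 = left.d0_apical_gap
            if hasattr(myosin_profile, "rest_fraction"):
                d0 *= max(0.0, myosin_profile.rest_fraction(pos, t))
            recs.append((left.labels["apical"], right.labels["apical"],
                         lam, d0, LINK_APICAL_CONSTRICTION))
    for cell in ordered:
        lam_sa, lam_sb = stiffness_schedule(cell.population, t)
        recs.append((cell.labels["apical"], cell.labels["core1"],
                     lam_sa * spring_scale, cell.d0_sub_apical, LINK_SUB_APICAL))
        recs.append((cell.labels["core2"], cell.labels["basal"],
                     lam_sb * spring_scale, cell.d0_sub_basal, LINK_SUB_BASAL))
    links = LinkSet.from_records(recs)
    for lab in np.concatenate([links.a, links.b]):
        if state.volume[lab] == 0:
            raise VanishedCompartmentError(f"link endpoint {lab} has vanished")
    return links


def grow_core2(state: SimState, cells, geom: GeometryConfig, t: float) -> None:
    """Ramp the mesodermal core2 target volume to emulate cell heightening.

    Linear increase by `geom.growth_rate` per MCS while t < growth
    duration, capped at growth_factor x the built core2 volume. The
    surface target is scaled along with the volume target (roughly
    linear, as for a column elongating at fixed width) so growth does
    not fight the surface constraint.
    """
    if geom.growth_rate <= 0 or t >= geom.growth_duration:
        return
    for cell in cells:
        if cell.is_mesodermal:
            lab = cell.labels["core2"]
            cap = geom.growth_factor * cell.v0_core2
            v_new = min(cap, state.target_V[lab] + geom.growth_rate)
            ratio = v_new / cell.v0_core2
            state.target_V[lab] = v_new
            state.target_S[lab] = cell.s0_core2 * (1.0 + 0.8 * (ratio - 1.0))
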