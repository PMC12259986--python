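"""Lattice Cellular Potts core: effective energy and Metropolis dynamics.

Generalized "cells" here are *compartments*: each biological cell is a set
of compartment labels occupying lattice sites. The effective energy is

    H = sum_neighbour_pairs J(kind_i, kind_j) * [sigma_i != sigma_j]
      + sum_labels lam_V * w_V(label) * (V - V_t)^2
      + sum_labels lam_S * w_S(label) * (S - S_t)^2
      + sum_links  lam_link * (d - d0)^2

with V the label's site count, S its surface (number of heterologous
neighbour pairs counted from the label's own sites), and d the Euclidean
distance between the centroids of a link's two endpoint compartments.
Dynamics are Metropolis label-copy attempts between 8-neighbour sites;
one Monte Carlo step (MCS) is as many attempts as there are non-frozen
lattice sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

# compartment kinds
MEDIUM, APICAL, CORE1, CORE2, BASAL, VITELLINE, YOLK = range(7)
N_KINDS = 7
KIND_NAMES = ("medium", "apical", "core1", "core2", "basal", "vitelline", "yolk")

# 2nd-order (Moore) neighbourhood; used for contact energy, surface
# counting and copy-attempt source selection alike.
NEIGHBOURS = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)

# dH returned for moves that would annihilate a non-medium compartment;
# effectively a hard rejection at any finite temperature.
_REJECT = 1e30

LINK_APICAL_CONSTRICTION = 0
LINK_SUB_APICAL = 1
LINK_SUB_BASAL = 2
LINK_KIND_NAMES = ("apical_constriction", "sub_apical", "sub_basal")


class ConsistencyError(ValueError):
    """Registry and lattice disagree (volumes, labels, or frozen set)."""


class FrozenLabelError(ValueError):
    """A copy attempt tried to grow or shrink a frozen compartment."""


class VanishedCompartmentError(ValueError):
    """An operation needed a compartment that has no lattice sites."""


@dataclass
class EnergyParams:
    """Global energy parameters: contact matrix, constraint multipliers, T.

    Parameters
    ----------
    J : (N_KINDS, N_KINDS) array
        Contact energy per heterologous neighbour pair, indexed by
        compartment kind. Must be symmetric.
    J_intra : (N_KINDS, N_KINDS) array, optional
        Contact energy applied instead of J when the two labels belong
        to the same parent cell (compartmentalized-CPM cohesion).
        Defaults to J, i.e. no intra/inter distinction.
    lam_V, lam_S : float
        Volume and surface constraint multipliers (per-label weights in
        the state registry scale these for special labels such as yolk).
    T : float
        Metropolis fluctuation amplitude.
    """

    J: np.ndarray
    lam_V: float = 2.0
    lam_S: float = 0.2
    T: float = 10.0
    J_intra: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.J = np.asarray(self.J, dtype=np.float64)
        if self.J.shape != (N_KINDS, N_KINDS):
            raise ValueError(f"J must be {N_KINDS}x{N_KINDS}")
        if not np.allclose(self.J, self.J.T):
            raise ValueError("contact matrix J must be symmetric")
        if self.J_intra is None:
            self.J_intra = self.J
        else:
            self.J_intra = np.asarray(self.J_intra, dtype=np.float64)
            if self.J_intra.shape != (N_KINDS, N_KINDS):
                raise ValueError(f"J_intra must be {N_KINDS}x{N_KINDS}")
            if not np.allclose(self.J_intra, self.J_intra.T):
                raise ValueError("contact matrix J_intra must be symmetric")
        if self.lam_V < 0 or self.lam_S < 0 or self.T < 0:
            raise ValueError("lam_V, lam_S and T must be non-negative")


@dataclass
class LinkSet:
    """Hookean links between compartment centroids, stored columnar.

    Energy of link i is lam[i] * (d_i - d0[i])**2 with d_i the Euclidean
    distance between the centroids of compartments a[i] and b[i].
    """

    a: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    b: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    lam: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.float64))
    d0: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.float64))
    kind: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=np.int64)
        self.b = np.asarray(self.b, dtype=np.int64)
        self.lam = np.asarray(self.lam, dtype=np.float64)
        self.d0 = np.asarray(self.d0, dtype=np.float64)
        self.kind = np.asarray(self.kind, dtype=np.int64)
        if np.any(self.lam < 0) or np.any(self.d0 < 0):
            raise ValueError("link stiffness and rest length must be >= 0")

    def __len__(self) -> int:
        return self.a.size

    @classmethod
    def from_records(cls, records) -> "LinkSet":
        """Build from an iterable of (a, b, lam, d0, kind) tuples."""
        recs = list(records)
        if not recs:
            return cls()
        a, b, lam, d0, kind = zip(*recs)
        return cls(np.array(a), np.array(b), np.array(lam), np.array(d0), np.array(kind))

    def incidence(self, n_labels: int):
        """CSR-style (ptr, idx) mapping label -> incident link indices."""
        counts = np.zeros(n_labels + 1, dtype=np.int64)
        for lab in self.a:
            counts[lab + 1] += 1
        for lab in self.b:
            counts[lab + 1] += 1
        ptr = np.cumsum(counts)
        idx = np.empty(ptr[-1], dtype=np.int64)
        fill = ptr[:-1].copy()
        for i in range(len(self)):
            for lab in (self.a[i], self.b[i]):
                idx[fill[lab]] = i
                fill[lab] += 1
        return ptr, idx


@dataclass
class SimState:
    """Labelled lattice plus per-compartment registry.

    The registry arrays are indexed by label (0 = medium) and kept
    incrementally consistent with the lattice by the Metropolis kernel:
    ``volume`` is the site count, ``surface`` the heterologous
    neighbour-pair count, and ``sum_r``/``sum_c`` coordinate sums from
    which centroids are derived. ``w_V``/``w_S`` are per-label weights
    multiplying the global constraint multipliers (0 disables the
    constraint for that label). ``parent`` is the parent-cell id of
    each compartment label (labels sharing a parent interact through
    J_intra); by default every label is its own parent.
    """

    lattice: np.ndarray
    kind: np.ndarray
    volume: np.ndarray
    surface: np.ndarray
    sum_r: np.ndarray
    sum_c: np.ndarray
    frozen: np.ndarray
    target_V: np.ndarray
    target_S: np.ndarray
    w_V: np.ndarray
    w_S: np.ndarray
    parent: np.ndarray = None
    time: int = 0
    _active_rc: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.parent is None:
            self.parent = np.arange(self.kind.size, dtype=np.int64)

    @property
    def n_labels(self) -> int:
        return self.kind.size

    @property
    def shape(self):
        return self.lattice.shape

    # ------------------------------------------------------------------
    @classmethod
    def from_lattice(cls, lattice, kind, frozen=None, target_V=None,
                     target_S=None, w_V=None, w_S=None, parent=None) -> "SimState":
        """Build a state with the registry recomputed from the lattice.

        Unset volume/surface targets default to the current values, so a
        freshly built state sits exactly at its constraint minima.
        """
        lattice = np.ascontiguousarray(lattice, dtype=np.int32)
        kind = np.asarray(kind, dtype=np.int8)
        n = kind.size
        if lattice.max() >= n or lattice.min() < 0:
            raise ConsistencyError("lattice contains labels without a registry entry")
        volume = np.bincount(lattice.ravel(), minlength=n).astype(np.int64)
        surface = _count_surfaces(lattice, n)
        rr, cc = np.indices(lattice.shape)
        sum_r = np.bincount(lattice.ravel(), weights=rr.ravel(), minlength=n)
        sum_c = np.bincount(lattice.ravel(), weights=cc.ravel(), minlength=n)
        if frozen is None:
            frozen = np.zeros(n, dtype=bool)
        frozen = np.asarray(frozen, dtype=bool)
        target_V = volume.astype(np.float64) if target_V is None else np.asarray(target_V, float)
        target_S = surface.astype(np.float64) if target_S is None else np.asarray(target_S, float)
        w_V = np.ones(n) if w_V is None else np.asarray(w_V, float)
        w_S = np.ones(n) if w_S is None else np.asarray(w_S, float)
        if parent is not None:
            parent = np.asarray(parent, dtype=np.int64)
        return cls(lattice, kind, volume, surface, sum_r.astype(np.float64),
                   sum_c.astype(np.float64), frozen, target_V, target_S, w_V,
                   w_S, parent)

    def copy(self) -> "SimState":
        return SimState(
            self.lattice.copy(), self.kind.copy(), self.volume.copy(),
            self.surface.copy(), self.sum_r.copy(), self.sum_c.copy(),
            self.frozen.copy(), self.target_V.copy(), self.target_S.copy(),
            self.w_V.copy(), self.w_S.copy(), self.parent.copy(), self.time,
        )

    def active_sites(self) -> np.ndarray:
        """(n, 2) row/col indices of sites whose label is not frozen.

        Frozen labels can neither grow nor shrink, so this set is
        invariant under the dynamics and is cached.
        """
        if self._active_rc is None:
            mask = ~self.frozen[self.lattice]
            self._active_rc = np.argwhere(mask).astype(np.int64)
        return self._active_rc

    def sites_of(self, label: int) -> np.ndarray:
        return np.argwhere(self.lattice == label)


def _count_surfaces(lattice: np.ndarray, n_labels: int) -> np.ndarray:
    """Per-label heterologous neighbour-pair counts (vectorized)."""
    surface = np.zeros(n_labels, dtype=np.int64)
    H, W = lattice.shape
    for dr, dc in NEIGHBOURS:
        r0, r1 = max(0, dr), min(H, H + dr)
        c0, c1 = max(0, dc), min(W, W + dc)
        a = lattice[r0:r1, c0:c1]
        b = lattice[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
        het = a != b
        np.add.at(surface, a[het], 1)
    return surface


# ----------------------------------------------------------------------
# energy evaluation


def check_state(state: SimState) -> None:
    """Raise ConsistencyError if the registry disagrees with the lattice."""
    n = state.n_labels
    lab = state.lattice.ravel()
    if lab.max() >= n or lab.min() < 0:
        raise ConsistencyError("unknown label on lattice")
    vol = np.bincount(lab, minlength=n)
    if not np.array_equal(vol, state.volume):
        raise ConsistencyError("registry volumes do not match lattice counts")
    surf = _count_surfaces(state.lattice, n)
    if not np.array_equal(surf, state.surface):
        raise ConsistencyError("registry surfaces do not match lattice")
    rr, cc = np.indices(state.lattice.shape)
    sr = np.bincount(lab, weights=rr.ravel(), minlength=n)
    sc = np.bincount(lab, weights=cc.ravel(), minlength=n)
    if not (np.allclose(sr, state.sum_r) and np.allclose(sc, state.sum_c)):
        raise ConsistencyError("registry centroid sums do not match lattice")


def compartment_centroid(state: SimState, label: int) -> tuple[float, float]:
    """Arithmetic mean (row, col) of the label's member sites."""
    v = state.volume[label]
    if v == 0:
        raise VanishedCompartmentError(f"compartment {label} has no sites")
    return state.sum_r[label] / v, state.sum_c[label] / v


def link_energy(links: LinkSet, state: SimState) -> float:
    """Sum over links of lam * (d - d0)^2 on centroid distances."""
    if len(links) == 0:
        return 0.0
    va = state.volume[links.a]
    vb = state.volume[links.b]
    if np.any(va == 0) or np.any(vb == 0):
        raise VanishedCompartmentError("link endpoint compartment has vanished")
    dr = state.sum_r[links.a] / va - state.sum_r[links.b] / vb
    dc = state.sum_c[links.a] / va - state.sum_c[links.b] / vb
    d = np.hypot(dr, dc)
    return float(np.sum(links.lam * (d - links.d0) ** 2))


def contact_energy(state: SimState, params: EnergyParams) -> float:
    """Adhesion term summed over unordered heterologous neighbour pairs.

    Pairs of labels sharing a parent cell use J_intra, all others J.
    """
    lattice = state.lattice
    kind = state.kind.astype(np.int64)
    parent = state.parent
    H, W = lattice.shape
    total = 0.0
    # half the neighbourhood -> each unordered pair once
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        r0, r1 = max(0, dr), min(H, H + dr)
        c0, c1 = max(0, dc), min(W, W + dc)
        a = lattice[r0:r1, c0:c1]
        b = lattice[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
        het = a != b
        la, lb = a[het], b[het]
        same = parent[la] == parent[lb]
        total += params.J[kind[la[~same]], kind[lb[~same]]].sum()
        total += params.J_intra[kind[la[same]], kind[lb[same]]].sum()
    return float(total)


def total_energy(state: SimState, params: EnergyParams, links: LinkSet | None = None) -> float:
    """Effective energy H of a state (contact + volume + surface + links)."""
    if links is None:
        links = LinkSet()
    e = contact_energy(state, params)
    e += float(np.sum(params.lam_V * state.w_V * (state.volume - state.target_V) ** 2))
    e += float(np.sum(params.lam_S * state.w_S * (state.surface - state.target_S) ** 2))
    e += link_energy(links, state)
    return e


# ----------------------------------------------------------------------
# Metropolis kernel (numba)


@njit(cache=True)
def _site_delta(lattice, r, c, new, kind, parent, volume, surface, sum_r, sum_c,
                target_V, target_S, w_V, w_S, J, J_intra, lam_V, lam_S,
                link_ptr, link_idx, la, lb, llam, ld0):
    """dH of copying label `new` onto site (r, c), plus surface deltas."""
    old = lattice[r, c]
    H, W = lattice.shape
    dE = 0.0
    h_old = 0
    h_new = 0
    kloc = 0
    for k in range(8):
        rr = r + NEIGHBOURS[k, 0]
        cc = c + NEIGHBOURS[k, 1]
        if rr < 0 or rr >= H or cc < 0 or cc >= W:
            continue
        kloc += 1
        t = lattice[rr, cc]
        kt = kind[t]
        if t != new:
            if parent[t] == parent[new]:
                dE += J_intra[kind[new], kt]
            else:
                dE += J[kind[new], kt]
        if t != old:
            if parent[t] == parent[old]:
                dE -= J_intra[kind[old], kt]
            else:
                dE -= J[kind[old], kt]
        if t == old:
            h_old += 1
        elif t == new:
            h_new += 1

    vo = volume[old]
    vn = volume[new]
    if vo <= 1 and old != 0:
        # never annihilate a non-medium compartment
        return _REJECT, 0, 0
    dE += lam_V * w_V[new] * ((vn + 1 - target_V[new]) ** 2 - (vn - target_V[new]) ** 2)
    dE += lam_V * w_V[old] * ((vo - 1 - target_V[old]) ** 2 - (vo - target_V[old]) ** 2)

    dS_old = 2 * h_old - kloc
    dS_new = kloc - 2 * h_new
    so = surface[old]
    sn = surface[new]
    dE += lam_S * w_S[old] * ((so + dS_old - target_S[old]) ** 2 - (so - target_S[old]) ** 2)
    dE += lam_S * w_S[new] * ((sn + dS_new - target_S[new]) ** 2 - (sn - target_S[new]) ** 2)

    # links incident to the two affected compartments
    for which in range(2):
        lab = old if which == 0 else new
        for p in range(link_ptr[lab], link_ptr[lab + 1]):
            i = link_idx[p]
            e1 = la[i]
            e2 = lb[i]
            if which == 1 and (e1 == old or e2 == old):
                continue  # already handled from old's list
            # before
            r1 = sum_r[e1] / volume[e1]
            c1 = sum_c[e1] / volume[e1]
            r2 = sum_r[e2] / volume[e2]
            c2 = sum_c[e2] / volume[e2]
            db = np.sqrt((r1 - r2) ** 2 + (c1 - c2) ** 2)
            # after
            if e1 == old:
                r1 = (sum_r[old] - r) / (vo - 1)
                c1 = (sum_c[old] - c) / (vo - 1)
            elif e1 == new:
                r1 = (sum_r[new] + r) / (vn + 1)
                c1 = (sum_c[new] + c) / (vn + 1)
            if e2 == old:
                r2 = (sum_r[old] - r) / (vo - 1)
                c2 = (sum_c[old] - c) / (vo - 1)
            elif e2 == new:
                r2 = (sum_r[new] + r) / (vn + 1)
                c2 = (sum_c[new] + c) / (vn + 1)
            da = np.sqrt((r1 - r2) ** 2 + (c1 - c2) ** 2)
            dE += llam[i] * ((da - ld0[i]) ** 2 - (db - ld0[i]) ** 2)

    return dE, dS_old, dS_new


@njit(cache=True)
def _sweep(lattice, kind, parent, volume, surface, sum_r, sum_c, frozen,
           target_V, target_S, w_V, w_S, J, J_intra, lam_V, lam_S, T,
           link_ptr, link_idx, la, lb, llam, ld0,
           act_r, act_c, pick, nbr, urand):
    """One MCS: len(pick) copy attempts with Metropolis acceptance."""
    accepted = 0
    H, W = lattice.shape
    for i in range(pick.size):
        r = act_r[pick[i]]
        c = act_c[pick[i]]
        rr = r + NEIGHBOURS[nbr[i], 0]
        cc = c + NEIGHBOURS[nbr[i], 1]
        if rr < 0 or rr >= H or cc < 0 or cc >= W:
            continue
        new = lattice[rr, cc]
        old = lattice[r, c]
        if new == old or frozen[new]:
            continue
        dE, dS_old, dS_new = _site_delta(
            lattice, r, c, new, kind, parent, volume, surface, sum_r, sum_c,
            target_V, target_S, w_V, w_S, J, J_intra, lam_V, lam_S,
            link_ptr, link_idx, la, lb, llam, ld0)
        if dE <= 0.0:
            ok = True
        elif T > 0.0:
            ok = urand[i] < np.exp(-dE / T)
        else:
            ok = False
        if ok:
            lattice[r, c] = new
            volume[old] -= 1
            volume[new] += 1
            surface[old] += dS_old
            surface[new] += dS_new
            sum_r[old] -= r
            sum_c[old] -= c
            sum_r[new] += r
            sum_c[new] += c
            accepted += 1
    return accepted


def metropolis_accept(dH: float, T: float, rng: np.random.Generator) -> bool:
    """Metropolis rule: accept if dH <= 0, else with probability exp(-dH/T).

    At T = 0 only non-increasing moves are accepted.
    """
    if T < 0:
        raise ValueError("temperature must be >= 0")
    if dH <= 0:
        return True
    if T == 0:
        return False
    return bool(rng.random() < np.exp(-dH / T))


def delta_energy(state: SimState, site: tuple[int, int], proposed_label: int,
                 params: EnergyParams, links: LinkSet | None = None) -> float:
    """Incremental dH = H(after copying proposed_label onto site) - H(before)."""
    if links is None:
        links = LinkSet()
    r, c = site
    old = state.lattice[r, c]
    if proposed_label == old:
        return 0.0
    if state.frozen[old] or state.frozen[proposed_label]:
        raise FrozenLabelError("copy attempts may not touch frozen compartments")
    ptr, idx = links.incidence(state.n_labels)
    dE, _, _ = _site_delta(
        state.lattice, r, c, proposed_label, state.kind.astype(np.int64),
        state.parent, state.volume, state.surface, state.sum_r, state.sum_c,
        state.target_V, state.target_S, state.w_V, state.w_S,
        params.J, params.J_intra, params.lam_V, params.lam_S,
        ptr, idx, links.a, links.b, links.lam, links.d0)
    return float(dE)


def run_mcs(state: SimState, params: EnergyParams, links: LinkSet | None,
            rng: np.random.Generator, n_steps: int = 1) -> int:
    """Advance the state by `n_steps` Monte Carlo steps in place.

    One MCS performs as many copy attempts as there are non-frozen
    lattice sites; registry volumes, surfaces and centroid sums are
    updated incrementally. Returns the number of accepted copies.
    """
    if links is None:
        links = LinkSet()
    ptr, idx = links.incidence(state.n_labels)
    act = state.active_sites()
    act_r = np.ascontiguousarray(act[:, 0])
    act_c = np.ascontiguousarray(act[:, 1])
    n = act_r.size
    kind64 = state.kind.astype(np.int64)
    accepted = 0
    for _ in range(n_steps):
        pick = rng.integers(0, n, n)
        nbr = rng.integers(0, 8, n)
        urand = rng.random(n)
        accepted += _sweep(
            state.lattice, kind64, state.parent, state.volume, state.surface,
            state.sum_r, state.sum_c, state.frozen,
            state.target_V, state.target_S, state.w_V, state.w_S,
            params.J, params.J_intra, params.lam_V, params.lam_S, params.T,
            ptr, idx, links.a, links.b, links.lam, links.d0,
            act_r, act_c, pick, nbr, urand)
        state.time += 1
    return int(accepted)
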