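"""Image-derived quantification for Brillouin-shift time-lapse data.

Covers the measurement chain used around the simulation: ROI summary
statistics on Brillouin-shift maps (GHz), onset normalisation,
top-fraction hotspot filtering anchored at a reference frame, mask
shape descriptors and the circularity-based two-phase tracking of the
columnar-to-squamous transition, orientation dispersion of a
fibrillar signal (MTSD), first-difference stationarisation with a KPSS
check, ARMA-residual Spearman association of paired series, and the
conversion of a Brillouin shift to a longitudinal modulus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage import measure

__all__ = [
    "RoiStats", "ShapeTrack", "MTSDResult", "AssociationResult",
    "ModulusParams", "roi_stats", "normalize_to_onset", "top_fraction_mask",
    "shape_descriptors", "track_axes", "select_cells_by_transition_time",
    "mtsd", "make_stationary", "residual_correlation", "shift_to_modulus",
]


class EmptyRoiError(ValueError):
    """The ROI mask selects no pixels."""


class DegenerateShapeError(ValueError):
    """The mask is too small for shape descriptors."""


class UndefinedOrientationError(ValueError):
    """The ROI carries no intensity to estimate an orientation from."""


# ----------------------------------------------------------------------
# ROI statistics and shift-map filtering


@dataclass
class RoiStats:
    """The five summary statistics of masked Brillouin-shift pixels."""

    median: float
    mean: float
    sd: float
    max: float
    min: float
    n_pixels: int


def roi_stats(shift_map: np.ndarray, mask: np.ndarray) -> RoiStats:
    """Median, mean, SD, max and min of the shift map inside the mask."""
    mask = np.asarray(mask, dtype=bool)
    vals = np.asarray(shift_map, dtype=float)[mask]
    if vals.size == 0:
        raise EmptyRoiError("ROI mask selects no pixels")
    return RoiStats(median=float(np.median(vals)), mean=float(vals.mean()),
                    sd=float(vals.std(ddof=0)), max=float(vals.max()),
                    min=float(vals.min()), n_pixels=int(vals.size))


def normalize_to_onset(series, onset_index: int) -> np.ndarray:
    """Subtract the value at the onset timepoint from every timepoint.

    This is the normalisation used for "norm." Brillouin-shift traces:
    the raw value at the end of cellularisation / onset of gastrulation
    becomes the zero of the series.
    """
    series = np.asarray(series, dtype=float)
    if not 0 <= onset_index < series.shape[0]:
        raise IndexError(f"onset index {onset_index} outside series")
    return series - series[onset_index]


def top_fraction_mask(maps, fraction: float = 0.04, reference_frame: int = 0,
                      roi: np.ndarray | None = None,
                      per_frame: bool = False) -> np.ndarray:
    """Select the top-fraction highest-shift pixels of each frame.

    The threshold is the (1 - fraction) quantile of the reference
    frame's pixels (optionally restricted to `roi`), frozen and applied
    to every frame — matching a thresholding anchored at the end of
    cellularisation. With ``per_frame=True`` the quantile is instead
    recomputed on each frame. Pixels >= threshold are selected, so a
    constant map selects everything (ties are kept).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    maps = np.asarray(maps, dtype=float)
    single = maps.ndim == 2
    stack = maps[None] if single else maps
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)

    def _threshold(frame):
        vals = frame[roi] if roi is not None else frame.ravel()
        if vals.size == 0:
            raise EmptyRoiError("reference ROI selects no pixels")
        return np.quantile(vals, 1.0 - fraction)

    if per_frame:
        out = np.stack([f >= _threshold(f) for f in stack])
    else:
        thr = _threshold(stack[reference_frame])
        out = stack >= thr
    if roi is not None:
        out = out & roi
    return out[0] if single else out


# ----------------------------------------------------------------------
# shape descriptors and phase tracking


def shape_descriptors(mask: np.ndarray, pixel_size: float = 1.0) -> dict:
    """Area, perimeter, moment-ellipse axes and circularity of a mask.

    The ellipse axes come from the mask's second-order moments
    (moment-equivalent ellipse); circularity is 4*pi*area/perimeter^2
    with the Crofton perimeter estimate. For near-circular discrete
    masks the estimate can exceed 1 by a few percent; it is reported
    unclamped so the circularity maximum stays unique along a track.
    `pixel_size` converts to physical units (areas scale with its
    square).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 5:
        raise DegenerateShapeError("mask has fewer than 5 pixels")
    lab, n = ndimage.label(mask)
    if n != 1:
        raise ValueError("mask must be a single connected region")
    props = measure.regionprops(lab.astype(np.uint8))[0]
    area = props.area * pixel_size ** 2
    perimeter = measure.perimeter_crofton(mask, directions=4) * pixel_size
    circ = 4.0 * np.pi * area / perimeter ** 2 if perimeter > 0 else 0.0
    return {
        "area": float(area),
        "perimeter": float(perimeter),
        "major_axis": float(props.axis_major_length * pixel_size),
        "minor_axis": float(props.axis_minor_length * pixel_size),
        "circularity": float(circ),
    }


@dataclass
class ShapeTrack:
    """Per-timepoint shape descriptors of one tracked cell.

    After :func:`track_axes` the frame additionally carries the phase
    label (1 before maximum circularity, 2 from it on) and the combined
    apical-basal / stretching axis series.
    """

    frame: pd.DataFrame
    cell_id: int | str = 0
    transition_index: int | None = None

    @classmethod
    def from_masks(cls, masks, pixel_size: float = 1.0, cell_id=0,
                   timestamps=None) -> "ShapeTrack":
        rows = []
        for i, m in enumerate(masks):
            d = shape_descriptors(m, pixel_size=pixel_size)
            d["t"] = timestamps[i] if timestamps is not None else i
            rows.append(d)
        return cls(frame=pd.DataFrame(rows), cell_id=cell_id)


def track_axes(track: ShapeTrack) -> ShapeTrack:
    """Assign the two shape phases and build the combined axis series.

    The timepoint of maximum circularity (earliest, on ties) marks the
    transition from phase 1 (columnar, apical-basal axis = major axis)
    to phase 2 (squamous, apical-basal axis = minor axis); the
    stretching axis is the complementary combination.
    """
    f = track.frame
    if len(f) < 3:
        raise ValueError("need at least 3 timepoints to assign phases")
    idx = int(np.argmax(f["circularity"].to_numpy()))
    n = len(f)
    phase = np.where(np.arange(n) < idx, 1, 2)
    major = f["major_axis"].to_numpy()
    minor = f["minor_axis"].to_numpy()
    apical_basal = np.where(phase == 1, major, minor)
    stretching = np.where(phase == 1, minor, major)
    out = f.copy()
    out["phase"] = phase
    out["apical_basal_axis"] = apical_basal
    out["stretching_axis"] = stretching
    return ShapeTrack(frame=out, cell_id=track.cell_id, transition_index=idx)


def select_cells_by_transition_time(tracks, low_pct: float = 10.0,
                                    high_pct: float = 90.0):
    """Keep tracks whose max-circularity time is within [P10, P90].

    Percentiles (linear interpolation) are taken over the distribution
    of transition times across tracks; bounds are inclusive. With
    fewer than 3 tracks the filter is inapplicable and all tracks are
    kept (with a warning).
    """
    tracks = list(tracks)
    if len(tracks) < 3:
        warnings.warn("fewer than 3 tracks: transition-time filter skipped")
        return tracks
    times = []
    for tr in tracks:
        if tr.transition_index is None:
            tr = track_axes(tr)
        t_col = tr.frame["t"].to_numpy()
        times.append(t_col[tr.transition_index])
    times = np.asarray(times, dtype=float)
    lo, hi = np.percentile(times, [low_pct, high_pct])
    return [tr for tr, t in zip(tracks, times) if lo <= t <= hi]


# ----------------------------------------------------------------------
# orientation dispersion (MTSD)


@dataclass
class MTSDResult:
    """Axial mean direction and angular dispersion of a fibrous signal."""

    mean_direction_deg: float   # axial, in [0, 180)
    mtsd_deg: float             # in [0, 90]
    weight_total: float


def mtsd(image: np.ndarray, roi: tuple | None = None, sigma: float = 1.5,
         anisotropy_gate: float = 0.9, derivative_sigma: float = 1.0) -> MTSDResult:
    """Orientation dispersion of a fibrillar image region.

    Per-pixel axial orientations come from a structure tensor built on
    derivative-of-Gaussian gradients (scale `derivative_sigma`; DoG
    kernels are nearly rotation-invariant, unlike finite differences)
    with tensor smoothing `sigma`; each pixel is weighted by its
    intensity times the tensor anisotropy, gated at `anisotropy_gate`
    so featureless background, crossings and fibre end caps carry no
    weight. The mean direction is the axial Frechet mean (the
    direction minimising the weighted mean squared wrap-around
    deviation, which stays well-defined for bimodal orientation fields
    where the vector resultant vanishes); the MTSD is the square root
    of that minimised deviation, with the wrap-around metric
    min(|d|, 180 - |d|).

    `roi` is an optional (row_slice, col_slice) pair restricting the
    analysis to a rectangular window.
    """
    img = np.asarray(image, dtype=float)
    if roi is not None:
        img = img[roi[0], roi[1]]
    if img.size == 0 or img.max() <= 0:
        raise UndefinedOrientationError("ROI carries no signal")
    g_r = ndimage.gaussian_filter(img, derivative_sigma, order=(1, 0))
    g_c = ndimage.gaussian_filter(img, derivative_sigma, order=(0, 1))
    Arr = ndimage.gaussian_filter(g_r * g_r, sigma)
    Arc = ndimage.gaussian_filter(g_r * g_c, sigma)
    Acc = ndimage.gaussian_filter(g_c * g_c, sigma)
    # eigen-decomposition of [[Arr, Arc], [Arc, Acc]]
    trace = Arr + Acc
    disc = np.sqrt((Arr - Acc) ** 2 + 4 * Arc ** 2)
    anisotropy = disc / np.where(trace > 0, trace, np.inf)
    # dominant gradient orientation measured from the row axis; for a
    # fibre at angle a (standard x-axis convention, y up) the gradient
    # points at angle a from the row axis, so this IS the fibre's
    # standard-convention axial angle
    theta = 0.5 * np.arctan2(2 * Arc, Arr - Acc)
    w = img * anisotropy * (disc > 1e-12) * (anisotropy > anisotropy_gate)
    wsum = w.sum()
    if wsum <= 0:
        raise UndefinedOrientationError("no oriented structure in ROI")
    theta_deg = np.degrees(theta) % 180.0
    # axial Frechet mean: the direction minimising the weighted mean
    # squared wrap-around deviation (well-defined even for bimodal
    # distributions where the vector resultant vanishes)
    nbins = 720
    hist, edges = np.histogram(theta_deg, bins=nbins, range=(0.0, 180.0),
                               weights=w)
    centers = 0.5 * (edges[:-1] + edges[1:])
    diff = np.abs(centers[None, :] - centers[:, None])
    dev2 = np.minimum(diff, 180.0 - diff) ** 2
    msd = dev2 @ hist / hist.sum()
    best = int(np.argmin(msd))
    return MTSDResult(mean_direction_deg=float(centers[best]),
                      mtsd_deg=float(np.sqrt(msd[best])),
                      weight_total=float(wsum))


# ----------------------------------------------------------------------
# detrended association


@dataclass
class AssociationResult:
    """Detrended residual association between two time series."""

    spearman_rho: float
    spearman_p: float
    order_a: tuple
    order_b: tuple
    kpss_stat_a: float | None = None
    kpss_stat_b: float | None = None
    n: int = 0


# 5% critical value of the KPSS level-stationarity statistic
_KPSS_CRIT_5PCT = 0.463


def make_stationary(series, window: slice | None = None,
                    difference: bool = True):
    """First-difference a (windowed) series and KPSS-check the result.

    Returns (differenced series, KPSS level statistic, flag) where the
    flag is True when the statistic exceeds the 5% critical value,
    i.e. when level stationarity of the differenced series is
    rejected. A constant differenced series (exact linear trend) has
    zero residual variance and is reported as stationary with
    statistic 0. With ``difference=False`` the series is checked as
    is (e.g. to confirm that an undifferenced random walk is flagged).
    """
    x = np.asarray(series, dtype=float)
    if window is not None:
        x = x[window]
    if x.size < 10:
        raise ValueError("window too short (need >= 10 points)")
    dx = np.diff(x) if difference else x
    if np.allclose(dx, dx[0]):
        return dx, 0.0, False
    from statsmodels.tsa.stattools import kpss
    # Schwert-style fixed bandwidth: good power against random-walk
    # alternatives without inflating size on short-memory series
    nlags = max(1, int(4 * (dx.size / 100.0) ** 0.25))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, _, _, _ = kpss(dx, regression="c", nlags=nlags)
    return dx, float(stat), bool(stat > _KPSS_CRIT_5PCT)


def _fit_best_arma(x: np.ndarray, max_order: int):
    """AICc-best ARMA(p, q) fit over (p, q) <= max_order; returns
    (residuals, (p, q)) or None if every fit fails."""
    from statsmodels.tsa.arima.model import ARIMA
    best = None
    for p in range(max_order + 1):
        for q in range(max_order + 1):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = ARIMA(x, order=(p, 0, q), trend="c").fit(
                        method_kwargs={"maxiter": 200})
                if np.isfinite(res.aicc) and (best is None or res.aicc < best[0]):
                    best = (res.aicc, res.resid, (p, q))
            except Exception:
                continue
    if best is None:
        return None
    return best[1], best[2]


def residual_correlation(series_a, series_b, max_order: int = 2) -> AssociationResult:
    """Spearman correlation between ARMA residuals of two series.

    Each (already stationarised) series gets an ARMA(p, q) model with
    (p, q) selected by AICc over {0..max_order}^2; the association is
    the Spearman rank correlation of the two residual series. If no
    ARMA fit converges for a series, its demeaned values are used
    instead (with a warning).
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    resids, orders = [], []
    for x in (a, b):
        fit = _fit_best_arma(x, max_order)
        if fit is None:
            warnings.warn("no ARMA fit converged; using demeaned series")
            resids.append(x - x.mean())
            orders.append((0, 0))
        else:
            resids.append(fit[0])
            orders.append(fit[1])
    rho, p = stats.spearmanr(resids[0], resids[1])
    return AssociationResult(spearman_rho=float(rho), spearman_p=float(p),
                             order_a=orders[0], order_b=orders[1], n=a.size)


def detrended_association(series_a, series_b, window: slice | None = None,
                          max_order: int = 2) -> AssociationResult:
    """Full detrending chain: difference, KPSS-check, ARMA residual
    Spearman correlation."""
    da, ka, _ = make_stationary(series_a, window)
    db, kb, _ = make_stationary(series_b, window)
    out = residual_correlation(da, db, max_order=max_order)
    out.kpss_stat_a = ka
    out.kpss_stat_b = kb
    return out


# ----------------------------------------------------------------------
# Brillouin shift -> longitudinal modulus


@dataclass
class ModulusParams:
    """Optical/material constants of the Brillouin scattering geometry."""

    refractive_index: float = 1.33
    density: float = 1000.0          # kg m^-3
    wavelength: float = 532e-9       # m (vacuum)
    scattering_angle_deg: float = 180.0

    def __post_init__(self) -> None:
        if self.refractive_index <= 1.0:
            raise ValueError("refractive index must exceed 1")
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.scattering_angle_deg <= 0:
            raise ValueError("scattering angle must be positive")


def shift_to_modulus(shift_hz, params: ModulusParams | None = None):
    """Longitudinal modulus M (Pa) from a Brillouin shift (Hz).

    The shift maps to the sound velocity v = shift * wavelength /
    (2 n sin(theta/2)) and the modulus is M = rho * v^2. Accepts
    scalars or arrays.
    """
    params = params or ModulusParams()
    shift = np.asarray(shift_hz, dtype=float)
    s = np.sin(np.radians(params.scattering_angle_deg) / 2.0)
    v = shift * params.wavelength / (2.0 * params.refractive_index * s)
    M = params.density * v ** 2
    return float(M) if M.ndim == 0 else M
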