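"""Synthetic inputs with known ground truth for the quantification chain.

Each generator emulates the statistical structure one measurement
stage assumes — shift-map stacks with a localized ramping hotspot,
cell-mask series interpolating columnar to squamous shapes,
fibre images with controlled axial dispersion, and paired trended
series with planted residual correlation — and returns a truth record
that fully determines the artifact given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from skimage.draw import ellipse as draw_ellipse


@dataclass
class SyntheticTruth:
    """Planted parameters of one generated artifact."""

    kind: str
    seed: int
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def _clean(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v
        return json.dumps({"kind": self.kind, "seed": self.seed,
                           "params": {k: _clean(v) for k, v in self.params.items()}})

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(kind=d["kind"], seed=d["seed"], params=d["params"])


def gen_shift_series(shape=(64, 64), background_ghz: float = 5.10,
                     hotspot_center=(32, 32), hotspot_radius: int = 8,
                     contrast_ghz: float = 0.025, noise_sd_ghz: float = 0.005,
                     n_frames: int = 10, seed: int = 0):
    """Brillouin shift-map stack with a linearly ramping hotspot.

    The hotspot is a disc whose contrast ramps 0 -> `contrast_ghz`
    across frames on a uniform background, plus i.i.d. Gaussian noise.
    Returns (stack [n_frames, H, W] in GHz, truth) with the hotspot
    mask in the truth record.
    """
    if contrast_ghz < 0 or noise_sd_ghz < 0:
        raise ValueError("contrast and noise SD must be >= 0")
    rng = np.random.default_rng(seed)
    H, W = shape
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_ellipse(*hotspot_center, hotspot_radius, hotspot_radius,
                          shape=shape)
    mask[rr, cc] = True
    ramp = np.linspace(0.0, 1.0, n_frames) if n_frames > 1 else np.ones(1)
    stack = np.full((n_frames, H, W), background_ghz, dtype=float)
    stack += ramp[:, None, None] * contrast_ghz * mask[None]
    stack += rng.normal(0.0, noise_sd_ghz, stack.shape)
    truth = SyntheticTruth(kind="shift_series", seed=seed, params={
        "background_ghz": background_ghz, "contrast_ghz": contrast_ghz,
        "noise_sd_ghz": noise_sd_ghz, "hotspot_mask": mask,
        "hotspot_area_fraction": float(mask.mean()), "n_frames": n_frames})
    return stack, truth


def gen_shape_track(h0: float = 40.0, w0: float = 10.0, h_final: float = 8.0,
                    w_final: float = 50.0, n_frames: int = 20,
                    noise: float = 0.0, pad: int = 8, seed: int = 0):
    """Elliptical cell masks interpolating columnar -> squamous shape.

    Height interpolates h0 -> h_final and width w0 -> w_final linearly
    over the frames (optionally with Gaussian jitter on the semi-axes).
    The truth records the real-valued crossing time of the two
    interpolants (the isotropy point) and the nearest frame index.
    """
    if not (h0 > w0 and h_final < w_final):
        raise ValueError("track must run columnar (h0 > w0) to squamous "
                         "(h_final < w_final)")
    rng = np.random.default_rng(seed)
    ts = np.linspace(0.0, 1.0, n_frames)
    heights = h0 + (h_final - h0) * ts
    widths = w0 + (w_final - w0) * ts
    # crossing of the interpolants: h0 + (hf-h0) t = w0 + (wf-w0) t
    t_iso = (h0 - w0) / ((w_final - w0) - (h_final - h0))
    iso_frame = int(np.argmin(np.abs(ts - t_iso)))
    size = int(max(h0, h_final, w0, w_final)) + 2 * pad
    cen = size // 2
    masks = []
    for h, w in zip(heights, widths):
        if noise > 0:
            h = max(4.0, h + rng.normal(0.0, noise))
            w = max(4.0, w + rng.normal(0.0, noise))
        m = np.zeros((size, size), dtype=bool)
        rr, cc = draw_ellipse(cen, cen, h / 2.0, w / 2.0, shape=m.shape)
        m[rr, cc] = True
        masks.append(m)
    truth = SyntheticTruth(kind="shape_track", seed=seed, params={
        "h0": h0, "w0": w0, "h_final": h_final, "w_final": w_final,
        "t_iso": float(t_iso), "iso_frame": iso_frame, "n_frames": n_frames,
        "noise": noise})
    return np.stack(masks), truth


def gen_orientation_image(n_fibers: int = 150, mean_deg: float = 30.0,
                          sd_deg: float = 10.0, length: float = 20.0,
                          width: float = 1.0, shape=(256, 256), seed: int = 0):
    """Gaussian-profile fibre segments with controlled axial dispersion.

    Each fibre is an analytic ridge (transverse Gaussian profile of SD
    `width` around the exact segment), so fibre orientations are free
    of rasterisation staircase artefacts. Segment angles are drawn
    Gaussian around `mean_deg` (axial: folded into [0, 180)); the
    truth records the realized axial SD about the realized mean with
    the wrap-around metric, which is what an orientation estimator
    should recover.
    """
    if sd_deg < 0:
        raise ValueError("sd_deg must be >= 0")
    rng = np.random.default_rng(seed)
    H, W = shape
    img = np.zeros(shape, dtype=float)
    angles = mean_deg + rng.normal(0.0, sd_deg, n_fibers)
    pad = 3.0 * width
    for ang in angles:
        r0 = rng.uniform(length, H - length)
        c0 = rng.uniform(length, W - length)
        # image rows grow downward: negative row step for positive angles
        ur = -np.sin(np.radians(ang))
        uc = np.cos(np.radians(ang))
        half = 0.5 * length
        rlo = max(0, int(np.floor(r0 - half * abs(ur) - pad)))
        rhi = min(H, int(np.ceil(r0 + half * abs(ur) + pad)) + 1)
        clo = max(0, int(np.floor(c0 - half * abs(uc) - pad)))
        chi = min(W, int(np.ceil(c0 + half * abs(uc) + pad)) + 1)
        rr, cc = np.mgrid[rlo:rhi, clo:chi]
        dr = rr - r0
        dc = cc - c0
        along = np.clip(dr * ur + dc * uc, -half, half)
        dist2 = (dr - along * ur) ** 2 + (dc - along * uc) ** 2
        img[rlo:rhi, clo:chi] += np.exp(-0.5 * dist2 / width ** 2)
    # realized axial mean/SD via the double-angle representation
    th = np.radians(angles * 2.0)
    mean_axial = 0.5 * np.degrees(np.arctan2(np.sin(th).mean(), np.cos(th).mean()))
    dev = (angles - mean_axial) % 180.0
    dev = np.minimum(dev, 180.0 - dev)
    truth = SyntheticTruth(kind="orientation_image", seed=seed, params={
        "mean_deg": mean_deg, "sd_deg": sd_deg,
        "realized_mean_deg": float(mean_axial % 180.0),
        "realized_sd_deg": float(np.sqrt(np.mean(dev ** 2))),
        "n_fibers": n_fibers})
    return img, truth


def _check_stationary(coefs) -> None:
    roots = np.roots(np.r_[1.0, -np.asarray(coefs)]) if len(coefs) else []
    if len(coefs) and np.any(np.abs(roots) >= 1.0):
        raise ValueError("AR coefficients are not stationary")


def gen_paired_series(n: int = 200, trend_coeffs=((0.0, 0.05), (0.0, -0.03)),
                      ar=(0.5,), ma=(0.3,), innovation_rho: float = 0.0,
                      innovation_sd: float = 1.0, seed: int = 0):
    """Two trended ARMA series with jointly Gaussian innovations.

    Each series is a polynomial trend (coefficients low -> high order)
    plus an ARMA(ar, ma) process; the innovation pairs are bivariate
    normal with correlation `innovation_rho`. Returns (a, b, truth).
    """
    if not -1.0 <= innovation_rho <= 1.0:
        raise ValueError("|innovation_rho| must be <= 1")
    _check_stationary(ar)
    rng = np.random.default_rng(seed)
    cov = innovation_sd ** 2 * np.array([[1.0, innovation_rho],
                                         [innovation_rho, 1.0]])
    eps = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    ar_poly = np.r_[1.0, -np.asarray(ar)]
    ma_poly = np.r_[1.0, np.asarray(ma)]
    t = np.arange(n, dtype=float)
    out = []
    for k in range(2):
        noise = signal.lfilter(ma_poly, ar_poly, eps[:, k])
        trend = np.polynomial.polynomial.polyval(t, trend_coeffs[k])
        out.append(trend + noise)
    truth = SyntheticTruth(kind="paired_series", seed=seed, params={
        "innovation_rho": innovation_rho, "ar": list(ar), "ma": list(ma),
        "trend_coeffs": [list(c) for c in trend_coeffs], "n": n,
        # Spearman rho implied by the Gaussian innovation correlation
        "expected_spearman": float(6.0 / np.pi * np.arcsin(innovation_rho / 2.0))})
    return out[0], out[1], truth
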