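"""Population receptive field (pRF) forward model and estimation.

A pRF is a circular 2D Gaussian in the visual field, parameterized by its
center ``(x, y)`` (deg; x positive rightward, y positive upward) and spread
``sigma`` (deg).  The predicted BOLD response is the pointwise product of the
Gaussian with the stimulus contrast aperture, summed over the field, then
convolved with a hemodynamic response function (HRF) modelled as a difference
of two gamma functions.

Estimation is coarse-to-fine: an exhaustive search over a coarse (x, y, sigma)
grid with per-candidate least-squares gain, followed by a local derivative-free
refinement from the best grid point.  Fits with variance explained R^2 <= 10%
are flagged as excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal
from scipy.stats import gamma as gamma_dist

from .stimulus import StimulusAperture

__all__ = [
    "PRFParams",
    "HRFParams",
    "PRFFit",
    "PRFGridSpec",
    "hrf_double_gamma",
    "predict_timecourse",
    "fit_prf_coarse_to_fine",
    "cartesian_to_polar",
    "percent_signal_change",
    "R2_INCLUSION_THRESHOLD",
]

#: variance-explained gate: analyses use vertices with R^2 > 10%
R2_INCLUSION_THRESHOLD = 0.10


@dataclass(frozen=True)
class PRFParams:
    """pRF center (deg) and spread (deg)."""

    x: float
    y: float
    sigma: float

    def __post_init__(self):
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("pRF center must be finite")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass(frozen=True)
class HRFParams:
    """Five-parameter difference-of-gammas HRF.

    ``peak_delay`` and ``undershoot_delay`` are the gamma means (s),
    ``peak_dispersion``/``undershoot_dispersion`` their scales, and
    ``ratio`` the peak:undershoot amplitude ratio.  Defaults are the
    canonical values (delays 6 and 16 s, unit dispersions, ratio 6).
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    ratio: float = 6.0

    def __post_init__(self):
        for name in ("peak_delay", "undershoot_delay", "peak_dispersion",
                     "undershoot_dispersion", "ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"HRF parameter {name} must be > 0")


@dataclass
class PRFFit:
    """Result of fitting one vertex."""

    params: PRFParams
    gain: float
    r2: float
    polar_angle: float
    eccentricity: float
    included: bool


def hrf_double_gamma(params: HRFParams = HRFParams(), dt: float = 1.0,
                     duration: float = 32.0) -> np.ndarray:
    """Sample the difference-of-gammas HRF kernel, normalized to unit peak."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    t = np.arange(0.0, duration + dt / 2.0, dt)
    peak = gamma_dist.pdf(t, params.peak_delay / params.peak_dispersion,
                          scale=params.peak_dispersion)
    under = gamma_dist.pdf(t, params.undershoot_delay / params.undershoot_dispersion,
                           scale=params.undershoot_dispersion)
    kernel = peak - under / params.ratio
    peak_val = kernel.max()
    if peak_val <= 0:
        raise ValueError("degenerate HRF: non-positive peak")
    return kernel / peak_val


def _gaussian_field(x: float, y: float, sigma: float,
                    X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    return np.exp(-((X - x) ** 2 + (Y - y) ** 2) / (2.0 * sigma**2))


def predict_timecourse(prf: PRFParams, aperture: StimulusAperture,
                       hrf: np.ndarray) -> np.ndarray:
    """Forward-model prediction: Gaussian x aperture, summed, HRF-convolved.

    Returns a series of length ``aperture.n_frames``.
    """
    X, Y = aperture.pixel_centers()
    g = _gaussian_field(prf.x, prf.y, prf.sigma, X, Y)
    pixel_area = aperture.deg_per_pixel**2
    neural = aperture.frames.reshape(aperture.n_frames, -1) @ g.ravel() * pixel_area
    return np.convolve(neural, hrf)[: aperture.n_frames]


def cartesian_to_polar(x: float, y: float) -> tuple[float, float]:
    """(x, y) in deg -> (polar angle deg in [0, 360), eccentricity deg).

    0 deg = right horizontal meridian, 90 deg = upper vertical, CCW.
    The origin maps to angle 0 by convention.
    """
    ecc = float(np.hypot(x, y))
    if ecc == 0.0:
        return 0.0, 0.0
    ang = float(np.degrees(np.arctan2(y, x))) % 360.0
    return ang, ecc


@dataclass
class PRFGridSpec:
    """Coarse search grid: log-spaced eccentricities x angles x log-spaced sigmas."""

    eccentricities: np.ndarray = field(
        default_factory=lambda: np.concatenate([[0.0], np.geomspace(0.5, 11.0, 8)]))
    n_angles: int = 16
    sigmas: np.ndarray = field(default_factory=lambda: np.geomspace(0.25, 6.0, 6))

    def centers(self) -> np.ndarray:
        """(n, 2) array of candidate (x, y) centers; the origin appears once."""
        pts = [(0.0, 0.0)] if self.eccentricities[0] == 0.0 else []
        eccs = self.eccentricities[self.eccentricities > 0]
        ang = np.deg2rad(np.arange(self.n_angles) * 360.0 / self.n_angles)
        for e in eccs:
            for a in ang:
                pts.append((e * np.cos(a), e * np.sin(a)))
        return np.asarray(pts)


class _CandidateBank:
    """Precomputed HRF-convolved predictions for the coarse grid."""

    def __init__(self, aperture: StimulusAperture, hrf: np.ndarray,
                 grid: PRFGridSpec):
        X, Y = aperture.pixel_centers()
        self.Xf, self.Yf = X.ravel(), Y.ravel()
        self.A = aperture.frames.reshape(aperture.n_frames, -1)
        self.pixel_area = aperture.deg_per_pixel**2
        self.hrf = hrf
        self.n_frames = aperture.n_frames
        centers = grid.centers()
        params = [(cx, cy, s) for cx, cy in centers for s in grid.sigmas]
        self.params = np.asarray(params)
        G = np.exp(
            -((self.Xf[None, :] - self.params[:, 0:1]) ** 2
              + (self.Yf[None, :] - self.params[:, 1:2]) ** 2)
            / (2.0 * self.params[:, 2:3] ** 2))
        neural = G @ self.A.T * self.pixel_area
        conv = signal.fftconvolve(neural, hrf[None, :], axes=1)[:, : self.n_frames]
        self.pred_centered = conv - conv.mean(axis=1, keepdims=True)
        self.pred_ss = np.einsum("ij,ij->i", self.pred_centered, self.pred_centered)

    def predict(self, x: float, y: float, sigma: float) -> np.ndarray:
        g = np.exp(-((self.Xf - x) ** 2 + (self.Yf - y) ** 2) / (2.0 * sigma**2))
        neural = self.A @ g * self.pixel_area
        return np.convolve(neural, self.hrf)[: self.n_frames]


def _rss_with_gain(pred: np.ndarray, y_centered: np.ndarray,
                   tss: float) -> tuple[float, float]:
    """RSS after absorbing a non-negative gain and free offset."""
    p = pred - pred.mean()
    ss = float(p @ p)
    # near-zero predictions (pRF far outside the aperture) carry no signal
    if ss <= 1e-20 * max(tss, 1.0):
        return tss, 0.0
    proj = float(p @ y_centered)
    if proj <= 0:
        return tss, 0.0
    gain = proj / ss
    return tss - gain * proj, gain


def fit_prf_coarse_to_fine(
    series: np.ndarray,
    aperture: StimulusAperture,
    hrf: np.ndarray | None = None,
    grid_spec: PRFGridSpec | None = None,
    refine: bool = True,
    _bank: "_CandidateBank | None" = None,
) -> PRFFit | list[PRFFit]:
    """Fit pRF parameters to one series (1D) or a stack of series (2D).

    Stage 1 is an exhaustive coarse-grid search with per-candidate optimal
    non-negative gain; stage 2 refines (x, y, log sigma) with Nelder-Mead.
    Ties on the grid break to the first-encountered minimum.  A flat series
    is returned excluded with R^2 = 0.
    """
    if hrf is None:
        hrf = hrf_double_gamma(dt=aperture.frame_duration)
    if grid_spec is None:
        grid_spec = PRFGridSpec()
    bank = _bank if _bank is not None else _CandidateBank(aperture, hrf, grid_spec)

    series = np.asarray(series, dtype=float)
    if series.ndim == 1:
        return _fit_one(series, bank, refine)
    return [_fit_one(row, bank, refine) for row in series]


def _fit_one(y: np.ndarray, bank: _CandidateBank, refine: bool) -> PRFFit:
    if y.shape[0] != bank.n_frames:
        raise ValueError("series length must equal the aperture frame count")
    yc = y - y.mean()
    tss = float(yc @ yc)
    if tss <= 0:
        return PRFFit(PRFParams(0.0, 0.0, 1.0), 0.0, 0.0, 0.0, 0.0, False)

    proj = bank.pred_centered @ yc
    valid = (bank.pred_ss > 1e-20 * max(tss, 1.0)) & (proj > 0)
    safe_ss = np.where(valid, bank.pred_ss, 1.0)
    gains = np.where(valid, proj / safe_ss, 0.0)
    rss = np.where(valid, tss - gains * proj, tss)
    best = int(np.argmin(rss))  # argmin takes the first minimum
    x0, y0, s0 = bank.params[best]
    gain = float(gains[best])
    best_rss = float(rss[best])

    if refine:
        def objective(p):
            px, py, logs = p
            sigma = float(np.exp(logs))
            pred = bank.predict(px, py, sigma)
            r, _ = _rss_with_gain(pred, yc, tss)
            return r

        # explicit initial simplex: degree-scale steps, independent of the
        # start value (the default perturbation degenerates at exact 0)
        p0 = np.array([x0, y0, np.log(s0)])
        steps = np.array([0.8, 0.8, 0.4])
        simplex = np.vstack([p0, p0 + np.diag(steps)])
        res = optimize.minimize(
            objective, p0, method="Nelder-Mead",
            bounds=[(-15.0, 15.0), (-15.0, 15.0),
                    (np.log(0.05), np.log(10.0))],
            options={"xatol": 1e-4, "fatol": 1e-8 * max(tss, 1.0),
                     "maxiter": 400, "initial_simplex": simplex})
        # one restart from the optimum polishes occasional premature stops
        p1 = res.x
        simplex = np.vstack([p1, p1 + np.diag(steps / 8.0)])
        res = optimize.minimize(
            objective, p1, method="Nelder-Mead",
            bounds=[(-15.0, 15.0), (-15.0, 15.0),
                    (np.log(0.05), np.log(10.0))],
            options={"xatol": 1e-4, "fatol": 1e-8 * max(tss, 1.0),
                     "maxiter": 200, "initial_simplex": simplex})
        if res.fun <= best_rss:
            x0, y0 = float(res.x[0]), float(res.x[1])
            s0 = float(np.exp(res.x[2]))
            pred = bank.predict(x0, y0, s0)
            best_rss, gain = _rss_with_gain(pred, yc, tss)

    r2 = float(np.clip(1.0 - best_rss / tss, 0.0, 1.0))
    ang, ecc = cartesian_to_polar(x0, y0)
    return PRFFit(PRFParams(float(x0), float(y0), float(s0)), gain, r2,
                  ang, ecc, r2 > R2_INCLUSION_THRESHOLD)


def percent_signal_change(series: np.ndarray) -> np.ndarray:
    """Convert a raw series to % change about its temporal mean (last axis)."""
    series = np.asarray(series, dtype=float)
    mean = series.mean(axis=-1, keepdims=True)
    if np.any(mean == 0):
        raise ValueError("zero-mean series cannot be converted to % change")
    return 100.0 * (series - mean) / mean
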