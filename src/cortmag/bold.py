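"""Forward simulation of BOLD time series from a retinotopic mesh.

Each vertex's series is the pRF forward prediction for its ground-truth
receptive field (center from the planted polar angle/eccentricity, spread
from a sigma map) plus i.i.d. Gaussian noise — the minimal generative model
the pRF estimator assumes.  No physiological noise structure is emulated.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .mesh import CorticalMesh
from .prf import HRFParams, hrf_double_gamma
from .stimulus import StimulusAperture

__all__ = ["simulate_bold", "default_sigma_map"]


def default_sigma_map(mesh: CorticalMesh) -> np.ndarray:
    """Typical V1 pRF sizes: sigma grows roughly linearly with eccentricity."""
    return 0.25 + 0.16 * mesh.eccentricity


def simulate_bold(
    mesh: CorticalMesh,
    aperture: StimulusAperture,
    hrf_params: HRFParams = HRFParams(),
    sigma_map: np.ndarray | float | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    chunk: int = 512,
) -> np.ndarray:
    """Simulate per-vertex BOLD (% signal), shape (n_vertices, n_frames).

    ``sigma_map`` may be a scalar, a per-vertex array, or None for the
    default eccentricity-scaled sizes.  ``noise_sd`` is the SD of the added
    Gaussian noise in the same % units.  Reproducible under a fixed seed.
    """
    if sigma_map is None:
        sigma_map = default_sigma_map(mesh)
    sigma = np.broadcast_to(np.asarray(sigma_map, dtype=float),
                            (mesh.n_vertices,))
    if np.any(sigma <= 0):
        bad = int(np.argmax(sigma <= 0))
        raise ValueError(f"sigma must be positive (vertex {bad})")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    t = np.deg2rad(mesh.polar_angle)
    px = mesh.eccentricity * np.cos(t)
    py = mesh.eccentricity * np.sin(t)

    hrf = hrf_double_gamma(hrf_params, dt=aperture.frame_duration)
    X, Y = aperture.pixel_centers()
    Xf, Yf = X.ravel(), Y.ravel()
    A = aperture.frames.reshape(aperture.n_frames, -1)
    pixel_area = aperture.deg_per_pixel**2

    out = np.empty((mesh.n_vertices, aperture.n_frames))
    for lo in range(0, mesh.n_vertices, chunk):
        hi = min(lo + chunk, mesh.n_vertices)
        G = np.exp(
            -((Xf[None, :] - px[lo:hi, None]) ** 2
              + (Yf[None, :] - py[lo:hi, None]) ** 2)
            / (2.0 * sigma[lo:hi, None] ** 2))
        neural = G @ A.T * pixel_area
        out[lo:hi] = signal.fftconvolve(
            neural, hrf[None, :], axes=1)[:, : aperture.n_frames]

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out += rng.normal(0.0, noise_sd, size=out.shape)
    return out
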