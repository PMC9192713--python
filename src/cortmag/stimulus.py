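"""Retinotopic-mapping bar-aperture stimulus.

The mapping stimulus is a bar aperture sweeping across a circular region of
the visual field: eight sweeps of 24 one-second steps each (one step per TR),
alternating cardinal and diagonal directions.  Cardinal sweeps traverse the
full diameter; for diagonal sweeps the second half of the steps are blank.
Only the binary contrast aperture matters for the pRF forward model, so no
carrier texture is rendered.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["StimulusAperture", "make_bar_aperture", "aperture_mass"]

#: default sweep direction angles (deg, direction of bar motion, CCW from +x),
#: alternating cardinal and diagonal
DEFAULT_SWEEP_DIRECTIONS: tuple[float, ...] = (0, 45, 90, 135, 180, 225, 270, 315)


@dataclass
class StimulusAperture:
    """Time-ordered binary aperture frames on a visual-field pixel grid.

    Attributes
    ----------
    frames : ndarray, shape (n_frames, n_pix, n_pix)
        Aperture contrast in [0, 1]; pixels outside the circular aperture are 0.
    deg_per_pixel : float
        Visual-field degrees spanned by one pixel.
    frame_duration : float
        Seconds per frame (equals the TR).
    radius : float
        Radius of the circular aperture (deg).
    schedule : list of (direction_deg, step_index, is_blank)
        One entry per frame.
    """

    frames: np.ndarray
    deg_per_pixel: float
    frame_duration: float
    radius: float
    schedule: list[tuple[float, int, bool]] = field(repr=False)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def grid_size(self) -> int:
        return self.frames.shape[1]

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) pixel-center coordinates in deg; x rightward, y upward."""
        n = self.grid_size
        half = n * self.deg_per_pixel / 2.0
        coords = (np.arange(n) + 0.5) * self.deg_per_pixel - half
        X, Y = np.meshgrid(coords, -coords)  # row 0 is the top of the field
        return X, Y

    def save(self, path_prefix: str) -> None:
        """Write frames as ``<prefix>.npz`` plus a JSON sidecar."""
        np.savez_compressed(path_prefix + ".npz", frames=self.frames)
        meta = {
            "deg_per_pixel": self.deg_per_pixel,
            "frame_duration": self.frame_duration,
            "radius": self.radius,
            "grid_size": self.grid_size,
            "schedule": [[d, int(i), bool(b)] for d, i, b in self.schedule],
        }
        with open(path_prefix + ".json", "w") as fh:
            json.dump(meta, fh)


def make_bar_aperture(
    radius: float = 12.4,
    bar_width_fraction: float = 1.0 / 8.0,
    n_steps_per_sweep: int = 24,
    sweep_directions: tuple[float, ...] = DEFAULT_SWEEP_DIRECTIONS,
    grid_size: int = 101,
    tr: float = 1.0,
) -> StimulusAperture:
    """Build the sweeping-bar aperture sequence.

    The bar is ``bar_width_fraction`` of the full stimulus extent (2*radius)
    wide.  Each sweep starts with the bar's leading edge at the aperture edge
    and advances in ``n_steps_per_sweep`` equal steps of one frame each.
    Diagonal sweeps (directions not multiple of 90 deg) show blank frames for
    the second half of their steps.  Generation is deterministic.
    """
    if grid_size < 64:
        raise ValueError("grid_size must be >= 64")
    extent = 2.0 * radius
    bar_width = bar_width_fraction * extent
    deg_per_pixel = extent / grid_size
    if bar_width < deg_per_pixel:
        raise ValueError(
            f"bar width {bar_width:.3f} deg is below one pixel "
            f"({deg_per_pixel:.3f} deg); increase grid_size"
        )

    half = extent / 2.0
    coords = (np.arange(grid_size) + 0.5) * deg_per_pixel - half
    X, Y = np.meshgrid(coords, -coords)
    in_disc = X**2 + Y**2 <= radius**2  # pixel-center containment

    n_frames = len(sweep_directions) * n_steps_per_sweep
    frames = np.zeros((n_frames, grid_size, grid_size), dtype=np.float32)
    schedule: list[tuple[float, int, bool]] = []

    f = 0
    for direction in sweep_directions:
        is_cardinal = (direction % 90.0) == 0.0
        u = np.cos(np.deg2rad(direction)) * X + np.sin(np.deg2rad(direction)) * Y
        # Bar centre travels from -radius to +radius in n_steps_per_sweep steps;
        # centred so step k covers [-r + k*step, ...], leading edge at the rim.
        travel = 2.0 * radius
        step = travel / n_steps_per_sweep
        for k in range(n_steps_per_sweep):
            blank = (not is_cardinal) and (k >= n_steps_per_sweep // 2)
            if not blank:
                center = -radius + (k + 0.5) * step
                in_bar = np.abs(u - center) <= bar_width / 2.0
                frames[f][in_bar & in_disc] = 1.0
            schedule.append((float(direction), k, blank))
            f += 1

    return StimulusAperture(
        frames=frames,
        deg_per_pixel=deg_per_pixel,
        frame_duration=tr,
        radius=radius,
        schedule=schedule,
    )


def aperture_mass(aperture: StimulusAperture, frame: int) -> float:
    """Visual-field area (deg^2) covered by the aperture in one frame."""
    if not 0 <= frame < aperture.n_frames:
        raise IndexError(f"frame {frame} out of range")
    pixel_area = aperture.deg_per_pixel**2
    return float(np.count_nonzero(aperture.frames[frame]) * pixel_area)
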