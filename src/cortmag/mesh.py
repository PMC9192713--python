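"""Synthetic V1 cortical surfaces with planted retinotopy and magnification.

A hemisphere is modelled as a triangulated sheet obtained by mapping a
log-spaced-eccentricity x uniform-polar-angle grid of the visual hemifield
onto cortical coordinates.  The map is constructed so that its Jacobian —
the local cortical area per unit visual-field area — equals the prescribed
areal magnification

    M(ecc, theta) = M0 * m(ecc)^2 * (1 + alpha*cos(2*theta) - gamma*sin(theta))

with the standard inverse-linear linear magnification m(ecc) = A/(ecc + e2).
``alpha`` plants a horizontal-vertical anisotropy (HVA, more area near the
horizontal meridian), ``gamma`` a vertical-meridian asymmetry (VMA, more area
for the lower than the upper vertical meridian).

Cortical coordinates: the first axis is the integrated radial magnification
u(ecc) = sqrt(M0) * integral of m, the second axis v(ecc, theta) =
sqrt(M0) * m(ecc) * ecc * G(theta), with G the integral of the angular
modulation from the hemifield centre.  Since u depends on eccentricity only,
the Jacobian is exactly du/decc * dv/dtheta = M(ecc, theta) * ecc, i.e. the
planted magnification times the polar area element.

Angle convention (pipeline-wide): 0 deg = right horizontal meridian,
90 deg = upper vertical, counter-clockwise; the left hemisphere serves the
right visual hemifield (theta in [-90, 90]) and the right hemisphere the
left hemifield (theta in [90, 270]).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "MagnificationModel",
    "CorticalMesh",
    "make_synthetic_hemisphere",
    "make_depth_surfaces",
    "wedge_area_analytic",
    "sector_area_analytic",
    "HEMIFIELD_CENTER",
]

#: visual-field centre (deg) of the hemifield each hemisphere serves
HEMIFIELD_CENTER = {"left": 0.0, "right": 180.0}

# wedge means of the angular basis functions over a +/-15 deg wedge,
# used to convert asymmetry indices into modulation amplitudes:
#   mean of cos(2t) over [-15, 15] deg  = sin(30 deg)/(pi/6)
#   mean of sin(t)  over [75, 105] deg  = 2*sin(15 deg)/(pi/6)
_COS2_WEDGE_MEAN = np.sin(np.pi / 6) / (np.pi / 6)
_SIN_WEDGE_MEAN = 2 * np.sin(np.pi / 12) / (np.pi / 6)


@dataclass(frozen=True)
class MagnificationModel:
    """Areal cortical magnification M0*(A/(ecc+e2))^2*(1+alpha*cos2t-gamma*sint).

    Parameters
    ----------
    M0 : overall scale. With A, e2 at defaults, M0 is tuned via
        :meth:`scaled_to_v1_area` to give realistic V1 sizes (~1500 mm^2 per
        hemisphere within 8 deg).
    A, e2 : linear magnification parameters, m(ecc) = A/(ecc+e2) in mm/deg.
    alpha : HVA amplitude of the cos(2*theta) term (dimensionless).
    gamma : VMA amplitude of the -sin(theta) term (dimensionless).
    """

    M0: float = 1.0
    A: float = 17.3
    e2: float = 0.75
    alpha: float = 0.0
    gamma: float = 0.0

    def __post_init__(self):
        if self.M0 <= 0 or self.A <= 0 or self.e2 <= 0:
            raise ValueError("M0, A and e2 must be positive")

    def linear(self, ecc):
        """Linear magnification m(ecc) = A/(ecc+e2), mm per deg."""
        return self.A / (np.asarray(ecc, dtype=float) + self.e2)

    def angular(self, theta_deg):
        """Angular modulation f(theta) = 1 + alpha*cos(2t) - gamma*sin(t)."""
        t = np.deg2rad(np.asarray(theta_deg, dtype=float))
        return 1.0 + self.alpha * np.cos(2 * t) - self.gamma * np.sin(t)

    def areal(self, ecc, theta_deg):
        """Areal magnification (mm^2 per deg^2)."""
        return self.M0 * self.linear(ecc) ** 2 * self.angular(theta_deg)

    def angular_integral(self, theta_deg):
        """G(theta) = integral of f from 0 of the angular modulation (radians in)."""
        t = np.deg2rad(np.asarray(theta_deg, dtype=float))
        return t + 0.5 * self.alpha * np.sin(2 * t) + self.gamma * (np.cos(t) - 1.0)

    def radial_integral(self, ecc_lo: float, ecc_hi: float) -> float:
        """Integral of m(e)^2 * e de over [ecc_lo, ecc_hi] (closed form)."""
        def F(e):
            return self.A**2 * (np.log(e + self.e2) + self.e2 / (e + self.e2))
        return float(F(ecc_hi) - F(ecc_lo))

    @classmethod
    def from_asymmetries(cls, hva: float, vma: float, **kwargs) -> "MagnificationModel":
        """Choose (alpha, gamma) so the analytic +/-15 deg wedge areas carry the
        given HVA and VMA indices (difference over mean, x100)."""
        a = hva / 200.0 / _COS2_WEDGE_MEAN
        g = vma * (1.0 - a * _COS2_WEDGE_MEAN) / 200.0 / _SIN_WEDGE_MEAN
        return cls(alpha=a, gamma=g, **kwargs)

    def scaled_to_v1_area(self, v1_area_both_hemis: float,
                          ecc_max: float = 8.0, ecc_min: float = 0.0
                          ) -> "MagnificationModel":
        """Rescale M0 so total V1 area (both hemispheres, to ecc_max) matches."""
        full = self.M0 * self.radial_integral(ecc_min, ecc_max) * 2.0 * np.pi
        return replace(self, M0=self.M0 * v1_area_both_hemis / full)


@dataclass
class CorticalMesh:
    """Triangulated hemisphere surface with per-vertex retinotopy and area.

    ``vertex_area`` holds each vertex's share of the surface (one third of
    its incident triangle areas, times any depth scaling), so areas sum to
    the total triangulated area at depth scale 1.
    """

    hemisphere: str
    depth: str
    vertices: np.ndarray          # (n, 2) or (n, 3) mm
    faces: np.ndarray             # (m, 3) int
    vertex_area: np.ndarray       # (n,) mm^2
    polar_angle: np.ndarray       # (n,) deg in [0, 360)
    eccentricity: np.ndarray      # (n,) deg

    def __post_init__(self):
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise ValueError("face indices out of range")
        if np.any(self.vertex_area < 0):
            raise ValueError("vertex areas must be non-negative")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def triangle_areas(self) -> np.ndarray:
        p = self.vertices[self.faces]
        e1 = p[:, 1] - p[:, 0]
        e2 = p[:, 2] - p[:, 0]
        if p.shape[2] == 2:
            cross = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
            return 0.5 * np.abs(cross)
        return 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)

    def total_area(self) -> float:
        return float(self.vertex_area.sum())

    def edges(self) -> np.ndarray:
        """Unique undirected edges, (k, 2) int."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                       self.faces[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    # --- plain-text interchange -------------------------------------------
    def to_json(self, path: str) -> None:
        bundle = {
            "hemisphere": self.hemisphere,
            "depth": self.depth,
            "vertices": self.vertices.tolist(),
            "faces": self.faces.tolist(),
            "vertex_area": self.vertex_area.tolist(),
            "polar_angle": self.polar_angle.tolist(),
            "eccentricity": self.eccentricity.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(bundle, fh)

    @classmethod
    def from_json(cls, path: str) -> "CorticalMesh":
        with open(path) as fh:
            b = json.load(fh)
        return cls(
            hemisphere=b["hemisphere"], depth=b["depth"],
            vertices=np.asarray(b["vertices"], dtype=float),
            faces=np.asarray(b["faces"], dtype=int),
            vertex_area=np.asarray(b["vertex_area"], dtype=float),
            polar_angle=np.asarray(b["polar_angle"], dtype=float),
            eccentricity=np.asarray(b["eccentricity"], dtype=float),
        )


def make_synthetic_hemisphere(
    magnification: MagnificationModel,
    n_ecc_rings: int = 96,
    n_angle_spokes: int = 145,
    ecc_range: tuple[float, float] = (0.2, 12.0),
    depth_scale: float = 1.0,
    hemisphere: str = "left",
    depth: str = "midgray",
    seed: int | None = None,
) -> CorticalMesh:
    """Build one hemisphere's V1 sheet with the prescribed magnification.

    The grid is log-spaced in eccentricity and uniform in polar angle over
    the hemifield the hemisphere serves (vertical-meridian spokes are present
    on both hemispheres; each carries only its own hemifield's triangles, so
    wedge areas are never double counted).  ``seed`` is accepted for interface
    uniformity; construction is deterministic.
    """
    if n_ecc_rings < 2 or n_angle_spokes < 3:
        raise ValueError("need n_ecc_rings >= 2 and n_angle_spokes >= 3")
    e_lo, e_hi = ecc_range
    if not (0.0 < e_lo < e_hi <= 12.4):
        raise ValueError("ecc_range must satisfy 0 < lo < hi <= 12.4")
    if hemisphere not in HEMIFIELD_CENTER:
        raise ValueError(f"unknown hemisphere {hemisphere!r}")

    center = HEMIFIELD_CENTER[hemisphere]
    eccs = np.geomspace(e_lo, e_hi, n_ecc_rings)
    thetas = center + np.linspace(-90.0, 90.0, n_angle_spokes)

    E, T = np.meshgrid(eccs, thetas, indexing="ij")
    f = magnification.angular(T)
    if np.any(f <= 0):
        i, j = np.unravel_index(np.argmin(f), f.shape)
        raise ValueError(
            f"non-positive magnification at ecc={E[i, j]:.2f} deg, "
            f"theta={T[i, j]:.1f} deg; reduce alpha/gamma")

    sqrtM0 = np.sqrt(magnification.M0)
    # radial coordinate: integral of the linear magnification
    u = sqrtM0 * magnification.A * np.log((E + magnification.e2)
                                          / (e_lo + magnification.e2))
    # tangential coordinate: ring arc-length density times angular integral
    G = magnification.angular_integral(T) - magnification.angular_integral(center)
    v = sqrtM0 * magnification.linear(E) * E * G

    vertices = np.column_stack([u.ravel(), v.ravel()])
    polar_angle = np.mod(T.ravel(), 360.0)
    eccentricity = E.ravel()

    # two triangles per grid quad
    idx = np.arange(n_ecc_rings * n_angle_spokes).reshape(n_ecc_rings,
                                                          n_angle_spokes)
    a = idx[:-1, :-1].ravel()
    b = idx[:-1, 1:].ravel()
    c = idx[1:, :-1].ravel()
    d = idx[1:, 1:].ravel()
    faces = np.vstack([np.column_stack([a, b, c]),
                       np.column_stack([b, d, c])])

    mesh = CorticalMesh(
        hemisphere=hemisphere, depth=depth, vertices=vertices, faces=faces,
        vertex_area=np.zeros(len(vertices)), polar_angle=polar_angle,
        eccentricity=eccentricity)
    tri = mesh.triangle_areas()
    area = np.zeros(len(vertices))
    np.add.at(area, faces.ravel(), np.repeat(tri / 3.0, 3))
    mesh.vertex_area = area * depth_scale
    return mesh


def make_depth_surfaces(mesh: CorticalMesh, pial_factor: float = 1.2,
                        white_factor: float = 0.85,
                        modulation_amp: float = 0.08,
                        seed: int = 0) -> dict[str, CorticalMesh]:
    """Emulate pial and white surfaces by per-vertex area scaling.

    The analysis only consumes vertex-area maps per depth, so the depth
    surfaces share the midgray geometry: their areas are the midgray areas
    times a global depth factor and a smooth gyral/sulcal-like modulation
    (anticorrelated between pial and white).
    """
    rng = np.random.default_rng(seed)
    # smooth pseudo-curvature field: low-frequency sinusoid mixture
    xy = mesh.vertices - mesh.vertices.mean(axis=0)
    scale = np.abs(xy).max() + 1e-9
    phases = rng.uniform(0, 2 * np.pi, size=3)
    freqs = rng.uniform(1.0, 3.0, size=(3, 2))
    curv = np.zeros(mesh.n_vertices)
    for (fx, fy), ph in zip(freqs, phases):
        curv += np.sin(fx * np.pi * xy[:, 0] / scale
                       + fy * np.pi * xy[:, 1] / scale + ph)
    curv /= np.abs(curv).max() + 1e-9

    out = {"midgray": mesh}
    for depth, factor, sign in (("pial", pial_factor, 1.0),
                                ("white", white_factor, -1.0)):
        area = mesh.vertex_area * factor * (1.0 + sign * modulation_amp * curv)
        out[depth] = CorticalMesh(
            hemisphere=mesh.hemisphere, depth=depth, vertices=mesh.vertices,
            faces=mesh.faces, vertex_area=np.clip(area, 0.0, None),
            polar_angle=mesh.polar_angle, eccentricity=mesh.eccentricity)
    return out


def wedge_area_analytic(model: MagnificationModel, meridian_deg: float,
                        half_width_deg: float = 15.0,
                        ecc_range: tuple[float, float] = (1.0, 8.0)) -> float:
    """Closed-form area (mm^2) of a wedge of visual field under the model.

    Integrates M(ecc, theta) * ecc over ecc in ``ecc_range`` and theta within
    ``half_width_deg`` of the meridian.  This is the oracle the mesh-based
    wedge-ROI measurement is checked against.
    """
    ang = (model.angular_integral(meridian_deg + half_width_deg)
           - model.angular_integral(meridian_deg - half_width_deg))
    return model.M0 * model.radial_integral(*ecc_range) * float(ang)


def sector_area_analytic(model: MagnificationModel, theta_lo: float,
                         theta_hi: float,
                         ecc_range: tuple[float, float]) -> float:
    """Area (mm^2) of an arbitrary angular sector of the visual field."""
    ang = (model.angular_integral(theta_hi) - model.angular_integral(theta_lo))
    return model.M0 * model.radial_integral(*ecc_range) * float(ang)
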