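"""Wedge-ROI cortical magnification on triangulated retinotopic meshes.

A wedge-ROI is the cortical patch representing a +/-15 deg polar-angle
sector of the visual field centred on a cardinal meridian, between 1 and 8
deg of eccentricity.  Rather than thresholding pRF polar-angle estimates
directly (which produces speckled ROIs), the boundary is found in cortical
distance: within each of 10 log-spaced eccentricity bands, the cortical
distance of the 15 deg iso-angle line from the meridian is estimated as the
mean geodesic distance of vertices whose pRF angles lie within +/-8 deg of
the 15 deg boundary; vertices closer to the meridian than that distance form
the band's sub-wedge, and the union over bands is the wedge-ROI mask.  Its
surface area is the sum of the member vertices' area at the chosen depth.

Each hemisphere carries one hemifield, so the horizontal-meridian wedge of
one hemifield lives entirely in one hemisphere while the vertical-meridian
wedges are split, 15 deg per hemisphere; upper and lower vertical areas are
summed across hemispheres, and the full vertical meridian is their sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .mesh import CorticalMesh
from .prf import PRFFit

__all__ = [
    "RetinotopyMap",
    "DistanceMap",
    "WedgeConfig",
    "WedgeROIMask",
    "hemisphere_meridians",
    "angular_offset",
    "meridian_line_vertices",
    "cortical_distance_map",
    "log_spaced_bands",
    "isoangle_boundary_distance",
    "build_wedge_mask",
    "wedge_surface_area",
    "combine_meridian_areas",
    "v1_total_area",
    "measure_wedge_areas",
]

#: visual-field polar angle (deg) of each cardinal meridian, and which
#: hemisphere's hemifield contains the corresponding wedge (left hemisphere
#: serves the right visual hemifield)
MERIDIAN_ANGLES = {"HM_right": 0.0, "UVM": 90.0, "HM_left": 180.0, "LVM": 270.0}


def hemisphere_meridians(hemisphere: str) -> dict[str, float]:
    """Meridians measurable on one hemisphere (VM wedges appear on both)."""
    if hemisphere == "left":
        return {"HM_right": 0.0, "UVM": 90.0, "LVM": 270.0}
    if hemisphere == "right":
        return {"HM_left": 180.0, "UVM": 90.0, "LVM": 270.0}
    raise ValueError(f"unknown hemisphere {hemisphere!r}")


@dataclass
class RetinotopyMap:
    """Per-vertex polar angle (deg), eccentricity (deg) and inclusion flag."""

    polar_angle: np.ndarray
    eccentricity: np.ndarray
    included: np.ndarray

    @classmethod
    def from_mesh(cls, mesh: CorticalMesh) -> "RetinotopyMap":
        """Ground-truth retinotopy of a synthetic mesh (all vertices included)."""
        return cls(polar_angle=mesh.polar_angle,
                   eccentricity=mesh.eccentricity,
                   included=np.ones(mesh.n_vertices, dtype=bool))

    @classmethod
    def from_fits(cls, fits: list[PRFFit]) -> "RetinotopyMap":
        return cls(
            polar_angle=np.array([f.polar_angle for f in fits]),
            eccentricity=np.array([f.eccentricity for f in fits]),
            included=np.array([f.included for f in fits], dtype=bool))


@dataclass
class DistanceMap:
    """Geodesic distance (mm) of every vertex from a meridian line-ROI."""

    distances: np.ndarray
    meridian: str
    seeds: np.ndarray

    @property
    def unreachable(self) -> np.ndarray:
        return ~np.isfinite(self.distances)


@dataclass
class WedgeConfig:
    """Wedge-ROI parameters (defaults follow the analysis conventions)."""

    half_width: float = 15.0        # deg of polar angle either side of meridian
    pool_half_width: float = 8.0    # deg around the iso-angle line
    ecc_range: tuple[float, float] = (1.0, 8.0)
    n_bands: int = 10
    depth: str = "midgray"
    meridian_angle_tol: float = 2.0  # deg, line-ROI selection
    pool_widen_step: float = 4.0     # deg, one-shot empty-pool fallback

    def __post_init__(self):
        if self.half_width <= 0 or self.pool_half_width <= 0:
            raise ValueError("half-widths must be positive")
        if self.n_bands < 1:
            raise ValueError("n_bands must be >= 1")
        if not self.ecc_range[0] < self.ecc_range[1]:
            raise ValueError("ecc_range must be increasing")


@dataclass
class WedgeROIMask:
    """Vertex set of one wedge-ROI plus per-band boundary distances (mm)."""

    meridian: str
    hemisphere: str
    vertex_indices: np.ndarray
    band_distances: list[float | None] = field(default_factory=list)


def angular_offset(theta_deg, meridian_deg) -> np.ndarray:
    """Unsigned circular distance (deg) between polar angles, in [0, 180]."""
    d = np.mod(np.asarray(theta_deg, dtype=float) - meridian_deg + 180.0,
               360.0) - 180.0
    return np.abs(d)


def meridian_line_vertices(
    retinotopy: RetinotopyMap,
    mesh: CorticalMesh,
    meridian: str,
    angle_tol: float = 2.0,
    n_ecc_bins: int = 32,
    ecc_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Automated line-ROI: vertices along a meridian's representation.

    Included vertices within ``angle_tol`` of the meridian are binned by
    eccentricity (log-spaced over ``ecc_range`` or the mapped range) and the
    angularly closest vertex per bin is kept, giving a thin path that spans
    the eccentricity range.
    """
    target = MERIDIAN_ANGLES[meridian]
    offset = angular_offset(retinotopy.polar_angle, target)
    cand = np.flatnonzero(retinotopy.included & (offset <= angle_tol))
    if cand.size == 0:
        raise ValueError(
            f"no vertices within {angle_tol} deg of {meridian}; "
            "increase angle_tol")
    ecc = retinotopy.eccentricity[cand]
    lo, hi = ecc_range if ecc_range is not None else (max(ecc.min(), 1e-3),
                                                      ecc.max())
    edges = np.geomspace(max(lo, 1e-3), hi, n_ecc_bins + 1)
    keep = []
    which = np.searchsorted(edges, ecc, side="right") - 1
    for b in range(n_ecc_bins):
        in_bin = np.flatnonzero(which == b)
        if in_bin.size:
            keep.append(cand[in_bin[np.argmin(offset[cand][in_bin])]])
    return np.array(sorted(set(keep)), dtype=int)


def cortical_distance_map(mesh: CorticalMesh, seeds: np.ndarray,
                          meridian: str = "") -> DistanceMap:
    """Multi-source shortest-path distance (mm) along mesh edges.

    Seed vertices are at exactly 0 mm; vertices disconnected from every seed
    get +inf and are flagged via :attr:`DistanceMap.unreachable`.
    """
    seeds = np.asarray(seeds, dtype=int)
    if seeds.size == 0:
        raise ValueError("seed set must be non-empty")
    edges = mesh.edges()
    lengths = np.linalg.norm(mesh.vertices[edges[:, 0]]
                             - mesh.vertices[edges[:, 1]], axis=1)
    n = mesh.n_vertices
    graph = coo_matrix(
        (np.concatenate([lengths, lengths]),
         (np.concatenate([edges[:, 0], edges[:, 1]]),
          np.concatenate([edges[:, 1], edges[:, 0]]))),
        shape=(n, n)).tocsr()
    dist = dijkstra(graph, directed=False, indices=seeds, min_only=True)
    return DistanceMap(distances=dist, meridian=meridian, seeds=seeds)


def log_spaced_bands(ecc_min: float = 1.0, ecc_max: float = 8.0,
                     n_bands: int = 10) -> np.ndarray:
    """n_bands+1 geometrically spaced eccentricity band edges."""
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    if not 0 < ecc_min < ecc_max:
        raise ValueError("need 0 < ecc_min < ecc_max")
    return np.geomspace(ecc_min, ecc_max, n_bands + 1)


def isoangle_boundary_distance(
    band: tuple[float, float],
    dist: DistanceMap,
    retinotopy: RetinotopyMap,
    meridian_deg: float,
    boundary_angle: float = 15.0,
    pool_half_width: float = 8.0,
) -> float | None:
    """Mean cortical distance (mm) of the iso-angle line within one band.

    Pools included vertices whose pRF eccentricity falls in the band and
    whose angular offset from the meridian lies within ``pool_half_width``
    of ``boundary_angle``.  Returns None when the pool is empty.
    """
    lo, hi = band
    offset = angular_offset(retinotopy.polar_angle, meridian_deg)
    pool = (retinotopy.included
            & (retinotopy.eccentricity >= lo)
            & (retinotopy.eccentricity < hi)
            & (np.abs(offset - boundary_angle) <= pool_half_width)
            & np.isfinite(dist.distances))
    if not np.any(pool):
        return None
    return float(dist.distances[pool].mean())


def build_wedge_mask(
    dist: DistanceMap,
    retinotopy: RetinotopyMap,
    cfg: WedgeConfig,
    meridian: str,
    hemisphere: str = "",
) -> WedgeROIMask:
    """Assemble the wedge-ROI from per-band distance thresholds.

    Per band, included vertices whose pRF eccentricity is in the band and
    whose cortical distance from the meridian is at most the band's boundary
    distance join the mask; bands with an empty pool are retried once with a
    pool widened by ``cfg.pool_widen_step`` and excluded if still empty.
    """
    meridian_deg = MERIDIAN_ANGLES[meridian]
    edges = log_spaced_bands(*cfg.ecc_range, cfg.n_bands)
    members: list[np.ndarray] = []
    band_distances: list[float | None] = []
    for b in range(cfg.n_bands):
        band = (edges[b], edges[b + 1])
        d = isoangle_boundary_distance(band, dist, retinotopy, meridian_deg,
                                       cfg.half_width, cfg.pool_half_width)
        if d is None:
            d = isoangle_boundary_distance(
                band, dist, retinotopy, meridian_deg, cfg.half_width,
                cfg.pool_half_width + cfg.pool_widen_step)
        band_distances.append(d)
        if d is None:
            continue
        hi_edge = edges[b + 1] if b < cfg.n_bands - 1 else edges[b + 1] + 1e-9
        sel = (retinotopy.included
               & (retinotopy.eccentricity >= edges[b])
               & (retinotopy.eccentricity < hi_edge)
               & (dist.distances <= d))
        members.append(np.flatnonzero(sel))
    if all(d is None for d in band_distances):
        raise ValueError(f"every band of the {meridian} wedge had an empty "
                         "pool; check retinotopy coverage")
    idx = (np.unique(np.concatenate(members)) if members
           else np.empty(0, dtype=int))
    return WedgeROIMask(meridian=meridian, hemisphere=hemisphere,
                        vertex_indices=idx, band_distances=band_distances)


def wedge_surface_area(mask: WedgeROIMask, mesh: CorticalMesh) -> float:
    """Summed vertex surface area (mm^2) of the wedge-ROI at the mesh depth."""
    if mask.vertex_indices.size and mask.vertex_indices.max() >= mesh.n_vertices:
        raise IndexError("mask indices out of range for this mesh")
    return float(mesh.vertex_area[mask.vertex_indices].sum())


def combine_meridian_areas(
    left_hemi: dict[str, float], right_hemi: dict[str, float]
) -> dict[str, float]:
    """Combine per-hemisphere wedge areas into the reported meridian areas.

    The horizontal-meridian wedges live entirely in one hemisphere each
    (right visual field -> left hemisphere and vice versa); the vertical-
    meridian wedges are summed across their two hemifield halves, and the
    full vertical meridian is UVM + LVM.  ``HM`` sums both horizontal wedges.
    """
    for need, d, name in (("HM_right", left_hemi, "left"),
                          ("HM_left", right_hemi, "right")):
        if need not in d or "UVM" not in d or "LVM" not in d:
            raise ValueError(f"{name} hemisphere is missing meridian areas")
    out = {
        "HM_left": right_hemi["HM_left"],
        "HM_right": left_hemi["HM_right"],
        "UVM": left_hemi["UVM"] + right_hemi["UVM"],
        "LVM": left_hemi["LVM"] + right_hemi["LVM"],
    }
    out["HM"] = out["HM_left"] + out["HM_right"]
    out["VM"] = out["UVM"] + out["LVM"]
    return out


def v1_total_area(mesh: CorticalMesh, retinotopy: RetinotopyMap | None = None,
                  ecc_max: float = 8.0) -> float:
    """V1 surface area (mm^2, one hemisphere) within ``ecc_max`` eccentricity."""
    if retinotopy is None:
        retinotopy = RetinotopyMap.from_mesh(mesh)
    sel = retinotopy.eccentricity <= ecc_max
    return float(mesh.vertex_area[sel].sum())


def measure_wedge_areas(
    mesh: CorticalMesh,
    retinotopy: RetinotopyMap | None = None,
    cfg: WedgeConfig | None = None,
) -> tuple[dict[str, float], dict[str, WedgeROIMask]]:
    """Full wedge-ROI measurement for one hemisphere.

    Returns (areas, masks) keyed by the meridians this hemisphere serves.
    """
    cfg = cfg or WedgeConfig()
    if retinotopy is None:
        retinotopy = RetinotopyMap.from_mesh(mesh)
    areas: dict[str, float] = {}
    masks: dict[str, WedgeROIMask] = {}
    for meridian in hemisphere_meridians(mesh.hemisphere):
        seeds = meridian_line_vertices(
            retinotopy, mesh, meridian, angle_tol=cfg.meridian_angle_tol,
            ecc_range=cfg.ecc_range)
        dist = cortical_distance_map(mesh, seeds, meridian)
        mask = build_wedge_mask(dist, retinotopy, cfg, meridian,
                                mesh.hemisphere)
        masks[meridian] = mask
        areas[meridian] = wedge_surface_area(mask, mesh)
    return areas, masks
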