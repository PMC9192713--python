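"""Synthetic observer cohorts with planted asymmetries, and Weibull observers.

The cohort generator plants the population structure the asymmetry analysis
assumes: a roughly twofold spread in V1 size across observers, group-level
horizontal-vertical (HVA) and vertical-meridian (VMA) asymmetries in both
wedge-ROI surface area and contrast sensitivity, and a tunable monotone
coupling between local surface area and sensitivity.  All quantities refer
to the four polar-angle locations at which sensitivity is measured:
``HM_left`` and ``HM_right`` (left/right horizontal meridian), ``UVM`` and
``LVM`` (upper/lower vertical meridian).

A Weibull psychometric observer turns a threshold contrast into stochastic
2AFC responses; its threshold parameter ``c_star`` is defined at the
staircase's convergence accuracy (79.4% for 3-down-1-up), so staircase
estimates are directly comparable to the planted value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .mesh import MagnificationModel

__all__ = [
    "LOCATIONS",
    "PsychometricObserver",
    "respond",
    "SubjectGroundTruth",
    "make_cohort",
    "cohort_to_frame",
    "planted_pooled_spearman",
]

LOCATIONS: tuple[str, ...] = ("HM_left", "HM_right", "UVM", "LVM")

#: accuracy at which a 3-down-1-up staircase converges: p^3 = 1/2
TARGET_ACCURACY = 0.5 ** (1.0 / 3.0)


@dataclass(frozen=True)
class PsychometricObserver:
    """2AFC Weibull observer.

    P(correct | c) = guess + (1 - guess - lapse) * (1 - exp(-(c/scale)^slope)),
    with ``scale`` solved so that P(correct | c_star) equals
    ``target_accuracy`` — i.e. ``c_star`` is the threshold the staircase is
    designed to estimate.
    """

    c_star: float
    slope: float = 3.5
    guess: float = 0.5
    lapse: float = 0.01
    target_accuracy: float = TARGET_ACCURACY

    def __post_init__(self):
        if not 0 < self.c_star <= 1:
            raise ValueError("c_star must be Michelson contrast in (0, 1]")
        upper = 1.0 - self.lapse
        if not self.guess < self.target_accuracy < upper:
            raise ValueError("target accuracy must lie between guess and 1-lapse")

    @property
    def scale(self) -> float:
        frac = (self.target_accuracy - self.guess) / (1.0 - self.guess - self.lapse)
        w = -np.log1p(-frac)
        return self.c_star / w ** (1.0 / self.slope)

    def p_correct(self, contrast) -> np.ndarray | float:
        c = np.asarray(contrast, dtype=float)
        p = self.guess + (1.0 - self.guess - self.lapse) * (
            1.0 - np.exp(-((c / self.scale) ** self.slope)))
        return float(p) if np.isscalar(contrast) else p


def respond(observer: PsychometricObserver, contrast: float,
            rng: np.random.Generator) -> bool:
    """One Bernoulli 2AFC trial at the given Michelson contrast."""
    if not 0 < contrast <= 1:
        raise ValueError("contrast must be in (0, 1]")
    return bool(rng.random() < observer.p_correct(contrast))


@dataclass
class SubjectGroundTruth:
    """Planted per-observer quantities the pipeline tries to recover."""

    observer_id: str
    v1_area_mm2: float                       # both hemispheres, 0-8 deg
    cortex_area_mm2: float                   # both hemispheres
    wedge_areas: dict[str, float]            # mm^2 per location (full +/-15 deg)
    contrast_sensitivity: dict[str, float]   # 1 / threshold contrast
    observers: dict[str, PsychometricObserver] = field(default_factory=dict)

    def __post_init__(self):
        for loc in LOCATIONS:
            if self.wedge_areas.get(loc, 0) <= 0:
                raise ValueError(f"non-positive wedge area at {loc}")
            if self.contrast_sensitivity.get(loc, 0) <= 0:
                raise ValueError(f"non-positive sensitivity at {loc}")


def _index_weights(hva: float, vma: float) -> dict[str, float]:
    """Location weights (mean 1) realizing the given asymmetry indices.

    HVA/VMA indices are difference-over-mean x 100, so weight 1 +/- index/200
    splits exactly: HM weights (1+a) each, UVM/LVM weights (1-a)(1 -/+ b).
    """
    a, b = hva / 200.0, vma / 200.0
    if not (-1 < a < 1 and -1 < b < 1):
        raise ValueError("asymmetry index magnitude must be < 200")
    return {
        "HM_left": 1.0 + a,
        "HM_right": 1.0 + a,
        "UVM": (1.0 - a) * (1.0 - b),
        "LVM": (1.0 - a) * (1.0 + b),
    }


def wedge_share(model: MagnificationModel | None = None,
                ecc_range: tuple[float, float] = (1.0, 8.0),
                v1_ecc_max: float = 8.0, half_width_deg: float = 15.0) -> float:
    """Fraction of V1 area (0 to v1_ecc_max) inside one isotropic +/-15 wedge."""
    model = model or MagnificationModel()
    r_wedge = model.radial_integral(*ecc_range)
    r_v1 = model.radial_integral(0.0, v1_ecc_max)
    return (2 * half_width_deg / 360.0) * r_wedge / r_v1


def make_cohort(
    n_observers: int = 29,
    size_spread: float = 2.0,
    group_hva_sa: float = 60.0,
    group_vma_sa: float = 25.0,
    group_hva_cs: float = 50.0,
    group_vma_cs: float = 20.0,
    coupling: float = 0.8,
    noise_sd: float = 0.05,
    index_sd: float = 15.0,
    mean_v1_area: float = 2900.0,
    mean_cortex_area: float = 200_000.0,
    mean_cs: float = 45.0,
    observer_cs_sd: float = 0.12,
    slope: float = 3.5,
    lapse: float = 0.01,
    seed: int = 0,
) -> list[SubjectGroundTruth]:
    """Generate a cohort with planted sizes, asymmetries and SA-CS coupling.

    Parameters
    ----------
    size_spread : expected max/min ratio of V1 sizes across the cohort.
    group_* : group-mean asymmetry indices (%) for surface area (sa) and
        contrast sensitivity (cs); per-observer indices are jittered with SD
        ``index_sd``.
    coupling : in [0, 1]. 1 makes log sensitivity a deterministic monotone
        function of the corresponding wedge area (pooled Spearman rho = 1 at
        zero noise); 0 makes sensitivity independent of area while still
        carrying the planted behavioral asymmetries.
    noise_sd : SD of multiplicative (log-normal) noise on areas and
        sensitivities.
    observer_cs_sd : between-observer SD of the area-independent log
        sensitivity trait.
    """
    if n_observers < 2:
        raise ValueError("need at least 2 observers")
    if not 0.0 <= coupling <= 1.0:
        raise ValueError("coupling must be in [0, 1]")
    rng = np.random.default_rng(seed)

    # log-normal V1 sizes: SD chosen so the expected extreme ratio over
    # n draws matches size_spread (Blom approximation for E[max z])
    z_extreme = norm.ppf((n_observers - 0.375) / (n_observers + 0.25))
    log_sd = np.log(size_spread) / (2.0 * z_extreme) if size_spread > 1 else 0.0
    z = rng.standard_normal(n_observers)
    v1 = mean_v1_area * np.exp(log_sd * z - 0.5 * log_sd**2)
    # total cortex varies much less than V1 and is only weakly coupled to it
    cortex = mean_cortex_area * np.exp(
        0.3 * log_sd * z + 0.06 * rng.standard_normal(n_observers))

    base_wedge = wedge_share() * v1

    # exponent mapping SA ratios to CS ratios so that the planted group SA
    # asymmetries induce the planted CS asymmetries under full coupling
    def _ratio(idx):
        return (1.0 + idx / 200.0) / (1.0 - idx / 200.0)
    q_terms = [np.log(_ratio(c)) / np.log(_ratio(s))
               for c, s in ((group_hva_cs, group_hva_sa),
                            (group_vma_cs, group_vma_sa))
               if abs(s) > 1e-12]
    q = float(np.mean(q_terms)) if q_terms else 1.0

    cohort: list[SubjectGroundTruth] = []
    for i in range(n_observers):
        hva_sa = rng.normal(group_hva_sa, index_sd)
        vma_sa = rng.normal(group_vma_sa, index_sd)
        hva_cs_ind = rng.normal(group_hva_cs, index_sd)
        vma_cs_ind = rng.normal(group_vma_cs, index_sd)

        w_sa = _index_weights(hva_sa, vma_sa)
        areas = {loc: base_wedge[i] * w_sa[loc]
                 * np.exp(rng.normal(0.0, noise_sd)) for loc in LOCATIONS}

        # area-driven sensitivity: monotone in the pooled wedge area
        log_cs_area = {loc: np.log(mean_cs)
                       + q * (np.log(areas[loc]) - np.log(wedge_share() * mean_v1_area))
                       for loc in LOCATIONS}
        # independent behavioral trait with its own planted asymmetries
        w_cs = _index_weights(hva_cs_ind, vma_cs_ind)
        trait = rng.normal(0.0, observer_cs_sd)
        log_cs_ind = {loc: np.log(mean_cs * w_cs[loc]) + trait
                      for loc in LOCATIONS}

        cs = {}
        for loc in LOCATIONS:
            # noise draw always taken so a noise_sd=0 run is the exact
            # noiseless twin of a noisy run with the same seed
            log_cs = (coupling * log_cs_area[loc]
                      + (1.0 - coupling) * log_cs_ind[loc]
                      + rng.normal(0.0, noise_sd))
            cs[loc] = float(np.exp(log_cs))

        observers = {
            loc: PsychometricObserver(
                c_star=float(np.clip(1.0 / cs[loc], 1e-3, 1.0)),
                slope=slope, lapse=lapse)
            for loc in LOCATIONS
        }
        cohort.append(SubjectGroundTruth(
            observer_id=f"S{i + 1:03d}",
            v1_area_mm2=float(v1[i]),
            cortex_area_mm2=float(cortex[i]),
            wedge_areas={k: float(v) for k, v in areas.items()},
            contrast_sensitivity=cs,
            observers=observers,
        ))
    return cohort


def cohort_to_frame(cohort: list[SubjectGroundTruth]) -> pd.DataFrame:
    """Tidy frame: one row per observer x location (the CSV interchange schema)."""
    rows = []
    for s in cohort:
        for loc in LOCATIONS:
            rows.append({
                "observer_id": s.observer_id,
                "location": loc,
                "contrast_sensitivity": s.contrast_sensitivity[loc],
                "wedge_area_mm2": s.wedge_areas[loc],
                "v1_area_mm2": s.v1_area_mm2,
                "cortex_area_mm2": s.cortex_area_mm2,
            })
    return pd.DataFrame(rows)


def planted_pooled_spearman(cohort: list[SubjectGroundTruth]) -> float:
    """Pooled Spearman rho of (sensitivity, wedge area) on the planted values."""
    from scipy.stats import spearmanr

    cs = [s.contrast_sensitivity[loc] for s in cohort for loc in LOCATIONS]
    sa = [s.wedge_areas[loc] for s in cohort for loc in LOCATIONS]
    return float(spearmanr(cs, sa).statistic)
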