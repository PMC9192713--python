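"""End-to-end orchestration: synthesize -> measure -> correlate.

``run_pipeline`` wires the stages together under one seeded config:

1. generate a synthetic observer cohort with planted V1 sizes, wedge-ROI
   areas and contrast sensitivities;
2. measure each observer's sensitivities behaviorally with interleaved
   3-down-1-up PEST staircases (or copy the planted values);
3. measure each observer's wedge-ROI surface areas on synthetic cortical
   meshes realized from their planted magnification (or copy the planted
   areas);
4. optionally simulate BOLD for one or more observers and refit the pRF
   model as a recovery diagnostic;
5. run the asymmetry statistics: per-observer indices, group paired tests,
   the pooled sensitivity-area Spearman correlation and its two shuffle
   nulls, and centered / V1-size correlations.

Everything is reproducible from (config, seed); the report is a plain dict
that serializes to JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bold, wedge
from .cohort import LOCATIONS, SubjectGroundTruth, make_cohort
from .mesh import MagnificationModel, make_synthetic_hemisphere
from .prf import PRFGridSpec, fit_prf_coarse_to_fine, hrf_double_gamma
from .staircase import aggregate_observer, run_observer
from .stats import (CohortTable, center_data, hva_index, observer_indices,
                    paired_t, pooled_correlation, shuffle_null, spearman_rho,
                    vma_index)
from .stimulus import make_bar_aperture
from .wedge import WedgeConfig

__all__ = ["RunConfig", "run_pipeline", "load_cohort_csv", "save_cohort_csv",
           "measure_observer_areas"]


@dataclass
class RunConfig:
    """Single-file configuration for a full pipeline run."""

    seed: int = 0
    # cohort
    n_observers: int = 29
    cohort_kwargs: dict = field(default_factory=dict)
    # behavioral measurement
    behavior: str = "staircase"            # "staircase" | "planted"
    n_blocks: int = 5
    n_trials_per_location: int = 50
    # cortical measurement
    sa_source: str = "mesh"                # "mesh" | "planted"
    mesh_rings: int = 96
    mesh_spokes: int = 145
    mesh_ecc_range: tuple[float, float] = (0.2, 12.0)
    wedge_kwargs: dict = field(default_factory=dict)
    # pRF recovery diagnostic
    n_fit_observers: int = 1
    n_fit_vertices: int = 200
    fit_mesh_rings: int = 18
    fit_mesh_spokes: int = 25
    bold_noise_sd: float = 0.3
    stim_grid_size: int = 101
    # statistics
    n_null_iter: int = 10_000
    output_dir: str | None = None

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "mesh_ecc_range" in raw:
            raw["mesh_ecc_range"] = tuple(raw["mesh_ecc_range"])
        return cls(**raw)


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) % (2**31) for s in
            np.random.SeedSequence(seed).generate_state(n)]


def measure_observer_areas(
    subject: SubjectGroundTruth,
    rings: int = 96,
    spokes: int = 145,
    ecc_range: tuple[float, float] = (0.2, 12.0),
    wedge_cfg: WedgeConfig | None = None,
) -> tuple[dict[str, float], float]:
    """Wedge-ROI areas and V1 size measured on this observer's cortex.

    Realizes left and right hemisphere meshes carrying the observer's
    planted magnification (asymmetries taken from the planted wedge areas,
    scale from the planted V1 size) and runs the full distance-map wedge
    measurement on each.  Returns (areas at the four locations, V1 area).
    """
    wa = subject.wedge_areas
    hva = hva_index(wa["HM_left"] + wa["HM_right"], wa["UVM"] + wa["LVM"])
    vma = vma_index(wa["LVM"], wa["UVM"])
    model = MagnificationModel.from_asymmetries(hva, vma).scaled_to_v1_area(
        subject.v1_area_mm2)
    per_hemi = {}
    v1 = 0.0
    for hemi in ("left", "right"):
        mesh = make_synthetic_hemisphere(
            model, n_ecc_rings=rings, n_angle_spokes=spokes,
            ecc_range=ecc_range, hemisphere=hemi)
        areas, _ = wedge.measure_wedge_areas(mesh, cfg=wedge_cfg)
        per_hemi[hemi] = areas
        v1 += wedge.v1_total_area(mesh)
    combined = wedge.combine_meridian_areas(per_hemi["left"],
                                            per_hemi["right"])
    return {loc: combined[loc] for loc in LOCATIONS}, v1


def _prf_recovery(subject: SubjectGroundTruth, config: RunConfig,
                  seed: int) -> dict:
    """Simulate BOLD on a coarse mesh and refit the pRF model."""
    model = MagnificationModel().scaled_to_v1_area(subject.v1_area_mm2)
    mesh = make_synthetic_hemisphere(
        model, n_ecc_rings=config.fit_mesh_rings,
        n_angle_spokes=config.fit_mesh_spokes, ecc_range=(0.5, 11.0))
    aperture = make_bar_aperture(grid_size=config.stim_grid_size)
    series = bold.simulate_bold(mesh, aperture,
                                noise_sd=config.bold_noise_sd, seed=seed)
    rng = np.random.default_rng(seed)
    n_fit = min(config.n_fit_vertices, mesh.n_vertices)
    pick = rng.choice(mesh.n_vertices, size=n_fit, replace=False)

    hrf = hrf_double_gamma(dt=aperture.frame_duration)
    fits = fit_prf_coarse_to_fine(series[pick], aperture, hrf, PRFGridSpec())

    t = np.deg2rad(mesh.polar_angle[pick])
    tx = mesh.eccentricity[pick] * np.cos(t)
    ty = mesh.eccentricity[pick] * np.sin(t)
    ts = bold.default_sigma_map(mesh)[pick]
    ex = np.array([f.params.x for f in fits]) - tx
    ey = np.array([f.params.y for f in fits]) - ty
    es = np.array([f.params.sigma for f in fits]) - ts
    r2 = np.array([f.r2 for f in fits])
    return {
        "observer_id": subject.observer_id,
        "n_vertices_fit": int(n_fit),
        "noise_sd": config.bold_noise_sd,
        "median_abs_error_x": float(np.median(np.abs(ex))),
        "median_abs_error_y": float(np.median(np.abs(ey))),
        "median_abs_error_sigma": float(np.median(np.abs(es))),
        "median_r2": float(np.median(r2)),
        "fraction_included": float(np.mean([f.included for f in fits])),
        "fraction_center_within_half_deg": float(
            np.mean(np.hypot(ex, ey) <= 0.5)),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a JSON-serializable run report."""
    cohort_seed, behav_seed, sa_seed, prf_seed, null_seed = _child_seeds(
        config.seed, 5)

    stage = "cohort"
    try:
        cohort = make_cohort(n_observers=config.n_observers,
                             seed=cohort_seed, **config.cohort_kwargs)

        stage = "behavior"
        if config.behavior == "staircase":
            obs_seeds = _child_seeds(behav_seed, len(cohort))
            measured_cs = {}
            block_thresholds = {}
            for s, oseed in zip(cohort, obs_seeds):
                blocks = run_observer(
                    s.observers, n_blocks=config.n_blocks,
                    n_trials_per_location=config.n_trials_per_location,
                    seed=oseed)
                meas = aggregate_observer(blocks, n_required=config.n_blocks)
                measured_cs[s.observer_id] = meas.sensitivity
                block_thresholds[s.observer_id] = [b.thresholds
                                                   for b in blocks]
        elif config.behavior == "planted":
            measured_cs = {s.observer_id: s.contrast_sensitivity
                           for s in cohort}
            block_thresholds = None
        else:
            raise ValueError(f"unknown behavior mode {config.behavior!r}")

        stage = "surface_area"
        wedge_cfg = WedgeConfig(**config.wedge_kwargs)
        if config.sa_source == "mesh":
            measured_sa = {}
            measured_v1 = {}
            for s in cohort:
                areas, v1 = measure_observer_areas(
                    s, rings=config.mesh_rings, spokes=config.mesh_spokes,
                    ecc_range=config.mesh_ecc_range, wedge_cfg=wedge_cfg)
                measured_sa[s.observer_id] = areas
                measured_v1[s.observer_id] = v1
        elif config.sa_source == "planted":
            measured_sa = {s.observer_id: s.wedge_areas for s in cohort}
            measured_v1 = {s.observer_id: s.v1_area_mm2 for s in cohort}
        else:
            raise ValueError(f"unknown sa_source {config.sa_source!r}")

        stage = "prf_recovery"
        prf_reports = []
        for s, pseed in zip(cohort[: config.n_fit_observers],
                            _child_seeds(prf_seed,
                                         max(config.n_fit_observers, 1))):
            prf_reports.append(_prf_recovery(s, config, pseed))

        stage = "statistics"
        table = CohortTable.from_cohort(cohort, cs=measured_cs,
                                        sa=measured_sa)
        table.v1_area = pd.Series(measured_v1)[table.cs.index]
        planted = CohortTable.from_cohort(cohort)

        idx = observer_indices(table)
        planted_idx = observer_indices(planted)
        rho, rho_p = pooled_correlation(table)
        null_obs = shuffle_null(table, "across_observers",
                                n_iter=config.n_null_iter, seed=null_seed)
        null_loc = shuffle_null(table, "across_locations",
                                n_iter=config.n_null_iter, seed=null_seed + 1)

        cs_obs_centered = center_data(table.cs, by="observer")
        sa_obs_centered = center_data(table.sa, by="observer")
        cs_loc_centered = center_data(table.cs, by="location")
        sa_loc_centered = center_data(table.sa, by="location")
        rho_meridian_effect = spearman_rho(
            cs_obs_centered.to_numpy().ravel(),
            sa_obs_centered.to_numpy().ravel())[0]
        rho_observer_effect = spearman_rho(
            cs_loc_centered.to_numpy().ravel(),
            sa_loc_centered.to_numpy().ravel())[0]

        mean_cs = table.cs.mean(axis=1)
        rho_v1_size = spearman_rho(mean_cs, table.v1_area)[0]
        rho_v1_norm = spearman_rho(
            mean_cs, table.v1_area / table.cortex_area)[0]

        from .stats import meridian_aggregate
        agg = meridian_aggregate(table)
        tests = {
            "cs_hm_vs_vm": dataclasses.asdict(
                paired_t(agg["CS_HM"], agg["CS_VM"])),
            "cs_lvm_vs_uvm": dataclasses.asdict(
                paired_t(agg["CS_LVM"], agg["CS_UVM"])),
            "sa_hm_vs_vm": dataclasses.asdict(
                paired_t(agg["SA_HM"], agg["SA_VM"])),
            "sa_lvm_vs_uvm": dataclasses.asdict(
                paired_t(agg["SA_LVM"], agg["SA_UVM"])),
        }
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    report = {
        "config": dataclasses.asdict(config),
        "n_observers": len(cohort),
        "group_indices": {k: float(idx[k].mean()) for k in idx.columns},
        "planted_group_indices": {k: float(planted_idx[k].mean())
                                  for k in planted_idx.columns},
        "pooled_rho": float(rho),
        "pooled_rho_p": float(rho_p),
        "planted_pooled_rho": float(pooled_correlation(planted)[0]),
        "null_across_observers_x95": null_obs.x95,
        "null_across_locations_x95": null_loc.x95,
        "significant_vs_observer_null": bool(null_obs.significant),
        "significant_vs_location_null": bool(null_loc.significant),
        "rho_meridian_effect": rho_meridian_effect,
        "rho_observer_effect": rho_observer_effect,
        "rho_v1_size": rho_v1_size,
        "rho_v1_size_normalized": rho_v1_norm,
        "paired_tests": tests,
        "prf_recovery": prf_reports,
    }
    if config.output_dir is not None:
        _write_outputs(Path(config.output_dir), table, report)
    return report


def _write_outputs(outdir: Path, table: CohortTable, report: dict) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    tidy = table.to_tidy()
    csv_path = outdir / "cohort_measured.csv"
    tidy.to_csv(csv_path, index=False)
    digest = hashlib.sha256(csv_path.read_bytes()).hexdigest()
    report["outputs"] = {"cohort_measured.csv": digest}
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)


# --- cohort CSV interchange (also the reader for the source-data layout) ---

def load_cohort_csv(path: str, column_map: dict[str, str] | None = None
                    ) -> CohortTable:
    """Read a tidy cohort CSV, optionally renaming columns via column_map.

    ``column_map`` maps the file's column names to the canonical schema
    (observer_id, location, contrast_sensitivity, wedge_area_mm2,
    v1_area_mm2, cortex_area_mm2), which is also the layout expected of the
    per-observer source-data tables.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    return CohortTable.from_tidy(df)


def save_cohort_csv(table: CohortTable, path: str) -> None:
    table.to_tidy().to_csv(path, index=False)
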