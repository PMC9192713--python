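"""Asymmetry indices, pooled correlations, shuffle nulls and group tests.

The two asymmetry indices are percentage differences normalized by the mean:

    HVA = 100 * (horizontal - vertical) / mean(horizontal, vertical)
    VMA = 100 * (lower vertical - upper vertical) / mean(lower, upper)

applied to contrast sensitivity or wedge-ROI surface area.  The brain-
behavior association is a pooled one-tailed Spearman correlation across
observers x locations, tested against two shuffle null distributions: one
permutes which observer's sensitivity quadruple is paired with which
observer's surface-area quadruple (removing between-observer structure while
preserving location ties), the other permutes location labels within each
observer (removing location structure while preserving observer ties).  The
95th percentile of each null, x0.95, is the significance cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import LOCATIONS, SubjectGroundTruth

__all__ = [
    "CohortTable",
    "NullDistributionResult",
    "GroupTestResult",
    "meridian_aggregate",
    "hva_index",
    "vma_index",
    "observer_indices",
    "spearman_rho",
    "pooled_correlation",
    "shuffle_null",
    "center_data",
    "normalize_v1",
    "paired_t",
    "block_reliability",
]


@dataclass
class CohortTable:
    """Per-observer sensitivities and wedge areas at the four locations.

    ``cs`` and ``sa`` are DataFrames indexed by observer with columns
    ``HM_left, HM_right, UVM, LVM``; ``v1_area`` and ``cortex_area`` are
    Series on the same index (mm^2, both hemispheres).
    """

    cs: pd.DataFrame
    sa: pd.DataFrame
    v1_area: pd.Series
    cortex_area: pd.Series

    def __post_init__(self):
        for name, df in (("cs", self.cs), ("sa", self.sa)):
            missing = set(LOCATIONS) - set(df.columns)
            if missing:
                raise ValueError(f"{name} table missing locations {missing}")
            if df.isna().any().any() or (df[list(LOCATIONS)] <= 0).any().any():
                raise ValueError(f"{name} table has missing or non-positive values")
        if len(self.cs) < 2:
            raise ValueError("need at least 2 observers")
        self.cs = self.cs[list(LOCATIONS)]
        self.sa = self.sa[list(LOCATIONS)]

    @property
    def n_observers(self) -> int:
        return len(self.cs)

    @classmethod
    def from_cohort(cls, cohort: list[SubjectGroundTruth],
                    cs: dict[str, dict[str, float]] | None = None,
                    sa: dict[str, dict[str, float]] | None = None
                    ) -> "CohortTable":
        """Build from planted ground truth, optionally overriding with
        measured sensitivities and/or areas (dicts keyed by observer id)."""
        ids = [s.observer_id for s in cohort]
        cs_rows = {s.observer_id: (cs[s.observer_id] if cs else
                                   s.contrast_sensitivity) for s in cohort}
        sa_rows = {s.observer_id: (sa[s.observer_id] if sa else
                                   s.wedge_areas) for s in cohort}
        return cls(
            cs=pd.DataFrame.from_dict(cs_rows, orient="index").loc[ids],
            sa=pd.DataFrame.from_dict(sa_rows, orient="index").loc[ids],
            v1_area=pd.Series({s.observer_id: s.v1_area_mm2 for s in cohort}),
            cortex_area=pd.Series({s.observer_id: s.cortex_area_mm2
                                   for s in cohort}),
        )

    @classmethod
    def from_tidy(cls, df: pd.DataFrame) -> "CohortTable":
        """Build from the tidy interchange schema (one row per
        observer x location)."""
        required = {"observer_id", "location", "contrast_sensitivity",
                    "wedge_area_mm2", "v1_area_mm2", "cortex_area_mm2"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"tidy table missing columns {sorted(missing)}")
        for oid, g in df.groupby("observer_id"):
            have = set(g["location"])
            if have != set(LOCATIONS):
                raise ValueError(
                    f"observer {oid} has locations {sorted(have)}, "
                    f"expected {sorted(LOCATIONS)}")
        cs = df.pivot(index="observer_id", columns="location",
                      values="contrast_sensitivity")
        sa = df.pivot(index="observer_id", columns="location",
                      values="wedge_area_mm2")
        per_obs = df.groupby("observer_id").first()
        return cls(cs=cs, sa=sa, v1_area=per_obs["v1_area_mm2"],
                   cortex_area=per_obs["cortex_area_mm2"])

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for oid in self.cs.index:
            for loc in LOCATIONS:
                rows.append({
                    "observer_id": oid, "location": loc,
                    "contrast_sensitivity": self.cs.loc[oid, loc],
                    "wedge_area_mm2": self.sa.loc[oid, loc],
                    "v1_area_mm2": self.v1_area.loc[oid],
                    "cortex_area_mm2": self.cortex_area.loc[oid],
                })
        return pd.DataFrame(rows)


@dataclass
class NullDistributionResult:
    """Observed pooled rho against a shuffle null distribution."""

    observed_rho: float
    null_rhos: np.ndarray
    x95: float
    mode: str
    seed: int

    @property
    def significant(self) -> bool:
        return self.observed_rho > self.x95


@dataclass
class GroupTestResult:
    """Paired t-test summary."""

    t: float
    df: int
    p: float
    cohen_d: float


def meridian_aggregate(table: CohortTable) -> pd.DataFrame:
    """Per-observer meridian aggregates.

    Sensitivity uses means (CS_HM = mean of left/right horizontal, CS_VM =
    mean of upper/lower vertical); surface area uses sums (each horizontal
    wedge already spans +/-15 deg, and the full vertical meridian is the sum
    of the upper and lower wedges).
    """
    out = pd.DataFrame(index=table.cs.index)
    out["CS_HM"] = table.cs[["HM_left", "HM_right"]].mean(axis=1)
    out["CS_VM"] = table.cs[["UVM", "LVM"]].mean(axis=1)
    out["CS_UVM"] = table.cs["UVM"]
    out["CS_LVM"] = table.cs["LVM"]
    out["SA_HM"] = table.sa[["HM_left", "HM_right"]].sum(axis=1)
    out["SA_VM"] = table.sa[["UVM", "LVM"]].sum(axis=1)
    out["SA_UVM"] = table.sa["UVM"]
    out["SA_LVM"] = table.sa["LVM"]
    return out


def _asymmetry(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("asymmetry indices require positive inputs")
    return 100.0 * (a - b) / ((a + b) / 2.0)


def hva_index(horizontal, vertical):
    """HVA index: (horizontal - vertical) / mean, x100. Zero iff equal."""
    out = _asymmetry(horizontal, vertical)
    return float(out) if out.ndim == 0 else out


def vma_index(lower, upper):
    """VMA index: (lower - upper vertical) / mean, x100. Zero iff equal."""
    out = _asymmetry(lower, upper)
    return float(out) if out.ndim == 0 else out


def observer_indices(table: CohortTable) -> pd.DataFrame:
    """Per-observer HVA and VMA indices for sensitivity and surface area."""
    agg = meridian_aggregate(table)
    return pd.DataFrame({
        "hva_cs": hva_index(agg["CS_HM"], agg["CS_VM"]),
        "vma_cs": vma_index(agg["CS_LVM"], agg["CS_UVM"]),
        "hva_sa": hva_index(agg["SA_HM"], agg["SA_VM"]),
        "vma_sa": vma_index(agg["SA_LVM"], agg["SA_UVM"]),
    }, index=agg.index)


def spearman_rho(x, y, alternative: str = "greater") -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    Raises on constant input, where the statistic is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman rho is undefined for a constant vector")
    res = sps.spearmanr(x, y, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def pooled_correlation(table: CohortTable,
                       alternative: str = "greater") -> tuple[float, float]:
    """One pooled Spearman rho over all observer x location (CS, SA) pairs."""
    return spearman_rho(table.cs.to_numpy().ravel(),
                        table.sa.to_numpy().ravel(), alternative)


def _pooled_rho_matrix(cs_flat: np.ndarray, sa_rank: np.ndarray) -> np.ndarray:
    """Pearson of ranks, vectorized over rows of ``cs_flat``."""
    r = sps.rankdata(cs_flat, axis=1)
    r = r - r.mean(axis=1, keepdims=True)
    s = sa_rank - sa_rank.mean()
    num = r @ s
    den = np.sqrt((r**2).sum(axis=1) * (s**2).sum())
    return num / den


def shuffle_null(table: CohortTable, mode: str = "across_observers",
                 n_iter: int = 10_000, seed: int = 0,
                 replacement: bool = False) -> NullDistributionResult:
    """Null distribution of the pooled rho under quadruple shuffling.

    mode="across_observers": each iteration re-pairs whole sensitivity
    quadruples with surface-area quadruples across observers (location ties
    kept), removing between-observer structure.  mode="across_locations":
    each iteration permutes the location labels of each observer's
    sensitivity quadruple (observer ties kept), removing location structure.
    Permutations are drawn uniformly per iteration; with
    ``replacement=True`` observer assignments are drawn i.i.d. (bootstrap)
    instead of as permutations.
    """
    if n_iter < 100:
        import warnings
        warnings.warn("n_iter < 100 gives a very coarse x0.95 estimate")
    rng = np.random.default_rng(seed)
    cs = table.cs.to_numpy()
    sa = table.sa.to_numpy()
    n, k = cs.shape
    observed, _ = pooled_correlation(table)

    if mode == "across_observers":
        if replacement:
            picks = rng.integers(0, n, size=(n_iter, n))
        else:
            picks = np.argsort(rng.random((n_iter, n)), axis=1)
        shuffled = cs[picks]                       # (n_iter, n, k)
    elif mode == "across_locations":
        perms = np.argsort(rng.random((n_iter, n, k)), axis=2)
        shuffled = np.take_along_axis(
            np.broadcast_to(cs, (n_iter, n, k)), perms, axis=2)
    else:
        raise ValueError(f"unknown shuffle mode {mode!r}")

    sa_rank = sps.rankdata(sa.ravel())
    null = _pooled_rho_matrix(shuffled.reshape(n_iter, n * k), sa_rank)
    x95 = float(np.percentile(null, 95.0))  # linear interpolation
    return NullDistributionResult(observed_rho=observed, null_rhos=null,
                                  x95=x95, mode=mode, seed=seed)


def center_data(matrix, by: str = "observer") -> np.ndarray | pd.DataFrame:
    """Remove observer (row) or location (column) means from an
    observers x locations matrix."""
    values = matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else \
        np.asarray(matrix, dtype=float)
    if by == "observer":
        centered = values - values.mean(axis=1, keepdims=True)
    elif by == "location":
        centered = values - values.mean(axis=0, keepdims=True)
    else:
        raise ValueError("by must be 'observer' or 'location'")
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(centered, index=matrix.index,
                            columns=matrix.columns)
    return centered


def normalize_v1(v1_area: float, cortex_area: float) -> float:
    """V1 size as a fraction of total cortical surface area."""
    if cortex_area <= 0:
        raise ValueError("cortex_area must be positive")
    return v1_area / cortex_area


def paired_t(a, b) -> GroupTestResult:
    """Two-sided paired t-test with Cohen's d on the differences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need equal-length vectors of length >= 2")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.all(diff == 0):  # identical samples: no effect at all
            return GroupTestResult(t=0.0, df=a.size - 1, p=1.0, cohen_d=0.0)
        raise ValueError("zero-variance non-zero differences: t undefined")
    res = sps.ttest_rel(a, b)
    return GroupTestResult(t=float(res.statistic), df=a.size - 1,
                           p=float(res.pvalue),
                           cohen_d=float(diff.mean() / sd))


def block_reliability(
    block_thresholds: dict[str, list[dict[str, float]]],
    split_a: tuple[int, ...] = (0, 2, 4),
    split_b: tuple[int, ...] = (1, 3),
) -> dict[str, float]:
    """Split-block reliability of the behavioral asymmetry indices.

    ``block_thresholds`` maps observer id -> per-block dicts of per-location
    thresholds.  Sensitivities are recomputed from each split's mean
    thresholds, HVA/VMA indices derived per observer, and the two splits'
    indices correlated (Spearman) across observers.
    """
    if not split_a or not split_b:
        raise ValueError("splits must be non-empty")

    def split_indices(split):
        hva, vma = [], []
        for blocks in block_thresholds.values():
            thr = {loc: np.mean([blocks[b][loc] for b in split])
                   for loc in LOCATIONS}
            cs = {loc: 1.0 / thr[loc] for loc in LOCATIONS}
            h = np.mean([cs["HM_left"], cs["HM_right"]])
            v = np.mean([cs["UVM"], cs["LVM"]])
            hva.append(hva_index(h, v))
            vma.append(vma_index(cs["LVM"], cs["UVM"]))
        return np.array(hva), np.array(vma)

    hva_a, vma_a = split_indices(split_a)
    hva_b, vma_b = split_indices(split_b)
    return {
        "hva": spearman_rho(hva_a, hva_b, "two-sided")[0],
        "vma": spearman_rho(vma_a, vma_b, "two-sided")[0],
    }
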