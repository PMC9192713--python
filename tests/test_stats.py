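"""Asymmetry indices, correlations, shuffle nulls and group tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cortmag as cm
from cortmag.stats import (CohortTable, block_reliability,
                           center_data, meridian_aggregate, observer_indices,
                           paired_t, pooled_correlation, shuffle_null,
                           spearman_rho)


def table_from_arrays(cs, sa, v1=None, cortex=None):
    cs = pd.DataFrame(cs, columns=list(cm.LOCATIONS))
    sa = pd.DataFrame(sa, columns=list(cm.LOCATIONS))
    n = len(cs)
    return CohortTable(cs=cs, sa=sa,
                       v1_area=pd.Series(v1 if v1 is not None
                                         else np.full(n, 2900.0)),
                       cortex_area=pd.Series(cortex if cortex is not None
                                             else np.full(n, 2e5)))


class TestIndices:
    def test_equal_inputs_give_zero(self):
        assert cm.hva_index(1.0, 1.0) == 0.0
        assert cm.vma_index(0.37, 0.37) == 0.0

    def test_hand_arithmetic(self):
        assert cm.hva_index(1.5, 1.0) == pytest.approx(40.0)
        assert cm.vma_index(1.2, 1.0) == pytest.approx(200.0 / 11.0)

    def test_antisymmetry(self):
        assert cm.hva_index(2.0, 3.0) == -cm.hva_index(3.0, 2.0)
        assert cm.vma_index(1.0, 1.2) == pytest.approx(-200.0 / 11.0)

    @settings(derandomize=True, max_examples=50)
    @given(h=st.floats(0.01, 1e4), v=st.floats(0.01, 1e4),
           k=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, h, v, k):
        assert cm.hva_index(k * h, k * v) == pytest.approx(
            cm.hva_index(h, v), rel=1e-9, abs=1e-9)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            cm.hva_index(0.0, 1.0)
        with pytest.raises(ValueError):
            cm.vma_index(1.0, -2.0)


class TestMeridianAggregate:
    def test_cs_means_and_sa_sums(self):
        t = table_from_arrays(
            cs=[[60.0, 40.0, 30.0, 30.0], [50.0, 50.0, 40.0, 40.0]],
            sa=[[700.0, 740.0, 300.0, 400.0], [650.0, 650.0, 350.0, 390.0]])
        agg = meridian_aggregate(t)
        assert agg.loc[0, "CS_HM"] == pytest.approx(50.0)
        assert agg.loc[0, "SA_HM"] == pytest.approx(1440.0)
        assert agg.loc[0, "SA_VM"] == pytest.approx(700.0)

    def test_equal_cs_everywhere_makes_hm_equal_vm(self):
        t = table_from_arrays(cs=[[25.0] * 4] * 2, sa=[[100.0] * 4] * 2)
        agg = meridian_aggregate(t)
        assert agg.loc[0, "CS_HM"] == agg.loc[0, "CS_VM"]


class TestSpearman:
    def test_perfect_monotone(self):
        rho, p = spearman_rho([1, 2, 3, 5], [10, 20, 25, 90])
        assert rho == pytest.approx(1.0)
        assert p < 0.05

    def test_reversed_order(self):
        rho, _ = spearman_rho([1, 2, 3, 4], [4, 3, 2, 1], "two-sided")
        assert rho == pytest.approx(-1.0)

    def test_ties_match_average_rank_oracle(self):
        """Brute-force oracle: explicit average ranks, then Pearson."""
        x = np.array([1.0, 2.0, 2.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])
        rank_x = np.array([1.0, 2.5, 2.5, 4.0])
        rank_y = np.array([1.0, 3.0, 2.0, 4.0])
        expected = np.corrcoef(rank_x, rank_y)[0, 1]
        rho, _ = spearman_rho(x, y, "two-sided")
        assert rho == pytest.approx(expected, rel=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])

    def test_pooled_rho_invariant_to_monotone_transform(self,
                                                        default_cohort):
        t = CohortTable.from_cohort(default_cohort)
        rho1, _ = pooled_correlation(t)
        t2 = CohortTable(cs=t.cs**3, sa=t.sa, v1_area=t.v1_area,
                         cortex_area=t.cortex_area)
        rho2, _ = pooled_correlation(t2)
        assert rho1 == pytest.approx(rho2, abs=1e-12)


class TestShuffleNull:
    def test_fixed_seed_is_bit_identical(self, default_cohort):
        t = CohortTable.from_cohort(default_cohort)
        a = shuffle_null(t, "across_observers", n_iter=500, seed=9)
        b = shuffle_null(t, "across_observers", n_iter=500, seed=9)
        assert a.x95 == b.x95
        assert np.array_equal(a.null_rhos, b.null_rhos)

    def test_null_vector_length_and_percentile(self, default_cohort):
        t = CohortTable.from_cohort(default_cohort)
        res = shuffle_null(t, "across_locations", n_iter=800, seed=0)
        assert res.null_rhos.shape == (800,)
        assert res.x95 == pytest.approx(np.percentile(res.null_rhos, 95))

    def test_unknown_mode_rejected(self, default_cohort):
        t = CohortTable.from_cohort(default_cohort)
        with pytest.raises(ValueError):
            shuffle_null(t, "bogus")

    def test_low_iteration_count_warns(self, default_cohort):
        t = CohortTable.from_cohort(default_cohort)
        with pytest.warns(UserWarning):
            shuffle_null(t, "across_observers", n_iter=50, seed=0)

    def test_location_only_structure_not_beaten_by_observer_null(self):
        """When only location effects exist, re-pairing observers keeps the
        correlation, so the observed rho sits inside that null."""
        cohort = cm.make_cohort(coupling=0.0, index_sd=0.0,
                                observer_cs_sd=0.0, size_spread=1.0,
                                noise_sd=0.02, seed=21)
        t = CohortTable.from_cohort(cohort)
        obs_null = shuffle_null(t, "across_observers", n_iter=1000, seed=0)
        loc_null = shuffle_null(t, "across_locations", n_iter=1000, seed=0)
        assert abs(obs_null.x95 - obs_null.observed_rho) < 0.12
        assert loc_null.x95 < obs_null.observed_rho - 0.3

    def test_observer_only_structure_not_beaten_by_location_null(self):
        cohort = cm.make_cohort(coupling=1.0, group_hva_sa=0.0,
                                group_vma_sa=0.0, group_hva_cs=0.0,
                                group_vma_cs=0.0, index_sd=0.0,
                                noise_sd=0.02, seed=22)
        t = CohortTable.from_cohort(cohort)
        obs_null = shuffle_null(t, "across_observers", n_iter=1000, seed=0)
        loc_null = shuffle_null(t, "across_locations", n_iter=1000, seed=0)
        assert abs(loc_null.x95 - loc_null.observed_rho) < 0.12
        assert obs_null.x95 < loc_null.observed_rho - 0.3


class TestCentering:
    def test_observer_centering_zeroes_rows(self, default_cohort):
        t = CohortTable.from_cohort(default_cohort)
        c = center_data(t.cs, by="observer")
        assert np.allclose(c.sum(axis=1), 0.0)

    def test_location_centering_zeroes_columns(self, default_cohort):
        t = CohortTable.from_cohort(default_cohort)
        c = center_data(t.cs, by="location")
        assert np.allclose(c.sum(axis=0), 0.0)

    def test_location_effect_dominates_observer_centered_rho(self):
        """With strong planted location effects, removing observer means
        leaves a stronger correlation than removing location means."""
        cohort = cm.make_cohort(coupling=0.9, noise_sd=0.02, seed=5)
        t = CohortTable.from_cohort(cohort)
        rho_merid = spearman_rho(
            center_data(t.cs, "observer").to_numpy().ravel(),
            center_data(t.sa, "observer").to_numpy().ravel())[0]
        rho_obs = spearman_rho(
            center_data(t.cs, "location").to_numpy().ravel(),
            center_data(t.sa, "location").to_numpy().ravel())[0]
        assert rho_merid > rho_obs


class TestGroupTests:
    def test_identical_samples_give_zero_effect(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.cohen_d == 0.0

    def test_hand_computed_t(self):
        res = paired_t([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert res.t == pytest.approx(2 * np.sqrt(3))
        assert res.df == 2
        assert res.cohen_d == pytest.approx(2.0)

    def test_sign_flip(self):
        a = np.array([3.0, 5.0, 4.0])
        b = np.array([1.0, 2.0, 2.5])
        fwd = paired_t(a, b)
        rev = paired_t(b, a)
        assert fwd.t == pytest.approx(-rev.t)
        assert fwd.cohen_d == pytest.approx(-rev.cohen_d)

    def test_constant_nonzero_difference_rejected(self):
        with pytest.raises(ValueError):
            paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])

    def test_normalize_v1(self):
        assert cm.normalize_v1(1300.0, 100_000.0) == pytest.approx(0.013)
        assert cm.normalize_v1(2600.0, 200_000.0) == pytest.approx(0.013)
        with pytest.raises(ValueError):
            cm.normalize_v1(1300.0, 0.0)


class TestBlockReliability:
    @staticmethod
    def _thresholds(rng, n_obs, noise):
        out = {}
        for i in range(n_obs):
            base = {loc: 0.02 * w for loc, w in
                    zip(cm.LOCATIONS, [0.8, 0.8, 1.3, 1.1])}
            obs_scale = rng.lognormal(0, 0.3)
            out[f"S{i}"] = [
                {loc: base[loc] * obs_scale * rng.lognormal(0, noise)
                 for loc in cm.LOCATIONS}
                for _ in range(5)]
        return out

    def test_identical_splits_correlate_perfectly(self):
        rng = np.random.default_rng(0)
        thr = self._thresholds(rng, 12, noise=0.2)
        res = block_reliability(thr, (0, 1, 2), (0, 1, 2))
        assert res["hva"] == pytest.approx(1.0)
        assert res["vma"] == pytest.approx(1.0)

    def test_low_noise_observers_highly_reliable(self):
        rng = np.random.default_rng(1)
        # spread asymmetries across observers so indices differ reliably
        thr = {}
        for i in range(15):
            w_h = 0.7 + 0.04 * i
            base = {"HM_left": 0.02 * w_h, "HM_right": 0.02 * w_h,
                    "UVM": 0.03, "LVM": 0.026}
            thr[f"S{i}"] = [{loc: v * rng.lognormal(0, 0.01)
                             for loc, v in base.items()} for _ in range(5)]
        res = block_reliability(thr)
        assert res["hva"] > 0.9

    def test_pure_noise_observers_unreliable(self):
        rng = np.random.default_rng(2)
        thr = {f"S{i}": [{loc: rng.lognormal(-3.5, 0.3)
                          for loc in cm.LOCATIONS} for _ in range(5)]
               for i in range(40)}
        res = block_reliability(thr)
        assert abs(res["hva"]) < 0.4

    def test_empty_split_rejected(self):
        with pytest.raises(ValueError):
            block_reliability({}, (), (1,))


class TestCohortTableValidation:
    def test_missing_location_rejected(self):
        cs = pd.DataFrame({"HM_left": [1.0], "HM_right": [1.0],
                           "UVM": [1.0]})
        with pytest.raises(ValueError):
            CohortTable(cs=cs, sa=cs.copy(), v1_area=pd.Series([1.0]),
                        cortex_area=pd.Series([1.0]))

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            table_from_arrays(cs=[[1, 1, 1, -1], [1, 1, 1, 1]],
                              sa=[[1, 1, 1, 1], [1, 1, 1, 1]])

    def test_single_observer_rejected(self):
        with pytest.raises(ValueError):
            table_from_arrays(cs=[[1, 1, 1, 1]], sa=[[1, 1, 1, 1]])

    def test_observer_indices_columns(self, default_cohort):
        idx = observer_indices(CohortTable.from_cohort(default_cohort))
        assert list(idx.columns) == ["hva_cs", "vma_cs", "hva_sa", "vma_sa"]
        assert len(idx) == len(default_cohort)
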