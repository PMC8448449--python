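"""Trajectory assembly, filtering, growth fits, cohorts, rare phenotypes."""

import itertools

import numpy as np
import pandas as pd
import pytest

from trapchip.analysis import (CloneTrajectory, GrowthFit,
                               assemble_trajectories, cohort_summary,
                               detect_rare_large, filter_trajectories,
                               fit_growth, occupancy_heatmap, resample_pvalue,
                               trajectories_from_ground_truth)
from trapchip.loading import make_chip_layout
from trapchip.population import ClonePopulationSpec, sample_clone_population


def make_traj(counts, t=None, area=130.0, street=0, position=0):
    counts = np.asarray(counts)
    t = np.arange(len(counts), dtype=float) if t is None else np.asarray(t)
    return CloneTrajectory(street=street, position=position, timepoints=t,
                           counts=counts, mean_area=np.full(len(counts), area),
                           mean_ecc=np.full(len(counts), 0.3))


def det_table(rows):
    return pd.DataFrame(rows, columns=["fov", "street", "position", "timepoint",
                                       "area_um2", "eccentricity"])


class TestAssemble:
    def test_counts_from_detections(self):
        rows = ([dict(fov=0, street=0, position=0, timepoint=t, area_um2=100.0,
                      eccentricity=0.2) for t in (0, 0)]  # 2 cells day 0? no: 1
                )
        rows = []
        for t, k in [(0, 1), (1, 2), (2, 4)]:
            rows += [dict(fov=0, street=0, position=0, timepoint=t,
                          area_um2=100.0, eccentricity=0.2)] * k
        trajectories = assemble_trajectories(det_table(rows))
        assert len(trajectories) == 1
        assert list(trajectories[0].counts) == [1, 2, 4]

    def test_missing_timepoint_counts_zero(self):
        rows = [dict(fov=0, street=0, position=0, timepoint=t, area_um2=1.0,
                     eccentricity=0.1) for t in (0, 2)]
        rows += [dict(fov=0, street=0, position=1, timepoint=t, area_um2=1.0,
                      eccentricity=0.1) for t in (0, 1, 2)]
        trajectories = {(tr.street, tr.position): tr
                        for tr in assemble_trajectories(det_table(rows))}
        assert list(trajectories[(0, 0)].counts) == [1, 0, 1]

    def test_conflicting_fovs_rejected(self):
        rows = [dict(fov=0, street=0, position=0, timepoint=0, area_um2=1.0,
                     eccentricity=0.1),
                dict(fov=1, street=0, position=0, timepoint=0, area_um2=1.0,
                     eccentricity=0.1)]
        with pytest.raises(ValueError, match="fields of view"):
            assemble_trajectories(det_table(rows))

    def test_round_trip_from_ground_truth(self):
        spec = ClonePopulationSpec(n_clones=30, seed=3)
        table = sample_clone_population(spec)
        trajectories = trajectories_from_ground_truth(table)
        counts = np.array([tr.counts for tr in trajectories])
        cols = [c for c in table.columns if c.startswith("count_t")]
        assert (counts == table[cols].to_numpy()).all()


class TestFilter:
    def test_all_length_four_patterns(self):
        # single-cell start + at least one cell at every timepoint
        for pattern in itertools.product(range(3), repeat=4):
            tr = make_traj(pattern)
            kept = filter_trajectories([tr])
            expected = pattern[0] == 1 and min(pattern) >= 1
            assert bool(kept) == expected, pattern

    def test_idempotent_and_order_independent(self):
        trajectories = [make_traj(p, position=i) for i, p in enumerate(
            [(1, 2, 0, 4), (2, 3, 4, 6), (1, 1, 2, 3), (1, 2, 4, 8)])]
        once = filter_trajectories(trajectories)
        twice = filter_trajectories(once)
        assert [id(t) for t in once] == [id(t) for t in twice]
        rev = filter_trajectories(trajectories[::-1])
        assert {(t.street, t.position) for t in rev} == \
               {(t.street, t.position) for t in once}


class TestFit:
    def test_exact_doubling(self):
        fit = fit_growth(make_traj([1, 2, 4, 8]))
        assert fit.lam == pytest.approx(1.0)
        assert fit.p0 == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_flat_trajectory_zero_rate(self):
        fit = fit_growth(make_traj([1, 1, 1, 1]))
        assert fit.lam == pytest.approx(0.0)
        assert fit.r_squared == 1.0

    def test_zero_count_directs_to_filter(self):
        with pytest.raises(ValueError, match="filter"):
            fit_growth(make_traj([1, 2, 0, 4]))

    def test_too_few_timepoints(self):
        with pytest.raises(ValueError, match="three"):
            fit_growth(make_traj([1, 2]))

    def test_exact_rates_recovered_before_rounding(self):
        # counts that are exact powers of two need no rounding at all
        for lam, p0 in [(1.0, 1), (2.0, 2), (1.0, 4)]:
            counts = (p0 * 2.0 ** (lam * np.arange(4))).astype(int)
            fit = fit_growth(make_traj(counts))
            assert fit.lam == pytest.approx(lam, abs=1e-12)
            assert fit.p0 == pytest.approx(p0, rel=1e-12)

    @pytest.mark.parametrize("lam", [0.2, 0.55, 0.95, 1.5])
    def test_mean_fitted_rate_within_rounding_tolerance(self, lam):
        # stochastic integerization over 4 daily timepoints
        spec = ClonePopulationSpec(n_clones=1500, growth_median=lam,
                                   growth_sigma=0.0, seed=17)
        table = sample_clone_population(spec, timepoints=[0, 1, 2, 3])
        fits = [fit_growth(tr) for tr in
                filter_trajectories(trajectories_from_ground_truth(table))]
        assert np.mean([f.lam for f in fits]) == pytest.approx(lam, abs=0.05)

    def test_crowding_saturation_lowers_fitted_rate(self):
        spec = ClonePopulationSpec(n_clones=300, growth_median=1.5,
                                   growth_sigma=0.0, capacity=10, seed=2)
        table = sample_clone_population(spec, timepoints=[0, 1, 2, 3, 4])
        fits = [fit_growth(tr) for tr in
                filter_trajectories(trajectories_from_ground_truth(table))]
        assert all(f.lam <= 1.5 + 1e-9 for f in fits)
        assert np.median([f.lam for f in fits]) < 1.5


class TestCohorts:
    def test_median_of_three(self):
        fits = [GrowthFit(0, i, lam, 1.0, 1.0, 130.0, 0.3)
                for i, lam in enumerate([0.5, 1.0, 1.5])]
        summary = cohort_summary(fits)
        assert summary.median_lam == 1.0
        assert summary.max_lam == 1.5

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cohort_summary([])

    @pytest.mark.parametrize("median", [0.95, 0.55])
    def test_cohort_median_recovery_at_3000_clones(self, median):
        spec = ClonePopulationSpec(n_clones=3000, growth_median=median,
                                   growth_sigma=0.2075, resistant_fraction=0.0,
                                   seed=int(median * 100))
        table = sample_clone_population(spec)
        fits = [fit_growth(tr) for tr in
                filter_trajectories(trajectories_from_ground_truth(table))]
        assert cohort_summary(fits).median_lam == pytest.approx(median, abs=0.03)


class TestResampling:
    def _rates(self, n, loc, seed):
        return np.random.default_rng(seed).normal(loc, 0.2, n)

    def test_identical_cohorts_rarely_significant(self):
        hits = 0
        for seed in range(20):
            values = self._rates(300, 0.9, seed)
            p, _ = resample_pvalue(list(values), list(values), n_sample=200,
                                   n_perm=199, seed=seed)
            hits += p > 0.05
        assert hits >= 18

    def test_shifted_cohorts_highly_significant(self):
        a = self._rates(1000, 0.95, 1)
        b = self._rates(1000, 0.55, 2)
        p, obs = resample_pvalue(list(a), list(b), n_sample=1000,
                                 n_perm=1999, seed=3)
        assert p < 0.001
        assert obs == pytest.approx(0.4, abs=0.05)

    def test_equal_cohorts_zero_statistic(self):
        a = list(self._rates(100, 0.9, 5))
        _, obs = resample_pvalue(a, a, n_sample=100, n_perm=99, seed=0)
        assert obs == 0.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            resample_pvalue([], [1.0])


class TestRarePhenotypes:
    def _fits(self, areas):
        return [GrowthFit(0, i, 1.0, 1.0, 1.0, a, 0.3)
                for i, a in enumerate(areas)]

    def test_single_outlier_flagged(self):
        areas = [100.0 + 0.1 * i for i in range(19)] + [1000.0]
        flagged, freq = detect_rare_large(self._fits(areas), z_threshold=5.0)
        assert len(flagged) == 1
        assert flagged[0].time_avg_area == 1000.0
        assert freq == pytest.approx(1 / 20)

    def test_infinite_threshold_flags_nothing(self):
        areas = list(np.linspace(90, 110, 20))
        flagged, freq = detect_rare_large(self._fits(areas), z_threshold=np.inf)
        assert flagged == [] and freq == 0.0

    def test_degenerate_distribution_rejected(self):
        with pytest.raises(ValueError, match="MAD"):
            detect_rare_large(self._fits([100.0] * 20))

    def test_too_few_fits_rejected(self):
        with pytest.raises(ValueError):
            detect_rare_large(self._fits([1.0] * 5))


class TestHeatmap:
    def _dets(self, entries):
        cols = ["fov", "street", "position", "timepoint", "area_um2",
                "eccentricity"]
        return pd.DataFrame([dict(fov=0, street=s, position=p, timepoint=t,
                                  area_um2=1.0, eccentricity=0.1)
                             for (s, p, t) in entries], columns=cols)

    def test_all_singlets_matrix_of_ones(self):
        layout = make_chip_layout(n_streets=2, apartments_per_street=3)
        entries = [(s, p, 0.0) for s in range(2) for p in range(3)]
        mat, logmat = occupancy_heatmap(self._dets(entries), layout, 0.0)
        assert (mat == 1).all()
        np.testing.assert_allclose(logmat, np.log10(2) * np.ones_like(logmat))

    def test_empty_chip_zero_matrix(self):
        layout = make_chip_layout(n_streets=2, apartments_per_street=3)
        mat, _ = occupancy_heatmap(self._dets([]), layout, 0.0)
        assert mat.shape == (2, 3)
        assert (mat == 0).all()

    def test_address_outside_layout_rejected(self):
        layout = make_chip_layout(n_streets=2, apartments_per_street=3)
        with pytest.raises(ValueError, match="outside layout"):
            occupancy_heatmap(self._dets([(5, 0, 0.0)]), layout, 0.0)

    def test_matrix_matches_ground_truth_counts(self):
        layout = make_chip_layout(n_streets=2, apartments_per_street=4)
        entries = [(0, 0, 0.0)] * 3 + [(1, 2, 0.0)] * 2 + [(0, 1, 1.0)]
        mat, _ = occupancy_heatmap(self._dets(entries), layout, 0.0)
        assert mat[0, 0] == 3 and mat[1, 2] == 2 and mat[0, 1] == 0
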