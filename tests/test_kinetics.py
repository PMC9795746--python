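"""Enzymology: unit arithmetic, saturation fits, optima, dilution endpoints."""

import numpy as np
import pytest
from oracle_gridsearch import gridsearch_ss

from aidbench.kinetics import (
    BindingDataset,
    DilutionSeries,
    KineticsDataset,
    ThermalProfile,
    catalytic_efficiency,
    dilution_fold_difference,
    estimate_optimum,
    et_concentration,
    fit_binding,
    fit_michaelis_menten,
    fold_change,
    group_mean_efficiency,
    molecular_weight,
    percent_deamination,
    percent_reduction,
    relative_deamination_efficiency,
)
from aidbench.simulate import KineticsSimSpec, gen_kinetics


class TestPercentDeamination:
    @pytest.mark.parametrize("cleaved,uncleaved,expected", [(0, 5, 0.0), (3, 3, 50.0), (1, 99, 1.0)])
    def test_examples(self, cleaved, uncleaved, expected):
        assert percent_deamination(cleaved, uncleaved) == pytest.approx(expected)

    def test_both_zero_flagged(self):
        with pytest.raises(ValueError):
            percent_deamination(0, 0)


class TestMolecularWeight:
    def test_average_mass_table(self):
        assert molecular_weight("G") == pytest.approx(75.07, abs=0.01)
        assert molecular_weight("GG") == pytest.approx(132.12, abs=0.01)

    @pytest.mark.parametrize("seq", ["", "GXG", "GBG"])
    def test_invalid_sequences_rejected(self, seq):
        with pytest.raises(ValueError):
            molecular_weight(seq)


class TestEtConcentration:
    def test_unit_arithmetic(self):
        assert et_concentration(48.0, 48000.0) == pytest.approx(1000.0)
        assert et_concentration(0.048, 48000.0) == pytest.approx(1.0)

    def test_linearity_in_mass(self):
        assert et_concentration(2.0, 50000.0) == pytest.approx(2 * et_concentration(1.0, 50000.0))


class TestMichaelisMentenFit:
    def test_noiseless_generative_recovery(self):
        data = gen_kinetics(KineticsSimSpec(kcat=1.0, km=50.0, et=10.0))
        fit = fit_michaelis_menten(data)
        assert fit.converged
        assert fit.kcat == pytest.approx(1.0, rel=1e-3)
        assert fit.km == pytest.approx(50.0, rel=1e-3)
        assert fit.vmax == pytest.approx(fit.et * fit.kcat)

    def test_half_saturation_point_consistent(self):
        with pytest.warns(UserWarning, match="fewer than 4"):
            fit = fit_michaelis_menten(
                KineticsDataset(enzyme_id="e", observations=[(50.0, 5.0, 0)], et=10.0)
            )
        assert fit.residual_ss == pytest.approx(0.0, abs=1e-12)

    def test_matches_gridsearch_oracle_on_seeded_noisy_data(self):
        for seed in range(8):
            spec = KineticsSimSpec(kcat=0.5, km=20.0, et=5.0, noise_cv=0.1, seed=seed)
            data = gen_kinetics(spec)
            fit = fit_michaelis_menten(data)
            oracle = gridsearch_ss(data.x, data.v)
            assert fit.residual_ss <= oracle * (1 + 1e-6)

    def test_efficiency_invariant_to_consistent_unit_rescaling(self):
        data = gen_kinetics(KineticsSimSpec(kcat=1.0, km=50.0, et=10.0, noise_cv=0.05, seed=9))
        fit = fit_michaelis_menten(data)
        scaled = KineticsDataset(
            enzyme_id="s",
            observations=[(x, v * 1000.0, r) for x, v, r in data.observations],
            et=data.et * 1000.0,
        )
        fit2 = fit_michaelis_menten(scaled)
        assert fit2.efficiency == pytest.approx(fit.efficiency, rel=1e-6)

    def test_fitted_curve_monotone_and_bounded_by_vmax(self):
        data = gen_kinetics(KineticsSimSpec(kcat=1.0, km=50.0, et=10.0, noise_cv=0.05, seed=3))
        fit = fit_michaelis_menten(data)
        xs = np.logspace(-3, 5, 200)
        pred = fit.predict(xs)
        assert np.all(np.diff(pred) > 0)
        assert np.all(pred < fit.vmax)

    def test_efficiency_recovery_median_within_ten_percent(self):
        # paper-style substrate design (0.0625-100 fmol), 5 % CV, >= 20 seeds
        errors = []
        for seed in range(20):
            spec = KineticsSimSpec(kcat=1.0, km=50.0, et=10.0, noise_cv=0.05, seed=seed)
            fit = fit_michaelis_menten(gen_kinetics(spec))
            errors.append(abs(fit.efficiency / (1.0 / 50.0) - 1.0))
        assert np.median(errors) <= 0.10


class TestEfficiencyArithmetic:
    def test_catalytic_efficiency_is_kcat_over_km(self):
        fit = fit_michaelis_menten(gen_kinetics(KineticsSimSpec(kcat=2.0, km=40.0, et=1.0)))
        assert catalytic_efficiency(fit) == pytest.approx(0.05, rel=1e-3)

    def test_ancestral_efficiency_ratio_from_printed_parameters(self):
        # kcat 1.89e-6 over Km 43.82 equals direct division
        assert 1.89e-6 / 43.82 == pytest.approx(4.3131e-8, rel=1e-4)
        assert fold_change(4.81e-08, 3.09e-08) == pytest.approx(1.5566, rel=1e-4)

    def test_percent_reduction_examples(self):
        assert percent_reduction(1.53e-07, 1.22e-09) == pytest.approx(99.2, abs=0.05)
        assert percent_reduction(2.5, 2.5) == 0.0

    def test_reduction_fold_change_consistency(self):
        a, b = 3.7e-6, 5.1e-8
        assert percent_reduction(a, b) == pytest.approx(100 * (1 - 1 / fold_change(a, b)))

    @pytest.mark.parametrize("fn", [fold_change, percent_reduction])
    def test_nonpositive_inputs_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(0.0, 1.0)


class TestGroupMeans:
    def test_arithmetic_mean_with_zero_activity_members(self):
        eff = {"a": 1e-7, "b": 3e-7, "dead": 0.0}
        grouping = {"a": "g1", "b": "g1", "dead": "g2"}
        means = group_mean_efficiency(eff, grouping)
        assert means == {"g1": pytest.approx(2e-7), "g2": 0.0}

    def test_permutation_invariance(self):
        eff = {"a": 1.0, "b": 2.0, "c": 6.0}
        g = {"a": "g", "b": "g", "c": "g"}
        rev = dict(reversed(list(g.items())))
        assert group_mean_efficiency(eff, g) == group_mean_efficiency(eff, rev)

    def test_empty_grouping_rejected(self):
        with pytest.raises(ValueError):
            group_mean_efficiency({}, {})


class TestSubstratePanel:
    def test_equal_activities_give_unit_relative_efficiency(self):
        res = relative_deamination_efficiency({s: 4.0 for s in "TGC AGC TAC GGC GTC GAC".split()})
        assert all(v == pytest.approx(1.0) for v in res.relative_efficiency.values())

    def test_single_active_substrate(self):
        acts = {"TGC": 6.0, "AGC": 0, "TAC": 0, "GGC": 0, "GTC": 0, "GAC": 0}
        res = relative_deamination_efficiency(acts)
        assert res.relative_efficiency["TGC"] == pytest.approx(6.0)

    def test_mean_is_exactly_one(self):
        acts = {"TGC": 5.1, "AGC": 3.3, "TAC": 2.2, "GGC": 0.4, "GTC": 0.6, "GAC": 0.2}
        rel = relative_deamination_efficiency(acts).relative_efficiency
        assert sum(rel.values()) / 6 == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_panel_flagged(self):
        with pytest.raises(ValueError):
            relative_deamination_efficiency({s: 0.0 for s in "TGC AGC TAC GGC GTC GAC".split()})


class TestBindingFit:
    @staticmethod
    def _dataset(bmax, kd, noise_rng=None):
        xs = np.array([0.025, 0.05, 0.1, 0.25, 0.5, 1.0, 2.5])
        ys = bmax * xs / (kd + xs)
        if noise_rng is not None:
            ys = ys * noise_rng.lognormal(0, 0.1, size=len(xs))
        return BindingDataset(enzyme_id="b", observations=[(x, y, 0) for x, y in zip(xs, ys)])

    def test_noiseless_exact_recovery(self):
        fit = fit_binding(self._dataset(12.0, 0.4))
        assert fit.bmax == pytest.approx(12.0, rel=1e-4)
        assert fit.kd == pytest.approx(0.4, rel=1e-4)

    def test_half_saturation_at_kd(self):
        fit = fit_binding(self._dataset(8.0, 0.25))
        assert fit.predict(fit.kd) == pytest.approx(fit.bmax / 2)

    def test_matches_gridsearch_oracle(self):
        for seed in range(5):
            data = self._dataset(10.0, 0.5, np.random.default_rng(seed))
            fit = fit_binding(data)
            assert fit.residual_ss <= gridsearch_ss(data.x, data.y) * (1 + 1e-6)


class TestOptimumEstimation:
    @staticmethod
    def _profile(values, grid=None):
        grid = grid if grid is not None else list(range(len(values)))
        return ThermalProfile(
            enzyme_id="t", points=[(float(g), float(v), 0) for g, v in zip(grid, values)]
        )

    def test_strictly_increasing_profile_flags_boundary(self):
        opt = estimate_optimum(self._profile([1, 2, 3, 4, 5]))
        assert opt.optimum == 4.0 and opt.boundary

    def test_normalized_profile_peaks_at_100(self):
        opt = estimate_optimum(self._profile([10, 40, 20]))
        assert opt.normalized.max() == pytest.approx(100.0)

    def test_flat_profile_undetermined(self):
        opt = estimate_optimum(self._profile([5, 5, 5]))
        assert opt.optimum is None and opt.flat

    def test_tie_resolves_to_lower_value(self):
        opt = estimate_optimum(self._profile([1, 7, 7, 1], grid=[0, 2, 4, 6]))
        assert opt.optimum == 2.0

    def test_replicates_are_averaged(self):
        profile = ThermalProfile(
            enzyme_id="t",
            points=[(0, 10, 0), (0, 30, 1), (2, 19, 0), (2, 19, 1), (4, 1, 0), (4, 1, 1)],
        )
        assert estimate_optimum(profile).optimum == 0.0


class TestDilutionFoldDifference:
    @staticmethod
    def _series(endpoint, grid=(2.0, 1e1, 1e2, 1e3, 1e4, 1e5, 1e6), reps=4):
        detections = [[d <= endpoint for d in grid] for _ in range(reps)]
        return DilutionSeries(enzyme_id="d", grid=list(grid), detections=detections)

    def test_identical_series_fold_one(self):
        a = self._series(1e4)
        assert dilution_fold_difference(a, a)[0] == 1.0

    def test_two_decade_shift_gives_fold_100_with_grid_interval(self):
        fold, (lo, hi) = dilution_fold_difference(self._series(1e6), self._series(1e4))
        assert fold == pytest.approx(100.0)
        assert (lo, hi) == (pytest.approx(10.0), pytest.approx(1000.0))

    def test_endpoint_monotone_in_added_detections(self):
        base = self._series(1e3)
        more = self._series(1e3)
        for row in more.detections[:2]:
            row[4] = True  # extra positives at 1e4 in half the replicates
        assert more.endpoint() >= base.endpoint()

    def test_all_negative_series_flagged(self):
        empty = self._series(0.1)
        with pytest.raises(ValueError, match="endpoint undefined"):
            dilution_fold_difference(empty, self._series(1e4))
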