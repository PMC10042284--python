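"""Limiting/non-limiting classification, critical points, SDM curve."""

import numpy as np
import pytest

from ricenc import DilutionCurve, critical_n
from ricenc.exceptions import (
    InsufficientReplicationError,
    NonResponsiveDateError,
    UnderdeterminedFitError,
)
from ricenc.sdm import (
    DateGroup,
    LimitingLabels,
    bootstrap_band,
    build_date_groups,
    classify_limiting,
    determine_nc_point,
    fit_sdm_curve,
    run_sdm,
)
from ricenc.synthetic import SyntheticConfig, generate_trial


def make_group(dw_means, n_means, reps=3, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    return DateGroup(
        experiment_id="E1",
        stage="PI",
        n_rates=np.arange(len(dw_means), dtype=float),
        dw=[m + noise * rng.standard_normal(reps) for m in dw_means],
        nconc=[np.full(reps, n) for n in n_means],
    )


class TestClassification:
    def test_identical_treatments_flagged_unusable(self):
        g = make_group([4.0, 4.0, 4.0, 4.0], [1.5, 2.0, 2.5, 3.0])
        labels = classify_limiting(g)
        assert not labels.usable
        assert labels.n_limiting == 0

    def test_degenerate_zero_variance_exact_comparison(self):
        # strictly increasing biomass, equal top two: only those two plateau
        g = make_group([2.0, 3.0, 4.0, 4.0], [1.2, 1.8, 2.4, 3.0])
        labels = classify_limiting(g)
        assert labels.usable
        assert labels.limiting.tolist() == [True, True, False, False]

    def test_labels_match_truth_under_moderate_noise(self):
        # Monte-Carlo oracle: with replicate noise at 5 % of the plateau,
        # treatments below/above the critical N stay correctly labelled
        plateau, a, b = 6.0, 3.5, 0.35
        nc = a * plateau ** (-b)
        mults = np.array([0.6, 0.83, 1.07, 1.3])
        slope = 0.9 * plateau / nc
        correct = total = 0
        for seed in range(100):
            n_means = mults * nc
            dw_means = plateau - slope * np.maximum(0.0, nc - n_means)
            g = make_group(dw_means, n_means, reps=3,
                           noise=0.05 * plateau, seed=seed)
            labels = classify_limiting(g)
            if not labels.usable:
                continue
            truth = n_means < nc
            correct += int((labels.limiting == truth).sum())
            total += len(mults)
        assert total > 0
        assert correct / total >= 0.95

    def test_insufficient_replication_rejected(self):
        with pytest.raises(InsufficientReplicationError):
            DateGroup(
                experiment_id="E", stage="TI",
                n_rates=np.array([0.0, 1.0, 2.0]),
                dw=[np.array([1.0]), np.array([2.0, 2.1]), np.array([3.0, 3.1])],
                nconc=[np.array([1.0]), np.array([2.0, 2.0]), np.array([3.0, 3.0])],
            )


class TestCriticalPoint:
    def test_two_point_line_plateau_intersection(self):
        g = make_group([2.0, 3.0, 4.0, 4.0], [1.5, 2.0, 2.6, 3.2])
        labels = LimitingLabels(
            limiting=np.array([True, True, False, False]), usable=True
        )
        pt = determine_nc_point(g, labels)
        assert pt.dw_c == pytest.approx(4.0)
        assert pt.nc == pytest.approx(2.5)  # slope 2, intercept -1

    def test_noise_free_generator_date_is_exact(self, noise_free_trial):
        _, samples, truth = noise_free_trial
        t = truth[0]
        groups = [
            g for g in build_date_groups(samples)
            if g.experiment_id == t.group_id
        ]
        for j, g in enumerate(groups):
            labels = classify_limiting(g)
            pt = determine_nc_point(g, labels)
            assert pt.dw_c == pytest.approx(t.plateau_dw[j], abs=1e-9)
            expected_nc = t.true_a * t.plateau_dw[j] ** (-t.true_b)
            assert pt.nc == pytest.approx(expected_nc, abs=1e-9)

    def test_non_responsive_date_rejected(self):
        g = make_group([4.0, 3.0, 2.0, 4.5], [1.5, 2.0, 2.5, 3.2])
        labels = LimitingLabels(
            limiting=np.array([True, True, True, False]), usable=True
        )
        with pytest.raises(NonResponsiveDateError):
            determine_nc_point(g, labels)


class TestSDMCurve:
    def test_recovery_under_low_noise(self):
        # biomass noise at 2 % of the earliest (smallest) plateau
        hits = 0
        for seed in range(20):
            cfg = SyntheticConfig(
                pop_mean_a=3.36, pop_mean_b=0.30, pop_sd_a=0.0, pop_sd_b=0.0,
                dw_noise_sd=0.01, n_noise_sd=0.02, seed=500 + seed,
            )
            samples, _ = generate_trial(cfg)
            curve, _, _ = run_sdm(samples)
            hits += abs(curve.a - 3.36) <= 0.15 and abs(curve.b - 0.30) <= 0.05
        assert hits >= 18

    def test_pooled_noise_free_points_recover_exactly(self, noise_free_trial):
        _, samples, _ = noise_free_trial
        curve, points, _ = run_sdm(samples)
        assert len(points) == 29 * 5
        assert curve.a == pytest.approx(3.36, abs=1e-6)
        assert curve.b == pytest.approx(0.30, abs=1e-6)

    def test_needs_biomass_span(self):
        from ricenc import NCPoint

        pts = [NCPoint(2.0 + 0.1 * i, 3.0 - 0.1 * i) for i in range(4)]
        with pytest.raises(UnderdeterminedFitError):
            fit_sdm_curve(pts)


class TestBootstrapBand:
    @staticmethod
    def _points(n, noise_sd, seed):
        rng = np.random.default_rng(seed)
        from ricenc import NCPoint

        dw = np.linspace(1.0, 10.0, n)
        nc = 3.4 * dw ** (-0.32) + noise_sd * rng.standard_normal(n)
        return [NCPoint(d, max(v, 0.1)) for d, v in zip(dw, nc)]

    def test_zero_residual_band_has_zero_width(self):
        pts = self._points(10, 0.0, 0)
        curve = fit_sdm_curve(pts)
        band = bootstrap_band(curve, pts, n_boot=200, seed=1)
        assert band.mean_width == pytest.approx(0.0, abs=1e-8)

    def test_band_is_deterministic_in_seed(self):
        pts = self._points(8, 0.1, 2)
        curve = fit_sdm_curve(pts)
        b1 = bootstrap_band(curve, pts, n_boot=100, seed=7)
        b2 = bootstrap_band(curve, pts, n_boot=100, seed=7)
        np.testing.assert_array_equal(b1.lower, b2.lower)
        np.testing.assert_array_equal(b1.upper, b2.upper)

    def test_band_narrows_with_more_points(self):
        # more sampling dates -> more critical points -> tighter band
        grid = np.linspace(1.5, 8.0, 25)
        wins = 0
        for seed in range(5):
            curve_s = fit_sdm_curve(self._points(8, 0.12, seed))
            w_small = bootstrap_band(
                curve_s, self._points(8, 0.12, seed),
                n_boot=300, seed=seed, dw_grid=grid,
            ).mean_width
            curve_l = fit_sdm_curve(self._points(16, 0.12, seed + 50))
            w_large = bootstrap_band(
                curve_l, self._points(16, 0.12, seed + 50),
                n_boot=300, seed=seed, dw_grid=grid,
            ).mean_width
            wins += w_large <= w_small
        assert wins >= 4


def test_emitted_points_lie_in_observed_n_range(default_trial):
    _, samples, _ = default_trial
    _, points, _ = run_sdm(samples)
    flagged = [p for p in points if p.extrapolated]
    in_range = [p for p in points if not p.extrapolated]
    assert len(in_range) > len(flagged)
    assert all(p.nc > 0 for p in points)
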