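"""GLM and grid-search fitting, cross-validation, voxel classification."""

import numpy as np
import pandas as pd
import pytest

from numadapt.design import TunedGrid, build_design, tuned_basis
from numadapt.models import (
    MonotonicResponseModel,  # noqa: F401 - used in fixtures below
    TunedResponseModel,
    VoxelRecord,
    classify_voxel,
    crossval_compare,
    fit_glm,
    grid_fit_tuned,
)


def make_voxel(y_runs, condition="changing", **meta):
    defaults = dict(voxel_id="v0", participant="P01", hemisphere="L",
                    map_label="V1", ecc_deg=0.5, polar_deg=0.0)
    defaults.update(meta)
    return VoxelRecord(timeseries={condition: [np.asarray(y) for y in y_runs]},
                       **defaults)


class TestFitGlm:
    def test_exact_linear_recovery(self, changing_design):
        y = 2.0 * changing_design["stimulus"].to_numpy() + 5.0
        fit = fit_glm(y, changing_design)
        assert fit.slope_ == pytest.approx(2.0, abs=1e-10)
        assert fit.baseline_ == pytest.approx(5.0, abs=1e-9)
        assert fit.r2_ == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations_on_random_instances(self, rng):
        for _ in range(10):
            X = pd.DataFrame({"stimulus": rng.normal(size=50),
                              "constant": np.ones(50)})
            y = rng.normal(size=50)
            fit = fit_glm(y, X)
            M = X.to_numpy()
            beta = np.linalg.solve(M.T @ M, M.T @ y)
            np.testing.assert_allclose(fit.coef_, beta, atol=1e-10)

    def test_pure_noise_gives_near_zero_r2_and_no_slope(self, changing_design,
                                                        rng):
        stim = changing_design["stimulus"].to_numpy()
        sxx = np.sum((stim - stim.mean()) ** 2)
        n_sig, r2s = 0, []
        for _ in range(100):
            y = rng.normal(size=264)
            fit = fit_glm(y, changing_design)
            r2s.append(fit.r2_)
            se = np.sqrt(np.sum((y - fit.predict(changing_design)) ** 2)
                         / 262 / sxx)
            n_sig += abs(fit.slope_ / se) > 1.96
        assert np.mean(r2s) < 0.05
        assert n_sig <= 12  # ~5% expected at alpha = 0.05

    def test_constant_adaptor_column_leaves_slope_unchanged(self, sequences,
                                                            power_table, rng):
        """An explicit constant adaptor regressor spans the same space as
        the baseline, so including it cannot change the fitted slope."""
        from numadapt.design import monotonic_neural_timecourse
        from numadapt.hrf import convolve_hrf

        X = build_design(sequences["low"], "monotonic", power_table=power_table)
        y = 1.7 * X["stimulus"].to_numpy() + rng.normal(size=264)
        adaptor_col = convolve_hrf(
            monotonic_neural_timecourse(sequences["low"], "adaptor",
                                        "log_power", power_table))
        assert np.ptp(adaptor_col) < 1e-9  # constant, but not equal to 1
        with_adaptor = pd.DataFrame({"stimulus": X["stimulus"],
                                     "adaptor": adaptor_col})
        assert fit_glm(y, X).slope_ == pytest.approx(
            fit_glm(y, with_adaptor).slope_, rel=1e-10)

    def test_rank_deficient_design_rejected(self, rng):
        X = pd.DataFrame({"stimulus": np.ones(20), "constant": np.ones(20)})
        with pytest.raises(ValueError):
            fit_glm(rng.normal(size=20), X)


class TestGridFitTuned:
    def test_matches_exhaustive_enumeration_on_mini_grid(self, changing_basis,
                                                         rng):
        prefs = np.repeat(np.linspace(0.2, 2.0, 5), 4)
        widths = np.tile(np.linspace(0.2, 1.0, 4), 5)
        grid = TunedGrid(prefs, widths)
        y = rng.normal(size=264)
        model = TunedResponseModel(grid=grid).fit(changing_basis, y)
        # brute force: explicit per-candidate least squares
        best = (np.inf, None)
        C = changing_basis.C
        for p, w in zip(prefs, widths):
            a = np.exp(-0.5 * ((np.log(changing_basis.numerosities) - p) / w) ** 2)
            x = a @ C
            xc, yc = x - x.mean(), y - y.mean()
            amp = max(0.0, float(xc @ yc) / float(xc @ xc))
            sse = float(np.sum((yc - amp * xc) ** 2))
            if sse < best[0] - 1e-12:
                best = (sse, (p, w))
        assert (model.pref_log_, model.width_log_) == best[1]
        assert model.sse_ == pytest.approx(best[0], abs=1e-8)

    def test_zero_noise_parameter_recovery_within_one_grid_step(
            self, changing_basis, full_grid):
        true_p, true_w = np.log(3), 0.5
        a = np.exp(-0.5 * ((np.log(changing_basis.numerosities) - true_p)
                           / true_w) ** 2)
        y = 1.3 * (a @ changing_basis.C) + 0.7
        m = TunedResponseModel(grid=full_grid).fit(changing_basis, y)
        assert abs(m.pref_log_ - true_p) <= 0.01
        assert abs(m.width_log_ - true_w) <= 0.0074
        assert m.amplitude_ > 0
        assert m.r2_ > 0.999

    def test_off_lattice_truths_recovered_to_joint_quantization_limit(
            self, changing_basis, full_grid, rng):
        """For truths between grid points the preference still lands within
        one step, while the width can shift a few steps to compensate the
        residual preference error (a property of the lattice, not noise)."""
        for _ in range(25):
            pref = rng.uniform(np.log(1.5), np.log(7.0))
            width = rng.uniform(0.2, 1.2)
            a = np.exp(-0.5 * ((np.log(changing_basis.numerosities) - pref)
                               / width) ** 2)
            y = a @ changing_basis.C
            m = TunedResponseModel(grid=full_grid).fit(changing_basis, y)
            assert abs(m.pref_log_ - pref) <= 0.01
            assert abs(m.width_log_ - width) <= 3 * 0.0074

    def test_noisy_recovery_median_error_below_three_grid_steps(
            self, changing_basis, full_grid, rng):
        true_p, true_w = np.log(4), 0.6
        a = np.exp(-0.5 * ((np.log(changing_basis.numerosities) - true_p)
                           / true_w) ** 2)
        clean = 1.0 * (a @ changing_basis.C)
        sd = 0.2 * clean.std()
        errs = []
        for _ in range(50):
            m = TunedResponseModel(grid=full_grid).fit(
                changing_basis, clean + rng.normal(0, sd, 264))
            errs.append(abs(m.pref_log_ - true_p))
        assert np.median(errs) < 3 * 0.01

    def test_amplitude_clipped_nonnegative(self, changing_basis, full_grid):
        # inverted tuned response: best nonneg-amplitude fit has amp >= 0
        a = np.exp(-0.5 * ((np.log(changing_basis.numerosities) - np.log(3))
                           / 0.5) ** 2)
        y = -1.0 * (a @ changing_basis.C)
        m = TunedResponseModel(grid=full_grid).fit(changing_basis, y)
        assert m.amplitude_ >= 0.0

    def test_tie_break_prefers_lowest_pref_then_width(self, changing_basis):
        grid = TunedGrid(np.array([0.5, 0.5, 1.0]), np.array([0.3, 0.6, 0.3]))
        # constant series: every candidate fits equally badly (amp -> 0)
        m = TunedResponseModel(grid=grid).fit(changing_basis, np.ones(264))
        assert (m.pref_log_, m.width_log_) == (0.5, 0.3)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            TunedGrid(np.array([]), np.array([]))

    def test_wrapper_equivalent_to_estimator(self, sequences, full_grid):
        basis = tuned_basis(sequences["changing"])
        a = np.exp(-0.5 * ((np.log(basis.numerosities) - 1.0) / 0.4) ** 2)
        y = a @ basis.C
        m1 = grid_fit_tuned(y, sequences["changing"], grid=full_grid)
        m2 = TunedResponseModel(grid=full_grid).fit(basis, y)
        assert (m1.pref_log_, m1.width_log_) == (m2.pref_log_, m2.width_log_)


class TestCrossvalAndClassification:
    def _mono_voxel(self, design, slope=1.5, noise=0.0, rng=None, runs=2):
        stim = design["stimulus"].to_numpy()
        ys = []
        for _ in range(runs):
            y = slope * stim + 2.0
            if noise and rng is not None:
                y = y + rng.normal(0, noise, len(y))
            ys.append(y)
        return make_voxel(ys)

    def _tuned_voxel(self, basis, pref, width=0.5, runs=2):
        a = np.exp(-0.5 * ((np.log(basis.numerosities) - pref) / width) ** 2)
        y = 1.2 * (a @ basis.C) + 0.3
        return make_voxel([y.copy() for _ in range(runs)])

    def test_simulated_monotonic_voxel_classified_monotonic(
            self, sequences, changing_design, changing_basis, full_grid,
            power_table):
        vox = self._mono_voxel(changing_design)
        cv = crossval_compare(vox, seq=sequences["changing"],
                              power_table=power_table, grid=full_grid,
                              design=changing_design, basis=changing_basis)
        assert cv.model_class == "monotonic"
        assert classify_voxel(cv) == "monotonic"
        assert cv.cv_r2["monotonic"] == pytest.approx(1.0, abs=1e-10)

    def test_simulated_tuned_voxel_classified_tuned(
            self, sequences, changing_design, changing_basis, full_grid,
            power_table):
        vox = self._tuned_voxel(changing_basis, np.log(3))
        cv = crossval_compare(vox, seq=sequences["changing"],
                              power_table=power_table, grid=full_grid,
                              design=changing_design, basis=changing_basis)
        assert cv.model_class == "tuned"
        assert classify_voxel(cv) == "tuned"

    def test_preference_above_seven_reclassified_monotonic(
            self, sequences, changing_design, changing_basis, full_grid,
            power_table):
        """A tuned fit preferring ~20 reflects a monotonic response."""
        vox = self._tuned_voxel(changing_basis, np.log(20))
        cv = crossval_compare(vox, seq=sequences["changing"],
                              power_table=power_table, grid=full_grid,
                              design=changing_design, basis=changing_basis)
        assert classify_voxel(cv) == "monotonic"

    def test_weak_tuned_fit_excluded_from_tuned_analyses(
            self, sequences, changing_design, changing_basis, full_grid,
            power_table, rng):
        a = np.exp(-0.5 * ((np.log(changing_basis.numerosities) - np.log(3))
                           / 0.5) ** 2)
        clean = a @ changing_basis.C
        sd = 6.0 * clean.std()  # overwhelm the signal
        runs = [clean + rng.normal(0, sd, 264) for _ in range(2)]
        vox = make_voxel(runs)
        cv = crossval_compare(vox, seq=sequences["changing"],
                              power_table=power_table, grid=full_grid,
                              design=changing_design, basis=changing_basis)
        if cv.model_class == "tuned" and np.exp(cv.tuned_fit.pref_log_) <= 7:
            assert cv.tuned_fit.r2_ < 0.2
            assert classify_voxel(cv) == "excluded"
        else:
            assert classify_voxel(cv) == "monotonic"

    def test_crossval_requires_two_runs(self, changing_design):
        vox = self._mono_voxel(changing_design, runs=1)
        with pytest.raises(ValueError):
            crossval_compare(vox)

    def test_cv_rescale_never_flips_sign(self, sequences, changing_design,
                                         changing_basis, full_grid,
                                         power_table):
        """A voxel anticorrelated between halves: rescaled evaluation clips
        the amplitude at zero rather than inverting the prediction."""
        stim = changing_design["stimulus"].to_numpy()
        vox = make_voxel([1.0 * stim, -1.0 * stim])
        cv = crossval_compare(vox, seq=sequences["changing"],
                              power_table=power_table, grid=full_grid,
                              design=changing_design, basis=changing_basis)
        for m, sse in cv.sse.items():
            # clipped amp = 0 leaves SS_tot as the residual, never more
            assert sse <= 2 * np.sum((stim - stim.mean()) ** 2) + 1e-6


class TestVoxelRecord:
    def test_unequal_run_lengths_rejected(self):
        with pytest.raises(ValueError):
            make_voxel([np.zeros(264), np.zeros(263)])

    def test_unknown_map_label_rejected(self):
        with pytest.raises(ValueError) as err:
            make_voxel([np.zeros(264)], map_label="V9")
        assert "V1" in str(err.value)

    def test_average_over_runs(self):
        vox = make_voxel([np.zeros(4), np.full(4, 2.0)])
        np.testing.assert_allclose(vox.average("changing"), 1.0)
        np.testing.assert_allclose(vox.average("changing", [1]), 2.0)
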