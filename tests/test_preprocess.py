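"""Pretreatment correctness: MSC, detrend, mean centering, SG derivatives."""

import numpy as np
import pytest

from mealnir.preprocess import (
    FittedPretreatment,
    PretreatmentSpec,
    Step,
    apply_pipeline,
    detrend,
    mean_center_fit,
    mean_center_transform,
    msc_fit_apply,
    msc_transform,
    sg_derivative,
)
from mealnir.spectra import SpectraError, SpectraSet, WavelengthGrid


def make_set(grid, rows, prefix="S"):
    rows = np.atleast_2d(rows)
    return SpectraSet(grid, rows, tuple(f"{prefix}{i}" for i in range(len(rows))))


class TestMSC:
    def test_rows_equal_to_mean_are_unchanged(self, small_grid):
        row = np.linspace(0.2, 0.7, len(small_grid))
        s = make_set(small_grid, np.tile(row, (4, 1)))
        out, fitted = msc_fit_apply(s)
        np.testing.assert_allclose(out.absorbance, s.absorbance, atol=1e-12)
        np.testing.assert_allclose(fitted.msc_coefficients[:, 0], 0, atol=1e-12)
        np.testing.assert_allclose(fitted.msc_coefficients[:, 1], 1, atol=1e-12)

    def test_exact_affine_model_recovered(self, small_grid):
        # two symmetric distortions keep the mean equal to the true reference
        ref = np.linspace(0.2, 0.7, len(small_grid)) + 0.1 * np.sin(
            np.arange(len(small_grid))
        )
        s1 = 1.5 * ref + 0.2
        s2 = 0.5 * ref - 0.2
        s = make_set(small_grid, np.vstack([s1, s2]))
        out, fitted = msc_fit_apply(s)
        np.testing.assert_allclose(out.absorbance[0], ref, atol=1e-9)
        a, b = fitted.msc_coefficients[0]
        assert a == pytest.approx(0.2, abs=1e-9)
        assert b == pytest.approx(1.5, abs=1e-9)

    def test_coefficients_match_normal_equations_oracle(self, random_spectra):
        out, fitted = msc_fit_apply(random_spectra)
        ref = random_spectra.absorbance.mean(axis=0)
        design = np.column_stack([np.ones_like(ref), ref])
        for i in range(random_spectra.n_samples):
            coef = np.linalg.solve(
                design.T @ design, design.T @ random_spectra.absorbance[i]
            )
            np.testing.assert_allclose(
                fitted.msc_coefficients[i], coef, atol=1e-10
            )
            np.testing.assert_allclose(
                out.absorbance[i],
                (random_spectra.absorbance[i] - coef[0]) / coef[1],
                atol=1e-10,
            )

    def test_transform_uses_stored_reference(self, rng, random_spectra,
                                             small_grid):
        _, fitted = msc_fit_apply(random_spectra)
        new = make_set(
            small_grid,
            0.25 + 0.04 * rng.standard_normal((5, len(small_grid))),
            prefix="V",
        )
        out = msc_transform(new, fitted)
        ref = fitted.msc_reference
        design = np.column_stack([np.ones_like(ref), ref])
        for i in range(5):
            a, b = np.linalg.lstsq(design, new.absorbance[i], rcond=None)[0]
            np.testing.assert_allclose(
                out.absorbance[i], (new.absorbance[i] - a) / b, atol=1e-10
            )

    def test_transform_of_scaled_reference_returns_reference(
        self, random_spectra, small_grid
    ):
        _, fitted = msc_fit_apply(random_spectra)
        new = make_set(small_grid, 2.0 * fitted.msc_reference, prefix="V")
        out = msc_transform(new, fitted)
        np.testing.assert_allclose(out.absorbance[0], fitted.msc_reference,
                                   atol=1e-10)

    def test_idempotence_on_scatter_family(self, rng, small_grid):
        # spectra of the form a + b*shape: one MSC pass removes the
        # scatter entirely, so a second pass is the identity
        shape = 0.2 + 0.3 * np.exp(
            -((small_grid.values - 1150.0) ** 2) / (2 * 15.0**2)
        )
        a = rng.uniform(-0.05, 0.05, 10)
        b = rng.uniform(0.8, 1.2, 10)
        s = make_set(small_grid, a[:, None] + b[:, None] * shape)
        once, _ = msc_fit_apply(s)
        twice, _ = msc_fit_apply(once)
        np.testing.assert_allclose(twice.absorbance, once.absorbance,
                                   atol=1e-9)

    def test_near_idempotence_on_band_spectra(self, rng, small_grid):
        # with per-sample band variation on top of scatter, a second MSC
        # pass moves each point far less than the first correction did
        shape = 0.2 + 0.3 * np.exp(
            -((small_grid.values - 1150.0) ** 2) / (2 * 15.0**2)
        )
        dev = 0.01 * rng.standard_normal((10, len(small_grid)))
        a = rng.uniform(-0.05, 0.05, 10)
        b = rng.uniform(0.8, 1.2, 10)
        s = make_set(small_grid, a[:, None] + b[:, None] * (shape + dev))
        once, _ = msc_fit_apply(s)
        twice, _ = msc_fit_apply(once)
        first_correction = np.abs(once.absorbance - s.absorbance).max()
        second_change = np.abs(twice.absorbance - once.absorbance).max()
        assert second_change < first_correction / 100.0

    def test_flat_spectrum_degenerate(self, small_grid):
        rows = np.vstack(
            [np.full(len(small_grid), 0.3), np.linspace(0.1, 0.9, len(small_grid))]
        )
        with pytest.raises(SpectraError, match="degenerate"):
            msc_fit_apply(make_set(small_grid, rows))


class TestDetrend:
    def test_exact_polynomial_removed(self, small_grid):
        lam = small_grid.values
        spectrum = 3.0 + 0.01 * lam + 1e-5 * lam**2
        out = detrend(make_set(small_grid, spectrum), order=2)
        np.testing.assert_allclose(out.absorbance, 0, atol=1e-9)

    def test_order_zero_subtracts_mean(self, random_spectra):
        out = detrend(random_spectra, order=0)
        expected = random_spectra.absorbance - random_spectra.absorbance.mean(
            axis=1, keepdims=True
        )
        np.testing.assert_allclose(out.absorbance, expected, atol=1e-12)

    def test_matches_polyfit_oracle(self, rng, small_grid):
        spectrum = 0.3 + 0.05 * rng.standard_normal(len(small_grid))
        out = detrend(make_set(small_grid, spectrum), order=2)
        lam = small_grid.values
        coef = np.polyfit(lam, spectrum, 2)
        np.testing.assert_allclose(
            out.absorbance[0], spectrum - np.polyval(coef, lam), atol=1e-9
        )

    def test_is_projection(self, random_spectra):
        once = detrend(random_spectra, order=2)
        twice = detrend(once, order=2)
        np.testing.assert_allclose(twice.absorbance, once.absorbance, atol=1e-9)

    def test_order_bound(self, small_grid):
        s = make_set(small_grid, np.zeros(len(small_grid)) + 0.1)
        with pytest.raises(SpectraError):
            detrend(s, order=len(small_grid))


class TestMeanCenter:
    def test_calibration_columns_centered(self, random_spectra):
        out, fitted = mean_center_fit(random_spectra)
        np.testing.assert_allclose(out.absorbance.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(
            fitted.column_means, random_spectra.absorbance.mean(axis=0)
        )

    def test_validation_row_at_mean_maps_to_zero(self, random_spectra,
                                                 small_grid):
        _, fitted = mean_center_fit(random_spectra)
        new = make_set(small_grid, fitted.column_means.copy(), prefix="V")
        out = mean_center_transform(new, fitted.column_means)
        np.testing.assert_allclose(out.absorbance, 0, atol=1e-12)

    def test_linearity(self, rng, small_grid):
        # centering commutes with linear combinations of whole sets
        p = len(small_grid)
        s1 = rng.standard_normal((4, p))
        s2 = rng.standard_normal((4, p))
        combo = make_set(small_grid, 2.0 * s1 + 3.0 * s2)
        out_combo, _ = mean_center_fit(combo)
        out1, _ = mean_center_fit(make_set(small_grid, s1))
        out2, _ = mean_center_fit(make_set(small_grid, s2))
        np.testing.assert_allclose(
            out_combo.absorbance,
            2.0 * out1.absorbance + 3.0 * out2.absorbance,
            atol=1e-12,
        )


class TestSGDerivative:
    def test_constant_spectrum_gives_zero(self, small_grid):
        s = make_set(small_grid, np.full(len(small_grid), 0.42))
        for deriv in (1, 2):
            out = sg_derivative(s, window=7, polyorder=3, deriv=deriv)
            np.testing.assert_allclose(out.absorbance, 0, atol=1e-12)

    def test_second_derivative_of_lambda_squared(self, small_grid):
        lam = small_grid.values
        s = make_set(small_grid, (lam - lam[0]) ** 2)
        out = sg_derivative(s, window=7, polyorder=3, deriv=2)
        interior = out.absorbance[0, 3:-3]
        np.testing.assert_allclose(interior, 2.0, atol=1e-6)

    def test_interior_matches_local_polyfit_oracle(self, rng, small_grid):
        spectrum = 0.3 + 0.02 * rng.standard_normal(len(small_grid))
        window, poly, deriv = 11, 3, 1
        out = sg_derivative(make_set(small_grid, spectrum), window, poly, deriv)
        half = window // 2
        step = small_grid.step
        x = (np.arange(window) - half) * step
        for j in (half, 20, len(small_grid) - half - 1):
            coef = np.polyfit(x, spectrum[j - half:j + half + 1], poly)
            # first derivative of the local fit at window centre
            expected = coef[-2]
            assert out.absorbance[0, j] == pytest.approx(expected, abs=1e-8)

    def test_even_window_rejected(self, random_spectra):
        with pytest.raises(SpectraError):
            sg_derivative(random_spectra, window=8, polyorder=2, deriv=1)


class TestPipeline:
    def test_none_is_identity(self, random_spectra):
        spec = PretreatmentSpec.parse("none")
        cal, others, _ = apply_pipeline(spec, random_spectra, [random_spectra])
        np.testing.assert_array_equal(cal.absorbance, random_spectra.absorbance)
        np.testing.assert_array_equal(
            others[0].absorbance, random_spectra.absorbance
        )

    def test_composition_matches_manual_sequence(self, rng, random_spectra,
                                                 small_grid):
        val = make_set(
            small_grid, 0.3 + 0.05 * rng.standard_normal((6, len(small_grid))),
            prefix="V",
        )
        spec = PretreatmentSpec.parse("msc+mc")
        cal, (val_out,), fitted = apply_pipeline(spec, random_spectra, [val])

        step1, f1 = msc_fit_apply(random_spectra)
        val1 = msc_transform(val, f1)
        step2, f2 = mean_center_fit(step1)
        val2 = mean_center_transform(val1, f2.column_means)
        np.testing.assert_allclose(cal.absorbance, step2.absorbance, atol=1e-12)
        np.testing.assert_allclose(val_out.absorbance, val2.absorbance,
                                   atol=1e-12)

    def test_double_mean_center_rejected(self):
        with pytest.raises(SpectraError):
            PretreatmentSpec((Step("mean_center"), Step("mean_center")), "mc+mc")

    def test_fitted_state_independent_of_validation_data(
        self, rng, random_spectra, small_grid
    ):
        # no leakage: fitted state must not change when validation changes
        spec = PretreatmentSpec.parse("msc+mc")
        v1 = make_set(small_grid, rng.standard_normal((4, len(small_grid))),
                      prefix="V")
        v2 = make_set(small_grid, rng.standard_normal((4, len(small_grid))),
                      prefix="W")
        _, _, f1 = apply_pipeline(spec, random_spectra, [v1])
        _, _, f2 = apply_pipeline(spec, random_spectra, [v2])
        np.testing.assert_array_equal(f1.msc_reference, f2.msc_reference)
        np.testing.assert_array_equal(f1.column_means, f2.column_means)

    def test_grid_mismatch_rejected(self, random_spectra):
        other = make_set(
            WavelengthGrid(1100.0 + 4.0 * np.arange(30)),
            np.zeros((2, 30)) + 0.1,
            prefix="V",
        )
        with pytest.raises(SpectraError):
            apply_pipeline(PretreatmentSpec.parse("mc"), random_spectra, [other])

    @pytest.mark.parametrize("label", ["none", "msc", "mc", "d1", "d2",
                                       "msc+detrend", "msc+mc"])
    def test_labels_round_trip(self, label):
        assert PretreatmentSpec.parse(label).label == label
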