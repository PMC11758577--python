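import math

import numpy as np
import pandas as pd
import pytest

from nanoscint.rl_spectra import (
    FitOptions,
    FitResult,
    GaussianComponent,
    Q_BAND_CENTERS_EV,
    Spectrum,
    component_report,
    default_component_set,
    ev_to_nm,
    fit_lm,
    model_eval,
    nm_to_ev,
)
from nanoscint.synthetic_data import SyntheticSpectrumSpec, make_spectrum


class TestConversions:
    @pytest.mark.parametrize("ev,nm", [(2.01, 617), (2.2, 564),
                                       (2.34, 530), (2.5, 496),
                                       (3.09, 401)])
    def test_q_band_pairs(self, ev, nm):
        assert round(ev_to_nm(ev)) == nm

    def test_inverse_round_trip(self):
        x = np.linspace(300.0, 900.0, 13)
        np.testing.assert_allclose(ev_to_nm(nm_to_ev(x)), x, rtol=1e-12)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            ev_to_nm(0.0)
        with pytest.raises(ValueError):
            nm_to_ev(-5.0)


class TestModelEval:
    def test_empty_component_list_is_zero(self):
        grid = np.linspace(1, 4, 50)
        np.testing.assert_array_equal(model_eval([], grid), 0.0)

    def test_unit_area_integrates_to_one(self):
        grid = np.linspace(-10, 14, 5000)
        c = GaussianComponent(2.0, 0.3, 1.0, "positive")
        y = model_eval([c], grid)
        assert np.trapezoid(y, grid) == pytest.approx(1.0, abs=1e-6)

    def test_equal_opposite_components_cancel(self):
        grid = np.linspace(1, 4, 200)
        cp = GaussianComponent(2.2, 0.2, 5.0, "positive")
        cn = GaussianComponent(2.2, 0.2, -5.0, "negative")
        np.testing.assert_allclose(model_eval([cp, cn], grid), 0.0,
                                   atol=1e-12)


class TestFit:
    def test_noiseless_single_gaussian_recovered(self):
        grid = np.linspace(1.2, 4.5, 400)
        truth = GaussianComponent(2.3, 0.21, 7.0, "positive")
        spec = Spectrum(grid, model_eval([truth], grid))
        init = GaussianComponent(2.25, 0.3, 2.0, "positive")
        fit = fit_lm(spec, [init])
        assert fit.converged
        c = fit.components[0]
        assert c.center == pytest.approx(2.3, rel=1e-6)
        assert c.sigma == pytest.approx(0.21, rel=1e-6)
        assert c.area == pytest.approx(7.0, rel=1e-6)

    def test_noiseless_full_component_set_recovered(self):
        spectrum, truth = make_spectrum(
            SyntheticSpectrumSpec(seed=0, noise_model="none"))
        fit = fit_lm(spectrum, default_component_set("functionalized"))
        assert fit.converged
        for c, t in zip(fit.components, truth):
            assert c.center == pytest.approx(t.center, abs=1e-5)

    def test_negative_component_initialised_positive_rejected(self):
        with pytest.raises(ValueError, match="negative-constrained"):
            GaussianComponent(2.2, 0.1, 1.0, "negative")

    def test_sign_constraints_respected_after_fit(self):
        spectrum, _ = make_spectrum(SyntheticSpectrumSpec(seed=3))
        fit = fit_lm(spectrum, default_component_set("functionalized"))
        for c in fit.components:
            if c.sign_constraint == "positive":
                assert c.area > 0
            elif c.sign_constraint == "negative":
                assert c.area < 0

    def test_descent_never_increases_chi_square(self):
        spectrum, _ = make_spectrum(SyntheticSpectrumSpec(seed=4))
        init = default_component_set("functionalized")
        fit = fit_lm(spectrum, init)
        # chi-square of the returned parameters cannot exceed that of any
        # accepted predecessor, in particular the (area-seeded) start
        spec = spectrum.crop(1.2, 4.5)
        winv = 1.0 / spec.uncertainty
        start = fit_lm(spec, init, FitOptions(max_iterations=1))
        assert fit.chi_square <= start.chi_square + 1e-9

    def test_grid_not_covering_centers_rejected(self):
        grid = np.linspace(1.2, 2.0, 100)
        spec = Spectrum(grid, np.ones_like(grid))
        with pytest.raises(ValueError, match="does not cover"):
            fit_lm(spec, [GaussianComponent(3.0, 0.1, 1.0, "positive")],
                   window=None)

    def test_non_monotone_grid_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            Spectrum(np.array([1.0, 0.9, 2.0]), np.zeros(3))


class TestDefaultSets:
    def test_functionalized_has_exactly_four_negatives(self):
        comps = default_component_set("functionalized")
        negs = [c for c in comps if c.sign_constraint == "negative"]
        assert len(negs) == 4
        assert sorted(c.center for c in negs) == list(Q_BAND_CENTERS_EV)

    def test_bare_has_no_negatives_and_required_bands(self):
        comps = default_component_set("bare")
        assert all(c.sign_constraint == "positive" for c in comps)
        centers = [c.center for c in comps]
        assert len(comps) >= 6
        assert 2.22 in centers and 3.09 in centers

    def test_all_centers_inside_window(self):
        for variant in ("bare", "functionalized", "dye-only"):
            for c in default_component_set(variant):
                assert 1.2 <= c.center <= 4.5

    def test_dye_only_has_no_excitonic_band(self):
        centers = [c.center for c in default_component_set("dye-only")]
        assert all(abs(c - 3.09) > 0.5 for c in centers)


class TestReport:
    def test_fwhm_closed_form(self):
        c = GaussianComponent(2.0, 1.0, 1.0, "positive")
        assert c.fwhm == pytest.approx(2.3548, abs=1e-4)

    def test_report_contents_and_round_trip(self, tmp_path):
        spectrum, _ = make_spectrum(SyntheticSpectrumSpec(seed=5))
        fit = fit_lm(spectrum, default_component_set("functionalized"))
        rep = component_report(fit)
        pos_share = rep.loc[rep.area > 0, "positive_share_pct"].sum()
        assert pos_share == pytest.approx(100.0, abs=1e-9)
        p = tmp_path / "report.csv"
        rep.to_csv(p, index=False)
        back = pd.read_csv(p)
        np.testing.assert_allclose(back["center_eV"].values,
                                   rep["center_eV"].values, rtol=1e-12)
        assert list(back.columns) == list(rep.columns)

    def test_unconverged_fit_refused(self):
        fake = FitResult([], 1.0, 1, False, None, np.zeros(3))
        with pytest.raises(ValueError, match="unconverged"):
            component_report(fake)


class TestRecoverySmoke:
    def test_centers_recovered_within_posterior_interval(self):
        # gross-regression guard: a handful of replicates, each requiring
        # nearly all centers inside their 3-sigma posterior interval (the
        # full 200-replicate recovery study enforces the strict joint
        # criterion)
        for seed in range(5):
            spectrum, truth = make_spectrum(SyntheticSpectrumSpec(seed=seed))
            fit = fit_lm(spectrum, default_component_set("functionalized"))
            assert fit.converged
            n_in = sum(
                fit.center_interval(i)[0] - 1e-12 <= t.center
                <= fit.center_interval(i)[1] + 1e-12
                for i, t in enumerate(truth))
            assert n_in >= 9  # at most one marginal miss out of ten
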