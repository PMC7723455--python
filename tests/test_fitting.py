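"""Order-parameter fitting: recovery, uncertainty, reporting."""

import numpy as np
import pytest

from spinorder import (
    DephasingCurve,
    MASCondition,
    dephasing_curve,
    estimate_uncertainty,
    fit_dephasing,
    fit_report,
)
from spinorder.fitting import BoundaryWarning
from conftest import REPORTED_S


def make_curve(s, pair, scale, mas, powder, **kw):
    c = dephasing_curve(scale.kappa * s * pair.d_rigid, mas, powder)
    return DephasingCurve(mas=mas, intensities=c.intensities, **kw)


class TestRecovery:
    def test_flat_curve_fits_zero(self, pair, scale, mas9, powder):
        flat = DephasingCurve(mas=mas9, intensities=np.ones(9))
        fit = fit_dephasing(flat, pair, scale, powder=powder, uncertainty="none")
        assert fit.S_fit == pytest.approx(0.0, abs=1e-3)

    @pytest.mark.parametrize("s_true", REPORTED_S)
    def test_noise_free_round_trip_reported_values(self, s_true, pair, scale,
                                                   mas9, powder):
        """Every reported order parameter round-trips within 0.01 on a
        noise-free 9-point curve."""
        curve = make_curve(s_true, pair, scale, mas9, powder)
        fit = fit_dephasing(curve, pair, scale, powder=powder, uncertainty="none")
        assert fit.S_fit == pytest.approx(s_true, abs=0.01)

    def test_noise_free_sweep_sub_millis_accuracy(self, pair, scale, mas9, powder):
        """Self-consistency sweep: S in {0.1 ... 0.9} recovered < 1e-3."""
        worst = 0.0
        for s_true in np.arange(0.1, 0.95, 0.1):
            curve = make_curve(float(s_true), pair, scale, mas9, powder)
            fit = fit_dephasing(curve, pair, scale, powder=powder,
                                uncertainty="none")
            worst = max(worst, abs(fit.S_fit - s_true))
        assert worst < 1e-3

    def test_seven_point_grid_also_fits(self, pair, scale, mas7, powder):
        curve = make_curve(0.6, pair, scale, mas7, powder)
        fit = fit_dephasing(curve, pair, scale, powder=powder, uncertainty="none")
        assert fit.S_fit == pytest.approx(0.6, abs=0.01)

    def test_distinct_s_give_distinct_fits(self, pair, scale, mas9, powder):
        fits = [fit_dephasing(make_curve(s, pair, scale, mas9, powder),
                              pair, scale, powder=powder,
                              uncertainty="none").S_fit
                for s in (0.2, 0.4, 0.6, 0.8)]
        assert np.all(np.diff(fits) > 0.1)

    def test_amplitude_absorbs_normalization_error(self, pair, scale, mas9, powder):
        curve = make_curve(0.5, pair, scale, mas9, powder)
        scaled = DephasingCurve(mas=mas9, intensities=curve.intensities * 1.05)
        fit = fit_dephasing(scaled, pair, scale, powder=powder,
                            uncertainty="none")
        assert fit.S_fit == pytest.approx(0.5, abs=0.01)

    def test_too_few_points_rejected(self, pair, scale, powder):
        mas = MASCondition(nu_r=5000.0, t1_grid=np.linspace(0, 2e-4, 4))
        curve = DephasingCurve(mas=mas, intensities=np.ones(4))
        with pytest.raises(ValueError, match="points"):
            fit_dephasing(curve, pair, scale, powder=powder)

    def test_boundary_fit_warns(self, pair, scale, mas9, powder):
        curve = make_curve(1.0, pair, scale, mas9, powder)
        with pytest.warns(BoundaryWarning):
            fit_dephasing(curve, pair, scale, powder=powder, uncertainty="none")


class TestUncertainty:
    def test_noise_free_jackknife_near_zero(self, pair, scale, mas9, powder):
        curve = make_curve(0.5, pair, scale, mas9, powder)
        fit = fit_dephasing(curve, pair, scale, powder=powder,
                            uncertainty="jackknife")
        assert fit.sigma_S < 1e-3
        assert fit.uncertainty_method == "jackknife"

    def test_jackknife_needs_six_points(self, pair, scale, powder):
        mas = MASCondition.evenly_spaced(5000.0, 5)
        curve = make_curve(0.5, pair, scale, mas, powder)
        fit = fit_dephasing(curve, pair, scale, powder=powder, uncertainty="none")
        with pytest.raises(ValueError, match="6 points"):
            estimate_uncertainty(curve, fit, method="jackknife",
                                 pair=pair, scale=scale, powder=powder)

    def test_jackknife_finite_on_noisy_nine_points(self, pair, scale, mas9,
                                                   powder, rng):
        base = make_curve(0.5, pair, scale, mas9, powder)
        noisy = DephasingCurve(mas=mas9,
                               intensities=base.intensities
                               + rng.normal(0, 0.02, 9))
        fit = fit_dephasing(noisy, pair, scale, powder=powder,
                            uncertainty="jackknife")
        assert np.isfinite(fit.sigma_S) and fit.sigma_S >= 0

    def test_jackknife_tracks_monte_carlo_spread(self, pair, scale, mas9,
                                                 powder, rng):
        """Jackknife sigma is consistent with the replicate scatter of
        S_fit within a factor of 2 (50 noisy replicates at S = 0.5)."""
        base = make_curve(0.5, pair, scale, mas9, powder)
        noise_sd = 0.02
        fits, sigmas = [], []
        for _ in range(50):
            noisy = DephasingCurve(
                mas=mas9,
                intensities=base.intensities + rng.normal(0, noise_sd, 9))
            f = fit_dephasing(noisy, pair, scale, powder=powder,
                              uncertainty="jackknife")
            fits.append(f.S_fit)
            sigmas.append(f.sigma_S)
        spread = np.std(fits)
        typical_sigma = np.median(sigmas)
        assert spread / 2 < typical_sigma < spread * 2

    def test_curvature_method_reasonable(self, pair, scale, mas9, powder, rng):
        base = make_curve(0.5, pair, scale, mas9, powder)
        noisy = DephasingCurve(mas=mas9,
                               intensities=base.intensities
                               + rng.normal(0, 0.02, 9))
        fit = fit_dephasing(noisy, pair, scale, powder=powder,
                            uncertainty="curvature")
        assert 0 < fit.sigma_S < 0.2

    def test_unknown_method_rejected(self, pair, scale, mas9, powder):
        curve = make_curve(0.5, pair, scale, mas9, powder)
        fit = fit_dephasing(curve, pair, scale, powder=powder, uncertainty="none")
        with pytest.raises(ValueError, match="unknown"):
            estimate_uncertainty(curve, fit, method="bootstrap",
                                 pair=pair, scale=scale)


class TestFitReport:
    def test_single_result_single_row(self, pair, scale, mas9, powder):
        fit = fit_dephasing(make_curve(0.5, pair, scale, mas9, powder),
                            pair, scale, powder=powder, uncertainty="none")
        table = fit_report([fit], labels=["helix"])
        assert len(table) == 1
        assert table.loc[0, "label"] == "helix"
        assert table.loc[0, "S"] == pytest.approx(0.5, abs=0.01)

    def test_three_conditions_ordered(self, pair, scale, mas9, powder):
        """cp 20 us, cp 700 us, direct sort into that order per label."""
        kw = [dict(excitation="cp", contact_time=700e-6),
              dict(excitation="direct"),
              dict(excitation="cp", contact_time=20e-6)]
        fits = [fit_dephasing(make_curve(0.5, pair, scale, mas9, powder, **k),
                              pair, scale, powder=powder, uncertainty="none")
                for k in kw]
        table = fit_report(fits, labels=["helix"] * 3)
        assert list(table["excitation"]) == ["cp", "cp", "direct"]
        assert table.loc[0, "contact_time_us"] == pytest.approx(20.0)
        assert table.loc[1, "contact_time_us"] == pytest.approx(700.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fit_report([])
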