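"""Chemical-shift classification and 1D/2D integration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinorder import (
    RegionTable,
    Spectrum1D,
    Spectrum2D,
    class_fractions,
    classify_dca_dcb,
    classify_shift,
    default_random_coil_table,
    default_region_table,
    gen_spectrum_1d,
    gen_spectrum_2d,
    integrate_crosspeaks_2d,
    integrate_region_1d,
)


class TestClassifyShift:
    @pytest.mark.parametrize("residue,ppm,expected", [
        ("Met", 57.0, "helix"),
        ("Met", 53.5, "coil"),
        ("Met", 52.0, "sheet"),
        ("Met", 60.0, "unassigned"),   # above the helix window
        ("Arg", 58.0, "helix"),
        ("Arg", 55.0, "coil"),
        ("Arg", 52.0, "sheet"),
        ("Arg", 53.7, "unassigned"),   # deliberate gap 53.3-54.0 ppm
        ("His", 57.5, "helix"),
        ("His", 54.0, "coil"),
        ("His", 51.0, "sheet"),
    ])
    def test_window_membership(self, residue, ppm, expected):
        assert classify_shift(residue, ppm) == expected

    def test_shared_boundary_goes_to_higher_ppm_window(self):
        # His helix and coil windows touch at 56.0; Met coil and sheet at 52.7
        assert classify_shift("His", 56.0) == "helix"
        assert classify_shift("Met", 52.7) == "coil"

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError, match="unknown residue"):
            classify_shift("Trp", 57.0)

    def test_misordered_windows_rejected(self):
        with pytest.raises(ValueError, match="ordered"):
            RegionTable(windows={"Xaa": {"helix": (50.0, 53.0),
                                         "coil": (54.0, 56.0),
                                         "sheet": 52.0}})


class TestClassifyDeltaShift:
    def test_zero_secondary_shift_is_coil(self):
        rc = default_random_coil_table()
        for res, (ca, cb) in rc.shifts.items():
            assert classify_dca_dcb(res, ca, cb) == "coil"

    def test_positive_delta_is_helix_negative_is_sheet(self):
        rc = default_random_coil_table()
        ca, cb = rc.shifts["Met"]
        assert classify_dca_dcb("Met", ca + 3.0, cb - 1.0) == "helix"
        assert classify_dca_dcb("Met", ca - 3.0, cb + 1.0) == "sheet"

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="random-coil"):
            classify_dca_dcb("Trp", 57.0, 30.0)

    def test_agrees_with_window_rule_at_window_centers(self):
        """Peaks with Calpha at window centers and Cbeta offset with the
        matching secondary-structure sign classify identically by both
        rules."""
        rc = default_random_coil_table()
        table = default_region_table()
        for res in table.residues():
            win = table.windows[res]
            ca_rc, cb_rc = rc.shifts[res]
            cases = {
                "helix": (np.mean(win["helix"]), cb_rc - 1.0),
                "sheet": (win["sheet"] - 2.0, cb_rc + 2.0),
            }
            for expected, (ca, cb) in cases.items():
                assert classify_shift(res, ca, table) == expected
                assert classify_dca_dcb(res, ca, cb, rc) == expected


class TestIntegration1D:
    def test_unit_rectangle_area(self):
        ppm = np.linspace(60, 50, 501)
        inten = np.where((ppm >= 54) & (ppm <= 56), 1.0, 0.0)
        spec = Spectrum1D(ppm=ppm, intensity=inten)
        assert integrate_region_1d(spec, (54, 56)) == pytest.approx(2.0, rel=1e-6)

    def test_gaussian_area_matches_analytic(self):
        ppm = np.linspace(70, 40, 2001)
        spec = gen_spectrum_1d([(55.0, 0.5, 3.0)], ppm)
        assert integrate_region_1d(spec, (50, 60)) == pytest.approx(3.0, rel=0.01)

    def test_flat_zero_baseline_integrates_to_zero(self):
        spec = Spectrum1D(ppm=np.linspace(60, 50, 101),
                          intensity=np.zeros(101))
        assert integrate_region_1d(spec, (52, 58)) == 0.0

    def test_orientation_independence(self):
        asc = np.linspace(50, 60, 501)
        y = np.exp(-0.5 * ((asc - 55) / 0.5) ** 2)
        a1 = integrate_region_1d(Spectrum1D(ppm=asc, intensity=y), (52, 58))
        a2 = integrate_region_1d(Spectrum1D(ppm=asc[::-1], intensity=y[::-1]),
                                 (52, 58))
        assert a1 == pytest.approx(a2, rel=1e-12)
        assert a1 > 0

    def test_empty_overlap_rejected(self):
        spec = Spectrum1D(ppm=np.linspace(60, 50, 101),
                          intensity=np.ones(101))
        with pytest.raises(ValueError, match="overlap"):
            integrate_region_1d(spec, (80, 90))

    def test_linearity(self, rng):
        ppm = np.linspace(60, 50, 301)
        y1 = rng.normal(size=301)
        y2 = rng.normal(size=301)
        w = (53, 57)
        s = integrate_region_1d(Spectrum1D(ppm=ppm, intensity=y1 + y2), w)
        parts = (integrate_region_1d(Spectrum1D(ppm=ppm, intensity=y1), w)
                 + integrate_region_1d(Spectrum1D(ppm=ppm, intensity=y2), w))
        assert s == pytest.approx(parts, abs=1e-10)


class TestIntegration2D:
    @pytest.fixture()
    def axes(self):
        return np.linspace(65, 45, 401), np.linspace(45, 20, 401)

    def test_unit_volume_gaussian_recovered(self, axes):
        f1, f2 = axes
        spec = gen_spectrum_2d([((56.0, 33.0), (0.4, 0.4), 1.0)], f1, f2)
        vol, = integrate_crosspeaks_2d(spec, [((53, 59), (30, 36))])
        assert vol == pytest.approx(1.0, rel=0.01)

    def test_empty_region_integrates_to_zero(self, axes):
        f1, f2 = axes
        spec = gen_spectrum_2d([((56.0, 33.0), (0.3, 0.3), 1.0)], f1, f2)
        vol, = integrate_crosspeaks_2d(spec, [((46, 50), (21, 25))])
        assert vol == pytest.approx(0.0, abs=1e-6)

    def test_box_order_invariance(self, axes):
        f1, f2 = axes
        spec = gen_spectrum_2d([((56.0, 33.0), (0.3, 0.3), 2.0),
                                ((50.0, 25.0), (0.3, 0.3), 1.0)], f1, f2)
        b1 = ((54, 58), (31, 35))
        b2 = ((48, 52), (23, 27))
        v12 = integrate_crosspeaks_2d(spec, [b1, b2])
        v21 = integrate_crosspeaks_2d(spec, [b2, b1])
        assert v12[0] == pytest.approx(v21[1])
        assert v12[1] == pytest.approx(v21[0])

    def test_overlapping_boxes_rejected(self, axes):
        f1, f2 = axes
        spec = gen_spectrum_2d([], f1, f2)
        with pytest.raises(ValueError, match="overlap"):
            integrate_crosspeaks_2d(spec, [((50, 56), (25, 35)),
                                           ((55, 60), (30, 40))])

    def test_box_outside_axes_rejected(self, axes):
        f1, f2 = axes
        spec = gen_spectrum_2d([], f1, f2)
        with pytest.raises(ValueError, match="overlap"):
            integrate_crosspeaks_2d(spec, [((80, 90), (25, 35))])


class TestClassFractions:
    def test_reported_met_sheet_fraction_structure(self):
        fracs = class_fractions({"helix": 77.0, "sheet": 23.0})
        assert fracs["sheet"] == pytest.approx(0.23)

    def test_single_class_is_one(self):
        assert class_fractions({"helix": 5.0}) == {"helix": 1.0}

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            class_fractions({"helix": 0.0, "sheet": 0.0})

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            class_fractions({"helix": -1.0, "sheet": 2.0})

    @given(values=st.lists(st.floats(min_value=0.01, max_value=1e3),
                           min_size=1, max_size=5))
    @settings(deadline=None)
    def test_fractions_sum_to_one(self, values):
        fracs = class_fractions({f"c{i}": v for i, v in enumerate(values)})
        assert sum(fracs.values()) == pytest.approx(1.0, abs=1e-12)


class TestSpectrumContainers:
    def test_non_monotone_axis_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            Spectrum1D(ppm=np.array([60.0, 55.0, 56.0]),
                       intensity=np.zeros(3))

    def test_ascending_input_normalized_to_descending(self):
        spec = Spectrum1D(ppm=np.array([50.0, 55.0, 60.0]),
                          intensity=np.array([1.0, 2.0, 3.0]))
        assert spec.original_order == "ascending"
        assert spec.ppm[0] > spec.ppm[-1]
        assert spec.intensity[0] == 3.0

    def test_2d_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            Spectrum2D(ppm_f1=np.linspace(60, 50, 4),
                       ppm_f2=np.linspace(40, 30, 5),
                       intensity=np.zeros((5, 4)))
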