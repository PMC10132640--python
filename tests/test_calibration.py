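import numpy as np
import pytest

from paleoiso.calibration import (
    CalConfig,
    CalibrationCurve,
    RadiocarbonDate,
    calbp_to_calbc,
    calibrate,
    load_curve,
    mixed_curve_draw,
    write_curve,
)
from paleoiso.synthetic_data import SyntheticScenario, gen_curves


def identity_curve(lo=2000.0, hi=4000.0, sigma=0.0, step=5.0):
    t = np.arange(lo, hi + step / 2, step)
    return CalibrationCurve("ident", t, t.copy(), np.full_like(t, sigma))


@pytest.fixture(scope="module")
def synth_curves():
    return gen_curves(SyntheticScenario(seed=1))


class TestLoadCurve:
    def test_reads_three_row_file(self, tmp_path):
        p = tmp_path / "c.14c"
        p.write_text("# hdr\n3000,2900,20\n2990, 2895,20\n2980 2890 21\n")
        c = load_curve(p)
        assert len(c) == 3
        assert c.cal_bp[0] == 2980  # sorted ascending

    def test_zero_sigma_row_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "c.14c"
        p.write_text("3000,2900,20\n2990,2895,0\n")
        with pytest.raises(ValueError, match=":2"):
            load_curve(p)

    def test_short_file_rejected(self, tmp_path):
        p = tmp_path / "c.14c"
        p.write_text("3000,2900,20\n")
        with pytest.raises(ValueError, match="at least 2"):
            load_curve(p)

    def test_duplicate_knots_rejected(self, tmp_path):
        p = tmp_path / "c.14c"
        p.write_text("3000,2900,20\n3000,2905,20\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_curve(p)

    def test_non_numeric_rejected(self, tmp_path):
        p = tmp_path / "c.14c"
        p.write_text("3000,abc,20\n2990,2895,20\n")
        with pytest.raises(ValueError, match="non-numeric"):
            load_curve(p)

    def test_roundtrip_preserves_knots_exactly(self, tmp_path, synth_curves):
        terr, _ = synth_curves
        p = tmp_path / "t.14c"
        write_curve(terr, p)
        back = load_curve(p)
        assert np.array_equal(back.cal_bp, terr.cal_bp)
        assert np.array_equal(back.mu, terr.mu)
        assert np.array_equal(back.sigma_curve, terr.sigma_curve)


class TestMixedCurve:
    def test_m_zero_is_terrestrial(self, synth_curves):
        terr, mar = synth_curves
        t, mu, sg = mixed_curve_draw(terr, mar, 0.0, -138.0)
        assert np.allclose(mu, terr.interp_mu(t))
        assert np.allclose(sg, terr.interp_sigma(t))

    def test_m_one_no_reservoir_is_marine(self, synth_curves):
        terr, mar = synth_curves
        t, mu, sg = mixed_curve_draw(terr, mar, 1.0, 0.0)
        assert np.allclose(mu, mar.interp_mu(t))
        assert np.allclose(sg, mar.interp_sigma(t))

    def test_quarter_marine_with_reservoir_offset(self, synth_curves):
        terr, mar = synth_curves
        t, mu, _ = mixed_curve_draw(terr, mar, 0.25, -138.0)
        # marine = terrestrial + 400, so mix = terr + 0.25*(400-138)
        assert np.allclose(mu - terr.interp_mu(t), 65.5)

    def test_bad_fraction_rejected(self, synth_curves):
        terr, mar = synth_curves
        with pytest.raises(ValueError):
            mixed_curve_draw(terr, mar, 1.5, 0.0)

    def test_outside_common_span_rejected(self, synth_curves):
        terr, mar = synth_curves
        with pytest.raises(ValueError):
            mixed_curve_draw(terr, mar, 0.5, 0.0, t=np.array([1e6]))


class TestCalibrate:
    def date(self, cra=3000.0, **kw):
        base = dict(
            lab_code="L", burial_id="B", cra=cra, sigma=30.0
        )
        base.update(kw)
        return RadiocarbonDate(**base)

    def test_identity_curve_matches_gaussian_two_sigma(self):
        res = calibrate(self.date(), identity_curve())
        assert res.range_2sigma.segments == ((1110.0, 990.0, pytest.approx(95.4, abs=0.2)),)

    def test_density_normalized(self, synth_curves):
        terr, mar = synth_curves
        res = calibrate(
            self.date(marine_frac=0.2, marine_frac_sd=0.1, deltaR=-138, deltaR_sd=23),
            terr,
            mar,
        )
        assert res.density.sum() == pytest.approx(1.0, abs=1e-6)

    def test_segment_probabilities_sum_to_level(self):
        # wiggly curve forces multi-segment ranges
        terr, mar = gen_curves(SyntheticScenario(seed=2, curve_model="wiggly",
                                                 wiggle_amplitude=40.0))
        res = calibrate(
            self.date(marine_frac=0.25, marine_frac_sd=0.12, deltaR=-138, deltaR_sd=23),
            terr,
            mar,
        )
        total = sum(p for _, _, p in res.range_2sigma.segments)
        assert total == pytest.approx(95.4, abs=0.2)

    def test_zero_marine_zero_reservoir_reduces_to_single_curve(self, synth_curves):
        terr, mar = synth_curves
        a = calibrate(self.date(), terr)
        b = calibrate(self.date(marine_frac=0.0, marine_frac_sd=0.0), terr, mar)
        assert np.allclose(a.density, b.density)

    def test_increasing_marine_fraction_shifts_posterior_older_calendar(self, synth_curves):
        """With a +400 yr reservoir (minus deltaR), more marine carbon means
        the same CRA maps to younger true ages; in cal BP the posterior
        median must decrease monotonically in m."""
        terr, mar = synth_curves
        medians = []
        for m in (0.0, 0.2, 0.4, 0.6):
            res = calibrate(self.date(marine_frac=m), terr, mar)
            cdf = np.cumsum(res.density)
            medians.append(res.grid_cal_bp[np.searchsorted(cdf, 0.5)])
        assert all(a > b for a, b in zip(medians, medians[1:]))

    def test_hdr_is_minimal_among_equal_mass_sets(self):
        """Brute force on a coarse grid: no other same-mass set of grid
        points is smaller than the HDR's."""
        terr = identity_curve(lo=2800, hi=3200, sigma=0.0, step=20.0)
        res = calibrate(self.date(), terr, config=CalConfig(grid_step=20.0))
        level = 0.954
        order = np.argsort(res.density)[::-1]
        n_hdr = int(np.searchsorted(np.cumsum(res.density[order]), level)) + 1
        # any other selection of grid points reaching the level needs >= n_hdr points
        for trial in range(50):
            rng = np.random.default_rng(trial)
            perm = rng.permutation(len(res.density))
            csum = np.cumsum(res.density[perm])
            n_other = int(np.searchsorted(csum, level)) + 1
            assert n_other >= n_hdr

    def test_edge_truncation_detected(self):
        terr = identity_curve(lo=2990, hi=3010, sigma=0.0)
        with pytest.raises(ValueError, match="wider"):
            calibrate(self.date(), terr)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            self.date(sigma=0.0)


class TestCalBCConversion:
    @pytest.mark.parametrize("bp,bc", [(2950, 1000), (3830, 1880), (1950, 0)])
    def test_datum_arithmetic(self, bp, bc):
        assert calbp_to_calbc(bp) == bc
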