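"""AEB estimator, log-log calibration, LOD, recovery, dilution linearity."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ddelisa as dd
from ddelisa.quantify import (
    AEBValue,
    SaturationError,
    compute_aeb,
    compute_lod,
    concentration_from_aeb,
    convert_units,
    dilution_linearity,
    fit_calibration,
)
from ddelisa.readout import DigitalCounts


def counts(n_on, n_beads=1000):
    return DigitalCounts(
        n_droplets_total=2 * n_beads, n_beads=n_beads, n_multibead=0,
        n_on={"green": n_on}, well_id="w",
    )


def aeb_value(aeb, n_beads=1000, saturated=False):
    f_on = 1 - math.exp(-aeb)
    return AEBValue(aeb=aeb, mode="poisson_corrected", f_on=f_on,
                    n_beads=n_beads, saturated=saturated)


class TestComputeAEB:
    def test_zero_f_on_gives_zero_both_modes(self):
        for mode in ("poisson_corrected", "naive"):
            assert compute_aeb(counts(0), "green", mode=mode).aeb == 0.0

    def test_poisson_correction_closed_form(self):
        v = compute_aeb(counts(100), "green")
        assert v.aeb == pytest.approx(-math.log(0.9), rel=1e-12)
        assert v.aeb == pytest.approx(0.10536, abs=1e-5)

    def test_modes_agree_at_low_f_on(self):
        for n_on in (1, 5, 10, 19):  # f_on < 0.02
            pc = compute_aeb(counts(n_on), "green", mode="poisson_corrected").aeb
            na = compute_aeb(counts(n_on), "green", mode="naive").aeb
            assert abs(pc - na) / na < 0.01
        for n_on in (50, 100):  # f_on <= 0.1; exact gap at 0.1 is 5.36%
            pc = compute_aeb(counts(n_on), "green", mode="poisson_corrected").aeb
            na = compute_aeb(counts(n_on), "green", mode="naive").aeb
            assert abs(pc - na) / na < 0.055

    def test_saturation_raises_with_dilution_advice(self):
        with pytest.raises(SaturationError, match="dilute"):
            compute_aeb(counts(1000), "green")

    def test_saturation_floor_mode(self):
        v = compute_aeb(counts(1000), "green", on_saturation="floor")
        assert v.saturated
        assert v.f_on == 1 - 0.5 / 1000

    def test_no_beads_undefined(self):
        c = DigitalCounts(n_droplets_total=10, n_beads=0, n_multibead=0, n_on={"green": 0})
        with pytest.raises(ValueError, match="no beads"):
            compute_aeb(c, "green")

    def test_recovers_simulated_mu_eff(self, opn):
        """Poisson-corrected AEB estimates μ_eff from a known simulation."""
        from ddelisa.readout import call_positives, gate_beads

        from helpers import FIXED_THRESHOLDS

        design = dd.DropletDesign(50.0, 65.45, 500_000, 10_000, 33.0, 0.422)
        quiet = dd.NoiseModel(false_positive_rate=0.0, background_sd=2.0)
        conc = 0.08
        mu_eff = dd.mean_molecules_per_bead(conc, opn, design) * quiet.label_efficiency
        t = dd.simulate_droplet_table(design, {"OPN": conc}, {"OPN": opn}, quiet, seed=21)
        thr = FIXED_THRESHOLDS
        c = call_positives(gate_beads(t, thr), thr)
        v = compute_aeb(c, "green")
        # multi-bead pooling inflates AEB by E[beads | occupied] ≈ 1 + λ/2
        lam = design.bead_lambda
        expected = mu_eff * lam / (1 - math.exp(-lam))
        se = math.sqrt(v.f_on / ((1 - v.f_on) * c.n_beads))
        assert abs(v.aeb - expected) < 3 * se


class TestFitCalibration:
    def _blanks(self, aeb=1e-4, n=3, jitter=0.0):
        return [aeb_value(aeb * (1 + jitter * i)) for i in range(n)]

    def ladder_points(self, concs=(0.01, 0.1, 1.0, 10.0), coeff=0.1):
        return [(c, aeb_value(coeff * c)) for c in concs]

    def test_exact_power_law(self):
        curve = fit_calibration(self.ladder_points(), self._blanks())
        assert curve.slope == pytest.approx(1.0, abs=1e-9)
        assert curve.intercept == pytest.approx(-1.0, abs=1e-9)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)
        assert curve.dynamic_range == (0.01, 10.0)

    def test_saturated_top_excluded_slope_stable(self):
        pts = self.ladder_points() + [(100.0, aeb_value(9.0, saturated=True))]
        curve = fit_calibration(pts, self._blanks())
        ref = fit_calibration(self.ladder_points(), self._blanks())
        assert curve.dynamic_range[1] == 10.0
        assert curve.slope == pytest.approx(ref.slope, rel=0.05)

    def test_all_below_lod_is_no_signal(self):
        pts = self.ladder_points(coeff=1e-9)
        with pytest.raises(ValueError, match="LOD"):
            fit_calibration(pts, self._blanks(aeb=1e-3))

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            fit_calibration(self.ladder_points(concs=(1.0, 10.0)), self._blanks())

    def test_too_few_blanks_rejected(self):
        with pytest.raises(ValueError, match="blank"):
            fit_calibration(self.ladder_points(), self._blanks(n=1))

    def test_blank_stats_and_lod_aeb(self):
        blanks = [aeb_value(0.001), aeb_value(0.002), aeb_value(0.003)]
        curve = fit_calibration(self.ladder_points(), blanks)
        assert curve.blank_aeb_mean == pytest.approx(0.002)
        assert curve.lod_aeb == pytest.approx(0.002 + 3 * np.std([0.001, 0.002, 0.003], ddof=1))

    def test_zero_blanks_floored_finite_lod(self):
        """Blanks with no positive beads still give a finite LOD."""
        zero_blanks = [
            AEBValue(aeb=0.0, mode="poisson_corrected", f_on=0.0, n_beads=1000)
            for _ in range(3)
        ]
        curve = fit_calibration(self.ladder_points(), zero_blanks)
        assert curve.lod_aeb == pytest.approx(-math.log1p(-0.5 / 1000))
        assert 0 < curve.lod_concentration < math.inf

    def test_json_roundtrip(self, tmp_path):
        curve = fit_calibration(self.ladder_points(), self._blanks())
        p = tmp_path / "curve.json"
        curve.to_json(p)
        assert dd.CalibrationCurve.from_json(p) == curve


class TestLodAndBackCalculation:
    def curve(self, **kw):
        pts = [(c, aeb_value(0.1 * c)) for c in (0.01, 0.1, 1.0, 10.0)]
        blanks = [aeb_value(1e-3), aeb_value(1e-3 * (1 + kw.get("blank_rel_spread", 0.1)))]
        return fit_calibration(pts, blanks)

    def test_lod_closed_form_inverse(self):
        c = self.curve()
        lod = compute_lod(c)
        # slope 1, intercept -1: concentration = 10 * aeb
        assert lod["lod_pg_ml"] == pytest.approx(10 * c.lod_aeb, rel=1e-9)

    def test_lod_example(self):
        assert 10 ** ((math.log10(0.01) - (-1.0)) / 1.0) == pytest.approx(0.1)

    def test_lod_monotone_in_blank_sd(self):
        lods = [compute_lod(self.curve(blank_rel_spread=s))["lod_pg_ml"]
                for s in (0.0, 0.1, 0.5, 1.0)]
        assert all(a <= b for a, b in zip(lods, lods[1:]))

    def test_zero_blank_sd_lod_is_blank_mean_inverse(self):
        c = self.curve(blank_rel_spread=0.0)
        assert c.lod_aeb == pytest.approx(c.blank_aeb_mean)
        assert c.lod_concentration == pytest.approx(10 * c.blank_aeb_mean, rel=1e-9)

    def test_back_calculation_closed_form(self):
        c = self.curve()
        conc, flag = concentration_from_aeb(c, aeb_value(1.0))
        assert conc == pytest.approx(10.0, rel=1e-9)
        assert flag == "in_range"

    def test_aeb_at_lod_maps_to_lod(self):
        c = self.curve()
        conc, flag = concentration_from_aeb(c, aeb_value(c.lod_aeb))
        assert conc == pytest.approx(c.lod_concentration, rel=1e-9)
        assert flag == "in_range"

    def test_below_lod_reported_not_censored(self):
        c = self.curve()
        conc, flag = concentration_from_aeb(c, aeb_value(c.lod_aeb / 2))
        assert flag == "below_LOD"
        assert conc > 0

    def test_zero_aeb(self):
        c = self.curve()
        v = AEBValue(aeb=0.0, mode="poisson_corrected", f_on=0.0, n_beads=100)
        assert concentration_from_aeb(c, v) == (0.0, "below_LOD")

    @given(st.floats(min_value=-3, max_value=0.5))
    def test_monotone_in_aeb(self, log_aeb):
        c = self.curve()
        a1, a2 = 10**log_aeb, 10 ** (log_aeb + 0.1)
        c1, _ = concentration_from_aeb(c, aeb_value(a1))
        c2, _ = concentration_from_aeb(c, aeb_value(a2))
        assert c2 > c1


class TestConvertUnits:
    def test_dimensional_oracle(self, opn):
        assert convert_units(1.0, opn) == pytest.approx(30.30, abs=0.01)

    def test_zero(self, opn):
        assert convert_units(0.0, opn) == 0.0

    @given(st.floats(min_value=1e-6, max_value=1e6))
    def test_roundtrip(self, c):
        from ddelisa.units import fm_to_pg_per_ml, pg_per_ml_to_fm

        assert fm_to_pg_per_ml(pg_per_ml_to_fm(c, 33.0), 33.0) == pytest.approx(c, rel=1e-12)


class TestDilutionLinearity:
    def test_perfect_series(self):
        c = 40.0
        rep = dilution_linearity([(1, c), (5, c / 5), (10, c / 10), (20, c / 20)])
        assert (rep.levels["recovery_pct"] == 100.0).all()
        assert rep.linear_range_bound == 20.0
        assert rep.r_squared == pytest.approx(1.0)

    def test_floor_censored_tail_bounds_linear_range(self):
        """Measurements clipped at blank level beyond 10-fold lose linearity."""
        neat = 5.33
        series = [(1, neat), (5, neat / 5 * 1.02), (10, 0.11), (20, 0.05)]
        rep = dilution_linearity(series)
        assert rep.linear_range_bound == 5.0
        assert rep.linear_range_bound < 20.0

    def test_nonpositive_dilution_rejected(self):
        with pytest.raises(ValueError):
            dilution_linearity([(1, 5.0), (0, 1.0), (10, 0.5)])

    def test_needs_neat(self):
        with pytest.raises(ValueError, match="neat"):
            dilution_linearity([(5, 1.0), (10, 0.5), (20, 0.25)])

    def test_needs_three_levels(self):
        with pytest.raises(ValueError):
            dilution_linearity([(1, 5.0), (10, 0.5)])


class TestEndToEndRecovery:
    def test_quantify_simulated_sample(self, small_calibration, small_design, opn, noise):
        """quantify(simulate(10 pg/ml)) recovers within ±15%."""
        from ddelisa.pipeline import quantify_sample

        cal, _ = small_calibration
        t = dd.simulate_droplet_table(small_design, {"OPN": 10.0}, {"OPN": opn}, noise, seed=77)
        q = quantify_sample(t, cal, {"OPN": opn})["OPN"]
        # 10 pg/ml sits at the top of the detected range; either flag is valid
        assert q["flag"] in ("in_range", "above_range")
        assert 8.5 <= q["concentration_pg_ml"] <= 11.5

    def test_calibration_r_squared(self, small_calibration):
        cal, _ = small_calibration
        assert cal.curves["OPN"].r_squared >= 0.97
        assert cal.curves["OPN"].slope > 0
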