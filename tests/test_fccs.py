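"""Cross-correlation amplitudes: closed-form oracle, inversion round trips,
dissociation-constant estimation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fcskit.fccs import (
    ConcentrationTriple,
    DetectionCalibration,
    FCCSAmplitudes,
    KdEstimate,
    UnphysicalAmplitudesError,
    forward_amplitudes,
    invert_amplitudes,
    kd_aggregate,
    kd_point,
)

CAL_NO_BG = DetectionCalibration(beta_R=0.0)
CAL_BG = DetectionCalibration()  # 400 Hz red background


def closed_form(conc, calib):
    """Independent oracle: reduced quasi-PIE forms (no cross-talk, q = 1)."""
    nav = calib.nav
    B = calib.beta_R / (calib.eta_rR * nav)
    g_g = 1.0 / (nav * (conc.Cg + conc.Cgr))
    g_r = (conc.Cr + conc.Cgr) / (nav * (conc.Cr + conc.Cgr + B) ** 2)
    g_x = conc.Cgr / (nav * (conc.Cg + conc.Cgr) * (conc.Cr + conc.Cgr + B))
    return g_g, g_r, g_x


class TestForward:
    def test_worked_example_against_arithmetic_oracle(self):
        """Cg=40, Cr=70, Cgr=25 nM at V_eff=0.5 fL (nav = 0.3011 /nM), no
        background: G_G0 = 1/(0.3011*65), G_R0 = 1/(0.3011*95),
        G_x0 = 25/(0.3011*65*95)."""
        conc = ConcentrationTriple(40.0, 70.0, 25.0)
        amps = forward_amplitudes(conc, CAL_NO_BG)
        nav = CAL_NO_BG.nav
        assert nav == pytest.approx(0.3011, abs=1e-4)
        assert amps.G_G0 == pytest.approx(1 / (nav * 65), rel=1e-12)
        assert amps.G_R0 == pytest.approx(1 / (nav * 95), rel=1e-12)
        assert amps.G_x0 == pytest.approx(25 / (nav * 65 * 95), rel=1e-12)
        assert amps.G_G0 == pytest.approx(0.0511, abs=1e-4)
        assert amps.G_R0 == pytest.approx(0.0350, abs=1e-4)
        assert amps.G_x0 == pytest.approx(0.01345, abs=1e-5)

    def test_matches_closed_form_with_background(self):
        conc = ConcentrationTriple(12.0, 30.0, 8.0)
        amps = forward_amplitudes(conc, CAL_BG)
        g_g, g_r, g_x = closed_form(conc, CAL_BG)
        assert amps.G_G0 == pytest.approx(g_g, rel=1e-12)
        assert amps.G_R0 == pytest.approx(g_r, rel=1e-12)
        assert amps.G_x0 == pytest.approx(g_x, rel=1e-12)

    def test_no_bound_species_means_zero_cross_amplitude(self):
        amps = forward_amplitudes(ConcentrationTriple(50.0, 50.0, 0.0), CAL_NO_BG)
        assert amps.G_x0 == 0.0

    def test_homogeneity_without_background(self):
        c1 = ConcentrationTriple(40.0, 70.0, 25.0)
        c10 = ConcentrationTriple(400.0, 700.0, 250.0)
        a1 = forward_amplitudes(c1, CAL_NO_BG)
        a10 = forward_amplitudes(c10, CAL_NO_BG)
        assert a10.G_G0 == pytest.approx(a1.G_G0 / 10, rel=1e-12)
        assert a10.G_R0 == pytest.approx(a1.G_R0 / 10, rel=1e-12)
        assert a10.G_x0 == pytest.approx(a1.G_x0 / 10, rel=1e-12)

    def test_cross_talk_enters_the_green_amplitude(self):
        conc = ConcentrationTriple(40.0, 70.0, 25.0)
        leaky = DetectionCalibration(beta_R=0.0, eta_rG=300.0)
        a0 = forward_amplitudes(conc, CAL_NO_BG)
        a1 = forward_amplitudes(conc, leaky)
        assert a1.G_G0 != pytest.approx(a0.G_G0, rel=1e-6)
        assert a1.G_x0 > a0.G_x0  # red species now visible in green channel


class TestInvert:
    @pytest.mark.parametrize("calib", [CAL_NO_BG, CAL_BG], ids=["no_bg", "bg400"])
    def test_round_trip_on_random_triples(self, calib):
        rng = np.random.default_rng(17)
        for _ in range(100):
            conc = ConcentrationTriple(*rng.uniform(1.0, 200.0, 3))
            rec = invert_amplitudes(forward_amplitudes(conc, calib), calib)
            assert rec.Cg == pytest.approx(conc.Cg, rel=1e-6)
            assert rec.Cr == pytest.approx(conc.Cr, rel=1e-6)
            assert rec.Cgr == pytest.approx(conc.Cgr, rel=1e-6)

    def test_round_trip_with_cross_talk(self):
        calib = DetectionCalibration(eta_rG=150.0, eta_gR=80.0, q_g=0.9, q_r=0.95)
        conc = ConcentrationTriple(30.0, 55.0, 12.0)
        rec = invert_amplitudes(forward_amplitudes(conc, calib), calib)
        assert rec.Cg == pytest.approx(conc.Cg, rel=1e-6)
        assert rec.Cgr == pytest.approx(conc.Cgr, rel=1e-6)

    def test_worked_example_recovers_concentrations_and_kd(self):
        conc = ConcentrationTriple(40.0, 70.0, 25.0)
        rec = invert_amplitudes(forward_amplitudes(conc, CAL_BG), CAL_BG)
        assert rec.Cg == pytest.approx(40.0, rel=1e-6)
        assert rec.Cr == pytest.approx(70.0, rel=1e-6)
        assert rec.Cgr == pytest.approx(25.0, rel=1e-6)
        assert kd_point(rec) == pytest.approx(112.0, rel=1e-6)

    def test_zero_cross_amplitude_gives_zero_bound(self):
        amps = forward_amplitudes(ConcentrationTriple(50.0, 80.0, 0.0), CAL_BG)
        rec = invert_amplitudes(amps, CAL_BG)
        assert rec.Cgr == pytest.approx(0.0, abs=1e-6)

    def test_unphysical_amplitudes_rejected(self):
        with pytest.raises(UnphysicalAmplitudesError):
            invert_amplitudes(FCCSAmplitudes(0.05, 0.03, 0.06), CAL_BG)

    @given(
        cg=st.floats(0.5, 300.0),
        cr=st.floats(2.0, 300.0),
        cgr=st.floats(0.1, 300.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_round_trip_property(self, cg, cr, cgr):
        """Unique-inverse regime: total red concentration above the
        background-equivalent occupancy (~1 nM at 400 Hz)."""
        conc = ConcentrationTriple(cg, cr, cgr)
        rec = invert_amplitudes(forward_amplitudes(conc, CAL_BG), CAL_BG)
        assert math.isclose(rec.Cg, cg, rel_tol=1e-6, abs_tol=1e-9)
        assert math.isclose(rec.Cr, cr, rel_tol=1e-6, abs_tol=1e-9)
        assert math.isclose(rec.Cgr, cgr, rel_tol=1e-6, abs_tol=1e-9)

    def test_subnanomolar_ambiguity_still_reproduces_amplitudes(self):
        """Below the background-equivalent red occupancy the inverse is
        two-valued; the returned root must still reproduce the amplitudes
        exactly even when it is not the generating triple."""
        conc = ConcentrationTriple(1.0, 0.5, 0.25)
        amps = forward_amplitudes(conc, CAL_BG)
        rec = invert_amplitudes(amps, CAL_BG)
        back = forward_amplitudes(rec, CAL_BG)
        assert back.G_G0 == pytest.approx(amps.G_G0, rel=1e-8)
        assert back.G_R0 == pytest.approx(amps.G_R0, rel=1e-8)
        assert back.G_x0 == pytest.approx(amps.G_x0, rel=1e-8)


class TestKd:
    def test_point_value_and_symmetry(self):
        conc = ConcentrationTriple(40.0, 70.0, 25.0)
        assert kd_point(conc) == pytest.approx(112.0)
        swapped = ConcentrationTriple(70.0, 40.0, 25.0)
        assert kd_point(swapped) == kd_point(conc)

    def test_equal_concentrations_give_kd_equal_to_concentration(self):
        assert kd_point(ConcentrationTriple(42.0, 42.0, 42.0)) == pytest.approx(42.0)

    def test_homogeneity(self):
        c = ConcentrationTriple(10.0, 20.0, 5.0)
        ck = ConcentrationTriple(30.0, 60.0, 15.0)
        assert kd_point(ck) == pytest.approx(3 * kd_point(c))

    def test_no_bound_species_reports_noninteracting(self):
        assert kd_point(ConcentrationTriple(10.0, 10.0, 0.0)) == math.inf

    def test_aggregate_exact_collinear_data(self):
        rng = np.random.default_rng(2)
        triples = []
        for _ in range(10):
            cg, cr = rng.uniform(10, 100, 2)
            triples.append(ConcentrationTriple(cg, cr, cg * cr / 112.0))
        est = kd_aggregate(triples)
        assert est.Kd == pytest.approx(112.0, rel=1e-9)
        assert est.R2 == pytest.approx(1.0)
        assert est.n_measurements == 10

    def test_aggregate_of_repeated_triple_equals_point_estimate(self):
        c = ConcentrationTriple(40.0, 70.0, 25.0)
        est = kd_aggregate([c, c, c])
        assert est.Kd == pytest.approx(kd_point(c))

    def test_aggregate_noisy_23_measurements_near_truth(self):
        """23 triples with 20% multiplicative noise around Kd = 112 nM: the
        regression slope lands within 15 nM of the truth."""
        rng = np.random.default_rng(23)
        triples = []
        for _ in range(23):
            cg, cr = rng.uniform(10, 100, 2)
            cgr = cg * cr / 112.0 * rng.lognormal(0.0, 0.2)
            triples.append(ConcentrationTriple(cg, cr, cgr))
        est = kd_aggregate(triples)
        assert abs(est.Kd - 112.0) < 15.0
        assert 0.0 <= est.R2 <= 1.0

    def test_aggregate_requires_three_usable_triples(self):
        c = ConcentrationTriple(10.0, 10.0, 0.0)
        with pytest.raises(ValueError):
            kd_aggregate([c, c, c, c])
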