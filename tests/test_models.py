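"""FCS model family: closed-form values, algebraic identities, fitting,
calibration and model selection."""

import numpy as np
import pytest

from fcskit import generate_model_acf
from fcskit.correlate import CorrelationCurve
from fcskit.models import (
    BOUNDS,
    ConfocalCalibration,
    FCSModelSpec,
    FitFailureError,
    D_to_tau,
    calibrate,
    eval_model,
    fit_fcs,
    mass_scaling_ratio,
    select_model,
    tau_to_D,
    triplet_factor,
)

from conftest import CALIB

ALL_SPECS = [
    FCSModelSpec("3D", 1, True),
    FCSModelSpec("3D", 2, True),
    FCSModelSpec("2D", 1, True),
    FCSModelSpec("2D", 2, True),
]

GRID = np.logspace(-6.5, 0.5, 100)


def _params(spec, **over):
    p = {"N": 10.0, "tau_d1": 5e-4, "G_inf": 0.0}
    if spec.n_components == 2:
        p.update(tau_d2=2.5e-2, F2=0.6)
    if spec.triplet:
        p.update(F_trip=0.15, tau_trip=1e-5)
    p.update(over)
    return p


class TestEvalModel:
    def test_triplet_factor_vanishes_without_triplet(self):
        assert np.allclose(triplet_factor(GRID, 0.0, 1e-5), 1.0)

    def test_half_amplitude_at_tau_d_in_2d_limit(self):
        """At tau = tau_d with a huge structure factor the axial term -> 1,
        leaving G = (1/N) * 1/2."""
        spec = FCSModelSpec("3D", 1, False)
        g = eval_model(spec, {"N": 10.0, "tau_d1": 1e-3, "G_inf": 0.0, "K": 1e6},
                       tau=np.array([1e-3]))
        assert g[0] == pytest.approx(0.05, rel=1e-6)

    def test_two_component_with_equal_taus_reduces_to_one_component(self):
        one = eval_model(FCSModelSpec("3D", 1, True), _params(FCSModelSpec("3D", 1, True)),
                         CALIB, GRID)
        p2 = _params(FCSModelSpec("3D", 2, True), tau_d2=5e-4)
        two = eval_model(FCSModelSpec("3D", 2, True), p2, CALIB, GRID)
        assert np.allclose(one, two, rtol=1e-12)

    @pytest.mark.parametrize("f2", [0.0, 1.0])
    def test_degenerate_fraction_reduces_to_one_component(self, f2):
        spec2 = FCSModelSpec("2D", 2, True)
        p2 = _params(spec2, F2=f2)
        two = eval_model(spec2, p2, CALIB, GRID)
        spec1 = FCSModelSpec("2D", 1, True)
        p1 = _params(spec1, tau_d1=p2["tau_d2"] if f2 == 1.0 else p2["tau_d1"])
        one = eval_model(spec1, p1, CALIB, GRID)
        assert np.allclose(one, two, rtol=1e-12)

    @pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.name)
    def test_monotone_nonincreasing_in_lag(self, spec):
        g = eval_model(spec, _params(spec), CALIB, GRID)
        assert np.all(np.diff(g) <= 1e-15)

    @pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.name)
    def test_amplitude_identity(self, spec):
        """G(0+) - G_inf = (1/N) / (1 - F_trip)."""
        p = _params(spec, G_inf=1.0)
        g0 = eval_model(spec, p, CALIB, np.array([1e-12]))[0]
        expected = (1.0 / p["N"]) / (1.0 - p.get("F_trip", 0.0))
        assert g0 - 1.0 == pytest.approx(expected, rel=1e-6)

    def test_3d_tends_to_2d_as_K_grows(self):
        p = _params(FCSModelSpec("3D", 1, True))
        p3 = {**p, "K": 1e8}
        g3 = eval_model(FCSModelSpec("3D", 1, True), p3, None, GRID)
        g2 = eval_model(FCSModelSpec("2D", 1, True), p, None, GRID)
        assert np.allclose(g3, g2, rtol=1e-6)

    def test_nonpositive_lag_rejected(self):
        with pytest.raises(ValueError):
            eval_model(FCSModelSpec("2D", 1, False), _params(FCSModelSpec("2D", 1, False)),
                       None, np.array([0.0, 1e-5]))

    def test_bad_K_rejected(self):
        with pytest.raises(ValueError):
            eval_model(FCSModelSpec("3D", 1, False),
                       {"N": 1, "tau_d1": 1e-4, "G_inf": 0, "K": -1.0}, None, GRID)


class TestFit:
    def test_noiseless_two_component_membrane_fixture_round_trip(self):
        """Fast/slow cell-border scenario (D = 27.6 / 0.6 µm²/s, F_slow 0.6):
        noiseless curves return every parameter to better than 1e-3."""
        spec = FCSModelSpec("2D", 2, True)
        truth = {
            "N": 10.0,
            "tau_d1": D_to_tau(27.6, CALIB.omega_xy),
            "tau_d2": D_to_tau(0.6, CALIB.omega_xy),
            "F2": 0.6,
            "F_trip": 0.15,
            "tau_trip": 1e-5,
            "G_inf": 1.0,
        }
        curve = generate_model_acf(spec, truth, np.logspace(-6.5, 0.5, 250))[0]
        fit = fit_fcs(curve, spec, CALIB, seed=0)
        assert fit.D_fast == pytest.approx(27.6, rel=1e-3)
        assert fit.D_slow == pytest.approx(0.6, rel=1e-3)
        assert fit.F_slow == pytest.approx(0.6, rel=1e-3)
        assert fit.N == pytest.approx(10.0, rel=1e-3)
        assert fit.tau_trip == pytest.approx(1e-5, rel=1e-2)

    def test_flat_noise_curve_fails_or_flags(self):
        rng = np.random.default_rng(5)
        curve = CorrelationCurve(GRID, 1.0 + rng.normal(0, 1e-4, GRID.size))
        try:
            fit = fit_fcs(curve, FCSModelSpec("3D", 2, True), CALIB, seed=0)
        except FitFailureError:
            return
        assert fit.flags, "degenerate input must not return an unflagged fit"

    def test_too_few_points_rejected(self):
        curve = CorrelationCurve(GRID[:10], np.linspace(1.1, 1.0, 10))
        with pytest.raises(ValueError):
            fit_fcs(curve, FCSModelSpec("3D", 2, True), CALIB)


class TestCalibrate:
    def test_reference_dye_curve_yields_quarter_micron_waist(self):
        """tau_d = 39.06 µs at D = 400 µm²/s corresponds to a 0.25 µm
        waist."""
        spec = FCSModelSpec("3D", 1, True)
        params = {"N": 5.0, "tau_d1": 39.06e-6, "F_trip": 0.1, "tau_trip": 3e-6,
                  "G_inf": 1.0, "K": 5.0}
        curve = generate_model_acf(spec, params, np.logspace(-7, -1, 200))[0]
        calib = calibrate(curve, dye_D_ref=400.0)
        assert calib.omega_xy == pytest.approx(0.25, rel=5e-3)
        assert calib.K == pytest.approx(5.0, rel=0.05)

    def test_effective_volume_arithmetic(self):
        calib = ConfocalCalibration.from_K(omega_xy=0.25, K=5.0)
        assert calib.omega_z == pytest.approx(1.25)
        assert calib.V_eff_fL == pytest.approx(np.pi ** 1.5 * 0.0625 * 1.25, rel=1e-12)
        assert calib.V_eff_fL == pytest.approx(0.435, abs=5e-4)

    def test_doubling_dye_reference_doubles_waist_squared(self):
        spec = FCSModelSpec("3D", 1, True)
        params = {"N": 5.0, "tau_d1": 39.06e-6, "F_trip": 0.1, "tau_trip": 3e-6,
                  "G_inf": 1.0, "K": 5.0}
        curve = generate_model_acf(spec, params, np.logspace(-7, -1, 200))[0]
        c1 = calibrate(curve, dye_D_ref=400.0)
        c2 = calibrate(curve, dye_D_ref=800.0)
        assert c2.omega_xy ** 2 == pytest.approx(2 * c1.omega_xy ** 2, rel=1e-9)

    def test_atypical_structure_factor_warns(self):
        spec = FCSModelSpec("3D", 1, True)
        params = {"N": 5.0, "tau_d1": 39.06e-6, "F_trip": 0.1, "tau_trip": 3e-6,
                  "G_inf": 1.0, "K": 20.0}
        curve = generate_model_acf(spec, params, np.logspace(-7, -1, 200))[0]
        with pytest.warns(UserWarning, match="structure factor"):
            calibrate(curve, dye_D_ref=400.0)


class TestSelectModel:
    def test_nested_models_on_clean_one_component_data(self):
        spec1 = FCSModelSpec("3D", 1, True)
        curve = generate_model_acf(spec1, _params(spec1, G_inf=1.0), GRID,
                                   calibration=CALIB)[0]
        best, table = select_model(curve, [spec1, FCSModelSpec("3D", 2, True)], CALIB)
        assert best.n_components == 1
        assert len(table) == 2

    def test_two_component_data_selects_two_components(self):
        spec2 = FCSModelSpec("3D", 2, True)
        p = _params(spec2, G_inf=1.0)  # D ratio 50
        curve = generate_model_acf(spec2, p, np.logspace(-6.5, 0.5, 250),
                                   noise_sd_fraction=0.02, seed=9,
                                   calibration=CALIB)[0]
        best, _ = select_model(curve, [FCSModelSpec("3D", 1, True), spec2], CALIB)
        assert best.n_components == 2

    def test_single_candidate_rejected(self):
        spec1 = FCSModelSpec("3D", 1, True)
        curve = generate_model_acf(spec1, _params(spec1, G_inf=1.0), GRID,
                                   calibration=CALIB)[0]
        with pytest.raises(ValueError):
            select_model(curve, [spec1], CALIB)


class TestScalars:
    def test_tau_to_d_inverts_calibration_example(self):
        assert tau_to_D(39.06e-6, 0.25) == pytest.approx(400.0, rel=2e-4)
        assert D_to_tau(400.0, 0.25) == pytest.approx(39.06e-6, rel=2e-4)

    def test_mass_scaling_of_tagged_ligand_vs_secreted_control(self):
        """73 kDa vs 33 kDa free diffusers: cube-root mass scaling predicts a
        ~30% difference in D."""
        ratio = mass_scaling_ratio(33.0, 73.0)
        assert ratio == pytest.approx(1.303, abs=5e-4)
        assert ratio - 1.0 == pytest.approx(0.30, abs=0.01)

    def test_mass_scaling_identity(self):
        assert mass_scaling_ratio(42.0, 42.0) == 1.0

    @pytest.mark.parametrize("fn,args", [(tau_to_D, (0, 0.25)), (tau_to_D, (1e-4, -1)),
                                         (mass_scaling_ratio, (0, 10))])
    def test_domain_errors(self, fn, args):
        with pytest.raises(ValueError):
            fn(*args)


def test_model_spec_parsing_round_trip():
    for spec in ALL_SPECS:
        assert FCSModelSpec.parse(spec.name) == spec
    with pytest.raises(ValueError):
        FCSModelSpec.parse("4d1p1t")
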