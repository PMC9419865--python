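"""Contact-mechanics core: forward models, contact point, fitting, adhesion."""

import numpy as np
import pytest

from epimech import synthetic
from epimech.contact import (
    ContactFitConfig,
    ContactModel,
    adhesion_energetics,
    aggregate_by_region,
    composite_forward,
    estimate_contact_point,
    hertz_force,
    jkr_force_at_depth,
    jkr_forward,
    jkr_min_depth,
    jkr_pulloff_force,
)
from epimech.datatypes import ContactModelParams, ForceCurve
from epimech.exceptions import DomainError, EmptyTableError, InvalidParameterError, NoContactError
from epimech.io import read_force_curve, write_force_curve

from conftest import JUNCTION_E, PROBE_R


class TestHertz:
    def test_contact_onset_zero_force(self):
        assert hertz_force(0.0, 1000.0, 0.5, PROBE_R) == 0.0
        assert hertz_force(-1e-7, 1000.0, 0.5, PROBE_R) == 0.0

    def test_hand_computed_value(self):
        # (4/3) * (1000/0.75) * sqrt(2.6e-6) * (1e-7)^1.5 = 9.065e-11 N
        f = hertz_force(100e-9, 1000.0, 0.5, PROBE_R)
        assert f == pytest.approx(9.065e-11, rel=1e-3)

    def test_linear_in_modulus(self):
        d = np.linspace(0, 4e-7, 50)
        np.testing.assert_allclose(
            hertz_force(d, 2000.0, 0.5, PROBE_R),
            2.0 * hertz_force(d, 1000.0, 0.5, PROBE_R),
            rtol=1e-12,
        )

    @pytest.mark.parametrize("bad", [dict(E=-1.0), dict(R=-1e-6), dict(E=0.0)])
    def test_invalid_parameters_raise(self, bad):
        kw = dict(E=1000.0, nu=0.5, R=PROBE_R)
        kw.update(bad)
        with pytest.raises(InvalidParameterError):
            hertz_force(1e-7, kw["E"], kw["nu"], kw["R"])


class TestJKR:
    def test_adhesionless_limit_matches_hertz(self):
        p = ContactModelParams(E=100.0, R=PROBE_R, w=0.0)
        a = np.linspace(1e-8, 3e-6, 1000)
        delta, force = jkr_forward(a, p)
        expected = hertz_force(delta, p.E, p.nu, p.R)
        np.testing.assert_allclose(force, expected, rtol=1e-9)

    def test_pulloff_equals_numerical_minimum(self):
        # independent oracle: dense-grid minimisation of the parametric branch
        p = ContactModelParams(E=100.0, R=PROBE_R, w=1e-4)
        a = np.linspace(1e-9, 5e-6, 400000)
        _, force = jkr_forward(a, p)
        assert force.min() == pytest.approx(-1.5 * np.pi * 1e-4 * PROBE_R, rel=1e-6)
        assert jkr_pulloff_force(p) == pytest.approx(force.min(), rel=1e-6)

    def test_loading_branch_monotone_above_pulloff(self):
        p = ContactModelParams(E=50.0, R=PROBE_R, w=5e-5)
        a = np.linspace(1e-7, 4e-6, 5000)
        delta, force = jkr_forward(a, p)
        start = int(np.argmin(delta))  # branch minimum: rising branch beyond
        assert delta[start] == pytest.approx(jkr_min_depth(p), rel=1e-4)
        assert np.all(np.diff(delta[start:]) > 0)
        assert np.all(np.isfinite(force))

    def test_depth_inversion_round_trip(self):
        p = ContactModelParams(E=100.0, R=PROBE_R, w=1e-5, K_m=3.5e-4, z0=1.0)
        a = np.linspace(3e-8, 2e-6, 500)
        delta, force = jkr_forward(a, p)
        sel = delta > 0
        z_um = delta[sel] * 1e6 + p.z0
        f_model = composite_forward(z_um, p) * 1e-9
        f_expected = force[sel] + p.K_m * delta[sel]
        np.testing.assert_allclose(f_model, f_expected, rtol=1e-3)

    def test_depth_below_branch_raises_domain_error(self):
        p = ContactModelParams(E=100.0, R=PROBE_R, w=1e-4)
        with pytest.raises(DomainError):
            jkr_force_at_depth(2.0 * jkr_min_depth(p), p)


class TestCompositeForward:
    def test_reduces_to_baseline_plus_hertz(self):
        p = ContactModelParams(E=200.0, R=PROBE_R, z0=0.5,
                               baseline_offset=0.3, baseline_slope=-0.1)
        z = np.linspace(0, 1.0, 300)
        f = composite_forward(z, p)
        baseline = 0.3 - 0.1 * z
        hertz_nn = hertz_force(np.clip(z - 0.5, 0, None) * 1e-6, 200.0, 0.5, PROBE_R) / 1e-9
        np.testing.assert_allclose(f, baseline + hertz_nn, rtol=1e-10, atol=1e-12)

    def test_membrane_spring_limit(self):
        # vanishing bulk modulus with a membrane leaves a pure linear spring
        p = ContactModelParams(E=1e-3, R=PROBE_R, K_m=1e-3, z0=0.5)
        z = np.linspace(0.5, 1.0, 100)
        delta_m = (z - 0.5) * 1e-6
        f = composite_forward(z, p) * 1e-9
        np.testing.assert_allclose(f, 1e-3 * delta_m, rtol=1e-3, atol=1e-16)


class TestContactPoint:
    def test_recovers_true_contact_point(self, junction_curve):
        curve, truth = junction_curve
        z0, diag = estimate_contact_point(curve)
        z_step = np.diff(np.sort(curve.approach[0]))[0]
        assert abs(z0 - truth.parameters["z0_um"]) <= z_step + 1e-12

    def test_translation_equivariance(self, junction_curve):
        curve, _ = junction_curve
        z0a, _ = estimate_contact_point(curve)
        shifted = ForceCurve(
            z=curve.z + 0.37, force=curve.force, segment=curve.segment,
            probe_radius=curve.probe_radius,
        )
        z0b, _ = estimate_contact_point(shifted)
        assert z0b - z0a == pytest.approx(0.37, abs=1e-9)

    def test_pure_baseline_raises_no_contact(self):
        rng = np.random.default_rng(0)
        n = 200
        z = np.linspace(0, 1, n)
        curve = ForceCurve(
            z=z, force=0.2 + 0.05 * z + rng.normal(0, 0.01, n),
            segment=np.array(["approach"] * n), probe_radius=2.6,
        )
        with pytest.raises(NoContactError):
            estimate_contact_point(curve)

    def test_rov_detector_finds_transition(self, junction_curve):
        curve, truth = junction_curve
        z0, diag = estimate_contact_point(curve, method="rov")
        assert diag["method"] == "rov"
        assert abs(z0 - truth.parameters["z0_um"]) < 0.15


class TestFit:
    def test_noise_free_recovery_at_junction_modulus(self, junction_curve):
        curve, _ = junction_curve
        res = ContactModel(curve).fit()
        assert res.converged
        assert res.params.E == pytest.approx(JUNCTION_E, rel=0.01)

    def test_nested_model_consistency(self, junction_curve):
        # Hertz-generated data must not leak into the adhesion/membrane terms
        curve, _ = junction_curve
        cfg = ContactFitConfig()
        res = ContactModel(curve, cfg).fit()
        assert res.params.w <= 0.01 * cfg.w_bounds[1]
        assert res.params.K_m <= 0.01 * cfg.K_m_bounds[1]

    def test_full_model_recovery_with_adhesion_and_membrane(self, adhesive_curve):
        curve, truth = adhesive_curve
        res = ContactModel(curve).fit()
        assert res.params.E == pytest.approx(truth.parameters["E_Pa"], rel=0.01)
        assert res.params.w == pytest.approx(truth.parameters["w_J_per_m2"], rel=0.01)
        assert res.params.K_m == pytest.approx(truth.parameters["K_m_N_per_m"], rel=0.01)
        assert res.beta == pytest.approx(truth.parameters["beta"], rel=0.02)

    def test_indentation_cap_warning(self, junction_curve):
        curve, _ = junction_curve
        cfg = ContactFitConfig(cell_height=0.5)  # 40% of 0.5 um << 0.4 um indent
        res = ContactModel(curve, cfg).fit()
        assert any("exceeds" in w for w in res.warnings)

    def test_summary_and_predict(self, junction_curve):
        curve, _ = junction_curve
        res = ContactModel(curve).fit()
        text = res.summary()
        assert "E " in text and "beta" in text
        z, f = curve.approach
        np.testing.assert_allclose(res.predict(z), f, atol=1e-8)

    def test_unit_safety_nm_vs_um(self, junction_curve, tmp_path):
        curve, _ = junction_curve
        path = write_force_curve(curve, tmp_path / "c.csv")
        import pandas as pd

        pd.DataFrame(
            {"z_nm": curve.z * 1000.0, "force_nN": curve.force, "segment": curve.segment}
        ).to_csv(tmp_path / "c_nm.csv", index=False)
        (tmp_path / "c_nm.json").write_text((tmp_path / "c.json").read_text())
        e_um = ContactModel(read_force_curve(path)).fit().params.E
        e_nm = ContactModel(read_force_curve(tmp_path / "c_nm.csv")).fit().params.E
        assert e_nm == pytest.approx(e_um, rel=1e-6)


class TestAdhesionEnergetics:
    def test_pulloff_work_recovery(self, adhesive_curve):
        curve, truth = adhesive_curve
        out = adhesion_energetics(curve)
        assert out["w_pulloff"] == pytest.approx(truth.parameters["w_J_per_m2"], rel=0.02)
        assert out["hysteresis_energy"] > 0

    def test_reversible_curve_has_zero_hysteresis(self):
        z = np.linspace(0, 1, 100)
        f = np.concatenate([z**2, z[::-1] ** 2])
        curve = ForceCurve(
            z=np.concatenate([z, z[::-1]]), force=f,
            segment=np.array(["approach"] * 100 + ["retract"] * 100),
            probe_radius=2.6,
        )
        out = adhesion_energetics(curve)
        assert out["hysteresis_energy"] == pytest.approx(0.0, abs=1e-18)

    def test_force_scaling_homogeneity(self, adhesive_curve):
        curve, _ = adhesive_curve
        doubled = ForceCurve(
            z=curve.z, force=2.0 * curve.force, segment=curve.segment,
            probe_radius=curve.probe_radius,
        )
        a = adhesion_energetics(curve)
        b = adhesion_energetics(doubled)
        assert b["w_pulloff"] == pytest.approx(2.0 * a["w_pulloff"], rel=1e-9)
        assert b["hysteresis_energy"] == pytest.approx(2.0 * a["hysteresis_energy"], rel=1e-9)

    def test_no_adhesion_flagged(self, junction_curve):
        curve, _ = junction_curve
        out = adhesion_energetics(curve)
        assert out["zero_adhesion"] or out["w_pulloff"] < 1e-7


class TestAggregate:
    def _results(self, e_values, region="junction", substrate="NCCI"):
        out = []
        for i, e in enumerate(e_values):
            p = ContactModelParams(E=e, R=PROBE_R, z0=1.0)
            c, _ = synthetic.gen_force_curve(
                p, z_range=1.4, n_points=200, seed=100 + i,
                region=region, substrate_label=substrate,
            )
            out.append(ContactModel(c).fit())
        return out

    def test_singleton_group_has_missing_sd(self):
        tab = aggregate_by_region(self._results([30.0]))
        assert tab.loc[0, "n"] == 1
        assert np.isnan(tab.loc[0, "E_Pa_std"])
        assert bool(tab.loc[0, "small_n"])

    def test_identical_results_zero_sd_and_group_ordering(self):
        res = self._results([30.0, 30.0]) + self._results(
            [10.0, 10.0], region="cytoplasm"
        )
        tab = aggregate_by_region(res).set_index("region")
        assert tab.loc["junction", "E_Pa_std"] == pytest.approx(0.0, abs=1e-6)
        assert tab.loc["junction", "E_Pa_mean"] > tab.loc["cytoplasm", "E_Pa_mean"]

    def test_empty_input_raises(self):
        with pytest.raises(EmptyTableError):
            aggregate_by_region([])
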