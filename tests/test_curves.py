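"""Power-law fitting, curve sampling, SSI/dSSI evaluation, nodal maps."""

import numpy as np
import pytest

from aortamech import (compute_indices, fit_power_law, nodal_index_map,
                       regional_average, sample_curve)
from aortamech.curves import CurveFit


def synth_pairs(l1, l2, l3, n=8, e_max=0.08):
    e = np.linspace(e_max / n, e_max, n)
    return e, l1 * e ** l2 + l3


class TestRegionalAverage:
    def test_uniform_field(self):
        vals = np.full(10, 3.7)
        areas = np.random.default_rng(0).uniform(0.5, 2.0, 10)
        out = regional_average(vals, areas, {"r": np.arange(10)})
        assert out["r"] == pytest.approx(3.7)

    def test_two_equal_area_regions(self):
        vals = np.array([1.0, 1.0, 3.0, 3.0])
        areas = np.ones(4)
        out = regional_average(vals, areas, {"a": [0, 1], "b": [2, 3]})
        assert out == {"a": 1.0, "b": 3.0}

    def test_area_weighting(self):
        vals = np.array([1.0, 3.0])
        areas = np.array([3.0, 1.0])
        out = regional_average(vals, areas, {"r": [0, 1]})
        assert out["r"] == pytest.approx(1.5)

    def test_empty_region_raises(self):
        with pytest.raises(ValueError, match="empty"):
            regional_average(np.ones(3), np.ones(3), {"r": []})


class TestPowerLawFit:
    @pytest.mark.parametrize("params", [(10.0, 2.0, 0.01), (5.0, 1.4, 0.0),
                                        (0.5, 3.2, 0.1)])
    def test_noiseless_recovery(self, params):
        e, tau = synth_pairs(*params)
        fit = fit_power_law(e, tau)
        assert fit.lambda1 == pytest.approx(params[0], rel=1e-6)
        assert fit.lambda2 == pytest.approx(params[1], rel=1e-6)
        assert fit.lambda3 == pytest.approx(params[2], abs=1e-6)
        assert fit.residual < 1e-9

    def test_linear_data_pins_exponent_at_bound(self):
        e = np.linspace(0.01, 0.08, 8)
        tau = 2.0 * e + 0.05          # true exponent 1 < allowed bound
        fit = fit_power_law(e, tau)
        assert fit.lambda2_at_bound

    def test_noisy_median_bias_below_five_percent(self):
        rng = np.random.default_rng(42)
        true = (10.0, 2.0, 0.01)
        e, tau0 = synth_pairs(*true)
        span = tau0.max() - tau0.min()
        est = []
        for _ in range(100):
            fit = fit_power_law(e, tau0 + rng.normal(0, 0.01 * span,
                                                     tau0.size))
            est.append([fit.lambda1, fit.lambda2, fit.lambda3])
        med = np.median(est, axis=0)
        assert abs(med[0] - true[0]) / true[0] < 0.05
        assert abs(med[1] - true[1]) / true[1] < 0.05

    def test_input_validation(self):
        with pytest.raises(ValueError, match="4"):
            fit_power_law([0.01, 0.02, 0.03], [1, 2, 3])
        with pytest.raises(ValueError, match="distinct"):
            fit_power_law([0.01, 0.01, 0.01, 0.02], [1, 1, 1, 2])


class TestSampleCurve:
    def test_default_grid(self):
        e = sample_curve(0.16, N=16)
        assert e[0] == pytest.approx(0.01)
        assert e[-1] == pytest.approx(0.16)
        assert np.all(e > 0.0) and np.all(e <= 0.16)

    def test_emin_anchored_grid(self):
        e = sample_curve(0.2, N=4, e_min=0.1)
        assert np.allclose(e, [0.125, 0.15, 0.175, 0.2])

    def test_validation(self):
        with pytest.raises(ValueError):
            sample_curve(0.0, 16)
        with pytest.raises(ValueError):
            sample_curve(0.1, 1)
        with pytest.raises(ValueError):
            sample_curve(0.1, 16, e_min=0.2)


class TestIndices:
    def test_closed_form_quadratic_case(self):
        # l1=1, l2=2, l3=0, e_max=1, p_s=1, N=16:
        # SSI = (1/16) sum 2 i/16 = (N+1)/N = 17/16; dSSI = 2
        fit = CurveFit(lambda1=1.0, lambda2=2.0, lambda3=0.0, residual=0.0)
        res = compute_indices(fit, e_max=1.0, p_s_mmhg=1.0, N=16)
        assert res.SSI == pytest.approx(17.0 / 16.0, rel=1e-12)
        assert res.dSSI == pytest.approx(2.0, rel=1e-12)

    def test_linearity_in_pressure_and_lambda1(self):
        fit = CurveFit(lambda1=3.0, lambda2=2.5, lambda3=0.2, residual=0.0)
        a = compute_indices(fit, 0.1, 100.0)
        b = compute_indices(fit, 0.1, 200.0)
        assert b.SSI == pytest.approx(a.SSI / 2.0)
        assert b.dSSI == pytest.approx(a.dSSI / 2.0)
        stiffer = CurveFit(lambda1=30.0, lambda2=2.5, lambda3=0.2,
                           residual=0.0)
        c = compute_indices(stiffer, 0.1, 100.0)
        assert c.SSI == pytest.approx(10.0 * a.SSI)
        assert c.dSSI == pytest.approx(10.0 * a.dSSI)

    def test_lambda3_invariance(self):
        a = CurveFit(lambda1=2.0, lambda2=1.8, lambda3=0.0, residual=0.0)
        b = CurveFit(lambda1=2.0, lambda2=1.8, lambda3=5.0, residual=0.0)
        ra = compute_indices(a, 0.1, 120.0)
        rb = compute_indices(b, 0.1, 120.0)
        assert ra.SSI == rb.SSI and ra.dSSI == rb.dSSI

    @pytest.mark.parametrize("l2", [1.3, 2.0, 3.0])
    def test_matches_numerical_differentiation(self, l2):
        # independent oracle: central differences of the fitted curve at
        # the sampled strains
        fit = CurveFit(lambda1=10.0, lambda2=l2, lambda3=0.01, residual=0.0)
        e_max, p_s, n = 0.1, 120.0, 16
        res = compute_indices(fit, e_max, p_s, N=n)
        e_i = sample_curve(e_max, n)
        # per-point relative steps balance truncation and round-off
        h1 = 1e-6 * e_i
        h2 = 1e-4 * e_i
        d1 = (fit.predict(e_i + h1) - fit.predict(e_i - h1)) / (2 * h1)
        d2 = (fit.predict(e_i + h2) - 2 * fit.predict(e_i)
              + fit.predict(e_i - h2)) / h2 ** 2
        scale = 1.0 / (e_max * p_s)
        assert res.SSI == pytest.approx(scale * d1.mean(), rel=1e-6)
        assert res.dSSI == pytest.approx(scale * d2.mean(), rel=1e-5)

    def test_dssi_monotone_in_exponent(self):
        # at unit strain amplitude a steeper exponent means a harder
        # curve; below e=1 the shrinking e**(l2-2) factor can reverse it
        vals = []
        for l2 in (1.5, 2.0, 2.5, 3.0):
            fit = CurveFit(lambda1=2.0, lambda2=l2, lambda3=0.0,
                           residual=0.0)
            vals.append(compute_indices(fit, 1.0, 120.0).dSSI)
        assert np.all(np.diff(vals) > 0)

    def test_exponent_contract_enforced(self):
        fit = CurveFit(lambda1=1.0, lambda2=0.9, lambda3=0.0, residual=0.0)
        with pytest.raises(ValueError, match="lambda2"):
            compute_indices(fit, 0.1, 120.0)


class TestNodalMaps:
    def test_uniform_cylinder_gives_uniform_maps(self):
        from aortamech import SyntheticCaseSpec, gen_pulsating_cylinder
        from aortamech.synthetic import SQRT3_2

        spec = SyntheticCaseSpec(n_circ=16, n_axial=8, length=30.0,
                                 n_phases=6, curve_law=(20.0, 2.0))
        seq, gt = gen_pulsating_cylinder(spec)
        mesh = seq.mesh
        areas = mesh.face_areas()
        # analytic per-element fields (uniform on the cylinder)
        strains = [np.full(mesh.n_faces, e) for e in gt.hoop_strain[:, 0]]
        tensions = [np.full(mesh.n_faces, t) for t in gt.tension[:, 0]]
        maps = nodal_index_map(mesh.faces, areas, mesh.n_nodes, strains,
                               tensions, p_s_mmhg=120.0)
        ssi = maps["SSI"][maps["ok"]]
        assert maps["ok"].all()
        assert np.std(ssi) / np.mean(ssi) < 0.05

    def test_failed_fit_flagged_not_zeroed(self):
        # one node with constant strain across phases cannot be fitted
        faces = np.array([[0, 1, 2]])
        areas = np.array([1.0])
        strains = [np.array([0.0])] * 6
        tensions = [np.array([0.1])] * 6
        maps = nodal_index_map(faces, areas, 3, strains, tensions, 120.0)
        assert not maps["ok"].any()
        assert np.isnan(maps["SSI"]).all()
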