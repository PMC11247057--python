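"""Resolution scaling, comparison metrics and the sensitivity battery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cowflow.errors import ConfigurationError, InvalidInputError
from cowflow.longitudinal import (ScanPair, alpha_from_networks, apply_alpha,
                                  carotid_inflow_ratio, classify_eta,
                                  network_smoothness_error, normalized_pressure,
                                  outflow_distribution, relative_variation,
                                  resolution_alpha, sensitivity_battery)
from cowflow.solver import SolverSettings, run_simulation
from cowflow.synthetic import SyntheticPatientSpec, generate_network, make_scan_pair

from .conftest import y_network_setup


class TestResolutionAlpha:
    def test_identical_triples_give_one(self):
        assert resolution_alpha([0.2, 0.2, 0.1], [0.2, 0.2, 0.1]) == 1.0

    @given(k=st.floats(0.7, 1.4))
    @settings(deadline=None, max_examples=50)
    def test_uniform_scaling_recovers_inverse(self, k):
        a = np.array([0.2, 0.22, 0.09])
        assert resolution_alpha(a, k * a) == pytest.approx(1.0 / k, rel=1e-12)

    def test_high_precision_mixed_triple(self):
        got = resolution_alpha([0.20, 0.20, 0.10], [0.18, 0.22, 0.10])
        s1 = 2 * 0.20**1.84 + 0.10**1.84
        s2 = 0.18**1.84 + 0.22**1.84 + 0.10**1.84
        assert got == pytest.approx((s1 / s2) ** (1 / 1.84), rel=1e-14)

    def test_missing_inlet_and_bad_area(self):
        with pytest.raises(ConfigurationError):
            resolution_alpha({"a": 1.0}, {"b": 1.0})
        with pytest.raises(InvalidInputError):
            resolution_alpha([0.1, 0.0, 0.1], [0.1, 0.1, 0.1])

    def test_network_distortion_recovery_and_idempotence(self, cohort):
        net1 = generate_network(SyntheticPatientSpec(seed=5), cohort)
        k = 1.21
        net2 = apply_alpha(net1, k)  # corrupt all areas by a known factor
        alpha = alpha_from_networks(net1, net2)
        assert alpha == pytest.approx(1.0 / k, rel=1e-12)
        # applying the recovered alpha re-balances the inflow sum exactly
        net2c = apply_alpha(net2, alpha)
        assert alpha_from_networks(net1, net2c) == pytest.approx(1.0, abs=1e-12)
        # radii scaled by sqrt(k)
        assert net2.arteries["BA"].mean_radius == pytest.approx(
            net1.arteries["BA"].mean_radius * np.sqrt(k), rel=1e-12)

    def test_apply_alpha_unity_is_identity(self, mean_cow):
        assert apply_alpha(mean_cow, 1.0) is mean_cow


class TestRelativeVariation:
    def test_definition_and_signs(self):
        assert relative_variation(1.0, 1.0) == 0.0
        assert relative_variation(1.0, 30.73) == pytest.approx(29.73)
        assert relative_variation(2.0, 1.0) == -0.5

    def test_zero_baseline_raises(self):
        with pytest.raises(InvalidInputError):
            relative_variation(0.0, 1.0)


class TestNetworkSmoothnessError:
    def test_reference_level_is_zero_and_weighted_mean(self):
        areas = {
            0.005: {"A": 1.00, "B": 2.00},
            0.01: {"A": 1.01, "B": 2.06},
        }
        lengths = {"A": 1.0, "B": 1.0}
        eps = network_smoothness_error(areas, lengths)
        assert eps[0.005] == 0.0
        assert eps[0.01] == pytest.approx(0.02)  # mean of 0.01 and 0.03

    def test_length_weighting(self):
        areas = {0.005: {"A": 1.0, "B": 1.0}, 0.02: {"A": 1.1, "B": 1.0}}
        eps = network_smoothness_error(areas, {"A": 3.0, "B": 1.0})
        assert eps[0.02] == pytest.approx(0.75 * 0.1)


@pytest.fixture(scope="module")
def y_result():
    net, params, bcs = y_network_setup(rt1=8000.0, rt2=12000.0)
    st = SolverSettings(dt=1e-3, n_cycles=4, analysis_cycles=2)
    return run_simulation(net, params=params, settings=st, bcs=bcs)


class TestResultMetrics:
    def test_outflow_fractions_sum_to_one(self, y_result):
        frac = outflow_distribution(y_result)
        assert sum(frac.values()) == pytest.approx(1.0, abs=1e-6)
        assert frac["D1"] > frac["D2"]  # lower resistance draws more flow

    def test_normalized_pressure_range_and_inlet_maximum(self, y_result):
        norm = normalized_pressure(y_result)
        vals = np.array(list(norm.values()))
        assert vals.min() == 0.0 and vals.max() == 1.0
        # pressure decays along the flow direction in a dissipative network
        assert norm["P"] == 1.0

    def test_normalized_pressure_affine_invariance(self):
        base = {"A": 80.0, "B": 90.0, "C": 100.0}
        lo, hi = min(base.values()), max(base.values())
        direct = {k: (v - lo) / (hi - lo) for k, v in base.items()}
        affine = {k: 3.0 * v + 7.0 for k, v in base.items()}
        lo2, hi2 = min(affine.values()), max(affine.values())
        again = {k: (v - lo2) / (hi2 - lo2) for k, v in affine.items()}
        assert direct == pytest.approx(again)
        assert direct == pytest.approx({"A": 0.0, "B": 0.5, "C": 1.0})


class TestCarotidRatio:
    def test_symmetric_anatomy_gives_unity(self, cohort):
        morph = cohort.zeroed_sd().symmetrized()
        net = generate_network(SyntheticPatientSpec(seed=0), morph)
        st = SolverSettings(dt=1e-3, n_cycles=3, analysis_cycles=2)
        res = run_simulation(net, settings=st)
        assert carotid_inflow_ratio(res) == pytest.approx(1.0, abs=1e-9)
        # symmetric outflow too
        frac = outflow_distribution(res)
        for lbl in ("OA", "MCA G3", "ACA G3", "PCA G3"):
            assert frac[f"R {lbl}"] == pytest.approx(frac[f"L {lbl}"], rel=1e-6)


class TestSensitivityBattery:
    def test_eta_definition_and_bands(self):
        assert classify_eta((0.15 - 0.10) / 0.10) == "orange"
        assert classify_eta(0.51) == "red"
        assert classify_eta(0.3) == "orange"
        assert classify_eta(0.1) == "yellow"
        assert classify_eta(-0.6) == "red"

    def test_self_pair_returns_eta_zero_everywhere(self, cohort):
        # a duplicated scan has eps_sc = 0; every perturbation applied to
        # both scans symmetrically must leave eta = 0
        net = generate_network(SyntheticPatientSpec(seed=4), cohort)
        pair = ScanPair.calibrated(net, net)
        assert pair.alpha == 1.0
        st = SolverSettings(dt=1e-3, n_cycles=2, analysis_cycles=2)
        cases = sensitivity_battery(pair, "L PCoA", settings=st)
        assert [c.case_id for c in cases] == [
            "reference", "alpha_1", "half_Rt", "double_Rt", "half_E", "double_E"]
        for c in cases:
            assert c.error is None, c
            assert c.eta == 0.0

    def test_alpha_one_differs_on_dilated_pair(self, cohort):
        # scan 2 globally dilated: skipping the calibration must change the
        # comparison for a flow-carrying vessel
        spec = SyntheticPatientSpec(seed=8, radius_perturbation=0.05,
                                    length_perturbation=0.0,
                                    resolution_distortion=1.2)
        pair, truth = make_scan_pair(spec, cohort)
        st = SolverSettings(dt=1e-3, n_cycles=2, analysis_cycles=2)
        cases = {c.case_id: c for c in sensitivity_battery(
            pair, "R MCA G1", settings=st)}
        ref, a1 = cases["reference"], cases["alpha_1"]
        assert ref.error is None and a1.error is None
        assert abs(a1.eps_sc - ref.eps_sc) > 1e-4
        assert a1.eta != 0.0
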