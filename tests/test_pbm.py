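import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from semgtorque.exceptions import InvalidInputError, InvalidParameterError
from semgtorque.muscles import build_muscles
from semgtorque.pbm import (
    ActivationParams,
    GAConfig,
    PBMParameters,
    activation_nonlinearity,
    calibrate_pbm,
    default_parameters,
    forward_pbm,
    joint_torque,
    minimize_ga,
    recursive_filter,
    two_channel_torque,
)

FS = 1000.0


class TestActivationParams:
    def test_unit_dc_gain_identity(self):
        # alpha - beta1 - beta2 = 1 for any admissible C1, C2
        for c1, c2 in [(0.5, -0.3), (0.0, 0.0), (-0.9, 0.9), (0.7, 0.7)]:
            p = ActivationParams(C1=c1, C2=c2)
            assert p.alpha - p.beta1 - p.beta2 == pytest.approx(1.0)

    @pytest.mark.parametrize("c1,c2", [(1.0, 0.0), (0.0, -1.2)])
    def test_unstable_coefficients_rejected(self, c1, c2):
        with pytest.raises(InvalidParameterError):
            ActivationParams(C1=c1, C2=c2)

    @pytest.mark.parametrize("d", [5.0, 150.0])
    def test_delay_bounds(self, d):
        with pytest.raises(InvalidParameterError):
            ActivationParams(d_ms=d)


class TestRecursiveFilter:
    def test_passthrough_with_delay(self):
        e = np.linspace(0, 1, 200)
        p = ActivationParams(C1=0.0, C2=0.0, d_ms=10.0)
        u = recursive_filter(e, p, FS)
        np.testing.assert_allclose(u[10:], e[:-10], atol=1e-12)
        np.testing.assert_allclose(u[:10], 0.0)

    def test_unit_dc_gain_steady_state(self):
        e = np.ones(4000)
        p = ActivationParams(C1=0.6, C2=-0.4, d_ms=20.0)
        u = recursive_filter(e, p, FS)
        assert u[-1] == pytest.approx(1.0, abs=1e-9)

    def test_impulse_response_matches_direct_recursion(self):
        p = ActivationParams(C1=0.5, C2=-0.3, d_ms=10.0)
        e = np.zeros(50)
        e[0] = 1.0
        u = recursive_filter(e, p, FS)
        # brute-force recursion oracle, term by term
        d = 10
        expected = np.zeros(50)
        for t in range(50):
            et = e[t - d] if t >= d else 0.0
            u1 = expected[t - 1] if t >= 1 else 0.0
            u2 = expected[t - 2] if t >= 2 else 0.0
            expected[t] = p.alpha * et - p.beta1 * u1 - p.beta2 * u2
        np.testing.assert_allclose(u, expected, atol=1e-12)

    @given(
        hst.floats(min_value=-0.9, max_value=0.9),
        hst.floats(min_value=-0.9, max_value=0.9),
        hst.integers(min_value=0, max_value=2**31 - 1),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_bounded_output_for_stable_coefficients(self, c1, c2, seed):
        e = np.random.default_rng(seed).random(500)
        p = ActivationParams(C1=c1, C2=c2, d_ms=15.0)
        u = recursive_filter(e, p, FS)
        # geometric bound: |u| <= alpha * sum |h| is finite; generous cap
        assert np.isfinite(u).all()
        assert np.abs(u).max() < 1e3


class TestActivationNonlinearity:
    @pytest.mark.parametrize("A", [-3.0, -1.5, -0.1, 0.0])
    def test_endpoints(self, A):
        assert activation_nonlinearity(np.array([0.0]), A)[0] == \
            pytest.approx(0.0)
        assert activation_nonlinearity(np.array([1.0]), A)[0] == \
            pytest.approx(1.0)

    def test_known_value(self):
        # (e^{-1.5} - 1)/(e^{-3} - 1) evaluated directly
        a = activation_nonlinearity(np.array([0.5]), -3.0)[0]
        assert a == pytest.approx(0.8175745, abs=1e-6)

    def test_linear_limit(self):
        u = np.linspace(0, 1, 101)
        np.testing.assert_allclose(
            activation_nonlinearity(u, -1e-8), u, atol=1e-9
        )
        np.testing.assert_array_equal(activation_nonlinearity(u, 0.0), u)

    @pytest.mark.parametrize("A", [-3.0, -1.0])
    def test_monotone_bijection_of_unit_interval(self, A):
        u = np.linspace(0, 1, 1001)
        a = activation_nonlinearity(u, A)
        assert np.all(np.diff(a) > 0)
        assert a.min() >= 0.0 and a.max() <= 1.0


class TestJointTorque:
    def test_zero_activation_zero_torque(self):
        params = default_parameters()
        tau = joint_torque(np.zeros((10, 8)), params)
        np.testing.assert_array_equal(tau, 0.0)

    def test_single_channel_unit_weight(self):
        from semgtorque.muscles import MusclePhysiology

        m = MusclePhysiology(
            name="FCR", role="flexor", fmax_N=70.0,
            fmax_bounds_N=(56.0, 84.0), ma_m=0.015,
            ma_bounds_m=(0.012, 0.018), pcsa_cm2=2.0,
            sigma_pcsa_cm2=2.0,  # sigma PCSA == PCSA -> weight 1
        )
        params = PBMParameters(activation=ActivationParams(), muscles=[m])
        tau = joint_torque(np.array([[0.5]]), params)
        assert tau[0] == pytest.approx(0.5 * 70.0 * 0.015)

    def test_two_channel_hand_computation(self):
        muscles = build_muscles(("FCR", "ECU"))
        params = PBMParameters(activation=ActivationParams(), muscles=muscles)
        a_f = np.array([0.6])
        a_e = np.array([0.8])
        tau = two_channel_torque(a_f, a_e, params)
        wf = muscles[0].pcsa_weight * muscles[0].fmax_N * muscles[0].ma_m
        we = muscles[1].pcsa_weight * muscles[1].fmax_N * muscles[1].ma_m
        assert tau[0] == pytest.approx(0.6 * wf + 0.8 * we)

    def test_flexors_positive_extensors_negative(self):
        params = default_parameters()
        flex_only = np.zeros((1, 8))
        flex_only[0, 4:] = 1.0  # FCR, PL, FDS, FCU
        ext_only = np.zeros((1, 8))
        ext_only[0, :4] = 1.0
        assert joint_torque(flex_only, params)[0] > 0
        assert joint_torque(ext_only, params)[0] < 0

    def test_linearity_superposition(self, rng):
        params = default_parameters()
        a1 = rng.random((20, 8))
        a2 = rng.random((20, 8))
        np.testing.assert_allclose(
            joint_torque(a1 + a2, params),
            joint_torque(a1, params) + joint_torque(a2, params),
            atol=1e-10,
        )

    def test_channel_count_mismatch(self):
        with pytest.raises(InvalidInputError):
            joint_torque(np.zeros((5, 3)), default_parameters())


class TestPCSARedistribution:
    def test_five_channel_weights(self):
        """Primary flexors absorb half the non-primary flexor PCSA each;
        primary extensors a third of the non-primary extensor PCSA."""
        from semgtorque.muscles import load_muscle_table

        table = load_muscle_table()
        five = {m.name: m for m in build_muscles(
            ("ECRL", "ECU", "ECRB", "FCR", "FCU"))}
        nonprim_flex = (table.loc["PL", "sigma_pcsa_cm2"]
                        + table.loc["FDS", "sigma_pcsa_cm2"])
        nonprim_ext = table.loc["EDC", "sigma_pcsa_cm2"]
        assert five["FCR"].sigma_pcsa_cm2 == pytest.approx(
            table.loc["FCR", "sigma_pcsa_cm2"] + nonprim_flex / 2
        )
        assert five["ECU"].sigma_pcsa_cm2 == pytest.approx(
            table.loc["ECU", "sigma_pcsa_cm2"] + nonprim_ext / 3
        )

    def test_two_channel_full_group_pcsa(self):
        from semgtorque.muscles import load_muscle_table

        table = load_muscle_table()
        pair = {m.name: m for m in build_muscles(("FCU", "ECRB"))}
        flex_total = table[table.role == "flexor"]["sigma_pcsa_cm2"].sum()
        assert pair["FCU"].sigma_pcsa_cm2 == pytest.approx(flex_total)

    def test_two_channels_same_role_rejected(self):
        with pytest.raises(InvalidInputError):
            build_muscles(("FCR", "FCU"))


class TestForwardPBM:
    def test_zero_envelopes_zero_torque(self):
        params = default_parameters()
        from semgtorque.processing import ProcessedRecording

        rec = ProcessedRecording(
            sample_rate_hz=FS,
            envelopes=np.zeros((500, 8)),
            torque=np.zeros(500),
        )
        np.testing.assert_array_equal(forward_pbm(rec, params), 0.0)

    def test_passthrough_composition(self):
        # C1 = C2 = 0 and A -> 0: torque is the delayed weighted sum
        muscles = build_muscles()
        act = ActivationParams(A=0.0, C1=0.0, C2=0.0, d_ms=10.0)
        params = PBMParameters(activation=act, muscles=muscles)
        env = np.random.default_rng(0).random((300, 8))
        tau = forward_pbm(env, params, sample_rate_hz=FS)
        w = params.torque_weights()
        np.testing.assert_allclose(tau[10:], env[:-10] @ w, atol=1e-10)

    def test_generator_self_consistency(self, subject, clean_recording):
        """Forward model with ground-truth parameters reproduces the
        generator's torque to well under 2% NRMSE."""
        from semgtorque.metrics import nrmse

        tau = forward_pbm(clean_recording, subject.ground_truth)
        assert nrmse(tau, clean_recording.torque) < 0.02


class TestGA:
    def test_sphere_minimum(self):
        res = minimize_ga(
            lambda x: float(x @ x),
            np.full(3, -5.0), np.full(3, 5.0),
            GAConfig(seed=3, population=40, generations=60),
        )
        assert res.fun < 1e-2

    def test_infeasible_bounds_rejected(self):
        with pytest.raises(InvalidParameterError):
            minimize_ga(lambda x: 0.0, np.array([1.0]), np.array([0.0]),
                        GAConfig())

    def test_seeded_determinism(self):
        cfg = GAConfig(seed=11, population=20, generations=15)
        f = lambda x: float((x - 0.3) @ (x - 0.3))
        a = minimize_ga(f, np.zeros(4), np.ones(4), cfg)
        b = minimize_ga(f, np.zeros(4), np.ones(4), cfg)
        np.testing.assert_array_equal(a.x, b.x)


class TestCalibration:
    def test_recovery_on_short_clean_recording(self, clean_recording):
        from semgtorque.metrics import nrmse
        from semgtorque.processing import resample_indices

        cfg = GAConfig(seed=5, population=40, generations=60, resample_k=20)
        res = calibrate_pbm(clean_recording, ga_config=cfg)
        assert res.parameters.activation.d_ms >= 10.0
        assert res.parameters.activation.d_ms <= 100.0
        idx = resample_indices(clean_recording.n_samples, 20)
        tau = forward_pbm(clean_recording, res.parameters)
        assert nrmse(tau[idx], clean_recording.torque[idx]) < 0.02

    def test_objective_no_worse_than_mean_start(self, clean_recording):
        from semgtorque.processing import resample_indices

        template = default_parameters(clean_recording.channel_names)
        idx = resample_indices(clean_recording.n_samples, 20)
        tau0 = forward_pbm(clean_recording, template)
        sse0 = float(((tau0[idx] - clean_recording.torque[idx]) ** 2).sum())
        cfg = GAConfig(seed=5, population=20, generations=5, resample_k=20)
        res = calibrate_pbm(clean_recording, ga_config=cfg)
        assert res.sse <= sse0 + 1e-9

    def test_same_seed_identical_parameters(self, clean_recording):
        cfg = GAConfig(seed=7, population=15, generations=8, resample_k=50)
        a = calibrate_pbm(clean_recording, ga_config=cfg)
        b = calibrate_pbm(clean_recording, ga_config=cfg)
        assert a.parameters.activation == b.parameters.activation
        np.testing.assert_array_equal(
            [m.fmax_N for m in a.parameters.muscles],
            [m.fmax_N for m in b.parameters.muscles],
        )
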