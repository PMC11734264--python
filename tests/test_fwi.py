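import numpy as np
import pytest

import fdfwi as fw
from fdfwi.exceptions import DegenerateSourceError, FrequencyLookupError
from fdfwi.fwi import (
    _FrequencyWorkspace,
    cg_update_block,
    estimate_source,
    receiver_mask,
)


class TestReceiverMask:
    def test_circular_exclusion(self):
        m = receiver_mask(8, 1)
        assert not m[0, 0] and not m[0, 1] and not m[0, 7]
        assert m[0, 2] and m[0, 6]
        assert m.sum() == 8 * 5

    def test_zero_exclusion_masks_only_diagonal(self):
        m = receiver_mask(6, 0)
        assert np.array_equal(m, ~np.eye(6, dtype=bool))


class TestEstimateSource:
    def test_exact_proportionality_recovered(self):
        rng = np.random.default_rng(0)
        sim = rng.standard_normal((2, 5)) + 1j * rng.standard_normal((2, 5))
        a = estimate_source(sim, 3j * sim)
        np.testing.assert_allclose(a, 3j, rtol=1e-12)

    def test_orthogonal_observation_gives_zero(self):
        sim = np.array([[1.0 + 0j, 1j, 0, 0, 0]])
        obs = np.array([[0, 0, 1.0 + 0j, 0, 0]])
        assert estimate_source(sim, obs)[0] == 0

    def test_matches_numerical_minimizer(self):
        """Independent oracle: minimize ||a sim - obs||^2 over Re(a), Im(a)."""
        from scipy.optimize import minimize

        rng = np.random.default_rng(1)
        sim = rng.standard_normal(5) + 1j * rng.standard_normal(5)
        obs = rng.standard_normal(5) + 1j * rng.standard_normal(5)
        a = estimate_source(sim[None, :], obs[None, :])[0]

        def cost(x):
            return np.sum(np.abs((x[0] + 1j * x[1]) * sim - obs) ** 2)

        res = minimize(cost, [0.0, 0.0], method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-14})
        assert a.real == pytest.approx(res.x[0], abs=1e-6)
        assert a.imag == pytest.approx(res.x[1], abs=1e-6)

    def test_zero_simulated_channel_rejected(self):
        with pytest.raises(DegenerateSourceError):
            estimate_source(np.zeros((1, 4), complex), np.ones((1, 4), complex))


class TestObjective:
    def test_zero_residual_at_generating_model(self, tiny_setup):
        """Same model, same solver, same injection stencil: E vanishes."""
        s = tiny_setup
        obs = fw.simulate_channel_spectra(
            s["truth"], s["ring"], None, [s["f0"]], pml=s["config"].pml,
            source_stencil="nearest",
        )
        E = fw.objective(s["truth"], obs, s["f0"], config=s["config"])
        scale = float(np.sum(np.abs(obs.values) ** 2))
        assert E < 1e-20 * scale

    def test_quadratic_scaling_of_residual(self, tiny_setup, tiny_observed):
        """obs' = 2 obs - sim doubles every residual: E quadruples."""
        s = tiny_setup
        ws = _FrequencyWorkspace(fw.homogeneous_model(s["grid"], 1480.0), tiny_observed,
                                 s["f0"], s["config"])
        sim = ws.sources[:, None] * ws.sim_unit
        obs2_vals = (2 * tiny_observed.values[:, :, 0] - sim)[:, :, None]
        # keep masked entries identical to the original so they stay ignored
        obs2 = fw.ChannelSpectra(obs2_vals, [s["f0"]], s["ring"], provenance="simulated")
        E1 = fw.objective(fw.homogeneous_model(s["grid"], 1480.0), tiny_observed,
                          s["f0"], sources=ws.sources, config=s["config"])
        E2 = fw.objective(fw.homogeneous_model(s["grid"], 1480.0), obs2,
                          s["f0"], sources=ws.sources, config=s["config"])
        assert E2 == pytest.approx(4 * E1, rel=1e-10)

    def test_masked_half_sum_arithmetic(self, tiny_setup, tiny_observed):
        """E equals the hand-computed half-sum of squared residual moduli."""
        s = tiny_setup
        model = fw.homogeneous_model(s["grid"], 1480.0)
        ws = _FrequencyWorkspace(model, tiny_observed, s["f0"], s["config"])
        manual = 0.0
        mask = receiver_mask(8, 1)
        for i in range(8):
            for r in range(8):
                if mask[i, r]:
                    d = ws.sources[i] * ws.sim_unit[i, r] - tiny_observed.values[i, r, 0]
                    manual += 0.5 * abs(d) ** 2
        assert ws.E == pytest.approx(manual, rel=1e-12)

    def test_absent_frequency_is_lookup_error(self, tiny_setup, tiny_observed):
        with pytest.raises(FrequencyLookupError):
            fw.objective(fw.homogeneous_model(tiny_setup["grid"], 1480.0),
                         tiny_observed, 999e3, config=tiny_setup["config"])


class TestGradient:
    @pytest.mark.parametrize("parameter", ["sound_speed", "attenuation"])
    def test_matches_central_finite_differences(self, tiny_setup, tiny_observed, parameter):
        """The module's core correctness oracle: adjoint-state directional
        derivative vs central differencing of the objective."""
        from scipy.ndimage import gaussian_filter

        s = tiny_setup
        start = fw.homogeneous_model(s["grid"], 1480.0, 0.1)
        E0, g = fw.gradient(start, tiny_observed, s["f0"], parameter, s["config"])
        rng = np.random.default_rng(21)
        delta = gaussian_filter(rng.standard_normal(s["grid"].shape), 1)
        delta[:8, :] = delta[-8:, :] = delta[:, :8] = delta[:, -8:] = 0.0
        dd_adj = float(np.sum(g * delta))
        eps = 1e-1 if parameter == "sound_speed" else 1e-3
        mp, mm = start.copy(), start.copy()
        setattr(mp, parameter, getattr(start, parameter) + eps * delta)
        setattr(mm, parameter, getattr(start, parameter) - eps * delta)
        Ep = _FrequencyWorkspace(mp, tiny_observed, s["f0"], s["config"]).E
        Em = _FrequencyWorkspace(mm, tiny_observed, s["f0"], s["config"]).E
        dd_fd = (Ep - Em) / (2 * eps)
        assert abs(dd_adj - dd_fd) / abs(dd_fd) < 1e-3

    def test_stationary_at_generating_model(self, tiny_setup):
        s = tiny_setup
        obs = fw.simulate_channel_spectra(
            s["truth"], s["ring"], None, [s["f0"]], pml=s["config"].pml,
            source_stencil="nearest",
        )
        E0, g0 = fw.gradient(s["truth"], obs, s["f0"], "sound_speed", s["config"])
        _, g1 = fw.gradient(
            fw.homogeneous_model(s["grid"], 1480.0), obs, s["f0"], "sound_speed", s["config"]
        )
        assert np.linalg.norm(g0) < 1e-8 * np.linalg.norm(g1)

    def test_negative_gradient_is_descent_direction(self, tiny_setup, tiny_observed):
        s = tiny_setup
        start = fw.homogeneous_model(s["grid"], 1480.0)
        E0, g = fw.gradient(start, tiny_observed, s["f0"], "sound_speed", s["config"])
        step = -1.0 * g / np.max(np.abs(g))  # 1 m/s max step downhill
        trial = start.copy()
        trial.sound_speed = start.sound_speed + step
        E1 = _FrequencyWorkspace(trial, tiny_observed, s["f0"], s["config"]).E
        assert E1 < E0


class TestCGBlock:
    def test_objective_nonincreasing_within_block(self, tiny_setup, tiny_observed):
        s = tiny_setup
        history = []
        model = cg_update_block(
            fw.homogeneous_model(s["grid"], 1480.0), tiny_observed, s["f0"],
            "sound_speed", 3, s["config"], history, pass_id="t",
        )
        Es = [e for (_, _, _, e) in history]
        assert len(Es) >= 2
        assert all(b <= a * (1 + 1e-12) for a, b in zip(Es, Es[1:]))

    def test_near_linear_problem_converges_fast(self, tiny_setup):
        """On a tiny-contrast target the first two CG iterations remove most
        of the misfit (quadratic-regime behavior)."""
        s = tiny_setup
        soft = s["truth"].copy()
        soft.sound_speed = 1480.0 + 0.05 * (s["truth"].sound_speed - 1480.0)
        soft.attenuation[:] = 0.0
        obs = fw.simulate_channel_spectra(
            soft, s["ring"], None, [s["f0"]], pml=s["config"].pml, source_stencil="nearest"
        )
        history = []
        cg_update_block(
            fw.homogeneous_model(s["grid"], 1480.0), obs, s["f0"],
            "sound_speed", 2, s["config"], history, pass_id="t",
        )
        Es = [e for (_, _, _, e) in history]
        assert Es[-1] < 0.35 * Es[0]


class TestProtocols:
    def test_two_pass_with_empty_schedule_returns_start(self, tiny_setup, tiny_observed):
        s = tiny_setup
        schedule = fw.FrequencySchedule((), ())
        start = fw.homogeneous_model(s["grid"], 1480.0)
        res = fw.run_two_pass_fwi(tiny_observed, schedule, start, s["config"])
        assert np.array_equal(res.model.sound_speed, start.sound_speed)
        assert res.objective_history == []

    def test_kickstart_requires_fd_provenance(self, tiny_setup, tiny_observed):
        schedule = fw.FrequencySchedule((), (), fd_band=None)
        with pytest.raises(ValueError, match="frequency_differenced"):
            fw.run_fd_kickstart(
                tiny_observed, schedule,
                fw.homogeneous_model(tiny_setup["grid"], 1480.0), tiny_setup["config"],
            )

    def test_kickstart_leaves_correct_homogeneous_model_unchanged(self, tiny_setup):
        """Homogeneous truth, start at the true speed: already optimal."""
        s = tiny_setup
        hom = fw.homogeneous_model(s["grid"], 1500.0)
        obs = fw.simulate_channel_spectra(
            hom, s["ring"], None, [s["f0"]], pml=s["config"].pml, source_stencil="nearest"
        )
        fd = obs.with_provenance("frequency_differenced")
        schedule = fw.FrequencySchedule((), (), cg_iterations_fd=2)
        out = fw.run_fd_kickstart(fd, schedule, hom.copy(), s["config"])
        assert np.max(np.abs(out.sound_speed - 1500.0)) < 0.5

    def test_engine_is_provenance_blind(self, tiny_setup, tiny_observed):
        """The difference-frequency objective is the same code path: retagging
        provenance changes nothing in E or the gradient."""
        s = tiny_setup
        model = fw.homogeneous_model(s["grid"], 1480.0)
        E_meas, g_meas = fw.gradient(model, tiny_observed, s["f0"], "sound_speed", s["config"])
        retagged = tiny_observed.with_provenance("frequency_differenced")
        E_fd, g_fd = fw.gradient(model, retagged, s["f0"], "sound_speed", s["config"])
        assert E_meas == E_fd
        assert np.array_equal(g_meas, g_fd)

    def test_history_records_pass_structure(self, tiny_setup, tiny_observed):
        s = tiny_setup
        schedule = fw.FrequencySchedule((s["f0"],), (s["f0"],), cg_iterations_main=1)
        res = fw.run_two_pass_fwi(
            tiny_observed, schedule, fw.homogeneous_model(s["grid"], 1480.0), s["config"]
        )
        passes = {p for (_, p, _, _) in res.objective_history}
        assert {"pass1", "pass2-c", "pass2-a"} <= passes


class TestScheduleValidation:
    def test_decreasing_frequencies_rejected(self):
        with pytest.raises(ValueError):
            fw.FrequencySchedule((2e5, 1e5), ())

    def test_zero_iteration_counts_rejected(self):
        with pytest.raises(ValueError):
            fw.FrequencySchedule((), (), cg_iterations_main=0)
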