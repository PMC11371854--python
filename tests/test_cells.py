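"""LTC and CfC cell dynamics: hand-computed values, an independent ODE
oracle, closed-form leak behavior, boundedness and masking."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from liquidecg.autodiff import Tensor
from liquidecg.cells import (
    CfCCell,
    LTCCell,
    LTCParameters,
    cfc_blend,
    cfc_step,
    ltc_rhs,
    semi_implicit_step,
    synapse_sigmoid,
    unroll,
)
from liquidecg.wiring import WiringConfig, build_wiring


def leak_params(cm=1.0, gl=1.0, x_leak=0.0, delta=0.1, n=1):
    """n uncoupled leak-only neurons (all synaptic weights zero)."""
    return LTCParameters.from_values(
        cm=np.full(n, cm), gl=np.full(n, gl), x_leak=np.full(n, x_leak),
        w=np.zeros((n, n)), gamma=np.ones((n, n)), mu=np.zeros((n, n)),
        E=np.ones((n, n)), delta=delta,
    )


class TestSynapseSigmoid:
    def test_midpoint_gives_half(self):
        assert synapse_sigmoid(0.7, 3.0, 0.7) == pytest.approx(0.5)

    def test_hand_value(self):
        # gamma=2, mu=0.5, x=1 -> 1/(1+e^-1)
        assert synapse_sigmoid(1.0, 2.0, 0.5) == pytest.approx(0.7310585786300049)

    def test_saturation_and_monotonicity(self):
        assert synapse_sigmoid(1e3, 2.0, 0.0) == pytest.approx(1.0)
        x = np.linspace(-5, 5, 101)
        y = synapse_sigmoid(x, 3.0, 0.2)
        assert np.all(np.diff(y) > 0) and np.all((y > 0) & (y < 1))


class TestLTCRhs:
    def test_leak_fixed_point(self):
        p = leak_params(x_leak=0.4)
        assert ltc_rhs(np.array([0.4]), None, p) == pytest.approx(0.0, abs=1e-12)

    def test_pure_leak_decay(self):
        p = leak_params(cm=1.0, gl=1.0, x_leak=0.0)
        np.testing.assert_allclose(ltc_rhs(np.array([1.0]), None, p), [-1.0], rtol=1e-12)

    def test_scalar_self_synapse_hand_value(self):
        cm, gl, xl, w, gamma, mu, e, x = 0.8, 0.5, 0.1, 0.6, 2.0, 0.3, -1.0, 0.9
        p = LTCParameters.from_values(
            cm=[cm], gl=[gl], x_leak=[xl], w=[[w]], gamma=[[gamma]], mu=[[mu]], E=[[e]]
        )
        sig = 1.0 / (1.0 + np.exp(-gamma * (x - mu)))
        tau = cm / gl
        expected = -(1 / tau + w / cm * sig) * x + (xl / tau + w / cm * sig * e)
        assert ltc_rhs(np.array([x]), None, p)[0] == pytest.approx(expected, rel=1e-12)


class TestSemiImplicitStep:
    def test_fixed_point(self):
        p = leak_params(x_leak=0.25, delta=0.5)
        out = semi_implicit_step(np.array([0.25]), None, p)
        assert out[0] == pytest.approx(0.25, abs=1e-14)

    def test_hand_value(self):
        # Cm=1, gl=1, x_leak=0, delta=0.1, x0=1 -> (1/0.1)/(1/0.1+1) = 10/11
        p = leak_params(delta=0.1)
        out = semi_implicit_step(np.array([1.0]), None, p)
        assert out[0] == pytest.approx(10.0 / 11.0, rel=1e-12)

    def test_leak_only_geometric_decay(self):
        """w=0: x converges to x_leak with per-step factor (Cm/D)/(Cm/D+gl)."""
        cm, gl, xl, delta = 0.7, 1.3, 0.2, 0.05
        p = leak_params(cm=cm, gl=gl, x_leak=xl, delta=delta)
        rho = (cm / delta) / (cm / delta + gl)
        x = np.array([1.0])
        for k in range(1, 30):
            x = semi_implicit_step(x, None, p)
            expected = xl + (1.0 - xl) * rho**k
            assert x[0] == pytest.approx(expected, abs=1e-12)

    def test_matches_fine_step_explicit_integrator(self):
        """Coupled 3-neuron system: the semi-implicit trajectory at small
        delta must track a high-accuracy adaptive RK solution of the ODE."""
        rng = np.random.default_rng(0)
        n = 3
        w = rng.uniform(0.2, 0.8, size=(n, n))
        p = LTCParameters.from_values(
            cm=rng.uniform(0.8, 1.2, n), gl=rng.uniform(0.5, 1.0, n),
            x_leak=rng.uniform(-0.3, 0.3, n), w=w,
            gamma=rng.uniform(2, 5, size=(n, n)), mu=rng.uniform(-0.2, 0.5, (n, n)),
            E=np.sign(rng.normal(size=(n, n))), delta=1e-3,
        )
        x0 = np.array([0.5, -0.2, 0.1])
        x = x0.copy()
        for _ in range(1000):
            x = semi_implicit_step(x, None, p)
        sol = solve_ivp(
            lambda t, y: ltc_rhs(y, None, p), (0.0, 1.0), x0,
            method="RK45", rtol=1e-10, atol=1e-12,
        )
        assert np.max(np.abs(x - sol.y[:, -1])) < 1e-3

    def test_tensor_and_numpy_paths_agree(self, rng):
        n = 4
        p = LTCParameters.from_values(
            cm=rng.uniform(0.5, 1.5, n), gl=rng.uniform(0.5, 1.5, n),
            x_leak=rng.uniform(-0.5, 0.5, n), w=rng.uniform(0, 1, (n, n)),
            gamma=rng.uniform(2, 6, (n, n)), mu=rng.uniform(-0.5, 0.5, (n, n)),
            E=np.sign(rng.normal(size=(n, n))), delta=0.3,
        )
        x = rng.uniform(-1, 1, n)
        out_np = semi_implicit_step(x, None, p)
        out_t = semi_implicit_step(Tensor(x.reshape(1, -1)), None, p)
        np.testing.assert_allclose(out_np, out_t.data[0], rtol=1e-12)

    def test_boundedness(self, rng):
        """With |x_leak| <= 1 and E in {-1,1}, every update is a positively
        weighted average of x, x_leak and polarities: states stay in [-1,1]."""
        for trial in range(20):
            n = int(rng.integers(2, 6))
            p = LTCParameters.from_values(
                cm=rng.uniform(0.2, 2, n), gl=rng.uniform(0.2, 2, n),
                x_leak=rng.uniform(-1, 1, n), w=rng.uniform(0, 5, (n, n)),
                gamma=rng.uniform(1, 8, (n, n)), mu=rng.uniform(-1, 1, (n, n)),
                E=np.sign(rng.normal(size=(n, n))), delta=float(rng.uniform(0.05, 2)),
            )
            x = rng.uniform(-1, 1, n)
            for _ in range(50):
                x = semi_implicit_step(x, None, p)
                assert np.all(np.abs(x) <= 1.0 + 1e-12)


class TestCfC:
    def test_gate_half_at_t_zero(self, rng):
        f = rng.uniform(0.1, 3, 5)
        g = rng.normal(size=5)
        h = rng.normal(size=5)
        np.testing.assert_allclose(cfc_blend(f, g, h, 0.0), (g + h) / 2, rtol=1e-12)

    def test_hand_value(self):
        # f=1, g=2, h=0, t=ln 3: sigma(-ln 3) = 1/4 -> X = 0.5
        assert cfc_blend(1.0, 2.0, 0.0, np.log(3.0)) == pytest.approx(0.5, rel=1e-12)

    def test_equal_compartments_passthrough(self, rng):
        g = rng.normal(size=4)
        for t in (0.0, 0.7, 50.0):
            np.testing.assert_allclose(cfc_blend(rng.uniform(0.1, 2, 4), g, g, t), g, rtol=1e-12)

    def test_gate_limits(self, rng):
        """f>0 fixed: X -> h as t -> inf; X -> g as sigma(-ft) -> 1."""
        f = rng.uniform(0.5, 2, 6)
        g = rng.normal(size=6)
        h = rng.normal(size=6)
        np.testing.assert_allclose(cfc_blend(f, g, h, 1e4), h, atol=1e-9)
        np.testing.assert_allclose(cfc_blend(-50.0, g, h, 1.0), g, atol=1e-9)

    def test_step_on_wiring_requires_nonnegative_time(self):
        cell = CfCCell(build_wiring(WiringConfig(seed=0)), seed=1)
        x = np.zeros(cell.n_hidden)
        i = np.zeros(75)
        with pytest.raises(ValueError):
            cfc_step(x, i, -1.0, cell.params)

    def test_masking_blocks_absent_synapses(self):
        """Zeroing a wiring edge makes the presynaptic value irrelevant."""
        g = build_wiring(WiringConfig(seed=0))
        cell = CfCCell(g, seed=1)
        mask = cell.params.mask
        src = int(np.flatnonzero(mask[:75].sum(axis=1) == 0)[0]) \
            if np.any(mask[:75].sum(axis=1) == 0) else None
        # find a sensory input with no outgoing synapse, or create one
        if src is None:
            src = 0
            cell.params.mask[0, :] = 0.0
            for W in (cell.params.Wf, cell.params.Wg, cell.params.Wh):
                W.data[0, :] = 0.0
        x = np.zeros(cell.n_hidden)
        i1 = np.zeros(75)
        i2 = np.zeros(75)
        i2[src] = 5.0
        np.testing.assert_allclose(
            cfc_step(x, i1, 1.0, cell.params),
            cfc_step(x, i2, 1.0, cell.params),
            rtol=1e-12,
        )


class TestUnroll:
    def make_cell(self, **kw):
        return LTCCell(build_wiring(WiringConfig(seed=0)), seed=2, **kw)

    def test_zero_weights_zero_input_stays_zero(self):
        cell = self.make_cell()
        p = cell.params
        p.sensory.raw_w.data[:] = -40.0  # softplus -> ~0
        p.state.raw_w.data[:] = -40.0
        p.x_leak.data[:] = 0.0
        frames = np.zeros((1, 5, 75))
        traj, final = unroll(cell, frames)
        assert np.allclose(traj, 0.0, atol=1e-12) and np.allclose(final, 0.0, atol=1e-12)

    def test_single_frame_equals_one_step(self, rng):
        cell = self.make_cell()
        frame = rng.uniform(-1, 1, size=(1, 1, 75))
        traj, final = unroll(cell, frame)
        x0 = Tensor(np.zeros((1, cell.n_hidden)))
        direct = cell.frame_step(x0, Tensor(frame[:, 0]), 0)
        np.testing.assert_allclose(final, direct.data, rtol=1e-12)

    def test_frame_step_is_unfolded_semi_implicit(self, rng):
        """One frame advance equals n_unfold explicit applications of the
        single-step operator with the same frame input."""
        cell = self.make_cell(n_unfold=3, delta=0.4)
        inputs = rng.uniform(-1, 1, 75)
        x = rng.uniform(-0.5, 0.5, cell.n_hidden)
        via_cell = cell.frame_step(Tensor(x.reshape(1, -1)), Tensor(inputs.reshape(1, -1))).data[0]
        x_ref = x.copy()
        for _ in range(3):
            x_ref = semi_implicit_step(x_ref, inputs, cell.params)
        np.testing.assert_allclose(via_cell, x_ref, rtol=1e-10)

    def test_step_halving_consistency(self, rng):
        """Halving delta while doubling n_unfold preserves the simulated time
        span; the discretization error is O(delta), so at small delta the
        final states agree to 1e-4 and the error shrinks with delta."""
        frames = rng.uniform(-1, 1, size=(1, 8, 75))
        base = self.make_cell(delta=2e-4, n_unfold=2)
        fine = self.make_cell(delta=1e-4, n_unfold=4)
        _, final_base = unroll(base, frames)
        _, final_fine = unroll(fine, frames)
        assert np.max(np.abs(final_base - final_fine)) < 1e-4
        # observed order >= 1 at a coarser scale
        coarse = [self.make_cell(delta=d, n_unfold=u) for d, u in
                  ((0.2, 2), (0.1, 4), (0.05, 8))]
        finals = [unroll(c, frames)[1] for c in coarse]
        err1 = np.max(np.abs(finals[0] - finals[2]))
        err2 = np.max(np.abs(finals[1] - finals[2]))
        assert err2 < err1

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            unroll(self.make_cell(), np.zeros((1, 0, 75)))

    def test_ltc_masking_blocks_absent_synapses(self):
        """A sensory input with no outgoing synapse cannot affect the state."""
        cell = self.make_cell()
        used = set(cell.params.sensory.src.tolist())
        free = [s for s in range(75) if s not in used]
        if not free:  # extremely unlikely under the default config
            pytest.skip("every sensory neuron is wired for this seed")
        frames = np.zeros((1, 4, 75))
        frames2 = frames.copy()
        frames2[:, :, free[0]] = 3.0
        _, f1 = unroll(cell, frames)
        _, f2 = unroll(cell, frames2)
        np.testing.assert_allclose(f1, f2, rtol=1e-12)
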