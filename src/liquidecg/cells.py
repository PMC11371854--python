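"""Liquid time-constant (LTC) and closed-form continuous-time (CfC) cells.

An LTC neuron is a leaky integrator whose effective time constant varies
with its synaptic input:

    dx_i/dt = -(1/tau_i + sum_j w_ij/Cm_i * sigma_ij(x_j)) * x_i
              + (x_leak_i/tau_i + sum_j w_ij/Cm_i * sigma_ij(x_j) * E_ij)

with tau_i = Cm_i/gl_i, sigmoidal synapse activation
``sigma_ij(x_j) = 1/(1 + exp(-gamma_ij (x_j - mu_ij)))`` and fixed synapse
polarity E_ij in {-1,+1}; the sums range only over synapses that exist in
the wiring graph. The discrete update is the semi-implicit Euler step, a
ratio that is a positively weighted average of x, x_leak and the polarities
— hence unconditionally stable and bounded:

    x(t+D) = (x Cm/D + gl x_leak + sum_j w sigma E)
             / (Cm/D + gl + sum_j w sigma)

The CfC cell replaces numerical integration with a closed-form gate blend

    X(t) = sigma(-f(x,I) t) * g(x,I) + (1 - sigma(-f(x,I) t)) * h(x,I)

where f, g, h are small wiring-masked affine subnetworks (f positive via
softplus; g, h tanh-bounded).

Synaptic parameters (w, gamma, mu, E) are stored per edge, mirroring the
sparsity of the wiring; gather/scatter between neurons and edges is done
with fixed one-hot matrices so the whole cell is a handful of dense matmul
and elementwise operations. Positive parameters (Cm, gl, w) live behind a
softplus reparameterization so positivity survives gradient training.
Every public function accepts plain numpy arrays (and returns numpy) or
autodiff Tensors (and stays differentiable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .wiring import WiringGraph


def _inv_softplus(v) -> np.ndarray:
    """Inverse of log(1+exp(.)), numerically safe for positive v."""
    v = np.asarray(v, dtype=float)
    return np.where(v > 30, v, np.log(np.expm1(np.clip(v, 1e-12, None))))


def synapse_sigmoid(x_j, gamma, mu):
    """Synaptic activation sigma(x_j) = 1/(1+exp(-gamma (x_j - mu))), in (0,1)."""
    if any(isinstance(a, Tensor) for a in (x_j, gamma, mu)):
        x_j = x_j if isinstance(x_j, Tensor) else Tensor(x_j)
        gamma = gamma if isinstance(gamma, Tensor) else Tensor(gamma)
        mu = mu if isinstance(mu, Tensor) else Tensor(mu)
        return ad.sigmoid(gamma * (x_j - mu))
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-np.asarray(gamma) * (np.asarray(x_j) - np.asarray(mu))))


@dataclass
class _EdgeBlock:
    """Edges sharing a presynaptic population, with one-hot maps.

    ``gather`` (n_pre, K) pulls presynaptic values onto edges;
    ``scatter`` (K, H) sums edge currents onto target neurons and
    ``scatter_e`` folds the polarity E into the same sum.
    """

    raw_w: Tensor  # (K,)
    gamma: Tensor  # (K,)
    mu: Tensor  # (K,)
    E: np.ndarray  # (K,)
    src: np.ndarray  # (K,) indices into the presynaptic population
    tgt: np.ndarray  # (K,) indices into the hidden neurons
    gather: np.ndarray = field(repr=False)
    scatter: np.ndarray = field(repr=False)
    scatter_e: np.ndarray = field(repr=False)

    @property
    def n_edges(self) -> int:
        return len(self.src)

    @classmethod
    def build(cls, src, tgt, w, gamma, mu, E, n_pre: int, n_hidden: int, dtype) -> "_EdgeBlock":
        src = np.asarray(src, dtype=int)
        tgt = np.asarray(tgt, dtype=int)
        k = len(src)
        gather = np.zeros((n_pre, k), dtype=dtype)
        scatter = np.zeros((k, n_hidden), dtype=dtype)
        gather[src, np.arange(k)] = 1.0
        scatter[np.arange(k), tgt] = 1.0
        e = np.asarray(E, dtype=dtype)
        return cls(
            raw_w=Tensor(_inv_softplus(np.clip(w, 1e-12, None)).astype(dtype), requires_grad=True),
            gamma=Tensor(np.asarray(gamma, dtype=dtype), requires_grad=True),
            mu=Tensor(np.asarray(mu, dtype=dtype), requires_grad=True),
            E=e,
            src=src,
            tgt=tgt,
            gather=gather,
            scatter=scatter,
            scatter_e=scatter * e[:, None],
        )

    def currents(self, pre) -> tuple:
        """(excitation, conductance): sum_j w sigma E and sum_j w sigma, (B, H).

        ``pre`` is the presynaptic population (B, n_pre), Tensor or ndarray.
        """
        if self.n_edges == 0:
            z = np.zeros((pre.shape[0], self.scatter.shape[1]), dtype=self.gather.dtype)
            return (Tensor(z), Tensor(z)) if isinstance(pre, Tensor) else (z, z)
        if isinstance(pre, Tensor):
            vals = pre @ Tensor(self.gather)  # (B, K)
            act = ad.softplus(self.raw_w) * ad.sigmoid(self.gamma * (vals - self.mu))
            return act @ Tensor(self.scatter_e), act @ Tensor(self.scatter)
        vals = pre @ self.gather
        w = np.log1p(np.exp(-np.abs(self.raw_w.data))) + np.maximum(self.raw_w.data, 0)
        act = w * synapse_sigmoid(vals, self.gamma.data, self.mu.data)
        return act @ self.scatter_e, act @ self.scatter

    def weights(self) -> np.ndarray:
        """Current non-negative synaptic weights, one per edge."""
        r = self.raw_w.data
        return np.log1p(np.exp(-np.abs(r))) + np.maximum(r, 0)


@dataclass
class LTCParameters:
    """Every trainable quantity of the LTC dynamics.

    Per-neuron: membrane capacitance Cm, leakage conductance gl and resting
    potential x_leak (Cm and gl behind softplus). Per-synapse: weight w
    (softplus), sigmoid steepness gamma and midpoint mu, frozen polarity E.
    Synapses are split into a sensory block (driven by the input frame) and
    a state block (driven by the hidden neurons themselves).
    """

    raw_cm: Tensor  # (H,)
    raw_gl: Tensor  # (H,)
    x_leak: Tensor  # (H,)
    sensory: _EdgeBlock
    state: _EdgeBlock
    delta: float = 1.0
    n_unfold: int = 6
    n_sensory: int = 0

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.n_unfold < 1:
            raise ValueError("n_unfold must be >= 1")

    @property
    def cm(self) -> Tensor:
        return ad.softplus(self.raw_cm)

    @property
    def gl(self) -> Tensor:
        return ad.softplus(self.raw_gl)

    @property
    def tau(self) -> np.ndarray:
        """Derived time constants Cm/gl (never stored independently)."""
        return self.cm.data / self.gl.data

    @property
    def n_hidden(self) -> int:
        return self.raw_cm.data.shape[0]

    def parameters(self) -> list[Tensor]:
        out = [self.raw_cm, self.raw_gl, self.x_leak]
        for blk in (self.sensory, self.state):
            if blk.n_edges:
                out += [blk.raw_w, blk.gamma, blk.mu]
        return out

    # constructors -------------------------------------------------------------

    @classmethod
    def init(
        cls,
        wiring: WiringGraph,
        seed: int = 0,
        delta: float = 1.0,
        n_unfold: int = 6,
        dtype=np.float64,
    ) -> "LTCParameters":
        """Seeded initialization: Cm, gl, w log-uniform in [0.4, 0.6];
        gamma uniform in [2, 6]; mu uniform in [-0.2, 0.5]; x_leak zero.

        The sigmoid midpoints straddle the resting state so a useful fraction
        of synapses is active (and carries gradient) from the first step;
        states here are bounded in [-1, 1] by the update's averaging form.
        """
        rng = np.random.default_rng(seed)
        ns = wiring.config.n_sensory
        h = wiring.n_hidden
        edges = sorted(wiring.edges.items())

        def block(items, n_pre, offset):
            if items:
                src = [s - offset for (s, _t), _ in items]
                tgt = [t - ns for (_s, t), _ in items]
                e = [pol for _, (pol, _m) in items]
            else:
                src, tgt, e = [], [], []
            k = len(src)
            return _EdgeBlock.build(
                src, tgt,
                w=np.exp(rng.uniform(np.log(0.4), np.log(0.6), size=k)),
                gamma=rng.uniform(2.0, 6.0, size=k),
                mu=rng.uniform(-0.2, 0.5, size=k),
                E=e, n_pre=n_pre, n_hidden=h, dtype=dtype,
            )

        sens = block([it for it in edges if it[0][0] < ns], ns, 0)
        state = block([it for it in edges if it[0][0] >= ns], h, ns)

        def pos(size):
            return np.exp(rng.uniform(np.log(0.4), np.log(0.6), size=size))

        return cls(
            raw_cm=Tensor(_inv_softplus(pos(h)).astype(dtype), requires_grad=True),
            raw_gl=Tensor(_inv_softplus(pos(h)).astype(dtype), requires_grad=True),
            x_leak=Tensor(np.zeros(h, dtype=dtype), requires_grad=True),
            sensory=sens,
            state=state,
            delta=delta,
            n_unfold=n_unfold,
            n_sensory=ns,
        )

    @classmethod
    def from_values(
        cls,
        cm,
        gl,
        x_leak,
        w,
        gamma,
        mu,
        E,
        mask=None,
        delta: float = 1.0,
        n_unfold: int = 1,
        n_sensory: int = 0,
    ) -> "LTCParameters":
        """Build from explicit dense (n_pre, n_hidden) parameter matrices;
        synapses exist wherever ``mask`` (default: wherever w is non-zero) is
        non-zero. The first ``n_sensory`` presynaptic rows are sensory inputs,
        the rest are the hidden neurons themselves. Used for hand-constructed
        systems."""
        w = np.atleast_2d(np.asarray(w, dtype=float))
        gamma = np.broadcast_to(np.asarray(gamma, dtype=float), w.shape)
        mu = np.broadcast_to(np.asarray(mu, dtype=float), w.shape)
        e_mat = np.broadcast_to(np.asarray(E, dtype=float), w.shape)
        mask = (w != 0).astype(float) if mask is None else np.broadcast_to(np.asarray(mask, dtype=float), w.shape)
        h = w.shape[1]

        def block(rows, offset, n_pre):
            src, tgt = np.nonzero(mask[rows])
            return _EdgeBlock.build(
                src, tgt, w[rows][src, tgt], gamma[rows][src, tgt],
                mu[rows][src, tgt], e_mat[rows][src, tgt],
                n_pre=n_pre, n_hidden=h, dtype=np.float64,
            )

        return cls(
            raw_cm=Tensor(_inv_softplus(cm), requires_grad=True),
            raw_gl=Tensor(_inv_softplus(gl), requires_grad=True),
            x_leak=Tensor(np.asarray(x_leak, dtype=float), requires_grad=True),
            sensory=block(slice(0, n_sensory), 0, n_sensory),
            state=block(slice(n_sensory, w.shape[0]), n_sensory, w.shape[0] - n_sensory),
            delta=delta,
            n_unfold=n_unfold,
            n_sensory=n_sensory,
        )


def _as_tensor_2d(a) -> tuple[Tensor, bool, bool]:
    """Coerce (H,) or (B,H) array/Tensor to a 2-D Tensor; report conversions."""
    was_numpy = not isinstance(a, Tensor)
    t = Tensor(a) if was_numpy else a
    was_1d = t.data.ndim == 1
    if was_1d:
        t = t.reshape(1, -1)
    return t, was_numpy, was_1d


def _sensory_2d(inputs, params) -> Tensor | None:
    if params.n_sensory == 0 or inputs is None:
        return None
    t, _, _ = _as_tensor_2d(inputs)
    return t


def ltc_rhs(state, inputs, params: LTCParameters):
    """Continuous-time right-hand side dx/dt of the LTC dynamics."""
    x, was_numpy, was_1d = _as_tensor_2d(state)
    exc, cond = params.state.currents(x)
    i_t = _sensory_2d(inputs, params)
    if i_t is not None:
        exc_s, cond_s = params.sensory.currents(i_t)
        exc, cond = exc + exc_s, cond + cond_s
    cm, gl = params.cm, params.gl
    inv_tau = gl / cm
    out = -(inv_tau + cond / cm) * x + (params.x_leak * inv_tau + exc / cm)
    if was_1d:
        out = out.reshape(-1)
    return out.data if was_numpy else out


def semi_implicit_step(state, inputs, params: LTCParameters):
    """One semi-implicit Euler step of size ``params.delta``.

    Synapse activations are evaluated at the current state/input, and the
    update is the stable ratio form; the denominator is strictly positive
    because Cm, gl and w are positive by construction.
    """
    x, was_numpy, was_1d = _as_tensor_2d(state)
    exc, cond = params.state.currents(x)
    i_t = _sensory_2d(inputs, params)
    if i_t is not None:
        exc_s, cond_s = params.sensory.currents(i_t)
        exc, cond = exc + exc_s, cond + cond_s
    out = _ratio_update(x, exc, cond, params)
    if was_1d:
        out = out.reshape(-1)
    return out.data if was_numpy else out


def _ratio_update(x: Tensor, exc, cond, params: LTCParameters) -> Tensor:
    cm_over_d = params.cm * (1.0 / params.delta)
    gl = params.gl
    num = x * cm_over_d + gl * params.x_leak + exc
    den = cm_over_d + gl + cond
    return num / den


class LTCCell:
    """Wiring-masked LTC cell advancing one input frame per call.

    Each frame applies ``n_unfold`` semi-implicit sub-steps; the sensory
    synapse activations depend only on the (frame-constant) input, so their
    currents are computed once per frame.
    """

    def __init__(
        self,
        wiring: WiringGraph,
        seed: int = 0,
        delta: float = 1.0,
        n_unfold: int = 6,
        dtype=np.float64,
    ):
        self.wiring = wiring
        self.params = LTCParameters.init(
            wiring, seed=seed, delta=delta, n_unfold=n_unfold, dtype=dtype
        )
        self.n_motor = wiring.config.n_motor
        self.n_hidden = wiring.n_hidden
        self.dtype = dtype

    def parameters(self) -> list[Tensor]:
        return self.params.parameters()

    def frame_step(self, x: Tensor, inputs: Tensor, frame_index: int = 0) -> Tensor:
        p = self.params
        exc_s, cond_s = p.sensory.currents(inputs)
        for _ in range(p.n_unfold):
            exc_x, cond_x = p.state.currents(x)
            x = _ratio_update(x, exc_s + exc_x, cond_s + cond_x, p)
        return x


@dataclass
class CfCParameters:
    """Three wiring-masked affine subnetworks f (positive), g and h (tanh)."""

    Wf: Tensor
    bf: Tensor
    Wg: Tensor
    bg: Tensor
    Wh: Tensor
    bh: Tensor
    mask: np.ndarray  # (S+H, H)
    delta: float = 1.0
    n_sensory: int = 0

    def parameters(self) -> list[Tensor]:
        return [self.Wf, self.bf, self.Wg, self.bg, self.Wh, self.bh]

    @classmethod
    def init(cls, wiring: WiringGraph, seed: int = 0, delta: float = 1.0, dtype=np.float64) -> "CfCParameters":
        rng = np.random.default_rng(seed)
        mask, _pol = wiring.source_target_masks()
        n_src, n_tgt = mask.shape
        scale = 1.0 / np.sqrt(max(1.0, mask.sum(axis=0).mean()))

        def w():
            return Tensor(
                (rng.normal(0.0, scale, size=(n_src, n_tgt)) * mask).astype(dtype),
                requires_grad=True,
            )

        def b():
            return Tensor(np.zeros(n_tgt, dtype=dtype), requires_grad=True)

        return cls(Wf=w(), bf=b(), Wg=w(), bg=b(), Wh=w(), bh=b(),
                   mask=mask.astype(dtype), delta=delta, n_sensory=wiring.config.n_sensory)


def cfc_blend(f, g, h, t: float):
    """Closed-form gate blend X = sigma(-f t) * g + (1 - sigma(-f t)) * h."""
    numpy_in = not any(isinstance(a, Tensor) for a in (f, g, h))
    f = f if isinstance(f, Tensor) else Tensor(np.asarray(f, dtype=float))
    g = g if isinstance(g, Tensor) else Tensor(np.asarray(g, dtype=float))
    h = h if isinstance(h, Tensor) else Tensor(np.asarray(h, dtype=float))
    gate = ad.sigmoid(-(f * float(t)))
    out = gate * g + (1.0 - gate) * h
    return out.data if numpy_in else out


def cfc_step(state, inputs, t: float, params: CfCParameters):
    """One CfC update at elapsed time ``t``: evaluate the f, g, h compartments
    on (state, input) and blend them with the time-continuous gate."""
    if t < 0:
        raise ValueError("elapsed time t must be non-negative")
    x, was_numpy, was_1d = _as_tensor_2d(state)
    i_t = _sensory_2d(inputs, params)
    pre = ad.concat([i_t, x], axis=1) if i_t is not None else x
    m = Tensor(params.mask)
    f = ad.softplus(pre @ (params.Wf * m) + params.bf)
    g = ad.tanh(pre @ (params.Wg * m) + params.bg)
    h = ad.tanh(pre @ (params.Wh * m) + params.bh)
    out = cfc_blend(f, g, h, t)
    if was_1d:
        out = out.reshape(-1)
    return out.data if was_numpy else out


class CfCCell:
    """Wiring-masked CfC cell; the gate time input is frame_index * delta."""

    def __init__(self, wiring: WiringGraph, seed: int = 0, delta: float = 1.0, dtype=np.float64):
        self.wiring = wiring
        self.params = CfCParameters.init(wiring, seed=seed, delta=delta, dtype=dtype)
        self.n_motor = wiring.config.n_motor
        self.n_hidden = wiring.n_hidden
        self.dtype = dtype

    def parameters(self) -> list[Tensor]:
        return self.params.parameters()

    def frame_step(self, x: Tensor, inputs: Tensor, frame_index: int = 0) -> Tensor:
        return cfc_step(x, inputs, frame_index * self.params.delta, self.params)


def unroll(cell, frame_sequence, return_trajectory: bool = True):
    """Run a cell over a sensory frame sequence from the zero resting state.

    Parameters
    ----------
    cell : LTCCell or CfCCell
    frame_sequence : array or Tensor, shape (B, T, n_sensory) or (T, n_sensory)

    Returns
    -------
    (motor_trajectory, final_state) where motor_trajectory has shape
    (B, T, n_motor) (list of per-frame Tensors when differentiable) and
    final_state is the full hidden state after the last frame.
    """
    frames = frame_sequence
    was_numpy = not isinstance(frames, Tensor)
    if was_numpy:
        frames = Tensor(np.asarray(frames, dtype=float))
    squeeze = frames.data.ndim == 2
    if squeeze:
        frames = frames.reshape(1, *frames.shape)
    b, n_frames, _ = frames.shape
    if n_frames == 0:
        raise ValueError("frame sequence must be non-empty")
    x = Tensor(np.zeros((b, cell.n_hidden), dtype=cell.dtype))
    motor = []
    for k in range(n_frames):
        x = cell.frame_step(x, frames[:, k, :], frame_index=k)
        if return_trajectory:
            motor.append(x[:, cell.n_hidden - cell.n_motor :])
    if was_numpy:
        traj = (
            np.stack([m.data for m in motor], axis=1) if return_trajectory else None
        )
        final = x.data
        if squeeze:
            traj = None if traj is None else traj[0]
            final = final[0]
        return traj, final
    return motor, x
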