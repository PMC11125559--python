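"""Network models: continuous-time RNN and feedforward baselines.

The RNN follows the standard rate equation

    tau dx/dt = -x + J r + B u + b + eta,    r = tanh(x)

integrated by Euler's method with step dt = tau/10, with linear readouts
z = W r + readout_bias. Per-unit Gaussian noise eta (s.d. ``noise_sd``) is
drawn independently at every step and enters the right-hand side of the rate
equation (i.e. it is scaled by dt/tau in the state update, like every other
term).

Trainability variants: ``f-RNN`` (all parameters trainable), ``r-RNN`` (only
the recurrent matrix J, plus biases and the initial state), ``ff-RNN`` (only
the feedforward matrices B and W, plus biases and the initial state), and
``r-RNN+W`` (r-RNN with the readout weights also trainable).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

VARIANTS = ("f-RNN", "r-RNN", "ff-RNN", "r-RNN+W")


class SimulationDivergedError(FloatingPointError):
    """Raised when the network state becomes non-finite."""

    def __init__(self, step: int):
        super().__init__(f"non-finite network state at step {step}")
        self.step = step


@dataclass(frozen=True)
class ConstraintRegime:
    """Initial-connectivity and regularization hyperparameters."""

    name: str
    h0: float  # input gain: B ~ N(0, h0^2 / N_in)
    g0: float  # recurrent gain: J ~ N(0, g0^2 / N)
    alpha: float  # L2 penalty on B and W
    beta: float  # metabolic penalty on rates


REGIMES: dict[str, ConstraintRegime] = {
    "highest": ConstraintRegime("highest", 1.0, 0.5, 1.0, 1.0),
    "high": ConstraintRegime("high", 1.0, 0.5, 0.01, 0.01),
    "intermediate": ConstraintRegime("intermediate", 1.0, 1.0, 0.01, 0.01),
    "low": ConstraintRegime("low", 1.0, 2.0, 0.0, 0.0),
    "lowest": ConstraintRegime("lowest", 1.5, 4.0, 0.0, 0.0),
}


def _trainability(variant: str) -> dict[str, bool]:
    if variant == "f-RNN":
        w = dict(J=True, B=True, W=True)
    elif variant == "r-RNN":
        w = dict(J=True, B=False, W=False)
    elif variant == "ff-RNN":
        w = dict(J=False, B=True, W=True)
    elif variant == "r-RNN+W":
        w = dict(J=True, B=False, W=True)
    else:
        raise KeyError(f"unknown variant {variant!r}; known: {VARIANTS}")
    # biases and the initial state are trainable in every variant
    w.update(bias=True, readout_bias=True, x0=True)
    return w


@dataclass
class NetworkParams:
    """All parameter blocks of one RNN instance plus its trainability mask."""

    J: np.ndarray  # (N, N) recurrent weights
    B: np.ndarray  # (N, N_in) input weights
    W: np.ndarray  # (N_out, N) readout weights
    bias: np.ndarray  # (N,) unit biases
    readout_bias: np.ndarray  # (N_out,)
    x0: np.ndarray  # (N,) initial state
    variant: str = "f-RNN"
    regime: str = "highest"
    tau: float = 1.0
    dt: float = 0.1
    seed: int | None = None

    @property
    def n(self) -> int:
        return self.J.shape[0]

    @property
    def n_in(self) -> int:
        return self.B.shape[1]

    @property
    def n_out(self) -> int:
        return self.W.shape[0]

    @property
    def trainable(self) -> dict[str, bool]:
        return _trainability(self.variant)

    def blocks(self) -> dict[str, np.ndarray]:
        return dict(
            J=self.J, B=self.B, W=self.W, bias=self.bias,
            readout_bias=self.readout_bias, x0=self.x0,
        )

    def copy(self) -> "NetworkParams":
        return replace(
            self, **{k: v.copy() for k, v in self.blocks().items()}
        )


def init_network(
    variant: str = "f-RNN",
    regime: str | ConstraintRegime = "highest",
    n: int = 100,
    n_in: int = 100,
    n_out: int = 3,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> NetworkParams:
    """Initialize a network: J ~ N(0, g0^2/N), B ~ N(0, h0^2/N_in),
    W, biases and x0 all zero."""
    reg = REGIMES[regime] if isinstance(regime, str) else regime
    mask = _trainability(variant)
    if rng is None:
        rng = np.random.default_rng(seed)
    J = rng.normal(0.0, reg.g0 / np.sqrt(n), (n, n))
    B = rng.normal(0.0, reg.h0 / np.sqrt(n_in), (n, n_in))
    if mask["W"]:
        W = np.zeros((n_out, n))
    else:
        # frozen readouts keep random initial values: a zero-initialized
        # frozen W could never produce a response
        W = rng.normal(0.0, 1.0 / np.sqrt(n), (n_out, n))
    return NetworkParams(
        J=J,
        B=B,
        W=W,
        bias=np.zeros(n),
        readout_bias=np.zeros(n_out),
        x0=np.zeros(n),
        variant=variant,
        regime=reg.name,
        seed=seed,
    )


def simulate(
    params: NetworkParams,
    u: np.ndarray,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Euler-integrate the RNN for an arbitrary input tensor.

    Parameters
    ----------
    u : (n_steps, N_in) or (M, n_steps, N_in) input time series.

    Returns
    -------
    x : (M, n_steps, N) unit activations (pre-nonlinearity), x[:, 0] = x0.
    z : (M, n_steps, N_out) readout time series.
    """
    squeeze = u.ndim == 2
    if squeeze:
        u = u[None]
    m, n_steps, _ = u.shape
    drive_in = u @ params.B.T  # (M, T, N)
    xs = _integrate(params, drive_in, noise_sd, rng)
    zs = np.tanh(xs) @ params.W.T + params.readout_bias
    if squeeze:
        return xs[0], zs[0]
    return xs, zs


def simulate_pulsed(
    params: NetworkParams,
    pulse_drives: dict[int, np.ndarray],
    n_steps: int,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    return_rates: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Fast path for pulse-structured input.

    ``pulse_drives`` maps timestep -> (M, N) precomputed input drive B @ u;
    all other steps have zero input. Semantics identical to :func:`simulate`.
    """
    m = next(iter(pulse_drives.values())).shape[0]
    n = params.n
    drive_in = np.zeros((m, n_steps, n))
    for t, d in pulse_drives.items():
        drive_in[:, t, :] = d
    xs = _integrate(params, drive_in, noise_sd, rng)
    rs = np.tanh(xs)
    zs = rs @ params.W.T + params.readout_bias
    if return_rates:
        return xs, zs, rs
    return xs, zs


def _integrate(
    params: NetworkParams,
    drive_in: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator | None,
) -> np.ndarray:
    m, n_steps, n = drive_in.shape
    a = params.dt / params.tau
    if noise_sd > 0 and rng is None:
        rng = np.random.default_rng()
    xs = np.empty((m, n_steps, n))
    x = np.broadcast_to(params.x0, (m, n)).copy()
    Jt = params.J.T
    for t in range(n_steps):
        xs[:, t, :] = x
        if t == n_steps - 1:
            break
        drive = np.tanh(x) @ Jt + params.bias + drive_in[:, t, :]
        if noise_sd > 0:
            drive += rng.normal(0.0, noise_sd, (m, n))
        x = x + a * (-x + drive)
        if not np.all(np.isfinite(x)):
            raise SimulationDivergedError(t + 1)
    return xs


# ---------------------------------------------------------------------------
# Feedforward baselines
# ---------------------------------------------------------------------------

@dataclass
class FeedforwardParams:
    """LR (no hidden layer) or single-hidden-layer MLP over the 2*N_in
    concatenated two-item input. ``W_in is None`` marks an LR."""

    W_out: np.ndarray  # (2, n_hidden or 2*N_in)
    b_out: np.ndarray  # (2,)
    W_in: np.ndarray | None = None  # (N, 2*N_in) for MLP
    b_in: np.ndarray | None = None  # (N,)
    seed: int | None = None

    @property
    def kind(self) -> str:
        return "LR" if self.W_in is None else "MLP"

    @property
    def n_in(self) -> int:
        return (self.W_in if self.W_in is not None else self.W_out).shape[1]

    def blocks(self) -> dict[str, np.ndarray]:
        out = dict(W_out=self.W_out, b_out=self.b_out)
        if self.W_in is not None:
            out.update(W_in=self.W_in, b_in=self.b_in)
        return out


def init_lr(n_in: int = 200, seed: int | None = 0) -> FeedforwardParams:
    return FeedforwardParams(
        W_out=np.zeros((2, n_in)), b_out=np.zeros(2), seed=seed
    )


def init_mlp(
    n_in: int = 200, n_hidden: int = 100, h0: float = 1.0, seed: int | None = 0
) -> FeedforwardParams:
    rng = np.random.default_rng(seed)
    return FeedforwardParams(
        W_out=np.zeros((2, n_hidden)),
        b_out=np.zeros(2),
        W_in=rng.normal(0.0, h0 / np.sqrt(n_in), (n_hidden, n_in)),
        b_in=np.zeros(n_hidden),
        seed=seed,
    )


def simulate_feedforward(
    params: FeedforwardParams,
    u: np.ndarray,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Output pair z for input(s) ``u`` of length 2*N_in.

    LR: noise is added to the two readouts. MLP: noise is added to the hidden
    units (pre-nonlinearity) before the tanh.
    """
    squeeze = u.ndim == 1
    if squeeze:
        u = u[None]
    if u.shape[1] != params.n_in:
        raise ValueError(f"input width {u.shape[1]} != expected {params.n_in}")
    if noise_sd > 0 and rng is None:
        rng = np.random.default_rng()
    if params.kind == "LR":
        z = u @ params.W_out.T + params.b_out
        if noise_sd > 0:
            z = z + rng.normal(0.0, noise_sd, z.shape)
    else:
        h = u @ params.W_in.T + params.b_in
        if noise_sd > 0:
            h = h + rng.normal(0.0, noise_sd, h.shape)
        z = np.tanh(h) @ params.W_out.T + params.b_out
    return z[0] if squeeze else z


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, params: NetworkParams, metadata: dict | None = None):
    """Write all parameter blocks plus variant/regime/seed to one npz file."""
    meta = dict(
        variant=params.variant,
        regime=params.regime,
        tau=params.tau,
        dt=params.dt,
        seed=params.seed,
        **(metadata or {}),
    )
    np.savez(
        path,
        _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **params.blocks(),
    )


def load_checkpoint(path) -> tuple[NetworkParams, dict]:
    with np.load(path) as f:
        meta = json.loads(bytes(f["_meta"]).decode())
        params = NetworkParams(
            J=f["J"],
            B=f["B"],
            W=f["W"],
            bias=f["bias"],
            readout_bias=f["readout_bias"],
            x0=f["x0"],
            variant=meta.pop("variant"),
            regime=meta.pop("regime"),
            tau=meta.pop("tau"),
            dt=meta.pop("dt"),
            seed=meta.pop("seed"),
        )
    return params, meta
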