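"""Optimization of RNN and feedforward models on the TI task.

The RNN loss is E = E_task + alpha * R_L2 + beta * R_FR with

- E_task : squared output error averaged over trials, time and output units,
- R_L2   : L2 penalty on the input and output weight matrices, normalized
  per element (mean of squares). A raw-sum penalty at alpha = 1 contributes
  ~100 at initialization (vs E_task ~8) and empirically drives the input
  weights to zero before the task can be learned, so the averaged form is
  the only one that produces working networks at the stated alpha values.
- R_FR   : metabolic penalty on rates, (1/(M T N)) sum_{m,t,i} r^2 dt with
  T the trial duration in time units — i.e. the time-averaged mean-square
  rate, mean(r^2). (Reading T as a step count instead would scale the
  penalty by dt and make it too weak to prevent rate saturation.)

Gradients are computed by backpropagation through time (implemented here
directly in NumPy) and applied with Adam, respecting each variant's
trainability mask. Batches of 128 trials are sampled uniformly from the
training (adjacent-pair) trial types only; training stops when the
noise-free network responds correctly on every trial type, when E_task
falls below 0.1, or at the epoch cap.

Feedforward baselines (LR / MLP) are trained with Adam on cross-entropy
plus weight decay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import models
from .behavior import decide_batch
from .task import TrialTiming, batch_targets, enumerate_trial_types


class TrainingDivergedError(RuntimeError):
    def __init__(self, epoch: int):
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


@dataclass
class LossBreakdown:
    e_task: float
    r_l2: float
    r_fr: float
    total: float
    batch_size: int
    trial_length: int


@dataclass
class TrainingConfig:
    """Optimizer and stopping-rule settings (values the source method leaves
    open are exposed here, not claimed)."""

    learning_rate: float = 2e-3
    batch_size: int = 128
    max_epochs: int = 30_000
    eval_every: int = 25
    task_loss_stop: float = 0.1
    noise_sd: float = 0.2
    #: divisor applied to the raw-sum L2 penalty on B and W (None =
    #: per-element mean, i.e. each matrix divided by its own size)
    l2_scale: float | None = None
    delay_variant: str = "basic"
    dt: float = 0.1
    n_items: int = 7
    seed: int = 0
    adam_betas: tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-8


@dataclass
class TrainingReport:
    epochs: int
    stop_reason: str  # all-correct | task-loss | epoch-cap
    loss_trace: list[dict]
    generalization: dict
    seed: int
    final_loss: LossBreakdown | None = None


def compute_loss(
    z: np.ndarray,
    targets: np.ndarray,
    params: models.NetworkParams,
    regime: models.ConstraintRegime | str,
    rates: np.ndarray | None = None,
) -> LossBreakdown:
    """Loss decomposition for a batch of output/target tensors (M, T, N_out).

    ``rates`` (M, T, N) are needed for R_FR; omitted -> R_FR = 0 reported.
    """
    reg = models.REGIMES[regime] if isinstance(regime, str) else regime
    if z.shape != targets.shape:
        raise ValueError(f"shape mismatch {z.shape} vs {targets.shape}")
    m, t, _ = z.shape
    e_task = float(np.mean((z - targets) ** 2))
    r_l2 = float((params.B ** 2).mean() + (params.W ** 2).mean())
    r_fr = float((rates ** 2).mean()) if rates is not None else 0.0
    total = e_task + reg.alpha * r_l2 + reg.beta * r_fr
    return LossBreakdown(e_task, r_l2, r_fr, total, m, t)


# ---------------------------------------------------------------------------
# BPTT internals (float32 for speed; parameters round-trip through float64)
# ---------------------------------------------------------------------------

def _forward(p, bu1, bu2, t_steps, p1, p2, a, noise_sd, rng):
    m = bu1.shape[0]
    n = p["J"].shape[0]
    dtype = p["J"].dtype
    rs = np.empty((t_steps, m, n), dtype=dtype)
    x = np.broadcast_to(p["x0"], (m, n)).astype(dtype).copy()
    jt = p["J"].T
    for t in range(t_steps):
        r = np.tanh(x)
        rs[t] = r
        drive = r @ jt + p["bias"]
        if t == p1:
            drive = drive + bu1
        elif t == p2:
            drive = drive + bu2
        if noise_sd > 0:
            drive = drive + rng.normal(0, noise_sd, (m, n)).astype(dtype)
        x = x + a * (drive - x)
    zs = rs @ p["W"].T + p["readout_bias"]
    return rs, zs


def _backward(p, rs, zs, targets, u1, u2, p1, p2, a, alpha_b, alpha_w, beta):
    t_steps, m, n = rs.shape
    n_out = zs.shape[2]
    dz = (2.0 / (m * t_steps * n_out)) * (zs - targets)
    g = {
        "W": np.einsum("tmo,tmn->on", dz, rs) + 2 * alpha_w * p["W"],
        "readout_bias": dz.sum(axis=(0, 1)),
        "J": np.zeros_like(p["J"]),
        "B": 2 * alpha_b * p["B"],
        "bias": np.zeros_like(p["bias"]),
    }
    fr = 2.0 * beta / rs.size  # d/dr of beta * mean(r^2)
    dx = np.zeros((m, n), dtype=rs.dtype)
    for t in range(t_steps - 1, -1, -1):
        # dx holds dL/dx_{t+1}; the step t update produced x_{t+1}
        g["J"] += a * dx.T @ rs[t]
        g["bias"] += a * dx.sum(axis=0)
        if t == p1:
            g["B"] += a * dx.T @ u1
        elif t == p2:
            g["B"] += a * dx.T @ u2
        dr = dz[t] @ p["W"] + fr * rs[t] + a * (dx @ p["J"])
        dx = dr * (1.0 - rs[t] ** 2) + (1.0 - a) * dx
    g["x0"] = dx.sum(axis=0)
    return g


def train_rnn(
    params: models.NetworkParams,
    panel: np.ndarray,
    config: TrainingConfig | None = None,
) -> TrainingReport:
    """Train an RNN in place; returns the training report.

    Only adjacent-pair (training) trial types are ever sampled into batches.
    The all-type correctness check runs noise-free every ``eval_every``
    epochs. Frozen blocks (per the variant's mask) are never updated.
    """
    cfg = config or TrainingConfig()
    reg = models.REGIMES[params.regime]
    rng = np.random.default_rng(cfg.seed)
    timing = _timing_for(cfg.delay_variant, cfg.dt)

    types = enumerate_trial_types(cfg.n_items)
    train_types = [t for t in types if t.is_training]
    ti1 = np.array([t.rank1 - 1 for t in train_types])
    ti2 = np.array([t.rank2 - 1 for t in train_types])
    tcc = np.array([t.correct_choice for t in train_types])

    p = {k: v.astype(np.float32) for k, v in params.blocks().items()}
    panel32 = panel.astype(np.float32)
    mask = params.trainable
    a = np.float32(params.dt / params.tau)

    mom = {k: np.zeros_like(v) for k, v in p.items()}
    vel = {k: np.zeros_like(v) for k, v in p.items()}
    b1, b2 = cfg.adam_betas
    eps = cfg.adam_eps
    if cfg.l2_scale is None:
        alpha_b = reg.alpha / p["B"].size
        alpha_w = reg.alpha / p["W"].size
    else:
        alpha_b = reg.alpha / cfg.l2_scale
        alpha_w = reg.alpha / cfg.l2_scale

    trace: list[dict] = []
    stop_reason = "epoch-cap"
    epochs_run = cfg.max_epochs
    variable = cfg.delay_variant == "variable"
    last_loss: LossBreakdown | None = None

    for epoch in range(1, cfg.max_epochs + 1):
        if variable:
            batch_timing = TrialTiming.variable(rng, cfg.dt)
        else:
            batch_timing = timing
        t_steps = batch_timing.n_steps
        p1, p2 = batch_timing.pulse1_index, batch_timing.pulse2_index

        sel = rng.integers(0, len(train_types), cfg.batch_size)
        u1, u2 = panel32[ti1[sel]], panel32[ti2[sel]]
        bu = panel32 @ p["B"].T
        rs, zs = _forward(
            p, bu[ti1[sel]], bu[ti2[sel]], t_steps, p1, p2, a,
            cfg.noise_sd, rng,
        )
        targets = batch_targets(batch_timing, tcc[sel]).transpose(1, 0, 2)
        targets = targets.astype(np.float32)
        e_task = float(np.mean((zs - targets) ** 2))
        if not np.isfinite(e_task):
            raise TrainingDivergedError(epoch)

        g = _backward(
            p, rs, zs, targets, u1, u2, p1, p2, a, alpha_b, alpha_w,
            reg.beta,
        )
        for k in p:
            if not mask[k]:
                continue
            mom[k] = b1 * mom[k] + (1 - b1) * g[k]
            vel[k] = b2 * vel[k] + (1 - b2) * g[k] ** 2
            p[k] -= cfg.learning_rate * (
                (mom[k] / (1 - b1 ** epoch))
                / (np.sqrt(vel[k] / (1 - b2 ** epoch)) + eps)
            )

        if epoch % cfg.eval_every == 0 or e_task < cfg.task_loss_stop:
            r_l2 = float((p["B"] ** 2).mean() + (p["W"] ** 2).mean())
            r_fr = float((rs ** 2).mean())
            last_loss = LossBreakdown(
                e_task, r_l2, r_fr,
                e_task + reg.alpha * r_l2 + reg.beta * r_fr,
                cfg.batch_size, t_steps,
            )
            trace.append(dict(epoch=epoch, **last_loss.__dict__))

        if e_task < cfg.task_loss_stop:
            stop_reason, epochs_run = "task-loss", epoch
            break

        if epoch % cfg.eval_every == 0:
            if _all_correct_f32(p, panel32, timing, types, a) and (
                not variable
                or _all_correct_f32(
                    p, panel32, _advanced_timing(timing), types, a
                )
            ):
                stop_reason, epochs_run = "all-correct", epoch
                break

    for k, v in params.blocks().items():
        if mask[k]:  # frozen blocks keep their exact original values
            v[...] = p[k].astype(v.dtype)

    gen = evaluate_generalization(params, panel, timing, cfg.n_items)
    return TrainingReport(
        epochs=epochs_run,
        stop_reason=stop_reason,
        loss_trace=trace,
        generalization=gen,
        seed=cfg.seed,
        final_loss=last_loss,
    )


def _timing_for(variant: str, dt: float) -> TrialTiming:
    if variant == "basic":
        return TrialTiming.basic(dt)
    if variant in ("extended", "variable"):
        t = TrialTiming.extended(dt)
        return t if variant == "extended" else TrialTiming(
            dt=dt, rest=0.5, delay=6.0, choice=6.0, variant="variable",
            realized_delay_steps=round(6.0 / dt),
        )
    raise KeyError(variant)


def _advanced_timing(timing: TrialTiming) -> TrialTiming:
    """Item 2 advanced by 67% of the longest delay (variable-delay check)."""
    full = round(6.0 / timing.dt)
    steps = full - round(0.67 * full)
    return TrialTiming(
        dt=timing.dt, rest=0.5, delay=6.0, choice=6.0, variant="variable",
        realized_delay_steps=steps,
    )


def _all_correct_f32(p, panel32, timing, types, a) -> bool:
    i1 = np.array([t.rank1 - 1 for t in types])
    i2 = np.array([t.rank2 - 1 for t in types])
    cc = np.array([t.correct_choice for t in types])
    bu = panel32 @ p["B"].T
    _, zs = _forward(
        p, bu[i1], bu[i2], timing.n_steps,
        timing.pulse1_index, timing.pulse2_index, a, 0.0, None,
    )
    choice, _, responded = decide_batch(
        np.asarray(zs, dtype=float).transpose(1, 0, 2), timing
    )
    return bool(responded.all() and (choice == cc).all())


def evaluate_generalization(
    params: models.NetworkParams,
    panel: np.ndarray,
    timing: TrialTiming | None = None,
    n_items: int = 7,
) -> dict:
    """Noise-free correctness on every trial type.

    Returns per-type correctness, counts, and phenotype flags:
    ``full_generalizer`` (all types correct) and ``memorizer`` (all training
    types correct but at least one test type wrong). No-response counts as
    incorrect.
    """
    timing = timing or TrialTiming.basic()
    types = enumerate_trial_types(n_items)
    i1 = np.array([t.rank1 - 1 for t in types])
    i2 = np.array([t.rank2 - 1 for t in types])
    cc = np.array([t.correct_choice for t in types])
    bu = panel @ params.B.T
    _, zs = models.simulate_pulsed(
        params,
        {timing.pulse1_index: bu[i1], timing.pulse2_index: bu[i2]},
        timing.n_steps,
    )
    choice, rt, responded = decide_batch(zs, timing)
    correct = responded & (choice == cc)
    training_mask = np.array([t.is_training for t in types])
    return dict(
        per_type=[
            dict(
                rank1=t.rank1, rank2=t.rank2, is_training=t.is_training,
                responded=bool(responded[k]), correct=bool(correct[k]),
                rt=float(rt[k]) if responded[k] else None,
            )
            for k, t in enumerate(types)
        ],
        n_correct=int(correct.sum()),
        n_responded=int(responded.sum()),
        n_types=len(types),
        n_training_correct=int(correct[training_mask].sum()),
        n_training=int(training_mask.sum()),
        full_generalizer=bool(correct.all()),
        memorizer=bool(
            correct[training_mask].all() and not correct.all()
        ),
    )


# ---------------------------------------------------------------------------
# Feedforward training
# ---------------------------------------------------------------------------

@dataclass
class FeedforwardConfig:
    learning_rate: float = 1e-2
    batch_size: int = 128
    max_epochs: int = 30_000
    patience: int = 1_000  # LR: stop when loss stops improving this long
    eval_every: int = 25
    weight_decay: float | None = None  # default 0.1 for LR, 0.001 for MLP
    n_items: int = 7
    seed: int = 0


def _softmax_xent(z: np.ndarray, labels: np.ndarray):
    zs = z - z.max(axis=1, keepdims=True)
    ez = np.exp(zs)
    probs = ez / ez.sum(axis=1, keepdims=True)
    nll = -np.log(probs[np.arange(len(labels)), labels] + 1e-300)
    grad = probs
    grad[np.arange(len(labels)), labels] -= 1.0
    return float(nll.mean()), grad / len(labels)


def train_feedforward(
    params: models.FeedforwardParams,
    panel: np.ndarray,
    config: FeedforwardConfig | None = None,
) -> TrainingReport:
    """Adam + cross-entropy training of an LR or MLP on traditional TI.

    LR trains to convergence (no loss improvement for ``patience`` epochs);
    MLP until noise-free correct on all trial types. Weight decay defaults:
    0.1 (LR), 0.001 (MLP).
    """
    cfg = config or FeedforwardConfig()
    wd = cfg.weight_decay
    if wd is None:
        wd = 0.1 if params.kind == "LR" else 0.001
    rng = np.random.default_rng(cfg.seed)

    types = enumerate_trial_types(cfg.n_items)
    train_types = [t for t in types if t.is_training]
    x_train = np.array(
        [np.concatenate([panel[t.rank1 - 1], panel[t.rank2 - 1]])
         for t in train_types]
    )
    y_train = np.array([t.correct_choice - 1 for t in train_types])

    p = params.blocks()
    mom = {k: np.zeros_like(v) for k, v in p.items()}
    vel = {k: np.zeros_like(v) for k, v in p.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8

    best = np.inf
    since_best = 0
    stop_reason = "epoch-cap"
    epochs_run = cfg.max_epochs
    trace: list[dict] = []

    for epoch in range(1, cfg.max_epochs + 1):
        sel = rng.integers(0, len(train_types), cfg.batch_size)
        xb, yb = x_train[sel], y_train[sel]
        if params.kind == "LR":
            z = xb @ p["W_out"].T + p["b_out"]
            loss, dz = _softmax_xent(z, yb)
            g = {"W_out": dz.T @ xb, "b_out": dz.sum(axis=0)}
        else:
            h = xb @ p["W_in"].T + p["b_in"]
            r = np.tanh(h)
            z = r @ p["W_out"].T + p["b_out"]
            loss, dz = _softmax_xent(z, yb)
            dr = dz @ p["W_out"]
            dh = dr * (1 - r ** 2)
            g = {
                "W_out": dz.T @ r,
                "b_out": dz.sum(axis=0),
                "W_in": dh.T @ xb,
                "b_in": dh.sum(axis=0),
            }
        for k in g:
            g[k] = g[k] + 2.0 * wd * p[k]
        loss_total = loss + wd * sum(float((v ** 2).sum()) for v in p.values())
        if not np.isfinite(loss_total):
            raise TrainingDivergedError(epoch)
        for k in p:
            mom[k] = b1 * mom[k] + (1 - b1) * g[k]
            vel[k] = b2 * vel[k] + (1 - b2) * g[k] ** 2
            p[k] -= cfg.learning_rate * (
                (mom[k] / (1 - b1 ** epoch))
                / (np.sqrt(vel[k] / (1 - b2 ** epoch)) + eps)
            )

        if epoch % cfg.eval_every == 0:
            trace.append(dict(epoch=epoch, loss=loss_total))

        if params.kind == "LR":
            if loss_total < best - 1e-12:
                best, since_best = loss_total, 0
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    stop_reason, epochs_run = "converged", epoch
                    break
        else:
            if epoch % cfg.eval_every == 0:
                gen = evaluate_feedforward_generalization(
                    params, panel, cfg.n_items
                )
                if gen["full_generalizer"]:
                    stop_reason, epochs_run = "all-correct", epoch
                    break

    gen = evaluate_feedforward_generalization(params, panel, cfg.n_items)
    return TrainingReport(
        epochs=epochs_run,
        stop_reason=stop_reason,
        loss_trace=trace,
        generalization=gen,
        seed=cfg.seed,
    )


def evaluate_feedforward_generalization(
    params: models.FeedforwardParams, panel: np.ndarray, n_items: int = 7
) -> dict:
    """Noise-free argmax correctness on all trial types."""
    types = enumerate_trial_types(n_items)
    x = np.array(
        [np.concatenate([panel[t.rank1 - 1], panel[t.rank2 - 1]])
         for t in types]
    )
    cc = np.array([t.correct_choice for t in types])
    z = models.simulate_feedforward(params, x)
    choice = z.argmax(axis=1) + 1
    correct = choice == cc
    training_mask = np.array([t.is_training for t in types])
    return dict(
        n_correct=int(correct.sum()),
        n_types=len(types),
        n_training_correct=int(correct[training_mask].sum()),
        full_generalizer=bool(correct.all()),
        memorizer=bool(correct[training_mask].all() and not correct.all()),
    )
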