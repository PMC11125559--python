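"""Population-level dynamical analysis.

PCA conventions, task-defined activity axes, least-squares inference of
linear dynamics over the delay period, fixed-point finding with analytic /
numerical linearization, identification of the delay-period comparison
oscillation, and the reduced oscillatory-mode simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from . import models
from .task import TrialTiming, enumerate_trial_types


class DegenerateAxisError(ValueError):
    """A requested activity axis has (numerically) zero norm."""


class DegenerateFitError(ValueError):
    """The linear-dynamics fit is degenerate (constant activity)."""


class LinearizationMismatchError(RuntimeError):
    """Analytic and numerical Jacobians disagree beyond tolerance."""


# ---------------------------------------------------------------------------
# PCA helpers
# ---------------------------------------------------------------------------

def pca_project(data: np.ndarray, n_pcs: int) -> tuple[np.ndarray, dict]:
    """Project mean-centered ``data`` (samples x features) onto top PCs.

    Returns the projected data and a dict with the PC basis (rows),
    the mean, and the explained-variance ratios.
    """
    mean = data.mean(axis=0)
    centered = data - mean
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    var = s ** 2
    evr = var / var.sum()
    basis = vt[:n_pcs]
    return centered @ basis.T, dict(basis=basis, mean=mean, evr=evr)


def explained_variance_ratios(data: np.ndarray) -> np.ndarray:
    """PCA explained-variance ratios of samples-x-features data."""
    centered = data - data.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    var = s ** 2
    return var / var.sum()


# ---------------------------------------------------------------------------
# Noise-free activity collection
# ---------------------------------------------------------------------------

def collect_activity(
    params: models.NetworkParams,
    panel: np.ndarray,
    timing: TrialTiming | None = None,
    n_items: int = 7,
) -> dict:
    """Noise-free activity for all trial types plus the delay block.

    Returns a dict with:
      - ``x``: (n_types, n_steps, N) activity for all ordered-pair types
      - ``delay``: (n_items, n_delay_steps, N) item-1-condition delay activity
      - ``types``, ``timing``
    """
    timing = timing or TrialTiming.basic()
    types = enumerate_trial_types(n_items)
    i1 = np.array([t.rank1 - 1 for t in types])
    i2 = np.array([t.rank2 - 1 for t in types])
    bu = panel @ params.B.T
    xs, _ = models.simulate_pulsed(
        params,
        {timing.pulse1_index: bu[i1], timing.pulse2_index: bu[i2]},
        timing.n_steps,
    )
    # during the delay activity depends only on item 1: take one type per rank
    first_idx = [next(k for k, t in enumerate(types) if t.rank1 == r)
                 for r in range(1, n_items + 1)]
    delay = xs[first_idx][:, timing.delay_slice, :]
    return dict(x=xs, delay=delay, types=types, timing=timing)


# ---------------------------------------------------------------------------
# Activity axes
# ---------------------------------------------------------------------------

@dataclass
class ActivityAxes:
    """Task-defined unit axes in the ambient (unit) space."""

    choice_axis: np.ndarray
    xcm_axis: np.ndarray
    readout_axis: np.ndarray
    xcm_trajectory: np.ndarray  # (n_steps, N)


def _unit(v: np.ndarray, name: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateAxisError(f"{name} axis has zero norm")
    return v / n


def compute_axes(
    activity: np.ndarray,
    types,
    timing: TrialTiming,
    W: np.ndarray,
) -> ActivityAxes:
    """Choice, XCM and readout axes from noise-free all-type activity.

    - choice axis: mean(choice-2 types) - mean(choice-1 types), averaged over
      the first quarter of the choice period, unit-normalized.
    - XCM axis: from the delay's first-quarter XCM to its last-quarter XCM.
    - readout axis: unit-normalized choice-1 readout weight row.
    """
    cs = timing.choice_slice
    q = max(1, (cs.stop - cs.start) // 4)
    early_choice = activity[:, cs.start:cs.start + q, :].mean(axis=1)
    c1 = np.array([t.correct_choice == 1 for t in types])
    choice_axis = _unit(
        early_choice[~c1].mean(axis=0) - early_choice[c1].mean(axis=0),
        "choice",
    )

    xcm = activity.mean(axis=0)  # (n_steps, N)
    ds = timing.delay_slice
    qd = max(1, (ds.stop - ds.start) // 4)
    xcm_first = xcm[ds.start:ds.start + qd].mean(axis=0)
    xcm_last = xcm[ds.stop - qd:ds.stop].mean(axis=0)
    xcm_axis = _unit(xcm_last - xcm_first, "XCM")

    readout_axis = _unit(W[0].astype(float), "readout")
    return ActivityAxes(choice_axis, xcm_axis, readout_axis, xcm)


def project_axis(axis: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Project an ambient-space axis onto a PC basis and re-normalize."""
    v = basis @ axis
    return _unit(v, "projected")


# ---------------------------------------------------------------------------
# Linear dynamics
# ---------------------------------------------------------------------------

@dataclass
class LinearDynamicsFit:
    A: np.ndarray  # (k, k) state matrix, convention dX/dt = X A (states rows)
    r_squared: float
    eigenvalues: np.ndarray  # continuous-time, units of 1/tau
    frequencies: np.ndarray  # |imag| in cycles/delay
    decay: np.ndarray  # real parts, 1/tau
    eigenvectors: np.ndarray  # columns, state-space (eigenvectors of A^T)
    delay_duration: float
    n_pcs: int
    pca: dict


def eig_to_cycles_per_delay(imag: np.ndarray, delay_duration: float) -> np.ndarray:
    """Continuous-time angular frequency -> cycles per delay duration."""
    return np.abs(imag) * delay_duration / (2.0 * np.pi)


def cycles_per_delay_to_eig(freq: np.ndarray, delay_duration: float) -> np.ndarray:
    return np.asarray(freq) * 2.0 * np.pi / delay_duration


def fit_linear_dynamics(
    delay_activity: np.ndarray,
    dt: float = 0.1,
    n_pcs: int = 10,
    delay_duration: float | None = None,
) -> LinearDynamicsFit:
    """Least-squares fit of dX/dt = X A to delay-period activity.

    Parameters
    ----------
    delay_activity : (n_conditions, n_steps, N). Derivatives are forward
        differences over dt; the fit is done in the top ``n_pcs`` PCs of the
        pooled delay activity.
    delay_duration : duration of the delay in tau (default n_steps * dt),
        used to express eigenfrequencies in cycles/delay.
    """
    n_cond, n_steps, _ = delay_activity.shape
    if delay_duration is None:
        delay_duration = n_steps * dt
    flat = delay_activity.reshape(n_cond * n_steps, -1)
    proj, pca = pca_project(flat, n_pcs)
    traj = proj.reshape(n_cond, n_steps, -1)

    x = traj[:, :-1, :].reshape(-1, traj.shape[2])
    xdot = np.diff(traj, axis=1).reshape(-1, traj.shape[2]) / dt
    if np.linalg.norm(xdot) < 1e-12:
        raise DegenerateFitError("constant delay activity; zero derivatives")
    A, *_ = np.linalg.lstsq(x, xdot, rcond=None)
    pred = x @ A
    ss_res = ((xdot - pred) ** 2).sum()
    ss_tot = ((xdot - xdot.mean(axis=0)) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot

    # states are row vectors: eigen-analysis on A^T puts eigenvectors in
    # state space
    lam, vec = np.linalg.eig(A.T)
    return LinearDynamicsFit(
        A=A,
        r_squared=float(r2),
        eigenvalues=lam,
        frequencies=eig_to_cycles_per_delay(lam.imag, delay_duration),
        decay=lam.real,
        eigenvectors=vec,
        delay_duration=delay_duration,
        n_pcs=n_pcs,
        pca=pca,
    )


# ---------------------------------------------------------------------------
# Fixed points
# ---------------------------------------------------------------------------

@dataclass
class FixedPoint:
    x: np.ndarray
    speed: float
    eigenvalues: np.ndarray | None = None
    classification: str | None = None  # attractor | saddle-1 | other
    unstable_axis: np.ndarray | None = None


def dynamics_speed(params: models.NetworkParams, x: np.ndarray) -> np.ndarray:
    """Mean-squared autonomous speed q(x) = mean(F(x)^2), F = tau*dx/dt."""
    f = -x + np.tanh(x) @ params.J.T + params.bias
    return (f ** 2).mean(axis=-1)


def find_fixed_points(
    params: models.NetworkParams,
    seeds: np.ndarray,
    max_iter: int = 50_000,
    patience: int = 5_000,
    lr: float = 0.01,
    speed_tol: float = 1e-5,
    dedup_tol: float = 1e-5,
    dedup_rule: str = "all-units",
) -> list[FixedPoint]:
    """Adam minimization of the autonomous speed from a batch of seeds.

    Candidates with speed below ``speed_tol`` are accepted; duplicates are
    removed greedily in order of ascending speed. Under ``all-units`` two
    candidates are distinct only if every unit differs by more than
    ``dedup_tol``; under ``any-unit`` a single differing unit suffices.
    """
    x = np.atleast_2d(np.asarray(seeds, dtype=float)).copy()
    m, n = x.shape
    mom = np.zeros_like(x)
    vel = np.zeros_like(x)
    b1, b2, eps = 0.9, 0.999, 1e-8
    best = np.full(m, np.inf)
    best_x = x.copy()
    stall = np.zeros(m, dtype=int)
    tau = params.tau
    for it in range(1, max_iter + 1):
        r = np.tanh(x)
        f = (-x + r @ params.J.T + params.bias) / tau
        # grad of mean(f^2): (2/N) * Jac^T f, Jac = (-I + J diag(1-r^2))/tau
        jf = (f @ params.J) * (1 - r ** 2)
        grad = (2.0 / n) * (-f + jf) / tau
        mom = b1 * mom + (1 - b1) * grad
        vel = b2 * vel + (1 - b2) * grad ** 2
        x = x - lr * (mom / (1 - b1 ** it)) / (np.sqrt(vel / (1 - b2 ** it)) + eps)
        q = (f ** 2).mean(axis=1)
        improved = q < best - 1e-16
        best_x[improved] = x[improved]
        stall = np.where(improved, 0, stall + 1)
        best = np.minimum(best, q)
        if (stall >= patience).all():
            break

    order = np.argsort(best)
    accepted: list[FixedPoint] = []
    for i in order:
        if best[i] >= speed_tol:
            continue
        cand = best_x[i]
        dup = False
        for fp in accepted:
            diff = np.abs(cand - fp.x)
            if dedup_rule == "all-units":
                # distinct only if EVERY unit differs by more than tol
                if not (diff > dedup_tol).all():
                    dup = True
                    break
            else:  # any-unit
                if not (diff > dedup_tol).any():
                    dup = True
                    break
        if not dup:
            accepted.append(FixedPoint(x=cand.copy(), speed=float(best[i])))
    return accepted


def trial_state_seeds(
    params: models.NetworkParams,
    panel: np.ndarray,
    timing: TrialTiming | None = None,
    n_random_batches: int = 5,
    batch_size: int = 50,
    extra_steps: int = 100,
    seed: int = 0,
    n_items: int = 7,
) -> np.ndarray:
    """Seed states for fixed-point finding from task trials.

    Listed trial-time states (start, both pulses, mid-delay, trial end, and
    the end of an extended-run trial) for all types, plus random batches of
    states from trials with jittered item timing.
    """
    rng = np.random.default_rng(seed)
    timing = timing or TrialTiming.basic()
    types = enumerate_trial_types(n_items)
    i1 = np.array([t.rank1 - 1 for t in types])
    i2 = np.array([t.rank2 - 1 for t in types])
    bu = panel @ params.B.T
    n_steps = timing.n_steps + extra_steps
    xs, _ = models.simulate_pulsed(
        params,
        {timing.pulse1_index: bu[i1], timing.pulse2_index: bu[i2]},
        n_steps,
    )
    p1, p2 = timing.pulse1_index, timing.pulse2_index
    mid = (p1 + p2) // 2
    listed = xs[:, [0, p1, p2, mid, timing.n_steps - 1, n_steps - 1], :]
    seeds = [listed.reshape(-1, params.n)]
    for _ in range(n_random_batches):
        k = rng.integers(0, len(types), batch_size)
        jp1 = rng.integers(0, timing.n_steps // 2, batch_size)
        jp2 = jp1 + 1 + rng.integers(1, timing.n_steps // 2, batch_size)
        states = np.empty((batch_size, params.n))
        for b in range(batch_size):
            drv = {int(jp1[b]): bu[i1[k[b]]][None],
                   int(jp2[b]): bu[i2[k[b]]][None]}
            xj, _ = models.simulate_pulsed(params, drv, timing.n_steps)
            states[b] = xj[0, rng.integers(0, timing.n_steps)]
        seeds.append(states)
    return np.vstack(seeds)


def linearize(
    params: models.NetworkParams,
    x_star: np.ndarray,
    check_numerical: bool = True,
    fd_eps: float = 1e-6,
    tol: float = 1e-6,
) -> FixedPoint:
    """Jacobian spectrum and classification at a fixed point.

    Analytic Jacobian (-I + J diag(1 - tanh(x*)^2)) / tau, cross-checked by
    central finite differences of the autonomous vector field.
    """
    tau = params.tau
    r = np.tanh(x_star)
    jac = (-np.eye(params.n) + params.J * (1 - r ** 2)[None, :]) / tau
    if check_numerical:
        num = np.empty_like(jac)
        for k in range(params.n):
            e = np.zeros(params.n)
            e[k] = fd_eps
            fp = (-(x_star + e) + np.tanh(x_star + e) @ params.J.T + params.bias) / tau
            fm = (-(x_star - e) + np.tanh(x_star - e) @ params.J.T + params.bias) / tau
            num[:, k] = (fp - fm) / (2 * fd_eps)
        scale = max(1.0, np.abs(jac).max())
        if np.abs(num - jac).max() / scale > tol:
            raise LinearizationMismatchError(
                "analytic and numerical Jacobians disagree"
            )
    lam, vec = np.linalg.eig(jac)
    n_pos = int((lam.real > 0).sum())
    if n_pos == 0:
        cls = "attractor"
        unstable = None
    elif n_pos == 1:
        cls = "saddle-1"
        k = int(np.argmax(lam.real))
        unstable = np.real(vec[:, k])
        unstable = unstable / np.linalg.norm(unstable)
    else:
        cls = "other"
        unstable = None
    return FixedPoint(
        x=x_star,
        speed=float(dynamics_speed(params, x_star)),
        eigenvalues=lam,
        classification=cls,
        unstable_axis=unstable,
    )


# ---------------------------------------------------------------------------
# Comparison oscillation
# ---------------------------------------------------------------------------

@dataclass
class OscillationMode:
    eigenvalue: complex  # in (decay 1/tau, frequency cycles/delay) units
    frequency: float  # cycles/delay, >= 0
    decay: float
    plane: np.ndarray | None  # (2, k) orthonormal basis
    distance_to_target: float
    found: bool = True


NO_OSCILLATION = OscillationMode(
    eigenvalue=0j, frequency=np.nan, decay=np.nan, plane=None,
    distance_to_target=np.inf, found=False,
)


def orthonormal_plane(eigvec: np.ndarray) -> np.ndarray:
    """Orthonormal 2D basis from a complex eigenvector: real part first,
    imaginary part Gram-Schmidt-orthogonalized against it."""
    a = np.real(eigvec)
    b = np.imag(eigvec)
    a = a / np.linalg.norm(a)
    b = b - (b @ a) * a
    nb = np.linalg.norm(b)
    if nb < 1e-12:
        raise DegenerateAxisError("eigenvector pair spans no plane")
    return np.vstack([a, b / nb])


def identify_comparison_oscillation(
    fit: LinearDynamicsFit,
    target: complex = 0.0 + 0.5j,
) -> OscillationMode:
    """Oscillatory mode with eigenvalue nearest ``target`` (default 0+0.5i)
    in (decay, cycles/delay) coordinates.

    Returns an explicit no-oscillation result for purely real spectra.
    """
    lam = fit.eigenvalues
    has_imag = np.abs(lam.imag) > 1e-12
    if not has_imag.any():
        return NO_OSCILLATION
    pts = lam.real + 1j * fit.frequencies
    d = np.abs(pts - target)
    d[~has_imag] = np.inf
    k = int(np.argmin(d))
    return OscillationMode(
        eigenvalue=pts[k],
        frequency=float(fit.frequencies[k]),
        decay=float(lam.real[k]),
        plane=orthonormal_plane(fit.eigenvectors[:, k]),
        distance_to_target=float(d[k]),
    )


# ---------------------------------------------------------------------------
# Reduced oscillatory-mode simulation
# ---------------------------------------------------------------------------

def _hard_margin_separable(x: np.ndarray, y: np.ndarray) -> bool:
    """LP feasibility: does a hyperplane strictly separate y=+1 from y=-1?"""
    m, d = x.shape
    # variables: w (d), b (1); constraints y_i (w.x_i + b) >= 1
    a_ub = -(y[:, None] * np.hstack([x, np.ones((m, 1))]))
    b_ub = -np.ones(m)
    res = linprog(
        c=np.zeros(d + 1),
        A_ub=a_ub,
        b_ub=b_ub,
        bounds=[(-1e6, 1e6)] * (d + 1),
        method="highs",
    )
    return res.status == 0


def mode_functional(fit: LinearDynamicsFit, target: complex = 0.0 + 0.5j) -> dict:
    """Right eigenvector, left functional, and eigenvalue of the comparison
    oscillation of a linear-dynamics fit.

    For non-normal dynamics the amplitude of a mode excited by an input is
    the *left*-eigenvector inner product, which generally differs from the
    orthogonal projection onto the mode plane — the distinction behind the
    reduced-2D vs full-dimensional simulation contrast.
    """
    m = fit.A.T  # column convention: d(x^T)/dt = M x^T
    lam, vr = np.linalg.eig(m)
    freqs = eig_to_cycles_per_delay(lam.imag, fit.delay_duration)
    pts = lam.real + 1j * freqs
    d = np.abs(pts - target)
    d[np.abs(lam.imag) <= 1e-12] = np.inf
    if not np.isfinite(d).any():
        raise DegenerateAxisError("no oscillatory mode in spectrum")
    k = int(np.argmin(d))
    vl = np.linalg.inv(vr)
    return dict(v=vr[:, k], w=vl[k, :], lam=lam[k])


def simulate_reduced_oscillation(
    frequency: float,
    item_encodings: np.ndarray,
    timing: TrialTiming | None = None,
    mode: str = "reduced2D",
    plane: np.ndarray | None = None,
    mode_basis: dict | None = None,
    decay: float = 0.0,
    n_items: int = 7,
) -> dict:
    """Evolve trial-structured input under a single oscillatory mode.

    ``reduced2D``: encodings are projected onto the (orthonormal)
    oscillation plane and evolve as a pure rotation (optionally decaying)
    at ``frequency`` cycles/delay.

    ``fullD``: encodings keep their full dimensionality; only the
    oscillatory mode carries dynamics, all other directions are left
    untouched by the flow. When ``mode_basis`` (from
    :func:`mode_functional`) is supplied, the mode amplitude excited by
    each pulse is the left-eigenvector functional of the fitted dynamics,
    and ``frequency``/``decay`` default to the fitted eigenvalue; otherwise
    an orthogonal projector onto ``plane`` is used.

    Returns trajectories, the choice-period states a quarter past item 2,
    and a hard-margin-certified linear-separability verdict for choice 1 vs
    choice 2.
    """
    timing = timing or TrialTiming.basic()
    if timing.delay_steps == 0:
        raise ValueError("zero-length delay")
    dim = item_encodings.shape[1]
    dt = timing.dt
    delay_dur = timing.delay_steps * timing.dt
    types = enumerate_trial_types(n_items)
    quarter = max(1, timing.choice_steps // 4)

    if mode == "fullD" and mode_basis is not None:
        v = mode_basis["v"]
        w = mode_basis["w"]
        lam = mode_basis["lam"]
        # persistent (non-mode) part of each pulse; the mode pair carries
        # complex amplitude a = w . u evolving as e^{lam t}
        def mode_state(amp: complex) -> np.ndarray:
            return 2.0 * np.real(amp * v)

        residual = item_encodings - np.array(
            [mode_state(w @ u) for u in item_encodings]
        )
        records = []
        for t in types:
            u1 = item_encodings[t.rank1 - 1]
            u2 = item_encodings[t.rank2 - 1]
            a1 = w @ u1
            a2 = w @ u2
            r1 = residual[t.rank1 - 1]
            r2 = residual[t.rank2 - 1]
            a_end = a1 * np.exp(lam * delay_dur)
            a_choice = (a_end + a2) * np.exp(lam * quarter * dt)
            records.append(
                dict(
                    type=t,
                    post_pulse=mode_state(a1) + r1,
                    delay_end=mode_state(a_end) + r1,
                    choice_state=mode_state(a_choice) + r1 + r2,
                    label=1.0 if t.correct_choice == 1 else -1.0,
                )
            )
    else:
        if plane is None:
            if mode == "reduced2D" and dim != 2:
                raise ValueError(
                    "reduced2D without a plane needs 2D encodings"
                )
            plane = np.eye(dim)[:2]
        omega = 2.0 * np.pi * frequency / delay_dur

        def rot(v2: np.ndarray, steps: int) -> np.ndarray:
            theta = omega * steps * dt
            g = np.exp(decay * steps * dt)
            c, s = np.cos(theta), np.sin(theta)
            rmat = g * np.array([[c, -s], [s, c]])
            return v2 @ rmat.T

        in_plane = item_encodings @ plane.T  # (n_items, 2)
        out_of_plane = (
            item_encodings - in_plane @ plane
            if mode == "fullD"
            else np.zeros((n_items, dim))
        )
        records = []
        for t in types:
            e1 = in_plane[t.rank1 - 1]
            e2 = in_plane[t.rank2 - 1]
            o1 = out_of_plane[t.rank1 - 1]
            o2 = out_of_plane[t.rank2 - 1]
            after_delay = rot(e1[None], timing.delay_steps)[0]
            at_choice = rot((after_delay + e2)[None], quarter)[0]
            if mode == "fullD":
                records.append(
                    dict(
                        type=t,
                        post_pulse=plane.T @ e1 + o1,
                        delay_end=plane.T @ after_delay + o1,
                        choice_state=plane.T @ at_choice + o1 + o2,
                        label=1.0 if t.correct_choice == 1 else -1.0,
                    )
                )
            else:
                records.append(
                    dict(
                        type=t,
                        post_pulse=e1,
                        delay_end=after_delay,
                        choice_state=at_choice,
                        label=1.0 if t.correct_choice == 1 else -1.0,
                    )
                )

    x = np.array([r["choice_state"] for r in records])
    y = np.array([r["label"] for r in records])
    return dict(
        records=records,
        choice_states=x,
        labels=y,
        separable=_hard_margin_separable(x, y),
        timing=timing,
    )
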