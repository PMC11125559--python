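"""Behavioral readout and analysis.

Converts network output time series into choices and response times via a
saturating threshold rule, titrates intrinsic noise to sub-asymptotic
performance, runs behavioral simulations over all trial types, and computes
the behavioral patterns (symbolic distance, end item, end order) for both
simulated networks and subject-format trial tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import models
from .task import ACTIVATED_TARGET, TrialTiming, enumerate_trial_types

#: Response threshold on the saturated output (85% of its 0..1 range).
THRESHOLD = 0.85


class TitrationError(RuntimeError):
    """No noise level on the grid satisfied the titration criteria."""


def saturate(z: np.ndarray, target_active: float = ACTIVATED_TARGET) -> np.ndarray:
    """Monotonic saturating map of readout activity onto (0, 1).

    Centered at half the activated target so that the 0.85 threshold is
    crossed when output reaches approximately 85% of the activated target
    value (z = 4.23 for a target of 5): a unit rising toward its target
    triggers a response on the way up, and an output exactly at target
    saturates near 1.
    """
    return 0.5 * np.tanh((z - target_active / 2.0) / 2.0) + 0.5


def decide_batch(
    zs: np.ndarray, timing: TrialTiming
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply the threshold rule to a batch of output time series.

    Parameters
    ----------
    zs : (M, n_steps, >=2) readout time series.

    Returns
    -------
    choice : (M,) int — 1 or 2, or 0 for no response.
    rt : (M,) float — crossing time as a fraction of the choice period
        (0 = first choice step); NaN for no response.
    responded : (M,) bool.
    """
    cs = timing.choice_slice
    zt = saturate(zs[:, cs, :2])  # (M, Tc, 2)
    n_choice = zt.shape[1]
    crossed = zt >= THRESHOLD
    any_cross = crossed.any(axis=1)  # (M, 2)
    first = np.where(any_cross, crossed.argmax(axis=1), n_choice + 1)

    choice = np.zeros(zs.shape[0], dtype=int)
    choice[first[:, 0] < first[:, 1]] = 1
    choice[first[:, 1] < first[:, 0]] = 2
    tie = (first[:, 0] == first[:, 1]) & any_cross[:, 0]
    if tie.any():
        idx = np.flatnonzero(tie)
        vals = zt[idx, first[idx, 0], :]
        # simultaneous crossings: larger saturated output wins, then unit 1
        choice[idx] = np.where(vals[:, 1] > vals[:, 0], 2, 1)

    responded = choice > 0
    rt = np.full(zs.shape[0], np.nan)
    cross_step = np.minimum(first[:, 0], first[:, 1])
    rt[responded] = cross_step[responded] / n_choice
    return choice, rt, responded


def decide(z: np.ndarray, timing: TrialTiming) -> tuple[int, float, bool]:
    """Single-trial version of :func:`decide_batch`."""
    choice, rt, responded = decide_batch(z[None], timing)
    return int(choice[0]), float(rt[0]), bool(responded[0])


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _pulse_drives(params, panel, i1, i2, timing):
    bu = panel @ params.B.T  # (n_items, N)
    return {timing.pulse1_index: bu[i1], timing.pulse2_index: bu[i2]}


def simulate_behavior(
    params: models.NetworkParams,
    panel: np.ndarray,
    noise_sd: float,
    timing: TrialTiming | None = None,
    n_per_type: int = 500,
    seed: int | np.random.Generator = 0,
    n_items: int = 7,
) -> pd.DataFrame:
    """Simulate ``n_per_type`` noisy trials of every trial type.

    Non-responding trials receive a random choice (counted in performance)
    but keep rt = NaN so they are excluded from RT statistics.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    timing = timing or TrialTiming.basic()
    types = enumerate_trial_types(n_items)
    i1 = np.repeat([t.rank1 - 1 for t in types], n_per_type)
    i2 = np.repeat([t.rank2 - 1 for t in types], n_per_type)

    drives = _pulse_drives(params, panel, i1, i2, timing)
    _, zs = models.simulate_pulsed(
        params, drives, timing.n_steps, noise_sd=noise_sd, rng=rng
    )
    choice, rt, responded = decide_batch(zs, timing)
    miss = ~responded
    choice[miss] = rng.integers(1, 3, int(miss.sum()))

    meta = pd.DataFrame(
        [
            dict(
                rank1=t.rank1,
                rank2=t.rank2,
                correct_choice=t.correct_choice,
                symbolic_distance=t.symbolic_distance,
                is_training=t.is_training,
                end_item_order=t.end_item_order,
            )
            for t in types
        ]
    )
    df = meta.loc[meta.index.repeat(n_per_type)].reset_index(drop=True)
    df["responded"] = responded
    df["choice"] = choice
    df["rt"] = rt
    df["correct"] = df["choice"] == df["correct_choice"]
    return df


def titration_criteria(df: pd.DataFrame, n_items: int = 7) -> bool:
    """Sub-asymptotic performance criteria on one simulated record table:
    >50% on choice-1 and choice-2 training pools (separately) and <96% on
    the two largest-symbolic-distance types (pooled)."""
    train = df[df.is_training]
    p1 = train[train.correct_choice == 1].correct.mean()
    p2 = train[train.correct_choice == 2].correct.mean()
    p_ext = df[df.symbolic_distance == n_items - 1].correct.mean()
    return bool(p1 > 0.5 and p2 > 0.5 and p_ext < 0.96)


def titrate_on_grid(evaluate, grid: np.ndarray, coarse_step: int = 1) -> float:
    """First grid level whose evaluation satisfies the criteria.

    ``evaluate(level) -> bool``. With ``coarse_step > 1`` the grid is first
    scanned at that stride and then refined within the bracketing segment
    (valid when the criteria are monotone in noise).
    """
    grid = np.asarray(grid, dtype=float)
    if coarse_step > 1:
        coarse_idx = list(range(0, len(grid), coarse_step))
        if coarse_idx[-1] != len(grid) - 1:
            coarse_idx.append(len(grid) - 1)
        hit = None
        for pos, gi in enumerate(coarse_idx):
            if evaluate(grid[gi]):
                hit = pos
                break
        if hit is None:
            raise TitrationError(
                "no grid noise level satisfied the titration criteria"
            )
        start = coarse_idx[hit - 1] + 1 if hit > 0 else 0
        stop = coarse_idx[hit]  # this one already passed
        for gi in range(start, stop):
            if evaluate(grid[gi]):
                return float(grid[gi])
        return float(grid[stop])
    for level in grid:
        if evaluate(level):
            return float(level)
    raise TitrationError(
        "no grid noise level satisfied the titration criteria"
    )


def titrate_noise(
    params: models.NetworkParams,
    panel: np.ndarray,
    timing: TrialTiming | None = None,
    grid: np.ndarray | None = None,
    n_per_type: int = 500,
    seed: int = 0,
    n_items: int = 7,
    coarse_step: int = 1,
) -> float:
    """Smallest grid noise level giving sub-asymptotic performance.

    The default grid is 0.5 to 5 in steps of 0.05. See
    :func:`titration_criteria` for the acceptance conditions.
    """
    timing = timing or TrialTiming.basic()
    if grid is None:
        grid = np.round(np.arange(0.5, 5.0 + 1e-9, 0.05), 2)
    rng = np.random.default_rng(seed)

    def evaluate(level: float) -> bool:
        df = simulate_behavior(
            params, panel, float(level), timing=timing,
            n_per_type=n_per_type, seed=rng, n_items=n_items,
        )
        return titration_criteria(df, n_items)

    return titrate_on_grid(evaluate, grid, coarse_step)


FEEDFORWARD_TITRATION_GRID = 2.0 ** np.arange(0, 8)  # 1 .. 128


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def end_order_index(rt_first: float, rt_second: float) -> float:
    """(RT_1st - RT_2nd) / (RT_1st + RT_2nd) over pool-average RTs."""
    return (rt_first - rt_second) / (rt_first + rt_second)


@dataclass
class BehaviorSummary:
    """Aggregate behavioral patterns for one cohort of trial records."""

    performance_matrix: np.ndarray  # (n, n), NaN diagonal
    rt_matrix: np.ndarray  # (n, n), NaN where no RTs
    distance_performance: pd.DataFrame  # columns: distance, choice, performance
    distance_rt: pd.DataFrame
    end_item_performance: dict  # {'end': .., 'non_end': ..}
    end_item_rt: dict
    rt_end_first: float
    rt_end_second: float
    end_order_index: float
    n_records: int
    noise_sd: float | None = None


def summarize_behavior(
    records: pd.DataFrame, n_items: int = 7, noise_sd: float | None = None
) -> BehaviorSummary:
    """Compute the behavioral patterns from a table of trial records.

    RT statistics use responded trials only; performance counts all trials.
    End-order pools exclude trials containing both end items.
    """
    n = n_items
    perf = np.full((n, n), np.nan)
    rt = np.full((n, n), np.nan)
    for (r1, r2), g in records.groupby(["rank1", "rank2"]):
        perf[r1 - 1, r2 - 1] = g.correct.mean()
        rts = g.rt[g.responded]
        rt[r1 - 1, r2 - 1] = rts.mean() if len(rts) else np.nan

    resp = records[records.responded]
    dist_perf = (
        records.groupby(["symbolic_distance", "correct_choice"])
        .correct.mean()
        .rename("performance")
        .reset_index()
    )
    dist_rt = (
        resp.groupby(["symbolic_distance", "correct_choice"])
        .rt.mean()
        .reset_index()
    )

    is_end = records.end_item_order != "none"
    end_perf = dict(
        end=records.correct[is_end].mean(),
        non_end=records.correct[~is_end].mean(),
    )
    r_end = resp.end_item_order != "none"
    end_rt = dict(
        end=resp.rt[r_end].mean(),
        non_end=resp.rt[~r_end].mean(),
    )

    first_pool = resp.rt[resp.end_item_order == "first"]
    second_pool = resp.rt[resp.end_item_order == "second"]
    rt1 = first_pool.mean() if len(first_pool) else np.nan
    rt2 = second_pool.mean() if len(second_pool) else np.nan
    eoi = (
        end_order_index(rt1, rt2)
        if np.isfinite(rt1) and np.isfinite(rt2)
        else np.nan
    )
    return BehaviorSummary(
        performance_matrix=perf,
        rt_matrix=rt,
        distance_performance=dist_perf,
        distance_rt=dist_rt,
        end_item_performance=end_perf,
        end_item_rt=end_rt,
        rt_end_first=float(rt1),
        rt_end_second=float(rt2),
        end_order_index=float(eoi),
        n_records=len(records),
        noise_sd=noise_sd,
    )


# ---------------------------------------------------------------------------
# Subject-table analysis
# ---------------------------------------------------------------------------

REQUIRED_SUBJECT_COLUMNS = {
    "subject", "phase", "block", "rank1", "rank2", "correct_choice",
    "symbolic_distance", "is_training", "end_item_order", "responded",
    "choice", "correct", "rt",
}


def sign_test(values: np.ndarray) -> float:
    """Exact two-sided sign test of median zero (zeros dropped)."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values) & (values != 0)]
    if len(values) == 0:
        return 1.0
    k = int((values > 0).sum())
    return stats.binomtest(k, len(values), 0.5).pvalue


def analyze_subjects(
    table: pd.DataFrame,
    max_no_response: int = 20,
    max_blur_events: int = 20,
    max_quiz_failures: int = 10,
    min_final_training_performance: float = 0.5,
    model_end_order_indices: np.ndarray | None = None,
) -> dict:
    """Subject-level behavioral analysis of a trial table.

    Applies the inclusion criteria (no-response count, optional blur-event
    and quiz-failure columns, final-training-block performance), then
    computes block-wise performance, first-presentation performance on
    critical trials (test types without end items), per-subject end-order
    indices with a cohort sign test, and optionally the Wasserstein distance
    to a model end-order-index distribution.
    """
    missing = REQUIRED_SUBJECT_COLUMNS - set(table.columns)
    if missing:
        raise KeyError(f"subject table missing columns: {sorted(missing)}")

    final_block = table.block[table.phase == "training"].max()
    included: list[int] = []
    exclusions: dict[int, list[str]] = {}
    for subj, g in table.groupby("subject"):
        reasons = []
        if (~g.responded).sum() >= max_no_response:
            reasons.append("no_response")
        if "blur_events" in g and g.blur_events.iloc[0] >= max_blur_events:
            reasons.append("blur_events")
        if "quiz_failures" in g and g.quiz_failures.iloc[0] >= max_quiz_failures:
            reasons.append("quiz_failures")
        final = g[(g.phase == "training") & (g.block == final_block)]
        if final.correct.mean() <= min_final_training_performance:
            reasons.append("final_training_performance")
        if reasons:
            exclusions[subj] = reasons
        else:
            included.append(subj)

    kept = table[table.subject.isin(included)]
    block_perf = (
        kept.groupby(["phase", "block", "subject"]).correct.mean()
        .rename("performance").reset_index()
    )

    # critical trials: test types containing no end item; first presentation
    # is the earliest testing-phase occurrence per subject and type
    testing = kept[kept.phase == "testing"].copy()
    crit = testing[(~testing.is_training) & (testing.end_item_order == "none")]
    crit = crit.sort_values(["subject", "block", "trial"] if "trial" in crit
                            else ["subject", "block"])
    first_pres = crit.groupby(["subject", "rank1", "rank2"]).first().reset_index()
    first_pres_perf = first_pres.groupby("subject").correct.mean()

    eoi = {}
    for subj, g in testing.groupby("subject"):
        resp = g[g.responded]
        f = resp.rt[resp.end_item_order == "first"]
        s = resp.rt[resp.end_item_order == "second"]
        if len(f) and len(s):
            eoi[subj] = end_order_index(f.mean(), s.mean())
    eoi_series = pd.Series(eoi, name="end_order_index")

    report = dict(
        included=included,
        exclusions=exclusions,
        n_included=len(included),
        block_performance=block_perf,
        first_presentation_performance=first_pres_perf,
        first_presentation_mean=float(first_pres_perf.mean())
        if len(first_pres_perf)
        else np.nan,
        end_order_indices=eoi_series,
        end_order_median=float(eoi_series.median()) if len(eoi_series) else np.nan,
        end_order_sign_test_p=sign_test(eoi_series.values),
    )
    if model_end_order_indices is not None and len(eoi_series):
        report["wasserstein_to_model"] = float(
            stats.wasserstein_distance(
                eoi_series.values, np.asarray(model_end_order_indices)
            )
        )
    return report
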