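"""Stochastic input generators.

Everything the pipeline consumes is generated here: random item panels
(standard-normal embeddings of the abstract items), synthetic subject trial
tables with planted behavioral effects (so the subject-level analysis code is
testable without any human dataset), and shape-matched Gaussian surrogates
for activity tensors (random baselines for the geometry indices).

A single experiment seed is split into named substreams so each component
can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task import TrialType, enumerate_trial_types

_SUBSTREAMS = ("panel", "training", "noise", "subjects")


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent RNG substream derived from one experiment seed."""
    if name not in _SUBSTREAMS:
        raise KeyError(f"unknown substream {name!r}; known: {_SUBSTREAMS}")
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(_SUBSTREAMS))
    return np.random.default_rng(children[_SUBSTREAMS.index(name)])


def make_item_panel(
    n_items: int = 7, n_in: int = 100, seed: int | None = 0
) -> np.ndarray:
    """(n_items, n_in) matrix of i.i.d. standard-normal item vectors.

    Bit-identical for identical seeds.
    """
    if n_in < 1:
        raise ValueError(f"n_in must be >= 1, got {n_in}")
    rng = substream(seed, "panel") if seed is not None else np.random.default_rng()
    return rng.standard_normal((n_items, n_in))


def random_activity_like(
    states: np.ndarray, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Gaussian surrogate with the exact shape of ``states``."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    return rng.standard_normal(states.shape)


@dataclass
class SyntheticSubjectConfig:
    """Generative model for synthetic subject behavior.

    RT model (seconds): ``base - distance_slope*(distance-1) - end_bonus*has_end
    + order_offset*(end item 2nd) + N(0, rt_noise_sd)`` truncated to
    ``(0, response_window]``. A negative ``order_offset`` makes end-item-second
    trials faster, i.e. a "2nd-faster" cohort with positive end-order index.

    Accuracy: logistic in symbolic distance with an end-item bonus, mixed with
    a lapse rate (lapses choose uniformly at random).
    """

    n_subjects: int = 20
    n_training_blocks: int = 3
    training_reps_per_type: int = 4  # 12 types x 4 = 48 trials/block
    n_testing_blocks: int = 6
    base_rt: float = 0.55
    distance_slope: float = 0.02
    end_bonus_rt: float = 0.04
    order_offset_rt: float = -0.05  # negative => end-item-first slower? see sign note
    rt_noise_sd: float = 0.08
    accuracy_intercept: float = 0.4
    accuracy_slope: float = 0.5
    end_item_accuracy_bonus: float = 0.6
    lapse_rate: float = 0.05
    no_response_rate: float = 0.02
    response_window: float = 1.0
    n_items: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rt_noise_sd < 0:
            raise ValueError("rt_noise_sd must be non-negative")
        for p in (self.lapse_rate, self.no_response_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def _p_correct(cfg: SyntheticSubjectConfig, t: TrialType) -> float:
    x = (
        cfg.accuracy_intercept
        + cfg.accuracy_slope * (t.symbolic_distance - 1)
        + cfg.end_item_accuracy_bonus * t.has_end_item
    )
    p = 1.0 / (1.0 + np.exp(-x))
    return cfg.lapse_rate * 0.5 + (1.0 - cfg.lapse_rate) * p


def _mean_rt(cfg: SyntheticSubjectConfig, t: TrialType) -> float:
    rt = cfg.base_rt - cfg.distance_slope * (t.symbolic_distance - 1)
    if t.has_end_item:
        rt -= cfg.end_bonus_rt
    if t.end_item_order == "second":
        rt += cfg.order_offset_rt
    return rt


def generate_subjects(cfg: SyntheticSubjectConfig) -> pd.DataFrame:
    """Simulate a cohort of synthetic subjects.

    Returns one row per trial with columns: subject, phase, block, trial,
    rank1, rank2, correct_choice, symbolic_distance, is_training,
    end_item_order, responded, choice, correct, rt.

    Every training block contains each adjacent-pair type
    ``training_reps_per_type`` times; every testing block contains each of
    the full set of types exactly once, both in subject-specific random order.
    """
    rng = substream(cfg.seed, "subjects")
    types = enumerate_trial_types(cfg.n_items)
    training_idx = np.array([k for k, t in enumerate(types) if t.is_training])
    all_idx = np.arange(len(types))

    # per-trial-type generative parameters
    p_correct = np.array([_p_correct(cfg, t) for t in types])
    mean_rt = np.array([_mean_rt(cfg, t) for t in types])
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

    frames = []
    for subj in range(cfg.n_subjects):
        blocks = [
            ("training", b, np.tile(training_idx, cfg.training_reps_per_type))
            for b in range(cfg.n_training_blocks)
        ] + [
            ("testing", b, all_idx.copy())
            for b in range(cfg.n_testing_blocks)
        ]
        for phase, b, block in blocks:
            k = block[rng.permutation(len(block))]
            n = len(k)
            responded = rng.random(n) >= cfg.no_response_rate
            correct = responded & (rng.random(n) < p_correct[k])
            cc = meta.correct_choice.values[k]
            choice = np.where(correct, cc, 3 - cc)
            choice[~responded] = 0
            rt = np.clip(
                mean_rt[k] + rng.normal(0, cfg.rt_noise_sd, n),
                1e-3,
                cfg.response_window,
            )
            rt[~responded] = np.nan
            df = meta.iloc[k].reset_index(drop=True)
            df.insert(0, "subject", subj)
            df.insert(1, "phase", phase)
            df.insert(2, "block", b)
            df.insert(3, "trial", np.arange(n))
            df["responded"] = responded
            df["choice"] = choice
            df["correct"] = correct
            df["rt"] = rt
            frames.append(df)
    return pd.concat(frames, ignore_index=True)
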