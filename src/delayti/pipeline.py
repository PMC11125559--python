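"""Sweep orchestration and report tables.

Runs (variant x regime x instance) cells end to end — train, filter to full
generalizers, titrate noise, simulate behavior, run dynamics and geometry
analyses — with per-instance caching under a run directory, and assembles
cohort-level report tables (generalizer counts, geometry/behavior summaries,
qualitative prediction grid).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, dynamics, geometry, models, training
from .synthdata import make_item_panel
from .task import TrialTiming


@dataclass
class ExperimentConfig:
    variants: list[str] = field(default_factory=lambda: ["f-RNN"])
    regimes: list[str] = field(default_factory=lambda: ["highest"])
    delay_variant: str = "basic"
    n_instances: int = 3
    seed: int = 0
    n_items: int = 7
    n: int = 100
    n_in: int = 100
    n_per_type: int = 500
    titration_step: float = 0.05
    max_epochs: int = 30_000
    learning_rate: float = 2e-3
    analyses: tuple[str, ...] = ("behavior", "geometry", "dynamics")
    out_dir: str = "runs/sweep"

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "analyses" in d:
            d["analyses"] = tuple(d["analyses"])
        return cls(**d)


def _instance_seed(cfg: ExperimentConfig, variant: str, regime: str, i: int) -> int:
    # unique, stable per cell and instance
    key = f"{cfg.seed}|{variant}|{regime}|{i}"
    return int(np.random.SeedSequence(
        [cfg.seed, hash(key) & 0x7FFFFFFF]
    ).generate_state(1)[0] & 0x7FFFFFFF)


def run_instance(
    variant: str,
    regime: str,
    seed: int,
    cfg: ExperimentConfig,
) -> dict:
    """Train and analyze one instance; returns a summary dict."""
    panel = make_item_panel(cfg.n_items, cfg.n_in, seed)
    params = models.init_network(
        variant, regime, n=cfg.n, n_in=cfg.n_in, seed=seed
    )
    tcfg = training.TrainingConfig(
        learning_rate=cfg.learning_rate,
        max_epochs=cfg.max_epochs,
        delay_variant=cfg.delay_variant,
        n_items=cfg.n_items,
        seed=seed,
    )
    report = training.train_rnn(params, panel, tcfg)
    timing = training._timing_for(cfg.delay_variant, tcfg.dt)
    if cfg.delay_variant == "variable":
        timing = TrialTiming.extended(tcfg.dt)  # analyses use max delay

    out = dict(
        variant=variant,
        regime=regime,
        seed=seed,
        epochs=report.epochs,
        stop_reason=report.stop_reason,
        full_generalizer=report.generalization["full_generalizer"],
        memorizer=report.generalization["memorizer"],
        n_correct=report.generalization["n_correct"],
    )
    state = dict(params=params, panel=panel, timing=timing)
    if not out["full_generalizer"]:
        return out, state

    act = dynamics.collect_activity(params, panel, timing, cfg.n_items)

    if "geometry" in cfg.analyses:
        geo = geometry.geometry_report(act["delay"], n_pcs=10)
        out.update(
            collinearity_early=geo.collinearity_early,
            collinearity_late=geo.collinearity_late,
            collinearity_change=geo.collinearity_change,
            ordered_collinearity_change=geo.ordered_collinearity_change,
            mean_angle_change=geo.mean_angle_change,
            mean_distance_change=geo.mean_distance_change,
        )
        evr = dynamics.explained_variance_ratios(
            act["x"].reshape(-1, params.n)
        )
        out["top3_variance"] = float(evr[:3].sum())

    if "dynamics" in cfg.analyses:
        try:
            fit = dynamics.fit_linear_dynamics(
                act["delay"], dt=tcfg.dt,
                delay_duration=timing.delay_steps * tcfg.dt,
            )
            osc = dynamics.identify_comparison_oscillation(fit)
            out.update(
                linfit_r2=fit.r_squared,
                oscillation_frequency=osc.frequency if osc.found else None,
                oscillation_decay=osc.decay if osc.found else None,
            )
        except dynamics.DegenerateFitError:
            out.update(linfit_r2=None, oscillation_frequency=None)

        axes = dynamics.compute_axes(
            act["x"], act["types"], timing, params.W
        )
        try:
            enc = geometry.encoding_index(
                act["delay"], axes.readout_axis, "readout"
            )
            out["encoding_index"] = enc.encoding_index
        except Exception:
            out["encoding_index"] = None

    if "behavior" in cfg.analyses:
        grid = np.round(
            np.arange(0.5, 5.0 + 1e-9, cfg.titration_step), 4
        )
        try:
            noise = behavior.titrate_noise(
                params, panel, timing, grid=grid,
                n_per_type=cfg.n_per_type, seed=seed,
            )
            records = behavior.simulate_behavior(
                params, panel, noise, timing,
                n_per_type=cfg.n_per_type, seed=seed + 1,
            )
            summ = behavior.summarize_behavior(records, cfg.n_items, noise)
            out.update(
                titrated_noise=noise,
                end_order_index=summ.end_order_index,
                no_response_rate=float(1 - records.responded.mean()),
            )
        except behavior.TitrationError:
            out.update(titrated_noise=None, end_order_index=None)

    return out, state


def run_sweep(cfg: ExperimentConfig) -> pd.DataFrame:
    """Run all cells of a sweep with caching; returns the manifest table.

    Each instance's summary is cached as JSON under ``out_dir``; rerunning
    with the same config reuses cached instances (checkpoints are stored
    alongside for resumability).
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for variant in cfg.variants:
        for regime in cfg.regimes:
            for i in range(cfg.n_instances):
                seed = _instance_seed(cfg, variant, regime, i)
                tag = f"{variant}_{regime}_{i}"
                cache = out_dir / f"{tag}.json"
                ckpt = out_dir / f"{tag}.npz"
                if cache.exists():
                    rows.append(json.loads(cache.read_text()))
                    continue
                try:
                    summary, state = run_instance(variant, regime, seed, cfg)
                    models.save_checkpoint(
                        ckpt, state["params"], {"summary_seed": seed}
                    )
                except Exception as exc:  # record, never abort the sweep
                    summary = dict(
                        variant=variant, regime=regime, seed=seed,
                        error=repr(exc),
                    )
                cache.write_text(json.dumps(summary))
                rows.append(summary)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def generalizer_table(manifest: pd.DataFrame) -> pd.DataFrame:
    """Counts of full generalizers per (regime, variant) cell."""
    if manifest.empty:
        return pd.DataFrame()
    tab = (
        manifest.assign(
            full_generalizer=manifest.get("full_generalizer", False)
        )
        .groupby(["regime", "variant"])
        .agg(
            n_trained=("seed", "count"),
            n_generalized=("full_generalizer", "sum"),
        )
        .reset_index()
    )
    return tab


#: thresholds used for the qualitative prediction grid
GRID_THRESHOLDS = dict(collinearity=0.5, sign=0.0)


def prediction_grid(manifest: pd.DataFrame) -> pd.DataFrame:
    """Qualitative per-cohort signs mirroring the headline prediction table.

    For each (variant, regime) cohort of full generalizers: end-order
    version (1st/2nd-faster by index sign), early/late collinearity vs 0.5,
    collinearity-change sign, mean-angle-change sign, and encoding type.
    """
    rows = []
    gen = manifest[manifest.get("full_generalizer", False) == True]  # noqa: E712
    for (variant, regime), g in gen.groupby(["variant", "regime"]):
        def mean(col):
            return g[col].dropna().mean() if col in g else np.nan

        eoi = mean("end_order_index")
        rows.append(
            dict(
                variant=variant,
                regime=regime,
                n=len(g),
                end_order="NA" if not np.isfinite(eoi) else (
                    "1st-faster" if eoi < 0 else "2nd-faster"
                ),
                collinearity_early_gt_half=mean("collinearity_early")
                > GRID_THRESHOLDS["collinearity"],
                collinearity_late_gt_half=mean("collinearity_late")
                > GRID_THRESHOLDS["collinearity"],
                collinearity_change_sign=np.sign(mean("collinearity_change")),
                mean_angle_change_sign=np.sign(mean("mean_angle_change")),
                oscillation_frequency=mean("oscillation_frequency"),
                encoding="NA" if not np.isfinite(mean("encoding_index")) else (
                    "1st-dominant" if mean("encoding_index") > 0
                    else "2nd-dominant"
                ),
            )
        )
    return pd.DataFrame(rows)


def build_report(
    manifest: pd.DataFrame,
    out_dir: str | Path | None = None,
    subject_end_order_indices: np.ndarray | None = None,
) -> dict:
    """Cohort report bundle: generalizer counts, per-cohort summary stats,
    prediction grid, and (optionally) model-vs-subject Wasserstein distances
    on end-order indices."""
    from scipy import stats

    report = dict(
        generalizers=generalizer_table(manifest),
        predictions=prediction_grid(manifest),
    )
    gen = manifest[manifest.get("full_generalizer", False) == True]  # noqa: E712
    stats_cols = [
        c for c in (
            "collinearity_early", "collinearity_late", "collinearity_change",
            "mean_angle_change", "mean_distance_change", "end_order_index",
            "oscillation_frequency", "encoding_index", "top3_variance",
        )
        if c in gen.columns
    ]
    if not gen.empty and stats_cols:
        report["cohort_stats"] = (
            gen.groupby(["variant", "regime"])[stats_cols]
            .agg(["mean", "std", "count"])
        )
    if subject_end_order_indices is not None and "end_order_index" in gen:
        w = {}
        for (variant, regime), g in gen.groupby(["variant", "regime"]):
            vals = g.end_order_index.dropna().values
            if len(vals):
                w[f"{variant}/{regime}"] = float(
                    stats.wasserstein_distance(
                        vals, subject_end_order_indices
                    )
                )
        report["wasserstein_to_subjects"] = w
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report["generalizers"].to_csv(out_dir / "generalizers.csv", index=False)
        report["predictions"].to_csv(out_dir / "predictions.csv", index=False)
        if "cohort_stats" in report:
            report["cohort_stats"].to_csv(out_dir / "cohort_stats.csv")
    return report
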