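"""Pipeline orchestration, table export and contrast-table annotations.

Ties the stages together in the order the analysis runs them: simulate (or
load) -> scale -> transform -> enumerate -> fit K -> 3-step unadjusted ->
fully adjusted.  Every stage writes CSV/JSON artifacts plus a structured log
with the seeds and convergence flags needed to regenerate any table.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from trajmix import lcga, rasch, simulate, three_step
from trajmix.enumeration import enumerate_classes
from trajmix.lcga import FitSettings, TrajectoryPanel, fit_lcga, predicted_curve
from trajmix.preprocess import handle_missing


def expected_false_positives(n_tests: int, alpha: float, superscripts_per_hit: int = 2) -> dict:
    """Chance-expected significant contrasts and table markers under the null.

    Each significant pairwise contrast is superscripted on both involved
    classes, so the expected marker count is twice the expected hit count.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be a probability")
    hits = n_tests * alpha
    return {"expected_hits": hits, "expected_markers": hits * superscripts_per_hit}


def binned_mean_curve(panel: TrajectoryPanel, bin_width: float) -> pd.DataFrame:
    """Mean aggression score by age bin (midpoint, mean, n).

    A plain binned-mean summary of the panel's age profile; bins partition
    [min age, max age] so every observation lands in exactly one bin.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if panel.n_obs == 0:
        raise ValueError("empty panel")
    lo = float(panel.age.min())
    n_bins = max(1, int(np.ceil((panel.age.max() - lo) / bin_width)))
    idx = np.minimum(((panel.age - lo) / bin_width).astype(int), n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        rows.append({
            "bin_midpoint": lo + (b + 0.5) * bin_width,
            "mean_score": float(panel.score[mask].mean()),
            "n": int(mask.sum()),
        })
    return pd.DataFrame(rows)


@dataclass
class PipelineConfig:
    """Run recipe for the end-to-end analysis."""

    out_dir: str = "results/pipeline"
    seed: int = 0
    n_children: int = 1141
    input_dir: str | None = None  # read panel/predictors/outcomes CSVs instead of simulating
    k_min: int = 1
    k_max: int = 9
    force_k: int | None = None
    select_criterion: str = "BIC"
    n_starts: int = 20
    max_iter: int = 2000
    tol: float = 1e-7
    blrt_reps: int = 0
    missing_policy: str = "complete-case"
    use_item_scaling: bool = True
    predictors: list[str] = field(default_factory=list)  # empty = all columns
    outcomes: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_jsonify))


def _jsonify(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    raise TypeError(type(x))


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis; returns the artifact directory.

    Any stage failure raises with the stage name; artifacts written by
    earlier stages persist.  Reruns with the same master seed reproduce the
    numeric outputs exactly.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed, "stages": {}}
    stage = "init"

    def tick(name, **info):
        log["stages"][name] = {"elapsed_s": round(time.time() - t0, 3), **info}
        _write_json(out / "run_log.json", log)

    try:
        # --- stage: cohort -------------------------------------------------
        stage = "cohort"
        t0 = time.time()
        if config.input_dir:
            ind = Path(config.input_dir)
            panel_df = pd.read_csv(ind / "panel.csv")
            predictors = pd.read_csv(ind / "predictors.csv")
            outcomes = pd.read_csv(ind / "outcomes.csv")
        else:
            cfg = simulate.default_config(config.n_children, seed=config.seed,
                                          include_items=config.use_item_scaling)
            cohort = simulate.generate_cohort(cfg, seed=config.seed)
            cohort.write_csv(out / "cohort")
            panel_df = cohort.item_responses if config.use_item_scaling else cohort.panel
            predictors = cohort.predictors
            outcomes = cohort.outcomes
        tick("cohort", n_children=int(predictors.shape[0]), n_obs=int(panel_df.shape[0]))

        # --- stage: scale --------------------------------------------------
        stage = "scale"
        t0 = time.time()
        item_cols = [c for c in panel_df.columns if c.startswith("item_")]
        if config.use_item_scaling and item_cols:
            bank = rasch.calibrate_items(panel_df)
            (out / "item_bank.json").write_text(bank.to_json())
            locations = rasch.score_persons(bank, panel_df)
            scored = pd.DataFrame(
                {
                    "child_id": [p.child_id for p in locations],
                    "age": [p.age for p in locations],
                    "score": [p.theta for p in locations],
                    "se": [p.se for p in locations],
                }
            )
            tick("scale", n_scored=len(scored), latent_sd=bank.latent_sd)
        else:
            scored = panel_df[["child_id", "age", "score"]].copy()
            tick("scale", n_scored=len(scored), skipped=True)
        scored.to_csv(out / "scored_panel.csv", index=False)
        panel = TrajectoryPanel.from_frame(scored)

        # --- stage: transform / missing policy ------------------------------
        stage = "transform"
        t0 = time.time()
        pred_table, report = handle_missing(predictors, config.missing_policy)
        out_table, report_y = handle_missing(outcomes, config.missing_policy)
        tick("transform", predictors=report, outcomes=report_y)

        # --- stage: enumerate ----------------------------------------------
        stage = "enumerate"
        t0 = time.time()
        settings = FitSettings(
            n_starts=config.n_starts, max_iter=config.max_iter,
            tol=config.tol, seed=config.seed,
        )
        if config.force_k is not None:
            chosen_k = config.force_k
            tick("enumerate", skipped=True, forced_k=chosen_k)
        else:
            table = enumerate_classes(
                panel, config.k_min, config.k_max, settings,
                blrt_reps=config.blrt_reps, seed=config.seed,
            )
            table.to_csv(out / "enumeration.csv")
            chosen_k = table.selected_k(config.select_criterion)
            tick("enumerate", selected_k=chosen_k, criterion=config.select_criterion)

        # --- stage: fit ------------------------------------------------------
        stage = "fit"
        t0 = time.time()
        model = fit_lcga(panel, chosen_k, settings)
        (out / "model.json").write_text(model.to_json())
        ages = np.linspace(1.0, 5.0, 81)
        curves = pd.DataFrame({"age": ages})
        for k in range(1, model.K + 1):
            curves[f"class_{k}"] = predicted_curve(model, k, ages)
        curves.to_csv(out / "curves.csv", index=False)
        binned_mean_curve(panel, 0.25).to_csv(out / "binned_means.csv", index=False)
        diag = lcga.classification_diagnostics(model)
        tick("fit", K=model.K, loglik=model.loglik,
             entropy=diag["relative_entropy"], converged=model.converged)

        # --- stage: three-step ------------------------------------------------
        stage = "three_step"
        t0 = time.time()
        if model.K == 1:
            tick("three_step", skipped=True,
                 reason="single-class solution: no class variation to predict")
            return out

        # align child-level tables with the panel's children
        pred_table = pred_table.set_index("child_id").loc[model.children].reset_index()
        out_table = out_table.set_index("child_id").loc[model.children].reset_index()
        assignment = three_step.modal_assign(model.posterior)
        _write_json(out / "assignment.json",
                    {"Q": assignment.Q, "counts": assignment.counts})

        pred_cols = config.predictors or [c for c in pred_table.columns if c != "child_id"]
        out_cols = config.outcomes or [c for c in out_table.columns if c != "child_id"]

        rows2 = []
        effects = {}
        for name in pred_cols:
            eff = three_step.fit_step3_predictor(assignment, pred_table[name].to_numpy())
            effects[name] = eff
            rows2.append({
                "predictor": name, "chi2": eff.chi2, "df": eff.df,
                "p": eff.p_value, "pseudo_R": eff.omega,
                **{f"coef_class_{k+1}": eff.std_gamma[k] for k in range(model.K)},
            })
        pd.DataFrame(rows2).to_csv(out / "unadjusted_predictors.csv", index=False)

        rows3 = []
        for name in out_cols:
            eff = three_step.fit_step3_distal(assignment, out_table[name].to_numpy())
            rows3.append({
                "outcome": name, "chi2": eff.chi2, "df": eff.df, "p": eff.p_value,
                "R": eff.r,
                **{f"std_diff_class_{k+1}": eff.std_diffs[k] for k in range(model.K)},
            })
        pd.DataFrame(rows3).to_csv(out / "unadjusted_distal.csv", index=False)

        X = pred_table[pred_cols].to_numpy()
        for name in out_cols:
            adj = three_step.fit_adjusted(
                assignment, X, out_table[name].to_numpy(), predictor_names=pred_cols,
            )
            rows4 = [{
                "predictor": p, **adj.predictor_lrt[p],
                "std_direct": adj.std_direct[j],
            } for j, p in enumerate(pred_cols)]
            chi2, df, p, r = adj.trajectory_lrt
            rows4.append({"predictor": "trajectory", "chi2": chi2, "df": df,
                          "p": p, "omega": r, "std_direct": np.nan})
            pd.DataFrame(rows4).to_csv(out / f"adjusted_{name}.csv", index=False)
        n_pairs = model.K * (model.K - 1) // 2
        _write_json(out / "contrast_annotation.json",
                    expected_false_positives(n_pairs, 0.05))
        tick("three_step", n_predictors=len(pred_cols), n_outcomes=len(out_cols))
        return out
    except Exception as exc:  # annotate with the failing stage, keep artifacts
        log["stages"]["FAILED"] = {"stage": stage, "error": str(exc)}
        _write_json(out / "run_log.json", log)
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
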