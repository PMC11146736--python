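"""Variable transformations and missing-data policies.

Non-binary predictors and skewed outcomes are made closer to within-class
normal by an ordered sequence of steps: percentile trimming (outliers recoded
back to the cut values), reversal of bounded scales, recentering to a minimum
of zero, mean-centering, and a square-root transform.  The constants fitted
by each step (percentile cuts, means, minima) are frozen at fit time so the
same spec can be re-applied to new data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_STEPS = ("trim", "reverse", "recenter_min_zero", "center_mean", "sqrt")


@dataclass
class TransformSpec:
    """Ordered transformation recipe for one variable.

    Parameters
    ----------
    variable : str
        Variable name (used in audit logs).
    steps : list of str
        Steps drawn from ``trim``, ``reverse``, ``recenter_min_zero``,
        ``center_mean``, ``sqrt``, applied in order.
    trim_percentiles : (float, float)
        Lower/upper trimming percentiles (default 2nd and 98th).
    scale_min, scale_max : float or None
        Bounds of the response scale, required by ``reverse``; the reversed
        value is ``(scale_max + scale_min) - value``.
    """

    variable: str
    steps: list[str] = field(default_factory=list)
    trim_percentiles: tuple[float, float] = (2.0, 98.0)
    scale_min: float | None = None
    scale_max: float | None = None
    fitted: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s in self.steps:
            if s not in VALID_STEPS:
                raise ValueError(f"unknown transform step {s!r}")

    @property
    def is_fitted(self) -> bool:
        return bool(self.fitted)


def _apply_step(x: np.ndarray, step: str, spec: TransformSpec, fit: bool) -> np.ndarray:
    obs = x[~np.isnan(x)]
    if step == "trim":
        if fit:
            if obs.size < 10:
                raise ValueError("need >= 10 non-missing values to fit percentile cuts")
            lo, hi = np.percentile(obs, spec.trim_percentiles)
            spec.fitted["trim_lo"], spec.fitted["trim_hi"] = float(lo), float(hi)
        return np.clip(x, spec.fitted["trim_lo"], spec.fitted["trim_hi"])
    if step == "reverse":
        if spec.scale_min is None or spec.scale_max is None:
            raise ValueError("reverse requires scale_min and scale_max")
        return (spec.scale_max + spec.scale_min) - x
    if step == "recenter_min_zero":
        if fit:
            spec.fitted["min"] = float(np.min(obs))
        return x - spec.fitted["min"]
    if step == "center_mean":
        if fit:
            spec.fitted["mean"] = float(np.mean(obs))
        return x - spec.fitted["mean"]
    if step == "sqrt":
        if np.nanmin(x) < 0:
            raise ValueError(
                f"square root requested for {spec.variable!r} with min < 0 after "
                "preceding steps; recenter first"
            )
        return np.sqrt(x)
    raise ValueError(step)  # pragma: no cover


def fit_transform(values, spec: TransformSpec) -> tuple[np.ndarray, TransformSpec]:
    """Apply the spec's steps in order, fitting constants on first use.

    Missing values (NaN) propagate unchanged through every step.  Returns
    the transformed vector and the spec with its fitted constants frozen.
    """
    x = np.asarray(values, dtype=float).copy()
    fit = not spec.is_fitted
    for step in spec.steps:
        x = _apply_step(x, step, spec, fit)
    return x, spec


def apply_transform(values, spec: TransformSpec) -> np.ndarray:
    """Re-apply a previously fitted spec to new data."""
    if not spec.is_fitted and any(s in ("trim", "recenter_min_zero", "center_mean") for s in spec.steps):
        raise ValueError("spec has not been fitted")
    x, _ = fit_transform(values, spec)
    return x


def handle_missing(table: pd.DataFrame, policy: str = "complete-case"):
    """Missing-data policy for a wide child-level table.

    ``complete-case`` drops rows with any missing cell; ``simple-impute``
    fills continuous columns with the column mean and binary columns with
    the mode, flagging imputed cells.  Returns the processed table and a
    report dict with counts.
    """
    if policy not in ("complete-case", "simple-impute"):
        raise ValueError(f"unknown policy {policy!r}")
    n_missing = int(table.isna().sum().sum())
    n_cells = int(table.size)
    for col in table.columns:
        if table[col].isna().all():
            raise ValueError(f"variable {col!r} is entirely missing")
    report = {
        "policy": policy,
        "n_rows_in": len(table),
        "n_missing_cells": n_missing,
        "missing_fraction": n_missing / n_cells if n_cells else 0.0,
    }
    if policy == "complete-case":
        out = table.dropna()
        report["n_rows_dropped"] = len(table) - len(out)
        report["n_rows_out"] = len(out)
        return out, report

    out = table.copy()
    imputed = {}
    for col in out.columns:
        mask = out[col].isna()
        if not mask.any():
            continue
        obs = out[col].dropna()
        if set(np.unique(obs)) <= {0, 1, 0.0, 1.0}:
            fill = obs.mode().iloc[0]
        else:
            fill = obs.mean()
        out.loc[mask, col] = fill
        imputed[col] = int(mask.sum())
    report["n_cells_imputed"] = int(sum(imputed.values()))
    report["imputed_by_column"] = imputed
    report["n_rows_out"] = len(out)
    return out, report
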