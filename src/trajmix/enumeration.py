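"""Choosing the number of trajectory classes.

Two complementary devices: information criteria (AIC, BIC, sample-size
adjusted BIC, CAIC) computed on the number of children as the independent
units, and the parametric bootstrap likelihood ratio test (BLRT) for
K vs K+1 classes, which simulates replicate panels from the fitted K-class
model at the observed measurement design and compares the observed LRT
statistic against the bootstrap null distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from trajmix.lcga import FitSettings, LcgaModel, TrajectoryPanel, fit_lcga, simulate_panel

logger = logging.getLogger(__name__)


def information_criteria(loglik: float, n_params: int, n: int) -> dict:
    """AIC, BIC, saBIC and CAIC for a fitted model.

    ``n`` is the number of children (the likelihood's independent units).
    saBIC replaces ln(n) by ln((n + 2) / 24); CAIC adds one unit per
    parameter on top of BIC.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    m2ll = -2.0 * loglik
    return {
        "AIC": m2ll + 2.0 * n_params,
        "BIC": m2ll + n_params * np.log(n),
        "saBIC": m2ll + n_params * np.log((n + 2) / 24.0),
        "CAIC": m2ll + n_params * (np.log(n) + 1.0),
    }


@dataclass
class EnumerationTable:
    """Fit summaries for a range of class counts."""

    rows: pd.DataFrame
    models: dict[int, LcgaModel] = field(default_factory=dict)

    def selected_k(self, criterion: str = "BIC") -> int:
        return int(self.rows.loc[self.rows[criterion].idxmin(), "K"])

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def enumerate_classes(
    panel: TrajectoryPanel,
    k_min: int = 1,
    k_max: int = 10,
    settings: FitSettings | None = None,
    blrt_reps: int = 0,
    blrt_settings: FitSettings | None = None,
    seed: int | None = None,
) -> EnumerationTable:
    """Fit K = k_min..k_max and tabulate criteria (and optionally the BLRT).

    With ``blrt_reps > 0`` the (K-1 vs K) BLRT is run for each K > k_min
    using the lighter ``blrt_settings`` for replicate fits.
    """
    settings = settings or FitSettings()
    rows = []
    models: dict[int, LcgaModel] = {}
    for K in range(k_min, k_max + 1):
        model = fit_lcga(panel, K, settings)
        models[K] = model
        ic = information_criteria(model.loglik, model.n_params, panel.n_children)
        row = {"K": K, "loglik": model.loglik, "n_params": model.n_params, **ic,
               "BLRT_stat": np.nan, "BLRT_p": np.nan, "BLRT_reps": 0}
        rows.append(row)
    if blrt_reps > 0:
        for K in range(k_min + 1, k_max + 1):
            stat, p = blrt(
                panel, K - 1, reps=blrt_reps,
                settings=settings, replicate_settings=blrt_settings,
                seed=seed, fitted_small=models.get(K - 1), fitted_big=models.get(K),
            )
            idx = K - k_min
            rows[idx]["BLRT_stat"], rows[idx]["BLRT_p"] = stat, p
            rows[idx]["BLRT_reps"] = blrt_reps
    return EnumerationTable(rows=pd.DataFrame(rows), models=models)


def blrt(
    panel: TrajectoryPanel,
    k_small: int,
    reps: int = 99,
    settings: FitSettings | None = None,
    replicate_settings: FitSettings | None = None,
    seed: int | None = None,
    fitted_small: LcgaModel | None = None,
    fitted_big: LcgaModel | None = None,
    max_redraws: int = 3,
) -> tuple[float, float]:
    """Parametric bootstrap LRT of k_small vs k_small + 1 classes.

    Replicate panels are simulated from the fitted k_small model at the
    observed (child, age) design; both models are refit to each replicate
    (with the lighter ``replicate_settings``, default 10 starts) and the
    p-value is ``(1 + #{bootstrap LRT >= observed}) / (reps + 1)``.
    A replicate whose refit degenerates is redrawn up to ``max_redraws``
    times and logged.
    """
    if k_small < 1:
        raise ValueError("k_small must be >= 1")
    if reps < 19:
        raise ValueError("need at least 19 bootstrap replicates")
    settings = settings or FitSettings()
    if replicate_settings is None:
        replicate_settings = FitSettings(
            n_starts=10, max_iter=settings.max_iter,
            tol=settings.tol, seed=settings.seed, variance_floor=settings.variance_floor,
        )
    small = fitted_small or fit_lcga(panel, k_small, settings)
    big = fitted_big or fit_lcga(panel, k_small + 1, settings)
    stat = max(0.0, 2.0 * (big.loglik - small.loglik))

    master = np.random.default_rng(settings.seed if seed is None else seed)
    boot = np.empty(reps)
    for r in range(reps):
        for attempt in range(max_redraws + 1):
            sim = simulate_panel(small, panel, master)
            rep_settings = FitSettings(
                n_starts=replicate_settings.n_starts,
                max_iter=replicate_settings.max_iter,
                tol=replicate_settings.tol,
                seed=int(master.integers(2**31 - 1)),
                variance_floor=replicate_settings.variance_floor,
            )
            try:
                m0 = fit_lcga(sim, k_small, rep_settings)
                m1 = fit_lcga(sim, k_small + 1, rep_settings)
                boot[r] = max(0.0, 2.0 * (m1.loglik - m0.loglik))
                break
            except RuntimeError:
                logger.info("BLRT replicate %d redrawn (attempt %d)", r, attempt + 1)
        else:
            raise RuntimeError(f"BLRT replicate {r} failed after {max_redraws} redraws")
    p = (1.0 + float(np.sum(boot >= stat))) / (reps + 1.0)
    return stat, p
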