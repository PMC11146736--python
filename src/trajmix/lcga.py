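"""Latent class growth analysis for irregularly timed aggression scores.

The model: each child i belongs to one of K latent trajectory classes with
probability pi_k.  Given class k, the score at age ``a`` is

    y_ij = sum_{p=0..4} beta_kp (a_ij - 2.2)^p + e_ij,   e_ij ~ N(0, sigma^2)

— a quartic class-mean curve on age centered at 2.2 years, no within-class
variability in the growth components, and a residual variance common to all
times and classes.  Children are the independent units; residuals are
independent given class.  Estimation is maximum likelihood by EM over
multiple random starts.  Classes are relabeled in ascending order of the
model-predicted score at age 5, so class 1 always has the lowest endpoint.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

AGE_CENTER = 2.2
DEGREE = 4  # quartic
N_COEF = DEGREE + 1


@dataclass
class TrajectoryPanel:
    """Long-format repeated measures: one row per (child, age) observation."""

    child_id: np.ndarray
    age: np.ndarray
    score: np.ndarray

    def __post_init__(self) -> None:
        self.child_id = np.asarray(self.child_id)
        self.age = np.asarray(self.age, dtype=float)
        self.score = np.asarray(self.score, dtype=float)
        if not (len(self.child_id) == len(self.age) == len(self.score)):
            raise ValueError("child_id, age, score must have equal length")
        if np.any(self.age < 0.5) or np.any(self.age > 5.5):
            raise ValueError("ages must lie in [0.5, 5.5]")
        pairs = list(zip(self.child_id.tolist(), self.age.tolist()))
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (child, age) observations")
        # sort by child for contiguous blocks
        order = np.lexsort((self.age, self.child_id))
        self.child_id = self.child_id[order]
        self.age = self.age[order]
        self.score = self.score[order]
        self.children, self.child_index, counts = np.unique(
            self.child_id, return_inverse=True, return_counts=True
        )
        self.block_starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        self.centered_age = self.age - AGE_CENTER
        self.design = np.vander(self.centered_age, N_COEF, increasing=True)

    @property
    def n_children(self) -> int:
        return len(self.children)

    @property
    def n_obs(self) -> int:
        return len(self.score)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, id_col="child_id", age_col="age", score_col="score"):
        return cls(df[id_col].to_numpy(), df[age_col].to_numpy(), df[score_col].to_numpy())


@dataclass
class FitSettings:
    """EM control knobs."""

    n_starts: int = 50
    max_iter: int = 2000
    tol: float = 1e-7
    seed: int = 0
    variance_floor: float = 1e-6
    max_restarts: int = 10

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.tol <= 0:
            raise ValueError("tolerance must be > 0")


@dataclass
class LcgaModel:
    """Fitted latent class growth model."""

    K: int
    B: np.ndarray  # K x 5 growth coefficients
    sigma2: float
    pi: np.ndarray
    loglik: float
    posterior: np.ndarray  # children x K
    children: np.ndarray
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.B = np.atleast_2d(np.asarray(self.B, dtype=float))
        self.pi = np.asarray(self.pi, dtype=float)
        if self.B.shape != (self.K, N_COEF):
            raise ValueError(f"B must be K x {N_COEF}")
        if abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must sum to 1")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")

    @property
    def n_params(self) -> int:
        # 5 growth means per class, K-1 free proportions, one residual variance
        return 5 * self.K + (self.K - 1) + 1

    def to_json(self) -> str:
        return json.dumps(
            {
                "K": self.K,
                "B": self.B.tolist(),
                "sigma2": self.sigma2,
                "pi": self.pi.tolist(),
                "loglik": self.loglik,
                "n_params": self.n_params,
                "converged": self.converged,
                "n_iter": self.n_iter,
            },
            indent=1,
        )


class DegenerateClassError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

def _child_class_loglik(panel: TrajectoryPanel, B: np.ndarray, sigma2: float) -> np.ndarray:
    """(children x K) log of the within-class response density products.

    Observations are summed per child in ascending (child, age) order, the
    documented summation order for reproducibility.
    """
    resid = panel.score[:, None] - panel.design @ B.T  # obs x K
    ll_obs = -0.5 * (np.log(2 * np.pi * sigma2) + resid**2 / sigma2)
    return np.add.reduceat(ll_obs, panel.block_starts, axis=0)


def loglik(model: LcgaModel, panel: TrajectoryPanel) -> float:
    """Observed-data mixture log-likelihood of the panel under the model."""
    if model.sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    lcc = _child_class_loglik(panel, model.B, model.sigma2)
    with np.errstate(divide="ignore"):
        logpi = np.log(model.pi)
    return float(np.sum(logsumexp(lcc + logpi, axis=1)))


def _posteriors(panel, B, sigma2, pi):
    lcc = _child_class_loglik(panel, B, sigma2)
    with np.errstate(divide="ignore"):
        lj = lcc + np.log(pi)
    norm = logsumexp(lj, axis=1)
    return np.exp(lj - norm[:, None]), float(norm.sum())


def posterior_matrix(panel: TrajectoryPanel, B, sigma2: float, pi) -> np.ndarray:
    """Class-membership posteriors of each child under given parameters.

    Useful for evaluating downstream machinery at the true generating
    parameters, independent of any fitted model.
    """
    post, _ = _posteriors(panel, np.atleast_2d(np.asarray(B, float)), float(sigma2),
                          np.asarray(pi, float))
    return post


def _m_step(panel, post, variance_floor):
    K = post.shape[1]
    X, y = panel.design, panel.score
    w_obs = post[panel.child_index]  # obs x K
    B = np.empty((K, N_COEF))
    sse = 0.0
    for k in range(K):
        w = w_obs[:, k]
        Xw = X * w[:, None]
        XtWX = X.T @ Xw
        XtWy = Xw.T @ y
        try:
            B[k] = np.linalg.solve(XtWX, XtWy)
        except np.linalg.LinAlgError:
            B[k] = np.linalg.lstsq(XtWX, XtWy, rcond=None)[0]
        r = y - X @ B[k]
        sse += float(w @ r**2)
    sigma2 = max(sse / panel.n_obs, variance_floor)
    pi = post.mean(axis=0)
    return B, sigma2, pi


def _run_em(panel, K, B0, pi0, sigma20, settings, track=None):
    B, pi, sigma2 = B0.copy(), pi0.copy(), sigma20
    ll_prev = -np.inf
    for it in range(settings.max_iter):
        post, ll = _posteriors(panel, B, sigma2, pi)
        if track is not None:
            track.append(ll)
        if post.sum(axis=0).min() < 1.0:
            raise DegenerateClassError(
                f"class {int(np.argmin(post.sum(axis=0))) + 1} holds < 1 child of posterior mass"
            )
        if ll - ll_prev < settings.tol and it > 0:
            return B, sigma2, pi, post, ll, it + 1, True
        ll_prev = ll
        B, sigma2, pi = _m_step(panel, post, settings.variance_floor)
    post, ll = _posteriors(panel, B, sigma2, pi)
    return B, sigma2, pi, post, ll, settings.max_iter, False


def _random_start(panel, K, rng):
    labels = rng.integers(0, K, size=panel.n_children)
    post = np.zeros((panel.n_children, K))
    post[np.arange(panel.n_children), labels] = 1.0
    # blend toward uniform so no class starts empty
    post = 0.9 * post + 0.1 / K
    return _m_step(panel, post, 1e-6)


def _quantile_start(panel, K):
    """Crude start: split children by mean score level."""
    sums = np.add.reduceat(panel.score, panel.block_starts)
    counts = np.diff(np.concatenate([panel.block_starts, [panel.n_obs]]))
    means = sums / counts
    qs = np.quantile(means, np.linspace(0, 1, K + 1))
    labels = np.clip(np.searchsorted(qs, means, side="right") - 1, 0, K - 1)
    post = np.zeros((panel.n_children, K))
    post[np.arange(panel.n_children), labels] = 1.0
    post = 0.9 * post + 0.1 / K
    return _m_step(panel, post, 1e-6)


def relabel(B, pi, post):
    """Deterministic label order: ascending predicted score at age 5."""
    t5 = np.vander(np.array([5.0 - AGE_CENTER]), N_COEF, increasing=True)[0]
    endpoint = B @ t5
    order = np.argsort(endpoint, kind="stable")
    return B[order], pi[order], post[:, order], order


def fit_lcga(panel: TrajectoryPanel, K: int, settings: FitSettings | None = None) -> LcgaModel:
    """Fit the K-class quartic LCGA by best-of-``n_starts`` EM.

    Starts are random child partitions plus one quantile split on child mean
    score.  A start whose EM path degenerates (a class with under one child
    of posterior mass) is redrawn up to ``max_restarts`` times.  The model
    with the highest log-likelihood is returned, relabeled so class 1 has
    the lowest predicted score at age 5.
    """
    settings = settings or FitSettings()
    if K < 1:
        raise ValueError("K must be >= 1")
    if panel.n_obs <= 5 * K + K:
        raise ValueError("too few observations for the requested K")

    cond = np.linalg.cond(panel.design.T @ panel.design)
    if cond > 1e10:
        warnings.warn(f"quartic design is ill-conditioned (cond = {cond:.3g})")

    rng = np.random.default_rng(settings.seed)
    best = None
    starts = [_quantile_start(panel, K)] + [
        _random_start(panel, K, rng) for _ in range(max(0, settings.n_starts - 1))
    ]
    for s_idx, (B0, sigma20, pi0) in enumerate(starts):
        attempts = 0
        while True:
            try:
                B, sigma2, pi, post, ll, n_iter, conv = _run_em(
                    panel, K, B0, pi0, sigma20, settings
                )
                break
            except DegenerateClassError:
                attempts += 1
                if attempts > settings.max_restarts:
                    logger.info("start %d abandoned after repeated degeneracy", s_idx)
                    B = None
                    break
                B0, sigma20, pi0 = _random_start(panel, K, rng)
        if B is None:
            continue
        if best is None or ll > best[4]:
            best = (B, sigma2, pi, post, ll, n_iter, conv)

    if best is None:
        raise RuntimeError("every EM start degenerated; reduce K or add data")
    B, sigma2, pi, post, ll, n_iter, conv = best
    if not conv:
        logger.warning("EM did not converge in %d iterations; best-so-far returned", settings.max_iter)
    B, pi, post, _ = relabel(B, pi, post)
    return LcgaModel(
        K=K, B=B, sigma2=sigma2, pi=pi, loglik=ll,
        posterior=post, children=panel.children, converged=conv, n_iter=n_iter,
    )


def predicted_curve(model: LcgaModel, k: int, ages) -> np.ndarray:
    """Class-k model-predicted score at the given ages (1-based class index)."""
    if not 1 <= k <= model.K:
        raise ValueError(f"class {k} outside 1..{model.K}")
    ages = np.asarray(ages, dtype=float)
    X = np.vander(ages - AGE_CENTER, N_COEF, increasing=True)
    return X @ model.B[k - 1]


def classification_diagnostics(model: LcgaModel) -> dict:
    """Relative entropy, mean posterior by assigned class, modal class sizes.

    Relative entropy is ``1 - sum_ik p_ik log p_ik / (n log K)``: 1 for
    one-hot posteriors, 0 for uniform ones.
    """
    post = model.posterior
    n, K = post.shape
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(post > 0, post * np.log(post), 0.0)
    if K == 1:
        rel_entropy = 1.0
    else:
        rel_entropy = 1.0 + plogp.sum() / (n * np.log(K))
    modal = post.argmax(axis=1)
    sizes = np.bincount(modal, minlength=K)
    avg_post = np.array([
        post[modal == k, k].mean() if sizes[k] else np.nan for k in range(K)
    ])
    return {
        "relative_entropy": float(rel_entropy),
        "avg_posterior_assigned": avg_post,
        "modal_sizes": sizes,
    }


def simulate_panel(model: LcgaModel, panel: TrajectoryPanel, rng: np.random.Generator) -> TrajectoryPanel:
    """Parametric draw from the model at the observed (child, age) design."""
    classes = rng.choice(model.K, size=panel.n_children, p=model.pi)
    mean = np.einsum("op,op->o", panel.design, model.B[classes[panel.child_index]])
    y = mean + rng.normal(0.0, np.sqrt(model.sigma2), size=panel.n_obs)
    return TrajectoryPanel(panel.child_id, panel.age, y)
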