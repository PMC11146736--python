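"""Manual 3-step structural models with fixed classification error.

After the trajectory mixture is fitted without covariates, each child's
repeated measures are replaced by a single most-likely (modal) class label
N_i.  The label is a fallible indicator of the true class C_i; its error
rates q_st = P(N = t | C = s) are estimated from the posterior matrix and
then held fixed while structural models are fitted by maximum likelihood:

- predictor -> class:   multinomial logistic P(C = s | x), class measured by
  N through the fixed q;
- class -> distal outcome: class-specific Normal means with common variance;
- fully adjusted: all predictor -> class paths, class -> outcome means, and
  direct predictor -> outcome paths simultaneously.

Effect sizes follow the field's conventions: Cohen's omega (pseudo-R)
sqrt(chi2 / n) for overall class-discrimination tests, R = sqrt(1 -
within/total variance) for class -> outcome effects, coefficients
standardized by sample standard deviations, and pairwise class contrasts
derived by subtraction of reference-class coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import minimize

Q_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# step 3 assignment
# ---------------------------------------------------------------------------

@dataclass
class StepThreeAssignment:
    """Modal class labels with the fixed classification-error matrix."""

    modal: np.ndarray  # 0-based class label per child
    Q: np.ndarray  # K x K, q_st = P(N = t | C = s)
    logits: np.ndarray  # K x K fixed measurement logits log(q_st / q_sK)
    counts: np.ndarray  # children per modal class

    @property
    def K(self) -> int:
        return self.Q.shape[0]

    @property
    def n(self) -> int:
        return len(self.modal)


def modal_assign(posteriors: np.ndarray) -> StepThreeAssignment:
    """Most-likely class assignment and posterior-weighted error matrix.

    Ties go to the lowest class index.  ``q_st`` is the posterior-weighted
    share of modal label t among children belonging to true class s:
    ``sum_i p_is 1[N_i = t] / sum_i p_is``.  Logits are floored at 1e-8 on q.
    """
    post = np.asarray(posteriors, dtype=float)
    if post.ndim != 2:
        raise ValueError("posteriors must be a children x K matrix")
    if not np.allclose(post.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("posterior rows must sum to 1")
    n, K = post.shape
    modal = post.argmax(axis=1)  # argmax takes the first (lowest) index on ties
    counts = np.bincount(modal, minlength=K)
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        raise ValueError(f"modal class {int(empty[0]) + 1} is empty")
    ind = np.zeros((n, K))
    ind[np.arange(n), modal] = 1.0
    Q = (post.T @ ind) / post.sum(axis=0)[:, None]
    qf = np.maximum(Q, Q_FLOOR)
    logits = np.log(qf) - np.log(qf[:, -1])[:, None]
    return StepThreeAssignment(modal=modal, Q=Q, logits=logits, counts=counts)


def _measurement_matrix(assignment: StepThreeAssignment) -> np.ndarray:
    """(children x K) matrix of q_{s, N_i}, floored."""
    qf = np.maximum(assignment.Q, Q_FLOOR)
    return qf[:, assignment.modal].T


# ---------------------------------------------------------------------------
# generic latent-class structural likelihood
# ---------------------------------------------------------------------------

class _Layout:
    """Bookkeeping between the flat optimizer vector and model matrices.

    Parameters are the multinomial coefficient matrix A ((K-1) x (1+P),
    intercept first; class 1 is the reference), optionally class outcome
    means m (or one pooled mean), direct slopes delta and log variance.
    Boolean masks pin coefficients at zero.
    """

    def __init__(self, K, P, with_y, means_equal=False,
                 A_mask=None, delta_mask=None):
        self.K, self.P, self.with_y = K, P, with_y
        self.means_equal = means_equal
        D = 1 + P
        self.A_mask = np.ones((K - 1, D), bool) if A_mask is None else A_mask
        self.delta_mask = (np.ones(P, bool) if delta_mask is None else delta_mask) if with_y else np.zeros(P, bool)
        self.n_mean = (1 if means_equal else K) if with_y else 0
        self.size = int(self.A_mask.sum()) + self.n_mean + int(self.delta_mask.sum()) + (1 if with_y else 0)

    def unpack(self, params):
        D = 1 + self.P
        A = np.zeros((self.K - 1, D))
        i = int(self.A_mask.sum())
        A[self.A_mask] = params[:i]
        m = delta = logv = None
        if self.with_y:
            if self.means_equal:
                m = np.full(self.K, params[i])
                i += 1
            else:
                m = params[i:i + self.K]
                i += self.K
            delta = np.zeros(self.P)
            nd = int(self.delta_mask.sum())
            delta[self.delta_mask] = params[i:i + nd]
            i += nd
            logv = params[i]
        return A, m, delta, logv

    def pack_grad(self, gA, gm, gdelta, glogv):
        parts = [gA[self.A_mask]]
        if self.with_y:
            parts.append(np.array([gm.sum()]) if self.means_equal else gm)
            parts.append(gdelta[self.delta_mask])
            parts.append(np.array([glogv]))
        return np.concatenate(parts)


def _negll_grad(params, layout, Xt, y, Wq):
    """Negative log-likelihood and gradient of the fixed-error model.

    ``Xt`` is the (n x (1+P)) design with a leading 1 column, ``Wq`` the
    (n x K) matrix of q_{s, N_i}.
    """
    A, m, delta, logv = layout.unpack(params)
    n, K = Wq.shape
    eta = np.concatenate([np.zeros((n, 1)), Xt @ A.T], axis=1)
    eta -= eta.max(axis=1, keepdims=True)
    expeta = np.exp(eta)
    pi = expeta / expeta.sum(axis=1, keepdims=True)

    logjoint = np.log(pi) + np.log(Wq)
    if layout.with_y:
        v = np.exp(logv)
        mu = m[None, :] + (Xt[:, 1:] @ delta)[:, None]
        resid = y[:, None] - mu
        logjoint = logjoint + (-0.5 * (np.log(2 * np.pi * v) + resid**2 / v))
    mx = logjoint.max(axis=1, keepdims=True)
    lse = mx[:, 0] + np.log(np.exp(logjoint - mx).sum(axis=1))
    ll = float(lse.sum())
    w = np.exp(logjoint - lse[:, None])  # n x K posterior

    gA = (w - pi)[:, 1:].T @ Xt  # (K-1) x D
    gm = gdelta = glogv = None
    if layout.with_y:
        wr = w * resid / v
        gm = wr.sum(axis=0)
        gdelta = Xt[:, 1:].T @ wr.sum(axis=1)
        glogv = float((w * (-0.5 + 0.5 * resid**2 / v)).sum())
        grad = layout.pack_grad(gA, gm, gdelta, glogv)
    else:
        grad = layout.pack_grad(gA, None, None, None)
    return -ll, -grad


def _fit(layout, Xt, y, Wq, x0=None, ridge=0.0):
    if x0 is None:
        x0 = np.zeros(layout.size)
        if layout.with_y:
            # start means at the outcome mean and logv at its log-variance
            i = int(layout.A_mask.sum())
            x0[i:i + layout.n_mean] = float(np.mean(y))
            x0[-1] = np.log(max(np.var(y), 1e-8))

    def obj(p):
        f, g = _negll_grad(p, layout, Xt, y, Wq)
        if ridge > 0:
            # penalize multinomial slopes only (not intercepts/means)
            A, _, _, _ = layout.unpack(p)
            pen_mask = layout.A_mask.copy()
            pen_mask[:, 0] = False
            f += 0.5 * ridge * float((A[pen_mask] ** 2).sum())
            gpen = np.zeros_like(A)
            gpen[pen_mask] = ridge * A[pen_mask]
            g += layout.pack_grad(
                gpen,
                np.zeros(layout.K) if layout.with_y else None,
                np.zeros(layout.P) if layout.with_y else None,
                0.0,
            )
        return f, g

    res = minimize(obj, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 5000, "ftol": 1e-13, "gtol": 1e-8})
    if not res.success and np.linalg.norm(res.jac) > 1e-3 * max(1, Wq.shape[0]):
        raise RuntimeError(f"structural model did not converge: {res.message}")
    return res.x, -res.fun


def _hessian(params, layout, Xt, y, Wq):
    """Observed information by central differences of the analytic gradient."""
    p = np.asarray(params, dtype=float)
    H = np.empty((p.size, p.size))
    for j in range(p.size):
        h = 1e-5 * (1.0 + abs(p[j]))
        pp, pm = p.copy(), p.copy()
        pp[j] += h
        pm[j] -= h
        _, gp = _negll_grad(pp, layout, Xt, y, Wq)
        _, gm_ = _negll_grad(pm, layout, Xt, y, Wq)
        H[:, j] = (gp - gm_) / (2 * h)
    return 0.5 * (H + H.T)


def _design(X, n):
    if X is None:
        return np.ones((n, 1)), 0
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != n:
        X = X.T
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) < X.shape[1] + 1:
        raise ValueError("rank-deficient predictor matrix")
    return np.column_stack([np.ones(n), X]), X.shape[1]


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class PredictorEffect:
    """Unadjusted multinomial effect of one predictor on class membership."""

    gamma: np.ndarray  # length K, reference class 1 fixed at 0 (raw scale)
    std_gamma: np.ndarray  # gamma scaled by the predictor's sample SD
    chi2: float
    df: int
    p_value: float
    omega: float
    cov_std: np.ndarray  # (K-1) x (K-1) covariance of standardized gamma_2..K
    sd_x: float
    penalized: bool = False


@dataclass
class DistalEffect:
    """Class-specific means of a distal outcome under fixed measurement error."""

    class_means: np.ndarray
    sigma2_within: float
    total_var: float
    r: float
    std_diffs: np.ndarray  # (m_k - m_1) / SD_y
    chi2: float
    df: int
    p_value: float
    mean_cov: np.ndarray  # K x K covariance of the class means
    sd_y: float

    def pairwise_tests(self):
        """All K(K-1)/2 Wald contrasts on the standardized-difference scale."""
        K = len(self.class_means)
        out = []
        for a in range(K):
            for b in range(a + 1, K):
                diff = self.class_means[a] - self.class_means[b]
                se = np.sqrt(
                    self.mean_cov[a, a] + self.mean_cov[b, b] - 2 * self.mean_cov[a, b]
                )
                zval = diff / se if se > 0 else np.nan
                out.append({
                    "class_a": a + 1, "class_b": b + 1,
                    "std_diff": diff / self.sd_y,
                    "z": zval, "p": 2 * stats.norm.sf(abs(zval)),
                })
        return out


@dataclass
class AdjustedModel:
    """Simultaneous predictors -> class -> outcome model."""

    Gamma: np.ndarray  # (K-1) x P multinomial slopes (raw scale)
    std_Gamma: np.ndarray  # scaled by predictor sample SDs
    intercepts: np.ndarray  # K-1 multinomial intercepts
    class_means: np.ndarray | None
    direct: np.ndarray | None  # raw direct predictor -> outcome slopes
    std_direct: np.ndarray | None
    sigma2: float | None
    loglik: float
    n: int
    predictor_lrt: dict = field(default_factory=dict)  # name -> (chi2, df, p, omega)
    trajectory_lrt: tuple | None = None  # (chi2, df, p, r)
    sd_x: np.ndarray | None = None
    sd_y: float | None = None
    std_diffs: np.ndarray | None = None


# ---------------------------------------------------------------------------
# fitting operations
# ---------------------------------------------------------------------------

def fit_step3_predictor(assignment: StepThreeAssignment, x) -> PredictorEffect:
    """Unadjusted multinomial logistic effect of one predictor on class.

    The class is measured by the modal label through the fixed error matrix;
    the likelihood ``prod_i sum_s P(C=s | x_i) q_{s, N_i}`` is maximized
    directly.  The overall test is the LRT against the zero-slope model
    (df = K - 1) and the effect size is Cohen's omega ``sqrt(chi2 / n)``.
    Detected separation (any slope beyond 10 on the logit scale) triggers a
    lightly ridge-penalized refit, flagged on the result.
    """
    x = np.asarray(x, dtype=float)
    if np.std(x) == 0:
        raise ValueError("predictor is constant")
    Wq = _measurement_matrix(assignment)
    n, K = Wq.shape
    Xt, _ = _design(x.reshape(-1, 1), n)

    lay_full = _Layout(K, 1, with_y=False)
    mask0 = np.ones((K - 1, 2), bool)
    mask0[:, 1] = False
    lay_null = _Layout(K, 1, with_y=False, A_mask=mask0)

    p_null, ll_null = _fit(lay_null, Xt, None, Wq)
    p_full, ll_full = _fit(lay_full, Xt, None, Wq)

    A, *_ = lay_full.unpack(p_full)
    penalized = False
    if np.abs(A[:, 1]).max() > 10:
        p_full, ll_full = _fit(lay_full, Xt, None, Wq, ridge=1e-3)
        A, *_ = lay_full.unpack(p_full)
        penalized = True

    chi2 = max(0.0, 2.0 * (ll_full - ll_null))
    df = K - 1
    pval = float(stats.chi2.sf(chi2, df))
    sd_x = float(np.std(x, ddof=1))
    gamma = np.concatenate([[0.0], A[:, 1]])

    H = _hessian(p_full, lay_full, Xt, None, Wq)
    cov = np.linalg.pinv(H)
    # slope positions within the packed vector: A is packed row-major over the mask
    pos = np.flatnonzero(np.array([[False, True]] * (K - 1)).ravel()[lay_full.A_mask.ravel()])
    cov_slopes = cov[np.ix_(pos, pos)]

    return PredictorEffect(
        gamma=gamma,
        std_gamma=gamma * sd_x,
        chi2=chi2,
        df=df,
        p_value=pval,
        omega=pseudo_r(chi2, n),
        cov_std=cov_slopes * sd_x**2,
        sd_x=sd_x,
        penalized=penalized,
    )


def fit_step3_distal(assignment: StepThreeAssignment, y) -> DistalEffect:
    """Class-specific distal-outcome means under fixed measurement error.

    Within-class Normal with a common variance; the overall effect is the
    LRT against equal means (df = K - 1) and
    ``R = sqrt(1 - within / total variance)``.  Standardized mean
    differences use the total-sample SD of the outcome, so class 1 (the
    reference) is exactly 0.
    """
    y = np.asarray(y, dtype=float)
    Wq = _measurement_matrix(assignment)
    n, K = Wq.shape
    if len(y) != n:
        raise ValueError("outcome length mismatch")
    Xt, _ = _design(None, n)

    lay_full = _Layout(K, 0, with_y=True)
    lay_null = _Layout(K, 0, with_y=True, means_equal=True)
    p_null, ll_null = _fit(lay_null, Xt, y, Wq)
    # start the full fit from modal-class means
    x0 = np.zeros(lay_full.size)
    i = K - 1
    means0 = np.array([
        y[assignment.modal == k].mean() if (assignment.modal == k).any() else y.mean()
        for k in range(K)
    ])
    x0[i:i + K] = means0
    x0[-1] = np.log(max(np.var(y), 1e-8))
    p_full, ll_full = _fit(lay_full, Xt, y, Wq, x0=x0)

    _, m, _, logv = lay_full.unpack(p_full)
    v = float(np.exp(logv))
    chi2 = max(0.0, 2.0 * (ll_full - ll_null))
    df = K - 1
    total = float(np.var(y))
    sd_y = float(np.std(y, ddof=1))
    r = float(np.sqrt(max(0.0, 1.0 - v / total)))

    H = _hessian(p_full, lay_full, Xt, y, Wq)
    cov = np.linalg.pinv(H)
    mean_pos = np.arange(K - 1, K - 1 + K)
    mean_cov = cov[np.ix_(mean_pos, mean_pos)]

    return DistalEffect(
        class_means=np.asarray(m),
        sigma2_within=v,
        total_var=total,
        r=r,
        std_diffs=(m - m[0]) / sd_y,
        chi2=chi2,
        df=df,
        p_value=float(stats.chi2.sf(chi2, df)),
        mean_cov=mean_cov,
        sd_y=sd_y,
    )


def fit_adjusted(
    assignment: StepThreeAssignment,
    X,
    y=None,
    predictor_names=None,
    direct_zero=(),
    lrt_predictors=True,
) -> AdjustedModel:
    """Fully adjusted simultaneous model.

    All predictors -> class multinomial paths, class -> outcome means and
    direct predictor -> outcome paths are estimated jointly with the
    classification error fixed.  ``y=None`` fits the class side only.
    ``direct_zero`` lists predictor indices whose direct path is constrained
    to zero (the published rule against adjusted sign reversals).  Each
    predictor's overall class effect is tested by an LRT that zeroes its
    K - 1 multinomial slopes (df = K - 1); with an outcome, the overall
    trajectory effect is the LRT against equal class means.
    """
    Wq = _measurement_matrix(assignment)
    n, K = Wq.shape
    Xt, P = _design(X, n)
    if P == 0:
        raise ValueError("at least one predictor required")
    names = list(predictor_names) if predictor_names is not None else [f"x{j+1}" for j in range(P)]
    yv = None if y is None else np.asarray(y, dtype=float)

    delta_mask = np.ones(P, bool)
    for j in direct_zero:
        delta_mask[j] = False
    lay = _Layout(K, P, with_y=yv is not None, delta_mask=delta_mask)
    p_hat, ll = _fit(lay, Xt, yv, Wq)
    A, m, delta, logv = lay.unpack(p_hat)

    sd_x = np.std(Xt[:, 1:], axis=0, ddof=1)
    result = AdjustedModel(
        Gamma=A[:, 1:],
        std_Gamma=A[:, 1:] * sd_x[None, :],
        intercepts=A[:, 0],
        class_means=None if yv is None else np.asarray(m),
        direct=None if yv is None else delta,
        std_direct=None,
        sigma2=None if yv is None else float(np.exp(logv)),
        loglik=ll,
        n=n,
        sd_x=sd_x,
    )
    if yv is not None:
        sd_y = float(np.std(yv, ddof=1))
        result.sd_y = sd_y
        result.std_direct = delta * sd_x / sd_y
        result.std_diffs = (m - m[0]) / sd_y

    if lrt_predictors:
        for j, name in enumerate(names):
            mask = np.ones((K - 1, 1 + P), bool)
            mask[:, 1 + j] = False
            lay0 = _Layout(K, P, with_y=yv is not None, delta_mask=delta_mask, A_mask=mask)
            _, ll0 = _fit(lay0, Xt, yv, Wq)
            chi2 = max(0.0, 2.0 * (ll - ll0))
            result.predictor_lrt[name] = {
                "chi2": chi2,
                "df": K - 1,
                "p": float(stats.chi2.sf(chi2, K - 1)),
                "omega": pseudo_r(chi2, n),
            }

    if yv is not None:
        lay_eq = _Layout(K, P, with_y=True, delta_mask=delta_mask, means_equal=True)
        _, ll_eq = _fit(lay_eq, Xt, yv, Wq)
        chi2 = max(0.0, 2.0 * (ll - ll_eq))
        r = float(np.sqrt(max(0.0, 1.0 - np.exp(logv) / np.var(yv))))
        result.trajectory_lrt = (chi2, K - 1, float(stats.chi2.sf(chi2, K - 1)), r)
    return result


# ---------------------------------------------------------------------------
# effect-size and contrast algebra
# ---------------------------------------------------------------------------

def pseudo_r(chi2: float, n: int) -> float:
    """Cohen's omega / pseudo-R for an overall class test: sqrt(chi2 / n)."""
    if chi2 < 0:
        raise ValueError("chi2 must be non-negative")
    if n <= 0:
        raise ValueError("n must be positive")
    return float(np.sqrt(chi2 / n))


def pairwise_contrast(effect: PredictorEffect, k1: int, k2: int):
    """Contrast between classes k1 and k2 (1-based) by subtraction.

    Coefficients are on the standardized log-odds scale relative to class 1,
    so the contrast is ``coef(k1) - coef(k2)``; the Wald SE comes from the
    coefficient covariance.  Returns (contrast, se, z, p).
    """
    K = len(effect.std_gamma)
    for k in (k1, k2):
        if not 1 <= k <= K:
            raise ValueError(f"class {k} outside 1..{K}")
    coef = effect.std_gamma
    contrast = float(coef[k1 - 1] - coef[k2 - 1])

    def basis(k):
        e = np.zeros(K - 1)
        if k >= 2:
            e[k - 2] = 1.0
        return e

    c = basis(k1) - basis(k2)
    var = float(c @ effect.cov_std @ c)
    se = float(np.sqrt(max(var, 0.0)))
    if se > 0:
        z = contrast / se
        p = float(2 * stats.norm.sf(abs(z)))
    else:
        z, p = (0.0, 1.0) if contrast == 0 else (np.inf, 0.0)
    return contrast, se, z, p


def odds_ratio(coef: float) -> float:
    """Odds ratio implied by a log-odds contrast coefficient."""
    if not np.isfinite(coef):
        raise ValueError("coefficient must be finite")
    return float(np.exp(coef))


def standardized_outcome_regression(x, y) -> float:
    """Fully standardized OLS slope of y on x (slope times SD_x / SD_y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sx, sy = np.std(x, ddof=1), np.std(y, ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance input")
    slope = np.cov(x, y, ddof=1)[0, 1] / sx**2
    return float(slope * sx / sy)
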