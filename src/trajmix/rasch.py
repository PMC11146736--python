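"""Rasch / partial-credit measurement of the aggression instrument.

The instrument has seven physical-aggression behaviors (hit, push, pull-hair,
pinch, throw, bite, kick) administered in two response formats: a 7-point
frequency scale on the questionnaire waves and a yes/no format on the phone
waves.  Both formats are calibrated concurrently on one latent scale so that
person locations from either format are directly comparable:

- binary items follow the dichotomous Rasch model
  ``P(x=1 | theta) = logistic(theta - b_i)``;
- 7-category items follow the partial-credit model
  ``P(x=c | theta) proportional to exp(sum_{s=2..c} (theta - tau_is))``.

Calibration maximizes the marginal likelihood under a Normal latent
distribution integrated by Gauss-Hermite quadrature.  Identification fixes
the grand mean of item locations (binary difficulties pooled with polytomous
threshold means) to zero, with the latent mean estimated freely.  Person
scoring uses Warm's weighted-likelihood estimator, which stays finite for
all-minimum / all-maximum response patterns.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize
from scipy.special import expit, logsumexp

logger = logging.getLogger(__name__)

BEHAVIORS = ("hit", "push", "pull_hair", "pinch", "throw", "bite", "kick")
N_CATEGORIES = 7  # categories 1..7 on the frequency format


@dataclass
class ItemBank:
    """Calibrated item parameters for both response formats.

    ``b`` holds binary difficulties (logits) and ``tau`` the 6 partial-credit
    thresholds per 7-category item; NaN marks items dropped for zero
    variance.  ``latent_mean`` / ``latent_sd`` describe the calibration
    population on the identified scale.
    """

    behaviors: tuple[str, ...] = BEHAVIORS
    b: np.ndarray = field(default_factory=lambda: np.zeros(len(BEHAVIORS)))
    tau: np.ndarray = field(default_factory=lambda: np.zeros((len(BEHAVIORS), N_CATEGORIES - 1)))
    latent_mean: float = 0.0
    latent_sd: float = 1.0

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        if self.b.shape != (len(self.behaviors),):
            raise ValueError("b must have one difficulty per behavior")
        if self.tau.shape != (len(self.behaviors), N_CATEGORIES - 1):
            raise ValueError("tau must be items x 6 thresholds")
        if not np.all(np.isfinite(self.b[~np.isnan(self.b)])):
            raise ValueError("non-finite difficulty")

    # --- response-model probabilities -------------------------------------
    def binary_logprob(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(items x nodes) log P(x=1) and log P(x=0)."""
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        eta = theta[None, :] - self.b[:, None]
        # stable log-logistic
        lp1 = -np.logaddexp(0.0, -eta)
        lp0 = -np.logaddexp(0.0, eta)
        return lp1, lp0

    def pcm_logprob(self, theta: np.ndarray) -> np.ndarray:
        """(items x nodes x categories) partial-credit log-probabilities."""
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        c = np.arange(N_CATEGORIES)  # c-1 in 0..6
        # cumulative thresholds T_c = sum_{s<=c} tau_s, T_1 = 0
        T = np.concatenate([np.zeros((len(self.behaviors), 1)), np.cumsum(self.tau, axis=1)], axis=1)
        eta = c[None, None, :] * theta[None, :, None] - T[:, None, :]
        return eta - logsumexp(eta, axis=2, keepdims=True)

    def to_json(self) -> str:
        return json.dumps(
            {
                "behaviors": list(self.behaviors),
                "b": self.b.tolist(),
                "tau": self.tau.tolist(),
                "latent_mean": self.latent_mean,
                "latent_sd": self.latent_sd,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ItemBank":
        d = json.loads(text)
        return cls(
            behaviors=tuple(d["behaviors"]),
            b=np.asarray(d["b"]),
            tau=np.asarray(d["tau"]),
            latent_mean=d["latent_mean"],
            latent_sd=d["latent_sd"],
        )


@dataclass
class PersonLocation:
    """Per-occasion latent aggression estimate."""

    child_id: object
    age: float
    theta: float
    se: float
    extreme_flag: bool


# ---------------------------------------------------------------------------
# response-table plumbing
# ---------------------------------------------------------------------------

def _item_columns(behaviors) -> list[str]:
    return [f"item_{b}" for b in behaviors]


def _split_formats(responses: pd.DataFrame, behaviors):
    """Binary and 7-category response matrices (NaN = missing)."""
    cols = _item_columns(behaviors)
    missing_cols = [c for c in cols if c not in responses.columns]
    if missing_cols:
        raise ValueError(f"response table lacks item columns {missing_cols}")
    fmt = responses["format"].astype(str).values
    Xb = responses.loc[fmt == "binary", cols].to_numpy(dtype=float)
    Xp = responses.loc[fmt == "7cat", cols].to_numpy(dtype=float)
    if Xb.size and np.nanmax(Xb) > 1:
        raise ValueError("binary responses must be 0/1")
    if Xp.size and (np.nanmin(Xp) < 1 or np.nanmax(Xp) > N_CATEGORIES):
        raise ValueError(f"7-category responses must be in 1..{N_CATEGORIES}")
    return Xb, Xp


def _gauss_hermite(n_nodes: int):
    """Nodes/weights for integrating against a standard Normal."""
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    return x * np.sqrt(2.0), w / np.sqrt(np.pi)


# ---------------------------------------------------------------------------
# marginal likelihood and calibration
# ---------------------------------------------------------------------------

def _pattern_loglik(bank: ItemBank, theta: np.ndarray, Xb: np.ndarray, Xp: np.ndarray):
    """Per-person x per-node response log-likelihood for both formats.

    Returns (ll_b, ll_p): matrices (n_binary_persons x nodes) and
    (n_poly_persons x nodes).
    """
    lp1, lp0 = bank.binary_logprob(theta)
    est_b = np.isfinite(bank.b)
    lp1 = np.where(est_b[:, None], lp1, 0.0)
    lp0 = np.where(est_b[:, None], lp0, 0.0)
    Mb = ~np.isnan(Xb) & est_b[None, :]
    Xb0 = np.where(Mb, Xb, 0.0)
    ll_b = Xb0 @ lp1 + (Mb & (Xb0 == 0)) @ lp0

    LP = bank.pcm_logprob(theta)  # items x nodes x cats
    est_p = np.isfinite(bank.tau).all(axis=1)
    LP = np.where(est_p[:, None, None], LP, 0.0)
    Mp = ~np.isnan(Xp) & est_p[None, :]
    codes = np.where(Mp, Xp - 1, 0).astype(int)
    ll_p = np.zeros((Xp.shape[0], len(theta)))
    for i in range(LP.shape[0]):
        contrib = LP[i][:, codes[:, i]].T  # persons x nodes
        ll_p += np.where(Mp[:, i][:, None], contrib, 0.0)
    return ll_b, ll_p


def marginal_loglik(bank: ItemBank, responses: pd.DataFrame, n_nodes: int = 61) -> float:
    """Marginal log-likelihood of the response table under the bank.

    Integrates the latent trait against Normal(latent_mean, latent_sd) with
    ``n_nodes`` Gauss-Hermite nodes.
    """
    z, w = _gauss_hermite(n_nodes)
    theta = bank.latent_mean + bank.latent_sd * z
    Xb, Xp = _split_formats(responses, bank.behaviors)
    ll_b, ll_p = _pattern_loglik(bank, theta, Xb, Xp)
    logw = np.log(w)
    total = 0.0
    if ll_b.size:
        total += float(np.sum(logsumexp(ll_b + logw, axis=1)))
    if ll_p.size:
        total += float(np.sum(logsumexp(ll_p + logw, axis=1)))
    return total


class CalibrationError(RuntimeError):
    pass


def calibrate_items(
    responses: pd.DataFrame,
    behaviors=BEHAVIORS,
    n_nodes: int = 61,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> ItemBank:
    """Concurrent marginal-ML calibration of both formats.

    Parameters
    ----------
    responses : DataFrame
        One row per measurement occasion with a ``format`` column
        (``binary`` / ``7cat``) and item columns ``item_<behavior>``
        (binary 0/1 or categories 1..7; NaN = not administered).
    n_nodes : int
        Gauss-Hermite nodes for the latent integral.
    tol : float
        Convergence tolerance on the (scaled) gradient.

    Returns the :class:`ItemBank` on the identified scale (grand mean of
    item locations zero).  Items with zero response variance are dropped
    (their parameters are NaN) with a warning.
    """
    behaviors = tuple(behaviors)
    n_items = len(behaviors)
    Xb, Xp = _split_formats(responses, behaviors)

    def _active(X, poly):
        act = []
        for i in range(n_items):
            col = X[:, i]
            col = col[~np.isnan(col)]
            if col.size >= 2 and np.nanvar(col) > 0:
                act.append(i)
            elif col.size:
                warnings.warn(
                    f"{'7cat' if poly else 'binary'} item {behaviors[i]!r} has zero "
                    "response variance and is dropped from calibration"
                )
        return np.array(act, dtype=int)

    act_b = _active(Xb, poly=False) if Xb.size else np.array([], dtype=int)
    act_p = _active(Xp, poly=True) if Xp.size else np.array([], dtype=int)
    if len(act_b) + len(act_p) < 2:
        raise CalibrationError("need at least two items with response variance")

    Xb = Xb[:, act_b] if Xb.size else np.empty((0, 0))
    Xp = Xp[:, act_p] if Xp.size else np.empty((0, 0))
    Mb, Mp = ~np.isnan(Xb), ~np.isnan(Xp)
    Xb0 = np.where(Mb, Xb, 0.0)
    # drop all-missing occasions per format block
    keep_b = Mb.any(axis=1) if Xb.size else np.array([], dtype=bool)
    keep_p = Mp.any(axis=1) if Xp.size else np.array([], dtype=bool)
    Xb, Mb, Xb0 = Xb[keep_b], Mb[keep_b], Xb0[keep_b]
    Xp, Mp = Xp[keep_p], Mp[keep_p]
    codes = np.where(Mp, Xp - 1, 0).astype(int) if Xp.size else np.empty((0, 0), int)

    nb, npoly = len(act_b), len(act_p)
    z, w = _gauss_hermite(n_nodes)
    logw = np.log(w)
    c_range = np.arange(N_CATEGORIES)

    # sufficient statistics that do not depend on parameters
    S_b = (Xb0 * Mb).sum(axis=0) if nb else np.zeros(0)  # sum of 1-responses per item
    # N_is = count of observed responses >= s (s = 2..7) per poly item
    if npoly:
        N_ge = np.stack(
            [((Xp >= s) & Mp).sum(axis=0) for s in range(2, N_CATEGORIES + 1)], axis=1
        ).astype(float)
    else:
        N_ge = np.zeros((0, N_CATEGORIES - 1))

    def unpack(params):
        b = params[:nb]
        tau = params[nb : nb + npoly * (N_CATEGORIES - 1)].reshape(npoly, N_CATEGORIES - 1)
        sigma = np.exp(params[-1])
        return b, tau, sigma

    def negloglik_grad(params):
        b, tau, sigma = unpack(params)
        theta = sigma * z  # latent mean fixed at 0 during optimization

        # binary probabilities at nodes
        if nb:
            eta = theta[None, :] - b[:, None]
            p1 = expit(eta)
            lp1 = -np.logaddexp(0.0, -eta)
            lp0 = -np.logaddexp(0.0, eta)
            ll_b = Xb0 @ lp1 + ((~ (Xb0.astype(bool))) & Mb) @ lp0
        else:
            ll_b = np.empty((0, n_nodes))

        if npoly:
            T = np.concatenate([np.zeros((npoly, 1)), np.cumsum(tau, axis=1)], axis=1)
            etap = c_range[None, None, :] * theta[None, :, None] - T[:, None, :]
            LP = etap - logsumexp(etap, axis=2, keepdims=True)
            P = np.exp(LP)  # items x nodes x cats
            m1 = (P * c_range).sum(axis=2)  # mean of (c-1)
            # upper-tail probabilities P(x >= s), s=2..7
            Pge = np.cumsum(P[:, :, ::-1], axis=2)[:, :, ::-1][:, :, 1:]
            ll_p = np.zeros((Xp.shape[0], n_nodes))
            for i in range(npoly):
                contrib = LP[i][:, codes[:, i]].T
                ll_p += np.where(Mp[:, i][:, None], contrib, 0.0)
        else:
            ll_p = np.empty((0, n_nodes))

        # gradient of the POSITIVE marginal log-likelihood, negated on return
        ll = 0.0
        grads = np.zeros_like(params)
        d_sigma = 0.0

        if nb:
            post_b = ll_b + logw
            norm_b = logsumexp(post_b, axis=1)
            ll += float(norm_b.sum())
            Wb = np.exp(post_b - norm_b[:, None])  # persons x nodes, rows sum to 1
            A_b = Mb.T @ Wb  # items x nodes: expected exposure per node
            grads[:nb] = (p1 * A_b).sum(axis=1) - S_b  # E[p - x] per item
            # d/dtheta of binary loglik summed over items, per person-node
            u_b = Xb0.sum(axis=1)[:, None] - Mb @ p1
            d_sigma += float(np.sum(Wb * z[None, :] * u_b))

        if npoly:
            post_p = ll_p + logw
            norm_p = logsumexp(post_p, axis=1)
            ll += float(norm_p.sum())
            Wp = np.exp(post_p - norm_p[:, None])
            A_p = Mp.T @ Wp  # items x nodes
            g_tau = np.einsum("iq,iqs->is", A_p, Pge) - N_ge
            grads[nb : nb + npoly * (N_CATEGORIES - 1)] = g_tau.ravel()
            u_p = np.where(Mp, Xp - 1, 0.0).sum(axis=1)[:, None] - Mp @ m1
            d_sigma += float(np.sum(Wp * z[None, :] * u_p))

        grads[-1] = d_sigma * sigma  # chain rule for log sigma
        return -ll, -grads

    x0 = np.zeros(nb + npoly * (N_CATEGORIES - 1) + 1)
    res = minimize(
        negloglik_grad,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": tol, "ftol": 1e-12},
    )
    if not res.success and np.linalg.norm(res.jac) > 1e-2 * max(1, len(responses)):
        raise CalibrationError(
            f"calibration did not converge: {res.message} (|grad| = {np.linalg.norm(res.jac):.3g})"
        )

    b_hat, tau_hat, sigma_hat = unpack(res.x)

    # identify the scale: grand mean of item locations = 0
    locations = np.concatenate([b_hat, tau_hat.mean(axis=1) if npoly else np.zeros(0)])
    shift = float(locations.mean())

    b_full = np.full(n_items, np.nan)
    tau_full = np.full((n_items, N_CATEGORIES - 1), np.nan)
    b_full[act_b] = b_hat - shift
    tau_full[act_p] = tau_hat - shift
    return ItemBank(
        behaviors=behaviors,
        b=b_full,
        tau=tau_full,
        latent_mean=-shift,
        latent_sd=float(sigma_hat),
    )


# ---------------------------------------------------------------------------
# person scoring (weighted likelihood)
# ---------------------------------------------------------------------------

def _item_moments(bank: ItemBank, theta: float, bin_items, poly_items):
    """Score residual pieces, information and its derivative at theta.

    For the Rasch family the item score is the natural sufficient statistic,
    so the information is the score variance and its theta-derivative is the
    third central moment.
    """
    mean_parts, info, dinfo = [], 0.0, 0.0
    if len(bin_items):
        p = expit(theta - bank.b[bin_items])
        mean_parts.append(p)
        v = p * (1 - p)
        info += v.sum()
        dinfo += (v * (1 - 2 * p)).sum()
    if len(poly_items):
        LP = bank.pcm_logprob(np.array([theta]))[poly_items, 0, :]  # items x cats
        P = np.exp(LP)
        c = np.arange(N_CATEGORIES)
        m1 = (P * c).sum(axis=1)
        m2 = (P * c**2).sum(axis=1)
        m3 = (P * c**3).sum(axis=1)
        mean_parts.append(m1)
        v = m2 - m1**2
        info += v.sum()
        dinfo += (m3 - 3 * m1 * m2 + 2 * m1**3).sum()
    return mean_parts, info, dinfo


def _wle_equation(theta, x_bin, bin_items, x_poly, poly_items, bank):
    means, info, dinfo = _item_moments(bank, theta, bin_items, poly_items)
    score = 0.0
    idx = 0
    if len(bin_items):
        score += float(np.sum(x_bin - means[idx]))
        idx += 1
    if len(poly_items):
        score += float(np.sum((x_poly - 1) - means[idx]))
    return score + dinfo / (2.0 * info)


def score_persons(bank: ItemBank, responses: pd.DataFrame) -> list[PersonLocation]:
    """Weighted-likelihood person locations per measurement occasion.

    Occasions with all items missing are omitted with a log entry.  The
    standard error comes from the observed test information at the estimate.
    """
    cols = _item_columns(bank.behaviors)
    cache: dict = {}
    out: list[PersonLocation] = []
    estimable_b = ~np.isnan(bank.b)
    estimable_p = ~np.isnan(bank.tau).any(axis=1)

    for row in responses.itertuples(index=False):
        d = row._asdict()
        fmt = str(d["format"])
        x = np.array([d[c] for c in cols], dtype=float)
        obs = ~np.isnan(x)
        if fmt == "binary":
            obs &= estimable_b
            if x[obs].size and (np.nanmax(x[obs]) > 1 or np.nanmin(x[obs]) < 0):
                raise ValueError("binary response outside 0/1")
        elif fmt == "7cat":
            obs &= estimable_p
            if x[obs].size and (np.nanmax(x[obs]) > N_CATEGORIES or np.nanmin(x[obs]) < 1):
                raise ValueError(f"7-category response outside 1..{N_CATEGORIES}")
        else:
            raise ValueError(f"unknown format {fmt!r}")
        if not obs.any():
            logger.info(
                "occasion (child=%s, age=%s) has no scorable responses; omitted",
                d.get("child_id"), d.get("age"),
            )
            continue

        key = (fmt, tuple(np.flatnonzero(obs)), tuple(x[obs]))
        if key not in cache:
            bin_items = np.flatnonzero(obs) if fmt == "binary" else np.array([], int)
            poly_items = np.flatnonzero(obs) if fmt == "7cat" else np.array([], int)
            x_bin = x[bin_items] if len(bin_items) else np.zeros(0)
            x_poly = x[poly_items] if len(poly_items) else np.zeros(0)
            g = lambda t: _wle_equation(t, x_bin, bin_items, x_poly, poly_items, bank)
            lo, hi = -15.0, 15.0
            glo, ghi = g(lo), g(hi)
            while glo < 0 and lo > -60:  # expand if needed; WLE score decreases in theta
                lo *= 2
                glo = g(lo)
            while ghi > 0 and hi < 60:
                hi *= 2
                ghi = g(hi)
            theta_hat = brentq(g, lo, hi, xtol=1e-10)
            _, info, _ = _item_moments(bank, theta_hat, bin_items, poly_items)
            lo_cat = 0 if fmt == "binary" else 1
            hi_cat = 1 if fmt == "binary" else N_CATEGORIES
            extreme = bool(np.all(x[obs] == lo_cat) or np.all(x[obs] == hi_cat))
            cache[key] = (theta_hat, 1.0 / np.sqrt(info), extreme)
        theta_hat, se, extreme = cache[key]
        out.append(
            PersonLocation(
                child_id=d.get("child_id"),
                age=float(d.get("age", np.nan)),
                theta=theta_hat,
                se=se,
                extreme_flag=extreme,
            )
        )
    return out
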