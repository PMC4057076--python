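"""Bayesian two-parameter-logistic (2PL) latent-trait model of disease severity.

Rule endorsements are treated as item responses on an unobserved per-subject
severity scale theta. Each rule j carries a discrimination a_j and a
difficulty b_j through the item characteristic curve

    P(x_ij = 1 | theta_i) = 1 / (1 + exp(-a_j (theta_i - b_j))),

and onset is linked to severity by logistic regression

    P(y_i = 1 | theta_i, z_i) = sigmoid(beta0 + beta1 theta_i + gamma' z_i).

All parameters are estimated jointly by a random-walk Metropolis-within-Gibbs
sampler; severity for new subjects is inferred by deterministic quadrature
against the N(0, 1) severity prior, and onset risk is the posterior-averaged
link probability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, log_expit
from scipy.stats import norm

from .errors import ConfigError, DegenerateItemError, SchemaError
from .rules import EndorsementMatrix

__all__ = [
    "PriorSpec",
    "ItemParams",
    "OutcomeLink",
    "LatentTraitModel",
    "PosteriorSamples",
    "icc",
    "iic",
    "log_posterior",
    "fit_mcmc",
    "point_estimates",
    "infer_theta",
    "predict_risk",
    "model_to_json",
    "model_from_json",
]


# ---------------------------------------------------------------------
# 2PL curves
# ---------------------------------------------------------------------

def icc(theta, a, b):
    """Item characteristic curve: endorsement probability at severity theta.

    ``1 / (1 + exp(-a (theta - b)))``; at ``theta = b`` the probability is
    exactly one half for any discrimination. Broadcasts over inputs.
    """
    theta = np.asarray(theta, dtype=float)
    return expit(np.asarray(a, dtype=float) * (theta - np.asarray(b, dtype=float)))


def iic(theta, a, b):
    """Item information curve: Fisher information about severity.

    For the 2PL this is ``a^2 P (1 - P)`` with ``P = icc(theta, a, b)``,
    algebraically identical to ``P'^2 / (P (1 - P))`` since
    ``P' = a P (1 - P)``. Maximized at ``theta = b`` with value ``a^2 / 4``.
    """
    p = icc(theta, a, b)
    a = np.asarray(a, dtype=float)
    return a * a * p * (1.0 - p)


# ---------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    """Gaussian prior scales (all priors are mean-zero normals).

    theta ~ N(0, 1) fixes the location and scale of the severity axis (the
    standard IRT identification convention); discriminations may be
    negative, encoding risk-decreasing rules.
    """

    theta_sd: float = 1.0
    a_sd: float = 2.0
    b_sd: float = 2.0
    beta_sd: float = 10.0


@dataclass
class ItemParams:
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        if self.a.shape != self.b.shape:
            raise ConfigError("a and b must have matching shapes")
        if not (np.isfinite(self.a).all() and np.isfinite(self.b).all()):
            raise ConfigError("item parameters must be finite")

    @property
    def n_items(self) -> int:
        return self.a.size


@dataclass
class OutcomeLink:
    beta0: float
    beta1: float
    gamma: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))


@dataclass
class LatentTraitModel:
    """Point-estimate summary of the fitted model."""

    items: ItemParams
    link: OutcomeLink
    theta: np.ndarray | None = None
    theta_sd: np.ndarray | None = None
    settings: dict = field(default_factory=dict)


@dataclass
class PosteriorSamples:
    """Retained MCMC draws (burn-in already discarded)."""

    a: np.ndarray        # (R, J)
    b: np.ndarray        # (R, J)
    beta0: np.ndarray    # (R,)
    beta1: np.ndarray    # (R,)
    gamma: np.ndarray    # (R, K)
    theta: np.ndarray | None  # (R, n) or None
    n_total: int
    n_burn: int
    acceptance: dict = field(default_factory=dict)
    seed: int | None = None
    settings: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.n_burn < self.n_total:
            raise ConfigError("n_burn must be smaller than n_total")

    @property
    def n_retained(self) -> int:
        return self.a.shape[0]

    def to_csv(self, path, include_theta: bool = False) -> None:
        """Write retained draws as a flat CSV (one row per draw)."""
        import pandas as pd

        J = self.a.shape[1]
        cols = {f"a_{j}": self.a[:, j] for j in range(J)}
        cols.update({f"b_{j}": self.b[:, j] for j in range(J)})
        cols["beta0"] = self.beta0
        cols["beta1"] = self.beta1
        for k in range(self.gamma.shape[1]):
            cols[f"gamma_{k}"] = self.gamma[:, k]
        if include_theta and self.theta is not None:
            for i in range(self.theta.shape[1]):
                cols[f"theta_{i}"] = self.theta[:, i]
        pd.DataFrame(cols).to_csv(path, index_label="draw")


# ---------------------------------------------------------------------
# posterior density
# ---------------------------------------------------------------------

def _as_binary(arr, name: str) -> np.ndarray:
    a = np.asarray(arr)
    if not np.isin(a, [0, 1]).all():
        raise SchemaError(f"{name} must be binary 0/1")
    return a.astype(float)


def _item_loglik(theta, a, b, X):
    """n-vector of per-subject item log-likelihood sums."""
    S = 2.0 * X - 1.0                       # (n, J) in {-1, +1}
    T = a[None, :] * (theta[:, None] - b[None, :])
    return log_expit(S * T).sum(axis=1)


def _link_logits(theta, beta0, beta1, gamma, Z):
    eta = beta0 + beta1 * theta
    if Z is not None and gamma.size:
        eta = eta + Z @ gamma
    return eta


def log_posterior(
    theta,
    a,
    b,
    beta0,
    beta1,
    gamma=None,
    *,
    endorsements,
    outcome,
    covariates=None,
    priors: PriorSpec = PriorSpec(),
) -> float:
    """Unnormalized log posterior density of the full parameter set.

    Sum of (i) Bernoulli log-likelihood of every endorsement under the 2PL
    ICC, (ii) Bernoulli log-likelihood of the outcome under the logistic
    link, and (iii) mean-zero Gaussian log-priors with scales from
    ``priors`` (normalizing constants included, so values are comparable
    across prior settings).
    """
    X = _as_binary(getattr(endorsements, "values", endorsements), "endorsements")
    y = _as_binary(outcome, "outcome")
    theta = np.asarray(theta, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    gamma = np.zeros(0) if gamma is None else np.atleast_1d(np.asarray(gamma, dtype=float))
    Z = None if covariates is None else np.asarray(covariates, dtype=float)
    if X.shape != (theta.size, a.size):
        raise SchemaError("endorsement matrix shape inconsistent with theta/items")

    ll_items = _item_loglik(theta, a, b, X).sum()
    sy = 2.0 * y - 1.0
    ll_y = log_expit(sy * _link_logits(theta, beta0, beta1, gamma, Z)).sum()
    lp = (
        norm.logpdf(theta, scale=priors.theta_sd).sum()
        + norm.logpdf(a, scale=priors.a_sd).sum()
        + norm.logpdf(b, scale=priors.b_sd).sum()
        + norm.logpdf(beta0, scale=priors.beta_sd)
        + norm.logpdf(beta1, scale=priors.beta_sd)
        + norm.logpdf(gamma, scale=priors.beta_sd).sum()
    )
    return float(ll_items + ll_y + lp)


# ---------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------

def _check_items(X: np.ndarray):
    means = X.mean(axis=0)
    bad = np.where((means == 0) | (means == 1))[0]
    if bad.size:
        raise DegenerateItemError(bad)


def fit_mcmc(
    endorsements,
    outcome=None,
    covariates=None,
    n_samples: int = 25000,
    n_burn: int = 5000,
    seed: int | None = None,
    priors: PriorSpec = PriorSpec(),
    joint: bool = True,
    store_theta: bool = True,
    target_accept: float = 0.3,
    adapt_interval: int = 50,
) -> PosteriorSamples:
    """Sample the joint posterior by adaptive Metropolis-within-Gibbs.

    Per sweep: all theta_i are updated by element-wise random-walk
    proposals (they are conditionally independent), each item's (a_j, b_j)
    pair is updated jointly, and the link block (beta0, beta1, gamma) is
    updated as one proposal. Scalar step sizes per block adapt during
    burn-in toward ``target_accept`` and are frozen afterwards.

    The model is invariant under the reflection
    (theta, a, b, beta1) -> (-theta, -a, -b, -beta1); each retained draw is
    flipped when needed so beta1 >= 0, making "higher severity = higher
    risk" the reporting convention. With ``joint=False`` the outcome term is
    omitted (items-only fit) and draws are instead flipped so the mean
    discrimination is nonnegative.

    Degenerate items (all-0 or all-1 columns) are rejected with their
    indices reported.
    """
    X = _as_binary(getattr(endorsements, "values", endorsements), "endorsements")
    n, J = X.shape
    if J < 2:
        raise ConfigError("need at least 2 items")
    if n < 20:
        raise ConfigError("need at least 20 subjects")
    _check_items(X)
    if joint:
        if outcome is None:
            raise ConfigError("joint fit requires an outcome vector")
        y = _as_binary(outcome, "outcome")
        sy = 2.0 * y - 1.0
    Z = None if covariates is None else np.asarray(covariates, dtype=float)
    K = 0 if Z is None else Z.shape[1]

    rng = np.random.default_rng(seed)
    S = 2.0 * X - 1.0

    # init: theta from the standardized endorsement count; item signs from
    # the point-biserial correlation with that score; difficulties matched
    # to the observed supports (expit(-a b) = support at theta = 0)
    rowscore = X.mean(axis=1)
    theta = (rowscore - rowscore.mean()) / (rowscore.std() + 1e-9)
    if joint and np.corrcoef(theta, y)[0, 1] < 0:
        theta = -theta  # orient the starting severity with the outcome
    theta += 0.01 * rng.standard_normal(n)
    p_hat = X.mean(axis=0)
    corr = ((X - p_hat) * theta[:, None]).mean(axis=0)
    a = np.where(corr >= 0, 1.0, -1.0)
    b = np.clip(-np.log(p_hat / (1.0 - p_hat)) / a, -3.0, 3.0)
    beta0, beta1 = 0.0, 0.5
    gamma = np.zeros(K)

    def item_ll_matrix(th, av, bv):
        return log_expit(S * (av[None, :] * (th[:, None] - bv[None, :])))

    L = item_ll_matrix(theta, a, b)          # (n, J)
    row_ll = L.sum(axis=1)
    if joint:
        link_ll = log_expit(sy * _link_logits(theta, beta0, beta1, gamma, Z))
    else:
        link_ll = np.zeros(n)

    s_th, s_lk = 0.5, 0.1
    s_it = np.full(J, 0.2)  # per-item step: ridge geometry differs across items
    acc = {"theta": [], "items": [], "link": []}
    win = {"theta": 0.0, "items": np.zeros(J), "link": 0.0, "n": 0}

    n_ret = n_samples - n_burn
    draws_a = np.empty((n_ret, J))
    draws_b = np.empty((n_ret, J))
    draws_b0 = np.empty(n_ret)
    draws_b1 = np.empty(n_ret)
    draws_g = np.empty((n_ret, K))
    draws_th = np.empty((n_ret, n), dtype=np.float32) if store_theta else None

    inv_th_var = 1.0 / priors.theta_sd**2
    inv_a_var = 1.0 / priors.a_sd**2
    inv_b_var = 1.0 / priors.b_sd**2
    inv_be_var = 1.0 / priors.beta_sd**2

    for it in range(n_samples):
        # -- theta block (element-wise) --------------------------------
        prop = theta + s_th * rng.standard_normal(n)
        Lp = item_ll_matrix(prop, a, b)
        row_p = Lp.sum(axis=1)
        if joint:
            link_p = log_expit(sy * _link_logits(prop, beta0, beta1, gamma, Z))
        else:
            link_p = link_ll
        delta = (row_p - row_ll) + (link_p - link_ll) \
            - 0.5 * inv_th_var * (prop**2 - theta**2)
        accept = np.log(rng.random(n)) < delta
        theta = np.where(accept, prop, theta)
        L[accept] = Lp[accept]
        row_ll = np.where(accept, row_p, row_ll)
        link_ll = np.where(accept, link_p, link_ll)
        win["theta"] += accept.mean()

        # -- item blocks (per item, vectorized) ------------------------
        ap = a + s_it * rng.standard_normal(J)
        bp = b + s_it * rng.standard_normal(J)

        Lp = item_ll_matrix(theta, ap, bp)
        col_delta = (Lp - L).sum(axis=0) \
            - 0.5 * inv_a_var * (ap**2 - a**2) - 0.5 * inv_b_var * (bp**2 - b**2)
        acc_j = np.log(rng.random(J)) < col_delta
        a = np.where(acc_j, ap, a)
        b = np.where(acc_j, bp, b)
        L[:, acc_j] = Lp[:, acc_j]
        win["items"] += acc_j

        # sign-flip involution (a_j, b_j) -> (-a_j, -b_j): lets an item
        # stuck on the wrong-sign likelihood ridge jump to the mirrored
        # ridge, which connects to its true mode
        Lp = item_ll_matrix(theta, -a, -b)
        col_delta = (Lp - L).sum(axis=0)  # priors are symmetric under the flip
        flip_j = np.log(rng.random(J)) < col_delta
        a = np.where(flip_j, -a, a)
        b = np.where(flip_j, -b, b)
        L[:, flip_j] = Lp[:, flip_j]
        row_ll = L.sum(axis=1)

        # -- link block ------------------------------------------------
        if joint:
            b0p = beta0 + s_lk * rng.standard_normal()
            b1p = beta1 + s_lk * rng.standard_normal()
            gp = gamma + s_lk * rng.standard_normal(K) if K else gamma
            link_p = log_expit(sy * _link_logits(theta, b0p, b1p, gp, Z))
            delta = (link_p.sum() - link_ll.sum()) \
                - 0.5 * inv_be_var * (b0p**2 - beta0**2 + b1p**2 - beta1**2
                                      + float(np.sum(gp**2) - np.sum(gamma**2)))
            if np.log(rng.random()) < delta:
                beta0, beta1, gamma = b0p, b1p, gp
                link_ll = link_p
                win["link"] += 1.0
        win["n"] += 1

        # -- adaptation (burn-in only) ---------------------------------
        if it < n_burn and win["n"] == adapt_interval:
            s_th = float(np.clip(
                s_th * np.exp(0.6 * (win["theta"] / adapt_interval - target_accept)),
                1e-3, 10.0))
            s_it = np.clip(
                s_it * np.exp(0.6 * (win["items"] / adapt_interval - target_accept)),
                1e-3, 10.0)
            s_lk = float(np.clip(
                s_lk * np.exp(0.6 * (win["link"] / adapt_interval - target_accept)),
                1e-3, 10.0))
            win = {"theta": 0.0, "items": np.zeros(J), "link": 0.0, "n": 0}
        elif it >= n_burn and win["n"] == adapt_interval:
            acc["theta"].append(win["theta"] / adapt_interval)
            acc["items"].append(float(np.mean(win["items"])) / adapt_interval)
            acc["link"].append(win["link"] / adapt_interval)
            win = {"theta": 0.0, "items": np.zeros(J), "link": 0.0, "n": 0}

        # -- store -----------------------------------------------------
        if it >= n_burn:
            r = it - n_burn
            flip = (beta1 < 0) if joint else (a.mean() < 0)
            sgn = -1.0 if flip else 1.0
            draws_a[r] = sgn * a
            draws_b[r] = sgn * b
            draws_b0[r] = beta0
            draws_b1[r] = sgn * beta1
            if K:
                draws_g[r] = gamma
            if store_theta:
                draws_th[r] = sgn * theta

    acceptance = {k: float(np.mean(v)) if v else float("nan") for k, v in acc.items()}
    return PosteriorSamples(
        a=draws_a,
        b=draws_b,
        beta0=draws_b0,
        beta1=draws_b1,
        gamma=draws_g,
        theta=draws_th,
        n_total=n_samples,
        n_burn=n_burn,
        acceptance=acceptance,
        seed=seed,
        settings={
            "priors": priors.__dict__.copy(),
            "joint": joint,
            "step_sizes": {"theta": s_th, "items": s_it, "link": s_lk},
            "target_accept": target_accept,
        },
    )


def point_estimates(samples: PosteriorSamples) -> LatentTraitModel:
    """Posterior means of all parameters over the retained draws."""
    if samples.n_retained == 0:
        raise ConfigError("no retained draws")
    items = ItemParams(samples.a.mean(axis=0), samples.b.mean(axis=0))
    link = OutcomeLink(
        float(samples.beta0.mean()),
        float(samples.beta1.mean()),
        samples.gamma.mean(axis=0) if samples.gamma.size else np.zeros(0),
    )
    theta = None
    theta_sd = None
    if samples.theta is not None:
        theta = samples.theta.mean(axis=0).astype(float)
        theta_sd = samples.theta.std(axis=0, ddof=1).astype(float)
    return LatentTraitModel(
        items=items,
        link=link,
        theta=theta,
        theta_sd=theta_sd,
        settings=dict(samples.settings, n_total=samples.n_total, n_burn=samples.n_burn,
                      seed=samples.seed, acceptance=samples.acceptance),
    )


# ---------------------------------------------------------------------
# inference for new subjects
# ---------------------------------------------------------------------

_GRID = np.linspace(-6.0, 6.0, 201)


def _theta_posterior_weights(model: LatentTraitModel, X: np.ndarray, grid=_GRID):
    """(n, G) normalized posterior weights of theta on the grid."""
    a, b = model.items.a, model.items.b
    P = icc(grid[:, None], a[None, :], b[None, :])          # (G, J)
    logP = np.log(np.clip(P, 1e-300, 1.0))
    logQ = np.log(np.clip(1.0 - P, 1e-300, 1.0))
    loglik = X @ logP.T + (1.0 - X) @ logQ.T                # (n, G)
    logpost = loglik + norm.logpdf(grid)[None, :]
    logpost -= logpost.max(axis=1, keepdims=True)
    w = np.exp(logpost)
    w /= w.sum(axis=1, keepdims=True)
    return w


def infer_theta(model: LatentTraitModel, endorsements_new, grid=_GRID):
    """Posterior mean and sd of severity for new subjects.

    Items are fixed at their point estimates; the severity prior is
    N(0, 1); the posterior is evaluated by deterministic quadrature on a
    201-point grid over [-6, 6]. When every item carries zero information
    (all a_j = 0) the prior is returned: mean 0, sd 1.
    """
    X = _as_binary(getattr(endorsements_new, "values", endorsements_new), "endorsements")
    if X.ndim != 2 or X.shape[1] != model.items.n_items:
        raise SchemaError(
            f"endorsement columns ({X.shape[1] if X.ndim == 2 else '?'}) do not match "
            f"model items ({model.items.n_items})"
        )
    if np.all(model.items.a == 0):
        n = X.shape[0]
        return np.zeros(n), np.ones(n)
    w = _theta_posterior_weights(model, X, grid)
    mean = w @ grid
    second = w @ (grid**2)
    sd = np.sqrt(np.maximum(second - mean**2, 0.0))
    return mean, sd


def predict_risk(
    model: LatentTraitModel,
    endorsements_new,
    covariates_new=None,
    marginalize: bool = True,
    grid=_GRID,
):
    """Per-subject onset probability.

    By default the logistic link is integrated against each subject's
    severity posterior (quadrature); ``marginalize=False`` plugs in the
    posterior-mean severity instead.
    """
    X = _as_binary(getattr(endorsements_new, "values", endorsements_new), "endorsements")
    if X.ndim != 2 or X.shape[1] != model.items.n_items:
        raise SchemaError("endorsement columns do not match model items")
    link = model.link
    offset = np.zeros(X.shape[0])
    if covariates_new is not None and link.gamma.size:
        offset = np.asarray(covariates_new, dtype=float) @ link.gamma
    if not marginalize or np.all(model.items.a == 0):
        mean, _ = infer_theta(model, X, grid)
        return expit(link.beta0 + link.beta1 * mean + offset)
    w = _theta_posterior_weights(model, X, grid)
    p_grid = expit(link.beta0 + link.beta1 * grid)          # (G,)
    base = w @ p_grid
    if np.any(offset != 0):
        # covariate offset shifts the logit; redo the integral per subject
        logits = link.beta0 + link.beta1 * grid[None, :] + offset[:, None]
        base = (w * expit(logits)).sum(axis=1)
    return base


# ---------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------

def model_to_json(model: LatentTraitModel, path=None, extra: dict | None = None) -> str:
    payload = {
        "items": [{"a": float(a), "b": float(b)} for a, b in zip(model.items.a, model.items.b)],
        "link": {
            "beta0": model.link.beta0,
            "beta1": model.link.beta1,
            "gamma": [float(g) for g in model.link.gamma],
        },
        "settings": _jsonable(model.settings),
    }
    if extra:
        payload.update(extra)
    text = json.dumps(payload, indent=2, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def model_from_json(source) -> LatentTraitModel:
    if isinstance(source, str) and source.lstrip().startswith("{"):
        payload = json.loads(source)
    else:
        with open(source) as fh:
            payload = json.load(fh)
    items = ItemParams(
        np.array([d["a"] for d in payload["items"]]),
        np.array([d["b"] for d in payload["items"]]),
    )
    link = OutcomeLink(
        float(payload["link"]["beta0"]),
        float(payload["link"]["beta1"]),
        np.asarray(payload["link"].get("gamma", []), dtype=float),
    )
    return LatentTraitModel(items=items, link=link, settings=payload.get("settings", {}))
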