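"""Marginal maximum likelihood estimation of Rasch and 2PL item models.

The TAMV-I yields, for each of six trials (four free-recall trials, one
delayed recall, one recognition), a vector of 12 dichotomous item scores.
This module fits the two classical unidimensional IRT models to one trial's
response matrix:

* Rasch (1PL): ``logit P(correct) = beta_i + beta * z`` — a per-item ease
  ``beta_i`` and one discrimination ``beta`` common to all items
  (13 free parameters for 12 items).
* 2PL: per-item slope/intercept, reported as discrimination ``a_i`` and
  difficulty ``b_i = -intercept_i / a_i`` (24 free parameters).

Both are estimated by Bock–Aitkin EM: the latent ability ``z`` is given a
fixed standard-normal prior (which identifies the scale), the E-step
computes posterior weights over Gauss–Hermite quadrature nodes, and the
M-step solves weighted logistic likelihoods by Newton iterations.  Model
choice between the two is by likelihood-ratio test (df = 11) and BIC,
reported separately because they can disagree on real data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logsumexp

N_ITEMS = 12

__all__ = [
    "Item",
    "ItemBank",
    "IrtFit",
    "ComparisonResult",
    "icc",
    "gauss_hermite_normal",
    "fit_rasch",
    "fit_2pl",
    "compare_models",
]


@dataclass
class Item:
    """One scored word: discrimination ``a`` and difficulty ``b``.

    ``a`` may be negative or near zero — unpenalized ML on real data
    produces such values, and they are retained rather than clipped.
    """

    label: str
    a: float
    b: float


@dataclass
class ItemBank:
    """The 12-item 2PL parameter set for one trial (1-based trial index)."""

    trial: int
    items: list[Item]

    def __post_init__(self) -> None:
        if len(self.items) != N_ITEMS:
            raise ValueError(
                f"an item bank must hold exactly {N_ITEMS} items, got {len(self.items)}"
            )

    @property
    def a(self) -> np.ndarray:
        return np.array([it.a for it in self.items], dtype=float)

    @property
    def b(self) -> np.ndarray:
        return np.array([it.b for it in self.items], dtype=float)

    @property
    def labels(self) -> list[str]:
        return [it.label for it in self.items]


@dataclass
class IrtFit:
    """A converged (or boundary-flagged) marginal ML fit for one trial."""

    family: str  # "rasch" | "2pl"
    bank: ItemBank
    ease: np.ndarray  # per-item intercepts beta_i (logit scale)
    loglik: float
    n_params: int
    n_persons: int
    bic: float
    converged: bool
    quadrature_nodes: int
    n_iter: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def slope_common(self) -> float | None:
        """Common discrimination for a Rasch fit, ``None`` for 2PL."""
        if self.family == "rasch":
            return float(self.bank.items[0].a)
        return None


@dataclass
class ComparisonResult:
    """Rasch-vs-2PL comparison: LRT (df = 11) and BIC, both reported."""

    lrt_stat: float
    df: int
    p_value: float
    bic_rasch: float
    bic_2pl: float
    preferred_lrt: str
    preferred_bic: str
    preferred: str
    alpha: float


def icc(a, b, theta):
    """Item characteristic curve ``P(correct) = 1 / (1 + exp(-a*(theta-b)))``.

    Vectorized over any broadcastable combination of arguments; strictly
    increasing in ``theta`` iff ``a > 0`` and identically 0.5 when ``a == 0``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    theta = np.asarray(theta, dtype=float)
    out = expit(a * (theta - b))
    if out.ndim == 0:
        return float(out)
    return out


def gauss_hermite_normal(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss–Hermite nodes/weights rescaled to integrate against N(0, 1)."""
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    return x * np.sqrt(2.0), w / np.sqrt(np.pi)


def _as_matrix(responses) -> np.ndarray:
    x = responses.to_numpy() if isinstance(responses, pd.DataFrame) else np.asarray(responses)
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != N_ITEMS:
        raise ValueError(f"response matrix must be n x {N_ITEMS}, got shape {x.shape}")
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValueError("responses must be dichotomous 0/1 with no missing cells")
    return x


def _collapse(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    patterns, counts = np.unique(x, axis=0, return_counts=True)
    return patterns, counts.astype(float)


def _pattern_loglik(c: np.ndarray, a: np.ndarray, patterns: np.ndarray,
                    z: np.ndarray) -> np.ndarray:
    """log P(pattern | z_k) for every (pattern, node): shape (npat, K)."""
    eta = c[:, None] + np.outer(a, z)  # items x K
    logp = -np.logaddexp(0.0, -eta)
    log1mp = -np.logaddexp(0.0, eta)
    return patterns @ logp + (1.0 - patterns) @ log1mp


def _marginal_loglik(c, a, patterns, counts, z, logw) -> float:
    lp = _pattern_loglik(c, a, patterns, z) + logw
    return float(counts @ logsumexp(lp, axis=1))


def _estep(c, a, patterns, counts, z, logw):
    lp = _pattern_loglik(c, a, patterns, z) + logw
    ll_pat = logsumexp(lp, axis=1)
    post = np.exp(lp - ll_pat[:, None])  # npat x K
    nk = counts @ post  # expected persons at each node
    rik = patterns.T @ (counts[:, None] * post)  # items x K expected correct
    return float(counts @ ll_pat), nk, rik


def _mstep_2pl(c, a, nk, rik, z, max_iter=25, tol=1e-10):
    """Per-item Newton on the collapsed weighted logistic likelihood."""
    c, a = c.copy(), a.copy()
    Z = np.column_stack([np.ones_like(z), z])
    for i in range(len(c)):
        beta = np.array([c[i], a[i]])
        r, obj_prev = rik[i], None
        for _ in range(max_iter):
            p = expit(Z @ beta)
            obj = float(r @ np.log(np.clip(p, 1e-300, None))
                        + (nk - r) @ np.log(np.clip(1 - p, 1e-300, None)))
            grad = Z.T @ (r - nk * p)
            wdiag = nk * p * (1 - p)
            hess = -(Z.T * wdiag) @ Z
            if obj_prev is not None and abs(obj - obj_prev) < tol:
                break
            obj_prev = obj
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError:
                break
            # step-halving guard against overshoot at extreme parameters
            for _ in range(30):
                cand = beta - step
                p2 = expit(Z @ cand)
                obj2 = float(r @ np.log(np.clip(p2, 1e-300, None))
                             + (nk - r) @ np.log(np.clip(1 - p2, 1e-300, None)))
                if obj2 >= obj - 1e-12:
                    beta = cand
                    break
                step /= 2.0
        c[i], a[i] = beta
    return c, a


def _mstep_rasch(c, a_common, nk, rik, z, max_iter=25, tol=1e-10):
    """Joint Newton over (13,) = per-item intercepts + one common slope."""
    k = len(c)
    theta = np.concatenate([c, [a_common]])
    obj_prev = None
    for _ in range(max_iter):
        cc, aa = theta[:k], theta[k]
        p = expit(cc[:, None] + aa * z[None, :])  # items x K
        resid = rik - nk[None, :] * p
        obj = float(np.sum(rik * np.log(np.clip(p, 1e-300, None))
                           + (nk[None, :] - rik) * np.log(np.clip(1 - p, 1e-300, None))))
        if obj_prev is not None and abs(obj - obj_prev) < tol:
            break
        obj_prev = obj
        grad = np.concatenate([resid.sum(axis=1), [float((resid * z).sum())]])
        w = nk[None, :] * p * (1 - p)  # items x K
        hess = np.zeros((k + 1, k + 1))
        hess[np.arange(k), np.arange(k)] = -w.sum(axis=1)
        hca = -(w * z).sum(axis=1)
        hess[:k, k] = hca
        hess[k, :k] = hca
        hess[k, k] = -(w * z**2).sum()
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        for _ in range(30):
            cand = theta - step
            p2 = expit(cand[:k, None] + cand[k] * z[None, :])
            obj2 = float(np.sum(rik * np.log(np.clip(p2, 1e-300, None))
                                + (nk[None, :] - rik) * np.log(np.clip(1 - p2, 1e-300, None))))
            if obj2 >= obj - 1e-12:
                theta = cand
                break
            step /= 2.0
    return theta[:k], float(theta[k])


def _start_values(x: np.ndarray) -> np.ndarray:
    pbar = np.clip(x.mean(axis=0), 0.02, 0.98)
    return np.log(pbar / (1 - pbar))


def _boundary_warnings(x: np.ndarray, a: np.ndarray, labels) -> list[str]:
    msgs = []
    pbar = x.mean(axis=0)
    for i, p in enumerate(pbar):
        if p in (0.0, 1.0):
            msgs.append(
                f"item {labels[i]!r} answered identically by all participants; "
                "its parameters sit on the likelihood boundary"
            )
    for i, ai in enumerate(a):
        if abs(ai) < 1e-3:
            msgs.append(
                f"item {labels[i]!r} has |a| < 1e-3; its difficulty b = -c/a is "
                "numerically unstable"
            )
    return msgs


def _finish(family, x, c, a, labels, trial, ll, n_nodes, converged, n_iter) -> IrtFit:
    n_persons = x.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        b = np.where(a != 0.0, -c / a, np.inf)
    items = [Item(labels[i], float(a[i]), float(b[i])) for i in range(N_ITEMS)]
    n_params = 24 if family == "2pl" else 13
    bic = -2.0 * ll + n_params * np.log(n_persons)
    msgs = _boundary_warnings(x, a, labels)
    for m in msgs:
        warnings.warn(m, stacklevel=3)
    return IrtFit(
        family=family,
        bank=ItemBank(trial=trial, items=items),
        ease=c.copy(),
        loglik=ll,
        n_params=n_params,
        n_persons=n_persons,
        bic=float(bic),
        converged=converged,
        quadrature_nodes=n_nodes,
        n_iter=n_iter,
        warnings=msgs,
    )


def _em(family, responses, labels=None, trial=1, n_nodes=21,
        max_iter=500, tol=1e-6) -> IrtFit:
    x = _as_matrix(responses)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 participants to fit an item model")
    if labels is None:
        labels = (list(responses.columns) if isinstance(responses, pd.DataFrame)
                  else [f"item_{i + 1:02d}" for i in range(N_ITEMS)])
    patterns, counts = _collapse(x)
    z, w = gauss_hermite_normal(n_nodes)
    logw = np.log(w)
    c = _start_values(x)
    a = np.ones(N_ITEMS)
    a_common = 1.0
    ll_prev = -np.inf
    converged = False
    for it in range(1, max_iter + 1):
        if family == "2pl":
            ll, nk, rik = _estep(c, a, patterns, counts, z, logw)
            c, a = _mstep_2pl(c, a, nk, rik, z)
        else:
            ll, nk, rik = _estep(c, np.full(N_ITEMS, a_common), patterns, counts, z, logw)
            c, a_common = _mstep_rasch(c, a_common, nk, rik, z)
        if abs(ll - ll_prev) < tol * (abs(ll) + 1.0):
            converged = True
            break
        ll_prev = ll
    if family == "rasch":
        a = np.full(N_ITEMS, a_common)
    ll = _marginal_loglik(c, a, patterns, counts, z, logw)
    return _finish(family, x, c, a, labels, trial, ll, n_nodes, converged, it)


def fit_rasch(responses, labels=None, trial=1, n_nodes=21,
              max_iter=500, tol=1e-6) -> IrtFit:
    """Fit the Rasch model (per-item ease, one common slope) by MML-EM.

    Parameters
    ----------
    responses : (n, 12) array or DataFrame of 0/1
        Complete response matrix for one trial.
    labels : optional item labels; taken from DataFrame columns if present.
    trial : 1-based trial index stored on the resulting bank.
    n_nodes : Gauss–Hermite nodes for the N(0,1) ability prior.
    """
    return _em("rasch", responses, labels, trial, n_nodes, max_iter, tol)


def fit_2pl(responses, labels=None, trial=1, n_nodes=21,
            max_iter=500, tol=1e-6) -> IrtFit:
    """Fit the 2PL model (per-item discrimination and difficulty) by MML-EM.

    The internal slope/intercept parameterization is converted to
    ``(a, b)`` with ``b = -intercept / slope``; items whose slope collapses
    toward zero are flagged (their ``b`` can be arbitrarily large, which is
    how extreme difficulty values arise on real data).
    """
    return _em("2pl", responses, labels, trial, n_nodes, max_iter, tol)


def loglik_at(fit: IrtFit, responses, n_nodes: int | None = None) -> float:
    """Marginal log-likelihood of ``responses`` at the fit's parameters.

    Useful for quadrature-consistency checks: the same parameters
    evaluated at different node counts should agree closely.
    """
    x = _as_matrix(responses)
    patterns, counts = _collapse(x)
    z, w = gauss_hermite_normal(n_nodes or fit.quadrature_nodes)
    a = fit.bank.a
    return _marginal_loglik(fit.ease, a, patterns, counts, z, np.log(w))


def compare_models(fit_r: IrtFit, fit_2: IrtFit, alpha: float = 0.001) -> ComparisonResult:
    """Likelihood-ratio test (df = 11) and BIC comparison of nested fits.

    The LRT at ``alpha`` is the primary selection criterion; BIC is
    reported alongside and the two can disagree.  Requires both fits to
    come from the same persons and quadrature settings.
    """
    if fit_r.family != "rasch" or fit_2.family != "2pl":
        raise ValueError("compare_models expects (rasch fit, 2pl fit) in that order")
    if fit_r.n_persons != fit_2.n_persons:
        raise ValueError(
            f"fits are not on the same data: {fit_r.n_persons} vs {fit_2.n_persons} persons"
        )
    stat = 2.0 * (fit_2.loglik - fit_r.loglik)
    stat = max(stat, 0.0)
    df = fit_2.n_params - fit_r.n_params
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    preferred_lrt = "2pl" if p < alpha else "rasch"
    preferred_bic = "2pl" if fit_2.bic < fit_r.bic else "rasch"
    return ComparisonResult(
        lrt_stat=float(stat),
        df=df,
        p_value=p,
        bic_rasch=fit_r.bic,
        bic_2pl=fit_2.bic,
        preferred_lrt=preferred_lrt,
        preferred_bic=preferred_bic,
        preferred=preferred_lrt,
        alpha=alpha,
    )
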