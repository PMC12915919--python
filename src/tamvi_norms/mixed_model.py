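"""Random-intercept linear mixed model of ability on demographics.

The six per-trial ability scores of one child are correlated, so they are
modeled jointly:

    theta_ij = beta_0 + b_0i + x_ij' beta + eps_ij,
    b_0i ~ N(0, sigma_b0^2),  eps_ij ~ N(0, sigma_eps^2),

with fixed effects built from age (degree-2 orthonormal polynomial basis),
ln(MPE + 1) where MPE is mean parental years of education, trial (five
indicators vs Trial 1), sex (girl vs boy), country (Ecuador / Honduras /
Spain vs Colombia), and second-order interactions among these.

The age basis is computed from the estimation sample (unit-norm columns
over the long-format fitting rows, the classical three-term recurrence)
and its recurrence coefficients are stored on the fit so that expected
abilities can be predicted for new children.  Variance components are
estimated by REML via :class:`statsmodels.regression.mixed_linear_model.MixedLM`;
model selection compares ML-based BIC because REML objectives are not
comparable across fixed-effect sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

SEX_LEVELS = ("boy", "girl")
COUNTRY_LEVELS = ("Colombia", "Ecuador", "Honduras", "Spain")
TRIALS = (1, 2, 3, 4, 5, 6)

MAIN_TERMS = ("age", "age2", "ln_mpe", "trial", "sex", "country")

__all__ = [
    "AgeBasis",
    "DesignSpec",
    "MixedModelFit",
    "candidate_terms",
    "build_design",
    "fit_lmm",
    "sequential_replacement_select",
    "predict_expected",
]


@dataclass
class AgeBasis:
    """Degree-2 orthonormal polynomial basis for age.

    Stores the three-term-recurrence coefficients (``alpha``, ``norm2``)
    fitted on the estimation sample, so the identical columns can be
    evaluated for any new age.  Columns have unit norm over the fitting
    rows; for a new age the raw recurrence value is divided by the stored
    norms, exactly reproducing the fitting-sample columns on those ages.
    """

    alpha: list[float]
    norm2: list[float]
    degree: int = 2
    age_range: tuple[float, float] = (6.0, 17.0)

    @classmethod
    def fit(cls, ages) -> "AgeBasis":
        x = np.asarray(ages, dtype=float)
        n = len(x)
        degree = 2
        Z = np.ones((n, degree + 1))
        alpha: list[float] = []
        norm2: list[float] = [1.0, float(n)]
        for j in range(1, degree + 1):
            prev = Z[:, j - 1]
            alpha.append(float((x * prev**2).sum() / (prev**2).sum()))
            z = (x - alpha[-1]) * prev
            if j >= 2:
                z = z - (prev**2).sum() / (Z[:, j - 2] ** 2).sum() * Z[:, j - 2]
            Z[:, j] = z
            norm2.append(float((z**2).sum()))
        return cls(alpha=alpha, norm2=norm2, degree=degree,
                   age_range=(float(x.min()), float(x.max())))

    def evaluate(self, ages) -> np.ndarray:
        x = np.atleast_1d(np.asarray(ages, dtype=float))
        if (x < self.age_range[0] - 1e-9).any() or (x > self.age_range[1] + 1e-9).any():
            warnings.warn(
                "age outside the range the basis was fitted on "
                f"{self.age_range}; extrapolating", stacklevel=2,
            )
        n = len(x)
        Z = np.ones((n, self.degree + 1))
        for j in range(1, self.degree + 1):
            z = (x - self.alpha[j - 1]) * Z[:, j - 1]
            if j >= 2:
                z = z - self.norm2[j] / self.norm2[j - 1] * Z[:, j - 2]
            Z[:, j] = z
        return Z[:, 1:] / np.sqrt(np.asarray(self.norm2[2:]))


@dataclass
class DesignSpec:
    """Which model terms are active, plus everything needed to rebuild
    the design matrix out-of-sample (age basis, reference levels)."""

    terms: tuple[str, ...]
    age_basis: AgeBasis
    reference_levels: dict = field(default_factory=lambda: {
        "trial": 1, "sex": "boy", "country": "Colombia"})


@dataclass
class MixedModelFit:
    beta: dict[str, float]
    bse: dict[str, float]
    sigma_b0: float
    sigma_eps: float
    loglik: float
    criterion: str  # "reml" | "ml"
    bic: float
    n_obs: int
    n_groups: int
    design: DesignSpec
    converged: bool
    boundary: bool  # sigma_b0 collapsed to ~0


def candidate_terms() -> tuple[str, ...]:
    """Main effects plus all admissible second-order interactions.

    ``age:age2`` is excluded (the quadratic term already is the
    second-order age effect); every other pair of main effects is a
    candidate, matching an initial model of demographics, trial, and
    their two-way products.
    """
    inter = []
    for i, t1 in enumerate(MAIN_TERMS):
        for t2 in MAIN_TERMS[i + 1:]:
            if {t1, t2} == {"age", "age2"}:
                continue
            inter.append(f"{t1}:{t2}")
    return MAIN_TERMS + tuple(sorted(inter))


def _term_columns(term: str, df: pd.DataFrame, basis: AgeBasis) -> tuple[list[str], np.ndarray]:
    """Expand one model term into named design columns."""
    if ":" in term:
        t1, t2 = term.split(":")
        n1, c1 = _term_columns(t1, df, basis)
        n2, c2 = _term_columns(t2, df, basis)
        names, cols = [], []
        for i, a in enumerate(n1):
            for j, b in enumerate(n2):
                names.append(f"{a}:{b}")
                cols.append(c1[:, i] * c2[:, j])
        return names, np.column_stack(cols)
    if term == "age":
        return ["age"], basis.evaluate(df["age"])[:, :1]
    if term == "age2":
        return ["age2"], basis.evaluate(df["age"])[:, 1:2]
    if term == "ln_mpe":
        return ["ln_mpe"], np.log1p(df["mpe"].to_numpy(float))[:, None]
    if term == "trial":
        tr = df["trial"].to_numpy()
        bad = set(np.unique(tr)) - set(TRIALS)
        if bad:
            raise ValueError(f"unknown trial index values {sorted(bad)}")
        return ([f"trial_{t}" for t in TRIALS[1:]],
                np.column_stack([(tr == t).astype(float) for t in TRIALS[1:]]))
    if term == "sex":
        sx = df["sex"].astype(str).to_numpy()
        bad = set(np.unique(sx)) - set(SEX_LEVELS)
        if bad:
            raise ValueError(f"unknown sex level(s) {sorted(bad)}; expected {SEX_LEVELS}")
        return ["sex_girl"], (sx == "girl").astype(float)[:, None]
    if term == "country":
        co = df["country"].astype(str).to_numpy()
        bad = set(np.unique(co)) - set(COUNTRY_LEVELS)
        if bad:
            raise ValueError(f"unknown country level(s) {sorted(bad)}; expected {COUNTRY_LEVELS}")
        return ([f"country_{c}" for c in COUNTRY_LEVELS[1:]],
                np.column_stack([(co == c).astype(float) for c in COUNTRY_LEVELS[1:]]))
    raise ValueError(f"unknown model term {term!r}; valid terms: {candidate_terms()}")


def build_design(df: pd.DataFrame, spec: DesignSpec) -> tuple[np.ndarray, list[str]]:
    """Build the fixed-effects matrix (with leading intercept column).

    ``df`` needs columns ``age, mpe, sex, country, trial``.  Column order
    is deterministic: intercept, then the spec's terms in their stored
    order, each expanded into its indicator/basis columns.
    """
    names = ["Intercept"]
    cols = [np.ones(len(df))]
    for term in spec.terms:
        n, c = _term_columns(term, df, spec.age_basis)
        names.extend(n)
        cols.append(c)
    return np.column_stack(cols), names


def _bic(loglik: float, n_params: int, n_obs: int) -> float:
    return -2.0 * loglik + n_params * np.log(n_obs)


def fit_lmm(data: pd.DataFrame, spec: DesignSpec | None = None,
            terms: tuple[str, ...] | None = None,
            criterion: str = "reml") -> MixedModelFit:
    """Fit the random-intercept LMM of ``theta`` on the spec's terms.

    Parameters
    ----------
    data : long-format DataFrame with columns
        ``id, trial, theta, age, sex, country, mpe`` (one row per
        participant per trial).
    spec : design to use; if omitted, built from ``terms`` with an age
        basis fitted on ``data``'s rows.
    criterion : "reml" (default, for the reported fit) or "ml"
        (for BIC-based comparison of fixed-effect sets).

    A fit whose random-intercept variance collapses to zero is returned
    with ``boundary=True`` rather than raising.
    """
    if criterion not in ("reml", "ml"):
        raise ValueError("criterion must be 'reml' or 'ml'")
    if spec is None:
        if terms is None:
            raise ValueError("provide a DesignSpec or a tuple of terms")
        spec = DesignSpec(terms=tuple(terms), age_basis=AgeBasis.fit(data["age"]))
    X, names = build_design(data, spec)
    y = data["theta"].to_numpy(float)
    groups = data["id"].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups)
        res = None
        # boundary variance estimates can leave a singular Hessian or a
        # degenerate (infinite) likelihood; fall through optimizers until
        # one yields a usable fit
        for method in (["lbfgs", "bfgs"], "powell", "nm"):
            try:
                cand = model.fit(reml=(criterion == "reml"), method=method)
            except np.linalg.LinAlgError:
                continue
            if np.isfinite(cand.llf) and np.isfinite(np.asarray(cand.fe_params)).all():
                res = cand
                break
        if res is None:
            raise np.linalg.LinAlgError(
                "mixed-model fit failed for every optimizer (singular Hessian)")
    sigma_eps = float(np.sqrt(res.scale))
    var_b0 = float(np.asarray(res.cov_re)[0, 0])
    sigma_b0 = float(np.sqrt(max(var_b0, 0.0)))
    boundary = sigma_b0 < 1e-4 * sigma_eps
    n_obs = len(y)
    n_params = X.shape[1] + 2  # fixed effects + two variance components
    fe = np.asarray(res.fe_params, dtype=float)
    se = np.asarray(res.bse_fe, dtype=float)
    return MixedModelFit(
        beta=dict(zip(names, map(float, fe))),
        bse=dict(zip(names, map(float, se))),
        sigma_b0=sigma_b0,
        sigma_eps=sigma_eps,
        loglik=float(res.llf),
        criterion=criterion,
        bic=_bic(float(res.llf), n_params, n_obs),
        n_obs=n_obs,
        n_groups=int(len(np.unique(groups))),
        design=spec,
        converged=bool(res.converged),
        boundary=boundary,
    )


def _requires(term: str) -> set[str]:
    """Marginality: the terms that must be present before ``term`` may enter."""
    req: set[str] = set()
    if term == "age2":
        req.add("age")
    if ":" in term:
        t1, t2 = term.split(":")
        req.update({t1, t2})
        if t1 == "age2":
            # the quadratic interaction only enters on top of the linear one
            req.add(f"age:{t2}")
    return req


def _admissible(included: set[str], term: str) -> bool:
    return _requires(term) <= included


def _droppable(included: set[str], term: str) -> bool:
    others = included - {term}
    return all(_requires(t) <= others for t in others)


def sequential_replacement_select(
    data: pd.DataFrame,
    candidates: tuple[str, ...] | None = None,
    start: tuple[str, ...] = (),
    max_moves: int = 200,
) -> tuple[MixedModelFit, list[dict]]:
    """BIC-guided sequential replacement over fixed-effect terms.

    Starting from ``start`` (default: intercept only), repeatedly scans
    add, drop, then swap moves in a fixed deterministic order (main
    effects before interactions, interactions alphabetical) and takes the
    first move that lowers the ML-based BIC, respecting marginality (an
    interaction needs its main effects; ``age2`` needs ``age``).  Stops
    when a full scan finds no improving move.

    Returns the final model refitted by REML on the selected terms,
    together with the complete move log.
    """
    if candidates is None:
        candidates = candidate_terms()
    basis = AgeBasis.fit(data["age"])

    def fit_terms(terms: tuple[str, ...]) -> MixedModelFit:
        spec = DesignSpec(terms=terms, age_basis=basis)
        return fit_lmm(data, spec=spec, criterion="ml")

    def ordered(terms) -> tuple[str, ...]:
        return tuple(t for t in candidates if t in terms)

    included: set[str] = set(start)
    current = fit_terms(ordered(included))
    log: list[dict] = [{"move": "start", "terms": ordered(included), "bic": current.bic}]
    for _ in range(max_moves):
        moved = False
        # adds
        for term in candidates:
            if term in included or not _admissible(included, term):
                continue
            trial_fit = fit_terms(ordered(included | {term}))
            if trial_fit.bic < current.bic - 1e-6:
                included.add(term)
                current = trial_fit
                log.append({"move": f"add {term}", "terms": ordered(included),
                            "bic": current.bic})
                moved = True
                break
        if moved:
            continue
        # drops
        for term in candidates:
            if term not in included or not _droppable(included, term):
                continue
            trial_fit = fit_terms(ordered(included - {term}))
            if trial_fit.bic < current.bic - 1e-6:
                included.discard(term)
                current = trial_fit
                log.append({"move": f"drop {term}", "terms": ordered(included),
                            "bic": current.bic})
                moved = True
                break
        if moved:
            continue
        # swaps: one in, one out
        for out_t in candidates:
            if out_t not in included or not _droppable(included, out_t):
                continue
            for in_t in candidates:
                reduced = included - {out_t}
                if in_t in included or not _admissible(reduced, in_t):
                    continue
                trial_fit = fit_terms(ordered(reduced | {in_t}))
                if trial_fit.bic < current.bic - 1e-6:
                    included = reduced | {in_t}
                    current = trial_fit
                    log.append({"move": f"swap {out_t} -> {in_t}",
                                "terms": ordered(included), "bic": current.bic})
                    moved = True
                    break
            if moved:
                break
        if not moved:
            break
    final = fit_lmm(data, spec=DesignSpec(terms=ordered(included), age_basis=basis),
                    criterion="reml")
    log.append({"move": "final (reml refit)", "terms": ordered(included),
                "bic": final.bic})
    return final, log


def predict_expected(fit: MixedModelFit, profile, trial: int) -> float:
    """Fixed-effects-only expected ability for a (possibly new) child.

    The random intercept of an unseen individual has mean zero, so the
    expectation is the linear predictor evaluated at the stored age basis
    and ln(MPE + 1) transform.
    """
    row = pd.DataFrame({
        "age": [float(profile.age)],
        "mpe": [float(profile.mpe)],
        "sex": [str(profile.sex)],
        "country": [str(profile.country)],
        "trial": [int(trial)],
    })
    if row.loc[0, "sex"] not in SEX_LEVELS:
        raise ValueError(f"unknown sex level {profile.sex!r}; expected {SEX_LEVELS}")
    if row.loc[0, "country"] not in COUNTRY_LEVELS:
        raise ValueError(
            f"unknown country level {profile.country!r}; expected {COUNTRY_LEVELS}")
    if trial not in TRIALS:
        raise ValueError(f"trial must be one of {TRIALS}")
    X, names = build_design(row, fit.design)
    beta = np.array([fit.beta[n] for n in names])
    return float(X[0] @ beta)
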