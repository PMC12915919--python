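import numpy as np
import pandas as pd
import pytest

from tamvi_norms.mixed_model import (
    AgeBasis,
    DesignSpec,
    MixedModelFit,
    build_design,
    candidate_terms,
    fit_lmm,
    predict_expected,
    sequential_replacement_select,
)
from tamvi_norms.data_io import ParticipantProfile
from tamvi_norms.synthetic import (
    CohortConfig,
    gen_abilities,
    gen_demographics,
    scaled_strata,
)


def _small_theta(seed=0, scale=0.2, fixed=None, sigma_b0=0.4, sigma_eps=0.571):
    cfg = CohortConfig(strata=scaled_strata(scale),
                       fixed_effects=fixed or {"Intercept": -0.3, "age": 4.0,
                                               "trial_2": -0.15, "trial_3": -0.14,
                                               "trial_4": -0.12, "trial_5": -0.12,
                                               "trial_6": -0.10},
                       sigma_b0=sigma_b0, sigma_eps=sigma_eps, seed=seed)
    profiles = gen_demographics(cfg)
    return gen_abilities(profiles, cfg), cfg


def test_age_basis_orthonormality():
    ages = np.repeat(np.arange(6.0, 18.0), 40)
    basis = AgeBasis.fit(ages)
    cols = basis.evaluate(ages)
    gram = cols.T @ cols
    np.testing.assert_allclose(gram, np.eye(2), atol=1e-10)
    # orthogonal to the intercept as well
    np.testing.assert_allclose(cols.sum(axis=0), [0.0, 0.0], atol=1e-9)


def test_age_basis_out_of_sample_consistency():
    ages = np.array([6, 7, 9, 11, 12, 14, 15, 17] * 5, float)
    basis = AgeBasis.fit(ages)
    full = basis.evaluate(ages)
    single = np.vstack([basis.evaluate([a])[0] for a in ages])
    np.testing.assert_allclose(full, single, atol=1e-12)


def test_age_basis_extrapolation_warns():
    basis = AgeBasis.fit(np.arange(6.0, 18.0))
    with pytest.warns(UserWarning, match="extrapolat"):
        basis.evaluate([25.0])


def test_reference_cell_has_zero_indicators():
    df = pd.DataFrame({"age": [11.0], "mpe": [12.0], "sex": ["boy"],
                       "country": ["Colombia"], "trial": [1]})
    spec = DesignSpec(terms=("trial", "sex", "country", "sex:country"),
                      age_basis=AgeBasis.fit(np.arange(6.0, 18.0)))
    X, names = build_design(df, spec)
    assert names[0] == "Intercept"
    np.testing.assert_array_equal(X[0, 1:], np.zeros(len(names) - 1))


def test_build_design_deterministic():
    df = pd.DataFrame({"age": [8.0, 15.0], "mpe": [10.0, 16.0],
                       "sex": ["girl", "boy"], "country": ["Spain", "Ecuador"],
                       "trial": [2, 5]})
    spec = DesignSpec(terms=("age", "age2", "ln_mpe", "trial", "sex", "country"),
                      age_basis=AgeBasis.fit(np.arange(6.0, 18.0)))
    X1, n1 = build_design(df, spec)
    X2, n2 = build_design(df, spec)
    assert n1 == n2
    np.testing.assert_array_equal(X1, X2)


def test_unknown_levels_rejected():
    df = pd.DataFrame({"age": [10.0], "mpe": [12.0], "sex": ["other"],
                       "country": ["Colombia"], "trial": [1]})
    spec = DesignSpec(terms=("sex",), age_basis=AgeBasis.fit(np.arange(6.0, 18.0)))
    with pytest.raises(ValueError, match="sex"):
        build_design(df, spec)


def test_fit_recovers_variance_components():
    data, cfg = _small_theta(seed=4, scale=0.3)
    fit = fit_lmm(data, terms=("age", "trial"), criterion="reml")
    assert fit.sigma_eps == pytest.approx(cfg.sigma_eps, rel=0.10)
    assert fit.sigma_b0 == pytest.approx(cfg.sigma_b0, rel=0.20)
    assert not fit.boundary
    assert fit.n_groups == data["id"].nunique()


def test_zero_random_intercept_flagged_boundary():
    data, _ = _small_theta(seed=5, scale=0.15, sigma_b0=0.0)
    fit = fit_lmm(data, terms=("age",), criterion="ml")
    assert fit.boundary
    assert fit.sigma_b0 == pytest.approx(0.0, abs=0.02)


def test_ml_loglik_monotone_in_nested_terms():
    data, _ = _small_theta(seed=6, scale=0.15)
    small = fit_lmm(data, terms=(), criterion="ml")
    large = fit_lmm(data, terms=("age", "trial"), criterion="ml")
    assert large.loglik >= small.loglik - 1e-6


def test_predict_constant_model():
    basis = AgeBasis.fit(np.arange(6.0, 18.0))
    fit = MixedModelFit(beta={"Intercept": 0.7}, bse={"Intercept": 0.1},
                        sigma_b0=0.3, sigma_eps=0.5, loglik=0.0,
                        criterion="reml", bic=0.0, n_obs=10, n_groups=5,
                        design=DesignSpec(terms=(), age_basis=basis),
                        converged=True, boundary=False)
    p = ParticipantProfile(id="x", age=9.0, sex="girl", country="Honduras", mpe=8.0)
    assert predict_expected(fit, p, trial=3) == pytest.approx(0.7)
    with pytest.raises(ValueError, match="country"):
        bad = ParticipantProfile(id="x", age=9.0, sex="girl", country="Peru", mpe=8.0)
        predict_expected(fit, bad, trial=3)


def test_predict_matches_training_linear_predictor():
    data, _ = _small_theta(seed=7, scale=0.1)
    fit = fit_lmm(data, terms=("age", "ln_mpe", "trial"), criterion="reml")
    X, names = build_design(data, fit.design)
    beta = np.array([fit.beta[n] for n in names])
    manual = X @ beta
    for idx in (0, 17, len(data) - 1):
        row = data.iloc[idx]
        p = ParticipantProfile(id=row["id"], age=row["age"], sex=row["sex"],
                               country=row["country"], mpe=row["mpe"])
        assert predict_expected(fit, p, int(row["trial"])) == pytest.approx(
            manual[idx], abs=1e-10)


def test_candidate_terms_marginality_structure():
    terms = candidate_terms()
    assert set(terms) >= {"age", "age2", "ln_mpe", "trial", "sex", "country"}
    assert "age:age2" not in terms and "age2:age" not in terms
    assert "age:trial" in terms and "trial:country" in terms


def test_selection_single_candidate_degenerates_to_add_decision():
    data, _ = _small_theta(seed=8, scale=0.15,
                           fixed={"Intercept": 0.0, "trial_2": 0.8,
                                  "trial_3": 0.8, "trial_4": 0.8,
                                  "trial_5": 0.8, "trial_6": 0.8})
    fit, log = sequential_replacement_select(data, candidates=("trial",))
    assert fit.design.terms == ("trial",)
    moves = [m["move"] for m in log]
    assert moves[1] == "add trial"


def test_selection_never_increases_bic():
    data, _ = _small_theta(seed=9, scale=0.1)
    fit, log = sequential_replacement_select(
        data, candidates=("age", "ln_mpe", "trial", "sex"))
    bics = [m["bic"] for m in log[:-1]]  # final entry is the REML refit
    assert all(b2 <= b1 + 1e-9 for b1, b2 in zip(bics, bics[1:]))


def test_roundtrip_prediction_through_json(tmp_path):
    from tamvi_norms.data_io import read_model, write_model

    data, _ = _small_theta(seed=10, scale=0.1)
    fit = fit_lmm(data, terms=("age", "trial", "country"), criterion="reml")
    path = tmp_path / "lmm.json"
    write_model(fit, path)
    back = read_model(path)
    p = ParticipantProfile(id="n", age=16.0, sex="boy", country="Spain", mpe=14.0)
    assert predict_expected(back, p, 6) == predict_expected(fit, p, 6)
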