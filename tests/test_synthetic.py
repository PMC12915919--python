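import numpy as np
import pytest

from tamvi_norms.irt import icc
from tamvi_norms.synthetic import (
    CohortConfig,
    default_item_banks,
    gen_abilities,
    gen_demographics,
    gen_responses,
    simulate_cohort,
)


def test_default_cohort_matches_published_strata():
    profiles = gen_demographics(CohortConfig(seed=0))
    assert len(profiles) == 1640
    colombia_young = [p for p in profiles
                      if p.country == "Colombia" and 6 <= p.age <= 8]
    assert len(colombia_young) == 121
    girls = sum(p.sex == "girl" for p in colombia_young)
    assert girls == 63
    assert all(6 <= p.age <= 17 for p in profiles)
    assert all(p.mpe >= 0 for p in profiles)


def test_generation_deterministic_under_seed():
    ds1, truth1 = simulate_cohort(CohortConfig(seed=99,
                                               strata=_one_stratum(20)))
    ds2, truth2 = simulate_cohort(CohortConfig(seed=99,
                                               strata=_one_stratum(20)))
    assert ds1 == ds2
    assert truth1["theta_long"].equals(truth2["theta_long"])


def _one_stratum(n, country="Ecuador"):
    return {(country, (6, 17)): {"girls": n, "boys": n,
                                 "mpe_mean": 13.0, "mpe_sd": 3.5}}


def test_noise_free_limit_is_linear_predictor():
    cfg = CohortConfig(strata=_one_stratum(10), sigma_b0=0.0, sigma_eps=0.0,
                       fixed_effects={"Intercept": -0.3, "trial_2": 0.5}, seed=1)
    th = gen_abilities(gen_demographics(cfg), cfg)
    t1 = th[th["trial"] == 1]["theta"]
    t2 = th[th["trial"] == 2]["theta"]
    assert np.allclose(t1, -0.3) and np.allclose(t2, 0.2)


def test_pure_noise_limit_standard_normal():
    cfg = CohortConfig(strata=_one_stratum(1500), sigma_b0=0.0, sigma_eps=1.0,
                       fixed_effects={"Intercept": 0.0}, seed=2)
    th = gen_abilities(gen_demographics(cfg), cfg)["theta"]
    assert th.mean() == pytest.approx(0.0, abs=0.03)
    assert th.std() == pytest.approx(1.0, abs=0.03)


def test_within_participant_covariance_matches_sigma_b0():
    """Across trials the shared intercept induces cov = sigma_b0^2 (5%)."""
    cfg = CohortConfig(strata=_one_stratum(2500), sigma_b0=0.4, sigma_eps=0.3,
                       fixed_effects={"Intercept": 0.0}, seed=3)
    th = gen_abilities(gen_demographics(cfg), cfg)
    wide = th.pivot(index="id", columns="trial", values="theta")
    cov = np.cov(wide.to_numpy().T)
    off_diag = cov[np.triu_indices(6, k=1)]
    assert off_diag.mean() == pytest.approx(0.16, rel=0.05)


def test_unknown_fixed_effect_name_rejected():
    cfg = CohortConfig(strata=_one_stratum(3),
                       fixed_effects={"Intercept": 0.0, "wealth": 1.0}, seed=4)
    with pytest.raises(ValueError, match="wealth"):
        gen_abilities(gen_demographics(cfg), cfg)


def test_empty_config_rejected():
    with pytest.raises(ValueError, match="strata"):
        CohortConfig(strata={})


@pytest.mark.parametrize(
    "a, b, theta, expected, tol",
    [
        (0.0, 1.3, -2.0, 0.5, 0.02),  # flat curve
        (1.5, 0.4, 0.4, 0.5, 0.02),  # theta at difficulty
        (2.0, 0.0, 2.0, 1.0 / (1.0 + np.exp(-4.0)), 0.006),  # ~0.982
    ],
)
def test_response_frequencies_match_icc(a, b, theta, expected, tol, rng):
    import pandas as pd

    from conftest import make_bank

    n = 10000
    theta_long = pd.DataFrame({
        "id": [f"p{i}" for i in range(n)], "trial": 1,
        "age": 10.0, "sex": "girl", "country": "Spain", "mpe": 12.0,
        "theta": theta,
    })
    bank = make_bank([a] * 12, [b] * 12)
    ds = gen_responses(theta_long, {1: bank}, rng=rng)
    mat, _ = ds.response_matrix(1)
    assert mat[:, 0].mean() == pytest.approx(expected, abs=tol)


def test_marginal_proportion_matches_integrated_icc(rng):
    """P(correct) over a simulated ability distribution equals the ICC
    integrated against that distribution, within binomial error."""
    from scipy.stats import norm as normal

    banks = default_item_banks()
    bank = banks[4]
    n = 20000
    theta = rng.standard_normal(n)
    x = (rng.random((n, 12)) < icc(bank.a, bank.b, theta[:, None]))
    # quadrature oracle for the marginal probability
    grid = np.linspace(-8, 8, 4001)
    phi = normal.pdf(grid)
    phi /= phi.sum()
    for i in range(12):
        expected = float((icc(bank.a[i], bank.b[i], grid) * phi).sum())
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(x[:, i].mean() - expected) < 4 * se + 1e-9


def test_bad_bank_size_rejected():
    from tamvi_norms.irt import Item, ItemBank

    with pytest.raises(ValueError, match="12"):
        ItemBank(trial=1, items=[Item("w", 1.0, 0.0)] * 5)
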