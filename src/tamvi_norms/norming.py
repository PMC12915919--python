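"""Demographically adjusted z-scores and percentile ranks.

An observed ability ``theta_obs`` is compared with the expected ability
``theta_hat`` of demographically matched peers (from the mixed model) on
the scale of the model's *residual* standard deviation:

    z  = (theta_obs - theta_hat) / sigma_eps
    PR = 100 * Phi(z)

The denominator is sigma_eps alone, not sqrt(sigma_b0^2 + sigma_eps^2):
the norm answers "where does this score fall among children with the
same demographic profile", conditioning on the profile-level expectation,
and the published worked example is reproduced exactly only under this
choice.  See docs/methods.md for the discussion.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import norm as _normal

__all__ = ["NormResult", "z_score", "percentile_rank"]


@dataclass
class NormResult:
    theta_obs: float
    theta_expected: float
    z: float
    cumulative_prob: float
    percentile: float
    sigma_eps_used: float


def z_score(theta_obs: float, theta_expected: float, sigma_eps: float) -> float:
    """Residual-scaled deviation of the observed from the expected ability."""
    if sigma_eps <= 0:
        raise ValueError(f"sigma_eps must be > 0, got {sigma_eps}")
    return (theta_obs - theta_expected) / sigma_eps


def percentile_rank(theta_obs: float, theta_expected: float,
                    sigma_eps: float) -> NormResult:
    """Percentile rank 100 * Phi(z) with every intermediate value kept."""
    z = z_score(theta_obs, theta_expected, sigma_eps)
    p = float(_normal.cdf(z))
    return NormResult(
        theta_obs=float(theta_obs),
        theta_expected=float(theta_expected),
        z=float(z),
        cumulative_prob=p,
        percentile=100.0 * p,
        sigma_eps_used=float(sigma_eps),
    )
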