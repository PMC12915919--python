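"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator reproduces the study design end-to-end so the whole
pipeline can be exercised and parameter recovery measured without any
real data:

1. demographics drawn stratum by stratum (country x age band x sex, with
   the published per-stratum counts and parental-education summaries),
2. per-trial latent abilities from the random-intercept mixed model
   (fixed effects + participant intercept b0 ~ N(0, sigma_b0^2) +
   residual eps ~ N(0, sigma_eps^2)),
3. dichotomous item responses from per-trial 2PL item banks.

Every stage takes its own child generator spawned from one global seed,
so stages are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ParticipantProfile, ResponseDataset
from .irt import Item, ItemBank, icc
from .mixed_model import AgeBasis, DesignSpec, build_design

__all__ = [
    "CohortConfig",
    "DEFAULT_STRATA",
    "DEFAULT_FIXED_EFFECTS",
    "default_item_banks",
    "gen_demographics",
    "gen_abilities",
    "gen_responses",
    "simulate_cohort",
]

AGE_BANDS = ((6, 8), (9, 11), (12, 14), (15, 17))

# Per (country, age band): girls, boys, parental-education mean and SD.
# These are the published sample strata; totals come to 1,640 children.
DEFAULT_STRATA: dict[tuple[str, tuple[int, int]], dict] = {
    ("Colombia", (6, 8)): {"girls": 63, "boys": 58, "mpe_mean": 12.3, "mpe_sd": 3.6},
    ("Colombia", (9, 11)): {"girls": 63, "boys": 54, "mpe_mean": 12.3, "mpe_sd": 3.7},
    ("Colombia", (12, 14)): {"girls": 59, "boys": 50, "mpe_mean": 12.3, "mpe_sd": 3.9},
    ("Colombia", (15, 17)): {"girls": 50, "boys": 37, "mpe_mean": 12.4, "mpe_sd": 4.2},
    ("Ecuador", (6, 8)): {"girls": 70, "boys": 72, "mpe_mean": 13.5, "mpe_sd": 3.5},
    ("Ecuador", (9, 11)): {"girls": 76, "boys": 68, "mpe_mean": 13.7, "mpe_sd": 4.0},
    ("Ecuador", (12, 14)): {"girls": 69, "boys": 67, "mpe_mean": 13.5, "mpe_sd": 3.6},
    ("Ecuador", (15, 17)): {"girls": 69, "boys": 66, "mpe_mean": 12.8, "mpe_sd": 3.7},
    ("Honduras", (6, 8)): {"girls": 36, "boys": 32, "mpe_mean": 13.2, "mpe_sd": 3.7},
    ("Honduras", (9, 11)): {"girls": 46, "boys": 46, "mpe_mean": 12.7, "mpe_sd": 3.6},
    ("Honduras", (12, 14)): {"girls": 39, "boys": 29, "mpe_mean": 12.0, "mpe_sd": 4.0},
    ("Honduras", (15, 17)): {"girls": 33, "boys": 23, "mpe_mean": 13.7, "mpe_sd": 3.3},
    ("Spain", (6, 8)): {"girls": 53, "boys": 50, "mpe_mean": 15.0, "mpe_sd": 3.8},
    ("Spain", (9, 11)): {"girls": 56, "boys": 58, "mpe_mean": 16.3, "mpe_sd": 3.6},
    ("Spain", (12, 14)): {"girls": 39, "boys": 38, "mpe_mean": 13.7, "mpe_sd": 4.0},
    ("Spain", (15, 17)): {"girls": 41, "boys": 30, "mpe_mean": 13.5, "mpe_sd": 3.5},
}

# The published final mixed-model coefficients, keyed by design-column
# name (age columns are on the unit-norm orthonormal-basis scale).
DEFAULT_FIXED_EFFECTS: dict[str, float] = {
    "Intercept": -0.302,
    "age": 6.515, "age2": 0.923, "ln_mpe": 0.118,
    "trial_2": -0.154, "trial_3": -0.142, "trial_4": -0.117,
    "trial_5": -0.122, "trial_6": -0.095,
    "sex_girl": 0.023,
    "country_Ecuador": -0.020, "country_Honduras": -0.086, "country_Spain": -0.265,
    "age:trial_2": 13.909, "age2:trial_2": -7.943,
    "age:trial_3": 18.500, "age2:trial_3": -9.077,
    "age:trial_4": 15.631, "age2:trial_4": -11.924,
    "age:trial_5": 17.740, "age2:trial_5": -13.021,
    "age:trial_6": 14.274, "age2:trial_6": -15.345,
    "ln_mpe:country_Ecuador": -0.016, "ln_mpe:country_Honduras": 0.033,
    "ln_mpe:country_Spain": 0.045,
    "sex_girl:country_Ecuador": 0.100, "sex_girl:country_Honduras": -0.039,
    "sex_girl:country_Spain": 0.027,
    "trial_2:country_Ecuador": 0.156, "trial_3:country_Ecuador": 0.089,
    "trial_4:country_Ecuador": 0.034, "trial_5:country_Ecuador": 0.072,
    "trial_6:country_Ecuador": 0.040,
    "trial_2:country_Honduras": 0.046, "trial_3:country_Honduras": 0.132,
    "trial_4:country_Honduras": 0.117, "trial_5:country_Honduras": 0.119,
    "trial_6:country_Honduras": 0.104,
    "trial_2:country_Spain": 0.420, "trial_3:country_Spain": 0.398,
    "trial_4:country_Spain": 0.381, "trial_5:country_Spain": 0.346,
    "trial_6:country_Spain": 0.276,
}

# Term set whose design columns span every coefficient name above.
TRUTH_TERMS = ("age", "age2", "ln_mpe", "trial", "sex", "country",
               "age:trial", "age2:trial", "ln_mpe:country", "sex:country",
               "trial:country")

WORDS = ["Zapato", "Bufanda", "Blusa", "Camisa", "Sillón", "Armario",
         "Escritorio", "Comedor", "Nariz", "Ojo", "Oreja", "Boca"]

# (a, b) per word per trial.  Values anchor on the published per-trial
# extremes (e.g. Nariz's negative slope in Trial 1, Ojo's 3.20 slope in
# Recognition, Sillón hardest in every trial) with moderate values filled
# in between: discrimination rises across free-recall trials and is
# steepest in recognition, while items grow easier as the list is learned.
_BANK_TABLE = {
    1: [(0.60, -0.8), (0.35, -6.0), (0.50, -0.5), (0.45, 0.2),
        (0.15, 8.0), (0.50, 0.5), (0.40, -1.0), (0.45, -1.5),
        (-1.19, -1.2), (0.50, -2.0), (0.55, -0.9), (0.50, -1.3)],
    2: [(1.00, -1.0), (0.80, -2.2), (0.90, -0.8), (0.80, -0.4),
        (0.70, 2.20), (1.75, -0.6), (0.05, -40.0), (0.80, -1.6),
        (0.60, -2.3), (0.90, -1.8), (0.85, -1.1), (0.80, -1.4)],
    3: [(1.39, -1.2), (1.00, -1.8), (1.10, -1.0), (1.00, -0.6),
        (0.33, 0.35), (1.20, -0.9), (0.90, -2.35), (1.00, -1.7),
        (0.70, -2.2), (1.00, -1.9), (1.05, -1.2), (1.00, -1.5)],
    4: [(1.09, -1.5), (0.95, -2.0), (1.00, -1.2), (0.90, -0.9),
        (0.30, -0.50), (1.00, -1.1), (0.85, -2.4), (0.95, -1.9),
        (0.80, -3.17), (0.95, -2.1), (1.00, -1.4), (0.90, -1.7)],
    5: [(1.10, -1.3), (0.90, -1.6), (1.24, -0.8), (0.85, -0.7),
        (0.70, 0.60), (0.90, -2.04), (0.80, -1.9), (1.00, -0.51),
        (0.57, -1.5), (0.95, -1.8), (1.05, -1.1), (0.90, -1.4)],
    6: [(2.40, -2.3), (2.60, -1.9), (2.50, -1.8), (2.30, -1.7),
        (2.00, -1.60), (1.63, -1.9), (2.20, -2.0), (1.97, -2.21),
        (2.10, -2.45), (3.20, -2.0), (2.70, -2.1), (2.65, -2.2)],
}


def default_item_banks() -> dict[int, ItemBank]:
    """Six 12-item 2PL banks used as the generator's true parameters."""
    return {t: ItemBank(trial=t, items=[Item(w, a, b) for w, (a, b)
                                        in zip(WORDS, _BANK_TABLE[t])])
            for t in _BANK_TABLE}


@dataclass
class CohortConfig:
    """Everything the generator needs; defaults are the study conditions."""

    strata: dict = field(default_factory=lambda: dict(DEFAULT_STRATA))
    item_banks: dict = field(default_factory=default_item_banks)
    fixed_effects: dict = field(default_factory=lambda: dict(DEFAULT_FIXED_EFFECTS))
    sigma_b0: float = 0.4
    sigma_eps: float = 0.571
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.strata:
            raise ValueError("cohort config has no strata")
        # zero SDs are allowed: they give the deterministic noise-free limit
        if self.sigma_b0 < 0 or self.sigma_eps < 0:
            raise ValueError("sigma_b0 and sigma_eps must be >= 0")
        for t, bank in self.item_banks.items():
            if len(bank.items) != 12:
                raise ValueError(f"item bank for trial {t} must have 12 items")

    def child_rngs(self) -> dict[str, np.random.Generator]:
        ss = np.random.SeedSequence(self.seed)
        keys = ("demographics", "abilities", "responses")
        return dict(zip(keys, map(np.random.default_rng, ss.spawn(len(keys)))))


def gen_demographics(config: CohortConfig,
                     rng: np.random.Generator | None = None) -> list[ParticipantProfile]:
    """Draw one profile per configured stratum slot.

    Ages are uniform over the whole years of the stratum's band (the
    published band means and SDs match a discrete uniform); parental
    education is truncated-normal at the stratum's mean/SD, floored at 0.
    """
    if rng is None:
        rng = config.child_rngs()["demographics"]
    profiles = []
    n = 0
    for (country, (lo, hi)), st in config.strata.items():
        for sex, count in (("girl", st["girls"]), ("boy", st["boys"])):
            if count < 0:
                raise ValueError("stratum counts must be >= 0")
            ages = rng.integers(lo, hi + 1, size=count).astype(float)
            a_trunc = (0.0 - st["mpe_mean"]) / st["mpe_sd"]
            mpe = stats.truncnorm.rvs(a_trunc, np.inf, loc=st["mpe_mean"],
                                      scale=st["mpe_sd"], size=count,
                                      random_state=rng)
            for age, m in zip(ages, mpe):
                n += 1
                profiles.append(ParticipantProfile(
                    id=f"P{n:05d}", age=float(age), sex=sex, country=country,
                    mpe=float(round(m, 2))))
    return profiles


def gen_abilities(profiles: list[ParticipantProfile], config: CohortConfig,
                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """True per-trial abilities from the mixed model.

    theta_ij = x_ij' beta + b0_i + eps_ij with b0_i shared across the six
    trials of participant i.  Returns a long DataFrame
    ``id, trial, age, sex, country, mpe, theta`` (theta is the truth);
    the age basis is fitted on the generated long-format rows.
    """
    if rng is None:
        rng = config.child_rngs()["abilities"]
    long = pd.DataFrame([
        {"id": p.id, "trial": t, "age": p.age, "sex": p.sex,
         "country": p.country, "mpe": p.mpe}
        for p in profiles for t in range(1, 7)
    ])
    spec = DesignSpec(terms=TRUTH_TERMS, age_basis=AgeBasis.fit(long["age"]))
    X, names = build_design(long, spec)
    unknown = set(config.fixed_effects) - set(names)
    if unknown:
        raise ValueError(
            f"unknown fixed-effect name(s) {sorted(unknown)}; valid names: {names}")
    beta = np.array([config.fixed_effects.get(nm, 0.0) for nm in names])
    b0 = dict(zip([p.id for p in profiles],
                  rng.normal(0.0, config.sigma_b0, size=len(profiles))))
    eps = rng.normal(0.0, config.sigma_eps, size=len(long))
    long["theta"] = X @ beta + long["id"].map(b0).to_numpy() + eps
    return long


def gen_responses(theta_long: pd.DataFrame, item_banks: dict[int, ItemBank],
                  rng: np.random.Generator | None = None,
                  profiles: list[ParticipantProfile] | None = None,
                  seed: int | None = None) -> ResponseDataset:
    """Bernoulli item responses from the 2PL curves at each true theta."""
    if rng is None:
        rng = np.random.default_rng(seed)
    for t, bank in item_banks.items():
        if len(bank.items) != 12:
            raise ValueError(f"item bank for trial {t} must have 12 items")
    theta = theta_long["theta"].to_numpy(float)
    if not np.isfinite(theta).all():
        raise ValueError("true abilities must be finite")
    if profiles is None:
        first = theta_long.drop_duplicates("id")
        profiles = [ParticipantProfile(id=str(r.id), age=float(r.age),
                                       sex=str(r.sex), country=str(r.country),
                                       mpe=float(r.mpe))
                    for r in first.itertuples()]
    responses = {}
    for row, th in zip(theta_long.itertuples(), theta):
        bank = item_banks[int(row.trial)]
        p = icc(bank.a, bank.b, th)
        draws = (rng.random(12) < p).astype(int)
        for i, v in enumerate(draws, start=1):
            responses[(str(row.id), int(row.trial), i)] = int(v)
    return ResponseDataset(profiles=profiles, responses=responses)


def simulate_cohort(config: CohortConfig) -> tuple[ResponseDataset, dict]:
    """Full pipeline: demographics -> abilities -> responses.

    Returns the dataset plus a truth record (true theta table, banks,
    coefficients, variance components) for recovery tests.
    """
    rngs = config.child_rngs()
    profiles = gen_demographics(config, rngs["demographics"])
    theta_long = gen_abilities(profiles, config, rngs["abilities"])
    dataset = gen_responses(theta_long, config.item_banks, rngs["responses"],
                            profiles=profiles)
    truth = {
        "theta_long": theta_long,
        "item_banks": config.item_banks,
        "fixed_effects": dict(config.fixed_effects),
        "sigma_b0": config.sigma_b0,
        "sigma_eps": config.sigma_eps,
    }
    return dataset, truth


def scaled_strata(factor: float) -> dict:
    """The default strata with every count scaled down (ceil, min 1) —
    for quick end-to-end runs that keep the design's shape."""
    out = {}
    for key, st in DEFAULT_STRATA.items():
        out[key] = {**st,
                    "girls": max(1, int(np.ceil(st["girls"] * factor))),
                    "boys": max(1, int(np.ceil(st["boys"] * factor)))}
    return out
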