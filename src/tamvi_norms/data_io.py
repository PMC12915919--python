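"""Tabular and model-file input/output plus the eligibility filter.

The canonical interchange layout is a wide CSV: one row per participant
with demographics (``id, country, sex, age, mpe`` and optional screening
scores ``iq, cdi, audit_c``) followed by 72 response columns
``t{1..6}_i{01..12}`` holding 0/1.  A long layout
(``id, demographics..., trial, item, response``) is accepted and
normalized to the same in-memory representation.

Fitted models (Rasch/2PL item banks, the mixed model) round-trip through
plain JSON files carrying a ``schema_version`` tag, full-precision
parameters, reference levels and the age-basis coefficients needed for
out-of-sample prediction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .irt import Item, ItemBank, IrtFit
from .mixed_model import (
    AgeBasis,
    COUNTRY_LEVELS,
    DesignSpec,
    MixedModelFit,
    SEX_LEVELS,
    TRIALS,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1
N_ITEMS = 12

RESPONSE_COLUMNS = [f"t{t}_i{i:02d}" for t in TRIALS for i in range(1, N_ITEMS + 1)]

__all__ = [
    "ParticipantProfile",
    "ResponseDataset",
    "read_dataset",
    "write_dataset",
    "filter_eligible",
    "write_model",
    "read_model",
    "write_bundle",
    "read_bundle",
]


@dataclass
class ParticipantProfile:
    id: str
    age: float
    sex: str
    country: str
    mpe: float
    iq: int | None = None
    cdi: int | None = None
    audit_c: int | None = None


@dataclass
class ResponseDataset:
    """Profiles plus sparse dichotomous responses keyed (id, trial, item)."""

    profiles: list[ParticipantProfile]
    responses: dict[tuple[str, int, int], int] = field(default_factory=dict)

    def profile_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(p) for p in self.profiles])

    def complete_ids(self) -> list[str]:
        """Ids with all 72 cells present, in profile order."""
        out = []
        for p in self.profiles:
            if all((p.id, t, i) in self.responses
                   for t in TRIALS for i in range(1, N_ITEMS + 1)):
                out.append(p.id)
        return out

    def response_matrix(self, trial: int, ids=None) -> tuple[np.ndarray, list[str]]:
        """(n, 12) 0/1 matrix for one trial, restricted to complete rows."""
        if ids is None:
            ids = [p.id for p in self.profiles
                   if all((p.id, trial, i) in self.responses
                          for i in range(1, N_ITEMS + 1))]
        mat = np.array([[self.responses[(pid, trial, i)]
                         for i in range(1, N_ITEMS + 1)] for pid in ids], dtype=float)
        return mat.reshape(len(ids), N_ITEMS), list(ids)

    def __eq__(self, other) -> bool:
        return (isinstance(other, ResponseDataset)
                and self.profiles == other.profiles
                and self.responses == other.responses)


def _opt_int(v):
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return int(v)


def _profile_from_row(row, rownum: int) -> ParticipantProfile:
    sex = str(row["sex"])
    country = str(row["country"])
    problems = []
    if sex not in SEX_LEVELS:
        problems.append(f"sex {sex!r} not in {SEX_LEVELS}")
    if country not in COUNTRY_LEVELS:
        problems.append(f"country {country!r} not in {COUNTRY_LEVELS}")
    mpe = float(row["mpe"])
    if not np.isfinite(mpe) or mpe < 0:
        problems.append(f"mpe {mpe!r} must be finite and >= 0")
    if problems:
        raise ValueError(f"row {rownum}: " + "; ".join(problems))
    return ParticipantProfile(
        id=str(row["id"]), age=float(row["age"]), sex=sex, country=country,
        mpe=mpe, iq=_opt_int(row.get("iq")), cdi=_opt_int(row.get("cdi")),
        audit_c=_opt_int(row.get("audit_c")),
    )


def _check_response(v, where: str) -> int | None:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    fv = float(v)
    if fv not in (0.0, 1.0):
        raise ValueError(f"non-dichotomous response value {v!r} at {where}")
    return int(fv)


def read_dataset(path, layout: str = "wide",
                 column_map: dict[str, str] | None = None) -> ResponseDataset:
    """Read a wide or long CSV into a validated :class:`ResponseDataset`.

    ``column_map`` renames raw file headers to the documented schema
    (``{"raw name": "schema name"}``) before validation, so files with
    different headers can be ingested without editing them.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    mandatory = ["id", "country", "sex", "age", "mpe"]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {missing}")
    if layout == "wide":
        return _read_wide(df)
    if layout == "long":
        return _read_long(df)
    raise ValueError(f"unknown layout {layout!r}; use 'wide' or 'long'")


def _read_wide(df: pd.DataFrame) -> ResponseDataset:
    profiles, responses = [], {}
    for rownum, (_, row) in enumerate(df.iterrows(), start=2):  # 1-based + header
        p = _profile_from_row(row, rownum)
        profiles.append(p)
        for t in TRIALS:
            for i in range(1, N_ITEMS + 1):
                col = f"t{t}_i{i:02d}"
                if col not in df.columns:
                    continue
                v = _check_response(row[col], f"row {rownum}, column {col}")
                if v is not None:
                    responses[(p.id, t, i)] = v
    return ResponseDataset(profiles=profiles, responses=responses)


def _read_long(df: pd.DataFrame) -> ResponseDataset:
    for col in ("trial", "item", "response"):
        if col not in df.columns:
            raise ValueError(f"missing mandatory column(s): ['{col}']")
    profiles, seen, responses = [], set(), {}
    for rownum, (_, row) in enumerate(df.iterrows(), start=2):
        pid = str(row["id"])
        if pid not in seen:
            profiles.append(_profile_from_row(row, rownum))
            seen.add(pid)
        t, i = int(row["trial"]), int(row["item"])
        if t not in TRIALS or not (1 <= i <= N_ITEMS):
            raise ValueError(f"row {rownum}: trial {t} / item {i} out of range")
        v = _check_response(row["response"], f"row {rownum}")
        if v is not None:
            responses[(pid, t, i)] = v
    return ResponseDataset(profiles=profiles, responses=responses)


def write_dataset(dataset: ResponseDataset, path, layout: str = "wide") -> None:
    path = Path(path)
    prof = dataset.profile_frame()
    opt = [c for c in ("iq", "cdi", "audit_c") if prof[c].notna().any()]
    prof = prof[["id", "country", "sex", "age", "mpe"] + opt]
    if layout == "wide":
        wide = prof.copy()
        for t in TRIALS:
            for i in range(1, N_ITEMS + 1):
                col = f"t{t}_i{i:02d}"
                wide[col] = [dataset.responses.get((p.id, t, i), "")
                             for p in dataset.profiles]
        wide.to_csv(path, index=False)
    elif layout == "long":
        rows = []
        for p in dataset.profiles:
            base = prof[prof["id"] == p.id].iloc[0].to_dict()
            for t in TRIALS:
                for i in range(1, N_ITEMS + 1):
                    v = dataset.responses.get((p.id, t, i))
                    if v is not None:
                        rows.append({**base, "trial": t, "item": i, "response": v})
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown layout {layout!r}")


# ---------------------------------------------------------------- eligibility

def filter_eligible(dataset: ResponseDataset,
                    return_report: bool = False):
    """Apply the study inclusion thresholds to a dataset.

    Retains participants with age in [6, 17], nonverbal IQ >= 80, CDI
    depression score < 19, and (for ages >= 12) AUDIT-C <= 5.  A missing
    screening score never excludes — pre-screened samples simply lack the
    columns — but is counted as "unscreened" in the report.  Idempotent.
    """
    kept, report = [], {
        "age": 0, "iq": 0, "cdi": 0, "audit_c": 0,
        "unscreened": 0, "n_input": len(dataset.profiles),
    }
    for p in dataset.profiles:
        reasons = []
        if not (6.0 <= p.age <= 17.0):
            reasons.append("age")
        if p.iq is not None and p.iq < 80:
            reasons.append("iq")
        if p.cdi is not None and p.cdi >= 19:
            reasons.append("cdi")
        if p.age >= 12.0 and p.audit_c is not None and p.audit_c > 5:
            reasons.append("audit_c")
        if p.iq is None or p.cdi is None:
            report["unscreened"] += 1
        if reasons:
            for r in reasons:
                report[r] += 1
            logger.info("excluding %s (%s)", p.id, ", ".join(reasons))
        else:
            kept.append(p)
    ids = {p.id for p in kept}
    responses = {k: v for k, v in dataset.responses.items() if k[0] in ids}
    report["n_output"] = len(kept)
    report["n_excluded"] = report["n_input"] - len(kept)
    logger.info("eligibility filter: %s", report)
    out = ResponseDataset(profiles=kept, responses=responses)
    return (out, report) if return_report else out


# ------------------------------------------------------------- model files

def _irt_to_dict(fit: IrtFit) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "family": fit.family,
        "trial": fit.bank.trial,
        "items": [{"label": it.label, "a": it.a, "b": it.b}
                  for it in fit.bank.items],
        "ease": list(map(float, fit.ease)),
        "loglik": fit.loglik,
        "n_params": fit.n_params,
        "n_persons": fit.n_persons,
        "bic": fit.bic,
        "converged": fit.converged,
        "quadrature_nodes": fit.quadrature_nodes,
        "warnings": fit.warnings,
    }


def _irt_from_dict(d: dict) -> IrtFit:
    bank = ItemBank(trial=d["trial"],
                    items=[Item(i["label"], i["a"], i["b"]) for i in d["items"]])
    return IrtFit(
        family=d["family"], bank=bank, ease=np.asarray(d["ease"], dtype=float),
        loglik=d["loglik"], n_params=d["n_params"], n_persons=d["n_persons"],
        bic=d["bic"], converged=d["converged"],
        quadrature_nodes=d["quadrature_nodes"], warnings=list(d.get("warnings", [])),
    )


def _lmm_to_dict(fit: MixedModelFit) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "family": "lmm",
        "beta": fit.beta,
        "bse": fit.bse,
        "sigma_b0": fit.sigma_b0,
        "sigma_eps": fit.sigma_eps,
        "loglik": fit.loglik,
        "criterion": fit.criterion,
        "bic": fit.bic,
        "n_obs": fit.n_obs,
        "n_groups": fit.n_groups,
        "converged": fit.converged,
        "boundary": fit.boundary,
        "terms": list(fit.design.terms),
        "age_basis": {
            "alpha": fit.design.age_basis.alpha,
            "norm2": fit.design.age_basis.norm2,
            "degree": fit.design.age_basis.degree,
            "age_range": list(fit.design.age_basis.age_range),
        },
        "reference_levels": fit.design.reference_levels,
    }


def _lmm_from_dict(d: dict) -> MixedModelFit:
    ab = d["age_basis"]
    spec = DesignSpec(
        terms=tuple(d["terms"]),
        age_basis=AgeBasis(alpha=list(ab["alpha"]), norm2=list(ab["norm2"]),
                           degree=ab["degree"], age_range=tuple(ab["age_range"])),
        reference_levels=dict(d["reference_levels"]),
    )
    return MixedModelFit(
        beta=dict(d["beta"]), bse=dict(d["bse"]), sigma_b0=d["sigma_b0"],
        sigma_eps=d["sigma_eps"], loglik=d["loglik"], criterion=d["criterion"],
        bic=d["bic"], n_obs=d["n_obs"], n_groups=d["n_groups"], design=spec,
        converged=d["converged"], boundary=d["boundary"],
    )


def write_model(fit, path) -> None:
    """Serialize an :class:`IrtFit` or :class:`MixedModelFit` to JSON."""
    if isinstance(fit, IrtFit):
        d = _irt_to_dict(fit)
    elif isinstance(fit, MixedModelFit):
        d = _lmm_to_dict(fit)
    else:
        raise TypeError(f"cannot serialize {type(fit).__name__}")
    Path(path).write_text(json.dumps(d, indent=1))


def read_model(path):
    """Read a model JSON back into the matching fit object."""
    d = json.loads(Path(path).read_text())
    version = d.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"model file schema_version {version!r} not supported "
            f"(reader supports {SCHEMA_VERSION})")
    family = d.get("family")
    if family in ("rasch", "2pl"):
        return _irt_from_dict(d)
    if family == "lmm":
        return _lmm_from_dict(d)
    raise ValueError(f"unknown model family tag {family!r}")


def write_bundle(irt_fits: dict[int, IrtFit], lmm_fit: MixedModelFit, path,
                 metadata: dict | None = None) -> None:
    """One JSON with all six item banks plus the LMM — the calculator input."""
    d = {
        "schema_version": SCHEMA_VERSION,
        "family": "bundle",
        "metadata": metadata or {},
        "irt": {str(t): _irt_to_dict(f) for t, f in sorted(irt_fits.items())},
        "lmm": _lmm_to_dict(lmm_fit),
    }
    Path(path).write_text(json.dumps(d, indent=1))


def read_bundle(path) -> tuple[dict[int, IrtFit], MixedModelFit, dict]:
    d = json.loads(Path(path).read_text())
    if d.get("schema_version") != SCHEMA_VERSION or d.get("family") != "bundle":
        raise ValueError("not a model bundle file this reader understands")
    irt_fits = {int(t): _irt_from_dict(f) for t, f in d["irt"].items()}
    return irt_fits, _lmm_from_dict(d["lmm"]), d.get("metadata", {})
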