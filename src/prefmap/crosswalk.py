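"""Apply the published mapping coefficients to new FACT-H&N data.

This is the end-user deliverable: given FACT-H&N domain (or total) scores
plus age and gender, predict SF-6D utilities with the published model of
choice -- a direct model ("ols:M1" ... "ols:M5", "tobit:M1" ... "tobit:M5",
"betamix:M5a") or the indirect response mapping ("oprobit:M5", which needs
a tariff to turn level probabilities into utilities).

Because the source never states its gender coding, prediction with a
model that uses gender requires an explicit ``gender_coding`` declaration
("female1" or "male1") describing the *input data*; inputs are converted
to the package's female = 1 convention before the coefficients are
applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import published
from .design import MODEL_SPECS, build_design
from .estimators import FittedModel, predict_direct
from .instruments import SF6D_DIMENSIONS, Tariff, default_tariff
from .response_mapping import ResponseModelSet, predict_expected_utilities

__all__ = ["PublishedCoefficients", "published_model", "crosswalk_predict", "available_ids"]


@dataclass(frozen=True)
class PublishedCoefficients:
    """A published, transcription-checked coefficient set."""

    id: str
    family: str
    spec_id: str
    payload: dict
    provenance: str
    unstable: bool = False


def available_ids() -> list[str]:
    return (
        [f"ols:M{i}" for i in range(1, 6)]
        + [f"tobit:M{i}" for i in range(1, 6)]
        + ["oprobit:M5", "betamix:M5a"]
    )


def published_model(model_id: str) -> PublishedCoefficients:
    """Look up a published coefficient set by id (e.g. ``"ols:M5"``)."""
    if model_id not in available_ids():
        raise KeyError(
            f"unknown published model {model_id!r}; available: {available_ids()}"
        )
    family, spec_id = model_id.split(":")
    if family == "ols":
        payload = {"beta": dict(published.OLS_COEFFICIENTS[spec_id])}
        prov = "published OLS coefficient table"
    elif family == "tobit":
        payload = {"beta": dict(published.TOBIT_COEFFICIENTS[spec_id])}
        prov = "published Tobit coefficient table"
    elif family == "oprobit":
        payload = {"dimensions": published.OPROBIT_M5}
        prov = "published indirect-mapping (ordered probit) table, model 5"
    else:
        payload = dict(published.BETAMIX_M5A)
        prov = "published beta-mixture table, model 5a (mass block unstable)"
    # transcription sanity: every name resolves to a design column; cutpoints increase
    spec_cols = ("const",) + MODEL_SPECS[spec_id.rstrip("a")].columns
    if family in ("ols", "tobit"):
        unknown = set(payload["beta"]) - set(spec_cols)
        if unknown:
            raise AssertionError(f"{model_id}: unmapped coefficient names {unknown}")
    if family == "oprobit":
        for dim, block in payload["dimensions"].items():
            cuts = block["cutpoints"]
            if not all(a < b for a, b in zip(cuts, cuts[1:])):
                raise AssertionError(f"{model_id}/{dim}: cutpoints not increasing")
    return PublishedCoefficients(
        id=model_id,
        family=family,
        spec_id="M5" if spec_id == "M5a" else spec_id,
        payload=payload,
        provenance=prov,
        unstable=bool(payload.get("unstable_transcription", False)),
    )


def _prepare(data: pd.DataFrame, spec_id: str, gender_coding: str | None) -> pd.DataFrame:
    data = data.copy()
    spec = MODEL_SPECS[spec_id]
    if "total" in spec.required_columns and "total" not in data.columns:
        domain_cols = ["pwb", "swb", "ewb", "fwb", "hncs"]
        if all(c in data.columns for c in domain_cols):
            data["total"] = data[domain_cols].sum(axis=1)
    if "gender" in spec.required_columns:
        if gender_coding is None:
            raise ValueError(
                "this model uses gender; pass gender_coding='female1' or 'male1' "
                "describing your input coding (the source does not state its own, "
                "so no silent default is applied)"
            )
        if gender_coding not in ("female1", "male1"):
            raise ValueError(f"unknown gender_coding {gender_coding!r}")
        if gender_coding == "male1":
            data["gender"] = 1 - data["gender"].astype(int)
    missing = [c for c in spec.required_columns if c not in data.columns]
    if missing:
        raise KeyError(f"input is missing predictor column(s): {missing}")
    bad = data[list(spec.required_columns)].isna().any(axis=1)
    if bad.any():
        raise ValueError(
            f"rows with missing predictors: {list(data.index[bad])[:10]}"
        )
    return data


def crosswalk_predict(
    data: pd.DataFrame,
    model_id: str,
    gender_coding: str | None = None,
    tariff: Tariff | None = None,
    clip: bool = False,
) -> np.ndarray:
    """Predict SF-6D utilities for new FACT-H&N rows with a published model.

    ``data`` needs the specification's predictors (``total`` is derived
    from the five domains when absent). Deterministic and row-order
    independent. ``clip`` clamps direct-model output into [floor, 1].
    """
    pub = published_model(model_id)
    data = _prepare(data, pub.spec_id, gender_coding)

    if pub.family in ("ols", "tobit"):
        X = build_design(data, pub.spec_id, intercept=True)
        beta = pub.payload["beta"]
        model = FittedModel(
            family=pub.family,
            spec_id=pub.spec_id,
            columns=X.columns,
            coefficients={c: float(beta[c]) for c in X.columns},
            loglik=float("nan"),
            n_params=len(beta) + (1 if pub.family == "tobit" else 0),
            n_obs=0,
            extras={"sigma": float("nan"), "upper": 1.0},
        )
        return predict_direct(model, X, clip=clip)

    if pub.family == "oprobit":
        tariff = tariff or default_tariff()
        X = build_design(data, pub.spec_id, intercept=False)
        models = {}
        for dim in SF6D_DIMENSIONS:
            block = pub.payload["dimensions"][dim]
            cuts = block["cutpoints"]
            models[dim] = FittedModel(
                family="oprobit",
                spec_id=pub.spec_id,
                columns=X.columns,
                coefficients={c: float(block["beta"][c]) for c in X.columns},
                loglik=float("nan"),
                n_params=len(X.columns) + len(cuts),
                n_obs=0,
                extras={
                    "cutpoints": list(cuts),
                    "n_categories": len(cuts) + 1,
                    "level_map": {str(j + 1): j for j in range(len(cuts) + 1)},
                    "dimension": dim,
                },
            )
        model_set = ResponseModelSet(spec_id=pub.spec_id, models=models)
        return predict_expected_utilities(model_set, data, tariff)

    # betamix:M5a -- single component, mass at full health, bounds (0.315, 1)
    X = build_design(data, pub.spec_id, intercept=True)
    mu = pub.payload["mu"]
    mass = pub.payload["mass"]
    model = FittedModel(
        family="betamix",
        spec_id=pub.spec_id,
        columns=X.columns,
        coefficients={f"c1_{c}": float(mu[c]) for c in X.columns},
        loglik=float("nan"),
        n_params=2 * len(X.columns) + 1,
        n_obs=0,
        extras={
            "components": 1,
            "beta_components": [[float(mu[c]) for c in X.columns]],
            "lnphi": [float(pub.payload["lnphi"])],
            "mixing_probs": [1.0],
            "mass_coefficients": {c: float(mass[c]) for c in X.columns},
            "bounds": [0.315, 1.0],
            "truncated": False,
            "mass_at_ub": True,
        },
    )
    with np.errstate(over="ignore", under="ignore"):
        return predict_direct(model, X, clip=clip)
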