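"""Indirect (two-stage) mapping: per-dimension ordered probits + tariff.

Stage one fits a separate ordered probit for each of the six SF-6D
dimensions on the same predictor set; stage two converts each row's
predicted level probabilities into an expected utility under a tariff,

    E[U | x] = sum over joint states s of tariff(s) * prod_d p_d(s_d | x),

assuming cross-dimension independence given the covariates. For a purely
additive tariff this collapses to constant + sum_d sum_j p_d(j) *
decrement(d, j); both routes are implemented and must agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignMatrix, ModelSpec, build_design
from .estimators import FitError, FittedModel
from .estimators import fit_ordered_probit as _fit_oprobit
from .instruments import SF6D_DIMENSIONS, SF6D_LEVEL_COUNTS, Tariff, apply_tariff, enumerate_states

__all__ = [
    "ResponseModelSet",
    "fit_response_mapping",
    "level_probabilities",
    "expected_utility",
    "predict_expected_utilities",
]


@dataclass
class ResponseModelSet:
    """Six per-dimension ordered-probit models sharing one specification."""

    spec_id: str
    models: dict[str, FittedModel]  # keyed by SF-6D dimension name

    def __post_init__(self) -> None:
        if tuple(self.models) != SF6D_DIMENSIONS:
            raise ValueError(
                f"expected one model per dimension in order {SF6D_DIMENSIONS}, "
                f"got {tuple(self.models)}"
            )

    @property
    def loglik(self) -> float:
        return float(sum(m.loglik for m in self.models.values()))

    @property
    def n_params(self) -> int:
        return int(sum(m.n_params for m in self.models.values()))

    @property
    def n_obs(self) -> int:
        return next(iter(self.models.values())).n_obs

    def to_dict(self) -> dict:
        return {
            "family": "response_mapping",
            "spec_id": self.spec_id,
            "dimensions": {d: m.to_dict() for d, m in self.models.items()},
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "ResponseModelSet":
        return cls(
            spec_id=raw["spec_id"],
            models={
                d: FittedModel.from_dict(m) for d, m in raw["dimensions"].items()
            },
        )


def fit_response_mapping(
    cohort: pd.DataFrame,
    spec: ModelSpec | str,
    compute_se: bool = True,
) -> ResponseModelSet:
    """Fit the six per-dimension ordered probits on a cohort."""
    X = build_design(cohort, spec, intercept=False)
    spec_id = spec if isinstance(spec, str) else spec.id
    models: dict[str, FittedModel] = {}
    for dim in SF6D_DIMENSIONS:
        col = f"sf6d_{dim}"
        if col not in cohort.columns:
            raise KeyError(f"cohort is missing SF-6D level column {col!r}")
        levels = cohort[col].to_numpy(dtype=int)[X.index]
        try:
            models[dim] = _fit_oprobit(
                X, levels, spec_id=spec_id, dimension=dim, compute_se=compute_se
            )
        except FitError as exc:
            raise FitError(f"dimension {dim!r}: {exc}") from exc
    return ResponseModelSet(spec_id=spec_id, models=models)


def level_probabilities(model: FittedModel, X: DesignMatrix) -> np.ndarray:
    """Per-row level probabilities P(j) = Phi(k_j - x b) - Phi(k_{j-1} - x b).

    Returns an (n, J) array over the model's fitted categories (collapsed
    categories excluded; see ``extras['level_map']`` for the alignment).
    """
    if tuple(X.columns) != tuple(model.columns):
        raise ValueError(
            f"design columns {X.columns} do not match model columns {model.columns}"
        )
    cut = np.asarray(model.extras["cutpoints"], dtype=float)
    eta = X.values @ model.beta
    edges = np.concatenate([[-np.inf], cut, [np.inf]])
    cdf = stats.norm.cdf(edges[None, :] - eta[:, None])
    return np.diff(cdf, axis=1)


def _expand_probs(model: FittedModel, probs: np.ndarray, n_levels: int) -> np.ndarray:
    """Map fitted-category probabilities back onto tariff level indices."""
    full = np.zeros((probs.shape[0], n_levels))
    level_map = model.extras.get("level_map") or {
        str(j + 1): j for j in range(probs.shape[1])
    }
    for level_str, cat_idx in level_map.items():
        full[:, int(level_str) - 1] = probs[:, cat_idx]
    return full


def expected_utility(
    probs: list[np.ndarray] | list[list[float]],
    tariff: Tariff,
    method: str = "auto",
) -> np.ndarray:
    """Expected utility from six per-dimension level-probability vectors.

    ``probs`` is a list of six arrays, each (n, J_d) (1-d vectors are
    treated as a single row). ``method`` 'additive' uses the closed form
    for tariffs without global terms; 'enumerate' sums over all joint
    states; 'auto' picks additive when exact, enumeration otherwise.
    """
    mats = []
    for dim_index, (dim, count) in enumerate(zip(SF6D_DIMENSIONS, SF6D_LEVEL_COUNTS)):
        a = np.atleast_2d(np.asarray(probs[dim_index], dtype=float))
        if a.shape[1] != count:
            raise ValueError(
                f"dimension {dim!r}: probability vector has {a.shape[1]} levels, "
                f"tariff expects {count}"
            )
        if not np.allclose(a.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError(f"dimension {dim!r}: probabilities do not sum to 1")
        mats.append(a)
    n = max(m.shape[0] for m in mats)
    mats = [np.broadcast_to(m, (n, m.shape[1])) for m in mats]

    if method == "auto":
        method = "additive" if not tariff.global_terms else "enumerate"
    if method == "additive":
        if tariff.global_terms:
            raise ValueError("additive shortcut is exact only without global terms")
        eu = np.full(n, tariff.constant)
        for dim_index, m in enumerate(mats):
            eu += m @ np.asarray(tariff.decrements[dim_index])
        return eu
    if method == "enumerate":
        eu = np.zeros(n)
        for state in enumerate_states(tariff):
            w = np.ones(n)
            for dim_index, level in enumerate(state.levels):
                w *= mats[dim_index][:, level - 1]
            eu += w * apply_tariff(state, tariff)
        return eu
    raise ValueError(f"unknown method {method!r}")


def predict_expected_utilities(
    model_set: ResponseModelSet,
    cohort: pd.DataFrame,
    tariff: Tariff,
    method: str = "auto",
) -> np.ndarray:
    """Expected utilities for cohort rows under a fitted response mapping."""
    X = build_design(cohort, model_set.spec_id, intercept=False)
    probs = []
    for dim_index, dim in enumerate(SF6D_DIMENSIONS):
        model = model_set.models[dim]
        p = level_probabilities(model, X)
        probs.append(_expand_probs(model, p, SF6D_LEVEL_COUNTS[dim_index]))
    return expected_utility(probs, tariff, method=method)
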