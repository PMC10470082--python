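"""Internal validation: fivefold cross-validation, 70/30 holdout, combined ARV.

Candidate models are refit on every training split. Cross-validation
metrics are computed once per model on the pooled out-of-fold prediction
vector (one statistic per model per validation, matching how the combined
selection table is laid out); a per-fold-average alternative is available
behind a flag. The final selection ranks the 10 validation statistics
(5 per procedure) across models with midranks and averages them; the
lowest combined ARV wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, train_test_split

from .design import build_design
from .estimators import (
    FitError,
    fit_beta_mixture,
    fit_ols,
    fit_tobit,
    predict_direct,
)
from .evaluation import RankResult, arv, ccc, error_metrics
from .instruments import Tariff, default_tariff
from .response_mapping import fit_response_mapping, predict_expected_utilities

__all__ = [
    "ModelCandidate",
    "kfold_split",
    "cross_validate",
    "holdout_validate",
    "combined_selection",
    "ValidationReport",
]

logger = logging.getLogger(__name__)

#: The five statistics reported per validation procedure.
VALIDATION_METRICS = ("rmse", "mae", "ccc", "ae_gt_005", "ae_gt_010")


@dataclass(frozen=True)
class ModelCandidate:
    """A (family, specification) pair plus family-specific options."""

    family: str  # ols | tobit | oprobit | betamix
    spec_id: str
    options: tuple[tuple[str, object], ...] = ()

    @property
    def label(self) -> str:
        suffix = dict(self.options).get("label_suffix", "")
        return f"{self.family.upper()} {self.spec_id}{suffix}"

    def fit_predict(
        self,
        train: pd.DataFrame,
        test: pd.DataFrame,
        tariff: Tariff | None = None,
    ) -> np.ndarray:
        """Fit on the training cohort, predict utilities for the test rows."""
        opts = {k: v for k, v in self.options if k != "label_suffix"}
        if self.family in ("ols", "tobit", "betamix"):
            Xtr = build_design(train, self.spec_id, intercept=True)
            Xte = build_design(test, self.spec_id, intercept=True)
            y = train["utility"].to_numpy(dtype=float)[Xtr.index]
            if self.family == "ols":
                model = fit_ols(Xtr, y, spec_id=self.spec_id)
            elif self.family == "tobit":
                model = fit_tobit(Xtr, y, spec_id=self.spec_id, compute_se=False, **opts)
            else:
                model = fit_beta_mixture(Xtr, y, spec_id=self.spec_id, **opts)
            return predict_direct(model, Xte)
        if self.family == "oprobit":
            model_set = fit_response_mapping(train, self.spec_id, compute_se=False)
            return predict_expected_utilities(
                model_set, test, tariff or default_tariff()
            )
        raise ValueError(f"unknown family {self.family!r}")


def kfold_split(n: int, k: int, seed: int = 0) -> np.ndarray:
    """Fold label (0..k-1) per row; sizes differ by at most one."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k = {k} exceeds n = {n}")
    labels = np.empty(n, dtype=int)
    for fold, (_, test_idx) in enumerate(
        KFold(n_splits=k, shuffle=True, random_state=seed).split(np.arange(n))
    ):
        labels[test_idx] = fold
    return labels


def _score(obs: np.ndarray, pred: np.ndarray) -> dict[str, float]:
    out = error_metrics(obs, pred)
    out["ccc"] = ccc(obs, pred)
    return {m: out[m] for m in VALIDATION_METRICS}


def cross_validate(
    candidates: list[ModelCandidate],
    cohort: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
    tariff: Tariff | None = None,
    per_fold_average: bool = False,
) -> pd.DataFrame:
    """K-fold CV metrics per candidate (pooled out-of-fold predictions)."""
    n = len(cohort)
    folds = kfold_split(n, k, seed)
    obs = cohort["utility"].to_numpy(dtype=float)
    rows = {}
    for cand in candidates:
        pooled = np.full(n, np.nan)
        fold_scores = []
        failed = False
        for fold in range(k):
            test_mask = folds == fold
            train = cohort.loc[~test_mask]
            test = cohort.loc[test_mask]
            try:
                pred = cand.fit_predict(train, test, tariff)
            except FitError as exc:
                logger.warning("%s failed on fold %d: %s", cand.label, fold, exc)
                failed = True
                break
            pooled[test_mask] = pred
            if per_fold_average:
                fold_scores.append(_score(obs[test_mask], pred))
        if failed:
            continue
        if per_fold_average:
            rows[cand.label] = pd.DataFrame(fold_scores).mean().to_dict()
        else:
            rows[cand.label] = _score(obs, pooled)
    return pd.DataFrame.from_dict(rows, orient="index")


def holdout_validate(
    candidates: list[ModelCandidate],
    cohort: pd.DataFrame,
    train_fraction: float = 0.70,
    seed: int = 0,
    tariff: Tariff | None = None,
) -> pd.DataFrame:
    """Random train/test split metrics per candidate."""
    idx = np.arange(len(cohort))
    train_idx, test_idx = train_test_split(
        idx, train_size=train_fraction, random_state=seed, shuffle=True
    )
    train, test = cohort.iloc[train_idx], cohort.iloc[test_idx]
    obs = test["utility"].to_numpy(dtype=float)
    rows = {}
    for cand in candidates:
        try:
            pred = cand.fit_predict(train, test, tariff)
        except FitError as exc:
            logger.warning("%s failed on holdout: %s", cand.label, exc)
            continue
        rows[cand.label] = _score(obs, pred)
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class ValidationReport:
    """Both validations' statistics, their joint ranks and combined ARV."""

    metrics: pd.DataFrame  # models x 10 columns (suffixes _cv / _holdout)
    rank_result: RankResult = field(init=False)

    def __post_init__(self) -> None:
        self.rank_result = arv(self.metrics, pool="combined-validation")

    @property
    def combined_arv(self) -> pd.Series:
        return self.rank_result.arv

    @property
    def winner(self) -> str:
        return self.rank_result.winner


def combined_selection(valI: pd.DataFrame, valII: pd.DataFrame) -> ValidationReport:
    """Combine CV and holdout statistics into the final ARV ranking."""
    if set(valI.index) != set(valII.index):
        raise ValueError("validation tables cover different model sets")
    joined = valI.add_suffix("_cv").join(valII.add_suffix("_holdout"))
    if joined.shape[1] != 2 * len(VALIDATION_METRICS):
        raise ValueError(
            f"expected {2 * len(VALIDATION_METRICS)} statistic columns, "
            f"got {joined.shape[1]}"
        )
    return ValidationReport(metrics=joined)
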