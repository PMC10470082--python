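"""Predictor sets for the five mapping model specifications.

M1: FACT-H&N total score.
M2: total + total squared.
M3: the five domain scores.
M4: domains + squared domains.
M5: M4 + age + gender.

Squared terms are raw squares of the unscaled scores; gender is coded
female = 1, male = 0 by default (configurable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .instruments import FACT_DOMAINS

__all__ = ["ModelSpec", "DesignMatrix", "MODEL_SPECS", "build_design"]

logger = logging.getLogger(__name__)

_DOMAINS = list(FACT_DOMAINS)


@dataclass(frozen=True)
class ModelSpec:
    """A named predictor set."""

    id: str
    predictors: tuple[str, ...]  # raw cohort columns used linearly
    squared: tuple[str, ...] = ()  # columns entering as raw squares
    covariates: tuple[str, ...] = ()  # age / gender

    @property
    def columns(self) -> tuple[str, ...]:
        """Design column names, excluding the intercept."""
        return (
            self.predictors
            + tuple(f"{c}_sq" for c in self.squared)
            + self.covariates
        )

    @property
    def n_predictors(self) -> int:
        return len(self.columns)

    @property
    def required_columns(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.predictors + self.squared + self.covariates))


MODEL_SPECS: dict[str, ModelSpec] = {
    "M1": ModelSpec("M1", ("total",)),
    "M2": ModelSpec("M2", ("total",), squared=("total",)),
    "M3": ModelSpec("M3", tuple(_DOMAINS)),
    "M4": ModelSpec("M4", tuple(_DOMAINS), squared=tuple(_DOMAINS)),
    "M5": ModelSpec(
        "M5", tuple(_DOMAINS), squared=tuple(_DOMAINS), covariates=("age", "gender")
    ),
}


@dataclass(frozen=True)
class DesignMatrix:
    """A numeric design matrix with a fixed, documented column order."""

    values: np.ndarray
    columns: tuple[str, ...]
    has_intercept: bool
    index: np.ndarray  # cohort row positions retained (complete cases)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        """Number of columns, including the intercept when present."""
        return self.values.shape[1]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.columns))


def build_design(
    cohort: pd.DataFrame,
    spec: ModelSpec | str,
    intercept: bool = True,
    square_divisor: float = 1.0,
) -> DesignMatrix:
    """Build the design matrix for a specification from a cohort frame.

    Rows with missing values on required columns are dropped
    (complete-case, logged). ``square_divisor`` optionally rescales the
    squared terms (x**2 / divisor); the default leaves them raw.

    The intercept is included for the direct models and should be
    disabled for ordered-probit fits, whose cutpoints absorb it.
    """
    if isinstance(spec, str):
        spec = MODEL_SPECS[spec]
    missing = [c for c in spec.required_columns if c not in cohort.columns]
    if missing:
        raise KeyError(f"cohort is missing required column(s): {missing}")

    sub = cohort[list(spec.required_columns)]
    complete = sub.notna().all(axis=1).to_numpy()
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("build_design(%s): dropped %d incomplete row(s)", spec.id, n_dropped)
    sub = sub.loc[complete]

    blocks = []
    names: list[str] = []
    if intercept:
        blocks.append(np.ones((len(sub), 1)))
        names.append("const")
    for col in spec.predictors:
        blocks.append(sub[col].to_numpy(dtype=float)[:, None])
        names.append(col)
    for col in spec.squared:
        blocks.append((sub[col].to_numpy(dtype=float) ** 2 / square_divisor)[:, None])
        names.append(f"{col}_sq")
    for col in spec.covariates:
        blocks.append(sub[col].to_numpy(dtype=float)[:, None])
        names.append(col)

    return DesignMatrix(
        values=np.hstack(blocks),
        columns=tuple(names),
        has_intercept=intercept,
        index=np.flatnonzero(complete),
    )
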