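"""Goodness-of-fit statistics and average-rank-value (ARV) model selection.

Error metrics (RMSE, MAE, percent of absolute errors above 0.05 / 0.10),
Lin's concordance correlation coefficient, AIC/BIC, Bland-Altman limits
of agreement, distributional descriptives, and the ARV machinery that
ranks models metric-by-metric (midranks on ties) and averages the ranks:
the model with the lowest ARV wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "error_metrics",
    "ccc",
    "information_criteria",
    "arv",
    "bland_altman",
    "descriptives",
    "spearman_band",
    "METRIC_ORIENTATION",
]

#: Better-direction per metric: -1 = lower is better, +1 = higher is better.
METRIC_ORIENTATION: dict[str, int] = {
    "rmse": -1,
    "mae": -1,
    "ccc": +1,
    "ae_gt_005": -1,
    "ae_gt_010": -1,
    "aic": -1,
    "bic": -1,
}


def _check_pair(obs, pred) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or obs.size == 0:
        raise ValueError(
            f"observed and predicted must be equal-length 1-d vectors, got "
            f"{obs.shape} and {pred.shape}"
        )
    return obs, pred


def error_metrics(obs, pred) -> dict[str, float]:
    """RMSE, MAE and the percent of absolute errors strictly above 0.05/0.10.

    The threshold statistics use strict inequality: an absolute error of
    exactly 0.05 does not count against the 0.05 threshold.
    """
    obs, pred = _check_pair(obs, pred)
    err = obs - pred
    return {
        "rmse": float(np.sqrt(np.mean(err**2))),
        "mae": float(np.mean(np.abs(err))),
        "ae_gt_005": float(100.0 * np.mean(np.abs(err) > 0.05)),
        "ae_gt_010": float(100.0 * np.mean(np.abs(err) > 0.10)),
    }


def ccc(obs, pred, bias_corrected: bool = False) -> float:
    """Lin's concordance correlation coefficient.

    2*s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2), with 1/n moment
    normalisation per Lin's original formulation (``bias_corrected``
    switches to n-1; the difference is negligible for n >= 100).
    """
    x, y = _check_pair(obs, pred)
    if x.size < 2:
        raise ValueError("ccc requires at least 2 observations")
    ddof = 1 if bias_corrected else 0
    sx2 = np.var(x, ddof=ddof)
    sy2 = np.var(y, ddof=ddof)
    sxy = np.cov(x, y, ddof=ddof)[0, 1] if ddof else np.mean(
        (x - x.mean()) * (y - y.mean())
    )
    denom = sx2 + sy2 + (x.mean() - y.mean()) ** 2
    if denom == 0:
        raise ValueError("ccc undefined: zero variance and equal means")
    return float(2.0 * sxy / denom)


def information_criteria(loglik: float, k: int, n: int) -> tuple[float, float]:
    """AIC = 2k - 2*loglik and BIC = k*ln(n) - 2*loglik."""
    if n <= 0 or k < 1:
        raise ValueError("need n > 0 and k >= 1")
    return 2.0 * k - 2.0 * loglik, k * float(np.log(n)) - 2.0 * loglik


@dataclass
class RankResult:
    """Per-model per-metric ranks and their average (ARV)."""

    pool: str
    ranks: pd.DataFrame  # models x metrics
    arv: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self.arv = self.ranks.mean(axis=1)

    @property
    def winner(self) -> str:
        return str(self.arv.idxmin())


def arv(
    metrics: pd.DataFrame,
    orientation: dict[str, int] | None = None,
    pool: str = "",
) -> RankResult:
    """Average rank value over a pool of models.

    ``metrics`` is a models-by-metrics frame. Each metric column is ranked
    across models -- ascending where lower is better, descending for CCC --
    with midranks on ties; the ARV is the mean rank across columns.
    """
    orientation = orientation or METRIC_ORIENTATION
    missing = metrics.isna()
    if missing.any().any():
        model = missing.any(axis=1).idxmax()
        metric = missing.loc[model].idxmax()
        raise ValueError(f"model {model!r} is missing metric {metric!r}")
    ranks = {}
    for col in metrics.columns:
        direction = orientation.get(_base_metric(col))
        if direction is None:
            raise ValueError(f"no orientation known for metric {col!r}")
        values = metrics[col].to_numpy(dtype=float)
        ranks[col] = stats.rankdata(-direction * values, method="average")
    return RankResult(pool=pool, ranks=pd.DataFrame(ranks, index=metrics.index))


def _base_metric(col: str) -> str:
    """Strip a validation-phase suffix, e.g. 'rmse_cv' -> 'rmse'."""
    for base in METRIC_ORIENTATION:
        if col == base or col.startswith(base + "_"):
            return base
    return col


def bland_altman(obs, pred) -> dict:
    """Bland-Altman agreement: mean difference, 95% limits, percent outside.

    diff = obs - pred; limits = mean(diff) +/- 1.96 * SD(diff) (sample SD);
    ``pct_outside`` counts points strictly outside the limits. The returned
    dict also carries the (mean-of-pair, diff) series for plotting.
    """
    obs, pred = _check_pair(obs, pred)
    if obs.size < 2:
        raise ValueError("bland_altman requires at least 2 observations")
    diff = obs - pred
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    lo, hi = mean_diff - 1.96 * sd, mean_diff + 1.96 * sd
    outside = (diff < lo) | (diff > hi)
    return {
        "mean_diff": mean_diff,
        "loa_low": lo,
        "loa_high": hi,
        "pct_outside": float(100.0 * outside.mean()),
        "pair_mean": (obs + pred) / 2.0,
        "diff": diff,
    }


def descriptives(
    values, floor: float | None = None, ceiling: float | None = None
) -> dict[str, float]:
    """Mean, SD, min/percentiles/max, moment skewness/kurtosis, floor/ceiling %."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("descriptives requires a non-empty vector")
    out = {
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0,
        "min": float(x.min()),
        "p10": float(np.percentile(x, 10)),
        "median": float(np.median(x)),
        "p90": float(np.percentile(x, 90)),
        "max": float(x.max()),
        "skewness": float(stats.skew(x)) if x.std() > 0 else 0.0,
        "kurtosis": float(stats.kurtosis(x, fisher=False)) if x.std() > 0 else float("nan"),
        "n": int(x.size),
    }
    if floor is not None:
        out["pct_floor"] = float(100.0 * np.mean(x <= floor))
    if ceiling is not None:
        out["pct_ceiling"] = float(100.0 * np.mean(x >= ceiling))
    return out


#: Interpretation bands for |Spearman rho|.
_SPEARMAN_BANDS = [
    (0.20, "very weak"),
    (0.40, "weak"),
    (0.60, "moderate"),
    (0.80, "strong"),
    (1.01, "very strong"),
]


def correlation_band(rho: float) -> str:
    """Strength label for |rho|: very weak < 0.20 <= weak < 0.40 <= moderate
    < 0.60 <= strong < 0.80 <= very strong."""
    mag = abs(rho)
    for upper, label in _SPEARMAN_BANDS:
        if mag < upper:
            return label
    return "very strong"


def spearman_band(x, y) -> tuple[float, str]:
    """Spearman rank correlation (midranks) and its strength band."""
    x, y = _check_pair(x, y)
    rho = float(stats.spearmanr(x, y).statistic)
    return rho, correlation_band(rho)
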