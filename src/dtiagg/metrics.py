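"""Regression evaluation: MSE, coefficient of determination, concordance index.

The concordance index (CI) is the probability that two randomly chosen
pairs with different true affinities are ranked in the correct order by
the predictions:

    CI = sum_{i,j} I(y_i > y_j) I(yhat_i > yhat_j) / sum_{i,j} I(y_i > y_j)

with a strict indicator, so tied predictions score 0 by default; the
0.5-credit convention common in survival analysis is available via
``ties``.  ``top_k_average`` reproduces the trial-aggregation used for
reporting: the arithmetic mean of each metric over the k
lowest-validation-loss configurations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class MetricError(ValueError):
    pass


@dataclass(frozen=True)
class MetricsReport:
    mse: float
    r2: float
    ci: float
    n: int
    param_count: int = 0

    def as_dict(self) -> dict:
        return {"mse": self.mse, "r2": self.r2, "ci": self.ci,
                "n": self.n, "param_count": self.param_count}


def _validate(y, yhat, min_n=1):
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise MetricError(f"length mismatch: {y.size} true vs {yhat.size} predicted")
    if y.size < min_n:
        raise MetricError(f"need at least {min_n} pairs, got {y.size}")
    return y, yhat


def mse(y, yhat) -> float:
    """Mean of the squared differences between predictions and true values."""
    y, yhat = _validate(y, yhat, min_n=1)
    return float(np.mean((yhat - y) ** 2))


def r_squared(y, yhat) -> float:
    """1 - SS_res / SS_tot; may be negative for predictors worse than the mean."""
    y, yhat = _validate(y, yhat, min_n=2)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise MetricError("r_squared undefined: true affinities are constant")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def concordance_index(y, yhat, ties: str = "strict") -> float:
    """Fraction of comparable pairs (y_i > y_j) ranked correctly by yhat.

    ``ties="strict"`` scores tied predictions as incorrect (literal
    indicator); ``ties="half"`` gives them 0.5 credit.
    """
    if ties not in ("strict", "half"):
        raise MetricError("ties must be 'strict' or 'half'")
    y, yhat = _validate(y, yhat, min_n=2)
    gt = y[:, None] > y[None, :]          # comparable ordered pairs
    n_comparable = int(gt.sum())
    if n_comparable == 0:
        raise MetricError("concordance undefined: no pair with y_i > y_j")
    correct = (yhat[:, None] > yhat[None, :]) & gt
    score = float(correct.sum())
    if ties == "half":
        tied = (yhat[:, None] == yhat[None, :]) & gt
        score += 0.5 * float(tied.sum())
    return score / n_comparable


def evaluate(y, yhat, param_count: int = 0, ties: str = "strict") -> MetricsReport:
    y = np.asarray(y, dtype=float).ravel()
    return MetricsReport(mse=mse(y, yhat), r2=r_squared(y, yhat),
                         ci=concordance_index(y, yhat, ties=ties),
                         n=int(y.size), param_count=param_count)


def top_k_average(trials: list[tuple[float, MetricsReport]], k: int = 5) -> MetricsReport:
    """Mean metrics of the k lowest-loss trials.

    ``trials`` is a list of (selection_loss, report); ties in the loss
    break by input order.
    """
    if k < 1:
        raise MetricError("k must be >= 1")
    if len(trials) < k:
        raise MetricError(f"need at least k={k} trials, got {len(trials)}")
    order = sorted(range(len(trials)), key=lambda i: (trials[i][0], i))[:k]
    chosen = [trials[i][1] for i in order]
    return MetricsReport(
        mse=float(np.mean([r.mse for r in chosen])),
        r2=float(np.mean([r.r2 for r in chosen])),
        ci=float(np.mean([r.ci for r in chosen])),
        n=int(np.mean([r.n for r in chosen])),
        param_count=int(round(np.mean([r.param_count for r in chosen]))),
    )
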