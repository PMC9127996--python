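"""Regression comparison of model-predicted versus observed soil guild rates."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["ModelFitSummary", "compare", "compare_keyed"]


@dataclass(frozen=True)
class ModelFitSummary:
    """OLS summary of observed soil rates regressed on model predictions.

    r_squared is symmetric in the two series; slope/intercept and the
    two-sided slope p-value refer to observed-on-predicted.  ``flag`` is set
    (and the statistics are NaN) when the predictions have zero variance and
    the regression is undefined.
    """

    organism: str
    model: str
    soil: str
    r_squared: float
    p_value: float
    n: int
    slope: float
    intercept: float
    flag: Optional[str] = None


def compare(predicted: Sequence[float], observed: Sequence[float],
            organism: str = "", model: str = "", soil: str = "") -> ModelFitSummary:
    """Ordinary least squares of observed on predicted rates.

    Requires n ≥ 3 matched points.  Zero-variance predictions make the
    regression undefined; the summary is then flagged rather than raising.
    """
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"unmatched series lengths {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 matched points, got {n}")
    if np.std(x) == 0:
        return ModelFitSummary(organism, model, soil, float("nan"), float("nan"),
                               n, float("nan"), float("nan"),
                               flag="zero-variance predictions: regression undefined")
    fit = sps.linregress(x, y)
    return ModelFitSummary(organism, model, soil, float(fit.rvalue**2),
                           float(fit.pvalue), n, float(fit.slope), float(fit.intercept))


def compare_keyed(predictions: dict, observations: dict,
                  organism: str = "", model: str = "", soil: str = "") -> ModelFitSummary:
    """Compare series keyed by (soil, temperature); keys must match exactly."""
    if set(predictions) != set(observations):
        missing = set(predictions) ^ set(observations)
        raise ValueError(f"unmatched keys between predicted and observed series: {sorted(missing)}")
    keys = sorted(predictions)
    return compare([predictions[k] for k in keys], [observations[k] for k in keys],
                   organism=organism, model=model, soil=soil)
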