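"""Agreement and error statistics between predictions and reference values.

Implements the evaluation battery used throughout the package: Pearson's r,
RMSE, range-normalized RMSE (in percent), Bland-Altman bias and 95% limits
of agreement, and the least-squares regression line of predictions on truths
with the two-sided Wald t-test p-value for a zero slope.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class EvaluationReport:
    """Agreement statistics between predictions and ground truth."""

    slope: float
    intercept: float
    pearson_r: float
    wald_p: float
    rmse: float
    nrmse: float     # percent of the reference range
    bias: float
    loa_low: float
    loa_high: float
    n: int

    def __post_init__(self):
        if not (self.loa_low <= self.bias <= self.loa_high):
            raise ValueError("limits of agreement must bracket the bias")
        if self.nrmse < 0:
            raise ValueError("nRMSE must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def summary(self) -> str:
        return (f"n={self.n}  slope={self.slope:.3f}  intercept={self.intercept:.4g}  "
                f"r={self.pearson_r:.3f} (p={self.wald_p:.2g})  "
                f"RMSE={self.rmse:.4g}  nRMSE={self.nrmse:.2f}%  "
                f"bias={self.bias:.4g} [{self.loa_low:.4g}, {self.loa_high:.4g}]")


def _arrays(predictions, truths):
    p = np.asarray(predictions, dtype=float).ravel()
    t = np.asarray(truths, dtype=float).ravel()
    if p.size != t.size:
        raise ValueError("predictions and truths must have equal length")
    if p.size < 1:
        raise ValueError("empty input")
    return p, t


def rmse(predictions, truths) -> float:
    """Root-mean-square error, in the units of the target."""
    p, t = _arrays(predictions, truths)
    return float(np.sqrt(np.mean((p - t) ** 2)))


def nrmse(predictions, truths) -> float:
    """RMSE normalized by the range of the reference variable, in percent.

    100 * RMSE / (max(truth) - min(truth)).
    """
    p, t = _arrays(predictions, truths)
    rng = float(np.max(t) - np.min(t))
    if rng == 0:
        raise ValueError("reference range is zero: nRMSE undefined")
    return 100.0 * rmse(p, t) / rng


def pearson(predictions, truths) -> float:
    """Pearson correlation coefficient."""
    p, t = _arrays(predictions, truths)
    return float(np.corrcoef(p, t)[0, 1])


def bland_altman(predictions, truths) -> tuple[float, float, float]:
    """(bias, loa_low, loa_high): mean difference +/- 1.96 sample SD."""
    p, t = _arrays(predictions, truths)
    d = p - t
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def linreg_wald(predictions, truths) -> tuple[float, float, float]:
    """(slope, intercept, p): least squares of predictions on truths.

    p is the two-sided Wald t-test p-value for the null hypothesis that the
    slope is zero.
    """
    p, t = _arrays(predictions, truths)
    res = sps.linregress(t, p)
    return float(res.slope), float(res.intercept), float(res.pvalue)


def evaluate(predictions, truths) -> EvaluationReport:
    """Full agreement report between predictions and reference values."""
    p, t = _arrays(predictions, truths)
    slope, intercept, pval = linreg_wald(p, t)
    bias, lo, hi = bland_altman(p, t)
    return EvaluationReport(
        slope=slope, intercept=intercept,
        pearson_r=pearson(p, t), wald_p=pval,
        rmse=rmse(p, t), nrmse=nrmse(p, t),
        bias=bias, loa_low=lo, loa_high=hi, n=int(p.size),
    )
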