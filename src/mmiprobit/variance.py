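"""Variance partitioning and inter-station reliability.

The total latent variance of a probit model is 1 (residual, fixed by
identification) plus the sum of the factor variance components; each
factor's percentage contribution is 100 * sigma2 / total.  Cronbach's alpha
treats the nine station totals as items over candidates with complete
station profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cpmm import VarianceComponents
from .data import MMIDataset


@dataclass(frozen=True)
class VarianceDecomposition:
    """Factor variances with their shares of total latent variance."""

    sigma2: dict[str, float]
    residual: float
    total: float
    percent: dict[str, float]
    residual_percent: float

    def to_frame(self, n_levels: dict[str, int] | None = None) -> pd.DataFrame:
        rows = []
        for f, v in self.sigma2.items():
            rows.append(
                {
                    "factor": f,
                    "n_levels": (n_levels or {}).get(f, np.nan),
                    "variance": v,
                    "percent": self.percent[f],
                }
            )
        rows.append(
            {
                "factor": "residual",
                "n_levels": np.nan,
                "variance": self.residual,
                "percent": self.residual_percent,
            }
        )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ReliabilityResult:
    """Cronbach's alpha across stations on complete candidate profiles."""

    alpha: float
    n_items: int
    n_complete: int


def decompose_variance(variances: VarianceComponents) -> VarianceDecomposition:
    """Partition total latent variance (residual 1 + sum sigma2) into shares.

    Values are kept at full precision; rounding (2 dp in the shipped
    reports) happens only at presentation.
    """
    total = variances.residual + sum(variances.sigma2.values())
    percent = {f: 100.0 * v / total for f, v in variances.sigma2.items()}
    return VarianceDecomposition(
        sigma2=dict(variances.sigma2),
        residual=variances.residual,
        total=total,
        percent=percent,
        residual_percent=100.0 * variances.residual / total,
    )


def cronbach_alpha(dataset: MMIDataset) -> ReliabilityResult:
    """Cronbach's alpha between stations.

    Pivots to a candidates x stations matrix, keeps complete cases, and
    evaluates alpha = k/(k-1) * (1 - sum(var_item) / var_total) with
    sample variances (denominator n-1).

    Raises
    ------
    ValueError
        With fewer than 2 stations, fewer than 2 complete candidate
        profiles, or zero total-score variance (alpha undefined).
    """
    wide = dataset.records.pivot(index="candidate", columns="station", values="score")
    k = wide.shape[1]
    if k < 2:
        raise ValueError(f"need at least 2 stations, got {k}")
    complete = wide.dropna()
    n = len(complete)
    if n < 2:
        raise ValueError(f"need at least 2 complete candidate profiles, got {n}")
    item_var = complete.var(axis=0, ddof=1)
    total_var = complete.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total-score variance is zero; alpha is undefined")
    alpha = k / (k - 1) * (1.0 - float(item_var.sum()) / float(total_var))
    return ReliabilityResult(alpha=float(alpha), n_items=int(k), n_complete=int(n))
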