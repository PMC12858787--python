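"""Candidate-block bootstrap for the CPMM variance components.

The exchangeable sampling unit of an MMI cohort is the candidate: a
replicate draws n_candidates whole candidate score-blocks with replacement
(keeping original interviewer/station/day labels), refits the model, and
records the variance components, the total latent variance, and the
per-replicate percentage contributions.  Summaries are medians and 95%
empirical percentile intervals over converged replicates.

Percentages are summarised per replicate and then aggregated; the median
percentage is NOT the ratio of median variances, and the two conventions
genuinely differ (a regression test pins this down).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cpmm import FitOptions, FittedModel, ModelSpec, fit_cpmm
from .data import MMIDataset

#: Quantile rule for the percentile intervals: linear interpolation of
#: order statistics (numpy's "linear" method).
QUANTILE_METHOD = "linear"


@dataclass(frozen=True)
class BootstrapResult:
    """Replicate table and percentile summaries.

    ``replicates`` has one row per converged replicate with columns
    ``var_<factor>``, ``total`` and ``pct_<factor>``.  ``medians`` and
    ``ci95`` (rows ``lower``/``upper``) are computed over converged
    replicates only, by the documented percentile rule.
    """

    replicates: pd.DataFrame
    medians: pd.Series
    ci95: pd.DataFrame
    n_requested: int
    n_converged: int
    seed: int

    def summary_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "median": self.medians,
                "ci_lower": self.ci95.loc["lower"],
                "ci_upper": self.ci95.loc["upper"],
            }
        )
        out.index.name = "quantity"
        return out


def block_resample(dataset: MMIDataset, rng: np.random.Generator) -> MMIDataset:
    """Resample whole candidate blocks with replacement.

    Each drawn block carries all of that candidate's records; the i-th
    drawn block is relabelled with a fresh candidate ID ``B<i>_<orig>`` so
    repeated draws of one candidate stay distinct blocks.
    """
    codes = dataset.codes["candidate"]
    n_cand = dataset.n_levels("candidate")
    order = np.argsort(codes, kind="stable")
    starts = np.searchsorted(codes[order], np.arange(n_cand + 1))
    draws = rng.integers(0, n_cand, size=n_cand)
    rows = np.concatenate([order[starts[c] : starts[c + 1]] for c in draws])
    out = dataset.records.iloc[rows].reset_index(drop=True)
    block_sizes = starts[draws + 1] - starts[draws]
    labels = dataset.levels["candidate"]
    new_ids = np.repeat(
        [f"B{i+1:04d}_{labels[c]}" for i, c in enumerate(draws)], block_sizes
    )
    out["candidate"] = new_ids
    return MMIDataset(out, dataset.range)


def bootstrap_variances(
    dataset: MMIDataset,
    spec: ModelSpec | None = None,
    B: int = 1000,
    seed: int = 0,
    options: FitOptions = FitOptions(),
    base_model: FittedModel | None = None,
    max_fail_frac: float = 0.2,
) -> BootstrapResult:
    """Candidate-block bootstrap of the fitted variance components.

    One master seed spawns an independent seed stream per replicate, so
    increasing B leaves earlier replicates unchanged.  Replicates are
    warm-started from the base fit.  Replicates whose outer optimisation
    fails to converge are dropped and counted; more than ``max_fail_frac``
    of failures aborts with diagnostics.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if base_model is None:
        base_model = fit_cpmm(dataset, spec, options=options)
    factors = [f for f in base_model.spec.factors if f not in base_model.dropped_factors]

    child_seeds = np.random.SeedSequence(seed).spawn(B)
    rows = []
    n_failed = 0
    failures: list[str] = []
    for r in range(B):
        rng = np.random.default_rng(child_seeds[r])
        rep = block_resample(dataset, rng)
        try:
            model = fit_cpmm(rep, base_model.spec, options=options, start=base_model)
        except (ValueError, RuntimeError) as exc:  # structurally degenerate resample
            n_failed += 1
            failures.append(f"replicate {r}: {exc}")
            continue
        if not model.converged:
            n_failed += 1
            failures.append(f"replicate {r}: not converged (|grad|={model.grad_norm:.2e})")
            continue
        row = {"replicate": r}
        total = model.variances.total
        for f in factors:
            v = model.variances.sigma2.get(f, np.nan)
            row[f"var_{f}"] = v
            row[f"pct_{f}"] = 100.0 * v / total
        row["total"] = total
        rows.append(row)
    if n_failed > max_fail_frac * B:
        detail = "\n".join(failures[:10])
        raise RuntimeError(
            f"{n_failed}/{B} bootstrap replicates failed to converge "
            f"(limit {max_fail_frac:.0%}); first failures:\n{detail}"
        )
    replicates = pd.DataFrame(rows).set_index("replicate")
    cols = [c for c in replicates.columns]
    medians = pd.Series(
        {c: float(np.quantile(replicates[c].dropna(), 0.5, method=QUANTILE_METHOD)) for c in cols}
    )
    ci95 = pd.DataFrame(
        {
            c: np.quantile(
                replicates[c].dropna(), [0.025, 0.975], method=QUANTILE_METHOD
            )
            for c in cols
        },
        index=["lower", "upper"],
    )
    return BootstrapResult(
        replicates=replicates,
        medians=medians,
        ci95=ci95,
        n_requested=B,
        n_converged=B - n_failed,
        seed=seed,
    )
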