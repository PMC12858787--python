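"""Synthetic MMI cohorts drawn from the generative CPMM.

Emulates the structure of a real interview season: candidates are
partitioned across day x circuit cells, duplicate parallel circuits run on
each day, each circuit-day staffs one interviewer per station (interviewers
keep a "home" station across days, mirroring how interviewer backgrounds
are matched to station content), and every candidate is scored once at
each station.

Scores are generated from the latent-variable model: draw zero-mean
Gaussian effects per level, form Y* = mu + S_i + T_j + U_k + V_t + eps with
standard-normal eps, and discretise through the thresholds.  The ground
truth (effects and latent draws) is retained for recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .cpmm import Thresholds
from .data import FACTORS, CategoryRange, MMIDataset

#: Default true SDs: square roots of the candidate/interviewer/station/day
#: variance components used for the cohort-scale preset.
DEFAULT_SIGMA: dict[str, float] = {
    "candidate": float(np.sqrt(0.361)),
    "interviewer": float(np.sqrt(0.1692)),
    "station": float(np.sqrt(0.035)),
    "day": float(np.sqrt(0.003)),
}

#: Default target marginal score distribution over 3..15: mildly
#: left-skewed with a mode near 11, a realistic shape for interview rubric
#: totals where most candidates cluster above the scale midpoint.
DEFAULT_TARGET_MARGINAL: np.ndarray = np.array(
    [1, 2, 4, 7, 11, 16, 22, 27, 30, 27, 20, 12, 5], dtype=float
) / 184.0


class DesignInfeasibleError(ValueError):
    """Raised when the circuit structure cannot be staffed."""


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters and circuit structure for a synthetic cohort.

    ``sigma`` maps each factor to its true SD on the latent scale.  When
    ``thresholds`` is None they are derived from ``target_marginal`` via
    :func:`auto_thresholds` so the implied marginal score distribution
    matches the target.
    """

    n_candidates: int = 352
    n_interviewers: int = 83
    n_stations: int = 9
    n_days: int = 7
    circuits_per_day: int = 2
    sigma: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SIGMA))
    mu: float = 0.0
    thresholds: Thresholds | None = None
    target_marginal: np.ndarray = field(
        default_factory=lambda: DEFAULT_TARGET_MARGINAL.copy()
    )
    range: CategoryRange = CategoryRange()
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_candidates", "n_interviewers", "n_stations", "n_days", "circuits_per_day"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if any(v < 0 for v in self.sigma.values()):
            raise ValueError("sigma values must be >= 0")

    @property
    def total_sd(self) -> float:
        """Total latent SD sqrt(1 + sum sigma^2)."""
        return float(np.sqrt(1.0 + sum(v**2 for v in self.sigma.values())))

    def resolve_thresholds(self) -> Thresholds:
        if self.thresholds is not None:
            return self.thresholds
        return auto_thresholds(self.target_marginal, self.mu, self.sigma)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def reference_cohort(seed: int = 0, **overrides) -> SimulationConfig:
    """Cohort-scale preset: 352 candidates, 83 interviewers, 9 stations,
    7 days with duplicate circuits, and the default variance components."""
    return SimulationConfig(seed=seed, **overrides)


@dataclass(frozen=True)
class SimulatedCohort:
    """A generated dataset with its generating truth.

    ``truth`` holds one row per (factor, level) with the true effect;
    ``latent`` is the latent draw per record (``dataset.records`` order),
    whose discretisation under ``config``'s thresholds equals the score.
    """

    dataset: MMIDataset
    truth: pd.DataFrame
    latent: np.ndarray
    config: SimulationConfig

    def true_effects(self, factor: str) -> pd.Series:
        t = self.truth[self.truth["factor"] == factor]
        return pd.Series(t["true_effect"].to_numpy(), index=pd.Index(t["level"]), name=factor)


def auto_thresholds(
    target_marginal: np.ndarray, mu: float, sigma: Mapping[str, float]
) -> Thresholds:
    """Thresholds whose implied marginal score distribution equals the target.

    With total latent SD s = sqrt(1 + sum sigma^2), the cut-point at
    cumulative probability c is mu + s * Phi^-1(c).
    """
    p = np.asarray(target_marginal, dtype=float)
    if np.any(p <= 0):
        raise ValueError("target marginal must be strictly positive in every category")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("target marginal must sum to 1")
    s = np.sqrt(1.0 + sum(v**2 for v in sigma.values()))
    cum = np.cumsum(p)[:-1]
    return Thresholds(mu + s * ndtri(cum))


def build_circuit_design(
    config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Assignment plan: one row per candidate x station encounter.

    Candidates are split near-evenly across day x circuit cells; each
    candidate meets every station exactly once; within a circuit-day one
    interviewer sits at each station.  Interviewers are dealt a home
    station and rotated through that station's circuit-day slots, so all
    candidates in the same cell share their nine interviewers.
    """
    C = config.circuits_per_day
    need = config.n_stations * C
    if config.n_interviewers < need:
        raise DesignInfeasibleError(
            f"need at least {need} interviewers "
            f"({config.n_stations} stations x {C} circuits), got {config.n_interviewers}"
        )
    interviewers = np.array([f"I{i+1:03d}" for i in range(config.n_interviewers)])
    rng.shuffle(interviewers)
    pools = [interviewers[k :: config.n_stations] for k in range(config.n_stations)]

    candidates = [f"C{i+1:04d}" for i in range(config.n_candidates)]
    cells = np.array_split(np.arange(config.n_candidates), config.n_days * C)

    rows = []
    for d in range(config.n_days):
        for c in range(C):
            cell = cells[d * C + c]
            staff = [pools[k][(d * C + c) % len(pools[k])] for k in range(config.n_stations)]
            for ci in cell:
                for k in range(config.n_stations):
                    rows.append(
                        (candidates[ci], staff[k], f"S{k+1}", f"D{d+1}", c + 1)
                    )
    return pd.DataFrame(
        rows, columns=["candidate", "interviewer", "station", "day", "circuit"]
    )


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Draw one cohort from the generative model, fully seed-reproducible."""
    rng = np.random.default_rng(config.seed)
    plan = build_circuit_design(config, rng)
    thresholds = config.resolve_thresholds()

    effects: dict[str, pd.Series] = {}
    for factor in FACTORS:
        levels = pd.Index(pd.unique(plan[factor]))
        sd = float(config.sigma.get(factor, 0.0))
        effects[factor] = pd.Series(sd * rng.standard_normal(len(levels)), index=levels)

    eta = config.mu + sum(
        effects[f].to_numpy()[pd.Index(effects[f].index).get_indexer(plan[f])]
        for f in FACTORS
    )
    latent = eta + rng.standard_normal(len(plan))
    scores = config.range.lo + np.searchsorted(thresholds.alpha, latent)

    records = plan[["candidate", "interviewer", "station", "day"]].copy()
    records["score"] = scores
    dataset = MMIDataset(records, config.range)

    truth = pd.concat(
        [
            pd.DataFrame(
                {"factor": f, "level": effects[f].index, "true_effect": effects[f].to_numpy()}
            )
            for f in FACTORS
        ],
        ignore_index=True,
    )
    return SimulatedCohort(dataset=dataset, truth=truth, latent=latent, config=config)
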