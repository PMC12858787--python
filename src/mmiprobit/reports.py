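"""Candidate ranking, offer allocation, and interviewer/station feedback.

The candidate's predicted ability S_i (a shrinkage estimate free of
interviewer-severity, station-difficulty and day effects) drives the
ranking; the raw total score is kept alongside because the offer process
first ranks by total to set a cut, then re-ranks by ability.  Interviewer
and station reports turn the fitted T_j and U_k effects into plain-language
feedback artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cpmm import FittedModel
from .data import MMIDataset

#: Narrative band cut-offs on the latent-SD scale (presentation defaults).
BAND_CUTS: tuple[float, float] = (0.5, 1.0)

OFFER, WAITLIST, REJECT = "offer", "waitlist", "reject"


@dataclass(frozen=True)
class RankedCandidate:
    candidate_id: str
    ability: float
    ability_standardised: float
    total_raw_score: int
    rank_by_ability: int
    rank_by_total: int


@dataclass(frozen=True)
class OfferList:
    """Offer/waitlist/reject status per candidate; exactly n_offers offers."""

    status: dict[str, str]
    n_offers: int

    def of(self, status: str) -> list[str]:
        return [c for c, s in self.status.items() if s == status]


@dataclass(frozen=True)
class InterviewerFeedback:
    interviewer_id: str
    severity: float
    severity_percentile: float
    n_scored: int
    mean_awarded: float
    cohort_mean: float
    histogram: dict[int, int]
    narrative_band: str


@dataclass(frozen=True)
class StationDiagnostics:
    station_id: str
    effect: float
    flagged: bool
    direction: str  # easy / hard / neutral


# --------------------------------------------------------------------------


def rank_candidates(model: FittedModel, dataset: MMIDataset) -> list[RankedCandidate]:
    """Rank candidates by predicted ability, descending.

    Ties break by total raw score descending, then candidate ID
    lexicographically; the total-score ranking (same tie-break tail) is
    reported alongside.
    """
    ability = model.effects["candidate"]
    totals = dataset.records.groupby("candidate", sort=False)["score"].sum()
    df = pd.DataFrame(
        {
            "candidate_id": ability.index,
            "ability": ability.to_numpy(),
            "total_raw_score": totals.reindex(ability.index).to_numpy(),
        }
    )
    df["ability_standardised"] = df["ability"] / np.sqrt(model.total_variance)
    by_ability = df.sort_values(
        ["ability", "total_raw_score", "candidate_id"],
        ascending=[False, False, True],
        kind="stable",
    )
    df.loc[by_ability.index, "rank_by_ability"] = np.arange(1, len(df) + 1)
    by_total = df.sort_values(
        ["total_raw_score", "candidate_id"], ascending=[False, True], kind="stable"
    )
    df.loc[by_total.index, "rank_by_total"] = np.arange(1, len(df) + 1)
    df = df.sort_values("rank_by_ability")
    return [
        RankedCandidate(
            candidate_id=r.candidate_id,
            ability=float(r.ability),
            ability_standardised=float(r.ability_standardised),
            total_raw_score=int(r.total_raw_score),
            rank_by_ability=int(r.rank_by_ability),
            rank_by_total=int(r.rank_by_total),
        )
        for r in df.itertuples(index=False)
    ]


def ranking_frame(ranked: list[RankedCandidate], offers: OfferList | None = None) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in ranked])[
        [
            "candidate_id",
            "ability",
            "ability_standardised",
            "total_raw_score",
            "rank_by_ability",
            "rank_by_total",
        ]
    ]
    if offers is not None:
        df["status"] = df["candidate_id"].map(offers.status)
    return df


def allocate_offers(ranked: list[RankedCandidate], n_offers: int) -> OfferList:
    """Offers to the top n by ability rank; total-score-only entrants waitlisted.

    A candidate inside the top n by total score but outside it by ability
    is waitlisted (they cleared the raw-score cut but not the
    severity-adjusted one); everyone else is rejected.
    """
    if not 0 <= n_offers <= len(ranked):
        raise ValueError(f"n_offers {n_offers} outside [0, {len(ranked)}]")
    status = {}
    for r in ranked:
        if r.rank_by_ability <= n_offers:
            status[r.candidate_id] = OFFER
        elif r.rank_by_total <= n_offers:
            status[r.candidate_id] = WAITLIST
        else:
            status[r.candidate_id] = REJECT
    return OfferList(status=status, n_offers=n_offers)


def interviewer_feedback(
    model: FittedModel,
    dataset: MMIDataset,
    band_cuts: tuple[float, float] = BAND_CUTS,
) -> list[InterviewerFeedback]:
    """One feedback record per interviewer.

    The severity percentile ranks the interviewer's fitted effect T_j
    among all interviewers (mean rank, in [0, 100]); the narrative band
    applies symmetric cut-offs (default +/-0.5 and +/-1.0 latent SD):
    positive effects read lenient (higher awarded scores), negative severe.
    """
    effects = model.effects["interviewer"]
    t = effects.to_numpy()
    cohort_mean = float(dataset.records["score"].mean())
    grouped = dataset.records.groupby("interviewer", sort=False)["score"]
    n_scored = grouped.count()
    mean_awarded = grouped.mean()
    out = []
    for ivr, tj in effects.items():
        pct = 100.0 * (np.sum(t < tj) + 0.5 * np.sum(t == tj)) / len(t)
        counts = dataset.records.loc[
            dataset.records["interviewer"] == ivr, "score"
        ].value_counts()
        hist = {int(c): int(counts.get(c, 0)) for c in dataset.range.categories}
        out.append(
            InterviewerFeedback(
                interviewer_id=str(ivr),
                severity=float(tj),
                severity_percentile=float(pct),
                n_scored=int(n_scored[ivr]),
                mean_awarded=float(mean_awarded[ivr]),
                cohort_mean=cohort_mean,
                histogram=hist,
                narrative_band=_band(float(tj), band_cuts),
            )
        )
    return out


def _band(t: float, cuts: tuple[float, float]) -> str:
    mild, marked = cuts
    if t >= marked:
        return "markedly lenient"
    if t >= mild:
        return "lenient"
    if t <= -marked:
        return "markedly severe"
    if t <= -mild:
        return "severe"
    return "typical"


def feedback_frame(feedback: list[InterviewerFeedback]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "interviewer_id": f.interviewer_id,
                "severity": f.severity,
                "severity_percentile": f.severity_percentile,
                "n_scored": f.n_scored,
                "mean_awarded": f.mean_awarded,
                "cohort_mean": f.cohort_mean,
                "narrative_band": f.narrative_band,
            }
            for f in feedback
        ]
    )


def feedback_letter(f: InterviewerFeedback) -> str:
    """Plain-text feedback letter for one interviewer."""
    direction = "above" if f.severity >= 0 else "below"
    lines = [
        f"Interviewer {f.interviewer_id}",
        "-" * 40,
        f"Candidates scored: {f.n_scored}",
        f"Mean score awarded: {f.mean_awarded:.2f} (cohort mean {f.cohort_mean:.2f})",
        f"Fitted marking effect: {f.severity:+.3f} latent SD ({direction} the cohort norm)",
        f"Percentile among interviewers: {f.severity_percentile:.0f}",
        f"Overall band: {f.narrative_band}",
        "",
        "The marking effect is estimated jointly with candidate ability,",
        "station difficulty and day effects, so it reflects systematic",
        "severity/leniency rather than the mix of candidates you saw.",
    ]
    return "\n".join(lines)


def station_diagnostics(
    model: FittedModel, flag_threshold: float = 1.0
) -> list[StationDiagnostics]:
    """Per-station difficulty effect with |U_k| >= threshold flagging.

    Direction is "easy" for effects at or above +threshold (the station
    lifted scores), "hard" at or below -threshold, else "neutral".
    """
    out = []
    for sid, u in model.effects["station"].items():
        u = float(u)
        flagged = abs(u) >= flag_threshold
        if u >= flag_threshold:
            direction = "easy"
        elif u <= -flag_threshold:
            direction = "hard"
        else:
            direction = "neutral"
        out.append(
            StationDiagnostics(station_id=str(sid), effect=u, flagged=flagged, direction=direction)
        )
    return out


def diagnostics_frame(diags: list[StationDiagnostics]) -> pd.DataFrame:
    return pd.DataFrame([d.__dict__ for d in diags])


def effect_histogram(
    model: FittedModel, factor: str, bin_width: float = 0.25
) -> pd.DataFrame:
    """Binned counts of fitted effects for one factor (histogram export).

    Bins are aligned to multiples of ``bin_width`` around zero.
    """
    e = model.effects[factor].to_numpy()
    lo = np.floor(e.min() / bin_width) * bin_width
    hi = np.ceil(e.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width])
    counts, edges = np.histogram(e, bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


# -- fitted-model serialisation --------------------------------------------


def model_to_dict(model: FittedModel) -> dict:
    """Machine-readable key-value summary (thresholds, variances, fit state)."""
    return {
        "loglik": float(model.loglik),
        "converged": bool(model.converged),
        "grad_norm": float(model.grad_norm),
        "n_obs": int(model.n_obs),
        "n_levels": {k: int(v) for k, v in model.n_levels.items()},
        "thresholds": [float(a) for a in model.thresholds.alpha],
        "variances": {k: float(v) for k, v in model.variances.sigma2.items()},
        "residual_variance": float(model.variances.residual),
        "total_variance": float(model.total_variance),
        "boundary": {k: bool(v) for k, v in model.boundary.items()},
        "dropped_factors": list(model.dropped_factors),
    }


def effects_frame(model: FittedModel) -> pd.DataFrame:
    """Long CSV-ready table: factor, level, effect, standardised_effect."""
    std = model.standardised_effects()
    frames = []
    for f, eff in model.effects.effects.items():
        frames.append(
            pd.DataFrame(
                {
                    "factor": f,
                    "level": eff.index,
                    "effect": eff.to_numpy(),
                    "standardised_effect": std[f].to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def model_summary_text(model: FittedModel) -> str:
    """Human-readable fit report."""
    from .variance import decompose_variance

    dec = decompose_variance(model.variances)
    lines = [
        "Cumulative probit mixed model fit",
        "=" * 40,
        f"Observations: {model.n_obs}",
        "Levels: " + ", ".join(f"{k}={v}" for k, v in model.n_levels.items()),
        f"Log-likelihood (Laplace): {model.loglik:.4f}",
        f"Converged: {model.converged} (|grad| = {model.grad_norm:.2e})",
        "",
        "Variance components (latent scale; residual fixed at 1):",
    ]
    for f, v in model.variances.sigma2.items():
        tag = " [boundary]" if model.boundary.get(f) else ""
        lines.append(f"  {f:<12} {v:8.4f}  ({dec.percent[f]:5.2f}%){tag}")
    lines.append(f"  {'residual':<12} {1.0:8.4f}  ({dec.residual_percent:5.2f}%)")
    lines.append(f"  total latent variance = {dec.total:.4f}")
    lines.append("")
    lines.append("Thresholds: " + ", ".join(f"{a:.3f}" for a in model.thresholds.alpha))
    return "\n".join(lines)
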