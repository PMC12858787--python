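"""Ranking, offer allocation, and interviewer/station feedback artefacts."""

import numpy as np
import pandas as pd
import pytest

from mmiprobit import (
    CategoryRange,
    MMIDataset,
    allocate_offers,
    fit_cpmm,
    interviewer_feedback,
    rank_candidates,
    station_diagnostics,
)
from mmiprobit.reports import (
    OFFER,
    REJECT,
    WAITLIST,
    RankedCandidate,
    effect_histogram,
    feedback_letter,
    model_to_dict,
    ranking_frame,
)


def _ranked(rows):
    """rows: (id, ability, total, rank_ability, rank_total)"""
    return [
        RankedCandidate(
            candidate_id=r[0],
            ability=r[1],
            ability_standardised=r[1],
            total_raw_score=r[2],
            rank_by_ability=r[3],
            rank_by_total=r[4],
        )
        for r in rows
    ]


class TestRankCandidates:
    def test_identical_rows_fall_through_to_id_order(self):
        rows = [
            (c, f"I{k}", f"S{k}", "D1", s)
            for c in ("B", "A", "C")
            for k, s in enumerate((9, 10, 11))
        ]
        ds = MMIDataset(
            pd.DataFrame(rows, columns=["candidate", "interviewer", "station", "day", "score"]),
            CategoryRange(3, 15),
        )
        m = fit_cpmm(ds)
        ranked = rank_candidates(m, ds)
        assert [r.candidate_id for r in ranked] == ["A", "B", "C"]
        assert [r.rank_by_ability for r in ranked] == [1, 2, 3]

    def test_ability_ordering_and_rank_permutation(self, small_cohort, small_model):
        ranked = rank_candidates(small_model, small_cohort.dataset)
        abilities = [r.ability for r in ranked]
        assert abilities == sorted(abilities, reverse=True)
        assert sorted(r.rank_by_ability for r in ranked) == list(
            range(1, len(ranked) + 1)
        )
        assert sorted(r.rank_by_total for r in ranked) == list(range(1, len(ranked) + 1))

    def test_ability_ranking_tracks_truth_better_than_totals(self, small_cohort, small_model):
        """Severity-adjusted ranks correlate with true ability at least as well
        as raw-total ranks on a cohort with interviewer variance."""
        from scipy.stats import spearmanr

        truth = small_cohort.true_effects("candidate")
        ranked = rank_candidates(small_model, small_cohort.dataset)
        ids = [r.candidate_id for r in ranked]
        s = truth.reindex(ids).to_numpy()
        rho_ability = spearmanr(s, [-r.rank_by_ability for r in ranked]).statistic
        rho_total = spearmanr(s, [-r.rank_by_total for r in ranked]).statistic
        assert rho_ability > 0.7
        assert rho_ability >= rho_total - 0.02


class TestAllocateOffers:
    def test_concordant_rankings_leave_waitlist_empty(self):
        ranked = _ranked([("A", 2.0, 40, 1, 1), ("B", 1.0, 35, 2, 2), ("C", 0.0, 30, 3, 3)])
        offers = allocate_offers(ranked, 2)
        assert offers.of(OFFER) == ["A", "B"]
        assert offers.of(WAITLIST) == []
        assert offers.of(REJECT) == ["C"]

    def test_zero_offers_means_no_offers_and_no_waitlist(self):
        ranked = _ranked([("A", 2.0, 40, 1, 1), ("B", 1.0, 35, 2, 2)])
        offers = allocate_offers(ranked, 0)
        assert offers.of(OFFER) == [] and offers.of(WAITLIST) == []
        assert set(offers.of(REJECT)) == {"A", "B"}

    def test_total_rank_entrant_displaced_by_ability_is_waitlisted(self):
        """5 candidates, totals (60,58,55,50,45); ability re-orders the 5th
        into the top 3, pushing the 3rd-by-total out (waitlist)."""
        ranked = _ranked(
            [
                ("C1", 1.5, 60, 1, 1),
                ("C2", 1.2, 58, 2, 2),
                ("C5", 0.9, 45, 3, 5),
                ("C3", 0.7, 55, 4, 3),
                ("C4", 0.2, 50, 5, 4),
            ]
        )
        offers = allocate_offers(ranked, 3)
        assert offers.of(OFFER) == ["C1", "C2", "C5"]
        assert offers.of(WAITLIST) == ["C3"]
        assert offers.of(REJECT) == ["C4"]

    def test_statuses_partition_candidates(self, small_cohort, small_model):
        ranked = rank_candidates(small_model, small_cohort.dataset)
        offers = allocate_offers(ranked, 40)
        assert len(offers.of(OFFER)) == 40
        assert len(offers.status) == len(ranked)
        df = ranking_frame(ranked, offers)
        assert set(df["status"]) <= {OFFER, WAITLIST, REJECT}

    def test_out_of_range_offers_rejected(self):
        ranked = _ranked([("A", 1.0, 40, 1, 1)])
        with pytest.raises(ValueError):
            allocate_offers(ranked, 2)


class TestInterviewerFeedback:
    def test_bands_percentiles_and_histograms(self, small_cohort, small_model):
        fb = interviewer_feedback(small_model, small_cohort.dataset)
        assert len(fb) == small_cohort.dataset.n_levels("interviewer")
        by_sev = sorted(fb, key=lambda f: f.severity)
        assert by_sev[0].severity_percentile < 10
        assert by_sev[-1].severity_percentile > 90
        for f in fb:
            assert 0 <= f.severity_percentile <= 100
            assert sum(f.histogram.values()) == f.n_scored
            if abs(f.severity) < 0.5:
                assert f.narrative_band == "typical"
            if f.severity <= -1.0:
                assert f.narrative_band == "markedly severe"
        # severity orders with mean awarded score overall (same exposure mix)
        sev = np.array([f.severity for f in fb])
        mean_awarded = np.array([f.mean_awarded for f in fb])
        assert np.corrcoef(sev, mean_awarded)[0, 1] > 0.5

    def test_feedback_letter_mentions_band_and_counts(self, small_cohort, small_model):
        fb = interviewer_feedback(small_model, small_cohort.dataset)[0]
        letter = feedback_letter(fb)
        assert fb.interviewer_id in letter
        assert fb.narrative_band in letter
        assert str(fb.n_scored) in letter


class TestStationDiagnostics:
    def test_zero_effects_flag_nothing(self, small_model):
        diags = station_diagnostics(small_model, flag_threshold=10.0)
        assert not any(d.flagged for d in diags)
        assert all(d.direction == "neutral" for d in diags)

    def test_threshold_zero_flags_everything(self, small_model):
        diags = station_diagnostics(small_model, flag_threshold=0.0)
        assert all(d.flagged for d in diags)

    def test_direction_matches_sign(self, small_model):
        for d in station_diagnostics(small_model, flag_threshold=0.01):
            if d.flagged:
                assert d.direction == ("easy" if d.effect > 0 else "hard")


class TestExports:
    def test_effect_histogram_counts_all_levels(self, small_model):
        hist = effect_histogram(small_model, "candidate", bin_width=0.25)
        assert hist["count"].sum() == small_model.n_levels["candidate"]
        widths = hist["bin_right"] - hist["bin_left"]
        np.testing.assert_allclose(widths, 0.25, atol=1e-9)

    def test_model_dict_is_serialisable_and_complete(self, small_model):
        import json

        d = model_to_dict(small_model)
        json.dumps(d)
        assert d["total_variance"] == pytest.approx(
            1 + sum(d["variances"].values())
        )
        assert len(d["thresholds"]) == 12
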