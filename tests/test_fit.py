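"""Fitting behaviour: null shrinkage, invariances, boundaries, predictions."""

import numpy as np
import pandas as pd
import pytest

from mmiprobit import (
    CategoryRange,
    MMIDataset,
    SimulationConfig,
    fit_cpmm,
    reference_cohort,
    predict_random_effects,
    simulate_cohort,
)

from conftest import small_config


def _null_config(seed):
    return reference_cohort(
        seed=seed,
        n_candidates=56,  # 56 x 9 = 504 observations
        n_interviewers=18,
        n_days=2,
        circuits_per_day=1,
        sigma={"candidate": 0.0, "interviewer": 0.0, "station": 0.0, "day": 0.0},
    )


class TestNullData:
    def test_pure_noise_variances_shrink_to_zero(self):
        """With no true effects each fitted sigma2 stays near 0 (median over seeds)."""
        fitted = {f: [] for f in ("candidate", "interviewer", "station", "day")}
        for seed in (1, 2, 3, 4, 5):
            m = fit_cpmm(simulate_cohort(_null_config(seed)).dataset)
            for f in fitted:
                fitted[f].append(m.variances.sigma2[f])
        for f, vals in fitted.items():
            assert np.median(vals) < 0.05, (f, vals)

    def test_boundary_factors_report_zero_variance_and_zero_effects(self):
        m = fit_cpmm(simulate_cohort(_null_config(1)).dataset)
        for f, flag in m.boundary.items():
            if flag:
                assert m.variances.sigma2[f] == 0.0
                assert np.all(m.effects[f].to_numpy() == 0.0)
        assert any(m.boundary.values())  # at least one hits the floor under the null


class TestInvariances:
    def test_candidate_relabelling_leaves_fit_invariant(self, small_cohort):
        ds = small_cohort.dataset
        m1 = fit_cpmm(ds)
        mapping = {c: f"Z{i:03d}" for i, c in enumerate(reversed(ds.levels["candidate"]))}
        relabelled = ds.records.assign(candidate=ds.records["candidate"].map(mapping))
        m2 = fit_cpmm(MMIDataset(relabelled, ds.range))
        assert m2.loglik == pytest.approx(m1.loglik, abs=1e-4)
        for f in m1.variances.sigma2:
            assert m2.variances.sigma2[f] == pytest.approx(
                m1.variances.sigma2[f], abs=1e-5
            )
        e1 = m1.effects["candidate"].rename(index=mapping).sort_index()
        e2 = m2.effects["candidate"].sort_index()
        np.testing.assert_allclose(e1.to_numpy(), e2.to_numpy(), atol=1e-4)

    def test_row_order_invariance(self, small_cohort):
        ds = small_cohort.dataset
        m1 = fit_cpmm(ds)
        shuffled = ds.records.sample(frac=1, random_state=0)
        m2 = fit_cpmm(MMIDataset(shuffled, ds.range))
        assert m2.loglik == pytest.approx(m1.loglik, abs=1e-4)
        e1 = m1.effects["station"].sort_index()
        e2 = m2.effects["station"].sort_index()
        np.testing.assert_allclose(e1.to_numpy(), e2.to_numpy(), atol=1e-4)

    def test_refit_is_deterministic(self, small_cohort, small_model):
        again = fit_cpmm(small_cohort.dataset)
        assert again.loglik == small_model.loglik
        assert again.variances.sigma2 == small_model.variances.sigma2


class TestDegenerateInputs:
    def test_single_category_data_is_a_hard_error(self):
        rows = [(f"C{i}", "I1", f"S{k}", "D1", 9) for i in range(4) for k in range(3)]
        ds = MMIDataset(
            pd.DataFrame(rows, columns=["candidate", "interviewer", "station", "day", "score"]),
            CategoryRange(3, 15),
        )
        with pytest.raises(ValueError, match="one category"):
            fit_cpmm(ds)

    def test_single_level_factor_dropped_with_warning(self):
        cfg = SimulationConfig(
            n_candidates=40,
            n_interviewers=4,
            n_stations=4,
            n_days=1,
            circuits_per_day=1,
            range=CategoryRange(3, 8),
            target_marginal=np.full(6, 1 / 6),
            seed=2,
        )
        ds = simulate_cohort(cfg).dataset
        assert ds.n_levels("day") == 1
        with pytest.warns(UserWarning, match="day"):
            m = fit_cpmm(ds)
        assert "day" in m.dropped_factors
        assert "day" not in m.variances.sigma2


class TestPredictions:
    def test_shrinkage_bounds_effect_spread(self, small_model):
        """Posterior-mode spread never exceeds the fitted prior variance."""
        for f, s2 in small_model.variances.sigma2.items():
            spread = float(np.var(small_model.effects[f].to_numpy()))
            assert spread <= s2 + 1e-10, (f, spread, s2)

    def test_identical_candidates_get_identical_ability(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(30):
            for k in range(3):
                rows.append((f"C{i}", f"I{k}", f"S{k}", "D1", int(rng.integers(3, 16))))
        # twins: identical score rows under the same interviewers/stations
        for k, s in enumerate((14, 13, 15)):
            rows.append(("TwinA", f"I{k}", f"S{k}", "D1", s))
            rows.append(("TwinB", f"I{k}", f"S{k}", "D1", s))
        ds = MMIDataset(
            pd.DataFrame(rows, columns=["candidate", "interviewer", "station", "day", "score"]),
            CategoryRange(3, 15),
        )
        m = fit_cpmm(ds)
        eff = m.effects["candidate"]
        assert eff["TwinA"] == pytest.approx(eff["TwinB"], abs=1e-6)

    def test_top_scorer_has_largest_ability_among_equal_exposure(self):
        rng = np.random.default_rng(1)
        rows = []
        for i in range(30):
            for k in range(3):
                rows.append((f"C{i}", f"I{k}", f"S{k}", "D1", int(rng.integers(3, 15))))
        for k in range(3):
            rows.append(("Star", f"I{k}", f"S{k}", "D1", 15))
        ds = MMIDataset(
            pd.DataFrame(rows, columns=["candidate", "interviewer", "station", "day", "score"]),
            CategoryRange(3, 15),
        )
        m = fit_cpmm(ds)
        eff = m.effects["candidate"]
        assert eff.idxmax() == "Star"

    def test_predict_random_effects_reproduces_fit_modes(self, small_cohort, small_model):
        pred = predict_random_effects(small_model, small_cohort.dataset)
        for f in small_model.variances.sigma2:
            np.testing.assert_allclose(
                pred[f].to_numpy(), small_model.effects[f].to_numpy(), atol=1e-6
            )

    def test_predict_errors_when_model_level_missing(self, small_cohort, small_model):
        ds = small_cohort.dataset
        cut = ds.records[ds.records["candidate"] != ds.levels["candidate"][0]]
        smaller = MMIDataset(cut, ds.range)
        with pytest.raises(ValueError, match="absent"):
            predict_random_effects(small_model, smaller)


class TestParameterRecovery:
    def test_variances_recovered_on_reduced_cohort(self):
        """Fits at the default true components land near truth (loose, one seed)."""
        cohort = simulate_cohort(small_config(seed=7))
        m = fit_cpmm(cohort.dataset)
        truth = {f: sd**2 for f, sd in cohort.config.sigma.items()}
        # candidate component is well identified even at 100 candidates
        assert m.variances.sigma2["candidate"] == pytest.approx(
            truth["candidate"], rel=0.5
        )
        assert m.converged
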