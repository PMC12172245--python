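"""Synthetic-cohort generator: determinism, scales, and agent behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coopbattery import econ_models as em
from coopbattery import synthetic_cohort as sc
from coopbattery.inferential_stats import welch_t
from coopbattery.svo_items import default_items, primary_items, secondary_items


def two_group_config(n=5, seed=0, **overrides):
    a = sc.GroupSpec(label="BPD", n=n, **overrides)
    b = sc.GroupSpec(label="HC", n=n, **overrides)
    return sc.CohortConfig(group_a=a, group_b=b, seed=seed)


class TestDeterminismAndShape:
    def test_same_seed_gives_identical_cohort(self):
        cfg = two_group_config(n=3, seed=7)
        t1 = sc.trials_frame(sc.generate_cohort(cfg))
        t2 = sc.trials_frame(sc.generate_cohort(cfg))
        assert t1.to_csv(index=False) == t2.to_csv(index=False)

    def test_different_seed_differs(self):
        t1 = sc.trials_frame(sc.generate_cohort(two_group_config(n=5, seed=1)))
        t2 = sc.trials_frame(sc.generate_cohort(two_group_config(n=5, seed=2)))
        assert t1.to_csv(index=False) != t2.to_csv(index=False)

    def test_study_scale_cohort_shape(self, default_cohort, default_trials):
        assert len(default_cohort) == 85
        ug = default_trials[default_trials["task"] == "ug"]
        jpe = default_trials[default_trials["task"] == "jpe"]
        assert (ug.groupby("participant_id").size() == 6).all()
        assert (jpe.groupby("participant_id").size() == 121).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="n must be"):
            sc.GroupSpec(label="X", n=0)
        with pytest.raises(ValueError, match="alpha_sd"):
            sc.GroupSpec(label="X", n=3, alpha_sd=-0.1)


class TestScaleContainment:
    @given(st.integers(0, 10_000), st.floats(0.0, 3.0), st.floats(0.2, 3.0))
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_all_responses_on_documented_scales(self, seed, noise, temp):
        cfg = two_group_config(n=2, seed=seed, noise_mean=noise, temperature_mean=temp)
        for p in sc.generate_cohort(cfg):
            assert all(1 <= c <= 9 for c in p.svo_choices.values())
            assert 0 <= p.dg_allocation <= 10
            assert set(p.ug_offers) == set(range(1, 7))
            assert all(r in (0, 1) for r in p.ug_rejected)
            assert 0 <= p.min_acceptance <= 10
            assert all(1 <= r <= 9 for r in p.fairness_ratings)
            assert p.jpe_ratings.min() >= 1 and p.jpe_ratings.max() <= 8
            assert 12 <= p.dissociality <= 60


class TestJpeRatings:
    def test_selfish_agent_monotone_in_own_payoff(self, grid):
        params = sc.UtilityParams(alpha=0.0, beta=0.0, noise_sd=0.0)
        ratings = sc.simulate_jpe_ratings(params, grid)
        df = grid.assign(rating=ratings)
        means = df.groupby("x_self")["rating"].mean()
        assert (np.diff(means.to_numpy()) >= 0).all()
        # within any x_other slice the rating depends only on x_self
        assert (df.groupby("x_self")["rating"].nunique() == 1).all()

    def test_equal_payoff_diagonal_ordered_by_own_payoff(self, grid):
        params = sc.UtilityParams(alpha=1.0, beta=1.0, noise_sd=0.0)
        ratings = sc.simulate_jpe_ratings(params, grid)
        df = grid.assign(rating=ratings)
        diag = df[df["x_self"] == df["x_other"]].sort_values("x_self")
        assert (np.diff(diag["rating"].to_numpy()) >= 0).all()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sc.simulate_jpe_ratings(
                sc.UtilityParams(0.5, 0.3), pd.DataFrame(columns=["x_self", "x_other"])
            )

    def test_larger_is_better_coding(self, grid):
        """(50, 50) must out-rate (-50, -50) for any inequality-averse agent."""
        params = sc.UtilityParams(alpha=0.8, beta=0.3, noise_sd=0.0)
        df = grid.assign(rating=sc.simulate_jpe_ratings(params, grid))
        best = df[(df.x_self == 50) & (df.x_other == 50)]["rating"].iloc[0]
        worst = df[(df.x_self == -50) & (df.x_other == -50)]["rating"].iloc[0]
        assert best > worst


class TestUgDecisions:
    def test_inequality_averse_deterministic_limit(self):
        params = sc.UtilityParams(alpha=5.0, beta=0.1, noise_sd=0.0, temperature=1e-3)
        rejected = sc.simulate_ug_decisions(params, range(1, 7), np.random.default_rng(0))
        assert rejected == [1, 1, 1, 1, 0, 0]  # below 5 rejected, 5+ accepted

    def test_selfish_agent_accepts_everything(self):
        params = sc.UtilityParams(alpha=0.0, beta=0.0, noise_sd=0.0, temperature=1e-3)
        rejected = sc.simulate_ug_decisions(params, range(1, 7), np.random.default_rng(0))
        assert rejected == [0] * 6

    def test_rejection_rate_strictly_decreasing_in_offer(self):
        params = sc.UtilityParams(alpha=1.5, beta=0.2, noise_sd=0.0, temperature=1.0)
        rng = np.random.default_rng(0)
        counts = np.zeros(6)
        n = 10_000
        for _ in range(n):
            counts += sc.simulate_ug_decisions(params, range(1, 7), rng)
        rates = counts / n
        assert (np.diff(rates) < 0).all()

    def test_offer_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            sc.simulate_ug_decisions(sc.UtilityParams(1.0, 0.3), [11])


class TestSvoChoices:
    def test_selfish_agent_takes_option_1_on_primary_item_6(self):
        # option 1 pays (100, 50): maximal own payoff
        params = sc.UtilityParams(alpha=0.0, beta=0.0, temperature=1e-6)
        item6 = [primary_items()[5]]
        choices = sc.simulate_svo_choices(params, item6, np.random.default_rng(0))
        assert choices[6] == 1

    def test_inequality_averse_agent_takes_option_9_on_primary_item_6(self):
        # option 9 pays (85, 85): equality
        params = sc.UtilityParams(alpha=3.0, beta=3.0, temperature=1e-6)
        item6 = [primary_items()[5]]
        choices = sc.simulate_svo_choices(params, item6, np.random.default_rng(0))
        assert choices[6] == 9

    def test_inequality_averse_agent_takes_option_4_on_secondary_item_9(self):
        # option 4 pays (81, 81)
        params = sc.UtilityParams(alpha=3.0, beta=3.0, temperature=1e-6)
        item9 = [it for it in secondary_items() if it.item_id == 9]
        choices = sc.simulate_svo_choices(params, item9, np.random.default_rng(0))
        assert choices[9] == 4

    def test_malformed_item_rejected(self):
        from coopbattery.svo_items import SliderItem
        with pytest.raises(ValueError):
            SliderItem(99, "primary", ((1, 1),) * 8)


class TestParameterInjection:
    def test_equal_group_means_give_centered_welch_t(self):
        """Latent alpha Welch t averages ~0 over 200 equal-mean replicates."""
        ts = []
        for seed in range(200):
            cfg = two_group_config(n=15, seed=seed)
            cohort = sc.generate_cohort(cfg)
            a = [p.params.alpha for p in cohort if p.group == "BPD"]
            b = [p.params.alpha for p in cohort if p.group == "HC"]
            ts.append(welch_t(a, b).statistic)
        assert abs(np.mean(ts)) < 0.2

    def test_power_increases_with_alpha_shift(self):
        """Detection rate of a latent alpha shift rises over a 3-point grid."""
        registry = em.model_registry()
        fs = registry["fehr_schmidt"]
        grid = em.jpe_grid()

        def rejection_rate(delta, n_rep=25):
            hits = 0
            for seed in range(n_rep):
                cfg = sc.CohortConfig(
                    group_a=sc.GroupSpec(label="BPD", n=20, alpha_mean=0.8 + delta),
                    group_b=sc.GroupSpec(label="HC", n=20, alpha_mean=0.8),
                    seed=1000 * seed + int(delta * 100),
                )
                cohort = sc.generate_cohort(cfg)
                alphas = {"BPD": [], "HC": []}
                for p in cohort:
                    fit = em.fit_subject(fs, grid, p.jpe_ratings.astype(float))
                    alphas[p.group].append(fit.alpha_hat)
                if welch_t(alphas["BPD"], alphas["HC"]).p < 0.05:
                    hits += 1
            return hits / n_rep

        rates = [rejection_rate(d) for d in (0.0, 0.3, 0.6)]
        assert rates[0] < rates[1] <= rates[2]
        assert rates[0] < 0.3       # near nominal under the null
        assert rates[2] > 0.8       # large shift almost always detected


class TestFrames:
    def test_participants_frame_columns(self, small_cohort):
        df = sc.participants_frame(small_cohort)
        assert len(df) == 12
        assert {"alpha", "beta", "dissociality", "dg_allocation"} <= set(df.columns)

    def test_trials_frame_covers_all_tasks(self, small_cohort):
        df = sc.trials_frame(small_cohort)
        assert set(df["task"].unique()) == {"svo", "dg", "ug", "minacc", "fairness", "jpe"}
        per_subject = df[df["task"] == "fairness"].groupby("participant_id").size()
        assert (per_subject == 11).all()
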