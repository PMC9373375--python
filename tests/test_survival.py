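import numpy as np
import pandas as pd
import pytest

from clonarch.survival import (
    bootstrap_stability,
    clonality_dummies,
    cox_fit,
    gene_survival_scan,
    km_estimate,
    logrank_test,
    stepwise_backward,
)


def logrank_oracle(t1, e1, t2, e2):
    """Independent O-E/V summation over pooled event times (two groups)."""
    t1, e1, t2, e2 = map(np.asarray, (t1, e1, t2, e2))
    event_times = np.unique(np.concatenate([t1[e1 == 1], t2[e2 == 1]]))
    O = E = V = 0.0
    for t in event_times:
        n1, n2 = (t1 >= t).sum(), (t2 >= t).sum()
        d1, d2 = ((t1 == t) & (e1 == 1)).sum(), ((t2 == t) & (e2 == 1)).sum()
        n, d = n1 + n2, d1 + d2
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V if V > 0 else 0.0


class TestKmEstimate:
    def test_no_censoring_equals_empirical_survival(self):
        curve = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        assert np.allclose(curve.survival, [0.75, 0.5, 0.25, 0.0])

    def test_all_censored_flat_at_one(self):
        curve = km_estimate([5, 6, 7], [0, 0, 0])
        assert curve.event_times.size == 0
        assert curve.probability_at(10) == 1.0

    def test_mixed_censoring_hand_product(self):
        # times 1,2,2,3 events 1,1,0,1: S(1)=3/4, S(2)=3/4*2/3=1/2, S(3)=0
        curve = km_estimate([1, 2, 2, 3], [1, 1, 0, 1])
        assert np.allclose(curve.survival, [0.75, 0.5, 0.0])

    def test_negative_times_error(self):
        with pytest.raises(ValueError):
            km_estimate([-1, 2], [1, 1])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [1, 2, 3, 4, 5]
        e = [1, 1, 0, 1, 1]
        stat, df, p = logrank_test({"a": (t, e), "b": (t, e)})
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_matches_oe_v_oracle_on_random_data(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            n1, n2 = rng.integers(5, 25, size=2)
            t1 = rng.exponential(10, n1).round(1) + 0.1
            t2 = rng.exponential(15, n2).round(1) + 0.1
            e1 = rng.integers(0, 2, n1)
            e2 = rng.integers(0, 2, n2)
            if e1.sum() + e2.sum() == 0:
                continue
            stat, _, _ = logrank_test({"a": (t1, e1), "b": (t2, e2)})
            assert stat == pytest.approx(logrank_oracle(t1, e1, t2, e2), abs=1e-9)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            logrank_test({"a": ([1], [1]), "b": ([], [])})

    def test_three_group_statistic_df(self):
        rng = np.random.default_rng(1)
        groups = {
            k: (rng.exponential(s, 30), rng.integers(0, 2, 30))
            for k, s in (("a", 5), ("b", 10), ("c", 20))
        }
        stat, df, p = logrank_test(groups)
        assert df == 2 and stat > 0


class TestCoxFit:
    @staticmethod
    def sim_binary(n, hr, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0 / (0.01 * hr**x))
        c = rng.uniform(0, t)
        event = rng.random(n) > 0.3
        return pd.DataFrame(
            {"x": x, "os_time": np.where(event, t, c), "os_event": event.astype(int)}
        )

    def test_null_effect_recovered(self):
        df = self.sim_binary(2000, 1.0, 0)
        res = cox_fit(df, ["x"])
        assert 0.85 <= res.summary.loc["x", "hr"] <= 1.18

    def test_hr3_recovered(self):
        df = self.sim_binary(2000, 3.0, 1)
        res = cox_fit(df, ["x"])
        assert 2.2 <= res.summary.loc["x", "hr"] <= 4.1

    def test_matches_partial_likelihood_grid_search(self):
        # exhaustive oracle on tiny untied data (Breslow = Efron with no ties)
        df = self.sim_binary(25, 2.0, 3)
        df["os_time"] += np.arange(len(df)) * 1e-6  # break accidental ties
        res = cox_fit(df, ["x"])

        times = df["os_time"].to_numpy()
        events = df["os_event"].to_numpy()
        x = df["x"].to_numpy()

        def neg_pl(beta):
            ll = 0.0
            for i in np.flatnonzero(events == 1):
                risk = times >= times[i]
                ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
            return -ll

        grid = np.arange(-3, 3, 1e-3)
        best = grid[np.argmin([neg_pl(b) for b in grid])]
        assert res.summary.loc["x", "coef"] == pytest.approx(best, abs=2e-3)

    def test_zero_event_level_flagged(self):
        rng = np.random.default_rng(4)
        n = 100
        x = np.repeat([0.0, 1.0], n // 2)
        t = rng.exponential(10, n)
        event = np.where(x == 1, 0, 1)  # no events in the x=1 level
        df = pd.DataFrame({"x": x, "os_time": t, "os_event": event})
        res = cox_fit(df, ["x"])
        assert (not res.converged) or bool(res.summary.loc["x", "flagged"])


class TestStepwise:
    @staticmethod
    def sim_one_signal(n=600, seed=0, noise=5):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, size=(n, noise + 1)).astype(float)
        lam = 0.01 * np.exp(np.log(3.0) * x[:, 0])
        t = rng.exponential(1.0 / lam)
        event = rng.random(n) > 0.3
        cols = {"signal": x[:, 0]}
        cols |= {f"noise{i}": x[:, i + 1] for i in range(noise)}
        cols |= {"os_time": np.where(event, t, rng.uniform(0, t)),
                 "os_event": event.astype(int)}
        return pd.DataFrame(cols)

    def test_single_weak_covariate_removed(self):
        df = self.sim_one_signal(seed=1)
        covs = [c for c in df.columns if c not in ("os_time", "os_event")]
        res = stepwise_backward(df, covs)
        assert "signal" in res.covariates
        assert (res.summary["p"] <= 0.05).all()

    def test_all_significant_model_unchanged(self):
        rng = np.random.default_rng(2)
        n = 800
        x1 = rng.integers(0, 2, n).astype(float)
        x2 = rng.integers(0, 2, n).astype(float)
        lam = 0.01 * np.exp(1.2 * x1 - 1.0 * x2)
        t = rng.exponential(1.0 / lam)
        df = pd.DataFrame({"x1": x1, "x2": x2, "os_time": t, "os_event": 1})
        res = stepwise_backward(df, ["x1", "x2"])
        assert set(res.covariates) == {"x1", "x2"}

    def test_true_signal_retained_across_seeds(self):
        hits = sum(
            "signal"
            in stepwise_backward(
                self.sim_one_signal(seed=s),
                [c for c in self.sim_one_signal(seed=s).columns
                 if c not in ("os_time", "os_event")],
            ).covariates
            for s in range(10)
        )
        assert hits >= 9


class TestBootstrap:
    def test_overwhelming_effect_always_included_noise_rarely(self):
        rng = np.random.default_rng(5)
        n = 500
        x = rng.integers(0, 2, n).astype(float)
        noise = rng.integers(0, 2, n).astype(float)
        lam = 0.01 * np.exp(np.log(10.0) * x)
        t = rng.exponential(1.0 / lam)
        df = pd.DataFrame({"x": x, "noise": noise, "os_time": t, "os_event": 1})
        res = bootstrap_stability(df, ["x", "noise"], B=40, seed=7)
        assert res.inclusion_frequency["x"] >= 0.99
        assert res.inclusion_frequency["noise"] < 0.5

    def test_same_seed_identical_frequencies(self):
        df = TestStepwise.sim_one_signal(n=200, seed=3, noise=2)
        covs = [c for c in df.columns if c not in ("os_time", "os_event")]
        a = bootstrap_stability(df, covs, B=20, seed=11)
        b = bootstrap_stability(df, covs, B=20, seed=11)
        assert a.inclusion_frequency == b.inclusion_frequency


class TestGeneScan:
    def test_ineligible_gene_flagged(self):
        rng = np.random.default_rng(0)
        patients = [f"P{i}" for i in range(50)]
        cats = pd.DataFrame({"G": ["WT"] * 50}, index=patients)
        cats.iloc[:4, 0] = "clonal"  # only 4 clonal carriers, 0 subclonal
        clin = pd.DataFrame(
            {"os_time": rng.exponential(10, 50), "os_event": 1}, index=patients
        )
        (res,) = gene_survival_scan(cats, clin)
        assert not res.eligible and res.p_overall is None

    def test_identical_survival_across_categories_p_near_one(self):
        patients = [f"P{i}" for i in range(30)]
        cats = pd.DataFrame(
            {"G": ["clonal"] * 10 + ["subclonal"] * 10 + ["WT"] * 10}, index=patients
        )
        times = np.tile(np.arange(1.0, 11.0), 3)
        clin = pd.DataFrame({"os_time": times, "os_event": 1}, index=patients)
        (res,) = gene_survival_scan(cats, clin)
        assert res.eligible
        assert res.p_clonal_vs_wt == pytest.approx(1.0, abs=0.05)
        assert res.p_clonal_vs_subclonal == pytest.approx(1.0, abs=0.05)


def test_clonality_dummies_encoding():
    cats = pd.DataFrame({"G": ["clonal", "subclonal", "WT"]}, index=["a", "b", "c"])
    d = clonality_dummies(cats, "G")
    assert list(d["G_clonal"]) == [1.0, 0.0, 0.0]
    assert list(d["G_subclonal"]) == [0.0, 1.0, 0.0]
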