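"""Association estimators: logistic ORs, block R², PCs, scans, sensitivity."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from tnfigrs._logistic import fit_logistic_scan
from tnfigrs.association import (
    apply_sensitivity_filter,
    bh_fdr,
    binomial_band,
    compute_pcs,
    linear_r2,
    logistic_assoc,
    run_sensitivity,
    scan_individual,
)


class TestLogisticAssoc:
    def test_two_by_two_closed_form(self):
        """Unadjusted binary exposure equals the contingency-table OR with
        the closed-form Wald interval."""
        df = pd.DataFrame(
            {
                "y": [1] * 40 + [0] * 60 + [1] * 20 + [0] * 80,
                "x": [1] * 100 + [0] * 100,
            }
        )
        res = logistic_assoc(df, "y", "x")[0]
        or_closed = (40 / 60) / (20 / 80)
        se = np.sqrt(1 / 40 + 1 / 60 + 1 / 20 + 1 / 80)
        assert res.estimate == pytest.approx(or_closed, rel=1e-6)
        assert res.ci_low == pytest.approx(or_closed * np.exp(-1.959964 * se), rel=1e-5)
        assert res.ci_high == pytest.approx(or_closed * np.exp(1.959964 * se), rel=1e-5)
        assert res.n == 200

    def test_perfect_separation_flagged_na(self):
        df = pd.DataFrame({"y": [0] * 50 + [1] * 50, "x": [0.0] * 50 + [1.0] * 50})
        res = logistic_assoc(df, "y", "x")[0]
        assert res.is_na
        assert res.note == "separation"

    def test_single_outcome_level_flagged_na(self):
        df = pd.DataFrame({"y": [1] * 20, "x": np.arange(20.0)})
        res = logistic_assoc(df, "y", "x")[0]
        assert res.is_na
        assert res.note == "empty_stratum"

    def test_quartile_contrasts_against_statsmodels(self, rng):
        n = 400
        q = rng.choice(["Q1", "Q2", "Q3", "Q4"], n)
        y = rng.binomial(1, 0.4 + 0.1 * (q == "Q4"), n)
        df = pd.DataFrame({"y": y, "q": q})
        results = logistic_assoc(df, "y", "q", categorical=True, reference="Q1")
        X = pd.get_dummies(pd.Series(q))[["Q2", "Q3", "Q4"]].astype(float)
        X.insert(0, "const", 1.0)
        ref = sm.Logit(y, X).fit(disp=0)
        for i, r in enumerate(results):
            assert r.contrast == f"Q{i + 2}-vs-Q1"
            assert np.log(r.estimate) == pytest.approx(ref.params.iloc[i + 1], abs=1e-6)

    def test_ci_brackets_estimate(self, rng):
        df = pd.DataFrame({"y": rng.binomial(1, 0.5, 300), "x": rng.standard_normal(300)})
        r = logistic_assoc(df, "y", "x", per_sd=True)[0]
        assert r.ci_low < r.estimate < r.ci_high


class TestBatchedLogistic:
    def test_matches_statsmodels_per_marker(self, rng):
        n, m = 400, 15
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 3))])
        G = rng.binomial(2, 0.3, (n, m)).astype(float)
        y = rng.binomial(1, expit(0.2 * X[:, 1] + 0.5 * G[:, 0] - 0.3)).astype(float)
        fit = fit_logistic_scan(y, X, G)
        for j in range(m):
            ref = sm.Logit(y, np.column_stack([X, G[:, j]])).fit(disp=0)
            assert fit.beta[j] == pytest.approx(ref.params[-1], abs=1e-6)
            assert fit.se[j] == pytest.approx(ref.bse[-1], abs=1e-6)

    def test_monomorphic_marker_flagged(self, rng):
        n = 100
        X = np.ones((n, 1))
        G = np.column_stack([np.zeros(n), rng.binomial(2, 0.4, n)]).astype(float)
        y = rng.binomial(1, 0.5, n).astype(float)
        fit = fit_logistic_scan(y, X, G)
        assert not fit.converged[0] and fit.note[0] == "monomorphic"
        assert fit.converged[1]


class TestLinearR2:
    def test_exact_linear_relation_gives_r2_one(self, rng):
        x = rng.standard_normal(100)
        df = pd.DataFrame({"y": 2 * x - 1, "x": x})
        r = linear_r2(df, "y", ["x"])
        assert r.estimate == pytest.approx(1.0, abs=1e-12)

    def test_equals_squared_pearson_without_covariates(self, rng):
        x = rng.standard_normal(200)
        y = 0.3 * x + rng.standard_normal(200)
        df = pd.DataFrame({"y": y, "x": x})
        r = linear_r2(df, "y", ["x"])
        assert r.estimate == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, abs=1e-12)

    def test_null_block_r2_expectation(self, rng):
        """Under the null, E[block R²] for one exposure is ~ 1/(n−1)."""
        n, reps = 653, 250
        vals = []
        for _ in range(reps):
            df = pd.DataFrame({"y": rng.standard_normal(n), "x": rng.standard_normal(n)})
            vals.append(linear_r2(df, "y", ["x"]).estimate)
        assert np.mean(vals) == pytest.approx(1 / (n - 1), abs=6e-4)

    def test_collinear_block_column_dropped(self, rng):
        x = rng.standard_normal(100)
        df = pd.DataFrame({"y": x + rng.standard_normal(100), "x1": x, "x2": 2 * x})
        r = linear_r2(df, "y", ["x1", "x2"])
        single = linear_r2(df, "y", ["x1"])
        assert r.estimate == pytest.approx(single.estimate, abs=1e-12)


class TestPCs:
    def test_separates_frequency_shifted_clusters(self, rng):
        n, m = 500, 300
        labels = rng.random(n) < 0.5
        f = np.where(labels[:, None], 0.35, 0.25)  # Fst-like shift
        g = rng.binomial(2, np.broadcast_to(f, (n, m)))
        pcs = compute_pcs(pd.DataFrame(g), k=5)
        r = np.corrcoef(pcs["pc1"], labels.astype(float))[0, 1]
        assert abs(r) > 0.9

    def test_duplicated_subjects_get_identical_scores(self, rng):
        g = pd.DataFrame(rng.binomial(2, 0.3, (30, 40)))
        dup = pd.concat([g, g.iloc[[0]]], ignore_index=True)
        pcs = compute_pcs(dup, k=3)
        assert np.allclose(pcs.iloc[0], pcs.iloc[-1])

    def test_k_zero_gives_empty_block(self, rng):
        g = pd.DataFrame(rng.binomial(2, 0.3, (20, 10)))
        assert compute_pcs(g, k=0).shape == (20, 0)

    def test_k_beyond_rank_refused(self, rng):
        g = pd.DataFrame(rng.binomial(2, 0.3, (5, 10)))
        with pytest.raises(ValueError):
            compute_pcs(g, k=6)


class TestScan:
    def test_zero_exposures_gives_empty_scan(self, rng):
        df = pd.DataFrame({"y": rng.binomial(1, 0.5, 20)})
        results, summary = scan_individual(df, [], "y")
        assert results == [] and summary.n_significant == 0 and summary.n_tests == 0

    def test_binomial_band_for_76_tests(self):
        assert binomial_band(76) == (1, 8)

    def test_bh_fdr_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 40)
        assert np.allclose(bh_fdr(p), multipletests(p, method="fdr_bh")[1])

    def test_injected_effect_has_smallest_p(self, rng):
        """One true effect (OR 2, MAF 0.3) among 75 nulls is top-ranked in
        most replicates at n=650."""
        hits = 0
        reps = 25
        for _ in range(reps):
            n = 650
            G = rng.binomial(2, 0.3, (n, 76)).astype(float)
            y = rng.binomial(1, expit(-0.5 + np.log(2.0) * G[:, 0])).astype(float)
            df = pd.DataFrame(G, columns=[f"s{j}" for j in range(76)])
            df["y"] = y
            results, _ = scan_individual(df, [f"s{j}" for j in range(76)], "y")
            ps = np.array([r.p for r in results])
            hits += int(np.nanargmin(ps) == 0)
        assert hits >= 0.8 * reps


class TestSensitivity:
    def _table(self, rng, n=120):
        df = pd.DataFrame(
            {
                "response": rng.binomial(1, 0.7, n),
                "eular": rng.choice(["good", "moderate", "none"], n),
                "drug": rng.choice(["infliximab", "adalimumab"], n),
                "eval_day": rng.integers(60, 241, n),
                "das28_baseline": np.full(n, 5.0),
                "grs_snp": rng.standard_normal(n),
                "acpa_positive": pd.array([True] * n, dtype="boolean"),
            }
        )
        return df

    def test_empty_high_das28_stratum_gives_na(self, rng):
        df = self._table(rng)  # every baseline exactly 5.0 (not > 5.1)
        rows = run_sensitivity(df, "high_das28", ["grs_snp"])
        assert all(r.is_na and r.note == "empty_stratum" for r in rows)

    def test_excluding_absent_drug_is_noop(self, rng):
        df = self._table(rng)  # no etanercept users
        main = logistic_assoc(df, "response", "grs_snp", per_sd=True)[0]
        sens = run_sensitivity(df, "excl_etanercept", ["grs_snp"])[0]
        assert sens.estimate == pytest.approx(main.estimate)
        assert sens.n == main.n

    def test_window_filter_postcondition(self, rng):
        df = self._table(rng, n=300)
        sub, outcome = apply_sensitivity_filter(df, "window_2_5m")
        assert outcome == "response"
        assert sub["eval_day"].between(60, 150).all()

    def test_good_vs_none_drops_moderate(self, rng):
        df = self._table(rng)
        sub, outcome = apply_sensitivity_filter(df, "good_vs_none")
        assert outcome == "response_good"
        assert set(sub["eular"]) <= {"good", "none"}

    def test_unknown_mode_refused(self, rng):
        with pytest.raises(ValueError):
            apply_sensitivity_filter(self._table(rng), "bogus")
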