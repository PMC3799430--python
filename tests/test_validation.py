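"""The six module-validation tests against constructed and null data."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import kstest

from aberlink.datamodel import GeneSetCollection
from aberlink.validation import (
    _cox_univariate,
    cocitation_test,
    coherence_test,
    cox_coefficients,
    effector_target_test,
    enrichment_test,
    ks_prognosis,
    recurrence_test,
    results_frame,
    summarize_validation,
)


def _breslow_partial_loglik(beta, x, time, event):
    """Independent oracle: direct evaluation of the Breslow partial
    log-likelihood by explicit risk-set summation."""
    ll = 0.0
    for i in np.flatnonzero(event == 1):
        risk = time >= time[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestCoxCoefficients:
    def test_worked_fixture_matches_partial_likelihood_solver(self):
        """A 5-subject fixture: the Newton estimate agrees with an
        independent numerical maximizer of the Breslow partial likelihood
        to 1e-6."""
        x = np.array([0.5, -1.0, 2.0, 0.0, 1.0])
        time = np.array([100.0, 250.0, 30.0, 400.0, 180.0])
        event = np.array([1, 1, 1, 0, 1])
        beta, p = _cox_univariate(x, time, event)
        res = minimize_scalar(lambda b: -_breslow_partial_loglik(b, x, time, event),
                              bounds=(-5, 5), method="bounded",
                              options={"xatol": 1e-10})
        assert beta == pytest.approx(res.x, abs=1e-6)

    def test_agrees_with_lifelines_on_tie_free_data(self, rng, toy_clinical):
        """Cross-check against lifelines (Efron == Breslow without ties)."""
        from lifelines import CoxPHFitter

        x = rng.normal(size=len(toy_clinical))
        df = toy_clinical.copy()
        df["x"] = x
        cph = CoxPHFitter()
        cph.fit(df, duration_col="survival_days", event_col="event")
        beta, _ = _cox_univariate(x, df["survival_days"].to_numpy(),
                                  df["event"].to_numpy())
        assert beta == pytest.approx(cph.params_["x"], abs=1e-4)

    def test_constructed_risk_gene_positive_coefficient(self, rng):
        n = 100
        time = np.sort(rng.exponential(300, n))[::-1].copy()
        event = np.ones(n, dtype=int)
        expr = pd.DataFrame(
            {"g_risk": -np.log(time) + rng.normal(0, 0.3, n),
             "g_null": rng.normal(size=n)}).T
        expr.columns = [f"s{i}" for i in range(n)]
        clinical = pd.DataFrame({"survival_days": time, "event": event},
                                index=expr.columns)
        coeffs = cox_coefficients(expr, clinical)
        assert coeffs.loc["g_risk", "coef"] > 0
        assert coeffs.loc["g_risk", "p"] < 0.01

    def test_null_genes_centered_with_calibrated_pvalues(self, toy_clinical):
        rng = np.random.default_rng(123)
        n_genes = 400
        expr = pd.DataFrame(rng.normal(size=(n_genes, len(toy_clinical))),
                            index=[f"g{i}" for i in range(n_genes)],
                            columns=toy_clinical.index)
        coeffs = cox_coefficients(expr, toy_clinical)
        assert abs(coeffs["coef"].mean()) < 0.05
        frac = (coeffs["p"] < 0.05).mean()
        assert 0.02 <= frac <= 0.09

    def test_all_censored_errors(self):
        expr = pd.DataFrame(np.ones((1, 20)), index=["g"],
                            columns=[f"s{i}" for i in range(20)])
        clinical = pd.DataFrame({"survival_days": np.arange(20) + 1.0,
                                 "event": 0}, index=expr.columns)
        with pytest.raises(ValueError, match="censored"):
            cox_coefficients(expr, clinical)


class TestKsPrognosis:
    def test_null_calibration(self):
        """Targets drawn from the background: pass rate ~ alpha over 500
        seeded replicates, and p-values roughly uniform."""
        rng = np.random.default_rng(7)
        background = pd.Series(rng.normal(size=2000))
        ps = []
        for _ in range(500):
            targets = background.sample(30, random_state=rng.integers(2**31))
            ps.append(ks_prognosis("M", targets, background).p_value)
        assert kstest(np.array(ps), "uniform").statistic < 0.08
        assert np.mean(np.array(ps) <= 0.05) < 0.1

    def test_shifted_targets_flag_worse_survival(self, rng):
        background = pd.Series(rng.normal(size=2000))
        targets = pd.Series(rng.normal(loc=1.0, size=100))
        res = ks_prognosis("M", targets, background)
        assert res.direction == "-" and res.p_value < 1e-4 and res.passed

    def test_identical_distributions_insignificant(self, rng):
        background = pd.Series(rng.normal(size=500))
        res = ks_prognosis("M", background, background)
        assert not res.passed and res.p_value > 0.5

    def test_too_few_targets_flagged_na(self, rng):
        res = ks_prognosis("M", pd.Series(rng.normal(size=3)),
                           pd.Series(rng.normal(size=100)))
        assert res.direction == "NA" and "few" in res.note


class TestCoherence:
    def test_latent_factor_targets_significant(self, rng):
        n = 80
        latent = rng.normal(size=n)
        rows = {f"t{i}": 0.9 * latent + rng.normal(0, 0.44, n) for i in range(10)}
        rows.update({f"r{i}": rng.normal(size=n) for i in range(10)})
        expr = pd.DataFrame(rows).T
        res = coherence_test("M", {f"t{i}" for i in range(10)}, expr,
                             {f"r{i}" for i in range(10)})
        assert res.p_value < 0.01 and res.passed

    def test_reference_equals_targets(self, rng):
        expr = pd.DataFrame(rng.normal(size=(8, 50)),
                            index=[f"g{i}" for i in range(8)])
        genes = set(expr.index)
        res = coherence_test("M", genes, expr, genes)
        assert res.p_value >= 0.5

    def test_missing_reference_errors(self, rng):
        expr = pd.DataFrame(rng.normal(size=(5, 30)),
                            index=[f"g{i}" for i in range(5)])
        with pytest.raises(ValueError, match="reference"):
            coherence_test("M", set(expr.index), expr, {"x1", "x2", "x3"})

    def test_pair_count_bookkeeping(self):
        from aberlink.validation import _pairwise_correlations

        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(size=(7, 40)),
                            index=[f"g{i}" for i in range(7)])
        corr = _pairwise_correlations(expr, list(expr.index))
        assert len(corr) == 7 * 6 // 2


class TestEffectorTarget:
    def test_planted_module_significant_in_external_data(self, default_cohort):
        from aberlink.simulate import generate_external

        ds, truth = default_cohort
        expr, _clin, _groups = generate_external(truth, seed=21, n_samples=120)
        key = "meth:methcl0"
        members, targets = truth.blueprint["meth_clusters"]["methcl0"]
        res = effector_target_test("M", set(targets), expr, list(members), "-",
                                   proxy_sign="-")
        assert res.p_value < 0.01 and res.passed and res.direction == "-"

    def test_permuted_targets_uniform(self, rng):
        expr = pd.DataFrame(rng.normal(size=(200, 60)),
                            index=[f"g{i}" for i in range(200)])
        ps = [effector_target_test(
            "M", set(rng.choice(expr.index[5:], 20, replace=False)),
            expr, ["g0", "g1"], "+").p_value for _ in range(100)]
        assert kstest(np.array(ps), "uniform").statistic < 0.15

    def test_wrong_direction_fails(self, rng):
        n = 60
        latent = rng.normal(size=n)
        rows = {"proxy": latent + rng.normal(0, 0.2, n)}
        rows.update({f"t{i}": latent + rng.normal(0, 0.4, n) for i in range(10)})
        rows.update({f"b{i}": rng.normal(size=n) for i in range(50)})
        expr = pd.DataFrame(rows).T
        # positively correlated targets tested under a negative module sign
        res = effector_target_test("M", {f"t{i}" for i in range(10)}, expr,
                                   ["proxy"], "-")
        assert not res.passed

    def test_no_proxies_is_na(self, rng):
        expr = pd.DataFrame(rng.normal(size=(10, 30)),
                            index=[f"g{i}" for i in range(10)])
        res = effector_target_test("M", {"g1"}, expr, ["absent"], "+")
        assert res.direction == "NA" and "no proxies" in res.note


class TestRecurrence:
    def test_shifted_disease_group(self, rng):
        vals = pd.Series(np.concatenate([rng.normal(-1, 1, 40), rng.normal(0, 1, 40)]),
                         index=[f"s{i}" for i in range(80)])
        groups = pd.Series(["GBM"] * 40 + ["non-GBM"] * 40, index=vals.index)
        res = recurrence_test("M", vals, groups)
        assert res.passed and res.direction == "-"

    def test_identical_groups_insignificant(self, rng):
        base = rng.normal(size=40)
        vals = pd.Series(np.concatenate([base, base]),
                         index=[f"s{i}" for i in range(80)])
        groups = pd.Series(["GBM"] * 40 + ["non-GBM"] * 40, index=vals.index)
        res = recurrence_test("M", vals, groups)
        assert res.p_value > 0.99

    def test_statistic_is_ecdf_max_gap(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(0.5, 1, 25)
        vals = pd.Series(np.concatenate([a, b]), index=[f"s{i}" for i in range(55)])
        groups = pd.Series(["GBM"] * 30 + ["non-GBM"] * 25, index=vals.index)
        res = recurrence_test("M", vals, groups)
        grid = np.concatenate([a, b])
        gap = max(abs(np.mean(a <= x) - np.mean(b <= x)) for x in grid)
        assert res.statistic == pytest.approx(gap, abs=1e-12)

    def test_empty_group_errors(self, rng):
        vals = pd.Series(rng.normal(size=10), index=[f"s{i}" for i in range(10)])
        groups = pd.Series(["GBM"] * 10, index=vals.index)
        with pytest.raises(ValueError, match="empty"):
            recurrence_test("M", vals, groups)


class TestEnrichment:
    def test_module_equals_set(self):
        universe = {f"g{i}" for i in range(1000)}
        gs = GeneSetCollection(sets={"hit": {f"g{i}" for i in range(20)},
                                     "other": {f"g{i}" for i in range(500, 540)}},
                               universe=universe)
        table = enrichment_test({f"g{i}" for i in range(20)}, gs)
        assert table.loc["hit", "p_adjusted"] < 1e-10
        assert table.loc["hit", "significant"]

    def test_hypergeometric_summation_oracle(self):
        """Table (a=5,b=5,c=5,d=985): the one-sided Fisher p equals the
        hypergeometric tail computed by explicit summation."""
        from math import comb

        universe = {f"g{i}" for i in range(1000)}
        module = {f"g{i}" for i in range(10)}            # a+b = 10
        geneset = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(500, 505)}
        gs = GeneSetCollection(sets={"s": geneset}, universe=universe)
        table = enrichment_test(module, gs)
        # P(X >= 5) with N=1000, K=10 (set size), n=10 (module size)
        tail = sum(comb(10, k) * comb(990, 10 - k) for k in range(5, 11)) / comb(1000, 10)
        assert table.loc["s", "p"] == pytest.approx(tail, abs=1e-12)

    def test_disjoint_module_p_one_region(self):
        universe = {f"g{i}" for i in range(100)}
        gs = GeneSetCollection(sets={"s": {f"g{i}" for i in range(10)}},
                               universe=universe)
        table = enrichment_test({f"g{i}" for i in range(50, 60)}, gs)
        assert table.loc["s", "p"] > 0.5

    def test_empty_universe_errors(self):
        gs = GeneSetCollection(sets={}, universe=set())
        with pytest.raises(ValueError, match="universe"):
            enrichment_test({"g1"}, gs)


class TestCocitation:
    def test_zero_overlap_p_one(self):
        res = cocitation_test("M", {"t1", "t2"}, {"E": {"x1"}}, {"E": 100})
        assert res[0].p_value == pytest.approx(1.0)

    def test_binomial_tail_summation_oracle(self):
        """n=100 targets, q=0.01, k=5 co-cited: upper binomial tail by
        explicit summation."""
        from math import comb

        targets = {f"t{i}" for i in range(100)}
        cocited = {"E": {f"t{i}" for i in range(5)}}
        counts = {"E": 227}   # 227 / 22697 = 0.01 background frequency
        res = cocitation_test("M", targets, cocited, counts, universe_size=22700)
        q = 227 / 22700
        tail = sum(comb(100, k) * q**k * (1 - q) ** (100 - k) for k in range(5, 101))
        assert res[0].p_value == pytest.approx(tail, rel=1e-9)

    def test_inconsistent_table_errors(self):
        with pytest.raises(ValueError, match="inconsistent"):
            cocitation_test("M", {"t1"}, {"E": {"t1"}}, {"E": 0})


class TestSummaries:
    def test_cross_dataset_counting_rules(self):
        from aberlink.validation import ValidationResult

        results = []
        for d in range(4):
            results.append(ValidationResult("M1", "prognosis", f"d{d}", 0.5,
                                            0.01, "-", passed=d < 3))
            results.append(ValidationResult("M2", "prognosis", f"d{d}", 0.2,
                                            0.5, "NA", passed=d < 2))
        summary = summarize_validation(results)
        row1 = summary[(summary.module_id == "M1")].iloc[0]
        row2 = summary[(summary.module_id == "M2")].iloc[0]
        assert row1.module_pass and row1.n_significant == 3
        assert not row2.module_pass

    def test_results_frame_is_ordering_invariant(self, rng):
        background = pd.Series(rng.normal(size=500))
        targets = pd.Series(rng.normal(loc=1.0, size=30))
        r1 = ks_prognosis("M", targets, background)
        r2 = ks_prognosis("M", targets.sample(frac=1, random_state=1), background)
        assert r1.p_value == pytest.approx(r2.p_value)
        assert len(results_frame([r1, r2])) == 2
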