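"""Soft-label logistic fitting, pairwise screening, thresholds, and FDR."""

import numpy as np
import pytest
from scipy.stats import kstest

from aberlink.association import (
    AssociationEdge,
    DEFAULT_THRESHOLDS,
    estimate_fdr,
    filter_pairs,
    fit_soft_logistic,
    intercept_only_loglik,
    score_pair,
    screen_pairs,
    soft_loglik,
)
from aberlink.quantize import encode_discrete, quantize_tristate, rank_to_cdf


def _soft_labels(values: np.ndarray) -> np.ndarray:
    return quantize_tristate(rank_to_cdf(values))


def _hard_labels(states: np.ndarray) -> np.ndarray:
    W = np.zeros((len(states), 3))
    W[np.arange(len(states)), states + 1] = 1.0
    return W


class TestFitSoftLogistic:
    def test_constant_target_gives_zero_slope(self, rng):
        W = np.tile([0.0, 1.0, 0.0], (30, 1))
        e = rng.choice([-1.0, 0.0, 1.0], size=30)
        alphas, lams, ll = fit_soft_logistic(W, e[:, None])
        assert abs(lams[0]) < 1e-4
        # the fitted model predicts p_nochange ~ 1
        assert alphas[0] < -5 and alphas[1] < -5

    def test_grid_search_oracle(self, rng):
        """The Newton optimum beats (and localizes to) a dense grid over
        (alpha_-, alpha_+, lambda)."""
        e = rng.choice([-1.0, 0.0, 1.0], size=30)
        t = e + rng.normal(0, 0.8, 30)
        W = _soft_labels(t)
        alphas, lams, ll = fit_soft_logistic(W, e[:, None])
        X = e[:, None]
        # coarse grid to locate the optimum, then a fine local grid
        grid = np.arange(-3.0, 3.001, 0.1)
        best, best_ll = None, -np.inf
        for am in grid:
            for ap in grid:
                for lam in grid:
                    v = soft_loglik(np.array([am, ap, lam]), X, W)
                    if v > best_ll:
                        best, best_ll = (am, ap, lam), v
        assert ll >= best_ll - 1e-9
        fine = np.arange(-0.1, 0.1001, 0.01)
        for i, centre in enumerate(best):
            for d in fine:
                theta = np.array(best, dtype=float)
                theta[i] = centre + d
                assert ll >= soft_loglik(theta, X, W) - 1e-9
        assert abs(lams[0] - best[2]) <= 0.1

    def test_collinear_duplicate_splits_slope(self, rng):
        """Duplicating an effector: the summed slope matches the single-
        effector slope (ridge makes the split identifiable)."""
        e = rng.choice([-1.0, 0.0, 1.0], size=100)
        t = e + rng.normal(0, 0.5, 100)
        W = _soft_labels(t)
        _, lam1, _ = fit_soft_logistic(W, e[:, None])
        _, lam2, _ = fit_soft_logistic(W, np.column_stack([e, e]))
        assert abs(lam2.sum() - lam1[0]) < 1e-4

    def test_zero_variance_effector_rejected(self):
        W = np.tile([0.2, 0.6, 0.2], (25, 1))
        with pytest.raises(ValueError, match="zero-variance"):
            fit_soft_logistic(W, np.ones((25, 1)))

    def test_perfect_separation_slope_bounded(self):
        """Perfectly separated hard labels do not blow up the slope: the
        ridge keeps the optimum finite and the configurable cap bounds it."""
        e = np.array([-1.0] * 15 + [1.0] * 15)
        W = _hard_labels(np.array([-1] * 15 + [1] * 15))
        _, lams, _ = fit_soft_logistic(W, e[:, None])
        assert abs(lams[0]) <= 20.0 + 1e-9
        with pytest.warns(UserWarning, match="capped"):
            _, lams_capped, _ = fit_soft_logistic(W, e[:, None], lam_cap=5.0)
        assert abs(lams_capped[0]) <= 5.0 + 1e-9

    def test_hard_labels_reduce_to_multinomial_likelihood(self, rng):
        """With point-mass targets the soft-label likelihood equals the
        ordinary multinomial logistic log-likelihood."""
        e = rng.choice([-1.0, 0.0, 1.0], size=60)
        y = np.sign(e + rng.normal(0, 0.7, 60)).astype(int)
        W = _hard_labels(y)
        theta = np.array([0.3, -0.2, 0.8])
        ll = soft_loglik(theta, e[:, None], W)
        # direct multinomial computation
        direct = 0.0
        for ei, yi in zip(e, y):
            eta = {-1: theta[0] - theta[2] * ei, 0: 0.0, 1: theta[1] + theta[2] * ei}
            z = sum(np.exp(v) for v in eta.values())
            direct += eta[yi] - np.log(z)
        assert ll == pytest.approx(direct, abs=1e-9)


class TestScorePair:
    def test_null_pvalues_uniform(self):
        """500 independent pairs at n=200: p-values are approximately
        Uniform(0,1) and type-I error at alpha=0.01 is calibrated."""
        rng = np.random.default_rng(99)
        ps = []
        for _ in range(500):
            e = _soft_labels(rng.normal(size=200))
            t = _soft_labels(rng.normal(size=200))
            ps.append(score_pair(e, t, "trans_cnv").p_value)
        ps = np.asarray(ps)
        assert kstest(ps, "uniform").statistic < 0.08
        assert 0.005 - 1e-9 <= np.mean(ps < 0.01) <= 0.02 + 1e-9

    def test_perfect_association(self, rng):
        x = rng.normal(size=100)
        E = _soft_labels(x)
        edge = score_pair(E, E, "trans_cnv")
        assert edge.llr > 50 and edge.sign == "+"

    def test_g_test_equivalence_on_contingency_fixture(self):
        """For hard-label inputs whose row-conditionals lie exactly in the
        shared-slope family, the screening llr equals the classical G
        statistic of the 3x3 contingency table, computed by explicit
        summation.  Fixture counts (rows = effector state -1/0/+1):
        (4,2,1) / (3,3,3) / (1,2,4)."""
        counts = np.array([[4, 2, 1], [3, 3, 3], [1, 2, 4]], dtype=float)
        e_states, y_states = [], []
        for i, s_e in enumerate((-1, 0, 1)):
            for j, s_y in enumerate((-1, 0, 1)):
                e_states += [s_e] * int(counts[i, j])
                y_states += [s_y] * int(counts[i, j])
        e = np.array(e_states, dtype=float)
        W = _hard_labels(np.array(y_states))
        E = _hard_labels(np.array(e_states))
        edge = score_pair(E, W, "trans_cnv", n_min=5)
        n = counts.sum()
        expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / n
        g = 2.0 * np.sum(counts * np.log(counts / expected))
        assert edge.llr == pytest.approx(g, abs=1e-4)

    def test_zero_variance_effector_flagged(self):
        E = encode_discrete(["wildtype"] * 30).probs
        T = _soft_labels(np.random.default_rng(0).normal(size=30))
        edge = score_pair(E, T, "mutation")
        assert edge.flagged and edge.llr == 0.0 and edge.p_value == 1.0

    def test_llr_nesting_monotone(self, rng):
        """Adding an effector never decreases the fitted log-likelihood."""
        e1 = rng.choice([-1.0, 0.0, 1.0], size=80)
        e2 = rng.normal(size=80)
        t = e1 + rng.normal(0, 0.8, 80)
        W = _soft_labels(t)
        _, _, ll1 = fit_soft_logistic(W, e1[:, None])
        _, _, ll12 = fit_soft_logistic(W, np.column_stack([e1, e2]))
        assert ll12 >= ll1 - 1e-6
        assert ll1 >= intercept_only_loglik(W) - 1e-6

    def test_sign_matches_correlation(self, rng):
        for _ in range(20):
            e = rng.normal(size=100)
            t = rng.choice([-1.0, 1.0]) * e + rng.normal(0, 1.0, 100)
            edge = score_pair(_soft_labels(e), _soft_labels(t), "trans_cnv")
            if abs(edge.corr) > 0.05:
                assert (edge.lam >= 0) == (edge.corr >= 0)


class TestFilterPairs:
    def _edge(self, type_, sign, llr=10.0, corr=0.5, p=1e-4):
        return AssociationEdge(
            effector="E", effector_modality="x", target="T", type=type_,
            sign=sign, llr=llr, p_value=p, corr=corr if sign == "+" else -abs(corr),
            n_effective=100, lam=1.0 if sign == "+" else -1.0,
        )

    def test_cis_cnv_negative_removed(self):
        assert filter_pairs([self._edge("cis_cnv", "-", llr=100.0)]) == []
        assert len(filter_pairs([self._edge("cis_cnv", "+")])) == 1

    def test_methylation_positive_removed(self):
        assert filter_pairs([self._edge("methylation", "+")]) == []
        assert len(filter_pairs([self._edge("methylation", "-")])) == 1

    def test_mirna_negative_only(self):
        assert filter_pairs([self._edge("mirna", "+")]) == []
        assert len(filter_pairs([self._edge("mirna", "-")])) == 1

    def test_snp_llr_boundary(self):
        assert filter_pairs([self._edge("snp_cis", "+", llr=6.9)]) == []
        assert len(filter_pairs([self._edge("snp_cis", "+", llr=7.0)])) == 1

    def test_unknown_type_errors(self):
        bad = self._edge("cis_cnv", "+")
        bad.type = "wibble"
        with pytest.raises(ValueError):
            filter_pairs([bad])


class TestEstimateFdr:
    def _screen_setup(self, rng, n=80, n_eff=8, n_targ=20, planted=0):
        effectors = {}
        target_probs = np.zeros((n_targ, n, 3))
        eff_values = []
        for i in range(n_eff):
            x = rng.normal(size=n)
            eff_values.append(x)
            effectors[f"e{i:02d}"] = (_soft_labels(x), "cnv", "trans_cnv")
        for j in range(n_targ):
            if j < planted:
                t = eff_values[j % n_eff] + rng.normal(0, 0.4, n)
            else:
                t = rng.normal(size=n)
            target_probs[j] = _soft_labels(t)

        class TM:
            features = [f"t{j:02d}" for j in range(n_targ)]
            samples = [f"s{i}" for i in range(n)]
            probs = target_probs

        return effectors, TM()

    def test_null_dataset_fdr_near_one(self, rng):
        effectors, tm = self._screen_setup(rng, planted=0)
        fdr = estimate_fdr(effectors, tm, "trans_cnv", n_perm=15, seed=3, n_min=10)
        est = fdr["trans_cnv"]
        assert est.fdr1 is None or est.fdr1 > 0.5

    def test_planted_effects_low_fdr(self, rng):
        effectors, tm = self._screen_setup(rng, planted=10)
        fdr = estimate_fdr(effectors, tm, "trans_cnv", n_perm=15, seed=3, n_min=10)
        est = fdr["trans_cnv"]
        assert est.n_real >= 8
        assert est.fdr1 is not None and est.fdr1 < 0.2

    def test_seed_determinism(self, rng):
        effectors, tm = self._screen_setup(rng, planted=5)
        a = estimate_fdr(effectors, tm, "trans_cnv", n_perm=12, seed=9, n_min=10)
        b = estimate_fdr(effectors, tm, "trans_cnv", n_perm=12, seed=9, n_min=10)
        assert vars(a["trans_cnv"]) == vars(b["trans_cnv"])

    def test_too_few_permutations_rejected(self, rng):
        effectors, tm = self._screen_setup(rng)
        with pytest.raises(ValueError):
            estimate_fdr(effectors, tm, "trans_cnv", n_perm=5, seed=0)
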