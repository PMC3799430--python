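"""Pairwise effector-target association scoring and permutation FDR.

The target's tristate probabilities act as soft labels y in {-1, 0, +1}
for a shared-slope multinomial logistic regression

    P(y = s | x)  proportional to  exp(alpha_s + s * sum_i lambda_i x_i),

with alpha_0 = 0 for identifiability and effectors encoded by their
expected state e = P(up) - P(down).  One coefficient lambda_i per
effector makes the association's sign directly interpretable.  The
expected-complete-data log-likelihood

    LL = sum_samples sum_s w_s(sample) * log P(y = s | x)

is maximized by a damped Newton iteration with a tiny ridge on the
slopes.  Marginal screening compares against the intercept-only model
with a 1-df chi-square likelihood-ratio test; false-discovery rates come
from permutations of the target matrix's sample labels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, pearsonr

log = logging.getLogger("aberlink")

ASSOCIATION_TYPES = (
    "cis_cnv", "trans_cnv", "mutation", "methylation", "mirna", "snp_cis", "snp_trans",
)

#: association-sign constraints: cis segment CNVs can only act positively,
#: methylation and microRNA only negatively; the rest go either way.
SIGN_CONSTRAINTS = {
    "cis_cnv": "+",
    "methylation": "-",
    "mirna": "-",
    "trans_cnv": None,
    "mutation": None,
    "snp_cis": None,
    "snp_trans": None,
}


class FitError(RuntimeError):
    """Soft-logistic optimization failed to converge."""


def _eta_lse(theta, X):
    n = X.shape[0]
    u = X @ theta[2:]
    eta = np.empty((n, 3))
    eta[:, 0] = theta[0] - u
    eta[:, 1] = 0.0
    eta[:, 2] = theta[1] + u
    m = eta.max(axis=1)
    lse = m + np.log(np.exp(eta - m[:, None]).sum(axis=1))
    return eta, lse


def _penalized_loglik(theta, X, W, ridge):
    """Penalized soft-label log-likelihood only (cheap line-search objective)."""
    lam = theta[2:]
    eta, lse = _eta_lse(theta, X)
    return float(np.sum(W * eta) - np.sum(lse)) - ridge * float(lam @ lam)


def _loglik_grad_hess(theta, X, W, ridge):
    """Penalized LL, gradient and Hessian for parameters [a_m, a_p, lam...]."""
    n, k = X.shape
    lam = theta[2:]
    eta, lse = _eta_lse(theta, X)
    P = np.exp(eta - lse[:, None])
    ll = float(np.sum(W * eta) - np.sum(lse)) - ridge * float(lam @ lam)

    rm = W[:, 0] - P[:, 0]
    rp = W[:, 2] - P[:, 2]
    grad = np.empty(2 + k)
    grad[0] = rm.sum()
    grad[1] = rp.sum()
    grad[2:] = X.T @ (rp - rm) - 2.0 * ridge * lam

    # Hessian of LL: -sum_n C_n^T (diag(P_n) - P_n P_n^T) C_n where C_n is the
    # 3 x (2+k) class-feature matrix [[1,0,-x],[0,0,0],[0,1,+x]]; the slope
    # feature takes value s*x over classes, so the cross terms reduce to
    #   d2LL/da_m dlam_j =  sum_n x_j * pm * (1 - pm + pp)
    #   d2LL/da_p dlam_j = -sum_n x_j * pp * (1 + pm - pp)
    pm, pp = P[:, 0], P[:, 2]
    H = np.zeros((2 + k, 2 + k))
    H[0, 0] = -np.sum(pm * (1 - pm))
    H[1, 1] = -np.sum(pp * (1 - pp))
    H[0, 1] = H[1, 0] = np.sum(pm * pp)
    cm = pm * (1.0 - pm + pp)
    cp = -(pp * (1.0 + pm - pp))
    H[0, 2:] = H[2:, 0] = X.T @ cm
    H[1, 2:] = H[2:, 1] = X.T @ cp
    # slope block: cov(lam_i, lam_j) per sample = x_i x_j * (E[s^2] - E[s]^2)
    # with s in {-1,0,1}: E[s^2] = pm+pp, E[s] = pp-pm
    var_s = (pm + pp) - (pp - pm) ** 2
    H[2:, 2:] = -(X.T * var_s) @ X - 2.0 * ridge * np.eye(k)
    return ll, grad, H


def fit_soft_logistic(
    target_probs: np.ndarray,
    effectors: np.ndarray,
    ridge: float = 1e-6,
    max_iter: int = 100,
    tol: float = 1e-6,
    lam_cap: float = 20.0,
):
    """Fit the shared-slope soft-label multinomial logistic model.

    Parameters
    ----------
    target_probs:
        (n, 3) soft labels in state order (down, nochange, up).
    effectors:
        (n, k) expected-state design matrix; no zero-variance columns.

    Returns
    -------
    (alphas, lambdas, loglik):
        alphas = (alpha_down, alpha_up) with alpha_nochange fixed at 0;
        lambdas = one slope per effector; loglik = maximized soft-label
        log-likelihood (unpenalized).

    Raises ``FitError`` on non-convergence; warns and caps slopes at
    ``lam_cap`` under perfect separation.
    """
    W = np.asarray(target_probs, dtype=float)
    X = np.atleast_2d(np.asarray(effectors, dtype=float))
    if X.shape[0] != W.shape[0]:
        X = X.T
    n, k = X.shape
    if k < 1:
        raise ValueError("need at least one effector")
    if n < 2:
        raise ValueError("need at least 2 samples")
    col_ptp = np.ptp(X, axis=0)
    if np.any(col_ptp == 0):
        raise ValueError("zero-variance effector column")

    theta = np.zeros(2 + k)
    ll, grad, H = _loglik_grad_hess(theta, X, W, ridge)
    capped = False
    converged = False
    for _ in range(max_iter):
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(H - 1e-10 * np.eye(len(theta)), grad)
        except np.linalg.LinAlgError:
            step = grad / max(1.0, np.linalg.norm(grad))
        step = -step  # Newton: theta - H^{-1} grad, H negative definite
        t = 1.0
        for _ in range(30):
            cand = theta + t * step
            ll_new = _penalized_loglik(cand, X, W, ridge)
            if ll_new >= ll - 1e-12:
                theta = cand
                ll, grad, H = _loglik_grad_hess(cand, X, W, ridge)
                break
            t *= 0.5
        else:
            break
        if np.any(np.abs(theta[2:]) > lam_cap):
            capped = True
            theta[2:] = np.clip(theta[2:], -lam_cap, lam_cap)
            ll, grad, H = _loglik_grad_hess(theta, X, W, ridge)
            warnings.warn("slope capped: likely perfect separation")
            break
    if not converged and not capped and np.linalg.norm(grad) >= 1e-3:
        raise FitError(
            f"soft-logistic did not converge: |grad|={np.linalg.norm(grad):.3g}, "
            f"n={n}, k={k}"
        )
    # report unpenalized LL at the solution
    ll_raw = soft_loglik(theta, X, W)
    return theta[:2].copy(), theta[2:].copy(), ll_raw


def soft_loglik(theta: np.ndarray, X: np.ndarray, W: np.ndarray) -> float:
    """Unpenalized soft-label log-likelihood at parameters theta."""
    eta, lse = _eta_lse(theta, X)
    return float(np.sum(W * eta) - np.sum(lse))


def label_dispersion_factor(target_probs: np.ndarray) -> float:
    """Sandwich correction for likelihood-ratio tests with soft labels.

    The expected-complete-data LLR uses graded labels, so the model-based
    information overstates the sampling variance of the score and the raw
    LLR is stochastically smaller than chi-square(1) under the null.  The
    asymptotic null is c * chi2(1) with

        c = Var(e) / [ (q_down + q_up) - (q_up - q_down)^2 ],

    the ratio of the empirical variance of the expected state e to the
    variance a hard {-1,0,+1} label with the same marginal state
    probabilities q would have.  Point-mass labels give c = 1 exactly,
    recovering the classical test.
    """
    W = np.asarray(target_probs, dtype=float)
    d = W[:, 2] - W[:, 0]
    q = W.mean(axis=0)
    var_s = (q[0] + q[2]) - (q[2] - q[0]) ** 2
    if var_s <= 0:
        return 1.0
    return float(np.clip(d.var() / var_s, 1e-12, 1.0))


def llr_pvalue(llr: float, target_probs: np.ndarray) -> float:
    """1-df likelihood-ratio p-value with the soft-label dispersion correction."""
    c = label_dispersion_factor(target_probs)
    return float(chi2.sf(llr / c, df=1))


def intercept_only_loglik(target_probs: np.ndarray) -> float:
    """Closed-form maximized LL with no effectors: class probabilities equal
    the mean soft labels."""
    W = np.asarray(target_probs, dtype=float)
    q = W.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lq = np.where(q > 0, np.log(np.where(q > 0, q, 1.0)), 0.0)
    return float(W.shape[0] * np.sum(q * lq))


@dataclass
class AssociationEdge:
    """One effector -> target marginal association."""

    effector: str
    effector_modality: str
    target: str
    type: str
    sign: str
    llr: float
    p_value: float
    corr: float
    n_effective: int
    lam: float = 0.0
    flagged: bool = False

    def passes(self, th: "TypeThresholds") -> bool:
        if self.flagged:
            return False
        if self.llr < th.min_llr:
            return False
        if th.max_p is not None and self.p_value > th.max_p:
            return False
        if th.min_abs_corr is not None and abs(self.corr) < th.min_abs_corr:
            return False
        constraint = SIGN_CONSTRAINTS[self.type]
        if constraint is not None and self.sign != constraint:
            return False
        return True


@dataclass
class TypeThresholds:
    min_llr: float = 5.0
    max_p: float | None = None
    min_abs_corr: float | None = 0.3


#: screening thresholds per association type; SNPs carry a stricter
#: log-likelihood-ratio cutoff (>= 7.0) because of their sheer number.
DEFAULT_THRESHOLDS: dict[str, TypeThresholds] = {
    "cis_cnv": TypeThresholds(),
    "trans_cnv": TypeThresholds(),
    "mutation": TypeThresholds(),
    "methylation": TypeThresholds(),
    "mirna": TypeThresholds(),
    "snp_cis": TypeThresholds(min_llr=7.0, min_abs_corr=None),
    "snp_trans": TypeThresholds(min_llr=7.0, min_abs_corr=None),
}


def score_pair(
    effector_probs: np.ndarray,
    target_probs: np.ndarray,
    assoc_type: str,
    effector_id: str = "",
    target_id: str = "",
    effector_modality: str = "",
    n_min: int = 20,
    ridge: float = 1e-6,
) -> AssociationEdge:
    """Score one effector-target pair with the 1-df likelihood-ratio test.

    Both inputs are (n, 3) tristate arrays on shared samples; samples
    missing in either are dropped pairwise.
    """
    if assoc_type not in ASSOCIATION_TYPES:
        raise ValueError(f"unknown association type {assoc_type!r}")
    E = np.asarray(effector_probs, dtype=float)
    T = np.asarray(target_probs, dtype=float)
    ok = np.isfinite(E).all(axis=1) & np.isfinite(T).all(axis=1)
    E, T = E[ok], T[ok]
    n = int(ok.sum())
    e = E[:, 2] - E[:, 0]

    def _edge(llr, p, corr, lam, flagged=False):
        return AssociationEdge(
            effector=effector_id, effector_modality=effector_modality,
            target=target_id, type=assoc_type,
            sign="+" if lam >= 0 else "-",
            llr=float(llr), p_value=float(p), corr=float(corr),
            n_effective=n, lam=float(lam), flagged=flagged,
        )

    if n < n_min or np.ptp(e) == 0:
        return _edge(0.0, 1.0, 0.0, 0.0, flagged=True)
    ll0 = intercept_only_loglik(T)
    try:
        _, lam, ll1 = fit_soft_logistic(T, e[:, None], ridge=ridge)
    except FitError:
        return _edge(0.0, 1.0, 0.0, 0.0, flagged=True)
    llr = max(0.0, 2.0 * (ll1 - ll0))
    p = llr_pvalue(llr, T)
    t = T[:, 2] - T[:, 0]
    corr = 0.0 if np.ptp(t) == 0 else float(pearsonr(e, t)[0])
    return _edge(llr, max(p, np.finfo(float).tiny), corr, lam[0])


def screen_pairs(
    effectors: dict[str, tuple[np.ndarray, str, str]],
    target_matrix,
    pair_types,
    n_min: int = 20,
) -> list[AssociationEdge]:
    """Score every (effector, target) pair.

    effectors: effector ID -> ((n,3) probs, modality, default type).
    target_matrix: TristateMatrix of the targets.
    pair_types: callable (effector_id, target_id) -> association type or
        None to skip; or a constant string.
    """
    edges = []
    type_fn = pair_types if callable(pair_types) else (lambda e, t: pair_types)
    for ti, target in enumerate(target_matrix.features):
        T = target_matrix.probs[ti]
        for eid, (E, modality, _default) in effectors.items():
            atype = type_fn(eid, target)
            if atype is None:
                continue
            edges.append(
                score_pair(E, T, atype, effector_id=eid, target_id=target,
                           effector_modality=modality, n_min=n_min)
            )
    return edges


def filter_pairs(
    edges: list[AssociationEdge],
    thresholds: dict[str, TypeThresholds] | None = None,
) -> list[AssociationEdge]:
    """Keep edges passing all type-specific thresholds plus sign constraints."""
    if thresholds is None:
        thresholds = DEFAULT_THRESHOLDS
    out = []
    for e in edges:
        if e.type not in thresholds:
            raise ValueError(f"no thresholds configured for type {e.type!r}")
        if e.passes(thresholds[e.type]):
            out.append(e)
    return out


@dataclass
class FdrEstimate:
    """Permutation-based false-discovery-rate estimates for one type."""

    type: str
    fdr1: float | None
    fdr2: float | None
    n_real: int
    mean_n_permuted: float
    n_permutations: int
    seed: int
    pi0: float = 1.0


def edges_to_frame(edges: list[AssociationEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "effector": e.effector, "modality": e.effector_modality,
                "target": e.target, "type": e.type, "sign": e.sign,
                "llr": e.llr, "p": e.p_value, "corr": e.corr,
                "n": e.n_effective, "lambda": e.lam,
            }
            for e in edges
        ]
    )


def estimate_fdr(
    effectors: dict[str, tuple[np.ndarray, str, str]],
    target_matrix,
    pair_types,
    thresholds: dict[str, TypeThresholds] | None = None,
    n_perm: int = 100,
    seed: int = 0,
    n_min: int = 20,
) -> dict[str, FdrEstimate]:
    """Estimate FDR1/FDR2 per association type by sample-label permutation.

    Each permutation shuffles the target matrix's sample labels as a unit
    (one permutation applied to every target, preserving inter-target and
    inter-effector correlation structure), reruns the full screen, and
    records the null discovery count R0.  FDR1 = mean(R0)/R; FDR2 applies
    the pi0 correction pi0 = min(1, 2 * mean(p > 0.5)) to FDR1.  Both are
    clipped to [0, 1]; R = 0 leaves the FDR undefined (None).
    """
    if n_perm < 10:
        raise ValueError("need at least 10 permutations")
    rng = np.random.default_rng(seed)
    real_edges = screen_pairs(effectors, target_matrix, pair_types, n_min=n_min)
    real_pass = filter_pairs(real_edges, thresholds)
    types = sorted({e.type for e in real_edges})
    R = {t: sum(1 for e in real_pass if e.type == t) for t in types}
    pi0 = {}
    for t in types:
        ps = np.array([e.p_value for e in real_edges if e.type == t and not e.flagged])
        pi0[t] = min(1.0, 2.0 * float(np.mean(ps > 0.5))) if len(ps) else 1.0

    n = len(target_matrix.samples)
    null_counts = {t: [] for t in types}
    perm_tm = _ShuffledTargets(target_matrix)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        perm_tm.set_perm(perm)
        perm_pass = filter_pairs(
            screen_pairs(effectors, perm_tm, pair_types, n_min=n_min), thresholds
        )
        for t in types:
            null_counts[t].append(sum(1 for e in perm_pass if e.type == t))

    out = {}
    for t in types:
        mean_r0 = float(np.mean(null_counts[t]))
        if R[t] == 0:
            fdr1 = fdr2 = None
        else:
            fdr1 = min(1.0, mean_r0 / R[t])
            fdr2 = min(1.0, pi0[t] * fdr1)
        out[t] = FdrEstimate(
            type=t, fdr1=fdr1, fdr2=fdr2, n_real=R[t],
            mean_n_permuted=mean_r0, n_permutations=n_perm, seed=seed, pi0=pi0[t],
        )
        log.info("FDR[%s]: R=%d mean R0=%.2f fdr1=%s fdr2=%s", t, R[t], mean_r0,
                 out[t].fdr1, out[t].fdr2)
    return out


class _ShuffledTargets:
    """View of a TristateMatrix with permuted sample labels (targets only)."""

    def __init__(self, tm):
        self.features = tm.features
        self.samples = tm.samples
        self._probs = tm.probs

    def set_perm(self, perm: np.ndarray) -> None:
        self.probs = self._probs[:, perm, :]
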