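"""Six statistical validation tests for association modules.

Each test consumes a module set plus one expression/clinical dataset
(internal or external) and emits a per-module statistic and p-value:

1. prognosis — one-sided KS between the Cox-coefficient distribution of
   module targets and the all-gene background (positive coefficients =
   shorter survival, so direction "-" means worse prognosis).
2. coherence — one-sided KS between within-module pairwise expression
   correlations and those of a strongly co-expressed reference set
   (ribosomal genes in practice).
3. effector-target — effector expressions proxy their aberrations in
   external data; one-sided KS of proxy-target correlations against a
   proxy-all-genes background, in the direction of the module sign.
4. recurrence — two-sided KS of proxy expression between disease groups
   (GBM vs non-GBM gliomas in the study design).
5. enrichment — one-sided Fisher exact tests against gene-set
   collections, Bonferroni-corrected.
6. co-citation — binomial upper tail for literature co-citation counts
   between a module's effectors and its targets, consumed from a
   precomputed table.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom, fisher_exact, ks_2samp

log = logging.getLogger("aberlink")

TEST_NAMES = ("prognosis", "coherence", "effector_target", "recurrence",
              "enrichment", "cocitation")

#: gene universe size used for co-citation background frequencies
DEFAULT_UNIVERSE_SIZE = 22_697


@dataclass
class ValidationResult:
    module_id: str
    test: str
    dataset: str
    statistic: float
    p_value: float
    direction: str = "NA"   # "+", "-", or "NA"
    passed: bool = False
    note: str = ""

    def to_dict(self) -> dict:
        return self.__dict__.copy()


# ---------------------------------------------------------------------------
# Cox regression (univariate, Breslow partial likelihood)

def _cox_univariate(x: np.ndarray, time: np.ndarray, event: np.ndarray,
                    max_iter: int = 50, tol: float = 1e-9):
    """Newton solve of the univariate Breslow Cox partial likelihood.

    Returns (beta, p) with a Wald p-value; NaN on failure.
    """
    order = np.argsort(-time, kind="stable")  # descending: risk sets are prefixes
    x, time, event = x[order], time[order], event[order]
    beta = 0.0
    for _ in range(max_iter):
        exb = np.exp(np.clip(beta * x, -500, 500))
        s0 = np.cumsum(exb)
        s1 = np.cumsum(exb * x)
        s2 = np.cumsum(exb * x * x)
        # ties share the full risk set: use the last index with the same time
        idx = np.searchsorted(-time, -time, side="right") - 1
        ev = event == 1
        mean = s1[idx] / s0[idx]
        grad = float(np.sum(x[ev] - mean[ev]))
        info = float(np.sum(s2[idx][ev] / s0[idx][ev] - mean[ev] ** 2))
        if info <= 0:
            return np.nan, np.nan
        step = grad / info
        beta += np.clip(step, -2.0, 2.0)
        if abs(step) < tol:
            break
    else:
        if abs(step) > 1e-4 or not np.isfinite(beta):
            return np.nan, np.nan
    if not np.isfinite(beta) or abs(beta) > 50:
        return np.nan, np.nan
    from scipy.stats import norm
    se = 1.0 / np.sqrt(info)
    p = 2.0 * norm.sf(abs(beta) / se)
    return float(beta), float(p)


def cox_coefficients(expr: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """Univariate Cox proportional-hazards coefficient per gene.

    expr is genes x samples; clinical is indexed by sample with columns
    ``survival_days`` and ``event``.  Requires at least 10 events; all-
    censored data raise.  Genes whose fit fails are reported NaN.
    """
    shared = [s for s in expr.columns if s in clinical.index]
    cl = clinical.loc[shared]
    time = cl["survival_days"].to_numpy(dtype=float)
    event = cl["event"].to_numpy(dtype=int)
    if event.sum() == 0:
        raise ValueError("all samples censored; Cox regression undefined")
    if event.sum() < 10:
        raise ValueError(f"need >= 10 events, got {int(event.sum())}")
    X = expr.loc[:, shared]
    out = np.full((len(X), 2), np.nan)
    for i in range(len(X)):
        x = X.iloc[i].to_numpy(dtype=float)
        ok = np.isfinite(x)
        if ok.sum() < 10 or np.ptp(x[ok]) == 0 or event[ok].sum() == 0:
            continue
        out[i] = _cox_univariate(x[ok], time[ok], event[ok])
    return pd.DataFrame(out, index=X.index, columns=["coef", "p"])


# ---------------------------------------------------------------------------
# KS helpers

def _one_sided_ks(sample: np.ndarray, background: np.ndarray):
    """One-sided KS in both directions.

    Returns (p_sample_larger, p_sample_smaller, stat_larger, stat_smaller)
    where "larger" means the sample is stochastically larger than the
    background.
    """
    larger = ks_2samp(sample, background, alternative="less")
    smaller = ks_2samp(sample, background, alternative="greater")
    return larger.pvalue, smaller.pvalue, larger.statistic, smaller.statistic


def ks_prognosis(
    module_id: str,
    target_coeffs: pd.Series,
    background_coeffs: pd.Series,
    dataset: str = "",
    alpha: float = 0.05,
) -> ValidationResult:
    """Compare module-target Cox coefficients with the all-gene background.

    Direction "-" (worse survival) when the targets' coefficients deviate
    positively; "+" when negatively.  Cross-dataset summarizing (the
    "significant in at least three datasets" rule) is done by
    :func:`summarize_validation`.
    """
    t = target_coeffs.dropna().to_numpy()
    b = background_coeffs.dropna().to_numpy()
    if len(t) < 5:
        return ValidationResult(module_id, "prognosis", dataset, np.nan, 1.0,
                                "NA", False, note="too few targets with coefficients")
    p_hi, p_lo, _s_hi, _s_lo = _one_sided_ks(t, b)
    # both one-sided directions are examined; the exact two-sided test is
    # their calibrated combination (uniform p under the null), with the
    # dominant side giving the direction
    res = ks_2samp(t, b, alternative="two-sided")
    direction = "-" if p_hi <= p_lo else "+"
    p = float(res.pvalue)
    return ValidationResult(module_id, "prognosis", dataset, float(res.statistic),
                            p, direction if p <= alpha else "NA", p <= alpha)


def _pairwise_correlations(expr: pd.DataFrame, genes: list[str]) -> np.ndarray:
    present = [g for g in genes if g in expr.index]
    if len(present) < 2:
        return np.array([])
    vals = expr.loc[present].to_numpy(dtype=float)
    cc = np.corrcoef(vals)
    iu = np.triu_indices(len(present), k=1)
    out = cc[iu]
    return out[np.isfinite(out)]


def coherence_test(
    module_id: str,
    targets: set[str],
    expr: pd.DataFrame,
    reference_genes: set[str],
    dataset: str = "",
    alpha: float = 0.05,
) -> ValidationResult:
    """Do module targets co-express at least as strongly as the reference set?

    One-sided KS testing whether within-target pairwise correlations are
    stochastically larger than within-reference correlations.
    """
    ref_present = [g for g in reference_genes if g in expr.index]
    if len(ref_present) < 3:
        raise ValueError(f"reference set absent from expression matrix "
                         f"({len(ref_present)} of {len(reference_genes)} present)")
    t_corr = _pairwise_correlations(expr, sorted(targets))
    r_corr = _pairwise_correlations(expr, sorted(ref_present))
    if len(t_corr) < 3:
        return ValidationResult(module_id, "coherence", dataset, np.nan, 1.0,
                                "NA", False, note="too few targets in matrix")
    p_hi, _, s_hi, _ = _one_sided_ks(t_corr, r_corr)
    return ValidationResult(module_id, "coherence", dataset, float(s_hi),
                            float(p_hi), "+" if p_hi <= alpha else "NA", p_hi <= alpha)


def proxy_profile(expr: pd.DataFrame, proxies: list[str]) -> pd.Series | None:
    """Per-sample median expression over proxy genes (None if none present)."""
    present = [g for g in proxies if g in expr.index]
    if not present:
        return None
    return expr.loc[present].median(axis=0)


def effector_target_test(
    module_id: str,
    targets: set[str],
    expr: pd.DataFrame,
    proxies: list[str],
    sign: str,
    dataset: str = "",
    alpha: float = 0.05,
    proxy_sign: str = "+",
) -> ValidationResult:
    """Are proxy-target correlations shifted in the module's direction?

    Effector gene expressions proxy the (unmeasured) aberrations; the
    distribution of proxy x target correlations is compared against proxy
    x all-genes, one-sided in the direction the module sign implies.
    ``proxy_sign`` states how the proxy tracks the aberration: "+" for
    CNV cis-targets and mutated genes, "-" for methylated genes (hyper-
    methylation silences its own gene, so the proxy anti-tracks it); the
    tested correlation direction is the product of the two signs.
    microRNA-effector modules have no mRNA proxies and should be skipped
    upstream.
    """
    prof = proxy_profile(expr, proxies)
    if prof is None:
        return ValidationResult(module_id, "effector_target", dataset, np.nan,
                                1.0, "NA", False, note="no proxies in dataset")
    vals = expr.to_numpy(dtype=float)
    p_vec = prof.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        cent = vals - np.nanmean(vals, axis=1, keepdims=True)
        pc = p_vec - np.nanmean(p_vec)
        num = np.nansum(cent * pc, axis=1)
        den = np.sqrt(np.nansum(cent**2, axis=1) * np.nansum(pc**2))
        corr = pd.Series(np.where(den > 0, num / den, np.nan), index=expr.index)
    t_corr = corr.loc[[g for g in sorted(targets) if g in corr.index]].dropna().to_numpy()
    b_corr = corr.dropna().to_numpy()
    if len(t_corr) < 3:
        return ValidationResult(module_id, "effector_target", dataset, np.nan,
                                1.0, "NA", False, note="too few targets in matrix")
    p_hi, p_lo, s_hi, s_lo = _one_sided_ks(t_corr, b_corr)
    if sign in ("+", "-"):
        expected = "+" if sign == proxy_sign else "-"
        (p, stat) = (p_hi, s_hi) if expected == "+" else (p_lo, s_lo)
    else:  # mixed-sign merged module: direction-free two-sided test
        res = ks_2samp(t_corr, b_corr, alternative="two-sided")
        p, stat = float(res.pvalue), float(res.statistic)
    return ValidationResult(module_id, "effector_target", dataset, float(stat),
                            float(p), sign if p <= alpha else "NA", p <= alpha)


def recurrence_test(
    module_id: str,
    proxy_values: pd.Series,
    group_labels: pd.Series,
    dataset: str = "",
    alpha: float = 0.05,
    positive_group: str = "GBM",
) -> ValidationResult:
    """Two-sided KS of proxy expression between disease and comparison groups.

    Direction is the sign of (median in positive group - median in rest).
    """
    shared = [s for s in proxy_values.index if s in group_labels.index]
    v = proxy_values.loc[shared]
    g = group_labels.loc[shared]
    a = v[g == positive_group].dropna().to_numpy()
    b = v[g != positive_group].dropna().to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("one group is empty")
    if len(a) < 5 or len(b) < 5:
        return ValidationResult(module_id, "recurrence", dataset, np.nan, 1.0,
                                "NA", False, note="fewer than 5 samples in a group")
    res = ks_2samp(a, b, alternative="two-sided")
    direction = "+" if np.median(a) >= np.median(b) else "-"
    return ValidationResult(module_id, "recurrence", dataset, float(res.statistic),
                            float(res.pvalue), direction if res.pvalue <= alpha else "NA",
                            res.pvalue <= alpha)


def enrichment_test(
    targets: set[str],
    gene_sets,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher exact enrichment against every set in the collection.

    The 2x2 table counts module membership against set membership over the
    collection's universe; p-values are Bonferroni-corrected by the number
    of sets.  Targets outside the universe are dropped (count logged).
    """
    universe = gene_sets.universe
    if not universe:
        raise ValueError("empty gene universe")
    inside = targets & universe
    dropped = len(targets) - len(inside)
    if dropped:
        log.info("enrichment: %d module targets outside universe dropped", dropped)
    n_sets = len(gene_sets.sets)
    rows = []
    for name in sorted(gene_sets.sets):
        gs = gene_sets.sets[name] & universe
        a = len(inside & gs)
        b = len(inside) - a
        c = len(gs) - a
        d = len(universe) - a - b - c
        odds, p = fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append({
            "set": name, "overlap": a, "set_size": len(gs),
            "odds_ratio": odds, "p": p,
            "p_adjusted": min(1.0, p * n_sets),
            "significant": min(1.0, p * n_sets) <= alpha,
        })
    return pd.DataFrame(rows).set_index("set")


def cocitation_test(
    module_id: str,
    targets: set[str],
    cocited: dict[str, set[str]],
    genomewide_counts: dict[str, int],
    universe_size: int = DEFAULT_UNIVERSE_SIZE,
    alpha: float = 0.05,
    dataset: str = "literature",
) -> list[ValidationResult]:
    """Binomial co-citation enrichment per effector.

    For effector E with q = (genome-wide co-cited count)/universe_size,
    the p-value is the upper binomial tail of observing at least
    k = |co-cited(E) ∩ targets| co-cited genes among n = |targets|.
    Effectors missing from the table yield NA results.
    """
    results = []
    n = len(targets)
    for eff in sorted(set(cocited) | set(genomewide_counts)):
        if eff not in cocited or eff not in genomewide_counts:
            results.append(ValidationResult(module_id, "cocitation", dataset,
                                            np.nan, 1.0, "NA", False,
                                            note=f"{eff}: absent from table"))
            continue
        k = len(cocited[eff] & targets)
        q = genomewide_counts[eff] / universe_size
        if q == 0 and k > 0:
            raise ValueError(f"inconsistent co-citation table for {eff!r}: "
                             f"background count 0 but {k} co-cited targets")
        p = float(binom.sf(k - 1, n, q)) if q > 0 else 1.0
        results.append(ValidationResult(module_id, "cocitation", dataset,
                                        float(k), p, "+" if p <= alpha else "NA",
                                        p <= alpha, note=eff))
    return results


# ---------------------------------------------------------------------------
# cross-dataset summarizer

#: minimum numbers of datasets in which a test must be significant for the
#: module-level pass (prognosis needs three, effector-target six, coherence
#: five of the nine datasets in the study design)
SUMMARY_RULES = {"prognosis": 3, "coherence": 5, "effector_target": 6}


def summarize_validation(results: list[ValidationResult],
                         rules: dict[str, int] | None = None) -> pd.DataFrame:
    """Count significant datasets per (module, test) and apply pass rules."""
    rules = dict(SUMMARY_RULES) if rules is None else rules
    df = pd.DataFrame([r.to_dict() for r in results])
    if df.empty:
        return df
    grouped = (
        df.groupby(["module_id", "test"])["passed"].sum().rename("n_significant").reset_index()
    )
    grouped["required"] = grouped["test"].map(lambda t: rules.get(t, 1))
    grouped["module_pass"] = grouped["n_significant"] >= grouped["required"]
    return grouped


def results_frame(results: list[ValidationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])
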