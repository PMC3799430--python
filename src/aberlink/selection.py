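"""Layered forward selection of effectors for each target gene.

Candidate effectors that survived the pairwise screen are admitted
level-by-level, in decreasing order of mechanistic directness:

* Level 1 — aberrations of the target gene itself: its mutations and DNA
  methylations, segment CNVs covering or within 1 Mb of the gene, and
  SNPs on the same chromosome.
* Level 2 — positive associations with segment CNVs on other
  chromosomes; positive and negative associations with non-local
  mutations; negative associations with non-local methylations;
  associations with non-local SNPs.
* Level 3 — negative associations with segment CNVs on other
  chromosomes.
* Level 4 — negative associations with microRNA expressions.

Within a level the greedy step adds the candidate with the largest
conditional log-likelihood ratio given the current model, provided its
1-df conditional test passes ``alpha_add`` and its jointly refitted sign
respects the type constraint.  All coefficients are re-estimated jointly
after each addition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .association import (
    SIGN_CONSTRAINTS,
    AssociationEdge,
    FitError,
    fit_soft_logistic,
    intercept_only_loglik,
    llr_pvalue,
)

log = logging.getLogger("aberlink")

CIS_WINDOW_BP = 1_000_000


@dataclass
class SelectedEffector:
    effector: str
    type: str
    level: int
    lam: float
    conditional_llr: float
    conditional_p: float


@dataclass
class TargetModel:
    """The joint layered model for one target."""

    target: str
    effectors: list[SelectedEffector] = field(default_factory=list)
    alphas: tuple[float, float] = (0.0, 0.0)
    loglik: float = 0.0

    @property
    def is_empty(self) -> bool:
        return not self.effectors

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "alphas": list(self.alphas),
            "loglik": self.loglik,
            "effectors": [
                {
                    "effector": e.effector, "type": e.type, "level": e.level,
                    "lambda": e.lam, "conditional_llr": e.conditional_llr,
                    "conditional_p": e.conditional_p,
                }
                for e in self.effectors
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TargetModel":
        return cls(
            target=d["target"],
            alphas=tuple(d["alphas"]),
            loglik=d["loglik"],
            effectors=[
                SelectedEffector(
                    effector=e["effector"], type=e["type"], level=e["level"],
                    lam=e["lambda"], conditional_llr=e["conditional_llr"],
                    conditional_p=e["conditional_p"],
                )
                for e in d["effectors"]
            ],
        )


def is_cis(seg_chrom: str, seg_span: tuple[int, int], gene_chrom: str,
           gene_span: tuple[int, int], window_bp: int = CIS_WINDOW_BP) -> bool:
    """True when the segment covers the gene or lies within 1 Mb of it."""
    if seg_chrom != gene_chrom:
        return False
    gap = max(seg_span[0] - gene_span[1], gene_span[0] - seg_span[1], 0)
    return gap <= window_bp


def candidate_levels(
    target: str,
    edges: list[AssociationEdge],
    target_annotation=None,
    segment_spans: dict[str, tuple[str, int, int]] | None = None,
    effector_genes: dict[str, str] | None = None,
    include_snps: bool = False,
) -> dict[int, list[AssociationEdge]]:
    """Assign each filtered edge of this target to exactly one priority level.

    Parameters
    ----------
    target_annotation:
        (chrom, start, end) for the target, or None if unannotated.
    segment_spans:
        segment effector ID -> (chrom, start bp, end bp).
    effector_genes:
        mutation/methylation effector ID -> gene symbol (to recognise
        aberrations of the target gene itself).
    include_snps:
        SNP effectors are scored but excluded from model building unless
        this flag is set (too few significant SNP pairs to trust).
    """
    segment_spans = segment_spans or {}
    effector_genes = effector_genes or {}
    levels: dict[int, list[AssociationEdge]] = {1: [], 2: [], 3: [], 4: []}
    for e in edges:
        if e.target != target:
            continue
        if e.type in ("snp_cis", "snp_trans") and not include_snps:
            continue
        if e.type in ("cis_cnv", "trans_cnv"):
            if target_annotation is None:
                log.warning("target %s has no coordinates; CNV candidate %s skipped",
                            target, e.effector)
                continue
            chrom, start, end = target_annotation
            span = segment_spans.get(e.effector)
            if span is None:
                continue
            if is_cis(span[0], (span[1], span[2]), chrom, (start, end)):
                levels[1].append(e)
            elif e.sign == "+":
                levels[2].append(e)
            else:
                levels[3].append(e)
        elif e.type == "mutation":
            own = effector_genes.get(e.effector) == target
            levels[1 if own else 2].append(e)
        elif e.type == "methylation":
            own = effector_genes.get(e.effector) == target
            levels[1 if own else 2].append(e)
        elif e.type == "mirna":
            levels[4].append(e)
        elif e.type in ("snp_cis", "snp_trans"):
            if target_annotation is None:
                continue
            levels[1 if e.type == "snp_cis" else 2].append(e)
    return levels


def select_model(
    target: str,
    target_probs: np.ndarray,
    level_candidates: dict[int, list[AssociationEdge]],
    effector_states: dict[str, np.ndarray],
    segment_chroms: dict[str, str] | None = None,
    alpha_add: float = 1e-3,
    max_effectors: int = 10,
    ridge: float = 1e-6,
) -> TargetModel:
    """Greedy layered forward selection for one target.

    effector_states maps effector ID -> per-sample expected-state vector
    aligned with ``target_probs`` rows.  ``segment_chroms`` maps segment
    effector IDs to chromosomes; at most one segment effector per
    chromosome is admitted.
    """
    segment_chroms = segment_chroms or {}
    W = np.asarray(target_probs, dtype=float)
    obs = np.isfinite(W).all(axis=1)
    model = TargetModel(target=target)
    selected: list[AssociationEdge] = []
    used_chroms: set[str] = set()

    def joint_fit(cands: list[AssociationEdge]):
        ids = [c.effector for c in cands]
        mask = obs.copy()
        for i in ids:
            mask &= np.isfinite(effector_states[i])
        Wm = W[mask]
        if not len(Wm):
            raise FitError("no complete samples")
        X = np.column_stack([effector_states[i][mask] for i in ids])
        if np.any(np.ptp(X, axis=0) == 0):
            raise FitError("zero-variance effector after masking")
        alphas, lams, ll = fit_soft_logistic(Wm, X, ridge=ridge)
        # compare against the nested model refit on the same sample mask
        if len(cands) > 1:
            Xp = X[:, :-1]
            _, _, ll_prev = fit_soft_logistic(Wm, Xp, ridge=ridge)
        else:
            ll_prev = intercept_only_loglik(Wm)
        return alphas, lams, ll, ll_prev

    admission: dict[str, tuple[int, float, float]] = {}  # effector -> (level, llr, p)
    final_fit = None
    for level in (1, 2, 3, 4):
        candidates = list(level_candidates.get(level, []))
        while candidates and len(selected) < max_effectors:
            scored = []
            for cand in candidates:
                if cand.effector in {s.effector for s in selected}:
                    continue
                chrom = segment_chroms.get(cand.effector)
                if chrom is not None and chrom in used_chroms:
                    continue
                try:
                    alphas, lams, ll, ll_prev = joint_fit(selected + [cand])
                except FitError as err:
                    log.debug("fit failed for %s + %s: %s", target, cand.effector, err)
                    continue
                llr = max(0.0, 2.0 * (ll - ll_prev))
                p = llr_pvalue(llr, W[obs])
                new_sign = "+" if lams[-1] >= 0 else "-"
                constraint = SIGN_CONSTRAINTS[cand.type]
                if cand.type == "trans_cnv":
                    constraint = cand.sign  # keep the level-2/3 semantics
                if constraint is not None and new_sign != constraint:
                    continue
                scored.append((llr, p, cand, alphas, lams, ll))
            qualifying = [s for s in scored if s[1] <= alpha_add]
            if not qualifying:
                break
            qualifying.sort(key=lambda s: (-s[0], s[2].effector))
            llr, p, best, alphas, lams, ll = qualifying[0]
            selected.append(best)
            admission[best.effector] = (level, float(llr), float(p))
            candidates = [c for c in candidates if c.effector != best.effector]
            chrom = segment_chroms.get(best.effector)
            if chrom is not None:
                used_chroms.add(chrom)
            final_fit = (alphas, lams, ll)
    if final_fit is not None:
        alphas, lams, ll = final_fit
        model.alphas = (float(alphas[0]), float(alphas[1]))
        model.loglik = float(ll)
        model.effectors = [
            SelectedEffector(
                effector=c.effector, type=c.type,
                level=admission[c.effector][0],
                lam=float(lams[i]),
                conditional_llr=admission[c.effector][1],
                conditional_p=admission[c.effector][2],
            )
            for i, c in enumerate(selected)
        ]
    if model.is_empty:
        q = np.nanmean(W[obs], axis=0)
        with np.errstate(divide="ignore"):
            a_m = float(np.log(q[0] / q[1])) if q[0] > 0 and q[1] > 0 else 0.0
            a_p = float(np.log(q[2] / q[1])) if q[2] > 0 and q[1] > 0 else 0.0
        model.alphas = (a_m, a_p)
        model.loglik = intercept_only_loglik(W[obs]) if obs.any() else 0.0
    return model
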