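"""End-to-end orchestration: quantize -> segment -> associate -> select ->
assemble -> validate -> align.

The library modules stay independent; this layer wires an
:class:`~aberlink.datamodel.OmicsDataset` through them with one
parameter object, and provides the ground-truth recovery evaluation used
with synthetic cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import association, modules, quantize, segmentation, selection
from .datamodel import OmicsDataset
from .simulate import GroundTruth

log = logging.getLogger("aberlink")


@dataclass
class PipelineParams:
    """Tunable parameters for a full pipeline run."""

    center: float = 0.5
    seg_model: segmentation.SegmentationModel = field(
        default_factory=segmentation.SegmentationModel)
    seg_tolerance_probes: int = 2
    seg_support_fraction: float = 0.1
    thresholds: dict = field(
        default_factory=lambda: dict(association.DEFAULT_THRESHOLDS))
    n_min: int = 20
    alpha_add: float = 1e-3
    max_effectors: int = 10
    r_min: float = 0.6
    merge_fraction: float = 1.0 / 3.0
    merge_min_overlap: int = 50
    include_snps: bool = False


@dataclass
class PipelineResult:
    segments: list
    edges: list
    filtered_edges: list
    target_models: list
    modules: list
    effector_states: dict
    target_matrix: object
    expr_cdf: pd.DataFrame


def build_effectors(ds: OmicsDataset, params: PipelineParams):
    """Quantize every non-mRNA modality into effector tristate arrays.

    Returns (effectors, segment_spans, segment_chroms, effector_genes,
    segments) where effectors maps effector ID ->
    (probs, modality, default type).
    """
    effectors: dict[str, tuple[np.ndarray, str, str]] = {}
    segment_spans: dict[str, tuple[str, int, int]] = {}
    segment_chroms: dict[str, str] = {}
    effector_genes: dict[str, str] = {}
    segments: list[segmentation.CnvSegment] = []

    if "cnv_probe" in ds.modalities:
        segments = segmentation.consensus_segments(
            ds.modalities["cnv_probe"], ds.feature_annotations["cnv_probe"],
            model=params.seg_model,
            tolerance_probes=params.seg_tolerance_probes,
            support_fraction=params.seg_support_fraction,
            center=params.center,
        )
        for seg in segments:
            effectors[seg.segment_id] = (seg.probs, "cnv", "trans_cnv")
            segment_spans[seg.segment_id] = (seg.chrom, seg.bp_span[0], seg.bp_span[1])
            segment_chroms[seg.segment_id] = seg.chrom

    if "methylation" in ds.modalities and len(ds.modalities["methylation"]):
        tm = quantize.quantize_matrix(
            ds.modalities["methylation"], center=params.center, modality="methylation")
        for i, f in enumerate(tm.features):
            effectors[f"meth:{f}"] = (tm.probs[i], "methylation", "methylation")
            effector_genes[f"meth:{f}"] = f

    if "mirna" in ds.modalities and len(ds.modalities["mirna"]):
        tm = quantize.quantize_matrix(
            ds.modalities["mirna"], center=params.center, modality="mirna")
        for i, f in enumerate(tm.features):
            effectors[f"mir:{f}"] = (tm.probs[i], "mirna", "mirna")

    if "mutation" in ds.modalities and len(ds.modalities["mutation"]):
        tm = quantize.encode_discrete_matrix(ds.modalities["mutation"], modality="mutation")
        for i, f in enumerate(tm.features):
            effectors[f"mut:{f}"] = (tm.probs[i], "mutation", "mutation")
            effector_genes[f"mut:{f}"] = f

    if params.include_snps and "snp" in ds.modalities and len(ds.modalities["snp"]):
        tm = quantize.encode_discrete_matrix(
            ds.modalities["snp"], mapping=quantize.SNP_ADDITIVE_MAPPING, modality="snp")
        for i, f in enumerate(tm.features):
            effectors[f"snp:{f}"] = (tm.probs[i], "snp", "snp_trans")

    return effectors, segment_spans, segment_chroms, effector_genes, segments


def _pair_type(effector_id: str, target: str, modality: str,
               segment_spans, gene_ann) -> str | None:
    if modality == "cnv":
        span = segment_spans.get(effector_id)
        ann = gene_ann.get(target)
        if span is None or ann is None:
            return None
        return ("cis_cnv"
                if selection.is_cis(span[0], (span[1], span[2]), ann[0], (ann[1], ann[2]))
                else "trans_cnv")
    if modality == "snp":
        ann = gene_ann.get(target)
        if ann is None:
            return None
        return "snp_cis"  # SNP positions are not modelled; scored as cis on-chromosome
    return {"methylation": "methylation", "mirna": "mirna", "mutation": "mutation"}[modality]


def run_association_stage(ds: OmicsDataset, params: PipelineParams):
    """Quantize, segment, screen all pairs, and filter by thresholds."""
    effectors, segment_spans, segment_chroms, effector_genes, segments = \
        build_effectors(ds, params)
    target_matrix = quantize.quantize_matrix(
        ds.modalities["mrna"], center=params.center, modality="mrna")
    gene_ann = {}
    ann = ds.feature_annotations.get("mrna")
    if ann is not None:
        for f in ann.index:
            row = ann.loc[f]
            gene_ann[f] = (str(row["chrom"]), int(row["start"]), int(row["end"]))

    def pair_type(effector_id, target):
        modality = effectors[effector_id][1]
        return _pair_type(effector_id, target, modality, segment_spans, gene_ann)

    edges = association.screen_pairs(effectors, target_matrix, pair_type,
                                     n_min=params.n_min)
    filtered = association.filter_pairs(edges, params.thresholds)
    log.info("screen: %d pairs, %d pass thresholds", len(edges), len(filtered))
    return effectors, segments, segment_spans, segment_chroms, effector_genes, \
        target_matrix, gene_ann, edges, filtered


def run_pipeline(ds: OmicsDataset, params: PipelineParams | None = None) -> PipelineResult:
    """Run the full module-construction pipeline on one dataset."""
    if params is None:
        params = PipelineParams()
    (effectors, segments, segment_spans, segment_chroms, effector_genes,
     target_matrix, gene_ann, edges, filtered) = run_association_stage(ds, params)

    by_target: dict[str, list] = {}
    for e in filtered:
        by_target.setdefault(e.target, []).append(e)

    effector_states = {
        eid: probs[:, 2] - probs[:, 0] for eid, (probs, _m, _t) in effectors.items()
    }
    target_models = []
    for ti, target in enumerate(target_matrix.features):
        t_edges = by_target.get(target)
        if not t_edges:
            continue
        levels = selection.candidate_levels(
            target, t_edges, target_annotation=gene_ann.get(target),
            segment_spans=segment_spans, effector_genes=effector_genes,
            include_snps=params.include_snps,
        )
        model = selection.select_model(
            target, target_matrix.probs[ti], levels, effector_states,
            segment_chroms=segment_chroms, alpha_add=params.alpha_add,
            max_effectors=params.max_effectors,
        )
        if not model.is_empty:
            target_models.append(model)
    log.info("selection: %d non-empty target models", len(target_models))

    used = sorted({s.effector for m in target_models for s in m.effectors})
    profiles = {e: effector_states[e] for e in used}
    clusters = modules.cluster_effectors(
        profiles, r_min=params.r_min,
        chrom_of={e: segment_chroms[e] for e in used if e in segment_chroms},
    )
    effector_types = {e: effectors[e][1] for e in used}
    target_states = target_matrix.expected_state
    mods = modules.assemble_modules(
        target_models, clusters, effector_types, target_states=target_states,
        fraction=params.merge_fraction, min_overlap=params.merge_min_overlap,
    )
    return PipelineResult(
        segments=segments, edges=edges, filtered_edges=filtered,
        target_models=target_models, modules=mods,
        effector_states=effector_states, target_matrix=target_matrix,
        expr_cdf=target_matrix.cdf,
    )


# ---------------------------------------------------------------------------
# ground-truth recovery evaluation


def effector_key(effector_id: str, truth: GroundTruth,
                 segment_chroms: dict[str, str] | None = None) -> str:
    """Map a pipeline effector ID onto a planted effector key."""
    if effector_id.startswith("mut:"):
        return effector_id
    if effector_id.startswith("meth:"):
        gene = effector_id.split(":", 1)[1]
        for key, members in truth.effector_clusters.items():
            if key.startswith("methcl") and gene in members:
                return f"meth:{key}"
        return effector_id
    if effector_id.startswith("mir:"):
        mir = effector_id.split(":", 1)[1]
        for key, members in truth.effector_clusters.items():
            if key.startswith("mircl") and mir in members:
                return f"mir:{key}"
        return effector_id
    if ":" in effector_id:  # segment: chrN:segK
        return f"cnv:{effector_id.split(':', 1)[0]}"
    return effector_id


def selected_edge_set(result: PipelineResult, truth: GroundTruth):
    """Selected (effector key, target, sign, level) tuples across all models."""
    out = set()
    for tm in result.target_models:
        for sel in tm.effectors:
            key = effector_key(sel.effector, truth)
            sign = "+" if sel.lam >= 0 else "-"
            out.add((key, tm.target, sign, sel.level))
    return out


def recovery_rates(result: PipelineResult, truth: GroundTruth):
    """(recall, spurious fraction) of planted effector-target edges.

    An edge counts as recovered only with the correct sign and level.
    """
    planted = truth.planted_edge_set()
    found = selected_edge_set(result, truth)
    planted_loose = {(k, t) for k, t, _s, _l in planted}
    recovered = planted & found
    spurious = {f for f in found if (f[0], f[1]) not in planted_loose}
    recall = len(recovered) / len(planted) if planted else float("nan")
    spur = len(spurious) / len(found) if found else 0.0
    return recall, spur
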