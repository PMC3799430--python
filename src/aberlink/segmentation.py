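"""Likelihood-based CNV segmentation with cross-sample consensus.

Copy-number aberrations stretch over contiguous probe runs, so the unit
of CNV analysis is a segment, not a probe.  Each chromosome is
recursively bisected under a naive-Bayes emission model: probes within a
segment are conditionally independent Gaussians whose mean is one of
three hidden copy states (loss < neutral < gain) shared by the whole
segment.  A split is accepted only when the gain in maximized
log-likelihood exceeds a BIC-style penalty; per-sample boundaries are
then pooled and clustered into consensus segments supported by a minimum
fraction of samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantize import quantize_tristate, rank_to_cdf

log = logging.getLogger("aberlink")


@dataclass
class SegmentationModel:
    """Emission model and stopping rule for recursive segmentation.

    means: fixed state means (loss, neutral, gain), log-ratio scale.
    sigma: shared probe SD; None = estimate from median absolute
        probe-to-probe difference of the data being segmented.
    penalty: log-likelihood gain required to accept a split; None = the
        BIC-style default 2*log(n_probes).
    min_probes: minimum probes per segment.
    """

    means: tuple[float, float, float] = (-0.5, 0.0, 0.5)
    sigma: float | None = None
    penalty: float | None = None
    min_probes: int = 5

    def __post_init__(self) -> None:
        lo, mid, hi = self.means
        if not (lo < mid < hi):
            raise ValueError("state means must satisfy loss < neutral < gain")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")


def estimate_sigma(values: np.ndarray) -> float:
    """Robust probe SD from the median absolute first difference.

    For iid Gaussian noise, |x_{i+1} - x_i| has median sigma*sqrt(2)*0.6745^{-1}...
    precisely MAD of the difference = sigma*sqrt(2)*Phi^{-1}(0.75); invert that.
    """
    values = np.asarray(values, dtype=float)
    diffs = np.abs(np.diff(values[np.isfinite(values)]))
    if len(diffs) == 0:
        return 1.0
    mad = float(np.median(diffs))
    sigma = mad / (np.sqrt(2.0) * 0.674489750196)
    return max(sigma, 1e-3)


class _SegmentScorer:
    """O(1) segment log-likelihoods via prefix sums.

    For fixed mean mu and sd sigma the Gaussian log-likelihood of probes
    [i, j) needs only the count, sum and sum of squares of the values.
    """

    def __init__(self, values: np.ndarray, model: SegmentationModel, sigma: float):
        self.s1 = np.concatenate([[0.0], np.cumsum(values)])
        self.s2 = np.concatenate([[0.0], np.cumsum(values**2)])
        self.means = np.asarray(model.means)
        self.sigma = sigma
        self._const = -0.5 * np.log(2.0 * np.pi * sigma**2)

    def loglik(self, i, j):
        """max over hidden state of the segment log-likelihood of [i, j).

        Accepts scalars or broadcastable integer arrays.
        """
        i = np.asarray(i)
        j = np.asarray(j)
        m = (j - i)[..., None]
        s1 = (self.s1[j] - self.s1[i])[..., None]
        s2 = (self.s2[j] - self.s2[i])[..., None]
        # sum (x-mu)^2 = s2 - 2 mu s1 + m mu^2, per candidate state
        ss = s2 - 2.0 * self.means * s1 + m * self.means**2
        ll = (m * self._const - ss / (2.0 * self.sigma**2)).max(axis=-1)
        return float(ll) if ll.ndim == 0 else ll


def segment_chromosome(probes: np.ndarray, model: SegmentationModel | None = None) -> list[int]:
    """Recursively segment one sample's probe vector; return interior boundaries.

    A boundary at k means segments [..., k) and [k, ...).  Missing probes
    are dropped for scoring and boundaries are mapped back to the original
    probe index space.  If fewer than ``min_probes`` probes are available a
    single segment is returned with a warning.
    """
    if model is None:
        model = SegmentationModel()
    probes = np.asarray(probes, dtype=float)
    finite_idx = np.flatnonzero(np.isfinite(probes))
    values = probes[finite_idx]
    n = len(values)
    if n < model.min_probes:
        warnings.warn(f"only {n} usable probes < min_probes={model.min_probes}; single segment")
        return []
    sigma = model.sigma if model.sigma is not None else estimate_sigma(values)
    penalty = model.penalty if model.penalty is not None else 2.0 * np.log(n)
    scorer = _SegmentScorer(values, model, sigma)
    boundaries: list[int] = []

    def recurse(i: int, j: int) -> None:
        if j - i < 2 * model.min_probes:
            return
        whole = scorer.loglik(i, j)
        ks = np.arange(i + model.min_probes, j - model.min_probes + 1)
        gains = scorer.loglik(i, ks) + scorer.loglik(ks, j) - whole
        best = int(np.argmax(gains))
        if gains[best] > penalty:
            k = int(ks[best])
            recurse(i, k)
            boundaries.append(k)
            recurse(k, j)
            return
        # an interior aberration flanked by equal states has no profitable
        # single split; test the best simultaneous split pair before stopping
        if j - i >= 3 * model.min_probes:
            k1s = np.arange(i + model.min_probes, j - 2 * model.min_probes + 1)
            k2s = np.arange(i + 2 * model.min_probes, j - model.min_probes + 1)
            pair_gain = (
                scorer.loglik(i, k1s)[:, None]
                + scorer.loglik(k1s[:, None], k2s[None, :])
                + scorer.loglik(k2s, j)[None, :]
                - whole
            )
            valid = k2s[None, :] - k1s[:, None] >= model.min_probes
            pair_gain = np.where(valid, pair_gain, -np.inf)
            a, b = np.unravel_index(np.argmax(pair_gain), pair_gain.shape)
            if pair_gain[a, b] > 2.0 * penalty:
                k1, k2 = int(k1s[a]), int(k2s[b])
                recurse(i, k1)
                boundaries.append(k1)
                recurse(k1, k2)
                boundaries.append(k2)
                recurse(k2, j)

    recurse(0, n)
    return sorted(int(finite_idx[b]) for b in boundaries)


def merge_boundaries(
    per_sample_boundaries: list[list[int]],
    tolerance_probes: int = 2,
    support_fraction: float = 0.1,
) -> list[int]:
    """Pool per-sample boundaries into a consensus list.

    Pooled boundary positions are single-linkage clustered (gap <=
    tolerance); a cluster is kept iff boundaries from at least
    ``support_fraction`` of the samples fall in it, and is represented by
    the floored median position.
    """
    n_samples = len(per_sample_boundaries)
    pooled = sorted(
        (pos, si) for si, bl in enumerate(per_sample_boundaries) for pos in bl
    )
    if not pooled:
        return []
    clusters: list[list[tuple[int, int]]] = [[pooled[0]]]
    for item in pooled[1:]:
        if item[0] - clusters[-1][-1][0] <= tolerance_probes:
            clusters[-1].append(item)
        else:
            clusters.append([item])
    consensus = []
    for cl in clusters:
        support = len({si for _, si in cl}) / n_samples
        if support >= support_fraction:
            consensus.append(int(np.floor(np.median([pos for pos, _ in cl]))))
    return sorted(set(consensus))


@dataclass
class CnvSegment:
    """A consensus chromosome segment with per-sample values and tristate probs."""

    segment_id: str
    chrom: str
    probe_span: tuple[int, int]   # [i, j) in probe indices
    bp_span: tuple[int, int]      # [start, end) in bp
    values: pd.Series             # per-sample mean probe log-ratio
    probs: np.ndarray = field(default=None, repr=False)  # (n_samples, 3)

    @property
    def n_probes(self) -> int:
        return self.probe_span[1] - self.probe_span[0]

    @property
    def expected_state(self) -> np.ndarray:
        return self.probs[:, 2] - self.probs[:, 0]


def consensus_segments(
    probe_matrix: pd.DataFrame,
    probe_bed: pd.DataFrame,
    model: SegmentationModel | None = None,
    tolerance_probes: int = 2,
    support_fraction: float = 0.1,
    center: float = 0.5,
) -> list[CnvSegment]:
    """Segment every chromosome across samples and build consensus segments.

    Per-sample segmentation first, then boundary merging; segment values
    are per-sample means over member probes, and segment tristate
    probabilities come from the rank-CDF of the segment value across
    samples (the same path the mRNA data take).
    """
    if model is None:
        model = SegmentationModel()
    segments: list[CnvSegment] = []
    samples = list(probe_matrix.columns)
    ann = probe_bed.loc[[p for p in probe_matrix.index if p in probe_bed.index]]
    for chrom in sorted(ann["chrom"].unique()):
        probes = ann[ann["chrom"] == chrom].sort_values("start")
        vals = probe_matrix.loc[probes.index].to_numpy(dtype=float)
        per_sample = [segment_chromosome(vals[:, j], model) for j in range(vals.shape[1])]
        bounds = merge_boundaries(per_sample, tolerance_probes, support_fraction)
        edges = [0, *bounds, vals.shape[0]]
        for si, (i, j) in enumerate(zip(edges[:-1], edges[1:])):
            seg_vals = pd.Series(np.nanmean(vals[i:j], axis=0), index=samples)
            cdf = rank_to_cdf(seg_vals.to_numpy())
            probs = quantize_tristate(cdf, center=center)
            start = int(probes["start"].iloc[i])
            end = int(probes["end"].iloc[j - 1])
            segments.append(
                CnvSegment(
                    segment_id=f"{chrom}:seg{si}",
                    chrom=chrom,
                    probe_span=(i, j),
                    bp_span=(start, end),
                    values=seg_vals,
                    probs=probs,
                )
            )
    log.info("consensus segmentation: %d segments", len(segments))
    return segments


def chromosome_representative(segments: list[CnvSegment], chrom: str) -> pd.Series:
    """One representative CNV profile per chromosome: probe-count-weighted
    mean of segment values (long-range intra-chromosome correlation makes a
    single profile adequate)."""
    segs = [s for s in segments if s.chrom == chrom]
    if not segs:
        raise ValueError(f"no segments on {chrom}")
    w = np.array([s.n_probes for s in segs], dtype=float)
    vals = np.stack([s.values.to_numpy() for s in segs])
    return pd.Series((w[:, None] * vals).sum(axis=0) / w.sum(), index=segs[0].values.index)


def cnv_autocorrelation(
    probe_matrix: pd.DataFrame,
    probe_bed: pd.DataFrame,
    bins: list[tuple[int, int]],
) -> pd.DataFrame:
    """Mean Pearson correlation of probe pairs per genomic-distance bin (QC).

    Pairs are intra-chromosome; empty bins report NaN.
    """
    ann = probe_bed.loc[[p for p in probe_matrix.index if p in probe_bed.index]]
    sums = np.zeros(len(bins))
    counts = np.zeros(len(bins), dtype=int)
    for chrom in ann["chrom"].unique():
        probes = ann[ann["chrom"] == chrom].sort_values("start")
        if len(probes) < 2:
            continue
        vals = probe_matrix.loc[probes.index].to_numpy(dtype=float)
        pos = probes["start"].to_numpy()
        cc = np.corrcoef(vals)
        for a in range(len(probes)):
            for b in range(a + 1, len(probes)):
                d = pos[b] - pos[a]
                for bi, (lo, hi) in enumerate(bins):
                    if lo <= d < hi:
                        if np.isfinite(cc[a, b]):
                            sums[bi] += cc[a, b]
                            counts[bi] += 1
                        break
    mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {"bin_lo": [b[0] for b in bins], "bin_hi": [b[1] for b in bins],
         "mean_correlation": mean, "n_pairs": counts}
    )
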