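"""Probabilistic quantization of continuous profiles into tristate probabilities.

Continuous measurements are rank-transformed per feature into CDF values
in (0, 1), then mapped to a probability triple
``[P(down), P(nochange), P(up)]`` by integrating over a family of
monotone two-threshold step quantizers: a sample is called *down* when its
CDF value v falls below a threshold a ~ Uniform(0, c) and *up* when it
exceeds b ~ Uniform(c, 1), with the two thresholds independent and the
center c = 0.5 by default.  Averaging the hard calls over the threshold
family gives the closed form

    p_down = max(0, (c - v) / c),   p_up = max(0, (v - c) / (1 - c)),

with p_nochange absorbing the rest.  This retains the continuous
information as graded probabilities instead of hard up/down calls.
Discrete modalities (mutation, SNP) are encoded as point masses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

#: tristate column order used everywhere
STATES = ("down", "nochange", "up")


def rank_to_cdf(values: np.ndarray) -> np.ndarray:
    """Mid-rank CDF transform ``(rank - 0.5) / n`` over non-missing entries.

    Ties receive their average rank, keeping tied samples symmetric; the
    -0.5 offset keeps all outputs strictly inside (0, 1).  Missing values
    (NaN) stay missing and do not contribute to n.
    """
    values = np.asarray(values, dtype=float)
    out = np.full(values.shape, np.nan)
    mask = np.isfinite(values)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("rank_to_cdf: all values missing")
    if n < 2:
        raise ValueError("rank_to_cdf: need at least 2 non-missing values")
    ranks = rankdata(values[mask], method="average")
    out[mask] = (ranks - 0.5) / n
    return out


def quantize_tristate(cdf, center: float = 0.5):
    """Map CDF value(s) in [0,1] to ``(p_down, p_nochange, p_up)``.

    Vectorized; NaN inputs yield NaN triples.
    """
    v = np.asarray(cdf, dtype=float)
    if not 0.0 < center < 1.0:
        raise ValueError("center must be in (0, 1)")
    finite = np.isfinite(v)
    if np.any((v[finite] < 0) | (v[finite] > 1)):
        raise ValueError("CDF values must lie in [0, 1]")
    p_down = np.clip((center - v) / center, 0.0, 1.0)
    p_up = np.clip((v - center) / (1.0 - center), 0.0, 1.0)
    p_nc = 1.0 - p_down - p_up
    if np.isscalar(cdf):
        return float(p_down), float(p_nc), float(p_up)
    return np.stack([p_down, p_nc, p_up], axis=-1)


@dataclass
class TristateProfile:
    """Per-sample tristate probabilities for one feature.

    ``probs`` has shape (n_samples, 3) in the order (down, nochange, up);
    rows sum to 1 (missing samples are all-NaN rows).
    """

    feature: str
    samples: list[str]
    probs: np.ndarray
    modality: str = ""
    discrete: bool = False

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(self.samples), 3):
            raise ValueError("probs must have shape (n_samples, 3)")
        rows = self.probs[np.isfinite(self.probs).all(axis=1)]
        if len(rows) and not np.allclose(rows.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"tristate rows of {self.feature!r} do not sum to 1")

    @property
    def expected_state(self) -> np.ndarray:
        """Scalar encoding e = P(up) - P(down) in [-1, 1] per sample."""
        return self.probs[:, 2] - self.probs[:, 0]

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.probs).all(axis=1)

    @property
    def zero_variance(self) -> bool:
        """True when the expected state is constant over observed samples."""
        e = self.expected_state[~self.missing]
        return len(e) == 0 or bool(np.ptp(e) == 0)


@dataclass
class TristateMatrix:
    """Tristate probabilities for a whole modality: (features, samples, 3)."""

    features: list[str]
    samples: list[str]
    probs: np.ndarray
    modality: str = ""
    cdf: pd.DataFrame | None = field(default=None, repr=False)

    def profile(self, feature: str) -> TristateProfile:
        i = self.features.index(feature)
        return TristateProfile(
            feature=feature, samples=self.samples, probs=self.probs[i], modality=self.modality
        )

    @property
    def expected_state(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.probs[:, :, 2] - self.probs[:, :, 0],
            index=self.features, columns=self.samples,
        )

    def __iter__(self):
        for f in self.features:
            yield self.profile(f)


def quantize_matrix(mat: pd.DataFrame, center: float = 0.5, modality: str = "") -> TristateMatrix:
    """Rank-CDF-transform each feature (row) across samples and quantize.

    Rows with fewer than 2 observed values come out all-missing.
    """
    probs = np.full((mat.shape[0], mat.shape[1], 3), np.nan)
    values = mat.to_numpy(dtype=float)
    cdfs = np.full_like(values, np.nan)
    for i in range(values.shape[0]):
        if np.isfinite(values[i]).sum() < 2:
            continue
        cdfs[i] = rank_to_cdf(values[i])
        probs[i] = quantize_tristate(cdfs[i], center=center)
    return TristateMatrix(
        features=list(mat.index), samples=list(mat.columns), probs=probs,
        modality=modality,
        cdf=pd.DataFrame(cdfs, index=mat.index, columns=mat.columns),
    )


#: default categorical -> tristate mappings
MUTATION_MAPPING = {"wildtype": 1, "missense": 2, "nonsense": 2, "mutated": 2}
SNP_ADDITIVE_MAPPING = {"0": 0, "1": 1, "2": 2}


def encode_discrete(
    calls,
    mapping: dict | None = None,
    feature: str = "",
    samples: list[str] | None = None,
    modality: str = "mutation",
) -> TristateProfile:
    """Encode a categorical call vector as point-mass tristate probabilities.

    ``mapping`` sends each label to a state index 0=down, 1=nochange, 2=up;
    the default is the mutation mapping (wildtype -> nochange, any mutation
    -> up).  Unknown labels raise, listing the accepted alphabet.
    """
    if mapping is None:
        mapping = MUTATION_MAPPING
    calls = [str(c) for c in calls]
    if samples is None:
        samples = [f"s{i}" for i in range(len(calls))]
    probs = np.zeros((len(calls), 3))
    for i, c in enumerate(calls):
        if c in ("NA", "."):
            probs[i] = np.nan
            continue
        if c not in mapping:
            raise ValueError(
                f"unseen label {c!r} for {feature!r}; alphabet: {sorted(mapping)}"
            )
        probs[i, mapping[c]] = 1.0
    return TristateProfile(
        feature=feature, samples=samples, probs=probs, modality=modality, discrete=True
    )


def encode_discrete_matrix(mat: pd.DataFrame, mapping: dict | None = None, modality: str = "mutation") -> TristateMatrix:
    probs = np.zeros((mat.shape[0], mat.shape[1], 3))
    for i, f in enumerate(mat.index):
        probs[i] = encode_discrete(
            mat.iloc[i].tolist(), mapping=mapping, feature=str(f),
            samples=list(mat.columns), modality=modality,
        ).probs
    return TristateMatrix(
        features=list(mat.index), samples=list(mat.columns), probs=probs, modality=modality
    )
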