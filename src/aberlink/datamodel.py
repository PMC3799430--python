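"""Typed containers for multi-modal tumor genomics data.

The pipeline operates on feature-by-sample matrices for up to six
modalities (mRNA, microRNA, CNV probes, DNA methylation, mutation calls,
SNP genotypes), genomic coordinates for features, and a clinical table
with survival information and molecular subtype labels.

Coordinates are 0-based half-open (BED convention) throughout; 1-based
inputs are converted at read time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: modality names with continuous measurements (rank/CDF transformed downstream)
CONTINUOUS_MODALITIES = frozenset({"mrna", "mirna", "cnv_probe", "methylation"})
#: modality names carrying categorical calls (point-mass tristate encoding)
DISCRETE_MODALITIES = frozenset({"mutation", "snp"})
MODALITIES = CONTINUOUS_MODALITIES | DISCRETE_MODALITIES

#: default mutation alphabet after collapsing synonymous calls
MUTATION_CODES = ("wildtype", "missense", "nonsense")

SUBTYPES = ("classical", "neural", "proneural", "mesenchymal")


@dataclass
class ClinicalRecord:
    """Survival and subtype annotation for one sample."""

    survival_days: float
    event: int
    subtype: Optional[str] = None
    gcimp: Optional[int] = None
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event!r}")
        if self.survival_days < 0:
            raise ValueError(f"survival_days must be >= 0, got {self.survival_days!r}")
        if self.subtype is not None and self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}; expected one of {SUBTYPES}")


@dataclass
class OmicsDataset:
    """A sample-aligned collection of modality matrices plus annotations.

    Attributes
    ----------
    samples:
        Ordered sample identifiers; every modality matrix has exactly these
        columns in this order.
    modalities:
        Modality name -> feature-by-sample ``DataFrame``.
    feature_annotations:
        Modality name -> ``DataFrame`` indexed by feature with columns
        ``symbol, chrom, start, end, strand`` (0-based half-open).
    clinical:
        Sample -> :class:`ClinicalRecord`.
    """

    samples: list[str]
    modalities: dict[str, pd.DataFrame]
    feature_annotations: dict[str, pd.DataFrame] = field(default_factory=dict)
    clinical: dict[str, ClinicalRecord] = field(default_factory=dict)

    def validate(self) -> None:
        """Check container invariants; raise ``ValueError`` on violation."""
        if len(self.samples) != len(set(self.samples)):
            raise ValueError("duplicate sample IDs")
        for name, mat in self.modalities.items():
            if name not in MODALITIES:
                raise ValueError(f"unknown modality {name!r}")
            if list(mat.columns) != list(self.samples):
                raise ValueError(f"modality {name!r} columns differ from dataset samples")
            if mat.index.has_duplicates:
                dup = mat.index[mat.index.duplicated()][0]
                raise ValueError(f"duplicate feature ID {dup!r} in modality {name!r}")
            if name in CONTINUOUS_MODALITIES:
                vals = mat.to_numpy(dtype=float)
                if np.isinf(vals).any():
                    raise ValueError(f"non-finite values in modality {name!r}")
        for name, ann in self.feature_annotations.items():
            bad = ann[(ann["start"] < 0) | (ann["start"] >= ann["end"])]
            if len(bad):
                raise ValueError(
                    f"invalid coordinates for {bad.index[0]!r} in modality {name!r}"
                )

    def clinical_frame(self) -> pd.DataFrame:
        """Clinical records as a DataFrame indexed by sample."""
        rows = {}
        for s in self.samples:
            rec = self.clinical.get(s)
            if rec is None:
                continue
            rows[s] = {
                "survival_days": rec.survival_days,
                "event": rec.event,
                "subtype": rec.subtype,
                "gcimp": rec.gcimp,
                **rec.covariates,
            }
        return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class GeneSetCollection:
    """Named gene sets over a fixed gene universe (GMT-style)."""

    sets: dict[str, set[str]]
    universe: set[str]

    def restrict(self) -> "GeneSetCollection":
        """Intersect every set with the universe and drop empty sets."""
        kept = {}
        for name, genes in self.sets.items():
            g = genes & self.universe
            if g:
                kept[name] = g
        return GeneSetCollection(sets=kept, universe=set(self.universe))

    def __len__(self) -> int:
        return len(self.sets)
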