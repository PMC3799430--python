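"""Readers and writers for every file format the pipeline touches.

TSV matrices (first column = feature ID, header = sample IDs, ``NA``/``.``
missing), 6-column BED coordinate tables, GMT gene sets, the clinical TSV,
and a YAML/JSON dataset config that ties them together.  All pipeline
outputs are JSON or TSV.
"""

from __future__ import annotations

import json
import logging
import os
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    CONTINUOUS_MODALITIES,
    MODALITIES,
    ClinicalRecord,
    GeneSetCollection,
    OmicsDataset,
)

log = logging.getLogger("aberlink")

_MISSING = {"NA", "."}


def read_matrix_tsv(path: str, discrete: bool = False) -> pd.DataFrame:
    """Read a feature-by-sample TSV matrix.

    Raises on duplicate feature IDs (naming the offender).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"matrix file not found: {path}")
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=sorted(_MISSING), keep_default_na=False,
        dtype=str if discrete else None,
    )
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate feature ID {dup!r} in {path}")
    if not discrete:
        df = df.astype(float)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_matrix_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", na_rep="NA", index_label="feature")


def read_bed(path: str, one_based: bool = False) -> pd.DataFrame:
    """Read a 6-column BED into an annotation frame indexed by feature ID.

    Columns out: symbol, chrom, start, end, strand (0-based half-open).
    BED column 4 (name) is the feature ID; symbol defaults to the ID.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"BED file not found: {path}")
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    if one_based:
        df["start"] = df["start"] - 1
    ann = pd.DataFrame(
        {
            "symbol": df["name"].astype(str).to_numpy(),
            "chrom": df["chrom"].astype(str).to_numpy(),
            "start": df["start"].astype(int).to_numpy(),
            "end": df["end"].astype(int).to_numpy(),
            "strand": df["strand"].astype(str).to_numpy(),
        },
        index=pd.Index(df["name"].astype(str).to_numpy(), name="feature"),
    )
    ann.index.name = "feature"
    return ann


def write_bed(ann: pd.DataFrame, path: str) -> None:
    out = pd.DataFrame(
        {
            "chrom": ann["chrom"],
            "start": ann["start"],
            "end": ann["end"],
            "name": ann.index,
            "score": 0,
            "strand": ann.get("strand", "+"),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_gmt(path: str, universe: Optional[set[str]] = None) -> GeneSetCollection:
    """Read a GMT file (name, description, genes...)."""
    sets: dict[str, set[str]] = {}
    genes_seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, _desc, *genes = parts
            members = {g for g in genes if g}
            if members:
                sets[name] = members
                genes_seen |= members
    coll = GeneSetCollection(sets=sets, universe=universe if universe is not None else genes_seen)
    return coll.restrict() if universe is not None else coll


def write_gmt(coll: GeneSetCollection, path: str) -> None:
    with open(path, "w") as fh:
        for name in sorted(coll.sets):
            fh.write("\t".join([name, "na", *sorted(coll.sets[name])]) + "\n")


def read_clinical(path: str) -> dict[str, ClinicalRecord]:
    if not os.path.exists(path):
        raise FileNotFoundError(f"clinical file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    for col in ("sample", "survival_days", "event"):
        if col not in df.columns:
            raise ValueError(f"clinical table missing required column {col!r}")
    records = {}
    extra = [c for c in df.columns if c not in {"sample", "survival_days", "event", "subtype", "gcimp"}]
    for _, row in df.iterrows():
        subtype = row.get("subtype")
        if isinstance(subtype, float) and np.isnan(subtype):
            subtype = None
        if subtype in ("NA", ""):
            subtype = None
        gcimp = row.get("gcimp")
        gcimp = None if gcimp is None or (isinstance(gcimp, float) and np.isnan(gcimp)) else int(gcimp)
        records[str(row["sample"])] = ClinicalRecord(
            survival_days=float(row["survival_days"]),
            event=int(row["event"]),
            subtype=subtype,
            gcimp=gcimp,
            covariates={c: row[c] for c in extra},
        )
    return records


def write_clinical(clinical: dict[str, ClinicalRecord], path: str) -> None:
    rows = []
    for s, rec in clinical.items():
        rows.append(
            {
                "sample": s,
                "survival_days": rec.survival_days,
                "event": rec.event,
                "subtype": rec.subtype if rec.subtype is not None else "NA",
                "gcimp": rec.gcimp if rec.gcimp is not None else "NA",
                **rec.covariates,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _sorted_features(mat: pd.DataFrame, ann: Optional[pd.DataFrame]) -> pd.DataFrame:
    """Deterministic feature order: (chrom, start, symbol) where annotated,
    else lexicographic by feature ID."""
    if ann is None:
        return mat.sort_index()
    keyed = []
    for f in mat.index:
        if f in ann.index:
            row = ann.loc[f]
            keyed.append((0, str(row["chrom"]), int(row["start"]), str(row["symbol"]), f))
        else:
            keyed.append((1, "", 0, "", f))
    order = [k[-1] for k in sorted(keyed)]
    return mat.loc[order]


def load_dataset(config_path: str) -> OmicsDataset:
    """Load a dataset from a YAML/JSON config naming per-modality files.

    Config schema::

        modalities:
          mrna: {matrix: path, bed: path}
          mutation: {matrix: path, bed: path, discrete: true}
        clinical: path
        one_based: false   # optional, applies to all BEDs

    The dataset is restricted to the intersection of sample IDs across all
    named modality matrices; fewer than 2 shared samples is fatal.
    """
    if not os.path.exists(config_path):
        raise FileNotFoundError(f"config not found: {config_path}")
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    base = os.path.dirname(os.path.abspath(config_path))

    def _p(path: str) -> str:
        return path if os.path.isabs(path) else os.path.join(base, path)

    one_based = bool(cfg.get("one_based", False))
    modalities: dict[str, pd.DataFrame] = {}
    annotations: dict[str, pd.DataFrame] = {}
    shared: Optional[set[str]] = None
    for name, entry in cfg["modalities"].items():
        if name not in MODALITIES:
            raise ValueError(f"unknown modality {name!r} in config")
        discrete = bool(entry.get("discrete", name in {"mutation", "snp"}))
        mat = read_matrix_tsv(_p(entry["matrix"]), discrete=discrete)
        ann = read_bed(_p(entry["bed"]), one_based=one_based) if entry.get("bed") else None
        mat = _sorted_features(mat, ann)
        modalities[name] = mat
        if ann is not None:
            annotations[name] = ann.loc[[f for f in mat.index if f in ann.index]]
        cols = set(mat.columns)
        shared = cols if shared is None else shared & cols
        log.info("modality %s: %d features x %d samples", name, *mat.shape)
    assert shared is not None
    if len(shared) < 2:
        raise ValueError(f"fewer than 2 shared samples across modalities ({len(shared)})")
    # keep the column order of the first modality for determinism
    first = next(iter(modalities.values()))
    samples = [s for s in first.columns if s in shared]
    modalities = {k: v.loc[:, samples] for k, v in modalities.items()}

    clinical: dict[str, ClinicalRecord] = {}
    if cfg.get("clinical"):
        clinical = {s: r for s, r in read_clinical(_p(cfg["clinical"])).items() if s in shared}

    ds = OmicsDataset(
        samples=samples,
        modalities=modalities,
        feature_annotations=annotations,
        clinical=clinical,
    )
    ds.validate()
    log.info("dataset: %d shared samples, %d modalities", len(samples), len(modalities))
    return ds


def write_dataset(ds: OmicsDataset, out_dir: str) -> str:
    """Write the dataset as a directory of TSV/BED files plus a config.

    Returns the path of the config file, suitable for :func:`load_dataset`.
    """
    os.makedirs(out_dir, exist_ok=True)
    cfg: dict = {"modalities": {}, "one_based": False}
    for name, mat in ds.modalities.items():
        mpath = f"{name}.tsv"
        write_matrix_tsv(mat, os.path.join(out_dir, mpath))
        entry = {"matrix": mpath, "discrete": name not in CONTINUOUS_MODALITIES}
        if name in ds.feature_annotations:
            bpath = f"{name}.bed"
            write_bed(ds.feature_annotations[name], os.path.join(out_dir, bpath))
            entry["bed"] = bpath
        cfg["modalities"][name] = entry
    if ds.clinical:
        write_clinical(ds.clinical, os.path.join(out_dir, "clinical.tsv"))
        cfg["clinical"] = "clinical.tsv"
    cfg_path = os.path.join(out_dir, "dataset.yaml")
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh)
    return cfg_path


def merge_replicates(mat_a: pd.DataFrame, mat_b: pd.DataFrame) -> pd.DataFrame:
    """Merge two replicate rank-CDF matrices into one gene-level matrix.

    Probes of the same gene (duplicate index labels) are averaged within
    each replicate first; gene-level values are then averaged across the
    replicates where the gene is present.  Genes present in only one
    replicate keep that replicate's value.
    """
    shared_samples = [s for s in mat_a.columns if s in set(mat_b.columns)]
    if not shared_samples:
        raise ValueError("replicates share no samples")
    a = mat_a.loc[:, shared_samples].groupby(level=0).mean()
    b = mat_b.loc[:, shared_samples].groupby(level=0).mean()
    genes = sorted(set(a.index) | set(b.index))
    if not (set(a.index) & set(b.index)):
        raise ValueError("replicates share no genes")
    out = pd.DataFrame(index=genes, columns=shared_samples, dtype=float)
    both = sorted(set(a.index) & set(b.index))
    only_a = sorted(set(a.index) - set(b.index))
    only_b = sorted(set(b.index) - set(a.index))
    out.loc[both] = (a.loc[both] + b.loc[both]) / 2.0
    out.loc[only_a] = a.loc[only_a]
    out.loc[only_b] = b.loc[only_b]
    out.index.name = mat_a.index.name
    return out


def write_json(obj, path: str) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)


def read_json(path: str):
    with open(path) as fh:
        return json.load(fh)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, set):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
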