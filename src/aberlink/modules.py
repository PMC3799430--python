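"""Assembly of association modules from per-target models.

Closely related effectors are first consolidated: segment CNVs on the
same chromosome are always combined, while methylation and microRNA
profiles are clustered as connected components of the graph whose edges
join profiles with Pearson correlation >= r_min.  Each consolidated
effector (cluster) and association sign then defines a proto-module
whose targets are the union over its member effectors; finally modules
sharing a substantial fraction of targets are merged to a fixed point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .selection import TargetModel

log = logging.getLogger("aberlink")


class _UnionFind:
    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller ID wins as root
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


def cluster_effectors(
    profiles: dict[str, np.ndarray],
    r_min: float = 0.6,
    chrom_of: dict[str, str] | None = None,
) -> list[list[str]]:
    """Group effector profiles into clusters.

    Edges join pairs with Pearson correlation of expected states >= r_min;
    clusters are connected components.  Segment CNV effectors listed in
    ``chrom_of`` are unconditionally combined per chromosome.
    """
    if not 0.0 < r_min <= 1.0:
        raise ValueError("r_min must be in (0, 1]")
    chrom_of = chrom_of or {}
    ids = sorted(profiles)
    uf = _UnionFind(ids)
    # same-chromosome segments always merge
    by_chrom: dict[str, list[str]] = {}
    for i in ids:
        if i in chrom_of:
            by_chrom.setdefault(chrom_of[i], []).append(i)
    for members in by_chrom.values():
        for other in members[1:]:
            uf.union(members[0], other)
    # correlation edges among non-segment effectors of the same modality set
    free = [i for i in ids if i not in chrom_of]
    for a_idx in range(len(free)):
        for b_idx in range(a_idx + 1, len(free)):
            a, b = free[a_idx], free[b_idx]
            xa, xb = profiles[a], profiles[b]
            ok = np.isfinite(xa) & np.isfinite(xb)
            if ok.sum() < 3 or np.ptp(xa[ok]) == 0 or np.ptp(xb[ok]) == 0:
                continue
            r = np.corrcoef(xa[ok], xb[ok])[0, 1]
            if r >= r_min:
                uf.union(a, b)
    clusters: dict[str, list[str]] = {}
    for i in ids:
        clusters.setdefault(uf.find(i), []).append(i)
    return [sorted(v) for _, v in sorted(clusters.items())]


def cluster_profile(profiles: dict[str, np.ndarray], members: list[str]) -> np.ndarray:
    """Per-sample mean expected state over cluster members."""
    return np.nanmean(np.stack([profiles[m] for m in members]), axis=0)


def mergeable(
    targets_a: set[str],
    targets_b: set[str],
    fraction: float = 1.0 / 3.0,
    min_overlap: int = 50,
) -> bool:
    """Merge rule: overlap strictly exceeds a third of the smaller module,
    or reaches the absolute floor of 50 genes."""
    if not targets_a or not targets_b:
        raise ValueError("modules must have at least one target")
    inter = len(targets_a & targets_b)
    return inter > fraction * min(len(targets_a), len(targets_b)) or inter >= min_overlap


@dataclass
class AssociationModule:
    """An effector cluster with per-effector association signs and targets.

    ``sign`` is the module-level direction: "+" or "-" when all effector
    associations share it, "±" for merged modules mixing both (a CNV
    module merged with a methylation module, say).
    """

    module_id: str
    effectors: list[tuple[str, str, str]]   # (effector ID, type, sign)
    sign: str
    targets: set[str]
    provenance: list[str] = field(default_factory=list)
    activity: pd.Series | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "module_id": self.module_id,
            "effectors": [list(e) for e in sorted(self.effectors)],
            "sign": self.sign,
            "targets": sorted(self.targets),
            "provenance": sorted(self.provenance),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AssociationModule":
        return cls(
            module_id=d["module_id"],
            effectors=[tuple(e) for e in d["effectors"]],
            sign=d["sign"],
            targets=set(d["targets"]),
            provenance=list(d.get("provenance", [])),
        )


def assemble_modules(
    target_models: list[TargetModel],
    effector_clusters: list[list[str]],
    effector_types: dict[str, str],
    target_states: pd.DataFrame | None = None,
    fraction: float = 1.0 / 3.0,
    min_overlap: int = 50,
) -> list[AssociationModule]:
    """Build proto-modules per (effector cluster, sign) and merge to fixed point.

    Positive and negative target sets of the same effector form separate
    modules.  Merging iterates over all pairs in a deterministic order
    (target-set size descending, module ID ascending) until no mergeable
    pair remains; merged modules union both effector and target sets.

    target_states (targets x samples expected-state frame) is optional and,
    when given, fills each module's per-sample activity with the median
    expected state over its targets.
    """
    cluster_of = {}
    for ci, members in enumerate(effector_clusters):
        for m in members:
            cluster_of[m] = ci

    proto: dict[tuple[int, str], AssociationModule] = {}
    for tm in target_models:
        for sel in tm.effectors:
            ci = cluster_of.get(sel.effector)
            if ci is None:
                continue
            sign = "+" if sel.lam >= 0 else "-"
            key = (ci, sign)
            if key not in proto:
                proto[key] = AssociationModule(
                    module_id=f"c{ci}{sign}",
                    effectors=sorted(
                        (e, effector_types.get(e, ""), sign)
                        for e in effector_clusters[ci]
                    ),
                    sign=sign,
                    targets=set(),
                    provenance=[f"c{ci}{sign}"],
                )
            proto[key].targets.add(tm.target)

    modules = [m for m in proto.values() if m.targets]
    changed = True
    while changed:
        changed = False
        modules.sort(key=lambda m: (-len(m.targets), m.module_id))
        for i in range(len(modules)):
            for j in range(i + 1, len(modules)):
                a, b = modules[i], modules[j]
                if mergeable(a.targets, b.targets, fraction, min_overlap):
                    signs = {s for _, _, s in set(a.effectors) | set(b.effectors)}
                    merged = AssociationModule(
                        module_id=a.module_id,
                        effectors=sorted(set(a.effectors) | set(b.effectors)),
                        sign=a.sign if signs == {a.sign} else "\u00b1",
                        targets=a.targets | b.targets,
                        provenance=sorted(set(a.provenance) | set(b.provenance)),
                    )
                    modules = [m for k, m in enumerate(modules) if k not in (i, j)]
                    modules.append(merged)
                    changed = True
                    break
            if changed:
                break

    modules.sort(key=lambda m: (-len(m.targets), m.module_id))
    for idx, m in enumerate(modules, start=1):
        m.module_id = f"M{idx:02d}"
        if target_states is not None:
            present = [t for t in sorted(m.targets) if t in target_states.index]
            if present:
                m.activity = target_states.loc[present].median(axis=0)
    log.info("assembled %d modules from %d proto-modules", len(modules), len(proto))
    return modules


def target_universe(modules: list[AssociationModule]) -> set[str]:
    out: set[str] = set()
    for m in modules:
        out |= m.targets
    return out
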