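"""Alignment of module activities with sample subtype labels.

Each module's representative per-sample value is the median of its
target expressions on the CDF scale; thresholding at 0.5 yields a binary
high/low class per sample.  Subtype concentration, joint multi-module
hallmarks with precision/recall against a truth label, and Kaplan-Meier
survival stratification with the logrank test complete the alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test


@dataclass
class HallmarkDefinition:
    """A conjunction of required module polarities, e.g. [("M01", "low"), ...]."""

    requirements: list[tuple[str, str]]

    def __post_init__(self) -> None:
        for mod, pol in self.requirements:
            if pol not in ("high", "low"):
                raise ValueError(f"polarity must be high/low, got {pol!r} for {mod!r}")


def module_representative(expr_cdf: pd.DataFrame, targets: set[str]) -> pd.Series:
    """Per-sample median of target expressions on the CDF scale."""
    present = [g for g in sorted(targets) if g in expr_cdf.index]
    if not present:
        raise ValueError("no module targets in the expression matrix")
    return expr_cdf.loc[present].median(axis=0)


def binary_classify(activity: pd.Series) -> pd.Series:
    """high iff the representative value >= 0.5; missing samples dropped."""
    act = activity.dropna()
    return pd.Series(np.where(act >= 0.5, "high", "low"), index=act.index)


def concentration(
    module_classes: pd.Series,
    subtype_labels: pd.Series,
    slack: int = 10,
) -> pd.DataFrame:
    """Per-subtype high/low overlap counts and the concentration flag.

    A subtype is concentrated in one binary class when no more than
    ``slack`` of its samples fall in the complementary class.
    """
    shared = [s for s in module_classes.index if s in subtype_labels.index]
    cls = module_classes.loc[shared]
    lab = subtype_labels.loc[shared].dropna()
    rows = []
    for subtype in sorted(lab.unique()):
        members = lab[lab == subtype].index
        n_high = int((cls.loc[members] == "high").sum())
        n_low = int((cls.loc[members] == "low").sum())
        concentrated = min(n_high, n_low) <= slack
        side = "NA"
        if concentrated:
            side = "high" if n_high >= n_low else "low"
        rows.append({"subtype": subtype, "n_high": n_high, "n_low": n_low,
                     "concentrated": concentrated, "side": side})
    return pd.DataFrame(rows).set_index("subtype")


def hallmark_precision_recall(
    hallmark: HallmarkDefinition,
    module_classes: pd.DataFrame,
    truth_labels: pd.Series,
):
    """Precision/recall of the joint hallmark against a binary truth label.

    module_classes is modules x samples with values "high"/"low".  The
    flagged set contains samples matching every required polarity; an
    empty hallmark flags all samples (vacuous conjunction).  Returns
    (precision, recall, flagged_ids); precision is NaN when nothing is
    flagged.
    """
    samples = list(module_classes.columns)
    flagged = set(samples)
    for mod, pol in hallmark.requirements:
        if mod not in module_classes.index:
            raise ValueError(f"hallmark module {mod!r} not classified")
        row = module_classes.loc[mod]
        flagged &= {s for s in samples if row[s] == pol}
    positives = {s for s in samples if bool(truth_labels.get(s))}
    tp = len(flagged & positives)
    precision = tp / len(flagged) if flagged else float("nan")
    recall = tp / len(positives) if positives else float("nan")
    return precision, recall, flagged


def km_logrank(groups: pd.Series, clinical: pd.DataFrame):
    """Kaplan-Meier medians and the logrank test between two groups.

    groups is a boolean/binary per-sample series; clinical carries
    ``survival_days`` and ``event``.  Returns a dict with per-group median
    survival (NaN when the curve never crosses 0.5), the logrank
    statistic and its p-value.
    """
    shared = [s for s in groups.index if s in clinical.index]
    g = groups.loc[shared].astype(bool)
    cl = clinical.loc[shared]
    if g.nunique() < 2:
        raise ValueError("need two non-empty groups")
    out = {"median_survival": {}, "km_curves": {}}
    for label, members in (("group1", g[g].index), ("group0", g[~g].index)):
        kmf = KaplanMeierFitter()
        kmf.fit(cl.loc[members, "survival_days"], cl.loc[members, "event"])
        med = kmf.median_survival_time_
        out["median_survival"][label] = float(med) if np.isfinite(med) else float("nan")
        out["km_curves"][label] = kmf.survival_function_
    res = logrank_test(
        cl.loc[g[g].index, "survival_days"], cl.loc[g[~g].index, "survival_days"],
        event_observed_A=cl.loc[g[g].index, "event"],
        event_observed_B=cl.loc[g[~g].index, "event"],
    )
    out["statistic"] = float(res.test_statistic)
    out["p_value"] = float(res.p_value)
    return out
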