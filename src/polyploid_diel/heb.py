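"""Five-category homoeolog-expression-bias (HEB) classification.

Each homoeologous gene group is scored at each time point by combining two
differential tests: the diploid-ortholog contrast (progenitor 1 vs progenitor
2) and the subgenome-homoeolog contrast within the allopolyploid.  The 3x3
grid of (diploid bias, subgenome bias) states collapses onto five categories:

========================  =====================  ================
diploid ortholog bias     subgenome bias         category
========================  =====================  ================
none                      none                   balance_retention
biased                    same direction         bias_retention
biased                    opposite direction     bias_switch
none                      biased                 bias_gain
biased                    none                   bias_loss
========================  =====================  ================

Across the six diurnal time points a group is "constitutive" when the same
non-balance category holds at every time point, "balance_retention_all" when
balanced throughout, and "temporal" otherwise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import HEB_CATEGORIES

__all__ = [
    "BIAS_STATES",
    "classify_timepoint",
    "bias_from_de",
    "classify_timepoints_table",
    "classify_group",
    "classify_all_groups",
    "heb_table",
    "eligible_groups",
]

#: Direction states for either contrast; "A_gt_B" means the first member of
#: the contrast (P1, or the Bd-subgenome) is the higher-expressed one.
BIAS_STATES = ("none", "A_gt_B", "B_gt_A")


def classify_timepoint(diploid_bias: str, subgenome_bias: str) -> str:
    """Map one (diploid bias, subgenome bias) pair to its HEB category.

    Total function on the 3x3 grid; directions are aligned so that ``A``
    refers to P1 in the diploid contrast and to the Bd-subgenome in the
    homoeolog contrast (P1 is the Bd donor).
    """
    for b in (diploid_bias, subgenome_bias):
        if b not in BIAS_STATES:
            raise ValueError(f"unknown bias state {b!r}")
    if diploid_bias == "none" and subgenome_bias == "none":
        return "balance_retention"
    if diploid_bias == "none":
        return "bias_gain"
    if subgenome_bias == "none":
        return "bias_loss"
    return "bias_retention" if diploid_bias == subgenome_bias else "bias_switch"


def bias_from_de(de: pd.DataFrame) -> pd.Series:
    """Turn one time point's Wald results into direction states.

    ``lfc`` is the log2 fold change of the contrast's second member (B) over
    the first (A); significance is the table's FDR flag.
    """
    return pd.Series(
        np.where(
            ~de["significant"], "none",
            np.where(de["lfc"] < 0, "A_gt_B", "B_gt_A"),
        ),
        index=de.index,
    )


def classify_timepoints_table(
    diploid_de: dict[float, pd.DataFrame],
    subgenome_de: dict[float, pd.DataFrame],
) -> pd.DataFrame:
    """Per-group per-time-point category table (genes x clock hours).

    Both dicts map clock hour to a Wald result table over the same gene
    universe; missing hours in either contrast raise.
    """
    hours = sorted(diploid_de)
    if sorted(subgenome_de) != hours:
        raise ValueError("diploid and subgenome contrasts cover different hours")
    cols = {}
    for t in hours:
        dip = bias_from_de(diploid_de[t])
        sub = bias_from_de(subgenome_de[t])
        if not dip.index.equals(sub.index):
            raise ValueError(f"gene universes differ at t={t}")
        both_none = (dip == "none") & (sub == "none")
        dip_none = (dip == "none") & ~both_none
        sub_none = (sub == "none") & ~both_none
        same = (dip == sub) & ~both_none
        cat = np.where(
            both_none, "balance_retention",
            np.where(dip_none, "bias_gain",
                     np.where(sub_none, "bias_loss",
                              np.where(same, "bias_retention", "bias_switch"))),
        )
        cols[t] = pd.Series(cat, index=dip.index)
    return pd.DataFrame(cols)


def classify_group(categories: pd.Series | list[str]) -> str:
    """Summarise one group's six per-time-point categories into a pattern.

    ``balance_retention_all`` if balanced at every time point,
    ``constitutive:<category>`` if the identical non-balance category holds
    at all time points, ``temporal`` otherwise.
    """
    cats = list(categories)
    if any(pd.isna(c) for c in cats):
        raise ValueError("missing time point in category series")
    uniq = set(cats)
    if uniq == {"balance_retention"}:
        return "balance_retention_all"
    if len(uniq) == 1:
        return f"constitutive:{cats[0]}"
    return "temporal"


def classify_all_groups(per_tp: pd.DataFrame) -> pd.Series:
    """Vectorised pattern classification over a genes x hours category table."""
    arr = per_tp.to_numpy()
    all_same = (arr == arr[:, [0]]).all(axis=1)
    balanced = all_same & (arr[:, 0] == "balance_retention")
    pattern = np.where(
        balanced, "balance_retention_all",
        np.where(all_same,
                 np.char.add("constitutive:", arr[:, 0].astype(str)), "temporal"),
    )
    return pd.Series(pattern, index=per_tp.index, name="pattern")


def modal_category(per_tp: pd.DataFrame) -> pd.Series:
    """Per-gene recovered category: the modal call across time points.

    The planted category of a synthetic gene is a per-gene property; the
    modal per-time-point call is its natural gene-level estimator (ties break
    lexicographically for reproducibility).
    """
    return per_tp.mode(axis=1)[0]


def category_recall(per_tp: pd.DataFrame, planted: pd.Series) -> dict[str, float]:
    """Gene-level confusion-diagonal recall per planted category."""
    modal = modal_category(per_tp)
    planted = planted.loc[per_tp.index]
    return {
        cat: float((modal[(planted == cat).to_numpy()] == cat).mean())
        for cat in sorted(planted.unique())
    }


def heb_table(patterns: pd.Series) -> pd.DataFrame:
    """Pattern-class counts with proportions (percent, 1 decimal).

    Rows cover balance_retention_all, each constitutive category, and
    temporal; counts partition the classified universe.
    """
    order = ["balance_retention_all"] + [
        f"constitutive:{c}" for c in HEB_CATEGORIES if c != "balance_retention"
    ] + ["temporal"]
    counts = patterns.value_counts()
    total = int(counts.sum())
    rows = [
        {"pattern": name, "count": int(counts.get(name, 0)),
         "percent": round(100.0 * counts.get(name, 0) / total, 1) if total else 0.0}
        for name in order
    ]
    return pd.DataFrame(rows)


def eligible_groups(
    rpm_by_channel: dict[str, pd.DataFrame],
    meta: pd.DataFrame,
    diploids: tuple[str, str] = ("P1", "P2"),
    subgenomes: tuple[str, str] = ("BdSub", "BsSub"),
    threshold: float = 1.0,
) -> pd.Series:
    """HEB eligibility: expressed in >= 1 diploid AND >= 1 subgenome.

    "Expressed" is the standard rule (RPM >= threshold in all replicates of
    at least one time point) evaluated on the full diurnal series of each
    channel.
    """
    from .diffexpr import expressed_filter

    expr = {
        ch: expressed_filter(rpm_by_channel[ch], meta, threshold)
        for ch in (*diploids, *subgenomes)
    }
    dip_ok = expr[diploids[0]] | expr[diploids[1]]
    sub_ok = expr[subgenomes[0]] | expr[subgenomes[1]]
    return dip_ok & sub_ok
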