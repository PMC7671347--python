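"""Expression-pattern similarity between ortholog and homoeolog pairs.

Quantifies the diurnal-synchronisation signature of allopolyploidy: Pearson
correlations of replicate-mean diel profiles for diploid ortholog pairs vs
allopolyploid homoeolog pairs, distribution shifts between those two sets,
circular concordance of rhythmic peak times, and flat hypergeometric GO-term
enrichment for gene selections.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .rhythm import circular_difference

__all__ = [
    "mean_profile",
    "pair_correlation",
    "pair_correlation_table",
    "correlation_shift",
    "fisher_lee_correlation",
    "peak_time_comparison",
    "hypergeometric_enrichment",
]


def mean_profile(expr: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Replicate-mean genes x clock-hour profile matrix."""
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    hours = meta.loc[expr.columns, "clock_hour"]
    prof = {
        float(h): expr[cols.index].mean(axis=1) for h, cols in hours.groupby(hours)
    }
    return pd.DataFrame(prof)


def pair_correlation(series1, series2) -> float:
    """Pearson r between two paired diel profiles; NaN if either is constant."""
    a = np.asarray(series1, dtype=float)
    b = np.asarray(series2, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need >= 3 paired time points")
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def pair_correlation_table(
    profiles1: pd.DataFrame, profiles2: pd.DataFrame
) -> pd.Series:
    """Rowwise Pearson r between two genes x hours profile matrices.

    Constant rows on either side yield NaN and are counted by the caller;
    both matrices must share gene index and hour columns.
    """
    if not profiles1.index.equals(profiles2.index):
        raise ValueError("gene indices differ")
    a = profiles1.to_numpy(dtype=float)
    b = profiles2[profiles1.columns].to_numpy(dtype=float)
    a_c = a - a.mean(axis=1, keepdims=True)
    b_c = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((a_c**2).sum(axis=1) * (b_c**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (a_c * b_c).sum(axis=1) / denom, np.nan)
    return pd.Series(r, index=profiles1.index, name="pearson_r")


def correlation_shift(dist_a, dist_b) -> dict[str, float]:
    """Location-shift summary between two correlation distributions.

    Reports medians, the median difference (B - A) and the two-sample
    Kolmogorov-Smirnov statistic with its p-value.  NaNs are dropped; each
    side needs >= 30 finite values.
    """
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 30 or len(b) < 30:
        raise ValueError("each distribution needs >= 30 finite values")
    ks = stats.ks_2samp(a, b)
    return {
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "delta_median": float(np.median(b) - np.median(a)),
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
        "n_a": int(len(a)),
        "n_b": int(len(b)),
    }


def fisher_lee_correlation(angles1, angles2) -> float:
    """Fisher-Lee circular correlation of two angle samples (radians).

    T-linear association: sums of sin(ai - aj) * sin(bi - bj) over pairs,
    normalised; equals 1 for identical angle sets.
    """
    a = np.asarray(angles1, dtype=float)
    b = np.asarray(angles2, dtype=float)
    da = np.sin(a[:, None] - a[None, :])
    db = np.sin(b[:, None] - b[None, :])
    num = (da * db).sum()
    den = np.sqrt((da**2).sum() * (db**2).sum())
    return float(num / den) if den > 0 else float("nan")


def peak_time_comparison(peaks1, peaks2, period: float = 24.0) -> dict:
    """Concordance of two peak-time samples on the clock circle.

    Excludes pairs with an undefined (NaN) peak on either side, reporting the
    exclusion count.  Returns the per-gene scatter table (linear hours plus
    the signed circular difference), the Fisher-Lee circular correlation, the
    plain Pearson correlation of the linear hours for reference, and the mean
    absolute circular difference.
    """
    p1 = np.asarray(peaks1, dtype=float)
    p2 = np.asarray(peaks2, dtype=float)
    ok = np.isfinite(p1) & np.isfinite(p2)
    d = circular_difference(p1[ok], p2[ok], period)
    ang1 = 2 * np.pi * p1[ok] / period
    ang2 = 2 * np.pi * p2[ok] / period
    scatter = pd.DataFrame(
        {"peak1_h": p1[ok], "peak2_h": p2[ok], "circular_diff_h": d}
    )
    return {
        "scatter": scatter,
        "circular_correlation": fisher_lee_correlation(ang1, ang2),
        "linear_pearson": pair_correlation(p1[ok], p2[ok]) if ok.sum() >= 3 else np.nan,
        "mean_abs_circular_diff_h": float(np.mean(np.abs(d))) if ok.any() else np.nan,
        "n_pairs": int(ok.sum()),
        "n_excluded": int((~ok).sum()),
    }


def hypergeometric_enrichment(
    selected: set[str] | list[str],
    annotation: pd.DataFrame,
    universe: set[str] | list[str],
    alpha: float = 1e-4,
) -> pd.DataFrame:
    """Upper-tail hypergeometric term enrichment (flat annotation, raw p).

    ``annotation`` maps gene_id to term_id (long format).  For each term with
    K annotated genes in the universe of size N and an overlap k with the n
    selected genes, p = P[X >= k], X ~ Hypergeom(N, K, n).  Terms are flagged
    enriched at the unadjusted ``alpha`` cutoff, matching the conventional
    GO-enrichment procedure.
    """
    universe = set(universe)
    selected = set(selected) & universe
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    ann = annotation[annotation["gene_id"].isin(universe)]
    if not selected:
        return pd.DataFrame(
            columns=["term_id", "universe", "annotated", "selected", "overlap",
                     "pvalue", "enriched"]
        )
    n_univ = len(universe)
    n_sel = len(selected)
    rows = []
    for term, genes in ann.groupby("term_id")["gene_id"]:
        gset = set(genes)
        k = len(gset & selected)
        p = float(stats.hypergeom.sf(k - 1, n_univ, len(gset), n_sel))
        rows.append(
            {"term_id": term, "universe": n_univ, "annotated": len(gset),
             "selected": n_sel, "overlap": k, "pvalue": p, "enriched": p < alpha}
        )
    return pd.DataFrame(rows).sort_values("pvalue", kind="stable").reset_index(drop=True)
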