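"""Expression transforms and group-comparison statistics.

TPM matrices (genes x samples) are transformed as log2(mean TPM + 1), with
technical replicates averaged on the TPM scale *before* the transform.
Group comparisons use a two-sided Student's t test or Wilcoxon rank-sum test
per feature (an "auto" mode screens each group with Shapiro-Wilk at alpha
0.05 and falls back to the rank test), with Benjamini-Hochberg adjustment
across features. Correlations are Pearson's r with BH-adjusted two-sided
p-values, significant at FDR < 0.05.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def log_transform(
    tpm: pd.DataFrame, replicate_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """log2(TPM + 1) transform of a genes x samples matrix.

    ``replicate_map`` maps replicate column names to a shared sample name;
    replicates are averaged on the TPM scale before transformation.
    """
    if (tpm.values < 0).any():
        raise ValueError("TPM values must be non-negative")
    if replicate_map:
        grouping = [replicate_map.get(c, c) for c in tpm.columns]
        tpm = tpm.T.groupby(grouping).mean().T
    out = np.log2(tpm + 1.0)
    out.attrs["log2_tpm_plus1"] = True
    return out


def group_medians(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    genes: list[str],
    group_col: str = "cancer_class",
) -> pd.DataFrame:
    """Per-group medians of each gene's expression (rows genes, cols groups)."""
    meta = metadata.set_index("model_id") if "model_id" in metadata.columns else metadata
    missing = [s for s in matrix.columns if s not in meta.index]
    if missing:
        raise KeyError(f"samples without metadata: {missing[:5]}")
    groups = meta.loc[matrix.columns, group_col]
    sub = matrix.loc[[g for g in genes if g in matrix.index]]
    return sub.T.groupby(groups.values).median().T


def pooled_median(matrix: pd.DataFrame, genes: list[str]) -> float:
    """Median over all values of the listed genes across all samples."""
    sub = matrix.loc[[g for g in genes if g in matrix.index]]
    if sub.empty:
        raise ValueError("none of the requested genes are in the matrix")
    return float(np.median(sub.values))


def _fold_change(m1: float, m2: float) -> float:
    # score scales (e.g. enrichment scores) may be negative; a ratio of means
    # is then meaningless, so report NaN and let the caller use the difference
    if m1 <= 0 or m2 <= 0:
        return float("nan")
    return m2 / m1


def compare_groups(
    matrix: pd.DataFrame,
    group1: list[str],
    group2: list[str],
    test: str = "auto",
    alpha_normality: float = 0.05,
) -> pd.DataFrame:
    """Per-feature two-group comparison with BH adjustment across features.

    ``matrix`` is features x samples; ``group1``/``group2`` are sample-column
    lists. Fold change is mean(group2)/mean(group1) on the score scale (NaN
    when either mean is non-positive; the difference of means is always
    reported). Returns one row per feature.
    """
    if len(group1) < 2 or len(group2) < 2:
        raise ValueError("each group needs at least 2 samples")
    rows = []
    for feature in matrix.index:
        x = matrix.loc[feature, group1].to_numpy(dtype=float)
        y = matrix.loc[feature, group2].to_numpy(dtype=float)
        chosen = test
        if test == "auto":
            normal = all(
                len(np.unique(v)) > 2 and stats.shapiro(v).pvalue >= alpha_normality
                for v in (x, y)
            )
            chosen = "t" if normal else "wilcoxon"
        if chosen == "t" and (np.ptp(x) == 0 and np.ptp(y) == 0):
            chosen = "wilcoxon"  # degenerate variance
        if chosen == "t":
            stat, p = stats.ttest_ind(x, y)
        elif chosen == "wilcoxon":
            stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append(
            {
                "feature": feature,
                "mean_group1": x.mean(),
                "mean_group2": y.mean(),
                "fold_change": _fold_change(x.mean(), y.mean()),
                "mean_difference": y.mean() - x.mean(),
                "statistic": float(stat),
                "p_value": float(p),
                "test": chosen,
            }
        )
    out = pd.DataFrame(rows).set_index("feature")
    out["p_adjusted"] = benjamini_hochberg(out["p_value"].to_numpy())
    return out


def correlate_scores(
    matrix: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlations between feature rows with BH-adjusted p-values.

    ``pairs`` defaults to all unordered feature pairs. Zero-variance features
    yield an undefined r (NaN) and are flagged.
    """
    if pairs is None:
        pairs = list(combinations(matrix.index, 2))
    rows = []
    for f1, f2 in pairs:
        x = matrix.loc[f1].to_numpy(dtype=float)
        y = matrix.loc[f2].to_numpy(dtype=float)
        if len(x) < 3:
            raise ValueError("Pearson correlation needs >=3 paired observations")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            r, p, flag = float("nan"), float("nan"), True
        else:
            r, p = stats.pearsonr(x, y)
            flag = False
        rows.append(
            {"feature1": f1, "feature2": f2, "r": float(r), "p_value": float(p),
             "zero_variance": flag}
        )
    out = pd.DataFrame(rows)
    valid = out["p_value"].notna()
    adj = np.full(len(out), np.nan)
    if valid.any():
        adj[valid.to_numpy()] = benjamini_hochberg(out.loc[valid, "p_value"].to_numpy())
    out["p_adjusted"] = adj
    out["significant"] = out["p_adjusted"] < fdr
    return out


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
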