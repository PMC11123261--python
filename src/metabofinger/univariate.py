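"""Per-feature two-group testing with a normality gate and fold-change rule.

Each feature is tested control vs exposed on the drift-corrected raw
intensities: a Shapiro-Wilk test per group decides between a two-sided
Welch t-test (both groups plausibly normal) and a two-sided Mann-Whitney U
test (either group non-normal or degenerate). P-values are corrected for
multiple testing (Benjamini-Hochberg by default) and a feature is selected
when its corrected p-value falls below alpha AND its exposed/control
fold change exceeds 5 or falls below 0.2 — a deliberately strict FC band
that keeps only the most distinctive features.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import FeatureTable, RunConfig


class SampleSizeError(ValueError):
    """Too few values for the requested test."""


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p. Constant input returns (NaN, NaN): degenerate,
    treated downstream as non-normal. Fewer than 3 values is an error."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 3:
        raise SampleSizeError("Shapiro-Wilk needs at least 3 values")
    if np.ptp(arr) == 0:
        return float("nan"), float("nan")
    res = stats.shapiro(arr)
    return float(res.statistic), float(res.pvalue)


def _normalish(values, alpha: float) -> bool:
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 3 or np.ptp(arr) == 0:
        return False
    return stats.shapiro(arr).pvalue >= alpha


def two_group_test(
    control, exposed, shapiro_alpha: float = 0.05, pooled_t: bool = False
) -> tuple[str, float]:
    """Normality-gated two-sided two-group test.

    Returns ``(test_used, raw_p)`` with test_used in {"t_test",
    "mann_whitney"}. The Mann-Whitney branch is exact when both groups have
    n <= 12 and no ties, otherwise the tie-corrected normal approximation.
    """
    c = np.asarray(control, dtype=float)
    c = c[np.isfinite(c)]
    e = np.asarray(exposed, dtype=float)
    e = e[np.isfinite(e)]
    if c.size < 2 or e.size < 2:
        raise SampleSizeError("each group needs at least 2 present values")
    if _normalish(c, shapiro_alpha) and _normalish(e, shapiro_alpha):
        res = stats.ttest_ind(e, c, equal_var=pooled_t)
        return "t_test", float(res.pvalue)
    pooled = np.concatenate([c, e])
    exact = c.size <= 12 and e.size <= 12 and len(np.unique(pooled)) == pooled.size
    res = stats.mannwhitneyu(
        e, c, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return "mann_whitney", float(res.pvalue)


def adjust_p(raw_p, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment: BH step-up (default) or Bonferroni."""
    arr = np.asarray(raw_p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "none":
        return arr.copy()
    sm_method = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[method]
    return multipletests(arr, method=sm_method)[1]


def fold_change(control, exposed) -> float:
    """Exposed-mean over control-mean on the raw intensity scale.

    Missing values are dropped; a zero control mean yields +inf (which
    passes the upper fold-change rule).
    """
    c = np.asarray(control, dtype=float)
    c = c[np.isfinite(c)]
    e = np.asarray(exposed, dtype=float)
    e = e[np.isfinite(e)]
    if c.size == 0 or e.size == 0:
        return float("nan")
    cm, em = c.mean(), e.mean()
    if cm == 0:
        return float("inf")
    return float(em / cm)


def univariate_select(
    snapshot: FeatureTable, config: RunConfig | None = None
) -> pd.DataFrame:
    """Run the full univariate arm on the drift-corrected raw snapshot.

    Returns a per-feature frame: shapiro_p_control, shapiro_p_exposed,
    test_used, raw_p, adjusted_p, fold_change, selected. Features with too
    few present values in either group are retained with NaN statistics,
    never selected, and an ``excluded_reason``.
    """
    cfg = config or RunConfig()
    ctrl_cols = snapshot.columns_of("biological", "control")
    expo_cols = snapshot.columns_of("biological", "exposed")
    rows = []
    for fid in snapshot.feature_ids:
        c = snapshot.intensities.loc[fid, ctrl_cols].to_numpy(float)
        e = snapshot.intensities.loc[fid, expo_cols].to_numpy(float)
        c = c[np.isfinite(c)]
        e = e[np.isfinite(e)]
        row: dict = {"feature_id": fid, "excluded_reason": ""}
        row["fold_change"] = fold_change(c, e)
        for name, vals in (("control", c), ("exposed", e)):
            if vals.size >= 3 and np.ptp(vals) > 0:
                row[f"shapiro_p_{name}"] = stats.shapiro(vals).pvalue
            else:
                row[f"shapiro_p_{name}"] = np.nan
        if c.size < 2 or e.size < 2:
            row.update(test_used="", raw_p=np.nan)
            row["excluded_reason"] = "insufficient values"
        else:
            test, p = two_group_test(c, e, cfg.shapiro_alpha, cfg.pooled_t)
            row.update(test_used=test, raw_p=p)
        rows.append(row)
    df = pd.DataFrame(rows).set_index("feature_id")
    testable = df["raw_p"].notna()
    adjusted = np.full(len(df), np.nan)
    if testable.any():
        adjusted[testable.to_numpy()] = adjust_p(
            df.loc[testable, "raw_p"].to_numpy(), cfg.p_adjust_method
        )
    df["adjusted_p"] = adjusted
    p_for_rule = df["adjusted_p"] if cfg.use_adjusted_p else df["raw_p"]
    fc = df["fold_change"]
    df["selected"] = (
        (p_for_rule < cfg.alpha) & ((fc > cfg.fc_upper) | (fc < cfg.fc_lower))
    ).fillna(False)
    return df
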