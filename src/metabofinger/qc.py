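"""Internal-standard checks, RSD summaries and sample-outlier diagnostics.

Analytical precision is summarized by the relative standard deviation (RSD,
100*sd/mean) of each feature within a sample group and by the group median
RSD (mRSD) over features; pooled-QC mRSD is the primary platform-precision
figure. Spiked internal standards (IS) gate individual samples: a sample
passes an IS only if the peak height exceeds 5000 counts without detector
saturation, the mass error is below 10 ppm, and the retention-time
deviation stays below 0.5 min on HILIC platforms or 0.2 min on RPLC
platforms. Sample-level outliers combine three signals: depressed
detected-feature counts relative to the sample's group, multivariate
distance in PCA score space, and IS failures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import FeatureTable, RunConfig, ValidationError


class ISFeatureMissingError(ValidationError):
    """An internal standard has no matching feature row in the table."""


def rsd(values) -> float:
    """Relative standard deviation in percent: 100 * sd(n-1) / mean.

    Missing values are ignored. Fewer than two present values, or a
    non-positive mean, yields NaN (undefined).
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        return float("nan")
    mean = arr.mean()
    if mean <= 0:
        return float("nan")
    return float(100.0 * arr.std(ddof=1) / mean)


@dataclass
class QCSummary:
    """Per-feature RSD by group and the group medians (mRSD, %)."""

    per_feature: pd.DataFrame  # index feature_id, one column per group
    mrsd: pd.Series  # index group, median of finite per-feature RSDs


def group_rsd_summary(table: FeatureTable) -> QCSummary:
    """RSD per feature for control, exposed and pooled-QC groups; blanks excluded."""
    groups = {
        "control": table.columns_of("biological", "control"),
        "exposed": table.columns_of("biological", "exposed"),
        "qc": table.columns_of("qc"),
    }
    per_feature = {}
    for name, cols in groups.items():
        if not cols:
            continue
        sub = table.intensities[cols].to_numpy(dtype=float)
        present = np.isfinite(sub)
        n_present = present.sum(axis=1)
        filled = np.where(present, sub, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = filled.sum(axis=1) / np.maximum(n_present, 1)
            ss = ((filled - mean[:, None]) ** 2 * present).sum(axis=1)
            sd = np.sqrt(ss / np.maximum(n_present - 1, 1))
            out = 100.0 * sd / mean
        out[(n_present < 2) | (mean <= 0)] = np.nan
        per_feature[name] = out
    df = pd.DataFrame(per_feature, index=table.features.index)
    mrsd = df.median(skipna=True)
    return QCSummary(df, mrsd)


@dataclass
class ISDefinition:
    """Expected coordinates of one spiked internal standard."""

    name: str
    expected_mz: float
    expected_rt: float
    platform_mode: str
    feature_id: str | None = None  # defaults to name

    def __post_init__(self) -> None:
        if self.expected_mz <= 0 or self.expected_rt <= 0:
            raise ValueError("IS expected m/z and RT must be positive")
        if self.feature_id is None:
            self.feature_id = self.name


@dataclass
class ISCheckResult:
    """Pass/fail of one (internal standard, sample) pair."""

    is_name: str
    sample_id: str
    height: float
    mass_error_ppm: float
    rt_deviation: float
    saturated: bool
    passed: bool
    failed_criteria: list[str] = field(default_factory=list)


def check_internal_standards(
    table: FeatureTable,
    definitions: list[ISDefinition],
    observed_mz: pd.DataFrame,
    observed_rt: pd.DataFrame,
    config: RunConfig | None = None,
) -> list[ISCheckResult]:
    """Evaluate every (IS, sample) pair against the deviation criteria.

    ``observed_mz`` / ``observed_rt`` are (IS name x sample_id) frames of the
    per-sample observed coordinates. Heights come from the table's intensity
    rows. A pair passes only if every criterion passes; failed criteria are
    labelled ``height``, ``saturation``, ``mass_error``, ``rt_deviation``.
    """
    cfg = config or RunConfig()
    results: list[ISCheckResult] = []
    for d in definitions:
        if d.feature_id not in table.intensities.index:
            raise ISFeatureMissingError(
                f"internal standard {d.name!r} has no feature row {d.feature_id!r}"
            )
        rt_tol = cfg.rt_tolerance(d.platform_mode)
        for sid in table.sample_ids:
            height = float(table.intensities.at[d.feature_id, sid])
            obs_mz = float(observed_mz.at[d.name, sid])
            obs_rt = float(observed_rt.at[d.name, sid])
            mass_error = abs(obs_mz - d.expected_mz) / d.expected_mz * 1e6
            rt_dev = abs(obs_rt - d.expected_rt)
            saturated = np.isfinite(height) and height >= cfg.saturation_ceiling
            failed = []
            if not np.isfinite(height) or height <= cfg.is_min_height:
                failed.append("height")
            if saturated:
                failed.append("saturation")
            if not mass_error < cfg.is_mass_ppm:
                failed.append("mass_error")
            if not rt_dev < rt_tol:
                failed.append("rt_deviation")
            results.append(
                ISCheckResult(
                    d.name, sid, height, mass_error, rt_dev, saturated,
                    passed=not failed, failed_criteria=failed,
                )
            )
    return results


def is_results_frame(results: list[ISCheckResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "is_name": r.is_name,
                "sample_id": r.sample_id,
                "height": r.height,
                "mass_error_ppm": r.mass_error_ppm,
                "rt_deviation": r.rt_deviation,
                "saturated": r.saturated,
                "passed": r.passed,
                "failed_criteria": ";".join(r.failed_criteria),
            }
            for r in results
        ]
    )


def flag_outlier_samples(
    table: FeatureTable,
    is_results: list[ISCheckResult] | None = None,
    scores: pd.DataFrame | None = None,
    explained_variance: np.ndarray | None = None,
    config: RunConfig | None = None,
) -> list[tuple[str, list[str]]]:
    """Flag samples failing any of three outlier criteria.

    (a) detected-feature count below group median - k*MAD (plain median
    absolute deviation, k configurable, default 3); groups are the two
    biological groups and the QC pool, blanks are never flagged;
    (b) squared Mahalanobis distance over the supplied PCA scores above the
    chi-square quantile (default 97.5%) with the component count as degrees
    of freedom; the per-component scale is a normal-consistent MAD so a
    gross outlier cannot mask itself by inflating the component variance
    (pass ``explained_variance`` to use the classical variances instead);
    (c) any internal-standard criterion fails for the sample.
    """
    cfg = config or RunConfig()
    reasons: dict[str, list[str]] = {}

    def add(sid: str, reason: str) -> None:
        reasons.setdefault(sid, []).append(reason)

    # (a) detected-feature counts per group
    detected = table.intensities.notna().sum(axis=0)
    group_of = {}
    for sid in table.sample_ids:
        stype = table.samples.at[sid, "sample_type"]
        if stype == "biological":
            group_of[sid] = str(table.samples.at[sid, "group"])
        elif stype == "qc":
            group_of[sid] = "qc"
    frame = pd.DataFrame(
        {"count": [detected[s] for s in group_of], "group": list(group_of.values())},
        index=list(group_of.keys()),
    )
    for _, sub in frame.groupby("group"):
        med = sub["count"].median()
        mad = stats.median_abs_deviation(sub["count"], scale=1.0)
        cut = med - cfg.outlier_mad_factor * mad
        for sid, cnt in sub["count"].items():
            if cnt < cut:
                add(sid, f"feature_count {cnt} < {cut:.1f}")

    # (b) Mahalanobis distance on PCA scores (components are uncorrelated,
    # so the distance is a variance-standardized squared score sum)
    if scores is not None and len(scores):
        mat = scores.to_numpy(dtype=float)
        if explained_variance is not None:
            var = np.asarray(explained_variance, dtype=float)
            centered = mat
        else:
            mad = stats.median_abs_deviation(mat, axis=0, scale="normal")
            var = mad.astype(float) ** 2
            centered = mat - np.median(mat, axis=0)
        keep = var > 1e-12
        if keep.any():
            z2 = (centered[:, keep] ** 2 / var[keep]).sum(axis=1)
            cut = stats.chi2.ppf(cfg.outlier_chi2_quantile, df=int(keep.sum()))
            for sid, d2 in zip(scores.index, z2):
                if d2 > cut:
                    add(str(sid), f"pca_distance {d2:.1f} > {cut:.1f}")

    # (c) IS failures
    if is_results:
        for r in is_results:
            if not r.passed:
                add(r.sample_id, f"is_failure {r.is_name}: {','.join(r.failed_criteria)}")

    return [(sid, rs) for sid, rs in reasons.items()]
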