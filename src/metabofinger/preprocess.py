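"""Feature-table pretreatment chain.

Fixed stage order: duplicate/isotope merging -> QC-anchored drift
correction -> blank filter (10x rule) -> group-presence filter (75%) ->
exposed-group RSD filter (<30%) -> random-forest imputation -> natural-log
transform -> probabilistic quotient normalization against the QC median
spectrum -> Pareto scaling. Filter order is part of the contract; the
filters are not order-invariant.

Fold changes downstream are computed on the drift-corrected, unimputed,
un-normalized snapshot that :func:`run_pretreatment` retains, so imputed
or normalized values never enter raw-ratio statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline
from sklearn.ensemble import RandomForestRegressor

from .core import (
    FeatureTable,
    RunConfig,
    RunReport,
    StageRecord,
    ValidationError,
    substream,
    substream_int,
)
from .qc import rsd


class NoBlankSamplesError(ValidationError):
    """Blank filtering requires at least one blank sample."""


class NonPositiveValueError(ValidationError):
    """Log transform requires strictly positive intensities."""


class AllMissingFeatureError(ValidationError):
    """A feature with zero present values cannot be imputed."""


class DegenerateReferenceError(ValidationError):
    """PQN reference spectrum has no usable (finite, positive) entries."""


@dataclass
class FilterLog:
    """Removed feature ids per stage, with the violated rule and quantity."""

    entries: list[dict] = field(default_factory=list)

    def add(self, stage: str, feature_id: str, rule: str, value: float | str) -> None:
        self.entries.append(
            {"stage": stage, "feature_id": feature_id, "rule": rule, "value": value}
        )

    def removed(self, stage: str | None = None) -> list[str]:
        return [
            e["feature_id"]
            for e in self.entries
            if stage is None or e["stage"] == stage
        ]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["stage", "feature_id", "rule", "value"])


@dataclass
class DriftModel:
    """Per-feature drift-correction outcome.

    ``applied`` is True only when the cubic-spline correction reduced the
    pooled-QC RSD of the feature; otherwise the feature is left untouched.
    """

    per_feature: pd.DataFrame  # columns: applied, qc_rsd_before, qc_rsd_after, reason

    def frame(self) -> pd.DataFrame:
        out = self.per_feature.copy()
        out.index.name = "feature_id"
        return out


# ---------------------------------------------------------------------------
# Duplicate / isotope merging
# ---------------------------------------------------------------------------

def merge_duplicates_and_isotopes(
    table: FeatureTable,
    mz_ppm: float = 5.0,
    rt_tol: float = 0.1,
    isotope_spacing: float = 1.00335,
    min_corr: float = 0.8,
) -> tuple[FeatureTable, FilterLog]:
    """Collapse split duplicate features and drop +1 isotopologue rows.

    Features agreeing in m/z within ``mz_ppm`` and RT within ``rt_tol`` are
    merged, keeping the row with the highest median intensity. A feature
    sitting one isotope spacing (singly charged) above a partner at the
    same RT, correlating with it at r >= ``min_corr`` and weaker in median
    intensity, is removed as the partner's isotope.
    """
    log = FilterLog()
    ids = np.array(table.feature_ids)
    mz = table.mz.to_numpy(float)
    rt = table.rt.to_numpy(float)
    inten = table.intensities.to_numpy(float)
    finite = np.isfinite(inten)
    median = np.full(len(inten), -np.inf)
    any_finite = finite.any(axis=1)
    if any_finite.any():
        median[any_finite] = np.nanmedian(
            np.where(finite, inten, np.nan)[any_finite], axis=1
        )

    order = np.argsort(mz)
    parent = np.arange(len(ids))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    # duplicate clustering: union features within both tolerances
    for a_pos in range(len(order)):
        i = order[a_pos]
        for b_pos in range(a_pos + 1, len(order)):
            j = order[b_pos]
            if (mz[j] - mz[i]) / mz[i] * 1e6 > mz_ppm:
                break
            if abs(rt[j] - rt[i]) <= rt_tol:
                parent[find(j)] = find(i)

    keep = np.ones(len(ids), bool)
    for root in np.unique([find(i) for i in range(len(ids))]):
        members = [i for i in range(len(ids)) if find(i) == root]
        if len(members) == 1:
            continue
        best = members[int(np.argmax(median[members]))]
        for m in members:
            if m != best:
                keep[m] = False
                log.add("dedupe", ids[m], "duplicate_of", ids[best])

    # isotope removal among survivors
    surv = np.flatnonzero(keep)
    surv = surv[np.argsort(mz[surv])]
    for pos, i in enumerate(surv):
        target = mz[i] + isotope_spacing
        for j in surv[pos + 1:]:
            if not keep[j]:
                continue
            if mz[j] > target * (1 + mz_ppm * 1e-6) + 1e-9:
                break
            if abs(mz[j] - target) / target * 1e6 > mz_ppm:
                continue
            if abs(rt[j] - rt[i]) > rt_tol:
                continue
            xi, xj = inten[i], inten[j]
            both = np.isfinite(xi) & np.isfinite(xj)
            if both.sum() < 3:
                continue
            a, b = xi[both], xj[both]
            if a.std() == 0 or b.std() == 0:
                continue
            r = float(np.corrcoef(a, b)[0, 1])
            if r >= min_corr and median[j] < median[i]:
                keep[j] = False
                log.add("deisotope", ids[j], "isotope_of", ids[i])

    kept_ids = [fid for fid, k in zip(ids, keep) if k]
    return table.select_features(kept_ids), log


# ---------------------------------------------------------------------------
# Drift correction
# ---------------------------------------------------------------------------

def _loo_corrected(x: np.ndarray, y: np.ndarray, s: float) -> np.ndarray | None:
    """Leave-one-out drift-corrected log QC values at penalty s.

    Each QC point is corrected by the spline fitted to the other QCs, so
    the gain attributed to the correction is out-of-sample and a spline
    that merely tracks QC noise shows no gain.
    """
    m = len(x)
    out = np.empty(m)
    for i in range(m):
        xt = np.delete(x, i)
        yt = np.delete(y, i)
        k = min(3, len(xt) - 1)
        try:
            sp = UnivariateSpline(xt, yt, k=k, s=s * (m - 1) / m)
            offset = float(sp(x[i])) - float(np.mean(sp(x)))
        except Exception:
            return None
        if not np.isfinite(offset):
            return None
        out[i] = y[i] - offset
    return out


def drift_correct(
    table: FeatureTable, config: RunConfig | None = None
) -> tuple[FeatureTable, DriftModel]:
    """QC-anchored cubic-smoothing-spline drift correction.

    Per feature, a cubic smoothing spline is fit to log QC intensity versus
    injection order, with the smoothing penalty chosen by leave-one-out
    cross-validation over the QC injections. All samples are corrected on
    the log scale by subtracting the spline's deviation from its mean level
    at the QC orders, then back-transformed. The correction is retained for
    a feature only if it lowers the pooled-QC RSD; otherwise the feature is
    left as measured.
    """
    cfg = config or RunConfig()
    qc_cols = table.columns_of("qc")
    orders = table.samples["injection_order"].to_numpy(float)
    qc_orders_all = table.samples.loc[qc_cols, "injection_order"].to_numpy(float)
    qc_idx = [table.sample_ids.index(c) for c in qc_cols]

    inten = table.intensities.to_numpy(float).copy()
    records = []
    for fi, fid in enumerate(table.feature_ids):
        row = inten[fi]
        qc_vals = row[qc_idx]
        ok = np.isfinite(qc_vals) & (qc_vals > 0)
        before = rsd(qc_vals[ok])
        if ok.sum() < 4:
            records.append(
                {"applied": False, "qc_rsd_before": before, "qc_rsd_after": before,
                 "reason": f"only {int(ok.sum())} usable QCs"}
            )
            continue
        x = qc_orders_all[ok]
        y = np.log(qc_vals[ok])
        sort = np.argsort(x)
        x, y = x[sort], y[sort]
        m = len(x)
        var = y.var()
        if var < 1e-18:
            # constant QCs: spline is flat, correction is the identity
            records.append(
                {"applied": False, "qc_rsd_before": before, "qc_rsd_after": before,
                 "reason": "constant QCs"}
            )
            continue
        # With a handful of QC points the spline must not approach
        # interpolation: the penalty grid floors at a quarter of the data
        # variance and tops out at an (unpenalized) single cubic segment, so
        # leave-one-out chooses between a least-squares cubic and mildly
        # wigglier fits, never a noise-tracking interpolant.
        candidates = [f * m * var for f in (0.25, 0.5, 1.0, 2.0, 1e6)]
        loo = {s: _loo_corrected(x, y, s) for s in candidates}
        loo = {s: v for s, v in loo.items() if v is not None}
        if not loo:
            records.append(
                {"applied": False, "qc_rsd_before": before, "qc_rsd_after": before,
                 "reason": "spline failure"}
            )
            continue
        best_s = min(loo, key=lambda s: float(np.var(loo[s])))
        spline = UnivariateSpline(x, y, k=min(3, m - 1), s=best_s)
        offset = spline(orders) - float(np.mean(spline(x)))
        present = np.isfinite(row) & (row > 0)
        corrected = row.copy()
        corrected[present] = np.exp(np.log(row[present]) - offset[present])
        # out-of-sample gain: RSD of the leave-one-out corrected QC values
        after = rsd(np.exp(loo[best_s]))
        if np.isfinite(after) and np.isfinite(before) and after < before:
            inten[fi] = corrected
            records.append(
                {"applied": True, "qc_rsd_before": before, "qc_rsd_after": after,
                 "reason": ""}
            )
        else:
            records.append(
                {"applied": False, "qc_rsd_before": before, "qc_rsd_after": before,
                 "reason": "no QC RSD improvement"}
            )
    out = table.copy()
    out.intensities = pd.DataFrame(
        inten, index=table.intensities.index, columns=table.intensities.columns
    )
    model = DriftModel(
        pd.DataFrame(
            records,
            index=table.features.index,
            columns=["applied", "qc_rsd_before", "qc_rsd_after", "reason"],
        )
    )
    return out, model


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def blank_filter(
    table: FeatureTable, factor: float = 10.0, missing_as_zero: bool = True
) -> tuple[FeatureTable, FilterLog]:
    """Remove background features via the 10x blank rule.

    A feature is removed iff its maximum present intensity over biological
    and QC samples is strictly below ``factor`` times its mean extraction-
    blank intensity (missing blank values count as zero by default).
    """
    blank_cols = table.columns_of("blank")
    if not blank_cols:
        raise NoBlankSamplesError("blank filter needs at least one blank sample")
    log = FilterLog()
    sample_cols = table.columns_of("biological") + table.columns_of("qc")
    blanks = table.intensities[blank_cols].to_numpy(float)
    if missing_as_zero:
        blank_mean = np.mean(np.where(np.isfinite(blanks), blanks, 0.0), axis=1)
    else:
        with np.errstate(invalid="ignore"):
            blank_mean = np.nanmean(blanks, axis=1)
        blank_mean = np.where(np.isfinite(blank_mean), blank_mean, 0.0)
    signal = table.intensities[sample_cols].to_numpy(float)
    with np.errstate(invalid="ignore"):
        max_signal = np.nanmax(np.where(np.isfinite(signal), signal, -np.inf), axis=1)
    max_signal = np.where(np.isfinite(max_signal), max_signal, 0.0)
    remove = max_signal < factor * blank_mean
    keep_ids = []
    for fid, rm, ms, bm in zip(table.feature_ids, remove, max_signal, blank_mean):
        if rm:
            log.add("blank", fid, "max_signal<factor*mean_blank", f"{ms:.4g}<{factor}*{bm:.4g}")
        else:
            keep_ids.append(fid)
    return table.select_features(keep_ids), log


def presence_filter(
    table: FeatureTable, fraction: float = 0.75
) -> tuple[FeatureTable, FilterLog]:
    """Keep features detected in >= ``fraction`` of either biological group.

    Only the control and exposed biological samples count toward the rule;
    QC and blank columns are ignored.
    """
    log = FilterLog()
    frac = {}
    for grp in ("control", "exposed"):
        cols = table.columns_of("biological", grp)
        if not cols:
            frac[grp] = np.zeros(table.n_features)
        else:
            frac[grp] = table.intensities[cols].notna().to_numpy().mean(axis=1)
    keep = (frac["control"] >= fraction) | (frac["exposed"] >= fraction)
    keep_ids = []
    for fid, k, fc, fe in zip(table.feature_ids, keep, frac["control"], frac["exposed"]):
        if k:
            keep_ids.append(fid)
        else:
            log.add("presence", fid, f"presence<{fraction}", f"ctrl={fc:.2f},exp={fe:.2f}")
    return table.select_features(keep_ids), log


def rsd_filter(
    table: FeatureTable, cutoff: float = 30.0
) -> tuple[FeatureTable, FilterLog]:
    """Keep features whose exposed-group RSD is strictly below ``cutoff`` %.

    Features whose exposed RSD is undefined (fewer than two present values)
    are removed with reason ``undefined``.
    """
    log = FilterLog()
    cols = table.columns_of("biological", "exposed")
    keep_ids = []
    for fid in table.feature_ids:
        val = rsd(table.intensities.loc[fid, cols])
        if np.isnan(val):
            log.add("rsd", fid, "undefined", "undefined")
        elif val >= cutoff:
            log.add("rsd", fid, f"rsd>={cutoff}", round(val, 3))
        else:
            keep_ids.append(fid)
    return table.select_features(keep_ids), log


# ---------------------------------------------------------------------------
# Imputation and pretreatment transforms
# ---------------------------------------------------------------------------

def impute_missing_rf(
    table: FeatureTable,
    max_iter: int = 10,
    n_trees: int = 100,
    tol: float = 1e-4,
    seed: int = 0,
) -> FeatureTable:
    """missForest-style iterative random-forest imputation on log intensities.

    Missing entries are initialized at the feature median; features are
    visited in order of increasing missingness, each regressed on all other
    features over the samples where it was observed, with its missing
    entries replaced by the forest prediction. Iteration stops when the
    relative change of the imputed values stops decreasing (the previous
    iterate is returned) or after ``max_iter`` sweeps. Deterministic under
    a fixed seed.
    """
    X = table.intensities.to_numpy(float).T  # samples x features
    mask = ~np.isfinite(X)  # missing
    if not mask.any():
        return table.copy()
    if mask.all(axis=0).any():
        bad = [table.feature_ids[j] for j in np.flatnonzero(mask.all(axis=0))]
        raise AllMissingFeatureError(f"features with no present values: {bad[:5]}")
    if np.nanmin(X) <= 0:
        # log scale needs positive values; measured zeros are nudged to the
        # smallest positive measurement
        floor = np.nanmin(X[X > 0]) if np.isfinite(np.nanmax(X)) else 1.0
        X = np.where(np.isfinite(X) & (X <= 0), floor, X)
    L = np.log(X)
    med = np.nanmedian(L, axis=0)
    L_imp = np.where(mask, med[None, :], L)

    order = np.argsort(mask.sum(axis=0))
    order = order[mask.sum(axis=0)[order] > 0]
    rng_seed = substream_int(seed, "impute")
    prev_diff = np.inf
    prev_L = L_imp.copy()
    for it in range(max_iter):
        old_vals = L_imp[mask].copy()
        for k, j in enumerate(order):
            obs = ~mask[:, j]
            others = np.delete(np.arange(L.shape[1]), j)
            forest = RandomForestRegressor(
                n_estimators=n_trees,
                max_features="sqrt",
                random_state=(rng_seed + it * 10007 + k) % (2**31 - 1),
                n_jobs=1,
            )
            forest.fit(L_imp[obs][:, others], L_imp[obs, j])
            miss = mask[:, j]
            L_imp[miss, j] = forest.predict(L_imp[miss][:, others])
        new_vals = L_imp[mask]
        denom = float(np.sum(new_vals**2)) or 1.0
        diff = float(np.sum((new_vals - old_vals) ** 2)) / denom
        if diff > prev_diff:
            L_imp = prev_L  # change grew: keep the previous sweep
            break
        if diff < tol:
            break
        prev_diff = diff
        prev_L = L_imp.copy()

    out = table.copy()
    out.intensities = pd.DataFrame(
        np.exp(L_imp).T, index=table.intensities.index, columns=table.intensities.columns
    )
    return out


def log_transform(table: FeatureTable) -> FeatureTable:
    """Elementwise natural log; any non-positive value is an error."""
    vals = table.intensities.to_numpy(float)
    present = np.isfinite(vals)
    if np.any(vals[present] <= 0):
        raise NonPositiveValueError("log transform requires strictly positive values")
    out = table.copy()
    out.intensities = pd.DataFrame(
        np.where(present, np.log(np.where(present, vals, 1.0)), np.nan),
        index=table.intensities.index,
        columns=table.intensities.columns,
    )
    return out


def pqn_normalize(
    table: FeatureTable, assume_log: bool = False
) -> tuple[FeatureTable, pd.Series]:
    """Probabilistic quotient normalization against the QC median spectrum.

    The reference spectrum is the per-feature median over pooled-QC samples
    on the raw intensity scale; each sample's dilution factor is the median
    over features of its intensity quotient against the reference, and the
    sample is divided by that factor. Log-scale input (``assume_log=True``)
    is back-transformed for the factor computation — so both paths agree
    exactly — and normalized by subtracting the log factor. Returns the
    normalized table and the raw-scale per-sample factors.
    """
    qc_cols = table.columns_of("qc")
    if not qc_cols:
        raise DegenerateReferenceError("PQN requires at least one QC sample")
    vals = table.intensities.to_numpy(float)
    raw = np.exp(vals) if assume_log else vals
    qc = raw[:, [table.sample_ids.index(c) for c in qc_cols]]
    with np.errstate(invalid="ignore"):
        ref = np.nanmedian(qc, axis=1)
    usable = np.isfinite(ref) & (ref > 0)
    if not usable.any():
        raise DegenerateReferenceError("PQN reference spectrum has no usable entries")
    factors = np.empty(table.n_samples)
    out_vals = vals.copy()
    for si in range(table.n_samples):
        with np.errstate(invalid="ignore", divide="ignore"):
            quot = raw[usable, si] / ref[usable]
        quot = quot[np.isfinite(quot) & (quot > 0)]
        f = float(np.median(quot)) if quot.size else 1.0
        factors[si] = f
        if assume_log:
            out_vals[:, si] = vals[:, si] - np.log(f)
        else:
            out_vals[:, si] = vals[:, si] / f
    out = table.copy()
    out.intensities = pd.DataFrame(
        out_vals, index=table.intensities.index, columns=table.intensities.columns
    )
    return out, pd.Series(factors, index=table.samples.index, name="pqn_factor")


def pareto_scale(table: FeatureTable) -> FeatureTable:
    """Center each feature and divide by the square root of its sd.

    Constant features are centered and left at zero. Pareto scaling leaves
    each feature with variance equal to its original standard deviation,
    compressing dynamic range less aggressively than unit-variance scaling.
    """
    vals = table.intensities.to_numpy(float)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(vals, axis=1, keepdims=True)
        sd = np.nanstd(vals, axis=1, ddof=1, keepdims=True)
    centered = vals - mean
    scale = np.sqrt(sd)
    scaled = np.where(scale > 0, centered / np.where(scale > 0, scale, 1.0), 0.0)
    scaled = np.where(np.isfinite(vals), scaled, np.nan)
    out = table.copy()
    out.intensities = pd.DataFrame(
        scaled, index=table.intensities.index, columns=table.intensities.columns
    )
    return out


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------

@dataclass
class PretreatmentResult:
    """Everything run_pretreatment produces.

    ``table`` is fully pretreated (imputed, log, PQN, Pareto) and feeds the
    multivariate models; ``univariate_snapshot`` is the drift-corrected,
    filtered but unimputed/un-normalized table on the raw intensity scale,
    from which fold changes and the normality-gated tests are computed.
    """

    table: FeatureTable
    drift_model: DriftModel
    filter_log: FilterLog
    report: RunReport
    univariate_snapshot: FeatureTable
    pqn_factors: pd.Series | None = None


def run_pretreatment(table: FeatureTable, config: RunConfig | None = None) -> PretreatmentResult:
    """Apply the full pretreatment chain in its fixed order."""
    cfg = config or RunConfig()
    report = RunReport(seed=cfg.seed)
    log = FilterLog()

    def record(stage: str, before: FeatureTable, after: FeatureTable, stage_log: FilterLog | None = None, **params):
        removed_samples = sorted(set(before.sample_ids) - set(after.sample_ids))
        report.record(
            StageRecord(
                stage=stage,
                n_features_in=before.n_features,
                n_features_out=after.n_features,
                n_samples_in=before.n_samples,
                n_samples_out=after.n_samples,
                removed_features=stage_log.removed() if stage_log else [],
                removed_samples=removed_samples,
                params=params,
            )
        )
        if stage_log:
            log.entries.extend(stage_log.entries)

    current = table
    merged, mlog = merge_duplicates_and_isotopes(
        current, cfg.merge_mz_ppm, cfg.merge_rt_tol, cfg.isotope_spacing, cfg.isotope_min_corr
    )
    record("dedupe_deisotope", current, merged, mlog,
           mz_ppm=cfg.merge_mz_ppm, rt_tol=cfg.merge_rt_tol)
    current = merged

    corrected, drift_model = drift_correct(current, cfg)
    record("drift_correction", current, corrected,
           applied=int(drift_model.per_feature["applied"].sum()))
    current = corrected

    if current.n_features:
        filtered, blog = blank_filter(current, cfg.blank_factor, cfg.blank_missing_as_zero)
        record("blank_filter", current, filtered, blog, factor=cfg.blank_factor)
        current = filtered

        filtered, plog = presence_filter(current, cfg.presence_fraction)
        record("presence_filter", current, filtered, plog, fraction=cfg.presence_fraction)
        current = filtered

        filtered, rlog = rsd_filter(current, cfg.rsd_cutoff)
        record("rsd_filter", current, filtered, rlog, cutoff=cfg.rsd_cutoff)
        current = filtered

    # blanks have served their purpose; drop them before modelling stages
    non_blank = [s for s in current.sample_ids
                 if current.samples.at[s, "sample_type"] != "blank"]
    dropped = current.select_samples(non_blank)
    record("drop_blanks", current, dropped)
    current = dropped

    snapshot = current.copy()

    if current.n_features:
        imputed = impute_missing_rf(
            current, cfg.impute_max_iter, cfg.impute_trees, cfg.impute_tol, cfg.seed
        )
        record("rf_imputation", current, imputed, trees=cfg.impute_trees)
        current = imputed

        logged = log_transform(current)
        record("log_transform", current, logged)
        current = logged

        normalized, factors = pqn_normalize(current, assume_log=True)
        record("pqn_normalization", current, normalized)
        current = normalized

        scaled = pareto_scale(current)
        record("pareto_scaling", current, scaled)
        current = scaled
        pqn_factors = factors
    else:
        pqn_factors = None

    return PretreatmentResult(
        table=current,
        drift_model=drift_model,
        filter_log=log,
        report=report,
        univariate_snapshot=snapshot,
        pqn_factors=pqn_factors,
    )
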