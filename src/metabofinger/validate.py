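"""Cross-batch confirmation of selected features and review exports.

Features selected by the univariate and/or multivariate arms in batch 1 are
kept only when the matched feature in an independent replicate batch is
also selected and changes in the same direction. Matching across batches is
greedy one-to-one on m/z (10 ppm default) and RT (the platform's IS
tolerance), nearest m/z first, ties broken on RT.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FeatureTable, RunConfig
from .simulate import SyntheticTruth


class PlatformMismatchError(ValueError):
    """Both tables must come from the same platform mode."""


def selection_records(
    univariate: pd.DataFrame, multivariate_selected: list, feature_ids: list
) -> pd.DataFrame:
    """Combine the two arms into per-feature selection records.

    ``combined_selected`` is the union of the arms; ``direction`` follows
    the fold change (up when exposed/control > 1).
    """
    df = pd.DataFrame(index=pd.Index(feature_ids, name="feature_id"))
    uni = univariate.reindex(df.index)
    df["univariate_selected"] = uni["selected"].fillna(False).astype(bool)
    df["multivariate_selected"] = df.index.isin(set(multivariate_selected))
    df["combined_selected"] = df["univariate_selected"] | df["multivariate_selected"]
    df["fold_change"] = uni["fold_change"]
    fc = df["fold_change"]
    df["direction"] = np.where(fc > 1, "up", np.where(fc < 1, "down", "flat"))
    df.loc[fc.isna(), "direction"] = "unknown"
    return df


def match_features(
    batch1: FeatureTable,
    batch2: FeatureTable,
    mz_ppm: float = 10.0,
    rt_tol: float | None = None,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Greedy one-to-one m/z-RT matching of batch-1 features onto batch 2.

    For each batch-1 feature (ascending m/z), the unused batch-2 feature
    within both tolerances with the smallest m/z difference wins; RT breaks
    ties. Returns a frame with ``feature_id_1``, ``feature_id_2`` (NaN when
    unmatched), ``d_mz_ppm``, ``d_rt``.
    """
    cfg = config or RunConfig()
    modes1 = set(batch1.samples["platform_mode"])
    modes2 = set(batch2.samples["platform_mode"])
    if modes1 != modes2:
        raise PlatformMismatchError(f"platform modes differ: {modes1} vs {modes2}")
    if rt_tol is None:
        rt_tol = cfg.rt_tolerance(next(iter(modes1)))
    mz2 = batch2.mz.to_numpy(float)
    rt2 = batch2.rt.to_numpy(float)
    ids2 = np.array(batch2.feature_ids)
    used = np.zeros(len(ids2), bool)
    rows = []
    order1 = batch1.mz.sort_values().index
    for fid in order1:
        mz1 = float(batch1.mz[fid])
        rt1 = float(batch1.rt[fid])
        d_ppm = np.abs(mz2 - mz1) / mz1 * 1e6
        d_rt = np.abs(rt2 - rt1)
        cand = np.flatnonzero((d_ppm <= mz_ppm) & (d_rt <= rt_tol) & ~used)
        if cand.size == 0:
            rows.append({"feature_id_1": fid, "feature_id_2": None,
                         "d_mz_ppm": np.nan, "d_rt": np.nan})
            continue
        best = cand[np.lexsort((d_rt[cand], d_ppm[cand]))[0]]
        used[best] = True
        rows.append({"feature_id_1": fid, "feature_id_2": ids2[best],
                     "d_mz_ppm": float(d_ppm[best]), "d_rt": float(d_rt[best])})
    matches = pd.DataFrame(rows)
    matched2 = matches["feature_id_2"].dropna()
    assert matched2.is_unique, "matching must be one-to-one"
    return matches


def validate_selection(
    records1: pd.DataFrame,
    records2: pd.DataFrame,
    matches: pd.DataFrame,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Keep features confirmed in both batches.

    validated iff combined-selected in both batches for the matched pair
    and (by default) the fold-change directions agree. Unvalidated matched
    pairs are retained with a reason.
    """
    cfg = config or RunConfig()
    rows = []
    for _, m in matches.iterrows():
        f1, f2 = m["feature_id_1"], m["feature_id_2"]
        r1 = records1.loc[f1]
        row = {
            "feature_id_1": f1,
            "feature_id_2": f2,
            "fold_change_1": r1["fold_change"],
            "fold_change_2": np.nan,
            "direction_1": r1["direction"],
            "direction_2": "",
            "consistent_direction": False,
            "validated": False,
            "reason": "",
        }
        if f2 is None or (isinstance(f2, float) and np.isnan(f2)):
            row["reason"] = "unmatched"
            rows.append(row)
            continue
        r2 = records2.loc[f2]
        row["fold_change_2"] = r2["fold_change"]
        row["direction_2"] = r2["direction"]
        row["consistent_direction"] = r1["direction"] == r2["direction"] != "unknown"
        if cfg.strict_same_arm:
            both = (r1["univariate_selected"] and r2["univariate_selected"]) or (
                r1["multivariate_selected"] and r2["multivariate_selected"]
            )
        else:
            both = bool(r1["combined_selected"] and r2["combined_selected"])
        if not both:
            row["reason"] = "not selected in both batches"
        elif cfg.require_direction_consistency and not row["consistent_direction"]:
            row["reason"] = "direction conflict"
        else:
            row["validated"] = True
        rows.append(row)
    return pd.DataFrame(rows)


def export_boxplots(
    snapshots: dict[int, FeatureTable],
    validated: pd.DataFrame,
    out_dir: str | Path,
) -> list[Path]:
    """One control-vs-exposed boxplot per validated feature, per batch.

    Writes ``<feature>.png`` files plus a deterministic ``index.csv`` and
    returns the plot paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    index_rows = []
    hits = validated[validated["validated"]]
    for _, row in hits.iterrows():
        fid1 = row["feature_id_1"]
        data, labels = [], []
        for batch in sorted(snapshots):
            table = snapshots[batch]
            fid = fid1 if batch == min(snapshots) else row["feature_id_2"]
            if fid not in table.intensities.index:
                continue
            for grp in ("control", "exposed"):
                vals = table.intensities.loc[fid, table.columns_of("biological", grp)]
                data.append(vals.dropna().to_numpy())
                labels.append(f"b{batch}\n{grp[:4]}")
        if not data:
            continue
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.boxplot(data, tick_labels=labels)
        ax.set_ylabel("intensity")
        ax.set_title(str(fid1))
        path = out_dir / f"{fid1}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        paths.append(path)
        index_rows.append({"feature_id": fid1, "file": path.name})
    pd.DataFrame(index_rows, columns=["feature_id", "file"]).to_csv(
        out_dir / "index.csv", index=False
    )
    return paths


@dataclass
class SelectionMetrics:
    """Confusion of a selected set against generator truth."""

    tp: int
    fp: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def fdr(self) -> float:
        return self.fp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "sensitivity": self.sensitivity, "fdr": self.fdr,
        }


def selection_metrics(selected_ids, truth: SyntheticTruth) -> SelectionMetrics:
    """TP/FP/FN, sensitivity and FDR of a selected id set against truth."""
    selected = set(selected_ids)
    true_set = set(truth.differential_ids)
    tp = len(selected & true_set)
    return SelectionMetrics(tp=tp, fp=len(selected - true_set), fn=len(true_set - selected))


def export_fingerprint(
    validated: pd.DataFrame,
    truth: SyntheticTruth | None = None,
    out: str | Path | None = None,
) -> tuple[pd.DataFrame, dict | None]:
    """Tabular fingerprint of validated features.

    Per validated feature: both batch fold changes, the mean log2 FC and a
    normalized log2 FC (scaled to [-1, 1] by the largest magnitude). When
    truth is supplied, confusion counts plus sensitivity/FDR of the
    validated set are returned (and written as a JSON sidecar).
    """
    hits = validated[validated["validated"]].copy()
    if len(hits):
        log2fc = np.log2(
            np.sqrt(hits["fold_change_1"].astype(float) * hits["fold_change_2"].astype(float))
        )
        scale = np.nanmax(np.abs(log2fc)) or 1.0
        hits["log2_fc"] = log2fc
        hits["normalized_log2_fc"] = log2fc / scale
    else:
        hits["log2_fc"] = pd.Series(dtype=float)
        hits["normalized_log2_fc"] = pd.Series(dtype=float)
    cols = [
        "feature_id_1", "feature_id_2", "fold_change_1", "fold_change_2",
        "direction_1", "log2_fc", "normalized_log2_fc",
    ]
    table = hits[cols].reset_index(drop=True)
    metrics = None
    if truth is not None:
        metrics = selection_metrics(table["feature_id_1"], truth).to_dict()
    if out is not None:
        out = Path(out)
        table.to_csv(out, index=False)
        if metrics is not None:
            import json

            Path(str(out) + ".metrics.json").write_text(json.dumps(metrics, indent=2))
    return table, metrics
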