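"""Synthetic LC-HRMS feature-table generator with known ground truth.

Emulates the statistical structure of a two-group cell-exposure study run on
multiple chromatography/ionization platforms: per run, 8 exposed + 8 control
biological samples, 6 pooled-QC injections at evenly spaced injection orders,
extraction blanks, 12 spiked internal standards, smooth injection-order
drift, intensity-dependent missingness (limit-of-detection censoring),
detector saturation, background/contaminant features that dominate in
blanks, and a known set of truly differential features. A second batch
replicates the design with the same truth but independent noise and drift,
so cross-batch validation can be exercised end to end.

The generative model, per feature f and sample s (natural-log scale):

    log I_fs = b_f + delta_f * 1[s exposed] + g_f * d(o_s)
               + eps_bio (biological only) + eps_ana

with b_f the feature baseline (log-normal across features), delta_f the
log true fold change (0 for non-differential features), d(o) a smooth
random cubic drift curve over injection order o shared across features with
feature gain g_f, and independent log-normal biological and analytical
noise whose coefficients of variation are configurable. QC samples sit at
the grand biological mean of the feature with analytical noise only; blanks
sit at a small background fraction of the biological level except for
contaminant features, which appear at biological scale in blanks. Values
below the run-level LOD quantile are censored to missing; values above the
saturation ceiling are clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FeatureTable, PLATFORM_MODES, substream


def _cv_to_sigma(cv: float) -> float:
    """Natural-log sd of a log-normal with the given coefficient of variation."""
    return float(np.sqrt(np.log1p(cv**2)))


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic study; defaults mirror the emulated design."""

    n_features: int = 2000
    n_differential: int = 100
    n_contaminant: int = 50
    n_is: int = 12
    n_per_group: int = 8
    n_qc: int = 6
    n_blank: int = 2
    #: magnitude range of |log2 FC| for differential features; spans the
    #: FC > 5 / FC < 0.2 selection bounds with margin (FC 8x..32x)
    log2_fc_range: tuple[float, float] = (3.0, 5.0)
    base_log_mean: float = 5.0  # log10 intensity scale
    base_log_sd: float = 0.8
    analytical_cv: float = 0.10
    biological_cv: float = 0.20
    drift_amplitude: float = 0.3
    missing_lod_quantile: float = 0.02
    missing_random_rate: float = 0.01
    blank_background_fraction: float = 0.05
    is_height: float = 2e5
    saturation_ceiling: float = 5e8
    mz_range: tuple[float, float] = (80.0, 1000.0)
    rt_range: tuple[float, float] = (0.5, 15.0)
    #: cross-batch coordinate jitter (uniform within +-tolerance)
    batch_mz_jitter_ppm: float = 3.0
    batch_rt_jitter: float = 0.05
    platform_modes: tuple[str, ...] = PLATFORM_MODES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_differential + self.n_contaminant + self.n_is > self.n_features:
            raise ValueError("differential + contaminant + IS counts exceed n_features")
        for name in ("missing_lod_quantile", "missing_random_rate", "blank_background_fraction"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_per_group < 2 or self.n_qc < 0 or self.n_blank < 0:
            raise ValueError("infeasible sample counts")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a generated run.

    ``features`` has one row per feature: ``differential`` (bool),
    ``direction`` (up/down/none), ``true_fc`` (exposed/control intensity
    ratio, 1 for non-differential), ``contaminant``, ``is_standard``.
    ``drift`` has one row per sample with the shared drift multiplier at its
    injection order.
    """

    features: pd.DataFrame
    drift: pd.DataFrame

    @property
    def differential_ids(self) -> list[str]:
        return list(self.features.index[self.features["differential"]])

    def to_csv(self, path: str | Path) -> None:
        out = self.features.copy()
        out.index.name = "feature_id"
        out.to_csv(path)


def _feature_truth(cfg: GeneratorConfig) -> pd.DataFrame:
    """Per-feature roles and effect sizes; deterministic in cfg.seed.

    Shared across batches and platform modes up to independent baselines:
    the identity, direction and magnitude of differential features are
    decided once per (cfg, platform) so batch 2 replicates batch 1's truth.
    """
    rng = substream(cfg.seed, "truth")
    n = cfg.n_features
    ids = [f"F{i:05d}" for i in range(n)]
    is_standard = np.zeros(n, bool)
    is_standard[:cfg.n_is] = True
    for i in range(cfg.n_is):
        ids[i] = f"IS_{i + 1:02d}"
    pool = np.flatnonzero(~is_standard)
    picked = rng.choice(pool, size=cfg.n_differential + cfg.n_contaminant, replace=False)
    diff_idx = picked[: cfg.n_differential]
    contam_idx = picked[cfg.n_differential:]
    differential = np.zeros(n, bool)
    differential[diff_idx] = True
    contaminant = np.zeros(n, bool)
    contaminant[contam_idx] = True
    direction = np.array(["none"] * n, dtype=object)
    half = cfg.n_differential // 2
    up = diff_idx[:half]
    down = diff_idx[half:]
    direction[up] = "up"
    direction[down] = "down"
    lo, hi = cfg.log2_fc_range
    mag = rng.uniform(lo, hi, size=cfg.n_differential)
    log2fc = np.zeros(n)
    log2fc[up] = mag[:half]
    log2fc[down] = -mag[half:]
    return pd.DataFrame(
        {
            "differential": differential,
            "direction": direction,
            "true_fc": np.exp2(log2fc),
            "contaminant": contaminant,
            "is_standard": is_standard,
        },
        index=pd.Index(ids, name="feature_id"),
    )


def _injection_layout(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign sample ids, types and injection orders for one run.

    QCs sit at evenly spaced orders spanning the run (first and last slots
    included); biological samples are randomized over the remaining slots;
    blanks take the final free slots, as in a typical sequence.
    """
    n_bio = 2 * cfg.n_per_group
    total = n_bio + cfg.n_qc + cfg.n_blank
    orders = np.arange(1, total + 1)
    if cfg.n_qc > 0:
        qc_orders = np.unique(np.round(np.linspace(1, total, cfg.n_qc)).astype(int))
        while len(qc_orders) < cfg.n_qc:  # collisions only in tiny runs
            extra = rng.choice(np.setdiff1d(orders, qc_orders), size=1)
            qc_orders = np.unique(np.concatenate([qc_orders, extra]))
    else:
        qc_orders = np.array([], dtype=int)
    free = np.setdiff1d(orders, qc_orders)
    blank_orders = free[-cfg.n_blank:] if cfg.n_blank else np.array([], dtype=int)
    bio_orders = rng.permutation(np.setdiff1d(free, blank_orders))
    rows = []
    groups = ["control"] * cfg.n_per_group + ["exposed"] * cfg.n_per_group
    for i, (grp, order) in enumerate(zip(groups, bio_orders)):
        rows.append(("bio", grp, int(order)))
    for order in qc_orders:
        rows.append(("qc", None, int(order)))
    for order in blank_orders:
        rows.append(("blank", None, int(order)))
    return pd.DataFrame(rows, columns=["kind", "group", "injection_order"])


def _drift_curve(cfg: GeneratorConfig, rng: np.random.Generator, total: int) -> np.ndarray:
    """Smooth random cubic drift over injection order, in log units.

    Centered to mean zero and scaled so the peak-to-mean log deviation maps
    to a multiplicative excursion of at most ``drift_amplitude``.
    """
    if cfg.drift_amplitude <= 0:
        return np.zeros(total)
    t = np.linspace(0.0, 1.0, total)
    coeffs = rng.normal(size=4)
    raw = np.polyval(coeffs, t)
    raw = raw - raw.mean()
    peak = np.max(np.abs(raw))
    if peak < 1e-12:
        return np.zeros(total)
    return raw / peak * np.log1p(cfg.drift_amplitude)


def generate_run(
    cfg: GeneratorConfig, batch: int = 1, platform_mode: str = "hilic_pos"
) -> tuple[FeatureTable, SyntheticTruth]:
    """Generate one analytical run (one batch, one platform mode)."""
    if platform_mode not in PLATFORM_MODES:
        raise ValueError(f"unknown platform_mode {platform_mode!r}")
    truth_features = _feature_truth(cfg)
    n = cfg.n_features
    # coordinates and baselines are platform-specific but batch-shared
    prng = substream(cfg.seed, f"platform:{platform_mode}")
    mz = np.sort(prng.uniform(*cfg.mz_range, size=n))
    rt = prng.uniform(*cfg.rt_range, size=n)
    base_log10 = prng.normal(cfg.base_log_mean, cfg.base_log_sd, size=n)
    ln10 = np.log(10.0)
    base = base_log10 * ln10
    is_mask = truth_features["is_standard"].to_numpy()
    base[is_mask] = np.log(cfg.is_height)
    # batch-specific randomness
    rng = substream(cfg.seed, f"run:{platform_mode}:b{batch}")
    layout = _injection_layout(cfg, rng)
    total = len(layout)
    drift = _drift_curve(cfg, rng, total)
    gain = rng.uniform(0.2, 1.0, size=n)
    gain[is_mask] = rng.uniform(0.2, 1.0, size=is_mask.sum())

    delta = np.log(truth_features["true_fc"].to_numpy())
    sig_bio = _cv_to_sigma(cfg.biological_cv)
    sig_ana = _cv_to_sigma(cfg.analytical_cv)
    contam = truth_features["contaminant"].to_numpy()

    ctrl_level = base
    expo_level = base + delta
    grand = np.log((np.exp(ctrl_level) + np.exp(expo_level)) / 2.0)
    blank_level = np.where(
        contam, grand, grand + np.log(max(cfg.blank_background_fraction, 1e-12))
    )

    cols = {}
    sample_rows = []
    prefix = f"{platform_mode}_b{batch}"
    counters = {"control": 0, "exposed": 0, "qc": 0, "blank": 0}
    for _, row in layout.iterrows():
        order = row["injection_order"]
        kind, grp = row["kind"], row["group"]
        d = drift[order - 1] * gain
        if kind == "bio":
            counters[grp] += 1
            sid = f"{prefix}_{grp}{counters[grp]:02d}"
            level = (ctrl_level if grp == "control" else expo_level) + d
            noise = rng.normal(0, sig_bio, n) + rng.normal(0, sig_ana, n)
            stype = "biological"
        elif kind == "qc":
            counters["qc"] += 1
            sid = f"{prefix}_qc{counters['qc']:02d}"
            level = grand + d
            noise = rng.normal(0, sig_ana, n)
            stype = "qc"
        else:
            counters["blank"] += 1
            sid = f"{prefix}_blank{counters['blank']:02d}"
            level = blank_level + d
            noise = rng.normal(0, sig_ana, n)
            stype = "blank"
        cols[sid] = np.exp(level + noise)
        sample_rows.append(
            {
                "sample_id": sid,
                "sample_type": stype,
                "group": grp,
                "batch": batch,
                "platform_mode": platform_mode,
                "injection_order": order,
            }
        )

    intensities = pd.DataFrame(cols, index=truth_features.index)
    # saturation clipping, then LOD censoring on the run-level low quantile
    intensities = intensities.clip(upper=cfg.saturation_ceiling)
    values = intensities.to_numpy()
    if cfg.missing_lod_quantile > 0:
        lod = np.quantile(values, cfg.missing_lod_quantile)
        values = np.where(values < lod, np.nan, values)
    if cfg.missing_random_rate > 0:
        drop = rng.random(values.shape) < cfg.missing_random_rate
        values = np.where(drop, np.nan, values)
    intensities = pd.DataFrame(values, index=intensities.index, columns=intensities.columns)

    # batch-2 coordinates jitter within the stated matching tolerances
    if batch != 1:
        jrng = substream(cfg.seed, f"jitter:{platform_mode}:b{batch}")
        mz = mz * (1 + jrng.uniform(-1, 1, n) * cfg.batch_mz_jitter_ppm * 1e-6)
        rt = rt + jrng.uniform(-1, 1, n) * cfg.batch_rt_jitter
        rt = np.clip(rt, 0.01, None)

    features = pd.DataFrame({"mz": mz, "rt": rt}, index=truth_features.index)
    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    table = FeatureTable(features, intensities, samples)
    drift_df = pd.DataFrame(
        {
            "sample_id": list(samples.index),
            "injection_order": samples["injection_order"].to_numpy(),
            "drift_multiplier": np.exp(drift[samples["injection_order"].to_numpy() - 1]),
        }
    ).set_index("sample_id")
    return table, SyntheticTruth(truth_features.copy(), drift_df)


def generate_experiment(
    cfg: GeneratorConfig,
) -> dict[tuple[int, str], tuple[FeatureTable, SyntheticTruth]]:
    """Two batches x requested platform modes with shared truth per platform.

    Batch 2 is an independent replication: same differential identities,
    directions and magnitudes, fresh noise and drift, and feature m/z / RT
    jittered within small tolerances to exercise cross-batch matching.
    """
    out: dict[tuple[int, str], tuple[FeatureTable, SyntheticTruth]] = {}
    for batch in (1, 2):
        for mode in cfg.platform_modes:
            out[(batch, mode)] = generate_run(cfg, batch=batch, platform_mode=mode)
    return out
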