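"""Core data model, file I/O, configuration and run reporting.

The central container is :class:`FeatureTable`: a non-negative intensity
matrix (features x samples, ``NaN`` marks a missing peak) together with
per-feature coordinates (m/z, retention time) and per-sample design
metadata (sample type, exposure group, batch, platform mode, injection
order). Every pipeline stage consumes and returns this object.

Missing values and measured zeros are distinct: a zero is a real measured
intensity, an empty cell on disk / ``NaN`` in memory means the peak was not
detected. Blank-subtraction and presence rules depend on this distinction.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

SAMPLE_TYPES = ("biological", "qc", "blank")
GROUPS = ("control", "exposed")
PLATFORM_MODES = ("hilic_pos", "hilic_neg", "rplc_pos", "rplc_neg")

SAMPLE_META_COLUMNS = [
    "sample_id",
    "sample_type",
    "group",
    "batch",
    "platform_mode",
    "injection_order",
]


class ValidationError(ValueError):
    """Base class for feature-table validation failures."""


class UnknownSampleError(ValidationError):
    """A sample id appears in one file but not the other."""


class DuplicateFeatureError(ValidationError):
    """A feature id occurs more than once."""


class NegativeIntensityError(ValidationError):
    """An intensity value is negative."""


class MissingGroupError(ValidationError):
    """A biological sample carries no control/exposed group label."""


class InvalidMetadataError(ValidationError):
    """Sample metadata violates a field-level constraint."""


class ConfigError(ValueError):
    """Configuration file contains an unknown key or out-of-range value."""


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible RNG substream derived from a root seed.

    Every source of randomness in the package (generator, CV folds,
    permutations, forests) pulls from its own named substream so a stage is
    reproducible in isolation.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


def substream_int(seed: int, name: str) -> int:
    """A 31-bit integer seed for libraries that take ``random_state`` ints."""
    return int(substream(seed, name).integers(0, 2**31 - 1))


@dataclass
class FeatureTable:
    """Feature x sample intensity matrix with feature and sample metadata.

    Parameters
    ----------
    features : pd.DataFrame
        Indexed by feature_id, columns ``mz`` (Th) and ``rt`` (min).
    intensities : pd.DataFrame
        Indexed by feature_id, one column per sample_id, float; ``NaN``
        marks a missing (undetected) value.
    samples : pd.DataFrame
        Indexed by sample_id, columns ``sample_type``, ``group``, ``batch``,
        ``platform_mode``, ``injection_order``; column order matches the
        intensity columns.
    """

    features: pd.DataFrame
    intensities: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------
    def validate(self) -> None:
        if not self.features.index.is_unique:
            dupes = self.features.index[self.features.index.duplicated()].tolist()
            raise DuplicateFeatureError(f"duplicate feature ids: {dupes[:5]}")
        if not self.features.index.equals(self.intensities.index):
            raise ValidationError("features and intensities are not row-aligned")
        if list(self.intensities.columns) != list(self.samples.index):
            raise UnknownSampleError(
                "intensity columns and sample metadata rows disagree: "
                f"{sorted(set(self.intensities.columns) ^ set(self.samples.index))[:5]}"
            )
        vals = self.intensities.to_numpy(dtype=float)
        if np.any(vals[np.isfinite(vals)] < 0):
            raise NegativeIntensityError("negative intensity value present")
        if len(self.features):
            mzrt = self.features[["mz", "rt"]].to_numpy(dtype=float)
            if not np.all(np.isfinite(mzrt)) or np.any(mzrt <= 0):
                raise ValidationError("m/z and RT must be finite and positive")
        st = self.samples["sample_type"]
        bad = ~st.isin(SAMPLE_TYPES)
        if bad.any():
            raise InvalidMetadataError(
                f"unknown sample_type: {st[bad].unique().tolist()}"
            )
        grp = self.samples["group"]
        bio = st == "biological"
        if (bio & (grp.isna() | (grp == ""))).any():
            missing = self.samples.index[bio & (grp.isna() | (grp == ""))].tolist()
            raise MissingGroupError(f"biological samples without group: {missing[:5]}")
        if (bio & ~grp.isin(GROUPS)).any():
            raise InvalidMetadataError("biological group must be control/exposed")
        if (~bio & grp.notna() & (grp != "")).any():
            raise InvalidMetadataError("qc/blank samples must not carry a group")
        order = self.samples["injection_order"]
        if (order <= 0).any():
            raise InvalidMetadataError("injection_order must be strictly positive")
        runs = self.samples.groupby(["platform_mode", "batch"], observed=True)
        for key, sub in runs:
            if sub["injection_order"].duplicated().any():
                raise InvalidMetadataError(f"duplicate injection_order in run {key}")

    # -- convenience selectors ---------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.features.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    @property
    def mz(self) -> pd.Series:
        return self.features["mz"]

    @property
    def rt(self) -> pd.Series:
        return self.features["rt"]

    def sample_mask(self, sample_type: str | None = None, group: str | None = None) -> pd.Series:
        mask = pd.Series(True, index=self.samples.index)
        if sample_type is not None:
            mask &= self.samples["sample_type"] == sample_type
        if group is not None:
            mask &= self.samples["group"] == group
        return mask

    def columns_of(self, sample_type: str | None = None, group: str | None = None) -> list[str]:
        return list(self.samples.index[self.sample_mask(sample_type, group)])

    def select_features(self, feature_ids: Iterable[str]) -> "FeatureTable":
        ids = list(feature_ids)
        return FeatureTable(
            self.features.loc[ids].copy(),
            self.intensities.loc[ids].copy(),
            self.samples.copy(),
        )

    def select_samples(self, sample_ids: Iterable[str]) -> "FeatureTable":
        ids = list(sample_ids)
        return FeatureTable(
            self.features.copy(),
            self.intensities[ids].copy(),
            self.samples.loc[ids].copy(),
        )

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.features.copy(), self.intensities.copy(), self.samples.copy()
        )

    def equals(self, other: "FeatureTable") -> bool:
        return (
            self.features.equals(other.features)
            and self.intensities.equals(other.intensities)
            and self.samples.equals(other.samples)
        )

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.samples)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _normalize_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    meta = meta.copy()
    missing = [c for c in SAMPLE_META_COLUMNS if c not in meta.columns]
    if missing:
        raise InvalidMetadataError(f"metadata lacks columns: {missing}")
    meta["sample_id"] = meta["sample_id"].astype(str)
    if meta["sample_id"].duplicated().any():
        raise InvalidMetadataError("duplicate sample_id in metadata")
    meta["group"] = meta["group"].where(meta["group"].notna(), None)
    meta["group"] = meta["group"].replace({"": None})
    meta["batch"] = meta["batch"].astype(int)
    meta["injection_order"] = meta["injection_order"].astype(int)
    return meta.set_index("sample_id")[
        ["sample_type", "group", "batch", "platform_mode", "injection_order"]
    ]


def read_feature_table(table_path: str | Path, metadata_path: str | Path) -> FeatureTable:
    """Read a wide CSV/TSV feature table plus its sample-metadata CSV.

    The table file has columns ``feature_id, mz, rt`` followed by one column
    per sample; empty cells are missing intensities. Sample columns are
    reordered to metadata order.
    """
    sep = "\t" if str(table_path).endswith((".tsv", ".txt")) else ","
    raw = pd.read_csv(table_path, sep=sep, dtype={"feature_id": str})
    for col in ("feature_id", "mz", "rt"):
        if col not in raw.columns:
            raise ValidationError(f"feature table lacks column {col!r}")
    meta = _normalize_metadata(pd.read_csv(metadata_path))
    table_samples = [c for c in raw.columns if c not in ("feature_id", "mz", "rt")]
    unknown = set(table_samples) ^ set(meta.index)
    if unknown:
        raise UnknownSampleError(
            f"sample ids not shared by table and metadata: {sorted(unknown)}"
        )
    if raw["feature_id"].duplicated().any():
        raise DuplicateFeatureError(
            f"duplicate feature ids: {raw['feature_id'][raw['feature_id'].duplicated()].tolist()[:5]}"
        )
    features = raw.set_index("feature_id")[["mz", "rt"]].astype(float)
    intensities = raw.set_index("feature_id")[list(meta.index)].astype(float)
    return FeatureTable(features, intensities, meta)


def write_feature_table(
    table: FeatureTable, table_path: str | Path, metadata_path: str | Path
) -> None:
    """Write a feature table to the wide-CSV contract of read_feature_table."""
    sep = "\t" if str(table_path).endswith((".tsv", ".txt")) else ","
    out = pd.concat([table.features[["mz", "rt"]], table.intensities], axis=1)
    out.index.name = "feature_id"
    out.to_csv(table_path, sep=sep)
    meta = table.samples.reset_index().rename(columns={"index": "sample_id"})
    if "sample_id" not in meta.columns:
        meta = meta.rename(columns={meta.columns[0]: "sample_id"})
    meta.to_csv(metadata_path, index=False)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def _range(lo: float | None, hi: float | None):
    return {"lo": lo, "hi": hi}


@dataclass
class RunConfig:
    """All tunable thresholds and seeds of the pipeline.

    Defaults follow the workflow's stated values: blank factor 10x, presence
    fraction 0.75, exposed-group RSD cutoff 30%, fold-change bounds 5 / 0.2,
    alpha 0.05, 1000 permutations, 7 CV folds, IS criteria (height 5000,
    10 ppm, RT 0.5 min HILIC / 0.2 min RPLC).
    """

    seed: int = 0
    # filtering
    blank_factor: float = 10.0
    blank_missing_as_zero: bool = True
    presence_fraction: float = 0.75
    rsd_cutoff: float = 30.0
    # duplicate / isotope merging
    merge_mz_ppm: float = 5.0
    merge_rt_tol: float = 0.1
    isotope_spacing: float = 1.00335
    isotope_min_corr: float = 0.8
    # univariate selection
    alpha: float = 0.05
    shapiro_alpha: float = 0.05
    fc_upper: float = 5.0
    fc_lower: float = 0.2
    use_adjusted_p: bool = True
    p_adjust_method: str = "bh"
    pooled_t: bool = False
    # multivariate
    cv_folds: int = 7
    max_components: int = 5
    component_rule: str = "improvement"  # or "max_q2"
    q2_improvement_threshold: float = 0.01
    n_permutations: int = 1000
    permutation_statistic: str = "pvalue"  # or "mean"
    vip_cutoff: float = 1.0
    mda_top_k: int = 50
    rf_trees: int = 500
    # imputation
    impute_trees: int = 100
    impute_max_iter: int = 10
    impute_tol: float = 1e-4
    # QC / outliers
    is_min_height: float = 5000.0
    is_mass_ppm: float = 10.0
    rt_tol_hilic: float = 0.5
    rt_tol_rplc: float = 0.2
    saturation_ceiling: float = 5e8
    outlier_mad_factor: float = 3.0
    outlier_chi2_quantile: float = 0.975
    # cross-batch matching / validation
    match_mz_ppm: float = 10.0
    require_direction_consistency: bool = True
    strict_same_arm: bool = False

    _RANGES = {
        "blank_factor": _range(0.0, None),
        "presence_fraction": _range(0.0, 1.0),
        "rsd_cutoff": _range(0.0, None),
        "alpha": _range(0.0, 1.0),
        "shapiro_alpha": _range(0.0, 1.0),
        "fc_upper": _range(1.0, None),
        "fc_lower": _range(0.0, 1.0),
        "cv_folds": _range(2, None),
        "max_components": _range(1, None),
        "n_permutations": _range(0, None),
        "vip_cutoff": _range(0.0, None),
        "mda_top_k": _range(0, None),
        "impute_trees": _range(1, None),
        "impute_max_iter": _range(1, None),
        "is_min_height": _range(0.0, None),
        "is_mass_ppm": _range(0.0, None),
        "rt_tol_hilic": _range(0.0, None),
        "rt_tol_rplc": _range(0.0, None),
        "match_mz_ppm": _range(0.0, None),
        "merge_mz_ppm": _range(0.0, None),
        "merge_rt_tol": _range(0.0, None),
        "isotope_min_corr": _range(-1.0, 1.0),
        "outlier_chi2_quantile": _range(0.0, 1.0),
    }

    def __post_init__(self) -> None:
        for key, rng in self._RANGES.items():
            val = getattr(self, key)
            if rng["lo"] is not None and val < rng["lo"]:
                raise ConfigError(f"{key}={val} below allowed minimum {rng['lo']}")
            if rng["hi"] is not None and val > rng["hi"]:
                raise ConfigError(f"{key}={val} above allowed maximum {rng['hi']}")
        if self.p_adjust_method not in ("bh", "bonferroni", "none"):
            raise ConfigError(f"unknown p_adjust_method {self.p_adjust_method!r}")
        if self.permutation_statistic not in ("pvalue", "mean"):
            raise ConfigError(
                f"unknown permutation_statistic {self.permutation_statistic!r}"
            )
        if self.component_rule not in ("improvement", "max_q2"):
            raise ConfigError(f"unknown component_rule {self.component_rule!r}")

    def rt_tolerance(self, platform_mode: str) -> float:
        return self.rt_tol_hilic if platform_mode.startswith("hilic") else self.rt_tol_rplc

    def replace(self, **kwargs: Any) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None = None, overrides: Mapping[str, Any] | None = None) -> RunConfig:
    """Load a RunConfig from a YAML key-value file, filling defaults.

    Unknown keys and out-of-range values raise :class:`ConfigError`.
    """
    data: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError("config file must contain a key-value mapping")
        data.update(loaded)
    if overrides:
        data.update(overrides)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


# ---------------------------------------------------------------------------
# Run reporting
# ---------------------------------------------------------------------------

@dataclass
class StageRecord:
    stage: str
    n_features_in: int
    n_features_out: int
    n_samples_in: int
    n_samples_out: int
    removed_features: list[str] = field(default_factory=list)
    removed_samples: list[str] = field(default_factory=list)
    params: dict[str, Any] = field(default_factory=dict)
    notes: str = ""


@dataclass
class RunReport:
    """Per-stage record of what went in, what came out and why."""

    stages: list[StageRecord] = field(default_factory=list)
    seed: int | None = None

    def record(self, record: StageRecord) -> None:
        if self.stages and record.n_features_out > record.n_features_in:
            raise ValueError("a stage may not create features")
        self.stages.append(record)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "seed": self.seed,
            "stages": [dataclasses.asdict(s) for s in self.stages],
        }
        text = json.dumps(payload, indent=2, default=str)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        payload = json.loads(text)
        report = cls(seed=payload.get("seed"))
        for s in payload.get("stages", []):
            report.stages.append(StageRecord(**s))
        return report

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": s.stage,
                    "features_in": s.n_features_in,
                    "features_out": s.n_features_out,
                    "samples_in": s.n_samples_in,
                    "samples_out": s.n_samples_out,
                    "removed_features": len(s.removed_features),
                }
                for s in self.stages
            ]
        )
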