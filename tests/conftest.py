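import numpy as np
import pandas as pd
import pytest

from metabofinger import FeatureTable, GeneratorConfig


def make_table(intensities, sample_types, groups=None, orders=None,
               mz=None, rt=None, platform_mode="hilic_pos", batch=1):
    """Build a small FeatureTable from a 2-D array and sample descriptors."""
    arr = np.asarray(intensities, dtype=float)
    n_feat, n_samp = arr.shape
    fids = [f"F{i}" for i in range(n_feat)]
    sids = [f"s{j}" for j in range(n_samp)]
    features = pd.DataFrame(
        {
            "mz": mz if mz is not None else 100.0 + 10.0 * np.arange(n_feat),
            "rt": rt if rt is not None else 1.0 + 0.5 * np.arange(n_feat),
        },
        index=pd.Index(fids, name="feature_id"),
    )
    inten = pd.DataFrame(arr, index=features.index, columns=sids)
    samples = pd.DataFrame(
        {
            "sample_type": sample_types,
            "group": groups if groups is not None else [
                None if t != "biological" else "control" for t in sample_types
            ],
            "batch": batch,
            "platform_mode": platform_mode,
            "injection_order": orders if orders is not None else np.arange(1, n_samp + 1),
        },
        index=pd.Index(sids, name="sample_id"),
    )
    return FeatureTable(features, inten, samples)


def two_group_table(control, exposed, qc=None, blank=None, **kwargs):
    """Feature table from per-group intensity blocks (features x samples each)."""
    blocks, types, groups = [], [], []
    for block, stype, grp in (
        (control, "biological", "control"),
        (exposed, "biological", "exposed"),
        (qc, "qc", None),
        (blank, "blank", None),
    ):
        if block is None:
            continue
        block = np.atleast_2d(np.asarray(block, dtype=float))
        blocks.append(block)
        types += [stype] * block.shape[1]
        groups += [grp] * block.shape[1]
    return make_table(np.hstack(blocks), types, groups, **kwargs)


@pytest.fixture
def toy_table():
    """3 features x 4 samples (2 control, 2 exposed) with one missing cell."""
    return make_table(
        [[100.0, 110.0, 500.0, 520.0],
         [50.0, np.nan, 45.0, 55.0],
         [7.0, 8.0, 9.0, 10.0]],
        ["biological"] * 4,
        ["control", "control", "exposed", "exposed"],
    )


@pytest.fixture
def small_generator_config():
    """Down-scaled study design for fast end-to-end tests."""
    return GeneratorConfig(
        n_features=120,
        n_differential=12,
        n_contaminant=6,
        platform_modes=("hilic_pos",),
        seed=7,
    )
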