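"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately re-derive results with naive per-feature loops or
exhaustive enumeration, sharing no code with the package implementation.
"""

from itertools import combinations

import numpy as np


def brute_force_filters(table, blank_factor=10.0, presence_fraction=0.75,
                        rsd_cutoff=30.0):
    """Naive per-feature application of the blank/presence/RSD rules.

    Returns the list of surviving feature ids after applying the three
    rules in order, each evaluated per feature with plain Python loops.
    """
    meta = table.samples
    blank_cols = [s for s in meta.index if meta.at[s, "sample_type"] == "blank"]
    bio_qc_cols = [s for s in meta.index if meta.at[s, "sample_type"] in ("biological", "qc")]
    ctrl = [s for s in meta.index
            if meta.at[s, "sample_type"] == "biological" and meta.at[s, "group"] == "control"]
    expo = [s for s in meta.index
            if meta.at[s, "sample_type"] == "biological" and meta.at[s, "group"] == "exposed"]

    survivors = []
    for fid in table.feature_ids:
        row = table.intensities.loc[fid]
        # blank rule: mean blank with missing-as-zero, strict <
        blank_vals = [row[s] if np.isfinite(row[s]) else 0.0 for s in blank_cols]
        mean_blank = sum(blank_vals) / len(blank_vals)
        signal = [row[s] for s in bio_qc_cols if np.isfinite(row[s])]
        max_signal = max(signal) if signal else 0.0
        if max_signal < blank_factor * mean_blank:
            continue
        # presence rule: >= fraction in either biological group
        pres_c = sum(np.isfinite(row[s]) for s in ctrl) / len(ctrl)
        pres_e = sum(np.isfinite(row[s]) for s in expo) / len(expo)
        if not (pres_c >= presence_fraction or pres_e >= presence_fraction):
            continue
        # exposed RSD rule: strict <, undefined removed
        vals = [row[s] for s in expo if np.isfinite(row[s])]
        if len(vals) < 2:
            continue
        mean = sum(vals) / len(vals)
        if mean <= 0:
            continue
        sd = (sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)) ** 0.5
        if not (100.0 * sd / mean < rsd_cutoff):
            continue
        survivors.append(fid)
    return survivors


def mann_whitney_exact_p(control, exposed):
    """Two-sided exact Mann-Whitney p by enumerating all rank assignments.

    Assumes no ties. The p-value is the null probability of a U statistic
    at least as far from its mean n1*n2/2 as the observed one.
    """
    c = list(control)
    e = list(exposed)
    pooled = sorted(c + e)
    n1, n2 = len(e), len(c)
    u_obs = sum(1 for x in e for y in c if x > y)
    center = n1 * n2 / 2.0
    dev = abs(u_obs - center)
    count = 0
    total = 0
    for combo in combinations(range(len(pooled)), n1):
        expo_vals = [pooled[i] for i in combo]
        ctrl_vals = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = sum(1 for x in expo_vals for y in ctrl_vals if x > y)
        total += 1
        if abs(u - center) >= dev - 1e-12:
            count += 1
    return count / total


def bh_adjust_by_hand(pvals):
    """Benjamini-Hochberg step-up computed with an explicit loop."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [None] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = min(1.0, pvals[i] * m / rank_from_top)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted
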