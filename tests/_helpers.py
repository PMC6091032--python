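"""Shared statistical helpers for tests (not collected by pytest)."""

import math

import numpy as np
import pandas as pd


def cluster_se_mean(values, clusters) -> float:
    """Cluster-robust standard error of a pooled mean: repeated measurements
    within a patient share a random effect and are not independent."""
    values = np.asarray(values, dtype=float)
    resid = values - values.mean()
    sums = pd.Series(resid).groupby(np.asarray(clusters)).sum().to_numpy()
    return float(np.sqrt((sums**2).sum()) / values.size)


def se_of_sd(values, clusters=None) -> float:
    """Delta-method standard error of a sample SD, optionally cluster-robust:
    SE(sd) = SE(variance-hat) / (2 * sd)."""
    values = np.asarray(values, dtype=float)
    z = (values - values.mean()) ** 2
    if clusters is None:
        se_var = float(z.std(ddof=1) / math.sqrt(z.size))
    else:
        se_var = cluster_se_mean(z, clusters)
    return se_var / (2.0 * values.std())
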