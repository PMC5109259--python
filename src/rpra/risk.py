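"""Risk characterization: summary statistics of Monte Carlo HQ distributions.

The reporting conventions: the mean and the 95th percentile (the customary
conservative estimate) of each HQ distribution, the coefficient of variation
in percent, the probability of exceeding the safety threshold HQ = 1, and
per-metal (or per-route) percentage contributions to a group's mean HQ.
Percentiles use linear interpolation between order statistics.  A bootstrap
standard error of the 95th percentile quantifies cross-run Monte Carlo
scatter.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "summarize",
    "exceedance_probability",
    "contribution_shares",
    "cumulative_curve",
    "bootstrap_p95_se",
]


def summarize(
    samples,
    threshold: float = 1.0,
    bootstrap: int = 0,
    seed: int = 0,
) -> dict:
    """Summary statistics of one HQ sample vector.

    Returns mean, median (p50), 95th percentile (p95), sd, cv_pct
    (sd/mean x 100), exceedance_pct at ``threshold`` and the sample size.
    With ``bootstrap`` > 0, adds ``p95_se``, the bootstrap standard error
    of the 95th percentile.  A zero mean with nonzero spread leaves the CV
    undefined (NaN, ``cv_defined=False``).
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("summarize expects a 1-D sample vector with >= 2 values")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    out = {
        "mean": mean,
        "p50": float(np.percentile(x, 50)),
        "p95": float(np.percentile(x, 95)),
        "sd": sd,
        "exceedance_pct": exceedance_probability(x, threshold),
        "n": int(x.size),
        "cv_defined": True,
    }
    if mean == 0.0 and sd > 0.0:
        warnings.warn("zero mean with nonzero sd: CV undefined", RuntimeWarning)
        out["cv_pct"] = float("nan")
        out["cv_defined"] = False
    elif mean == 0.0:
        out["cv_pct"] = 0.0
    else:
        out["cv_pct"] = 100.0 * sd / mean
    if bootstrap > 0:
        out["p95_se"] = bootstrap_p95_se(x, n_boot=bootstrap, seed=seed)
    return out


def exceedance_probability(samples, threshold: float = 1.0) -> float:
    """Percent of iterations with HQ strictly above ``threshold``."""
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    x = np.asarray(samples, dtype=float)
    return 100.0 * float(np.count_nonzero(x > threshold)) / x.size


def contribution_shares(samples_by_key: Mapping[str, np.ndarray]) -> pd.Series:
    """Percent contribution of each member (metal or route) to the group mean.

    ``share_k = 100 * mean(HQ_k) / sum_j mean(HQ_j)``; shares are exactly
    additive to 100%.  An all-zero group has undefined shares (NaN, with a
    warning).
    """
    keys = list(samples_by_key)
    lengths = {np.asarray(v).size for v in samples_by_key.values()}
    if len(lengths) > 1:
        raise ValueError(f"mismatched iteration counts: {sorted(lengths)}")
    means = np.array([float(np.mean(samples_by_key[k])) for k in keys])
    total = means.sum()
    if total == 0.0:
        warnings.warn("all-zero group: contribution shares undefined", RuntimeWarning)
        return pd.Series(np.nan, index=keys, name="share_pct")
    return pd.Series(100.0 * means / total, index=keys, name="share_pct")


def cumulative_curve(samples, n_points: int | None = None) -> pd.DataFrame:
    """Empirical cumulative distribution as (hq, cumulative_probability) pairs.

    ``cumulative_probability`` at a value v is the fraction of iterations
    with HQ <= v, so ``1 - F(threshold)`` equals the exceedance probability.
    With ``n_points``, the curve is thinned to evenly spaced quantiles.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    probs = np.arange(1, x.size + 1) / x.size
    if n_points is not None and n_points < x.size:
        idx = np.linspace(0, x.size - 1, n_points).round().astype(int)
        x, probs = x[idx], probs[idx]
    return pd.DataFrame({"hq": x, "cumulative_probability": probs})


def bootstrap_p95_se(samples, n_boot: int = 200, seed: int = 0) -> float:
    """Bootstrap standard error of the 95th percentile."""
    x = np.asarray(samples, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence((int(seed) % (2**31), 0x9B5)))
    stats = np.empty(n_boot)
    for b in range(n_boot):
        stats[b] = np.percentile(rng.choice(x, size=x.size, replace=True), 95)
    return float(stats.std(ddof=1))
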