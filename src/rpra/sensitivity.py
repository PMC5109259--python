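"""Sensitivity analysis: rank inputs by their correlation with scenario THQ.

Each sampled input column is correlated against the per-iteration total
hazard quotient; parameters are ranked by the magnitude of the coefficient.
Spearman rank correlation is the default — robust to the lognormal skew of
both inputs and output, and invariant to monotone transforms — with Pearson
available as an option.  Significance is assessed two-tailed at the 0.01
level, with no multiplicity correction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .params import SampleMatrix

__all__ = ["sensitivity_ranking"]


def sensitivity_ranking(
    inputs,
    output,
    top_k: int = 5,
    method: str = "spearman",
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Rank input parameters by |correlation| with the output.

    Parameters
    ----------
    inputs
        :class:`SampleMatrix` or DataFrame of per-iteration input draws.
    output
        Per-iteration THQ (or any scalar model output), same length.
    top_k
        Number of rows returned (all, if fewer non-constant inputs).
    method
        ``"spearman"`` (rank, default) or ``"pearson"``.
    alpha
        Two-tailed significance level for the ``significant`` flag.

    Returns a DataFrame with columns rank, parameter, coefficient, p_value,
    significant and a ``method`` attribute recorded in ``DataFrame.attrs``.
    Constant input columns have undefined correlation and are excluded with
    a warning.
    """
    if top_k < 1:
        raise ValueError(f"top_k must be >= 1, got {top_k}")
    if method not in ("spearman", "pearson"):
        raise ValueError(f"method must be 'spearman' or 'pearson', got {method!r}")
    data = inputs.data if isinstance(inputs, SampleMatrix) else pd.DataFrame(inputs)
    y = np.asarray(output, dtype=float)
    if len(data) != y.size:
        raise ValueError(
            f"inputs have {len(data)} iterations but output has {y.size}"
        )

    rows = []
    for name in data.columns:
        x = data[name].to_numpy(dtype=float)
        if np.ptp(x) == 0.0:
            warnings.warn(
                f"input {name!r} is constant; correlation undefined, excluded",
                RuntimeWarning,
            )
            continue
        if method == "spearman":
            res = stats.spearmanr(x, y)
            coef, p = float(res.statistic), float(res.pvalue)
        else:
            coef, p = (float(v) for v in stats.pearsonr(x, y))
        rows.append({"parameter": name, "coefficient": coef, "p_value": p})

    table = pd.DataFrame(rows, columns=["parameter", "coefficient", "p_value"])
    table = table.reindex(
        table["coefficient"].abs().sort_values(ascending=False, kind="stable").index
    ).head(top_k)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    table["significant"] = table["p_value"] < alpha
    table = table.reset_index(drop=True)
    table.attrs["method"] = method
    table.attrs["alpha"] = alpha
    return table
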