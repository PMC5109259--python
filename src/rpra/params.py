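"""Uncertain-parameter declaration and correlated Monte Carlo sampling.

Every uncertain quantity in the risk model — an exposure factor, a soil-water
partition coefficient, a metal concentration in a medium — is declared as a
:class:`ParameterSpec` giving its distribution family (``point``,
``lognormal`` or ``triangular``), its arithmetic mean and spread, and optional
truncation bounds.  Lognormal specs are parameterized by *arithmetic* mean and
standard deviation, converted internally to log-space via the moment
identities ``mu = ln(m^2 / sqrt(m^2 + s^2))`` and
``sigma^2 = ln(1 + s^2 / m^2)``.

Rank correlations between parameters (body weight with skin surface area,
plant uptake with soil sorption) are imposed with the Iman–Conover method:
a distribution-free reordering of independently drawn columns that matches
their ranks to a correlated set of van der Waerden scores, preserving every
marginal exactly.

Sampling is reproducible: a single top-level seed is combined with each
parameter's name to derive an independent stream, so adding or removing a
parameter never perturbs the draws of the others.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ParameterSpec",
    "CorrelationSpec",
    "SampleMatrix",
    "sample_parameter",
    "sample_parameters",
    "induce_correlations",
    "fit_summary_to_spec",
    "read_parameter_table",
]

_FAMILIES = ("point", "lognormal", "triangular")

#: Minimum acceptance rate for rejection-truncated sampling before the
#: truncation bounds are considered infeasible for the declared distribution.
MIN_ACCEPTANCE_RATE = 0.01


@dataclass(frozen=True)
class ParameterSpec:
    """One uncertain model quantity and its marginal distribution.

    Parameters
    ----------
    name
        Identifier, unique within a study (e.g. ``"BW"``, ``"Kd_As"``).
    family
        ``"point"`` (degenerate), ``"lognormal"`` (arithmetic mean/sd with
        optional truncation) or ``"triangular"`` (min, mode, max).
    mean
        Arithmetic mean in the declared units.
    sd
        Arithmetic standard deviation (lognormal only).
    minimum, maximum
        Truncation bounds for lognormal; support limits for triangular.
    mode
        Triangular mode; defaults to ``mean`` clipped into [minimum, maximum].
    units
        Free-text units, carried through to reports.
    """

    name: str
    family: str = "lognormal"
    mean: float = 0.0
    sd: float = 0.0
    minimum: float | None = None
    maximum: float | None = None
    mode: float | None = None
    units: str = ""

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(
                f"parameter {self.name!r}: unknown family {self.family!r}; "
                f"expected one of {_FAMILIES}"
            )
        if self.family == "lognormal":
            if self.mean <= 0:
                raise ValueError(
                    f"parameter {self.name!r}: lognormal requires mean > 0, got {self.mean}"
                )
            if self.sd < 0:
                raise ValueError(f"parameter {self.name!r}: sd must be >= 0, got {self.sd}")
            if self.minimum is not None and self.maximum is not None:
                if not (self.minimum <= self.mean <= self.maximum):
                    raise ValueError(
                        f"parameter {self.name!r}: require minimum <= mean <= maximum, "
                        f"got [{self.minimum}, {self.maximum}] around mean {self.mean}"
                    )
        elif self.family == "triangular":
            if self.minimum is None or self.maximum is None:
                raise ValueError(f"parameter {self.name!r}: triangular requires minimum and maximum")
            mode = self.triangular_mode
            if not (self.minimum <= mode <= self.maximum):
                raise ValueError(
                    f"parameter {self.name!r}: triangular requires minimum <= mode <= maximum, "
                    f"got ({self.minimum}, {mode}, {self.maximum})"
                )

    @property
    def triangular_mode(self) -> float:
        """Mode of the triangular family; the mean clipped into bounds if unset."""
        if self.mode is not None:
            return self.mode
        return float(np.clip(self.mean, self.minimum, self.maximum))


@dataclass(frozen=True)
class CorrelationSpec:
    """Target pairwise rank correlations between declared parameters."""

    pairs: tuple[tuple[str, str, float], ...] = ()

    def __post_init__(self) -> None:
        for a, b, rho in self.pairs:
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"correlation for ({a}, {b}) must be in [-1, 1], got {rho}")
            if a == b:
                raise ValueError(f"self-correlation declared for {a!r}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str, float]]) -> "CorrelationSpec":
        return cls(tuple((str(a), str(b), float(r)) for a, b, r in pairs))

    def restrict(self, names: Iterable[str]) -> "CorrelationSpec":
        """Keep only pairs whose both members are in ``names``."""
        keep = set(names)
        return CorrelationSpec(
            tuple(p for p in self.pairs if p[0] in keep and p[1] in keep)
        )


class SampleMatrix:
    """An iterations x parameters table of Monte Carlo draws.

    Wraps a :class:`pandas.DataFrame` (columns = parameter names) together
    with the seed that produced it.  Deterministic given (specs,
    correlations, seed, n_iterations).
    """

    def __init__(self, data: pd.DataFrame, seed: int):
        if data.isna().any().any():
            bad = data.columns[data.isna().any()].tolist()
            raise ValueError(f"sample matrix contains missing values in columns {bad}")
        self.data = data
        self.seed = int(seed)

    @property
    def n_iterations(self) -> int:
        return len(self.data)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def __contains__(self, name: str) -> bool:
        return name in self.data.columns

    def copy(self) -> "SampleMatrix":
        return SampleMatrix(self.data.copy(), self.seed)


def _stream(seed: int, name: str) -> np.random.Generator:
    # Independent, platform-stable stream per (seed, parameter name).
    digest = hashlib.blake2b(name.encode(), digest_size=8).digest()
    key = int.from_bytes(digest, "big") % (2**31)
    return np.random.default_rng(np.random.SeedSequence((int(seed) % (2**31), key)))


def _lognormal_logparams(mean: float, sd: float) -> tuple[float, float]:
    """Log-space (mu, sigma) matching an arithmetic mean and sd."""
    var_ratio = (sd / mean) ** 2
    sigma2 = np.log1p(var_ratio)
    mu = np.log(mean) - 0.5 * sigma2
    return mu, float(np.sqrt(sigma2))


def sample_parameter(spec: ParameterSpec, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` independent values from a parameter's marginal distribution.

    Lognormal draws reproduce the declared *arithmetic* mean and sd of the
    untruncated distribution; when truncation bounds are declared, values are
    rejection-sampled into [minimum, maximum].  An acceptance rate below
    ``MIN_ACCEPTANCE_RATE`` raises, naming the parameter.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = _stream(seed, spec.name)

    if spec.family == "point" or (spec.family == "lognormal" and spec.sd == 0):
        return np.full(n, float(spec.mean))

    if spec.family == "triangular":
        return rng.triangular(spec.minimum, spec.triangular_mode, spec.maximum, size=n)

    mu, sigma = _lognormal_logparams(spec.mean, spec.sd)
    lo, hi = spec.minimum, spec.maximum
    if lo is None and hi is None:
        return rng.lognormal(mu, sigma, size=n)

    lo = -np.inf if lo is None else lo
    hi = np.inf if hi is None else hi
    out = np.empty(n)
    filled = 0
    proposed = 0
    accepted = 0
    while filled < n:
        batch = max(n - filled, 1024)
        draw = rng.lognormal(mu, sigma, size=batch)
        keep = draw[(draw >= lo) & (draw <= hi)]
        proposed += batch
        accepted += len(keep)
        take = min(len(keep), n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
        if proposed >= max(100 * n, 10_000) and accepted / proposed < MIN_ACCEPTANCE_RATE:
            raise ValueError(
                f"parameter {spec.name!r}: truncation bounds [{spec.minimum}, "
                f"{spec.maximum}] exclude nearly all lognormal mass "
                f"(acceptance rate {accepted / proposed:.2%})"
            )
    return out


def _target_matrix(
    columns: Sequence[str], corr: CorrelationSpec
) -> np.ndarray:
    """Full Pearson target matrix for normal scores from declared Spearman pairs.

    A target Spearman rho maps to the Pearson correlation of the underlying
    normal scores via 2*sin(pi*rho/6).
    """
    idx = {name: i for i, name in enumerate(columns)}
    k = len(columns)
    target = np.eye(k)
    for a, b, rho in corr.pairs:
        for name in (a, b):
            if name not in idx:
                raise KeyError(f"correlated parameter {name!r} is not a sampled column")
        r = 2.0 * np.sin(np.pi * rho / 6.0)
        i, j = idx[a], idx[b]
        target[i, j] = target[j, i] = r
    return target


def induce_correlations(draws: SampleMatrix, corr: CorrelationSpec) -> SampleMatrix:
    """Impose target rank correlations by Iman–Conover reordering.

    Each output column is a permutation of the corresponding input column
    (marginals preserved exactly); the achieved Spearman correlation of each
    declared pair approaches its target as n grows.
    """
    if not corr.pairs:
        return draws

    columns = draws.columns
    target = _target_matrix(columns, corr)
    eigvals = np.linalg.eigvalsh(target)
    if eigvals.min() < -1e-10:
        raise ValueError(
            "declared correlation structure is not positive semi-definite; "
            f"offending pairs: {[(a, b, r) for a, b, r in corr.pairs]}"
        )

    n = draws.n_iterations
    k = len(columns)
    rng = _stream(draws.seed, "__iman_conover__")

    # van der Waerden scores, independently shuffled per column
    scores = stats.norm.ppf((np.arange(1, n + 1)) / (n + 1))
    m = np.empty((n, k))
    for j in range(k):
        m[:, j] = rng.permutation(scores)

    # rotate the score matrix to the target correlation
    jitter = 1e-12 * np.eye(k)
    p_chol = np.linalg.cholesky(target + jitter)
    emp = np.corrcoef(m, rowvar=False)
    q_chol = np.linalg.cholesky(emp + jitter)
    t = m @ np.linalg.inv(q_chol).T @ p_chol.T

    out = {}
    order_t = np.argsort(np.argsort(t, axis=0), axis=0)  # ranks of score columns
    for j, name in enumerate(columns):
        col = np.sort(draws[name])
        out[name] = col[order_t[:, j]]
    return SampleMatrix(pd.DataFrame(out, columns=columns), draws.seed)


def sample_parameters(
    specs: Sequence[ParameterSpec],
    n: int,
    seed: int,
    correlations: CorrelationSpec | None = None,
) -> SampleMatrix:
    """Draw all parameters independently, then induce declared correlations."""
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        dupes = sorted({x for x in names if names.count(x) > 1})
        raise ValueError(f"duplicate parameter names: {dupes}")
    data = pd.DataFrame(
        {s.name: sample_parameter(s, n, seed) for s in specs}, columns=names
    )
    matrix = SampleMatrix(data, seed)
    if correlations is not None:
        matrix = induce_correlations(matrix, correlations.restrict(names))
    return matrix


def fit_summary_to_spec(summary, name: str | None = None) -> ParameterSpec:
    """Bridge a concentration summary (mean, sd, min, max) to a sampler spec.

    Returns a truncated-lognormal :class:`ParameterSpec` carrying the
    summary's four statistics.  ``summary`` is any object with attributes
    ``mean``, ``sd``, ``minimum``, ``maximum`` and optionally ``units`` /
    ``metal`` / ``stratum`` (a :class:`rpra.synthetic.ConcentrationSummary`
    or a DataFrame row).
    """
    mean = float(summary.mean)
    if mean <= 0:
        raise ValueError(
            f"cannot fit lognormal to summary with nonpositive mean {mean}"
        )
    if name is None:
        metal = getattr(summary, "metal", "conc")
        name = f"C_{metal}"
    return ParameterSpec(
        name=name,
        family="lognormal",
        mean=mean,
        sd=float(summary.sd),
        minimum=float(summary.minimum),
        maximum=float(summary.maximum),
        units=str(getattr(summary, "units", "")),
    )


def read_parameter_table(path) -> list[ParameterSpec]:
    """Read parameter specs from CSV with columns
    name, family, mean, sd, min, max, mode, units (extra columns ignored)."""
    df = pd.read_csv(path, comment="#")
    specs = []
    for row in df.itertuples(index=False):
        def _opt(value):
            return None if pd.isna(value) else float(value)

        specs.append(
            ParameterSpec(
                name=str(row.name),
                family=str(row.family),
                mean=float(row.mean),
                sd=0.0 if pd.isna(row.sd) else float(row.sd),
                minimum=_opt(getattr(row, "min")),
                maximum=_opt(getattr(row, "max")),
                mode=_opt(getattr(row, "mode")),
                units="" if pd.isna(row.units) else str(row.units),
            )
        )
    return specs
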