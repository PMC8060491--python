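"""Statistical kernels used throughout the toolkit.

Implements the two designs of two-tailed t-test reported in the study
(two-sample with pooled or Welch variance, and paired) and ordinary least
squares on log-transformed data for power-law exponent estimation.  The
statistics are computed from their closed-form definitions; two-tailed
p-values come from the regularized incomplete beta function,

    p = I_{df/(df+t^2)}(df/2, 1/2),

which is the exact tail integral of the t density.  No table lookups, no
delegation of the statistic itself to a stats library (library routines are
used only as independent oracles in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betainc

from .errors import DegenerateInputError, PairingError, ParameterError

__all__ = [
    "TTestResult",
    "GroupSummary",
    "GroupComparison",
    "t_test",
    "summarize_group",
    "OlsFit",
    "ols_loglog",
    "t_sf_two_tailed",
]


@dataclass(frozen=True)
class TTestResult:
    """A two-tailed t-test outcome."""

    t_statistic: float
    degrees_of_freedom: float
    p_two_tailed: float
    design: str  # "two-sample" | "paired"
    variance_assumption: str  # "pooled" | "welch" (paired: "pooled")

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_two_tailed <= 1.0):
            raise ParameterError(f"p-value outside [0, 1]: {self.p_two_tailed}")
        if self.degrees_of_freedom <= 0:
            raise ParameterError("degrees of freedom must be positive")


@dataclass(frozen=True)
class GroupSummary:
    name: str
    n: int
    mean: float
    sd: float
    sem: float


@dataclass(frozen=True)
class GroupComparison:
    """Per-group descriptive stats plus the t-test between the groups.

    ``sd``/``sem`` use the n−1 (sample) convention; reported spreads are
    SEM unless a caller states otherwise, matching the reporting convention
    of morphometric mean ± SEM tables.
    """

    group_a: GroupSummary
    group_b: GroupSummary
    test: TTestResult
    metric: str = ""
    spread_convention: str = "sem"


def _as_clean_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < 2:
        raise ParameterError(f"{name} needs at least 2 values, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ParameterError(f"{name} contains non-finite values")
    return arr


def t_sf_two_tailed(t: float, df: float) -> float:
    """Two-tailed p-value for a t statistic via the regularized incomplete beta."""
    if df <= 0:
        raise ParameterError("df must be positive")
    t = float(t)
    if t == 0.0:
        return 1.0
    x = df / (df + t * t)
    return float(betainc(df / 2.0, 0.5, x))


def t_test(
    a,
    b,
    design: str = "two-sample",
    variance_assumption: str = "pooled",
) -> TTestResult:
    """Two-tailed t-test between two numeric vectors.

    Parameters
    ----------
    design:
        ``"two-sample"`` for independent groups, ``"paired"`` for matched
        observations (requires equal lengths; reduces to a one-sample test
        on the differences).
    variance_assumption:
        ``"pooled"`` (classic Student) or ``"welch"``; ignored for paired.

    Zero-variance conventions: if all data are identical the test reports
    t = 0, p = 1; zero variance with unequal means is a degenerate input.
    """
    a = _as_clean_vector(a, "a")
    b = _as_clean_vector(b, "b")
    if design == "paired":
        if a.size != b.size:
            raise PairingError(f"paired design needs equal lengths ({a.size} vs {b.size})")
        d = a - b
        n = d.size
        sd = float(d.std(ddof=1))
        mean = float(d.mean())
        df = float(n - 1)
        if sd == 0.0:
            if mean == 0.0:
                return TTestResult(0.0, df, 1.0, "paired", "pooled")
            raise DegenerateInputError("zero variance of differences with non-zero mean")
        t = mean / (sd / np.sqrt(n))
        return TTestResult(float(t), df, t_sf_two_tailed(t, df), "paired", "pooled")

    if design != "two-sample":
        raise ParameterError(f"unknown design: {design!r}")
    na, nb = a.size, b.size
    va, vb = float(a.var(ddof=1)), float(b.var(ddof=1))
    diff = float(a.mean() - b.mean())
    if variance_assumption == "pooled":
        df = float(na + nb - 2)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se2 = sp2 * (1.0 / na + 1.0 / nb)
    elif variance_assumption == "welch":
        se2 = va / na + vb / nb
        if se2 > 0.0:
            df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        else:
            df = float(na + nb - 2)
    else:
        raise ParameterError(f"unknown variance assumption: {variance_assumption!r}")
    if se2 == 0.0:
        if diff == 0.0:
            return TTestResult(0.0, float(df), 1.0, "two-sample", variance_assumption)
        raise DegenerateInputError("zero pooled variance with unequal means")
    t = diff / np.sqrt(se2)
    return TTestResult(float(t), float(df), t_sf_two_tailed(t, df), "two-sample", variance_assumption)


def summarize_group(values, name: str = "") -> GroupSummary:
    v = _as_clean_vector(values, name or "group")
    sd = float(v.std(ddof=1))
    return GroupSummary(name=name, n=int(v.size), mean=float(v.mean()), sd=sd, sem=sd / float(np.sqrt(v.size)))


def compare_groups(
    a,
    b,
    names: tuple[str, str] = ("A", "B"),
    metric: str = "",
    design: str = "two-sample",
    variance_assumption: str = "pooled",
) -> GroupComparison:
    """Bundle per-group mean/SD/SEM with the requested t-test."""
    return GroupComparison(
        group_a=summarize_group(a, names[0]),
        group_b=summarize_group(b, names[1]),
        test=t_test(a, b, design=design, variance_assumption=variance_assumption),
        metric=metric,
    )


@dataclass(frozen=True)
class OlsFit:
    slope: float
    intercept: float
    slope_stderr: float
    r_squared: float
    n: int


def ols_loglog(x, y) -> OlsFit:
    """Least squares of log(y) on log(x); the slope is a power-law exponent.

    Both vectors must be strictly positive and of length >= 3.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ParameterError("x and y must have equal length")
    if x.size < 3:
        raise ParameterError("need at least 3 points for the fit")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ParameterError("non-finite values in fit input")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ParameterError("log-log fit requires strictly positive values")
    lx, ly = np.log(x), np.log(y)
    n = lx.size
    mx, my = lx.mean(), ly.mean()
    sxx = float(np.sum((lx - mx) ** 2))
    if sxx == 0.0:
        raise DegenerateInputError("all x values identical; slope undefined")
    sxy = float(np.sum((lx - mx) * (ly - my)))
    slope = sxy / sxx
    intercept = my - slope * mx
    resid = ly - (intercept + slope * lx)
    rss = float(np.sum(resid**2))
    tss = float(np.sum((ly - my) ** 2))
    r2 = 1.0 if tss == 0.0 else 1.0 - rss / tss
    stderr = np.sqrt(rss / (n - 2) / sxx) if n > 2 else float("nan")
    return OlsFit(float(slope), float(intercept), float(stderr), float(r2), int(n))
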