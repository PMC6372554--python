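"""Group-comparison and coupling statistics.

Two-sample t-tests (Welch by default), Pearson and Spearman correlations with
the t-approximation for p-values, summary-statistic entry points for all
three (so printed means/SDs or r values can be re-tested without raw data),
and iterative Grubbs outlier screening.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatResult",
    "two_sample_ttest",
    "ttest_from_summary",
    "pearson_corr",
    "pearson_from_summary",
    "spearman_corr",
    "spearman_from_summary",
    "detect_outliers",
    "OutlierResult",
]


@dataclass
class StatResult:
    """One test: estimate (mean difference or correlation), statistic,
    degrees of freedom, two-tailed p, per-group n, and bookkeeping flags."""

    name: str
    estimate: float
    statistic: float
    df: float
    p: float
    n: tuple[int, ...]
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.p) and not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "name": self.name, "estimate": self.estimate,
            "statistic": self.statistic, "df": self.df, "p": self.p,
            "n": list(self.n), **{f"flag_{k}": v for k, v in self.flags.items()},
        }


def _finite(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    return x[np.isfinite(x)]


def two_sample_ttest(a, b, *, welch: bool = True, name: str = "ttest") -> StatResult:
    """Two-tailed independent two-sample t-test (Welch unless ``welch=False``)."""
    a, b = _finite(a), _finite(b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return StatResult(name, 0.0, 0.0, float(len(a) + len(b) - 2), 1.0,
                              (len(a), len(b)), {"welch": welch,
                                                 "degenerate": True})
        raise ValueError("zero variance in both groups with unequal means")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return StatResult(
        name=name,
        estimate=float(a.mean() - b.mean()),
        statistic=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        n=(len(a), len(b)),
        flags={"welch": welch},
    )


def ttest_from_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    *, welch: bool = True, name: str = "ttest",
) -> StatResult:
    """The same test computed from printed summary statistics."""
    res = sps.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=not welch
    )
    if welch:
        va, vb = sd1**2 / n1, sd2**2 / n2
        df = (va + vb) ** 2 / (va**2 / (n1 - 1) + vb**2 / (n2 - 1))
    else:
        df = n1 + n2 - 2
    return StatResult(
        name=name, estimate=float(mean1 - mean2),
        statistic=float(res.statistic), df=float(df), p=float(res.pvalue),
        n=(n1, n2), flags={"welch": welch, "summary_input": True},
    )


def _r_to_p(r: float, n: int) -> tuple[float, float]:
    """t statistic and two-tailed p for a correlation via the t-approximation
    ``t = r * sqrt((n-2) / (1-r^2))`` on n-2 degrees of freedom."""
    df = n - 2
    if abs(r) >= 1.0:
        return float(np.inf) * np.sign(r), 0.0
    t = r * np.sqrt(df / (1.0 - r**2))
    return float(t), float(2.0 * sps.t.sf(abs(t), df))


def pearson_corr(x, y, *, name: str = "pearson") -> StatResult:
    x, y = np.asarray(x, float).ravel(), np.asarray(y, float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("constant input")
    r = float(sps.pearsonr(x, y).statistic)
    t, p = _r_to_p(r, n)
    return StatResult(name, r, t, float(n - 2), p, (n,), {})


def pearson_from_summary(r: float, n: int, *, name: str = "pearson") -> StatResult:
    if n < 3:
        raise ValueError("need n >= 3")
    t, p = _r_to_p(float(r), n)
    return StatResult(name, float(r), t, float(n - 2), p, (n,),
                      {"summary_input": True})


def spearman_corr(x, y, *, name: str = "spearman") -> StatResult:
    """Spearman rho (Pearson r of mid-ranks) with the t-approximation p."""
    x, y = np.asarray(x, float).ravel(), np.asarray(y, float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 pairs")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    if np.ptp(rx) == 0.0 or np.ptp(ry) == 0.0:
        raise ValueError("constant ranks")
    rho = float(sps.pearsonr(rx, ry).statistic)
    t, p = _r_to_p(rho, n)
    return StatResult(name, rho, t, float(n - 2), p, (n,), {})


def spearman_from_summary(rho: float, n: int, *, name: str = "spearman") -> StatResult:
    if n < 4:
        raise ValueError("need n >= 4")
    t, p = _r_to_p(float(rho), n)
    return StatResult(name, float(rho), t, float(n - 2), p, (n,),
                      {"summary_input": True})


@dataclass
class OutlierResult:
    flags: np.ndarray  # True where flagged as outlier
    cleaned: np.ndarray
    log: list[dict]


def _grubbs_critical(n: int, alpha: float) -> float:
    t = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def detect_outliers(values, *, alpha: float = 0.05,
                    max_fraction: float = 0.1) -> OutlierResult:
    """Iterative two-sided Grubbs screening at level ``alpha``.

    At most ``floor(n * max_fraction)`` points are removed; every removal is
    logged with its test statistic and critical value.
    """
    x = np.asarray(values, dtype=float).ravel()
    if len(x) < 3:
        raise ValueError("need at least 3 values")
    flags = np.zeros(len(x), dtype=bool)
    log: list[dict] = []
    max_removals = int(np.floor(len(x) * max_fraction))
    for _ in range(max_removals):
        active = np.flatnonzero(~flags)
        sub = x[active]
        if len(sub) < 3:
            break
        sd = sub.std(ddof=1)
        if sd == 0.0:
            break
        dev = np.abs(sub - sub.mean())
        idx = int(np.argmax(dev))
        g = dev[idx] / sd
        g_crit = _grubbs_critical(len(sub), alpha)
        if g <= g_crit:
            break
        flags[active[idx]] = True
        log.append({"index": int(active[idx]), "value": float(x[active[idx]]),
                    "G": float(g), "G_crit": float(g_crit)})
    return OutlierResult(flags=flags, cleaned=x[~flags], log=log)
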