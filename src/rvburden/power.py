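"""Effect-size estimation (Cohen's d) and two-sample t-test power projection.

Power is computed exactly through the noncentral t distribution: for a
one-sided level-alpha test with n subjects per group, the noncentrality is
delta = d * sqrt(n1*n2 / (n1+n2)) and power = P(T' > t_crit) with T'
noncentral t on n1+n2-2 degrees of freedom. A normal approximation is
provided for cross-checking only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class EffectSizeEstimate:
    d: float                # signed: (mean_case - mean_control) / pooled SD
    pooled_sd: float
    n_case: int
    n_control: int
    defined: bool = True    # False when pooled SD is zero


@dataclass(frozen=True)
class PowerResult:
    d: float
    n_per_group: int
    alpha: float
    sided: str              # "one" | "two"
    noncentrality: float
    power: float


def cohens_d(case_values: Sequence[float], control_values: Sequence[float]) -> EffectSizeEstimate:
    """Standardized mean difference with the df-weighted pooled SD."""
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two values per group")
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    sp = math.sqrt(sp2)
    if sp == 0.0:
        return EffectSizeEstimate(d=math.nan, pooled_sd=0.0, n_case=n1, n_control=n2, defined=False)
    return EffectSizeEstimate(
        d=float((x.mean() - y.mean()) / sp), pooled_sd=sp, n_case=n1, n_control=n2
    )


def power_two_sample_t(
    d: float, n_per_group: int, alpha: float = 0.05, sided: str = "one"
) -> PowerResult:
    """Exact power of the two-sample pooled-variance t test at effect size d."""
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if not 0.0 < alpha <= 0.5:
        raise ValueError("alpha must be in (0, 0.5]")
    if sided not in ("one", "two"):
        raise ValueError(f"sided must be 'one' or 'two', got {sided!r}")
    n1 = n2 = n_per_group
    df = n1 + n2 - 2
    ncp = d * math.sqrt(n1 * n2 / (n1 + n2))
    if sided == "one":
        t_crit = stats.t.isf(alpha, df)
        power = _nct_tail(t_crit, df, ncp, upper=True)
    else:
        t_crit = stats.t.isf(alpha / 2.0, df)
        power = _nct_tail(t_crit, df, ncp, upper=True) + _nct_tail(-t_crit, df, ncp, upper=False)
    return PowerResult(
        d=d, n_per_group=n_per_group, alpha=alpha, sided=sided,
        noncentrality=ncp, power=float(min(max(power, 0.0), 1.0)),
    )


def _nct_tail(t: float, df: float, ncp: float, upper: bool) -> float:
    """Noncentral-t tail probability, robust to scipy's NaN at extreme ncp
    (where the true tail mass is 0 or 1 to double precision)."""
    val = stats.nct.sf(t, df, ncp) if upper else stats.nct.cdf(t, df, ncp)
    if math.isnan(val):
        # far into the tail: the upper tail is ~1 iff the mass sits above t
        far_above = ncp > t
        val = float(far_above) if upper else float(not far_above)
    return float(val)


def power_normal_approx(
    d: float, n_per_group: int, alpha: float = 0.05, sided: str = "one"
) -> float:
    """Large-sample normal approximation to the same power (cross-check)."""
    ncp = d * math.sqrt(n_per_group / 2.0)
    if sided == "one":
        z = stats.norm.isf(alpha)
        return float(stats.norm.sf(z - ncp))
    z = stats.norm.isf(alpha / 2.0)
    return float(stats.norm.sf(z - ncp) + stats.norm.cdf(-z - ncp))


def power_table(
    effect_sizes: Iterable[tuple[str, float]],
    n_grid: Sequence[int],
    alpha: float = 0.05,
    sided: str = "one",
) -> pd.DataFrame:
    """Cross-product power projection: one row per (label, n) cell."""
    rows = []
    for label, d in effect_sizes:
        for n in n_grid:
            res = power_two_sample_t(d, n, alpha=alpha, sided=sided)
            rows.append(
                {"gene_set": label, "d": d, "n_per_group": n, "alpha": alpha,
                 "sided": sided, "power": res.power}
            )
    return pd.DataFrame(rows, columns=["gene_set", "d", "n_per_group", "alpha", "sided", "power"])


def simulate_power(
    d: float,
    n_per_group: int,
    alpha: float = 0.05,
    sided: str = "one",
    n_reps: int = 10_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Monte-Carlo rejection rate of the pooled t test on Gaussian data.

    Vectorised over replicates; serves as an independent check of the
    analytic noncentral-t computation.
    """
    rng = rng or np.random.default_rng()
    n = n_per_group
    x = rng.normal(d, 1.0, size=(n_reps, n))
    y = rng.normal(0.0, 1.0, size=(n_reps, n))
    df = 2 * n - 2
    sp2 = ((n - 1) * x.var(axis=1, ddof=1) + (n - 1) * y.var(axis=1, ddof=1)) / df
    t = (x.mean(axis=1) - y.mean(axis=1)) / np.sqrt(sp2 * (2.0 / n))
    if sided == "one":
        reject = t > stats.t.isf(alpha, df)
    else:
        reject = np.abs(t) > stats.t.isf(alpha / 2.0, df)
    return float(reject.mean())
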