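"""Exact distribution theory for the Pearson correlation test.

Everything here follows from the bivariate-normal sampling model.  Under the
null (population correlation rho = 0) the sample correlation r with ``df``
degrees of freedom (df = N - 2) has density

    f0(r | df) = (1 - r^2)^((df-2)/2) / B(1/2, df/2),   r in (-1, 1),

equivalently t = r * sqrt(df) / sqrt(1 - r^2) is Student-t with df degrees of
freedom.  Under rho != 0 the density of r is Hotelling's exact form (a Gauss
hypergeometric series); power and required sample size are computed by
integrating that density over the rejection region, with the Fisher-z normal
approximation available as a labelled cross-check only.

Sidedness convention: one-sided tests take the observed direction as the
hypothesized one, so the one-sided p is always half the two-sided p.  This is
an upper bound on significance, matching how mined significance claims are
audited.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, special, stats

from .records import Sidedness

__all__ = [
    "PowerQuery",
    "NullExpectation",
    "r_to_t",
    "exact_p",
    "critical_r",
    "null_density",
    "null_mean_abs_r",
    "expected_abs_r_nonsig",
    "nonnull_density",
    "power_at_n",
    "power_at_n_fisher",
    "required_n",
    "fisher_z",
    "inverse_fisher_z",
]


@dataclass(frozen=True)
class PowerQuery:
    """A required-sample-size question: effect size, level, target power."""

    r: float
    alpha: float = 0.05
    power: float = 0.8
    sidedness: Sidedness = Sidedness.TWO_SIDED

    def __post_init__(self) -> None:
        if not 0.0 < self.r < 1.0:
            raise ValueError(f"r={self.r} outside (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha={self.alpha} outside (0, 1)")
        if not 0.0 < self.power < 1.0:
            raise ValueError(f"power={self.power} outside (0, 1)")


@dataclass(frozen=True)
class NullExpectation:
    """Expected |r| among non-significant results if the null were true."""

    df: int
    alpha: float
    sidedness: Sidedness
    r_crit: float
    expected_abs_r_nonsig: float


def r_to_t(r: float, df: float) -> float:
    """t statistic of a correlation: t = r * sqrt(df) / sqrt(1 - r^2).

    |r| = 1 maps to signed infinity (p = 0 downstream).
    """
    if df < 1:
        raise ValueError(f"df={df} < 1")
    if abs(r) > 1:
        raise ValueError(f"|r|={abs(r)} > 1")
    if abs(r) == 1.0:
        return math.copysign(math.inf, r)
    return r * math.sqrt(df) / math.sqrt(1.0 - r * r)


def exact_p(r: float, df: float, sidedness: Sidedness = Sidedness.TWO_SIDED) -> float:
    """Exact p-value of a Pearson correlation from r and df.

    Two-sided: 2 * P(T_df >= |t|).  One-sided: P(T_df >= |t|), i.e. the
    observed direction is taken as the hypothesized one.
    """
    if df < 1:
        raise ValueError(f"df={df} < 1")
    t = r_to_t(r, df)
    if math.isinf(t):
        return 0.0
    tail = stats.t.sf(abs(t), df)
    return float(min(1.0, 2.0 * tail)) if sidedness is Sidedness.TWO_SIDED else float(tail)


def critical_r(df: float, alpha: float = 0.05, sidedness: Sidedness = Sidedness.TWO_SIDED) -> float:
    """Smallest |r| significant at level alpha for given df and sidedness.

    Inverts the t transform: r_crit = t_crit / sqrt(t_crit^2 + df).
    """
    if df < 1:
        raise ValueError(f"df={df} < 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha={alpha} outside (0, 1)")
    tail = alpha / 2.0 if sidedness is Sidedness.TWO_SIDED else alpha
    t_crit = stats.t.isf(tail, df)
    return float(t_crit / math.sqrt(t_crit * t_crit + df))


def null_density(r, df: float):
    """Density of r under rho = 0: (1 - r^2)^((df-2)/2) / B(1/2, df/2)."""
    if df < 1:
        raise ValueError(f"df={df} < 1")
    r = np.asarray(r, dtype=float)
    log_norm = special.betaln(0.5, df / 2.0)
    out = np.exp((df - 2.0) / 2.0 * np.log1p(-np.square(r)) - log_norm)
    return out if out.ndim else float(out)


def null_mean_abs_r(df: float) -> float:
    """E[|r|] under the null: 2 / (df * B(1/2, df/2)) (closed form)."""
    if df < 1:
        raise ValueError(f"df={df} < 1")
    return float(2.0 / (df * np.exp(special.betaln(0.5, df / 2.0))))


def expected_abs_r_nonsig(
    df: int,
    alpha: float = 0.05,
    sidedness: Sidedness = Sidedness.TWO_SIDED,
    normalized: bool = True,
) -> NullExpectation:
    """Expected |r| of a *non-significant* result if the null were true.

    Integrates u * 2 f0(u | df) from 0 to the critical boundary r_crit;
    with ``normalized=True`` (default) the integral is divided by
    P(|r| < r_crit | H0), giving the conditional mean of |r| given
    non-significance.  The antiderivative is closed-form:

        int_0^c u (1-u^2)^((df-2)/2) du = (1 - (1-c^2)^(df/2)) / df.
    """
    c = critical_r(df, alpha, sidedness)
    log_beta = special.betaln(0.5, df / 2.0)
    partial = 2.0 * (1.0 - (1.0 - c * c) ** (df / 2.0)) / (df * np.exp(log_beta))
    if normalized:
        prob_nonsig = 1.0 - exact_p(c, df, Sidedness.TWO_SIDED)
        value = float(partial / prob_nonsig)
    else:
        value = float(partial)
    return NullExpectation(
        df=df, alpha=alpha, sidedness=sidedness, r_crit=c, expected_abs_r_nonsig=value
    )


def nonnull_density(r, rho: float, n: int):
    """Hotelling's exact density of the sample correlation r.

    For n bivariate-normal pairs with population correlation rho:

        f(r) = (n-2) G(n-1) (1-rho^2)^((n-1)/2) (1-r^2)^((n-4)/2)
               / (sqrt(2 pi) G(n-1/2) (1-rho r)^(n-3/2))
               * 2F1(1/2, 1/2; (2n-1)/2; (rho r + 1)/2)

    with G the gamma function.  Evaluated in log space for numerical range.
    """
    if n < 4:
        raise ValueError(f"n={n} < 4")
    if not -1.0 < rho < 1.0:
        raise ValueError(f"rho={rho} outside (-1, 1)")
    r = np.asarray(r, dtype=float)
    log_const = (
        math.log(n - 2)
        + special.gammaln(n - 1)
        - 0.5 * math.log(2.0 * math.pi)
        - special.gammaln(n - 0.5)
        + (n - 1) / 2.0 * math.log1p(-rho * rho)
    )
    with np.errstate(divide="ignore"):
        log_kernel = (n - 4) / 2.0 * np.log1p(-np.square(r)) - (n - 1.5) * np.log1p(-rho * r)
    hyp = special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1.0) / 2.0)
    out = np.exp(log_const + log_kernel) * hyp
    return out if out.ndim else float(out)


def power_at_n(
    r: float,
    n: int,
    alpha: float = 0.05,
    sidedness: Sidedness = Sidedness.TWO_SIDED,
) -> float:
    """Exact power of the correlation test at sample size n.

    Probability that the sample correlation of ``n`` bivariate-normal pairs
    with population correlation ``r`` lands in the rejection region of the
    level-``alpha`` test.  Two-sided: both tails |r| >= r_crit; one-sided:
    the tail in the direction of the effect.
    """
    if n < 4:
        raise ValueError(f"n={n} < 4")
    if not 0.0 < r < 1.0:
        raise ValueError(f"r={r} outside (0, 1)")
    c = critical_r(n - 2, alpha, sidedness)

    def dens(x):
        return nonnull_density(x, r, n)

    upper, _ = integrate.quad(dens, c, 1.0, limit=200)
    if sidedness is Sidedness.TWO_SIDED:
        lower, _ = integrate.quad(dens, -1.0, -c, limit=200)
    else:
        lower = 0.0
    return float(min(1.0, upper + lower))


def power_at_n_fisher(
    r: float,
    n: int,
    alpha: float = 0.05,
    sidedness: Sidedness = Sidedness.TWO_SIDED,
) -> float:
    """Fisher-z approximate power (cross-check; may differ from exact by ~1-2 N)."""
    if n < 4:
        raise ValueError(f"n={n} < 4")
    zr = math.atanh(r)
    se = 1.0 / math.sqrt(n - 3)
    if sidedness is Sidedness.TWO_SIDED:
        z_crit = stats.norm.isf(alpha / 2.0)
        return float(
            stats.norm.sf(z_crit - zr / se) + stats.norm.cdf(-z_crit - zr / se)
        )
    z_crit = stats.norm.isf(alpha)
    return float(stats.norm.sf(z_crit - zr / se))


def required_n(query: PowerQuery, n_cap: int = 1_000_000, method: str = "exact") -> int:
    """Smallest integer N with power_at_n(r, N, alpha, sidedness) >= power.

    Integer bisection on the (monotone in N) power curve; no fractional
    rounding is involved.  Raises if the target power is unattainable below
    ``n_cap``.
    """
    power_fn = power_at_n if method == "exact" else power_at_n_fisher
    lo, hi = 4, 8
    if power_fn(query.r, lo, query.alpha, query.sidedness) >= query.power:
        return lo
    while power_fn(query.r, hi, query.alpha, query.sidedness) < query.power:
        lo = hi
        hi *= 2
        if hi > n_cap:
            raise ValueError(
                f"power {query.power} unattainable for r={query.r} below N cap {n_cap}"
            )
    # invariant: power(lo) < target <= power(hi)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_fn(query.r, mid, query.alpha, query.sidedness) >= query.power:
            hi = mid
        else:
            lo = mid
    return hi


def fisher_z(r: float) -> float:
    """Fisher's variance-stabilizing transform z = atanh(r)."""
    if abs(r) >= 1.0:
        raise ValueError(f"|r|={abs(r)} >= 1")
    return math.atanh(r)


def inverse_fisher_z(z: float) -> float:
    """Inverse of :func:`fisher_z` (tanh)."""
    return math.tanh(z)
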