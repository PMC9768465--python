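"""Distributional summaries of mined correlation records.

Quartiles of |r| (overall and stratified), cumulative quartile curves by
maximum degrees of freedom, rolling block medians along the df axis,
bootstrap confidence intervals for medians (the "standard normal interval"
construction), and yearly Spearman associations between |r| and df.

Quantiles throughout use linear interpolation of order statistics at
position 1 + (n-1)p (numpy's default, R's type 7), and summaries are never
weighted by sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .records import Location, RecordSet, SigLabel, StatRecord
from .stats import fisher_z, inverse_fisher_z

__all__ = [
    "PercentileSummary",
    "CumulativeCurve",
    "BootstrapCI",
    "YearlyAssociation",
    "percentile_summary",
    "cumulative_percentiles_by_max_df",
    "rolling_group_medians",
    "bootstrap_median_ci",
    "spearman_r_vs_df_by_year",
    "stratified_summary",
]


@dataclass(frozen=True)
class PercentileSummary:
    """25th/50th/75th percentiles of a batch of values (|r| or N)."""

    n: int
    q25: float | None
    q50: float | None
    q75: float | None
    stratum: str = "all"

    @property
    def is_empty(self) -> bool:
        return self.n == 0


@dataclass
class CumulativeCurve:
    """Quartiles of |r| over all records with df <= df_max, per distinct df."""

    rows: list[tuple[int, int, float, float, float]] = field(default_factory=list)
    # each row: (df_max, n_included, q25, q50, q75)

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class BootstrapCI:
    estimate: float
    lower: float
    upper: float
    reps: int
    method: str
    seed: int


@dataclass(frozen=True)
class YearlyAssociation:
    year: int
    n_records_with_df: int
    rho: float | None
    ci_lower: float | None
    ci_upper: float | None


def percentile_summary(values: Sequence[float], stratum: str = "all") -> PercentileSummary:
    """Quartiles by linear interpolation of order statistics at 1 + (n-1)p.

    An empty batch yields an explicit empty-stratum marker (n=0, quartiles
    None), never NaN quartiles.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        return PercentileSummary(n=0, q25=None, q50=None, q75=None, stratum=stratum)
    q25, q50, q75 = np.quantile(arr, [0.25, 0.5, 0.75])
    return PercentileSummary(n=int(arr.size), q25=float(q25), q50=float(q50), q75=float(q75), stratum=stratum)


def cumulative_percentiles_by_max_df(record_set: RecordSet) -> CumulativeCurve:
    """Quartiles of |r| as a function of the maximum df included.

    Records lacking both df and n are excluded.  For each distinct df value d
    (ascending) the row holds the quartiles of |r| over all records with
    df <= d; the final row therefore equals the overall summary of the
    df-bearing records.
    """
    pairs = [
        (rec.effective_df(), rec.abs_r)
        for rec in record_set
        if rec.effective_df() is not None
    ]
    if not pairs:
        return CumulativeCurve(rows=[])
    pairs.sort(key=lambda p: p[0])
    dfs = np.asarray([p[0] for p in pairs])
    abs_r = np.asarray([p[1] for p in pairs])
    rows = []
    for d in np.unique(dfs):
        mask = dfs <= d
        q25, q50, q75 = np.quantile(abs_r[mask], [0.25, 0.5, 0.75])
        rows.append((int(d), int(mask.sum()), float(q25), float(q50), float(q75)))
    return CumulativeCurve(rows=rows)


def rolling_group_medians(
    record_set: RecordSet, group_size: int
) -> list[tuple[float, float]]:
    """Block medians of |r| along the df axis.

    Records (df-bearing only) are sorted by df ascending and cut into
    consecutive non-overlapping blocks of ``group_size`` (the last block may
    be smaller); each block contributes (median df, median |r|).
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    pairs = sorted(
        (
            (rec.effective_df(), rec.abs_r)
            for rec in record_set
            if rec.effective_df() is not None
        ),
        key=lambda p: p[0],
    )
    points = []
    for start in range(0, len(pairs), group_size):
        block = pairs[start : start + group_size]
        dfs = [p[0] for p in block]
        rs = [p[1] for p in block]
        points.append((float(np.median(dfs)), float(np.median(rs))))
    return points


def bootstrap_median_ci(
    values: Sequence[float],
    reps: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
) -> BootstrapCI:
    """Normal-interval bootstrap CI for the median.

    Resamples with replacement ``reps`` times; the interval is the
    bias-corrected center 2*m - mean(m*) plus/minus z_{(1+level)/2} times the
    bootstrap standard deviation, where m is the sample median and m* the
    bootstrap medians.  Deterministic given the seed.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, arr.size, size=(reps, arr.size))
    boot_medians = np.median(arr[idx], axis=1)
    estimate = float(np.median(arr))
    center = 2.0 * estimate - float(boot_medians.mean())
    sd = float(boot_medians.std(ddof=1))
    z = float(sps.norm.ppf(0.5 + level / 2.0))
    return BootstrapCI(
        estimate=estimate,
        lower=center - z * sd,
        upper=center + z * sd,
        reps=reps,
        method="normal",
        seed=seed,
    )


def spearman_r_vs_df_by_year(
    record_set: RecordSet,
    min_records: int = 10,
    level: float = 0.95,
) -> list[YearlyAssociation]:
    """Spearman rho between |r| and df for each publication year.

    Ties get average ranks (scipy's convention).  The CI is the Fisher-z
    normal approximation with SE = 1/sqrt(n-3).  Years with fewer than
    ``min_records`` df-bearing records are emitted with rho absent.
    """
    by_year: dict[int, list[tuple[float, int]]] = {}
    for rec in record_set:
        d = rec.effective_df()
        if rec.year is None or d is None:
            continue
        by_year.setdefault(rec.year, []).append((rec.abs_r, d))

    out = []
    z_mult = float(sps.norm.ppf(0.5 + level / 2.0))
    for year in sorted(by_year):
        pairs = by_year[year]
        n = len(pairs)
        if n < min_records:
            out.append(YearlyAssociation(year, n, None, None, None))
            continue
        abs_r = [p[0] for p in pairs]
        dfs = [p[1] for p in pairs]
        if len(set(abs_r)) < 2 or len(set(dfs)) < 2:
            # constant input: rank correlation undefined
            out.append(YearlyAssociation(year, n, None, None, None))
            continue
        rho = float(sps.spearmanr(abs_r, dfs).statistic)
        if abs(rho) >= 1.0 or n <= 3:
            lo = hi = rho
        else:
            z = fisher_z(rho)
            half = z_mult / np.sqrt(n - 3)
            lo, hi = inverse_fisher_z(z - half), inverse_fisher_z(z + half)
        out.append(YearlyAssociation(year, n, rho, float(lo), float(hi)))
    return out


_STRATA_FIELDS = ("year", "subfield", "journal", "sig_label", "location")


def _stratum_key(rec: StatRecord, strata: Sequence[str]) -> str:
    parts = []
    for name in strata:
        value = getattr(rec, name)
        if value is None:
            parts.append(f"{name}=unknown")
        elif hasattr(value, "value"):
            parts.append(f"{name}={value.value}")
        else:
            parts.append(f"{name}={value}")
    return ",".join(parts) if parts else "all"


def stratified_summary(
    record_set: RecordSet,
    strata: Sequence[str] = (),
) -> dict[str, dict]:
    """Per-stratum quartiles of |r| and of N, plus significance proportions.

    ``strata`` is a subset of {year, subfield, journal, sig_label, location};
    records with a missing stratum value fall into an "unknown" stratum.
    Returns a mapping from stratum key to a block with the |r| summary, the
    N summary, the record count, and the proportion of each significance
    label within the stratum.
    """
    for name in strata:
        if name not in _STRATA_FIELDS:
            raise ValueError(f"unknown stratum field {name!r}")
    groups: dict[str, list[StatRecord]] = {}
    for rec in record_set:
        groups.setdefault(_stratum_key(rec, strata), []).append(rec)

    out: dict[str, dict] = {}
    for key in sorted(groups):
        recs = groups[key]
        abs_r = [rec.abs_r for rec in recs]
        n_values = [rec.n for rec in recs if rec.n is not None]
        label_counts = {label.value: 0 for label in SigLabel}
        for rec in recs:
            label_counts[rec.sig_label.value] += 1
        total = len(recs)
        out[key] = {
            "n_records": total,
            "abs_r": percentile_summary(abs_r, stratum=key),
            "sample_size": percentile_summary(n_values, stratum=key),
            "sig_counts": label_counts,
            "sig_proportions": {k: v / total for k, v in label_counts.items()},
        }
    return out
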