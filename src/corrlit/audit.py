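"""Auditing reported significance claims against exact critical boundaries.

Each record's claimed significance status is compared with the exact
critical |r| for its degrees of freedom: a reportedly significant r below
the two-sided boundary, or a reportedly non-significant r at or above it,
is flagged as a *suspect* (never an "error" — legitimate multiplicity
adjustments can move an author's own boundary).  Significance means
p <= alpha, so |r| exactly at the boundary counts as significant.

Records whose significance was never specified are resolved by recomputing
the exact p-value from r and df under both sidedness conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .records import AnalysisConfig, Comparator, Location, RecordSet, SigLabel, StatRecord
from .stats import critical_r, exact_p
from .records import Sidedness

__all__ = [
    "ConsistencyStatus",
    "ConsistencyLabel",
    "AuditReport",
    "classify_record",
    "resolve_unspecified",
    "audit_summary",
]


class ConsistencyStatus(Enum):
    CONSISTENT_SIG = "CONSISTENT_SIG"
    CONSISTENT_NONSIG = "CONSISTENT_NONSIG"
    TOO_SMALL_FOR_SIG = "TOO_SMALL_FOR_SIG"
    TOO_LARGE_FOR_NONSIG = "TOO_LARGE_FOR_NONSIG"
    UNRESOLVABLE = "UNRESOLVABLE"
    UNSPECIFIED = "UNSPECIFIED"


@dataclass(frozen=True)
class ConsistencyLabel:
    """Audit outcome for one record, with the boundary it was judged against."""

    status: ConsistencyStatus
    df: int | None = None
    r_crit_two_sided: float | None = None
    r_crit_one_sided: float | None = None


@dataclass
class AuditReport:
    """Corpus-level audit tallies; label counts partition the record set."""

    n_records: int
    label_counts: dict[str, int]
    label_proportions: dict[str, float]
    sig_proportions_overall: dict[str, float]
    sig_proportions_by_location: dict[str, dict[str, float]]
    unspecified_significant_two_sided: int
    unspecified_significant_one_sided: int
    n_unspecified: int
    n_zero_r: int
    per_record: list[tuple[str, ConsistencyLabel]] = field(default_factory=list)


def _effective_sig_label(rec: StatRecord, alpha: float = 0.05) -> SigLabel:
    """The significance claim carried by a record.

    A bare "p < v" report with v <= alpha and no explicit label is itself a
    significance claim and is audited as SIGNIFICANT.
    """
    if rec.sig_label is not SigLabel.UNSPECIFIED:
        return rec.sig_label
    if rec.p_report is not None and rec.p_report.comparator is Comparator.LT and rec.p_report.value <= alpha:
        return SigLabel.SIGNIFICANT
    return SigLabel.UNSPECIFIED


def classify_record(rec: StatRecord, cfg: AnalysisConfig = AnalysisConfig()) -> ConsistencyLabel:
    """Judge one record's significance claim against the exact boundary.

    Uses df as reported, else n - 2.  The two-sided critical |r| at
    cfg.alpha is the audit criterion; the one-sided boundary is recorded
    alongside for context.  Records lacking both n and df are UNRESOLVABLE.
    """
    df = rec.effective_df()
    label = _effective_sig_label(rec, cfg.alpha)
    if label is SigLabel.UNSPECIFIED:
        if df is None:
            return ConsistencyLabel(ConsistencyStatus.UNSPECIFIED)
        return ConsistencyLabel(
            ConsistencyStatus.UNSPECIFIED,
            df=df,
            r_crit_two_sided=critical_r(df, cfg.alpha, Sidedness.TWO_SIDED),
            r_crit_one_sided=critical_r(df, cfg.alpha, Sidedness.ONE_SIDED),
        )
    if df is None or df < 1:
        return ConsistencyLabel(ConsistencyStatus.UNRESOLVABLE)

    r_two = critical_r(df, cfg.alpha, Sidedness.TWO_SIDED)
    r_one = critical_r(df, cfg.alpha, Sidedness.ONE_SIDED)
    if label is SigLabel.SIGNIFICANT:
        status = (
            ConsistencyStatus.CONSISTENT_SIG
            if rec.abs_r >= r_two
            else ConsistencyStatus.TOO_SMALL_FOR_SIG
        )
    else:
        status = (
            ConsistencyStatus.TOO_LARGE_FOR_NONSIG
            if rec.abs_r >= r_two
            else ConsistencyStatus.CONSISTENT_NONSIG
        )
    return ConsistencyLabel(status, df=df, r_crit_two_sided=r_two, r_crit_one_sided=r_one)


def resolve_unspecified(
    record_set: RecordSet, cfg: AnalysisConfig = AnalysisConfig()
) -> tuple[int, int, int]:
    """Recompute significance for records reported without a p-value or label.

    Returns (count significant two-sided, count significant one-sided,
    total unspecified).  The one-sided count is never smaller than the
    two-sided count (one-sided p is half the two-sided p).
    """
    n_unspecified = 0
    sig_two = 0
    sig_one = 0
    for rec in record_set:
        if _effective_sig_label(rec, cfg.alpha) is not SigLabel.UNSPECIFIED:
            continue
        n_unspecified += 1
        df = rec.effective_df()
        if df is None or df < 1:
            continue
        if exact_p(rec.r, df, Sidedness.TWO_SIDED) <= cfg.alpha:
            sig_two += 1
        if exact_p(rec.r, df, Sidedness.ONE_SIDED) <= cfg.alpha:
            sig_one += 1
    return sig_two, sig_one, n_unspecified


def audit_summary(
    record_set: RecordSet, cfg: AnalysisConfig = AnalysisConfig()
) -> AuditReport:
    """Full audit of a record set: labels, proportions, unspecified resolution."""
    per_record = [(rec.record_id, classify_record(rec, cfg)) for rec in record_set]
    label_counts = {status.value: 0 for status in ConsistencyStatus}
    for _, label in per_record:
        label_counts[label.status.value] += 1

    n = len(record_set)
    sig_counts = {label.value: 0 for label in SigLabel}
    by_location: dict[str, dict[str, int]] = {}
    n_zero = 0
    for rec in record_set:
        label = _effective_sig_label(rec, cfg.alpha)
        sig_counts[label.value] += 1
        loc = rec.location.value
        by_location.setdefault(loc, {l.value: 0 for l in SigLabel})[label.value] += 1
        if rec.r == 0.0:
            n_zero += 1

    sig_two, sig_one, n_unspec = resolve_unspecified(record_set, cfg)
    return AuditReport(
        n_records=n,
        label_counts=label_counts,
        label_proportions={k: (v / n if n else 0.0) for k, v in label_counts.items()},
        sig_proportions_overall={k: (v / n if n else 0.0) for k, v in sig_counts.items()},
        sig_proportions_by_location={
            loc: {k: v / total for k, v in counts.items()}
            for loc, counts in by_location.items()
            if (total := sum(counts.values()))
        },
        unspecified_significant_two_sided=sig_two,
        unspecified_significant_one_sided=sig_one,
        n_unspecified=n_unspec,
        n_zero_r=n_zero,
        per_record=per_record,
    )
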