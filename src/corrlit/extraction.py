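"""Mining correlation reports ("r(df) = x, p = y") from plain article text.

The miner finds every standalone lowercase ``r`` — optionally followed by a
parenthesized degrees-of-freedom token — that is followed by ``=``, ignoring
ASCII spaces between ``r``, ``(``, ``)`` and ``=``.  From each match it takes
a window of at most 56 characters starting at the ``r`` and parses the
correlation value, the degrees of freedom and any trailing p-value report.

Two deliberate fidelity choices shape the miss profile:

* the window terminates at a newline (a line break inside a report defeats
  the parse) unless ``join_lines`` is enabled;
* ``r`` followed by a letter, digit or underscore (``r_extraversion``,
  ``r2``, regression ``R``) is never a candidate.

Sign handling: Unicode minus/dash variants are mapped to ASCII ``-`` before
matching (PDF extraction mangles minus signs notoriously), and the default
*strict-absolute* mode discards signs entirely when building records.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .records import (
    Comparator,
    Location,
    PValueReport,
    RecordSet,
    SigLabel,
    StatRecord,
)
from .simulate import AnnotatedDocument

__all__ = [
    "ExtractionHit",
    "RecallReport",
    "WINDOW_LENGTH",
    "find_candidates",
    "parse_hit",
    "extract_document",
    "validate_extraction",
]

WINDOW_LENGTH = 56

# Unicode minus/dash look-alikes that PDF text extraction produces for "-"
_MINUS_VARIANTS = dict.fromkeys(map(ord, "−‐‑‒–—"), "-")

# standalone lowercase r, optional parenthesized token, then '='
# (ASCII spaces between the tokens are ignored; newline is not a separator)
_CANDIDATE = re.compile(r"(?<![A-Za-z0-9_])r *(?:\(([^()\n]*)\) *)?=")

_NUMBER = r"[+-]?(?:\d+\.\d*|\.\d+|\d+)"
_R_VALUE = re.compile(rf" *({_NUMBER})")  # anchored right after the candidate "="
_P_REPORT = re.compile(rf"\bp *([=<>≤]) *({_NUMBER})")
_INT = re.compile(r"^\d+$")


@dataclass(frozen=True)
class ExtractionHit:
    """One candidate correlation report found in text."""

    doc_id: str
    match_offset: int  # 0-based index of the matched "r" in the document
    window: str  # raw extracted span, <= 56 characters
    parsed: StatRecord | None = None
    reject_reason: str | None = None

    def __post_init__(self) -> None:
        if len(self.window) > WINDOW_LENGTH:
            raise ValueError("window exceeds 56 characters")
        if self.parsed is not None and self.reject_reason is not None:
            raise ValueError("parsed and reject_reason are mutually exclusive")


@dataclass
class RecallReport:
    """Extraction performance against an annotated corpus."""

    n_truth: int
    n_detected: int
    n_false_positive: int
    recall: float
    miss_breakdown: dict[str, int] = field(default_factory=dict)


def _normalize(text: str) -> str:
    """NFKC-normalize and map minus-sign variants to ASCII; length may change
    only through NFKC on non-normalized input (annotated corpora are NFKC)."""
    return unicodedata.normalize("NFKC", text).translate(_MINUS_VARIANTS)


def find_candidates(text: str, doc_id: str = "doc", join_lines: bool = False) -> list[ExtractionHit]:
    """Locate every standalone "r [(df)] =" pattern in the text.

    Returns unparsed hits carrying the <= 56-character window starting at the
    "r".  By default the window is truncated at the first newline, so a line
    break inside a report leaves no value to parse.
    """
    text = _normalize(text)
    hits = []
    for match in _CANDIDATE.finditer(text):
        start = match.start()
        window = text[start : start + WINDOW_LENGTH]
        if join_lines:
            window = window.replace("\n", " ")
        else:
            window = window.split("\n", 1)[0]
        hits.append(ExtractionHit(doc_id=doc_id, match_offset=start, window=window))
    return hits


def parse_hit(hit: ExtractionHit) -> ExtractionHit:
    """Parse a candidate window into a record, or reject it with a reason.

    The correlation is the first numeric token after "=" (optional sign,
    leading-dot decimals accepted); values outside [-1, 1] are rejected.  A
    parenthesized non-negative integer becomes df; a following "p" token with
    a comparator and a value in [0, 1] becomes the p-value report.  Absent
    df/p simply leave those fields absent.
    """
    window = _normalize(hit.window)  # idempotent on pipeline-produced hits
    candidate = _CANDIDATE.match(window)
    value_match = _R_VALUE.match(window, candidate.end()) if candidate else None
    if value_match is None:
        return replace(hit, reject_reason="no_value")
    r = float(value_match.group(1))
    if not -1.0 <= r <= 1.0:
        return replace(hit, reject_reason="out_of_range")

    df = None
    if candidate is not None and candidate.group(1) is not None:
        token = candidate.group(1).strip()
        if _INT.match(token):
            df = int(token)  # non-integers (e.g. "34.5") store no df, keep r

    p_report = None
    p_match = _P_REPORT.search(window, value_match.end())
    if p_match is not None:
        symbol, value_text = p_match.groups()
        value = float(value_text)
        if 0.0 <= value <= 1.0:
            comparator = {
                "=": Comparator.EQ,
                "<": Comparator.LT,
                ">": Comparator.GT,
                "≤": Comparator.LT,  # "p <= x" coded as LT
            }[symbol]
            p_report = PValueReport(comparator, value)

    record = StatRecord(
        record_id=f"{hit.doc_id}@{hit.match_offset}",
        r=r,
        df=df,
        p_report=p_report,
        sig_label=SigLabel.UNSPECIFIED,
        location=Location.TEXT,
        study_id=hit.doc_id,
    )
    return replace(hit, parsed=record)


def extract_document(
    text: str,
    doc_id: str = "doc",
    strict_absolute: bool = True,
    join_lines: bool = False,
) -> RecordSet:
    """Mine all correlation reports from one document, in document order.

    ``strict_absolute`` (default) discards signs — mined records carry |r| —
    because PDF character-coding corruption makes mined signs unreliable.
    Extraction is a pure function of the text.
    """
    records = []
    for hit in find_candidates(text, doc_id=doc_id, join_lines=join_lines):
        parsed_hit = parse_hit(hit)
        if parsed_hit.parsed is None:
            continue
        rec = parsed_hit.parsed
        if strict_absolute and rec.r < 0:
            rec = replace(rec, r=abs(rec.r))
        records.append(rec)
    return RecordSet(records=records, provenance=f"extracted:{doc_id}")


def validate_extraction(
    corpus: Sequence[AnnotatedDocument],
    offset_tolerance: int = 2,
    join_lines: bool = False,
) -> RecallReport:
    """Score extraction against an annotated corpus.

    A truth record counts as detected when some parsed hit sits within
    ``offset_tolerance`` characters of the truth offset and its |r| equals
    the truth |r| to two decimals.  Unmatched parsed hits are false
    positives; misses are broken down by format variant.
    """
    n_truth = 0
    n_detected = 0
    n_false_positive = 0
    misses: dict[str, int] = {}

    for doc in corpus:
        parsed = []
        for hit in find_candidates(doc.text, doc_id=doc.doc_id, join_lines=join_lines):
            parsed_hit = parse_hit(hit)
            if parsed_hit.parsed is not None:
                parsed.append(parsed_hit)
        used = [False] * len(parsed)
        for offset, truth_rec, variant in doc.truth:
            n_truth += 1
            found = False
            for i, hit in enumerate(parsed):
                if used[i]:
                    continue
                if (
                    abs(hit.match_offset - offset) <= offset_tolerance
                    and abs(round(hit.parsed.abs_r, 2) - round(abs(truth_rec.r), 2)) < 5e-3
                ):
                    used[i] = True
                    found = True
                    break
            if found:
                n_detected += 1
            else:
                misses[variant] = misses.get(variant, 0) + 1
        n_false_positive += used.count(False)

    recall = n_detected / n_truth if n_truth else 0.0
    return RecallReport(
        n_truth=n_truth,
        n_detected=n_detected,
        n_false_positive=n_false_positive,
        recall=recall,
        miss_breakdown=misses,
    )
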