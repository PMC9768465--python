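"""Synthetic literature generator with known ground truth.

Emulates the statistical structure of a published correlational literature:
studies draw a sample size N from a heavy-tailed (log-normal) distribution,
report a batch of correlations whose population values are a mixture of
exact nulls (rho = 0, share ``null_fraction``) and non-null effects
(|rho| ~ Beta, random sign), and each observed r is the sample correlation of
N simulated bivariate-normal pairs.  Reporting behaviour is then layered on
top: significant results are preferentially placed in running text rather
than tables (a multiplicative odds model), a small fraction of significance
labels are flipped (misreporting), and a small fraction are left unspecified.

:func:`render_corpus` serializes text-placed records into pseudo-article
sentences in canonical and adversarial notation ("r(34) = .52, p < .01",
line-broken reports, subscripted symbols, verbal descriptions), recording
character-exact ground truth for extraction-recall evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .records import (
    Comparator,
    Location,
    PValueReport,
    RecordSet,
    SigLabel,
    StatRecord,
)
from .stats import exact_p

__all__ = [
    "GeneratorConfig",
    "GeneratorTruth",
    "AnnotatedDocument",
    "FORMAT_VARIANTS",
    "DEFAULT_VARIANT_MIX",
    "sample_observed_r",
    "generate_records",
    "render_corpus",
]

# Log-normal sigma for N: least-squares fit (in log space) to sample-size
# quartiles 140 / 230 / 564; a two-parameter log-normal cannot match the
# printed asymmetry exactly, so both quartile residuals are balanced.
_DEFAULT_N_SIGMA = math.log(564.0 / 140.0) / (2.0 * 0.6744897501960817)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition knobs for the synthetic literature.

    Defaults are calibrated to the reference corpus: median sample size 230
    with quartiles ~140/564, median 26 correlations per study, ~3% of records
    without a specified significance status, ~6% of records in text with
    significant results over-represented there (83% significant in text vs
    59% in tables at ~58% significant overall).
    """

    n_studies: int = 200
    records_per_study_median: float = 26.0
    records_per_study_sigma: float = 1.0
    sample_size_median: float = 230.0
    sample_size_sigma: float = _DEFAULT_N_SIGMA
    null_fraction: float = 0.1
    effect_beta_a: float = 1.2
    effect_beta_b: float = 5.0
    text_emphasis_odds: float = 3.8
    base_text_prob: float = 0.03
    misreport_rate: float = 0.005
    unspecified_rate: float = 0.03
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("null_fraction", "base_text_prob", "misreport_rate", "unspecified_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        if self.text_emphasis_odds <= 0:
            raise ValueError("text_emphasis_odds must be > 0")
        if self.n_studies < 1:
            raise ValueError("n_studies must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha={self.alpha} outside (0, 1)")


@dataclass
class GeneratorTruth:
    """Per-record ground truth retained alongside a generated RecordSet."""

    true_rho: np.ndarray
    exact_p_two_sided: np.ndarray
    true_significant: np.ndarray  # label before misreporting/unspecified
    true_location: np.ndarray  # placement before any label noise ("TEXT"/"TABLE")
    flipped: np.ndarray  # bool: sig_label was inverted by misreporting
    unspecified: np.ndarray  # bool: sig_label was blanked
    abs_r_quartiles: tuple[float, float, float]
    proportion_significant: float


@dataclass
class AnnotatedDocument:
    """Pseudo-article text plus character-exact extraction ground truth."""

    doc_id: str
    text: str
    truth: list[tuple[int, StatRecord, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for offset, _, variant in self.truth:
            if not 0 <= offset < max(1, len(self.text)):
                raise ValueError(f"truth offset {offset} outside document")
            if variant not in FORMAT_VARIANTS:
                raise ValueError(f"unknown format variant {variant!r}")


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_observed_r(
    rho: float,
    n: int,
    seed: int | np.random.Generator = 0,
    size: int = 1,
    method: str = "pairs",
) -> float | np.ndarray:
    """Draw sample Pearson correlations for n pairs with population rho.

    ``method="pairs"`` (default) simulates n bivariate-normal observations
    and computes their correlation — unambiguous data-level ground truth.
    ``method="exact"`` draws from the exact sampling distribution in O(1)
    per draw via the sufficient-statistic decomposition
    u = rho*sqrt(W1) + sqrt(1-rho^2)*Z,  r = u / sqrt(u^2 + (1-rho^2)*W2)
    with W1 ~ chi2(n-1), Z ~ N(0,1), W2 ~ chi2(n-2); both methods agree in
    distribution.

    Returns a scalar when ``size == 1``, else an array of length ``size``.
    """
    if n < 3:
        raise ValueError(f"n={n} < 3")
    if not -1.0 < rho < 1.0:
        raise ValueError(f"rho={rho} outside (-1, 1)")
    rng = _as_rng(seed)
    if method == "pairs":
        x = rng.standard_normal((n, size))
        e = rng.standard_normal((n, size))
        y = rho * x + math.sqrt(1.0 - rho * rho) * e
        xc = x - x.mean(axis=0)
        yc = y - y.mean(axis=0)
        num = (xc * yc).sum(axis=0)
        den = np.sqrt((xc * xc).sum(axis=0) * (yc * yc).sum(axis=0))
        out = num / den
    elif method == "exact":
        w1 = rng.chisquare(n - 1, size)
        z = rng.standard_normal(size)
        w2 = rng.chisquare(n - 2, size)
        u = rho * np.sqrt(w1) + math.sqrt(1.0 - rho * rho) * z
        out = u / np.sqrt(u * u + (1.0 - rho * rho) * w2)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(out[0]) if size == 1 else out


def _text_probability(significant: bool, cfg: GeneratorConfig) -> float:
    base_odds = cfg.base_text_prob / (1.0 - cfg.base_text_prob)
    odds = base_odds * cfg.text_emphasis_odds if significant else base_odds
    return odds / (1.0 + odds)


def generate_records(cfg: GeneratorConfig) -> tuple[RecordSet, GeneratorTruth]:
    """Generate a synthetic literature; fully reproducible from cfg.seed.

    Per study: draw N (log-normal, floored at 5) and a record count, draw each
    true rho (0 with probability ``null_fraction``, else a signed Beta draw),
    observe r as the correlation of N simulated bivariate-normal pairs,
    compute the exact two-sided p, derive the significance label from
    p <= alpha, then apply unspecified/misreporting noise and the
    text-emphasis placement model.
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[StatRecord] = []
    rho_list: list[float] = []
    p_list: list[float] = []
    true_sig: list[bool] = []
    true_loc: list[str] = []
    flipped: list[bool] = []
    unspec: list[bool] = []

    for study in range(cfg.n_studies):
        n = max(5, int(round(rng.lognormal(math.log(cfg.sample_size_median), cfg.sample_size_sigma))))
        k = max(
            1,
            int(round(rng.lognormal(math.log(cfg.records_per_study_median), cfg.records_per_study_sigma))),
        )
        year = int(rng.integers(2010, 2020))
        subfield = "developmental" if study % 2 == 0 else "social"

        is_null = rng.random(k) < cfg.null_fraction
        magnitudes = rng.beta(cfg.effect_beta_a, cfg.effect_beta_b, k)
        signs = np.where(rng.random(k) < 0.5, -1.0, 1.0)
        rhos = np.where(is_null, 0.0, signs * magnitudes)
        # one shared N per study; simulate all of the study's records at once
        x = rng.standard_normal((n, k))
        e = rng.standard_normal((n, k))
        y = rhos * x + np.sqrt(1.0 - rhos * rhos) * e
        xc = x - x.mean(axis=0)
        yc = y - y.mean(axis=0)
        r_obs = (xc * yc).sum(axis=0) / np.sqrt(
            (xc * xc).sum(axis=0) * (yc * yc).sum(axis=0)
        )

        for j in range(k):
            r = float(np.clip(r_obs[j], -1.0, 1.0))
            p = exact_p(r, n - 2)
            sig = p <= cfg.alpha
            in_text = rng.random() < _text_probability(sig, cfg)

            blank = rng.random() < cfg.unspecified_rate
            flip = (not blank) and rng.random() < cfg.misreport_rate
            if blank:
                label = SigLabel.UNSPECIFIED
            elif flip:
                label = SigLabel.NON_SIGNIFICANT if sig else SigLabel.SIGNIFICANT
            else:
                label = SigLabel.SIGNIFICANT if sig else SigLabel.NON_SIGNIFICANT

            p_report = None if blank else PValueReport(Comparator.EQ, float(min(1.0, round(p, 3))))
            records.append(
                StatRecord(
                    record_id=f"s{study}_r{j}",
                    r=r,
                    n=n,
                    df=n - 2,
                    p_report=p_report,
                    sig_label=label,
                    location=Location.TEXT if in_text else Location.TABLE,
                    study_id=f"s{study}",
                    journal=None,
                    subfield=subfield,
                    year=year,
                )
            )
            rho_list.append(float(rhos[j]))
            p_list.append(p)
            true_sig.append(sig)
            true_loc.append("TEXT" if in_text else "TABLE")
            flipped.append(flip)
            unspec.append(blank)

    abs_r = np.abs([rec.r for rec in records])
    q25, q50, q75 = np.quantile(abs_r, [0.25, 0.5, 0.75])
    truth = GeneratorTruth(
        true_rho=np.asarray(rho_list),
        exact_p_two_sided=np.asarray(p_list),
        true_significant=np.asarray(true_sig),
        true_location=np.asarray(true_loc),
        flipped=np.asarray(flipped),
        unspecified=np.asarray(unspec),
        abs_r_quartiles=(float(q25), float(q50), float(q75)),
        proportion_significant=float(np.mean(true_sig)),
    )
    record_set = RecordSet(records=records, provenance=f"corrlit.simulate seed={cfg.seed}")
    return record_set, truth


# --- corpus rendering -------------------------------------------------------

FORMAT_VARIANTS = (
    "canonical",
    "no_df",
    "no_p",
    "p_inequality",
    "leading_dot",
    "negative",
    "linebreak",
    "subscript",
    "verbal",
)

#: Formats the extraction rules fully cover (miss-free by construction).
COVERED_VARIANTS = ("canonical", "no_df", "no_p", "p_inequality", "leading_dot", "negative")

DEFAULT_VARIANT_MIX: dict[str, float] = {
    "canonical": 0.50,
    "no_df": 0.12,
    "no_p": 0.10,
    "p_inequality": 0.10,
    "leading_dot": 0.08,
    "negative": 0.03,
    "linebreak": 0.02,
    "subscript": 0.02,
    "verbal": 0.03,
}

_SUBSCRIPT_WORDS = ("extraversion", "age", "anxiety", "iq", "baseline")


def _fmt_r(r: float, leading_dot: bool = False, unicode_minus: bool = False) -> str:
    text = f"{abs(r):.2f}"
    if leading_dot:
        text = text[1:]  # "0.52" -> ".52"
    if r < 0 or unicode_minus:
        text = ("−" if unicode_minus else "-") + text
    return text


def _fmt_p(rec: StatRecord) -> str:
    if rec.p_report is None:
        return "p = .050"
    value = max(0.001, round(rec.p_report.value, 3))
    symbol = {Comparator.EQ: "=", Comparator.LT: "<", Comparator.GT: ">"}[rec.p_report.comparator]
    return f"p {symbol} {value:.3f}"


def _render_one(rec: StatRecord, variant: str, rng: np.random.Generator) -> tuple[str, StatRecord]:
    """Serialize one record; returns (report string, truth record as rendered).

    The truth record's r and p_report are adjusted to the printed precision
    so that byte-faithful extraction reproduces it.
    """
    r2 = round(abs(rec.r), 2) * (1 if rec.r >= 0 else -1)
    df = rec.df if rec.df is not None else (rec.n - 2 if rec.n is not None else None)
    p_eq = None
    if rec.p_report is not None:
        p_eq = PValueReport(rec.p_report.comparator, max(0.001, round(rec.p_report.value, 3)))

    def with_df(core: str) -> str:
        return core if df is None else core.replace("r =", f"r({df}) =", 1)

    if variant == "canonical":
        text = with_df(f"r = {_fmt_r(r2)}, {_fmt_p(rec)}")
        truth = replace(rec, r=r2, p_report=p_eq)
    elif variant == "no_df":
        text = f"r = {_fmt_r(r2)}, {_fmt_p(rec)}"
        truth = replace(rec, r=r2, df=None, n=None, p_report=p_eq)
    elif variant == "no_p":
        text = with_df(f"r = {_fmt_r(r2)}")
        truth = replace(rec, r=r2, p_report=None)
    elif variant == "p_inequality":
        sig = rec.sig_label is SigLabel.SIGNIFICANT
        comp = Comparator.LT if sig else Comparator.GT
        text = with_df(f"r = {_fmt_r(r2)}, p {'<' if sig else '>'} .05")
        truth = replace(rec, r=r2, p_report=PValueReport(comp, 0.05))
    elif variant == "leading_dot":
        text = with_df(f"r = {_fmt_r(r2, leading_dot=True)}, {_fmt_p(rec)}")
        truth = replace(rec, r=r2, p_report=p_eq)
    elif variant == "negative":
        # exercises Unicode-minus normalization; analysis is sign-blind
        text = with_df(f"r = {_fmt_r(-abs(r2), unicode_minus=True)}, {_fmt_p(rec)}")
        truth = replace(rec, r=-abs(r2), p_report=p_eq)
    elif variant == "linebreak":
        text = with_df(f"r =\n{_fmt_r(r2)}, {_fmt_p(rec)}")
        truth = replace(rec, r=r2, p_report=p_eq)
    elif variant == "subscript":
        word = _SUBSCRIPT_WORDS[int(rng.integers(len(_SUBSCRIPT_WORDS)))]
        text = f"r_{word} = {_fmt_r(r2)}"
        truth = replace(rec, r=r2, p_report=None)
    elif variant == "verbal":
        text = f"the correlation was {abs(r2):.2f}"
        truth = replace(rec, r=r2, p_report=None)
    else:
        raise ValueError(f"unknown format variant {variant!r}")
    return text, truth


_FILLER = (
    "Participants completed the questionnaire battery described above.",
    "Descriptive statistics are reported in the supplementary material.",
    "The measure showed adequate internal consistency.",
    "Scores were standardized before analysis.",
)


def render_corpus(
    record_set: RecordSet,
    variant_mix: Mapping[str, float] | None = None,
    seed: int | np.random.Generator = 0,
) -> list[AnnotatedDocument]:
    """Serialize TEXT-placed records into annotated pseudo-articles.

    One document per study (records without a study_id share one document).
    TABLE-placed records are deliberately NOT rendered — text mining cannot
    see them, emulating the table blind spot of text-only extraction.
    Returns documents with (offset, truth record, variant) annotations, where
    the offset points at the first character of the rendered report.
    """
    rng = _as_rng(seed)
    mix = dict(DEFAULT_VARIANT_MIX if variant_mix is None else variant_mix)
    names = list(mix)
    weights = np.asarray([mix[v] for v in names], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("variant_mix weights must sum to a positive value")
    weights = weights / weights.sum()

    by_doc: dict[str, list[StatRecord]] = {}
    for rec in record_set:
        if rec.location is not Location.TEXT:
            continue
        by_doc.setdefault(rec.study_id or "doc", []).append(rec)

    documents = []
    for doc_id, recs in by_doc.items():
        parts: list[str] = []
        cursor = 0
        truth: list[tuple[int, StatRecord, str]] = []

        def emit(chunk: str) -> None:
            nonlocal cursor
            parts.append(chunk)
            cursor += len(chunk)

        emit(f"Results for {doc_id}. ")
        for rec in recs:
            variant = names[int(rng.choice(len(names), p=weights))]
            report, truth_rec = _render_one(rec, variant, rng)
            emit("We observed ")
            truth.append((cursor, truth_rec, variant))
            emit(report)
            emit(" in this analysis. ")
            emit(_FILLER[int(rng.integers(len(_FILLER)))] + " ")
        documents.append(AnnotatedDocument(doc_id=doc_id, text="".join(parts), truth=truth))
    return documents
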