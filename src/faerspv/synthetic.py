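"""Synthetic FAERS-like report generator with known ground truth.

The generator emulates the structure the pipeline consumes — reports carrying
one drug mention (rendered as generic or brand name, with route and dosage
strings), one or more reaction preferred terms, and a receipt quarter — with
a planted drug-event association of known odds ratio and, optionally,
injected duplicate records sharing the deduplication key. Every stage of the
pipeline (I/O, dedup, filtering, contingency, metrics) is therefore testable
against generator bookkeeping, with no external download.

The event model is report-level: given the drug, the report carries at least
one matching event term with probability p1 (target drug) or p0 (any other
drug), the term chosen uniformly from the event list. The planted reporting
odds ratio is therefore [p1/(1-p1)] / [p0/(1-p0)] analytically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError
from .filters import SAMT_TERMS
from .io import build_vocabulary
from .model import (
    DrugMention,
    DrugRole,
    Quarter,
    ReactionMention,
    ReportUniverse,
    SafetyReport,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "config_for_odds_ratio",
    "generate",
    "RecoveryReport",
    "recover_parameters",
]

#: Background reaction terms, deliberately disjoint from the stomatitis sets.
NOISE_TERMS = (
    "nausea",
    "fatigue",
    "headache",
    "diarrhoea",
    "rash",
    "dizziness",
    "vomiting",
    "pyrexia",
)

_ROUTES = ("ORAL", "INTRAVENOUS", "")
_DOSAGES = ("50 MG", "10 MG DAILY", "200 MG, QD", "")

_DEFAULT_VOCAB: dict[str, tuple[str, ...]] = {
    "ALPELISIB": ("PIQRAY", "VIJOICE"),
    "CAPIVASERTIB": ("TRUQAP",),
    "EVEROLIMUS": ("AFINITOR", "ZORTRESS"),
    "PALBOCICLIB": ("IBRANCE",),
    "LETROZOLE": ("FEMARA",),
    "FULVESTRANT": ("FASLODEX",),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults mimic an everolimus-scale signal.

    ``background_event_prob`` (p0) is the per-report probability that a
    non-target-drug report carries an event term; ``target_event_prob`` (p1)
    is the same probability for the target drug. Defaults p0=0.005 and
    p1 chosen for a planted odds ratio of 30 emulate the strongest signal
    scale seen for mTOR inhibition, at a desk-scale n of 50,000 reports.
    """

    n_reports: int = 50_000
    drug_vocabulary: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_VOCAB)
    )
    background_drug_weights: Mapping[str, float] | None = None
    target_drug: str = "EVEROLIMUS"
    event_terms: tuple[str, ...] = SAMT_TERMS
    background_event_prob: float = 0.005
    target_event_prob: float = 0.13116
    duplicate_rate: float = 0.0
    duplicate_mode: str = "exact"  # "exact" | "new_version"
    synonym_swap_rate: float = 0.3
    quarter_range: tuple[Quarter, Quarter] = (Quarter(2009, 2), Quarter(2025, 1))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports <= 0:
            raise ConfigurationError("n_reports must be positive")
        for name in ("background_event_prob", "target_event_prob",
                     "duplicate_rate", "synonym_swap_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.target_drug not in self.drug_vocabulary:
            raise ConfigurationError(
                f"target drug {self.target_drug!r} not in the drug vocabulary"
            )
        if self.duplicate_mode not in ("exact", "new_version"):
            raise ConfigurationError(f"unknown duplicate mode {self.duplicate_mode!r}")
        if not self.event_terms:
            raise ConfigurationError("event_terms must be non-empty")

    @property
    def true_odds_ratio(self) -> float:
        p0, p1 = self.background_event_prob, self.target_event_prob
        return (p1 / (1 - p1)) / (p0 / (1 - p0))


def config_for_odds_ratio(odds_ratio: float, p0: float = 0.005, **kwargs) -> SyntheticConfig:
    """Config whose planted odds ratio is exactly *odds_ratio* at background p0."""
    odds1 = odds_ratio * p0 / (1 - p0)
    return SyntheticConfig(
        background_event_prob=p0, target_event_prob=odds1 / (1 + odds1), **kwargs
    )


@dataclass
class GroundTruth:
    """Generator bookkeeping: the oracle for recovery and dedup tests."""

    true_odds_ratio: float
    planted_duplicates: int
    target_drug: str
    event_terms: tuple[str, ...]
    drug_labels: list[str]
    event_labels: list[bool]
    duplicate_of: list[str]  # primary_id of the original, one entry per injected record


def _quarters_between(start: Quarter, end: Quarter) -> list[Quarter]:
    out, y, q = [], start.year, start.quarter
    while (y, q) <= (end.year, end.quarter):
        out.append(Quarter(y, q))
        y, q = (y + 1, 1) if q == 4 else (y, q + 1)
    return out


def _clone(report: SafetyReport, primary_id: str | None = None) -> SafetyReport:
    return SafetyReport(
        primary_id=primary_id or report.primary_id,
        case_id=report.case_id,
        receipt_quarter=report.receipt_quarter,
        drugs=[DrugMention(d.raw_name, d.normalized_name, d.route, d.dosage, d.role)
               for d in report.drugs],
        reactions=list(report.reactions),
    )


def generate(config: SyntheticConfig) -> tuple[ReportUniverse, GroundTruth]:
    """Draw a report universe plus its ground truth; reproducible by seed.

    Reports are independent. Duplicates are appended after the base draw
    from a separate random stream, so deduplicating a duplicate-injected
    universe restores exactly the duplicate-free universe of the same seed:
    in ``exact`` mode copies share the primary ID (exercising duplicate
    removal), in ``new_version`` mode they get a higher-versioned primary ID
    under the same case ID (exercising case-version collapse).
    """
    ss = np.random.SeedSequence(config.seed)
    base_rng, dup_rng = (np.random.default_rng(c) for c in ss.spawn(2))

    tokens = sorted(config.drug_vocabulary)
    if config.background_drug_weights is None:
        weights = np.full(len(tokens), 1.0 / len(tokens))
    else:
        weights = np.array([config.background_drug_weights.get(t, 0.0) for t in tokens])
        if weights.sum() <= 0:
            raise ConfigurationError("background_drug_weights sum to zero")
        weights = weights / weights.sum()

    n = config.n_reports
    quarters = _quarters_between(*config.quarter_range)
    vocab = build_vocabulary(config.drug_vocabulary)

    drug_idx = base_rng.choice(len(tokens), size=n, p=weights)
    is_target = np.array(tokens)[drug_idx] == config.target_drug
    p = np.where(is_target, config.target_event_prob, config.background_event_prob)
    has_event = base_rng.random(n) < p
    event_term_idx = base_rng.integers(0, len(config.event_terms), size=n)
    noise_idx = base_rng.integers(0, len(NOISE_TERMS), size=n)
    swap = base_rng.random(n) < config.synonym_swap_rate
    syn_pick = base_rng.integers(0, 1 << 30, size=n)
    q_idx = base_rng.integers(0, len(quarters), size=n)
    route_idx = base_rng.integers(0, len(_ROUTES), size=n)
    dose_idx = base_rng.integers(0, len(_DOSAGES), size=n)

    reports: list[SafetyReport] = []
    drug_labels: list[str] = []
    event_labels: list[bool] = []
    for i in range(n):
        token = tokens[drug_idx[i]]
        synonyms = config.drug_vocabulary[token]
        raw = synonyms[syn_pick[i] % len(synonyms)] if (swap[i] and synonyms) else token
        reactions = [ReactionMention(NOISE_TERMS[noise_idx[i]])]
        if has_event[i]:
            reactions.append(ReactionMention(config.event_terms[event_term_idx[i]]))
        reports.append(
            SafetyReport(
                primary_id=f"{i + 1:08d}",
                case_id=f"C{i + 1:08d}",
                receipt_quarter=quarters[q_idx[i]],
                drugs=[
                    DrugMention(
                        raw_name=raw,
                        normalized_name=vocab.get(raw, raw),
                        route=_ROUTES[route_idx[i]],
                        dosage=_DOSAGES[dose_idx[i]],
                        role=DrugRole.SUSPECT,
                    )
                ],
                reactions=reactions,
            )
        )
        drug_labels.append(token)
        event_labels.append(bool(has_event[i]))

    n_dup = int(round(config.duplicate_rate * n))
    duplicate_of: list[str] = []
    version_counter: dict[str, int] = {}
    if n_dup:
        dup_sources = dup_rng.integers(0, n, size=n_dup)
        for j in dup_sources:
            original = reports[j]
            if config.duplicate_mode == "exact":
                reports.append(_clone(original))
            else:
                v = version_counter.get(original.primary_id, 1) + 1
                version_counter[original.primary_id] = v
                reports.append(_clone(original, primary_id=f"{original.primary_id}-{v}"))
            duplicate_of.append(original.primary_id)

    truth = GroundTruth(
        true_odds_ratio=config.true_odds_ratio,
        planted_duplicates=n_dup,
        target_drug=config.target_drug,
        event_terms=tuple(config.event_terms),
        drug_labels=drug_labels,
        event_labels=event_labels,
        duplicate_of=duplicate_of,
    )
    return ReportUniverse(reports=reports), truth


@dataclass
class RecoveryReport:
    """Estimated vs planted association for one generated universe."""

    estimated_ror: float
    ror_low: float
    ror_high: float
    true_odds_ratio: float
    covered: bool
    table: "object"


def recover_parameters(
    universe: ReportUniverse,
    truth: GroundTruth,
    query=None,
    term_set=None,
    zero_policy: str = "haldane",
) -> RecoveryReport:
    """Run the full pipeline on a generated universe and compare to truth.

    Deduplicates, collapses case versions, builds the 2x2 table for the
    target drug and event term set, and reports the ROR with its 95%
    interval, flagging whether the interval covers the planted odds ratio.
    """
    from .dedup import case_version_resolution, deduplicate
    from .filters import DrugQuery, TermSet
    from .stats import build_table, ror_with_ci

    if query is None:
        query = DrugQuery(token=truth.target_drug)
    if term_set is None:
        term_set = TermSet(name="planted-events", terms=truth.event_terms)

    deduped = deduplicate(universe).universe
    resolved = case_version_resolution(deduped, mode="latest")
    table = build_table(resolved, query, term_set)
    est = ror_with_ci(table, zero_policy=zero_policy)
    covered = est.low <= truth.true_odds_ratio <= est.high
    return RecoveryReport(
        estimated_ror=est.point,
        ror_low=est.low,
        ror_high=est.high,
        true_odds_ratio=truth.true_odds_ratio,
        covered=covered,
        table=table,
    )
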