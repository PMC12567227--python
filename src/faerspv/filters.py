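"""Reaction-term filter sets and per-drug extraction windows.

Four screening strategies are provided for stomatitis-associated adverse
events, at increasing breadth:

* ``stomatitis`` — the single preferred term "stomatitis";
* SAMT (Stomatitis-Associated Main Terms) — the three most frequent
  stomatitis-related preferred terms: stomatitis, aphthous ulcer, mouth
  ulceration;
* CTT (Comprehensive Trial Terms) — the eleven preferred terms pooled from
  the four drugs' phase III registration trials;
* OTT (Original Trial Terms) — per-drug registration-trial term sets,
  supplied through configuration because they differ by drug label.

Matching is exact on preferred terms (case-insensitive, trimmed), never
substring-based: the preferred terms are controlled vocabulary, and
substring matching would capture terms that are deliberately out of these
sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

from .errors import ConfigurationError
from .io import build_vocabulary, normalize_drug_name
from .model import Quarter, ReportUniverse, SafetyReport, term_key

__all__ = [
    "TermSet",
    "DrugQuery",
    "BuiltinTermSets",
    "builtin_term_sets",
    "STOMATITIS_TERM",
    "SAMT_TERMS",
    "CTT_TERMS",
    "DEFAULT_DRUG_QUERIES",
    "select_drug_reports",
    "TermCounts",
    "count_term_matches",
]

logger = logging.getLogger(__name__)

STOMATITIS_TERM = "stomatitis"

SAMT_TERMS = ("stomatitis", "aphthous ulcer", "mouth ulceration")

CTT_TERMS = (
    "stomatitis",
    "aphthous ulcer",
    "mouth ulceration",
    "lip ulceration",
    "glossodynia",
    "glossitis",
    "cheilitis",
    "oral pain",
    "gingival pain",
    "oral discomfort",
    "oropharyngeal pain",
)


@dataclass(frozen=True)
class TermSet:
    """A named set of reaction preferred terms."""

    name: str
    terms: tuple[str, ...]
    per_drug: bool = False  # True for OTT-style drug-specific membership

    def __post_init__(self) -> None:
        if not self.terms:
            raise ConfigurationError(f"term set {self.name!r} is empty")

    @property
    def keys(self) -> frozenset[str]:
        return frozenset(term_key(t) for t in self.terms)

    def contains(self, term: str) -> bool:
        return term_key(term) in self.keys

    def issubset(self, other: "TermSet") -> bool:
        return self.keys <= other.keys

    def __len__(self) -> int:
        return len(self.keys)


class BuiltinTermSets(NamedTuple):
    stomatitis_only: TermSet
    samt: TermSet
    ctt: TermSet
    ott: dict[str, TermSet]


def builtin_term_sets(
    ott_config: Mapping[str, Iterable[str]] | None = None,
) -> BuiltinTermSets:
    """Return the built-in filter strategies.

    OTT membership is drug-specific and comes from *ott_config* (canonical
    drug token -> term list); when absent an empty mapping is returned with
    a warning, since no universal default exists.
    """
    ott: dict[str, TermSet] = {}
    if ott_config:
        for drug, terms in ott_config.items():
            token = normalize_drug_name(drug)
            ott[token] = TermSet(name=f"OTT[{token}]", terms=tuple(terms), per_drug=True)
    else:
        logger.warning("no OTT configuration supplied; OTT term sets are empty")
    return BuiltinTermSets(
        stomatitis_only=TermSet(name="stomatitis", terms=(STOMATITIS_TERM,)),
        samt=TermSet(name="SAMT", terms=SAMT_TERMS),
        ctt=TermSet(name="CTT", terms=CTT_TERMS),
        ott=ott,
    )


@dataclass(frozen=True)
class DrugQuery:
    """A drug of interest: canonical token, synonyms, and extraction window."""

    token: str
    synonyms: tuple[str, ...] | None = None  # None -> the token itself
    window: tuple[Quarter, Quarter] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "token", normalize_drug_name(self.token))
        if not self.token:
            raise ConfigurationError("drug query has an empty canonical token")
        syns = (self.token,) if self.synonyms is None else tuple(self.synonyms)
        if not syns:
            raise ConfigurationError(f"drug query {self.token!r} has an empty synonym list")
        object.__setattr__(self, "synonyms", syns)
        if self.window is not None and self.window[0] > self.window[1]:
            raise ConfigurationError(
                f"drug query {self.token!r}: window start {self.window[0]} "
                f"is after end {self.window[1]}"
            )

    def vocabulary(self) -> dict[str, str]:
        return build_vocabulary({self.token: self.synonyms})

    def matches(self, report: SafetyReport, _vocab: dict[str, str] | None = None) -> bool:
        vocab = _vocab if _vocab is not None else self.vocabulary()
        return any(
            normalize_drug_name(d.normalized_name, vocab) == self.token for d in report.drugs
        )

    def in_window(self, report: SafetyReport) -> bool:
        if self.window is None:
            return True
        if report.receipt_quarter is None:
            return False
        return self.window[0] <= report.receipt_quarter <= self.window[1]


def _q(label: str) -> Quarter:
    return Quarter.from_label(label)


#: The four kinase-inhibitor queries with their marketing-era extraction
#: windows (first approval quarter through 2025Q1).
DEFAULT_DRUG_QUERIES = (
    DrugQuery("ALPELISIB", ("ALPELISIB", "PIQRAY", "VIJOICE"), (_q("2019Q2"), _q("2025Q1"))),
    DrugQuery("CAPIVASERTIB", ("CAPIVASERTIB", "TRUQAP"), (_q("2023Q4"), _q("2025Q1"))),
    DrugQuery("EVEROLIMUS", ("EVEROLIMUS", "AFINITOR", "ZORTRESS"), (_q("2009Q2"), _q("2025Q1"))),
    DrugQuery("PALBOCICLIB", ("PALBOCICLIB", "IBRANCE"), (_q("2015Q1"), _q("2025Q1"))),
)


def select_drug_reports(universe: ReportUniverse, query: DrugQuery) -> ReportUniverse:
    """Reports mentioning the queried drug, inside its extraction window.

    The output is always a subset of the input; with no window the selection
    is the identity on drug-matching reports.
    """
    vocab = query.vocabulary()  # built once; matching touches every report
    selected = [r for r in universe if query.matches(r, vocab) and query.in_window(r)]
    return ReportUniverse(reports=selected)


class TermCounts(NamedTuple):
    """Per-term report counts plus the aggregate under a counting mode."""

    per_term: dict[str, int]
    total: int
    mode: str


def count_term_matches(
    selected: ReportUniverse, term_set: TermSet, mode: str = "sum_of_terms"
) -> TermCounts:
    """Count reports matching each term of a filter set.

    ``per_term[t]`` is the number of reports containing term *t* (a report
    listing a term twice counts once for that term). The total depends on the
    counting mode:

    * ``sum_of_terms`` — the sum of the per-term counts; a report matching
      two terms contributes twice. This is the aggregation under which the
      per-term columns of a count table sum to the filter total.
    * ``unique_reports`` — the number of distinct reports matching at least
      one term; never larger than ``sum_of_terms``.
    """
    if mode not in ("sum_of_terms", "unique_reports"):
        raise ConfigurationError(f"unknown counting mode {mode!r}")
    per_term = {t: 0 for t in term_set.terms}
    key_to_term = {term_key(t): t for t in term_set.terms}
    unique = 0
    for report in selected:
        hits = report.reaction_keys() & term_set.keys
        if hits:
            unique += 1
            for k in hits:
                per_term[key_to_term[k]] += 1
    total = sum(per_term.values()) if mode == "sum_of_terms" else unique
    return TermCounts(per_term=per_term, total=total, mode=mode)
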