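"""Core data model for spontaneous adverse-event reports.

A :class:`SafetyReport` is the unit of analysis: one case report carrying one
or more drug mentions, one or more reaction preferred terms (a MedDRA-PT-like
controlled vocabulary), and a receipt calendar quarter. A
:class:`ReportUniverse` is the collection over which disproportionality
contingency tables are built; its ``total_count`` is the N of every 2x2 table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator

__all__ = [
    "DrugRole",
    "Quarter",
    "DrugMention",
    "ReactionMention",
    "SafetyReport",
    "ReportUniverse",
    "term_key",
]


def term_key(term: str) -> str:
    """Canonical comparison key for a reaction preferred term.

    Preferred terms are controlled vocabulary; comparison is case-insensitive
    after whitespace trimming, never substring-based.
    """
    return " ".join(term.split()).lower()


class DrugRole(str, Enum):
    """Reporting role of a drug within a case report."""

    SUSPECT = "suspect"
    CONCOMITANT = "concomitant"
    INTERACTING = "interacting"
    UNKNOWN = "unknown"

    @classmethod
    def from_faers_code(cls, code: str) -> "DrugRole":
        """Map FAERS ``role_cod`` values (PS, SS, C, I) to roles."""
        code = code.strip().upper()
        if code in ("PS", "SS"):
            return cls.SUSPECT
        if code == "C":
            return cls.CONCOMITANT
        if code == "I":
            return cls.INTERACTING
        return cls.UNKNOWN

    def to_faers_code(self) -> str:
        return {
            DrugRole.SUSPECT: "PS",
            DrugRole.CONCOMITANT: "C",
            DrugRole.INTERACTING: "I",
            DrugRole.UNKNOWN: "",
        }[self]


@dataclass(frozen=True, order=True, slots=True)
class Quarter:
    """A calendar quarter (e.g. 2020Q3); ordering is chronological."""

    year: int
    quarter: int

    def __post_init__(self) -> None:
        if self.quarter not in (1, 2, 3, 4):
            raise ValueError(f"quarter index must be in 1..4, got {self.quarter}")

    @classmethod
    def from_date_string(cls, yyyymmdd: str) -> "Quarter":
        """Parse a FAERS-style date (YYYYMMDD, or YYYYMM / YYYY prefixes)."""
        s = yyyymmdd.strip()
        if len(s) < 6 or not s[:6].isdigit():
            raise ValueError(f"cannot derive quarter from date {yyyymmdd!r}")
        year, month = int(s[:4]), int(s[4:6])
        if not 1 <= month <= 12:
            raise ValueError(f"invalid month in date {yyyymmdd!r}")
        return cls(year, (month - 1) // 3 + 1)

    @classmethod
    def from_label(cls, label: str) -> "Quarter":
        """Parse a quarter label such as ``2020Q3`` or ``2020q3``."""
        s = label.strip().upper()
        try:
            year_s, q_s = s.split("Q")
            return cls(int(year_s), int(q_s))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"cannot parse quarter label {label!r}") from exc

    def first_date(self) -> str:
        """First day of the quarter as YYYYMMDD (round-trip anchor)."""
        return f"{self.year:04d}{3 * self.quarter - 2:02d}01"

    def __str__(self) -> str:
        return f"{self.year}Q{self.quarter}"


@dataclass(slots=True)
class DrugMention:
    """One drug record within a report.

    ``raw_name`` is preserved exactly as read; ``normalized_name`` is the
    canonical active-ingredient token after uppercasing, trimming, trademark
    glyph removal and synonym mapping.
    """

    raw_name: str
    normalized_name: str
    route: str = ""
    dosage: str = ""
    role: DrugRole = DrugRole.UNKNOWN


@dataclass(frozen=True, slots=True)
class ReactionMention:
    """One reaction preferred term within a report."""

    preferred_term: str

    def key(self) -> str:
        return term_key(self.preferred_term)


@dataclass(slots=True)
class SafetyReport:
    """One adverse-event case report."""

    primary_id: str
    case_id: str
    receipt_quarter: Quarter | None
    drugs: list[DrugMention] = field(default_factory=list)
    reactions: list[ReactionMention] = field(default_factory=list)

    def reaction_keys(self) -> frozenset[str]:
        return frozenset(r.key() for r in self.reactions)

    def is_analyzable(self) -> bool:
        return bool(self.primary_id) and bool(self.drugs) and bool(self.reactions)


@dataclass(slots=True)
class ReportUniverse:
    """A collection of safety reports; the denominator universe (N)."""

    reports: list[SafetyReport] = field(default_factory=list)

    @property
    def total_count(self) -> int:
        """Number of distinct reports (distinct primary IDs)."""
        return len({r.primary_id for r in self.reports})

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self) -> Iterator[SafetyReport]:
        return iter(self.reports)
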