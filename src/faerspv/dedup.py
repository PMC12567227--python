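"""Duplicate-report removal.

FAERS receives the same case from multiple reporters and in multiple
versions, so disproportionality counts are only meaningful after
deduplication. The matching key is the tuple (primary ID, normalized drug
name, route of administration, dosage). Because a report carries one primary
ID but many drugs, the key is applied at two levels:

1. within a report, drug mentions sharing an identical key collapse to one;
2. across records, a report whose primary ID, full drug-key multiset and
   reaction set duplicate an already-seen report is dropped (first
   occurrence in file order wins).

Missing route/dosage fields are treated as empty strings and compare equal
to each other, so behaviour on sparse fields is deterministic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import NamedTuple

from .errors import ConfigurationError
from .model import ReportUniverse, SafetyReport

__all__ = ["DedupKey", "DedupLog", "DedupResult", "deduplicate", "case_version_resolution"]


@dataclass(frozen=True, slots=True)
class DedupKey:
    """The four-field duplicate-matching key for one drug mention."""

    primary_id: str
    normalized_name: str
    route: str
    dosage: str

    @classmethod
    def for_mention(cls, report: SafetyReport, mention) -> "DedupKey":
        return cls(
            primary_id=report.primary_id,
            normalized_name=mention.normalized_name,
            route=mention.route.strip().upper(),
            dosage=mention.dosage.strip().upper(),
        )


@dataclass(slots=True)
class DedupLog:
    """Counts of records removed, per rule."""

    drug_mentions_collapsed: int = 0
    duplicate_reports_removed: int = 0

    def as_rows(self) -> list[dict]:
        return [
            {"rule": "within_report_drug_collapse", "count": self.drug_mentions_collapsed},
            {"rule": "duplicate_report_drop", "count": self.duplicate_reports_removed},
        ]


class DedupResult(NamedTuple):
    universe: ReportUniverse
    log: DedupLog


def _report_signature(report: SafetyReport) -> tuple:
    keys = Counter(DedupKey.for_mention(report, d) for d in report.drugs)
    return (report.primary_id, frozenset(keys.items()), report.reaction_keys())


def deduplicate(universe: ReportUniverse) -> DedupResult:
    """Remove duplicate drug mentions and duplicate reports.

    Idempotent; never increases ``total_count``; an empty universe passes
    through. Drug names must already be normalized (the reader does this).
    """
    log = DedupLog()
    seen: set[tuple] = set()
    kept: list[SafetyReport] = []
    for report in universe:
        # level 1: collapse identical drug keys within the report
        mention_keys: set[DedupKey] = set()
        drugs = []
        for d in report.drugs:
            k = DedupKey.for_mention(report, d)
            if k in mention_keys:
                log.drug_mentions_collapsed += 1
                continue
            mention_keys.add(k)
            drugs.append(d)
        collapsed = replace(report, drugs=drugs) if len(drugs) != len(report.drugs) else report

        # level 2: drop reports duplicating an already-seen signature
        sig = _report_signature(collapsed)
        if sig in seen:
            log.duplicate_reports_removed += 1
            continue
        seen.add(sig)
        kept.append(collapsed)
    return DedupResult(ReportUniverse(reports=kept), log)


def case_version_resolution(universe: ReportUniverse, mode: str = "latest") -> ReportUniverse:
    """Collapse multiple versions of the same case.

    FAERS primary IDs encode case versions; under ``mode="latest"`` only the
    report with the highest primary ID per case ID survives (natural numeric
    ordering on digit runs, so "100-2" beats "100-1" and "10" beats "9").
    ``mode="all"`` is the identity.
    """
    if mode == "all":
        return universe
    if mode != "latest":
        raise ConfigurationError(f"unknown case-version mode {mode!r}; use 'latest' or 'all'")

    def natural(pid: str) -> tuple:
        import re

        return tuple(
            int(part) if part.isdigit() else part for part in re.split(r"(\d+)", pid) if part
        )

    best: dict[str, SafetyReport] = {}
    for report in universe:
        cur = best.get(report.case_id)
        if cur is None or natural(report.primary_id) > natural(cur.primary_id):
            best[report.case_id] = report
    winners = set(id(r) for r in best.values())
    return ReportUniverse(reports=[r for r in universe if id(r) in winners])
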