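"""Shared fixtures: tiny hand-built report universes."""

from __future__ import annotations

import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")

from faerspv.model import (
    DrugMention,
    DrugRole,
    Quarter,
    ReactionMention,
    ReportUniverse,
    SafetyReport,
)


def make_report(
    pid: str,
    drugs: list[tuple[str, str]] | list[str],
    reactions: list[str],
    quarter: str = "2020Q3",
    case_id: str | None = None,
    route: str = "ORAL",
    dosage: str = "50 MG",
) -> SafetyReport:
    """Build a report; each drug is 'NAME' or ('raw', 'NORMALIZED')."""
    mentions = []
    for d in drugs:
        raw, norm = (d, d) if isinstance(d, str) else d
        mentions.append(
            DrugMention(
                raw_name=raw,
                normalized_name=norm,
                route=route,
                dosage=dosage,
                role=DrugRole.SUSPECT,
            )
        )
    return SafetyReport(
        primary_id=pid,
        case_id=case_id or pid,
        receipt_quarter=Quarter.from_label(quarter),
        drugs=mentions,
        reactions=[ReactionMention(r) for r in reactions],
    )


@pytest.fixture
def ten_report_universe() -> ReportUniverse:
    """Ten reports: four with the target drug (two matching the event term),
    six without (one matching) -> 2x2 cells (2, 2, 1, 5)."""
    reports = [
        make_report("01", ["EVEROLIMUS"], ["stomatitis"]),
        make_report("02", ["EVEROLIMUS"], ["mouth ulceration"]),
        make_report("03", ["EVEROLIMUS"], ["nausea"]),
        make_report("04", ["EVEROLIMUS"], ["fatigue"]),
        make_report("05", ["LETROZOLE"], ["stomatitis"]),
        make_report("06", ["LETROZOLE"], ["rash"]),
        make_report("07", ["FULVESTRANT"], ["nausea"]),
        make_report("08", ["FULVESTRANT"], ["headache"]),
        make_report("09", ["LETROZOLE"], ["dizziness"]),
        make_report("10", ["FULVESTRANT"], ["vomiting"]),
    ]
    return ReportUniverse(reports=reports)
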