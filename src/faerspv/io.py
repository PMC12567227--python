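"""Read and write FAERS-style quarterly report files.

The public FAERS quarterly ASCII distribution ships three record types per
quarter — demographics (DEMO), drug (DRUG), and reaction (REAC) — as
dollar-sign-delimited text with one header row, keyed by ``primaryid``. This
module reads that dialect (and a plain CSV alternative) into a
:class:`~faerspv.model.ReportUniverse`, and writes a universe back out such
that a read reproduces it exactly.

Only the columns the pipeline needs are required; extra columns are ignored
because FAERS schemas vary by quarter.
"""

from __future__ import annotations

import logging
import re
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import FormatError, InputFileError
from .model import (
    DrugMention,
    DrugRole,
    Quarter,
    ReactionMention,
    ReportUniverse,
    SafetyReport,
)

__all__ = [
    "Dialect",
    "normalize_drug_name",
    "build_vocabulary",
    "DEFAULT_DRUG_VOCABULARY",
    "read_quarterly_files",
    "write_quarterly_files",
]

logger = logging.getLogger(__name__)

DEMO_COLUMNS = ["primaryid", "caseid", "fda_dt"]
DRUG_COLUMNS = ["primaryid", "role_cod", "drugname", "route", "dose_vbm"]
REAC_COLUMNS = ["primaryid", "pt"]

# Trademark glyphs and their ASCII renderings, stripped before vocabulary lookup.
_TRADEMARK_RE = re.compile(r"[®™]|\(R\)|\(TM\)", re.IGNORECASE)


class Dialect(str, Enum):
    """Supported file dialects for the quarterly record files."""

    FAERS = "faers"  # dollar-sign delimited, the public ASCII distribution
    CSV = "csv"

    @property
    def sep(self) -> str:
        return "$" if self is Dialect.FAERS else ","


def normalize_drug_name(raw: str, vocabulary: Mapping[str, str] | None = None) -> str:
    """Map a free-text drug name to its canonical active-ingredient token.

    Uppercases, trims, strips trademark glyphs, collapses internal whitespace,
    then maps through the synonym vocabulary (case-insensitive). Unmapped
    names are returned cleaned but otherwise untouched, so the function is
    total and idempotent.
    """
    cleaned = _TRADEMARK_RE.sub("", raw)
    cleaned = " ".join(cleaned.split()).upper()
    if vocabulary:
        return vocabulary.get(cleaned, cleaned)
    return cleaned


def build_vocabulary(canonical_to_synonyms: Mapping[str, Iterable[str]]) -> dict[str, str]:
    """Invert a canonical-token -> synonym-list map into a lookup table.

    Keys are cleaned synonym strings; every canonical token also maps to
    itself, which keeps :func:`normalize_drug_name` idempotent.
    """
    vocab: dict[str, str] = {}
    for canonical, synonyms in canonical_to_synonyms.items():
        token = normalize_drug_name(canonical)
        vocab[token] = token
        for syn in synonyms:
            vocab[normalize_drug_name(syn)] = token
    return vocab


#: Generic and brand names for the four kinase inhibitors the pipeline ships
#: queries for. Brand names appear in reports with or without trademark marks.
DEFAULT_DRUG_VOCABULARY = build_vocabulary(
    {
        "ALPELISIB": ["PIQRAY", "VIJOICE"],
        "CAPIVASERTIB": ["TRUQAP"],
        "EVEROLIMUS": ["AFINITOR", "ZORTRESS"],
        "PALBOCICLIB": ["IBRANCE"],
    }
)


def _read_table(path: Path, required: list[str], sep: str) -> pd.DataFrame:
    if not path.exists():
        raise InputFileError(f"input file not found: {path}")
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file, expected header {required}") from exc
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: malformed header, missing columns {missing}; expected at least {required}"
        )
    return df


def read_quarterly_files(
    demo_path: str | Path,
    drug_path: str | Path,
    reac_path: str | Path,
    dialect: Dialect | str = Dialect.FAERS,
    vocabulary: Mapping[str, str] | None = None,
    quarter_label: str | None = None,
) -> ReportUniverse:
    """Read DEMO/DRUG/REAC files into a report universe.

    One :class:`SafetyReport` is produced per demographics record, with drug
    and reaction records joined by ``primaryid``. Raw strings are preserved;
    drug names are additionally normalized through *vocabulary*. The receipt
    quarter is parsed from the ``fda_dt`` date when present, else taken from
    *quarter_label* (e.g. ``"2025Q1"``), else left unset.

    Drug or reaction records whose ``primaryid`` has no demographics record
    are orphans: counted, warned about, and attached to nothing.
    """
    dialect = Dialect(dialect)
    sep = dialect.sep
    demo = _read_table(Path(demo_path), DEMO_COLUMNS, sep)
    drug = _read_table(Path(drug_path), DRUG_COLUMNS, sep)
    reac = _read_table(Path(reac_path), REAC_COLUMNS, sep)

    fallback_quarter = Quarter.from_label(quarter_label) if quarter_label else None

    # A primaryid can occur on several demographics rows (duplicate records);
    # drug/reaction rows carry no finer key, so they attach to every report
    # sharing the id. Deduplication later collapses the identical unions.
    reports: dict[str, list[SafetyReport]] = {}
    order: list[SafetyReport] = []
    for row in demo.itertuples(index=False):
        pid = row.primaryid.strip()
        quarter = fallback_quarter
        if row.fda_dt.strip():
            try:
                quarter = Quarter.from_date_string(row.fda_dt)
            except ValueError:
                logger.warning("unparseable fda_dt %r for report %s", row.fda_dt, pid)
        report = SafetyReport(
            primary_id=pid,
            case_id=row.caseid.strip() or pid,
            receipt_quarter=quarter,
        )
        reports.setdefault(pid, []).append(report)
        order.append(report)

    orphan_drugs = orphan_reacs = 0
    for row in drug.itertuples(index=False):
        pid = row.primaryid.strip()
        targets = reports.get(pid)
        if not targets:
            orphan_drugs += 1
            continue
        raw = row.drugname
        mention = DrugMention(
            raw_name=raw,
            normalized_name=normalize_drug_name(raw, vocabulary),
            route=row.route.strip(),
            dosage=row.dose_vbm.strip(),
            role=DrugRole.from_faers_code(row.role_cod),
        )
        for target in targets:
            target.drugs.append(
                mention if target is targets[0] else
                DrugMention(mention.raw_name, mention.normalized_name,
                            mention.route, mention.dosage, mention.role)
            )
    for row in reac.itertuples(index=False):
        pid = row.primaryid.strip()
        targets = reports.get(pid)
        if not targets:
            orphan_reacs += 1
            continue
        for target in targets:
            target.reactions.append(ReactionMention(preferred_term=row.pt.strip()))

    if orphan_drugs or orphan_reacs:
        logger.warning(
            "orphan records not attached to any report: %d drug, %d reaction",
            orphan_drugs,
            orphan_reacs,
        )
    logger.info(
        "read %d demo, %d drug, %d reaction records -> %d reports "
        "(%d drug / %d reaction records joined)",
        len(demo), len(drug), len(reac), len(order),
        len(drug) - orphan_drugs, len(reac) - orphan_reacs,
    )
    return ReportUniverse(reports=order)


def write_quarterly_files(
    universe: ReportUniverse,
    out_dir: str | Path,
    dialect: Dialect | str = Dialect.FAERS,
) -> list[Path]:
    """Write a universe as DEMO/DRUG/REAC files in the chosen dialect.

    Reading the emitted files back with the same vocabulary reproduces the
    universe exactly (the receipt quarter round-trips through the first day
    of the quarter). Returns the three paths written.
    """
    dialect = Dialect(dialect)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ext = "txt" if dialect is Dialect.FAERS else "csv"
    sep = dialect.sep

    demo_rows, drug_rows, reac_rows = [], [], []
    for r in universe:
        demo_rows.append(
            {
                "primaryid": r.primary_id,
                "caseid": r.case_id,
                "fda_dt": r.receipt_quarter.first_date() if r.receipt_quarter else "",
            }
        )
        for d in r.drugs:
            drug_rows.append(
                {
                    "primaryid": r.primary_id,
                    "role_cod": d.role.to_faers_code(),
                    "drugname": d.raw_name,
                    "route": d.route,
                    "dose_vbm": d.dosage,
                }
            )
        for rx in r.reactions:
            reac_rows.append({"primaryid": r.primary_id, "pt": rx.preferred_term})

    paths = []
    for name, rows, cols in (
        ("DEMO", demo_rows, DEMO_COLUMNS),
        ("DRUG", drug_rows, DRUG_COLUMNS),
        ("REAC", reac_rows, REAC_COLUMNS),
    ):
        path = out / f"{name}.{ext}"
        pd.DataFrame(rows, columns=cols).to_csv(path, sep=sep, index=False)
        paths.append(path)
    return paths
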