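"""End-to-end orchestration: read -> dedup -> select -> count -> 2x2 -> metrics.

The pipeline mirrors the standard spontaneous-report workflow: the quarterly
files (or the synthetic generator) provide the report universe, duplicates
are removed, reports are selected per drug query and extraction window, the
term filters are counted, and a disproportionality signal table is computed
per drug x filter. Outputs are plain tables:

* a per-term count matrix (terms x drugs, with totals under both counting
  modes),
* a signal-result table (one row per drug x filter, with the 2x2 cells, all
  metrics, bounds, p-values and significance flags),
* a percentage table (filter total / drug total x 100, both counting modes),
* a JSON run manifest (version, config echo, seed, formula variants).

Counting-mode caveat: the ``sum_of_terms`` total counts a report once per
matching term, so it can exceed the number of distinct matching reports
(``unique_reports``); the 2x2 cells always use unique-report counting so the
cells sum to N. Both totals are emitted so the difference is visible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .dedup import DedupLog, case_version_resolution, deduplicate
from .errors import ConfigurationError, FaersError
from .filters import (
    DrugQuery,
    TermSet,
    builtin_term_sets,
    count_term_matches,
    select_drug_reports,
)
from .io import Dialect, read_quarterly_files
from .model import Quarter, ReportUniverse
from .stats import build_table, compute_signal
from .synthetic import SyntheticConfig, generate

__all__ = ["RunConfig", "RunResult", "run", "percent_of_reports", "load_run_config"]

logger = logging.getLogger(__name__)

FORMULA_VARIANTS = {
    "ror": "cross-product (a*d)/(b*c); 95% CI exp(ln ROR +/- 1.96*sqrt(1/a+1/b+1/c+1/d))",
    "prr": "[a/(a+b)]/[c/(c+d)]; 95% CI exp(ln PRR +/- 1.96*sqrt(1/a-1/(a+b)+1/c-1/(c+d)))",
    "ic": "log2((a+0.5)/(E+0.5)), E=(a+b)(a+c)/n; credibility bounds "
          "IC-3.3*(a+.5)^-1/2-2*(a+.5)^-3/2, IC+2.4*(a+.5)^-1/2-0.5*(a+.5)^-3/2",
    "zero_cells": "Haldane-Anscombe +0.5 on all cells, applied only when a cell is 0",
}

OUTPUT_NOTES = (
    "sum_of_terms totals count a report once per matching term and can exceed "
    "the distinct-report (unique_reports) totals; 2x2 cells always use "
    "unique-report counting so cells sum to N."
)


def percent_of_reports(filter_total: int, drug_total: int) -> float:
    """Share of a drug's reports captured by a filter, as a percentage.

    Returns 100 * filter_total / drug_total rounded to 2 decimals; undefined
    when the drug has no reports.
    """
    if drug_total <= 0:
        raise ConfigurationError("percentage undefined: drug_total is zero")
    return round(100.0 * filter_total / drug_total, 2)


@dataclass
class RunConfig:
    """One analysis run: exactly one input source, plus queries and filters."""

    drug_queries: Sequence[DrugQuery]
    term_sets: Sequence[TermSet]
    demo_path: Path | None = None
    drug_path: Path | None = None
    reac_path: Path | None = None
    dialect: Dialect | str = Dialect.FAERS
    quarter_label: str | None = None
    vocabulary: Mapping[str, str] | None = None
    synthetic: SyntheticConfig | None = None
    counting_mode: str = "sum_of_terms"
    zero_policy: str = "haldane"
    dedup_mode: str = "latest"
    out_dir: Path | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        has_files = self.demo_path is not None
        if has_files == (self.synthetic is not None):
            raise ConfigurationError(
                "exactly one input source required: quarterly files or a synthetic config"
            )
        if has_files and (self.drug_path is None or self.reac_path is None):
            raise ConfigurationError("file input needs demo, drug and reac paths")
        if not self.drug_queries:
            raise ConfigurationError("no drug queries configured")
        if not self.term_sets:
            raise ConfigurationError("no term sets configured")
        if self.counting_mode not in ("sum_of_terms", "unique_reports"):
            raise ConfigurationError(f"unknown counting mode {self.counting_mode!r}")


@dataclass
class RunResult:
    universe_total: int
    dedup_log: DedupLog
    term_counts: pd.DataFrame
    signals: pd.DataFrame
    percents: pd.DataFrame
    manifest: dict


def _stage(name: str):
    """Context manager logging stage timing and re-raising with the stage name."""
    class _Stage:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                logger.info("stage %s done in %.2fs", name, dt)
                return False
            raise FaersError(f"stage {name!r} failed: {exc}") from exc

    return _Stage()


def run(config: RunConfig) -> RunResult:
    """Execute the full analysis and optionally write the output tables."""
    with _stage("input"):
        if config.synthetic is not None:
            syn = config.synthetic
            if config.seed is not None:
                syn = dataclasses.replace(syn, seed=config.seed)
            universe, _truth = generate(syn)
        else:
            universe = read_quarterly_files(
                config.demo_path, config.drug_path, config.reac_path,
                dialect=config.dialect, vocabulary=config.vocabulary,
                quarter_label=config.quarter_label,
            )

    with _stage("dedup"):
        deduped, dedup_log = deduplicate(universe)
        resolved = case_version_resolution(deduped, mode=config.dedup_mode)

    term_rows: dict[str, dict[str, int]] = {}
    signal_rows = []
    percent_rows = []
    with _stage("analysis"):
        for query in config.drug_queries:
            selected = select_drug_reports(resolved, query)
            drug_total = len(selected.reports)
            col = term_rows.setdefault(query.token, {})
            col["Total number of reports"] = drug_total
            for ts in config.term_sets:
                counts_sum = count_term_matches(selected, ts, mode="sum_of_terms")
                counts_unique = count_term_matches(selected, ts, mode="unique_reports")
                for term, k in counts_sum.per_term.items():
                    col[term] = k
                col[f"Total reports: {ts.name} (sum_of_terms)"] = counts_sum.total
                col[f"Total reports: {ts.name} (unique_reports)"] = counts_unique.total

                table = build_table(resolved, query, ts)
                sig = compute_signal(table, zero_policy=config.zero_policy)
                signal_rows.append(
                    {
                        "drug": query.token,
                        "term_set": ts.name,
                        "a": table.a, "b": table.b, "c": table.c, "d": table.d,
                        "n": table.n,
                        "degenerate": table.degenerate,
                        "ror": sig.ror, "ror_low": sig.ror_low, "ror_high": sig.ror_high,
                        "prr": sig.prr, "prr_low": sig.prr_low, "prr_high": sig.prr_high,
                        "ic": sig.ic, "ic_low": sig.ic_low, "ic_high": sig.ic_high,
                        "fisher_p": sig.fisher_p,
                        "chi2": sig.chi2, "chi2_p": sig.chi2_p,
                        "chi2_yates": sig.chi2_yates, "chi2_yates_p": sig.chi2_yates_p,
                        "significant_ror": sig.significant_ror,
                        "significant_prr": sig.significant_prr,
                        "significant_ic": sig.significant_ic,
                    }
                )
                for mode, total in (
                    ("sum_of_terms", counts_sum.total),
                    ("unique_reports", counts_unique.total),
                ):
                    row = {"drug": query.token, "term_set": ts.name, "mode": mode,
                           "filter_total": total, "drug_total": drug_total,
                           "flagged": drug_total == 0}
                    row["percent"] = (
                        percent_of_reports(total, drug_total) if drug_total else float("nan")
                    )
                    percent_rows.append(row)

    term_counts = pd.DataFrame(term_rows).fillna(0).astype(int)
    signals = pd.DataFrame(signal_rows)
    percents = pd.DataFrame(percent_rows)
    manifest = {
        "package": "faerspv",
        "version": __version__,
        "seed": config.seed if config.seed is not None else (
            config.synthetic.seed if config.synthetic else None
        ),
        "counting_mode": config.counting_mode,
        "zero_policy": config.zero_policy,
        "dedup_mode": config.dedup_mode,
        "universe_total": resolved.total_count,
        "dedup_removed": dedup_log.as_rows(),
        "formula_variants": FORMULA_VARIANTS,
        "notes": OUTPUT_NOTES,
        "drugs": [q.token for q in config.drug_queries],
        "term_sets": {ts.name: list(ts.terms) for ts in config.term_sets},
    }

    result = RunResult(
        universe_total=resolved.total_count,
        dedup_log=dedup_log,
        term_counts=term_counts,
        signals=signals,
        percents=percents,
        manifest=manifest,
    )
    if config.out_dir is not None:
        with _stage("write"):
            out = Path(config.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            term_counts.to_csv(out / "term_counts.csv", index_label="term")
            signals.to_csv(out / "signal_results.csv", index=False)
            percents.to_csv(out / "percent_of_reports.csv", index=False)
            pd.DataFrame(dedup_log.as_rows()).to_csv(out / "dedup_log.csv", index=False)
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result


def _parse_term_sets(raw: list, builtins) -> list[TermSet]:
    out = []
    for item in raw:
        if isinstance(item, str) or "builtin" in item:
            name = item if isinstance(item, str) else item["builtin"]
            key = name.strip().lower()
            mapping = {"stomatitis": builtins.stomatitis_only,
                       "samt": builtins.samt, "ctt": builtins.ctt}
            if key not in mapping:
                raise ConfigurationError(f"unknown builtin term set {name!r}")
            out.append(mapping[key])
        else:
            out.append(TermSet(name=item["name"], terms=tuple(item["terms"])))
    return out


def load_run_config(path: str | Path, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file.

    Top-level keys: ``input`` (demo/drug/reac paths, dialect, quarter_label)
    or ``synthetic`` (generator parameters); ``drugs`` (token, synonyms,
    window as a [start, end] pair of quarter labels); ``term_sets`` (builtin
    names or name+terms mappings); ``mode``; ``zero_policy``; ``dedup_mode``;
    ``seed``. Keyword *overrides* take precedence.
    """
    data = yaml.safe_load(Path(path).read_text()) or {}
    builtins = builtin_term_sets(data.get("ott"))

    queries = []
    for d in data.get("drugs", []):
        window = None
        if d.get("window"):
            start, end = d["window"]
            window = (Quarter.from_label(str(start)), Quarter.from_label(str(end)))
        queries.append(
            DrugQuery(
                token=d["token"],
                synonyms=tuple(d["synonyms"]) if d.get("synonyms") else None,
                window=window,
            )
        )

    term_sets = _parse_term_sets(data.get("term_sets", []), builtins)

    kwargs: dict = {
        "drug_queries": queries,
        "term_sets": term_sets,
        "counting_mode": data.get("mode", "sum_of_terms"),
        "zero_policy": data.get("zero_policy", "haldane"),
        "dedup_mode": data.get("dedup_mode", "latest"),
        "seed": data.get("seed"),
    }
    if "input" in data:
        inp = data["input"]
        kwargs.update(
            demo_path=Path(inp["demo"]), drug_path=Path(inp["drug"]),
            reac_path=Path(inp["reac"]), dialect=inp.get("dialect", "faers"),
            quarter_label=inp.get("quarter_label"),
        )
    if "synthetic" in data:
        syn = dict(data["synthetic"])
        if "quarter_range" in syn:
            start, end = syn["quarter_range"]
            syn["quarter_range"] = (Quarter.from_label(str(start)), Quarter.from_label(str(end)))
        if "event_terms" in syn:
            syn["event_terms"] = tuple(syn["event_terms"])
        kwargs["synthetic"] = SyntheticConfig(**syn)
    kwargs.update(overrides)
    return RunConfig(**kwargs)
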