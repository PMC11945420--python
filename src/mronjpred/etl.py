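"""Merge, deduplicate and clean FAERS-shaped report tables.

The cleaning sequence mirrors how spontaneous-report analyses build a single
analysis table from the quarterly extracts: deduplicate each of the four
tables, keep only first/second suspect drug rows, inner-join Drug+Therapy on
(primary id, drug sequence) and then Reaction and Demographic on primary id,
and finally keep only rows whose event onset falls inside the therapy window
(start <= onset <= end).  Every filter records how many rows it removed so
the resulting table carries a reconcilable provenance trail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError
from .synthetic import TARGET_EVENT_TERM

logger = logging.getLogger(__name__)

#: Canonical column names.  Inputs with other headers are renamed through a
#: schema map ({input column -> canonical column}) before processing.
DRUG_KEYS = ("primaryid", "drug_seq", "drug_name", "role_code")
REACTION_KEYS = ("primaryid", "pt")
DEMO_KEYS = ("primaryid",)
THERAPY_KEYS = ("primaryid", "drug_seq", "start_dt", "end_dt")

SUSPECT_ROLES = frozenset({"PS", "SS"})
KNOWN_ROLES = frozenset({"PS", "SS", "C", "I"})


@dataclass
class Provenance:
    """Row-count bookkeeping for one ETL run."""

    duplicates_removed: dict[str, int] = field(default_factory=dict)
    role_filtered: int = 0
    unknown_role_dropped: int = 0
    merged_rows: int = 0
    date_order_excluded: int = 0
    date_missing_excluded: int = 0
    rows_out: int = 0

    def reconciles(self) -> bool:
        return self.rows_out == (self.merged_rows - self.date_order_excluded
                                 - self.date_missing_excluded)


@dataclass
class AnalysisTable:
    """The cleaned analysis table plus its provenance counters."""

    frame: pd.DataFrame
    provenance: Provenance


def apply_schema(table: pd.DataFrame, schema: dict[str, str] | None) -> pd.DataFrame:
    """Rename input columns to the canonical names via a schema map."""
    return table.rename(columns=schema) if schema else table


def _require(table: pd.DataFrame, columns, where: str) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise SchemaError(f"{where}: missing columns {missing}")


def deduplicate(table: pd.DataFrame, key_columns,
                version_column: str | None = None,
                provenance: Provenance | None = None,
                table_name: str = "table") -> pd.DataFrame:
    """Drop duplicate keys, keeping the highest version (or last occurrence).

    With a ``version_column`` the row with the largest version wins; without
    one the last occurrence in input order wins — the convention for
    resubmitted spontaneous reports, where later rows supersede earlier ones.
    """
    key_columns = list(key_columns)
    _require(table, key_columns + ([version_column] if version_column else []),
             f"deduplicate({table_name})")
    if version_column is not None:
        deduped = (table.sort_values(version_column, kind="stable")
                   .drop_duplicates(key_columns, keep="last")
                   .sort_index())
    else:
        deduped = table.drop_duplicates(key_columns, keep="last")
    removed = len(table) - len(deduped)
    logger.info("dedup %s: removed %d of %d rows", table_name, removed, len(table))
    if provenance is not None:
        provenance.duplicates_removed[table_name] = removed
    return deduped.reset_index(drop=True)


def filter_suspect_drugs(drug_table: pd.DataFrame,
                         provenance: Provenance | None = None) -> pd.DataFrame:
    """Keep only first- and second-suspect drug rows (roles PS and SS)."""
    _require(drug_table, ["role_code"], "filter_suspect_drugs")
    roles = drug_table["role_code"]
    unknown = ~roles.isin(KNOWN_ROLES)
    if unknown.any():
        logger.warning("dropping %d rows with unknown role codes %s",
                       int(unknown.sum()),
                       sorted(roles[unknown].unique().tolist()))
    keep = roles.isin(SUSPECT_ROLES)
    if provenance is not None:
        provenance.role_filtered = int((~keep & ~unknown).sum())
        provenance.unknown_role_dropped = int(unknown.sum())
    return drug_table[keep].reset_index(drop=True)


def merge_tables(drug: pd.DataFrame, therapy: pd.DataFrame,
                 demographic: pd.DataFrame, reaction: pd.DataFrame,
                 provenance: Provenance | None = None) -> pd.DataFrame:
    """Inner-join the four tables into one row per (drug, event) pair.

    Join order: Drug + Therapy on (primaryid, drug_seq), then Demographic
    and Reaction on primaryid.  Inner joins drop reports missing any piece:
    a retained row always has a drug, a therapy window, an onset date and an
    event term.
    """
    _require(drug, DRUG_KEYS, "merge_tables(drug)")
    _require(therapy, THERAPY_KEYS, "merge_tables(therapy)")
    _require(demographic, DEMO_KEYS + ("event_dt",), "merge_tables(demographic)")
    _require(reaction, REACTION_KEYS, "merge_tables(reaction)")
    merged = drug.merge(therapy, on=["primaryid", "drug_seq"], how="inner")
    merged = merged.merge(demographic, on="primaryid", how="inner")
    merged = merged.merge(reaction, on="primaryid", how="inner")
    if provenance is not None:
        provenance.merged_rows = len(merged)
    return merged


def parse_report_dates(values: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Parse report dates; return (parsed, is_partial).

    Accepts datetime columns, ISO strings and the compact FAERS ``YYYYMMDD``
    integers.  Partial dates (``YYYY`` or ``YYYYMM``) are controlled
    imprecision, not noise, so they are flagged separately; both partial and
    unparseable values come back as NaT.
    """
    if pd.api.types.is_datetime64_any_dtype(values):
        return values, pd.Series(False, index=values.index)
    text = values.astype("string").str.strip()
    digits = text.str.fullmatch(r"\d+").fillna(False)
    partial = digits & text.str.len().isin([4, 6])
    compact = digits & (text.str.len() == 8)
    parsed = pd.Series(pd.NaT, index=values.index, dtype="datetime64[ns]")
    parsed[compact] = pd.to_datetime(text[compact], format="%Y%m%d",
                                     errors="coerce")
    other = ~digits & text.notna()
    parsed[other] = pd.to_datetime(text[other], errors="coerce")
    return parsed, partial


def apply_timeseries_filter(table: pd.DataFrame,
                            provenance: Provenance | None = None) -> pd.DataFrame:
    """Keep rows whose onset falls inside the therapy window (inclusive).

    Rows are kept iff start <= onset <= end.  Rows where any of the three
    dates is missing, partial, or unparseable are excluded (counted
    separately from ordering violations), never raised.
    """
    _require(table, ["start_dt", "event_dt", "end_dt"], "apply_timeseries_filter")
    start, p1 = parse_report_dates(table["start_dt"])
    onset, p2 = parse_report_dates(table["event_dt"])
    end, p3 = parse_report_dates(table["end_dt"])
    missing = (start.isna() | onset.isna() | end.isna() | p1 | p2 | p3)
    in_order = (start <= onset) & (onset <= end) & ~missing
    if provenance is not None:
        provenance.date_missing_excluded = int(missing.sum())
        provenance.date_order_excluded = int((~in_order & ~missing).sum())
    logger.info("time-series filter: kept %d / %d rows",
                int(in_order.sum()), len(table))
    out = table[in_order].copy()
    out["start_dt"], out["event_dt"], out["end_dt"] = (
        start[in_order], onset[in_order], end[in_order])
    return out.reset_index(drop=True)


def flag_target_event(table: pd.DataFrame,
                      target_term: str = TARGET_EVENT_TERM) -> pd.DataFrame:
    """Add ``is_target_event`` by case-insensitive exact preferred-term match."""
    _require(table, ["pt"], "flag_target_event")
    out = table.copy()
    normalized = out["pt"].astype("string").str.strip().str.casefold()
    out["is_target_event"] = (normalized == target_term.strip().casefold())
    return out


def run_etl(drug: pd.DataFrame, therapy: pd.DataFrame,
            demographic: pd.DataFrame, reaction: pd.DataFrame,
            target_term: str = TARGET_EVENT_TERM,
            schemas: dict[str, dict[str, str]] | None = None) -> AnalysisTable:
    """Run the full cleaning sequence and return the analysis table."""
    schemas = schemas or {}
    drug = apply_schema(drug, schemas.get("drug"))
    therapy = apply_schema(therapy, schemas.get("therapy"))
    demographic = apply_schema(demographic, schemas.get("demographic"))
    reaction = apply_schema(reaction, schemas.get("reaction"))

    prov = Provenance()
    drug = deduplicate(drug, DRUG_KEYS, provenance=prov, table_name="drug")
    reaction = deduplicate(reaction, REACTION_KEYS, provenance=prov,
                           table_name="reaction")
    version = "caseversion" if "caseversion" in demographic.columns else None
    demographic = deduplicate(demographic, DEMO_KEYS, version_column=version,
                              provenance=prov, table_name="demographic")
    therapy = deduplicate(therapy, THERAPY_KEYS, provenance=prov,
                          table_name="therapy")

    drug = filter_suspect_drugs(drug, provenance=prov)
    merged = merge_tables(drug, therapy, demographic, reaction, provenance=prov)
    cleaned = apply_timeseries_filter(merged, provenance=prov)
    cleaned = flag_target_event(cleaned, target_term)
    prov.rows_out = len(cleaned)
    assert prov.reconciles()
    return AnalysisTable(frame=cleaned, provenance=prov)
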