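"""CSV schemas for necropsy records, HI results and simulation ground truth.

The record schema is one row per animal with the eight HI parameters as
columns; system-set cells hold semicolon-separated controlled-vocabulary
tokens.  An empty cell means "not assessed"; an assessed parameter with no
affected systems is written as the reserved token ``none`` so that missing
and empty survive a round trip.  Malformed rows are rejected with row-level
diagnostics, never silently coerced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .cohort import CohortSummary
from .scoring import HIResult, NecropsyRecord, OrganSystem, Parameter, Taxon
from .simulate import SimulatedCohort

__all__ = [
    "RECORD_COLUMNS",
    "ReadReport",
    "read_records",
    "write_records",
    "write_results",
    "read_results",
    "write_summaries",
    "write_ground_truth",
    "read_hi_table",
]

RECORD_COLUMNS = (
    "record_id",
    "taxon",
    "species",
    "carcass_code",
    "body_score",
    "systems_macro",
    "cutaneous_score",
    "systems_organized",
    "systems_histo",
    "parasitosis_score",
    "lymphoid_depletion_score",
    "thyroid_score",
)

_ORDINAL_COLUMNS = (
    "body_score",
    "cutaneous_score",
    "parasitosis_score",
    "lymphoid_depletion_score",
    "thyroid_score",
)
_SYSTEM_COLUMNS = ("systems_macro", "systems_organized", "systems_histo")

#: Reserved system-set token: parameter assessed, zero affected systems.
EMPTY_SET_TOKEN = "none"

FRESH_CODE = 2


@dataclass
class ReadReport:
    """Accounting for one read: every input row lands in exactly one bucket."""

    n_rows: int = 0
    n_accepted: int = 0
    n_filtered: int = 0
    rejections: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)


def _parse_ordinal(cell: str, column: str) -> Optional[int]:
    if cell == "":
        return None
    try:
        value = int(cell)
    except ValueError:
        raise ValueError(f"{column}: {cell!r} is not an integer") from None
    if not 0 <= value <= 3:
        raise ValueError(f"{column}: {value} outside ordinal range 0-3")
    return value


def _parse_systems(cell: str, column: str) -> Optional[frozenset]:
    if cell == "":
        return None
    if cell.strip() == EMPTY_SET_TOKEN:
        return frozenset()
    tokens = [t.strip() for t in cell.split(";") if t.strip()]
    systems = []
    for token in tokens:
        try:
            systems.append(OrganSystem(token))
        except ValueError:
            raise ValueError(f"{column}: unknown organ system token {token!r}") from None
    if len(set(systems)) != len(systems):
        dupes = sorted({s.value for s in systems if systems.count(s) > 1})
        raise ValueError(f"{column}: duplicate organ system token(s) {', '.join(dupes)}")
    return frozenset(systems)


def _row_to_record(row: pd.Series) -> NecropsyRecord:
    try:
        taxon = Taxon(row["taxon"])
    except ValueError:
        raise ValueError(f"taxon: unknown taxon {row['taxon']!r}") from None
    try:
        carcass_code = int(row["carcass_code"])
    except ValueError:
        raise ValueError(f"carcass_code: {row['carcass_code']!r} is not an integer") from None
    kwargs = {}
    for column in _ORDINAL_COLUMNS:
        kwargs[column] = _parse_ordinal(row[column], column)
    for column in _SYSTEM_COLUMNS:
        kwargs[column] = _parse_systems(row[column], column)
    return NecropsyRecord(
        record_id=str(row["record_id"]),
        taxon=taxon,
        species=str(row["species"]),
        carcass_code=carcass_code,
        **kwargs,
    )


def read_records(path: Union[str, Path],
                 filter_fresh: bool = True) -> tuple[list[NecropsyRecord], ReadReport]:
    """Read the record CSV, optionally keeping only fresh carcasses (code 2).

    Returns the accepted records and a :class:`ReadReport` with the dropped
    count and per-row rejection diagnostics.  Unknown columns are ignored;
    a missing mandatory column raises.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing_cols)}")

    report = ReadReport(n_rows=len(df))
    records: list[NecropsyRecord] = []
    for i, row in df.iterrows():
        try:
            record = _row_to_record(row)
        except ValueError as exc:
            report.rejections.append((int(i) + 2, str(exc)))  # +2: header + 1-based
            continue
        if filter_fresh and record.carcass_code != FRESH_CODE:
            report.n_filtered += 1
            continue
        records.append(record)
    report.n_accepted = len(records)
    return records, report


def _systems_cell(systems: Optional[frozenset]) -> str:
    if systems is None:
        return ""
    if not systems:
        return EMPTY_SET_TOKEN
    return ";".join(sorted(s.value for s in systems))


def write_records(records: Sequence[NecropsyRecord], path: Union[str, Path]) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "record_id": r.record_id,
                "taxon": Taxon(r.taxon).value,
                "species": r.species,
                "carcass_code": r.carcass_code,
                "body_score": "" if r.body_score is None else r.body_score,
                "systems_macro": _systems_cell(r.systems_macro),
                "cutaneous_score": "" if r.cutaneous_score is None else r.cutaneous_score,
                "systems_organized": _systems_cell(r.systems_organized),
                "systems_histo": _systems_cell(r.systems_histo),
                "parasitosis_score": "" if r.parasitosis_score is None else r.parasitosis_score,
                "lymphoid_depletion_score": ""
                if r.lymphoid_depletion_score is None
                else r.lymphoid_depletion_score,
                "thyroid_score": "" if r.thyroid_score is None else r.thyroid_score,
            }
        )
    pd.DataFrame(rows, columns=list(RECORD_COLUMNS)).to_csv(path, index=False)


def write_results(results: Sequence[HIResult], path: Union[str, Path]) -> None:
    """HI results CSV: ``NA`` marks an indeterminable HI; values to 4 decimals."""
    rows = []
    for res in results:
        row = {
            "record_id": res.record_id,
            "hi": f"{res.hi:.4f}" if res.determinable else "NA",
            "determinable": res.determinable,
            "missing_parameters": ";".join(res.missing_parameters),
            "raw_sum": res.raw_sum if res.determinable else "",
            "himax": res.himax,
        }
        for p in Parameter:
            row[f"value_{p.value}"] = res.value_of(p) if res.determinable else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_results(path: Union[str, Path]) -> pd.DataFrame:
    """Read a results CSV back; the ``hi`` column is float with NaN for NA."""
    df = pd.read_csv(path, dtype={"record_id": str}, na_values=["NA"], keep_default_na=False)
    df["hi"] = pd.to_numeric(df["hi"], errors="coerce")
    return df


def write_summaries(summaries: Sequence[CohortSummary], path: Union[str, Path]) -> None:
    pd.DataFrame(
        {
            "group": [s.group_label for s in summaries],
            "n": [s.n for s in summaries],
            "mean_hi": [s.mean_hi for s in summaries],
            "sd_hi": [s.sd_hi for s in summaries],
            "min_hi": [s.min_hi for s in summaries],
            "max_hi": [s.max_hi for s in summaries],
            "g1": [s.g1 for s in summaries],
        }
    ).to_csv(path, index=False)


def write_ground_truth(cohort: SimulatedCohort, path: Union[str, Path]) -> None:
    pd.DataFrame(
        {
            "record_id": [r.record_id for r in cohort.records],
            "latent_morbidity": [cohort.latent_morbidity[r.record_id] for r in cohort.records],
            "vet_rating": [cohort.vet_rating[r.record_id] for r in cohort.records],
        }
    ).to_csv(path, index=False)


def read_hi_table(path: Union[str, Path],
                  hi_column: str = "hi",
                  group_column: Optional[str] = None) -> pd.DataFrame:
    """Loose reader for any CSV carrying an HI-value column.

    Intended for benchmark summaries over externally produced tables (for
    example a deposited raw-HI dataset) whose exact layout is not ours.
    Non-numeric and out-of-range HI cells are dropped.  Returns a frame with
    columns ``hi`` and, if requested, ``group``.
    """
    df = pd.read_csv(path)
    if hi_column not in df.columns:
        raise ValueError(f"no column {hi_column!r} in {path}")
    out = pd.DataFrame({"hi": pd.to_numeric(df[hi_column], errors="coerce")})
    if group_column is not None:
        if group_column not in df.columns:
            raise ValueError(f"no column {group_column!r} in {path}")
        out["group"] = df[group_column].astype(str)
    out = out.dropna(subset=["hi"])
    out = out[(out["hi"] >= 0) & (out["hi"] <= 1)]
    return out.reset_index(drop=True)
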