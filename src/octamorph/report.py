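"""Per-subject/site morphometry reports and summary statistics.

A :class:`MorphometryReport` holds one row per (subject, site) with the
measured quantities — vessel density (%), vessel diameter (mean ± SD, µm) and
epithelial thickness (µm) — with missing cells allowed (e.g., where the
dermal–epidermal junction could not be distinguished).  Missing cells
serialize as empty CSV fields and render as an em-dash in the human-readable
table.  A packaged fixture ships the published clinical reference table in
the same format so summary statistics can be checked against printed values.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .quantify import SITES

__all__ = [
    "COLUMNS",
    "NUMERIC_COLUMNS",
    "MorphometryReport",
    "SummaryStats",
    "summarize",
    "load_reference_table",
]

COLUMNS = ["subject_id", "group", "site", "density_pct",
           "diameter_mean_um", "diameter_sd_um", "vuet_um"]
NUMERIC_COLUMNS = ["density_pct", "diameter_mean_um", "diameter_sd_um", "vuet_um"]
_FLOAT_FMT = "%.10g"


@dataclass
class MorphometryReport:
    """Wrapper around a DataFrame with one row per (subject, site)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"report missing columns {missing}")
        self.df = self.df[COLUMNS].reset_index(drop=True)
        for c in NUMERIC_COLUMNS:
            self.df[c] = pd.to_numeric(self.df[c], errors="coerce")
        dup = self.df.duplicated(subset=["subject_id", "site"])
        if dup.any():
            raise ValueError("duplicate (subject, site) rows in report")
        vals = self.df[NUMERIC_COLUMNS].to_numpy(dtype=float)
        if np.nan_to_num(vals, nan=0.0).min() < 0:
            raise ValueError("numeric cells must be nonnegative")

    @classmethod
    def from_rows(cls, rows: list[dict]) -> "MorphometryReport":
        return cls(pd.DataFrame(rows, columns=COLUMNS))

    def to_csv(self, path: str | Path) -> None:
        """Missing cells are written as empty fields; a fixed float format
        keeps rewrites byte-identical."""
        self.df.to_csv(path, index=False, float_format=_FLOAT_FMT, na_rep="")

    @classmethod
    def from_csv(cls, path: str | Path) -> "MorphometryReport":
        return cls(pd.read_csv(path, dtype={"subject_id": str}))

    def render_table(self) -> str:
        """Human-readable table with em-dashes for missing cells."""
        disp = self.df.copy()
        for c in NUMERIC_COLUMNS:
            disp[c] = disp[c].map(
                lambda v: "—" if pd.isna(v) else f"{v:g}")
        return disp.to_string(index=False)


@dataclass
class SummaryStats:
    """Per-column min / max / n_nonmissing, thickness broken out per
    anatomical site, and per-group aggregates.  ``None`` marks an
    all-missing column."""

    columns: dict
    vuet_by_site: dict
    by_group: dict
    n_rows: int

    def to_dict(self) -> dict:
        return {
            "columns": self.columns,
            "vuet_by_site": self.vuet_by_site,
            "by_group": self.by_group,
            "n_rows": self.n_rows,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _col_stats(series: pd.Series) -> dict:
    vals = pd.to_numeric(series, errors="coerce").dropna()
    if vals.empty:
        return {"min": None, "max": None, "n_nonmissing": 0}
    return {"min": float(vals.min()), "max": float(vals.max()),
            "n_nonmissing": int(vals.size)}


def summarize(report: MorphometryReport) -> SummaryStats:
    """Exact arithmetic summary of a report: column ranges and counts
    (ignoring missing), thickness per site, and per-group aggregates."""
    df = report.df
    if df.empty:
        raise ValueError("report is empty")
    columns = {c: _col_stats(df[c]) for c in NUMERIC_COLUMNS}
    vuet_by_site = {}
    for site in SITES:
        sub = df[df["site"] == site]
        if not sub.empty:
            vuet_by_site[site] = _col_stats(sub["vuet_um"])
    by_group = {}
    for grp, sub in df.groupby("group"):
        by_group[str(grp)] = {c: _col_stats(sub[c]) for c in NUMERIC_COLUMNS}
    return SummaryStats(columns=columns, vuet_by_site=vuet_by_site,
                        by_group=by_group, n_rows=int(len(df)))


def load_reference_table() -> MorphometryReport:
    """The packaged clinical reference table (8 subjects × 3 vulvar sites;
    vessel density and diameter measured on the labia minora; epithelial
    thickness per site, with missing values where the DEJ was not
    distinguishable)."""
    with resources.files("octamorph.data").joinpath("table1.csv").open() as f:
        return MorphometryReport(pd.read_csv(f, dtype={"subject_id": str}))
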