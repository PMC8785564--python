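"""Reading, validating and reshaping long-format bioassay tables.

The canonical input is a delimited text file with one row per batch of
organisms: a population label, the dose applied (0 marks an unexposed
control batch), the number of organisms exposed and the number that
responded.  Column matching is case-insensitive and tolerates the common
synonyms (``Strain`` for population, ``Insecticide`` for stimulus).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

#: canonical column -> accepted (lower-cased) header names
_SYNONYMS = {
    "population": ("strain", "population", "populations", "pop"),
    "dose": ("dose", "conc", "concentration"),
    "total": ("total", "n", "exposed"),
    "dead": ("dead", "responded", "response"),
    "replicate": ("replicate", "rep"),
    "date": ("date",),
    "stimulus": ("insecticide", "stimulus", "compound"),
}
MANDATORY = ("population", "dose", "total", "dead")
_WRITE_HEADERS = {
    "population": "Strain",
    "dose": "Dose",
    "total": "Total",
    "dead": "Dead",
    "replicate": "Replicate",
    "date": "Date",
    "stimulus": "Insecticide",
}


@dataclass
class AssayTable:
    """A validated long-format bioassay table.

    Parameters
    ----------
    data
        One row per batch with canonical columns ``population``, ``dose``,
        ``total``, ``dead``, ``replicate`` (and optionally ``date``,
        ``stimulus``).  Dose 0 identifies control batches.
    dose_unit
        Free-text unit label; doses are never converted, all reporting is
        in input units.
    """

    data: pd.DataFrame
    dose_unit: str | None = None

    def __post_init__(self) -> None:
        missing = [c for c in (*MANDATORY, "replicate") if c not in self.data.columns]
        if missing:
            raise SchemaError(f"missing canonical column(s): {', '.join(missing)}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.data["population"]))

    def for_population(self, population: str) -> "AssayTable":
        sub = self.data[self.data["population"] == population]
        return AssayTable(sub.reset_index(drop=True), self.dose_unit)

    def mortality(self) -> pd.Series:
        """Raw observed mortality dead/total per row."""
        return self.data["dead"] / self.data["total"]


def _resolve_columns(columns: list[str]) -> dict[str, str]:
    lower = {str(c).strip().lower(): c for c in columns}
    mapping: dict[str, str] = {}
    for canon, names in _SYNONYMS.items():
        for name in names:
            if name in lower:
                mapping[canon] = lower[name]
                break
    return mapping


def read_assay_table(
    path: str | Path,
    delimiter: str | None = None,
    dose_unit: str | None = None,
) -> AssayTable:
    """Read a delimited bioassay table from disk.

    CSV is the default; tab delimiting is auto-detected from a ``.tsv``
    extension.  Header row required; column order is irrelevant.

    Raises
    ------
    SchemaError
        If a mandatory column is absent or the data section is empty.
    ParseError
        If dose/total/dead cannot be parsed as numbers (reports the
        1-based file row).
    ValidationError
        If a record violates ``dead <= total``, ``total >= 1`` or
        ``dose >= 0`` (reports the 1-based file row).
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    raw = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)
    mapping = _resolve_columns(list(raw.columns))
    missing = [c for c in MANDATORY if c not in mapping]
    if missing:
        raise SchemaError(
            f"{path.name}: missing mandatory column(s): {', '.join(missing)} "
            f"(headers found: {', '.join(map(str, raw.columns))})"
        )
    if len(raw) == 0:
        raise SchemaError(f"{path.name}: header present but no data rows")

    out = pd.DataFrame(index=raw.index)
    out["population"] = raw[mapping["population"]].astype(str).str.strip()
    for canon, kind in (("dose", float), ("total", int), ("dead", int)):
        col = pd.to_numeric(raw[mapping[canon]], errors="coerce")
        bad = col.isna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"column '{mapping[canon]}' value "
                f"{raw[mapping[canon]].iloc[i]!r} is not numeric",
                row=i + 2,  # +1 header, +1 one-based
            )
        if kind is int:
            frac = (col % 1 != 0)
            if frac.any():
                i = int(np.flatnonzero(frac.to_numpy())[0])
                raise ParseError(
                    f"column '{mapping[canon]}' value {col.iloc[i]} is not an integer",
                    row=i + 2,
                )
            col = col.astype(int)
        out[canon] = col

    if "replicate" in mapping:
        out["replicate"] = raw[mapping["replicate"]].astype(str).str.strip()
    else:
        out["replicate"] = "1"
    for canon in ("date", "stimulus"):
        if canon in mapping:
            out[canon] = raw[mapping[canon]].astype(str).str.strip()

    _validate_records(out)
    return AssayTable(out, dose_unit=dose_unit)


def _validate_records(df: pd.DataFrame) -> None:
    for cond, msg in (
        (df["total"] < 1, "total must be >= 1"),
        (df["dead"] < 0, "dead must be >= 0"),
        (df["dose"] < 0, "dose must be >= 0"),
        (df["dead"] > df["total"], "dead exceeds total"),
    ):
        if cond.any():
            i = int(np.flatnonzero(cond.to_numpy())[0])
            raise ValidationError(msg, row=i + 2)


def write_assay_table(table: AssayTable, path: str | Path, delimiter: str | None = None) -> None:
    """Write a table back to delimited text with canonical headers."""
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    cols = [c for c in _WRITE_HEADERS if c in table.data.columns]
    out = table.data[cols].rename(columns=_WRITE_HEADERS)
    out.to_csv(path, sep=delimiter, index=False)


def split_controls(table: AssayTable) -> tuple[AssayTable, AssayTable]:
    """Partition into (controls, treatments) by ``dose == 0``."""
    is_control = table.data["dose"] == 0
    controls = AssayTable(table.data[is_control].reset_index(drop=True), table.dose_unit)
    treatments = AssayTable(table.data[~is_control].reset_index(drop=True), table.dose_unit)
    return controls, treatments


def aggregate_replicates(table: AssayTable) -> AssayTable:
    """Pool replicates: one row per population x dose with summed counts.

    The replicate label becomes ``"pooled"``; the optional stimulus label
    is kept as a grouping key when present (pooling never mixes stimuli),
    dates are dropped.
    """
    keys = ["population", "dose"]
    if "stimulus" in table.data.columns:
        keys = ["stimulus", *keys]
    pooled = (
        table.data.groupby(keys, sort=False, as_index=False)[["total", "dead"]].sum()
    )
    pooled["replicate"] = "pooled"
    return AssayTable(pooled, table.dose_unit)
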