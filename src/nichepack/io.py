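"""Reading, validating and writing community trait and isotope tables.

Two on-disk schemas are supported, both plain delimited text with a header
row:

* **trait tables** — one row per captured specimen: identifiers
  (``specimen_id``, ``species``, ``site``, ``foraging_group``), body mass in
  grams and up to ten linear measurements in millimetres (four external:
  total, tail, forearm, hindfoot length; six craniodental: GSKL, ZYGO, GBW,
  MAND, CM3, CC).
* **isotope tables** — one row per specimen: the same identifiers plus
  ``d13C`` and ``d15N`` in per mil (‰).

Column headers are configurable through a mapping (optionally loaded from
YAML) so that files from different labs can be read without editing them;
the delimiter is auto-detected among comma, semicolon and tab. Missing
measurement cells are preserved as missing (NaN), never silently zeroed.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FORAGING_GROUPS",
    "TRAIT_NAMES",
    "ID_COLUMNS",
    "ValidationError",
    "load_schema",
    "read_trait_table",
    "read_isotope_table",
    "write_table",
    "aggregate_to_species",
]

#: The four functional foraging groups used to classify bat species.
FORAGING_GROUPS = ("open", "edge", "clutter", "fruitbat")

#: The ten linear measurements entering the size-corrected morphospace.
#: External measurements are recorded to 1 mm (forearm to 0.1 mm),
#: craniodental measurements to 0.01 mm.
TRAIT_NAMES = (
    "total_length",
    "tail_length",
    "forearm_length",
    "hindfoot_length",
    "GSKL",
    "ZYGO",
    "GBW",
    "MAND",
    "CM3",
    "CC",
)

ID_COLUMNS = ("specimen_id", "species", "site", "foraging_group")

_ISOTOPE_COLUMNS = ("d13C", "d15N")


class ValidationError(ValueError):
    """A table failed schema validation; the message names offending rows."""


def load_schema(path: str | Path) -> dict[str, str]:
    """Load a ``{file column -> canonical column}`` mapping from YAML."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, Mapping):
        raise ValidationError(f"schema file {path} must contain a mapping")
    return {str(k): str(v) for k, v in mapping.items()}


def _sniff_delimiter(path: Path) -> str:
    sample = path.read_text(errors="replace")[:4096]
    try:
        return csv.Sniffer().sniff(sample, delimiters=",;\t").delimiter
    except csv.Error:
        return ","


def _read_raw(path: str | Path, schema: Mapping[str, str] | None) -> pd.DataFrame:
    path = Path(path)
    if not path.is_file():
        raise OSError(f"cannot read table: {path} does not exist")
    df = pd.read_csv(path, sep=_sniff_delimiter(path), skipinitialspace=True)
    if schema:
        df = df.rename(columns=dict(schema))
    df.columns = [str(c).strip() for c in df.columns]
    return df


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")


def _check_groups(df: pd.DataFrame, path) -> None:
    groups = df["foraging_group"].astype(str).str.strip().str.lower()
    bad = sorted(set(groups) - set(FORAGING_GROUPS))
    if bad:
        rows = [int(i) + 2 for i in df.index[groups.isin(bad)]]  # 1-based + header
        raise ValidationError(
            f"{path}: unknown foraging group label(s) {bad} in file row(s) {rows}; "
            f"expected one of {list(FORAGING_GROUPS)}"
        )
    df["foraging_group"] = groups


def read_trait_table(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read and validate a per-specimen trait table.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    schema
        Optional ``{file column -> canonical column}`` renaming applied
        before validation (see :func:`load_schema`).

    Returns
    -------
    DataFrame with the identifier columns, ``body_mass`` (g) and the ten
    trait columns (mm); absent trait columns are created as all-missing.
    Blank measurement cells stay NaN.

    Raises
    ------
    ValidationError
        On unknown foraging-group labels, non-positive masses or traits,
        or non-numeric measurement cells, naming the offending rows.
    """
    df = _read_raw(path, schema)
    _require_columns(df, ID_COLUMNS + ("body_mass",), path)
    _check_groups(df, path)
    for col in ("body_mass",) + TRAIT_NAMES:
        if col not in df.columns:
            df[col] = np.nan
            continue
        raw = df[col]
        df[col] = pd.to_numeric(raw, errors="coerce")
        bad = df.index[raw.notna() & df[col].isna()]
        if len(bad):
            raise ValidationError(
                f"{path}: non-numeric value(s) in column {col!r}, "
                f"file row(s) {[int(i) + 2 for i in bad]}"
            )
    bad_mass = df.index[~(df["body_mass"] > 0)]
    if len(bad_mass):
        raise ValidationError(
            f"{path}: body_mass must be positive; "
            f"file row(s) {[int(i) + 2 for i in bad_mass]}"
        )
    for col in TRAIT_NAMES:
        bad = df.index[df[col].notna() & (df[col] <= 0)]
        if len(bad):
            raise ValidationError(
                f"{path}: trait {col!r} must be positive where present; "
                f"file row(s) {[int(i) + 2 for i in bad]}"
            )
    return df[list(ID_COLUMNS) + ["body_mass"] + list(TRAIT_NAMES)]


def read_isotope_table(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read and validate a per-specimen isotope table (δ13C, δ15N in ‰)."""
    df = _read_raw(path, schema)
    _require_columns(df, ID_COLUMNS + _ISOTOPE_COLUMNS, path)
    _check_groups(df, path)
    for col in _ISOTOPE_COLUMNS:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[~np.isfinite(numeric)]
        if len(bad):
            raise ValidationError(
                f"{path}: column {col!r} must be finite and numeric; "
                f"file row(s) {[int(i) + 2 for i in bad]}"
            )
        df[col] = numeric
    return df[list(ID_COLUMNS) + list(_ISOTOPE_COLUMNS)]


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table as comma-delimited text (full precision, NaN blank)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def aggregate_to_species(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-specimen records to per-(site, species) mean records.

    Numeric fields are averaged over a species' specimens within a site;
    missing cells are excluded pairwise, so a trait's mean uses only the
    specimens that have it. The foraging group is carried over from the
    specimens and must be unique per (site, species).
    """
    if records.empty:
        raise ValidationError("cannot aggregate an empty table")
    numeric = [c for c in records.columns if pd.api.types.is_numeric_dtype(records[c])]
    conflicts = (
        records.groupby(["site", "species"])["foraging_group"].nunique(dropna=True)
    )
    bad = conflicts[conflicts > 1]
    if len(bad):
        pairs = [f"{s}/{sp}" for s, sp in bad.index]
        raise ValidationError(
            f"species assigned to multiple foraging groups within a site: {pairs}"
        )
    grouped = records.groupby(["site", "species"], sort=True)
    out = grouped[numeric].mean()
    out["foraging_group"] = grouped["foraging_group"].first()
    out["n_specimens"] = grouped.size()
    return out.reset_index()
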