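"""CSV readers/writers and validation for every pipeline input.

CSV is the single interchange format: UTF-8, "." decimal separator. Values
copied out of publications often carry the Unicode minus (U+2212), en dashes
in range labels, and the micro sign; all are normalized to ASCII on parse so
that "−18.2" reads as -18.2 and "200–1000 µm" matches "200-1000 um".

Readers validate the full table and raise :class:`ValidationError` carrying
*every* offending cell, not just the first, so a report can show all problems
in one pass. Writers are exact inverses of readers on valid data.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    CONSUMER_GROUP,
    MONTH_ORDER_DEFAULT,
    SIZE_CLASSES,
    EnvAvailabilityTable,
    FattyAcidTable,
    IsotopeSampleSet,
    PreyCountTable,
    SchemaError,
    ValidationError,
)

_CHAR_MAP = str.maketrans({
    "−": "-",   # minus sign
    "–": "-",   # en dash
    "—": "-",   # em dash
    "µ": "u",   # micro sign
    "μ": "u",   # greek mu
})


def normalize_text(s: str) -> str:
    """Normalize publication-style glyphs to ASCII equivalents."""
    return str(s).translate(_CHAR_MAP).strip()


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.empty and df.columns.empty:
        raise ValidationError([f"{path}: empty file"])
    df.columns = [normalize_text(c) for c in df.columns]
    return df


def _to_number(raw: str, *, where: str, problems: list[str],
               integer: bool = False, nonnegative: bool = False) -> float:
    s = normalize_text(raw)
    if s == "":
        problems.append(f"{where}: missing value")
        return math.nan
    try:
        x = float(s)
    except ValueError:
        problems.append(f"{where}: non-numeric value {raw!r}")
        return math.nan
    if integer and not float(x).is_integer():
        problems.append(f"{where}: non-integer count {raw!r}")
    if nonnegative and x < 0:
        problems.append(f"{where}: negative value {raw!r}")
    return x


def _check_months(values: Sequence[str], months: Sequence[str], problems: list[str]) -> None:
    allowed = set(months)
    for i, m in enumerate(values):
        if m not in allowed:
            problems.append(f"row {i}: month {m!r} not in calendar {list(months)}")


# ---------------------------------------------------------------- prey counts

def read_prey_counts(path, schema: Mapping[str, str] | None = None,
                     months: Sequence[str] = MONTH_ORDER_DEFAULT) -> PreyCountTable:
    """Read per-predator stomach counts; every non-id column is a taxon.

    ``schema`` optionally maps the canonical column names ``predator_id`` and
    ``month`` to the file's actual headers. Missing taxon cells are structural
    zeros; negative or fractional counts are validation errors.
    """
    df = _read_csv(path)
    schema = dict(schema or {})
    rename = {schema.get(k, k): k for k in ("predator_id", "month")}
    df = df.rename(columns=rename)
    problems: list[str] = []
    if "month" not in df.columns:
        raise SchemaError([f"{path}: required column 'month' missing"])
    if "predator_id" not in df.columns:
        df.insert(0, "predator_id", [f"P{i}" for i in range(len(df))])
    taxa = [c for c in df.columns if c not in ("predator_id", "month")]
    if not taxa:
        raise SchemaError([f"{path}: no taxon columns found"])
    df["month"] = [normalize_text(m) for m in df["month"]]
    _check_months(df["month"], months, problems)
    for t in taxa:
        vals = []
        for i, raw in enumerate(df[t]):
            if normalize_text(raw) == "":
                vals.append(0.0)  # structural zero
                continue
            vals.append(_to_number(raw, where=f"row {i}, taxon {t!r}",
                                   problems=problems, integer=True, nonnegative=True))
        df[t] = vals
    if problems:
        raise ValidationError(problems)
    df[taxa] = df[taxa].astype(np.int64)
    return PreyCountTable(data=df.reset_index(drop=True), taxa=tuple(taxa),
                          months=tuple(months))


def write_prey_counts(table: PreyCountTable, path) -> None:
    table.data.to_csv(path, index=False)


# ---------------------------------------------------- environment availability

def read_env_availability(path, months: Sequence[str] = MONTH_ORDER_DEFAULT
                          ) -> EnvAvailabilityTable:
    """Read zooplankton densities (ind m^-3); optional ``volume_sampled`` m^3."""
    df = _read_csv(path)
    problems: list[str] = []
    if "month" not in df.columns:
        raise SchemaError([f"{path}: required column 'month' missing"])
    if "sample_id" not in df.columns:
        df.insert(0, "sample_id", [f"E{i}" for i in range(len(df))])
    meta = ["sample_id", "month"]
    if "volume_sampled" in df.columns:
        meta.append("volume_sampled")
    taxa = [c for c in df.columns if c not in meta]
    if not taxa:
        raise SchemaError([f"{path}: no taxon columns found"])
    df["month"] = [normalize_text(m) for m in df["month"]]
    _check_months(df["month"], months, problems)
    for c in taxa + (["volume_sampled"] if "volume_sampled" in meta else []):
        df[c] = [
            _to_number(raw, where=f"row {i}, column {c!r}", problems=problems,
                       nonnegative=True)
            for i, raw in enumerate(df[c])
        ]
    if problems:
        raise ValidationError(problems)
    return EnvAvailabilityTable(data=df.reset_index(drop=True), taxa=tuple(taxa),
                                months=tuple(months))


def write_env_availability(table: EnvAvailabilityTable, path) -> None:
    table.data.to_csv(path, index=False)


# ------------------------------------------------------------------- isotopes

_D13C_PLAUSIBLE = (-40.0, 0.0)


def read_isotope_samples(path, months: Sequence[str] = MONTH_ORDER_DEFAULT
                         ) -> IsotopeSampleSet:
    """Read δ13C/δ15N records (per mil) with a group label per row.

    Group labels may be months, plankton size classes or ``"consumer"``;
    size-class spellings with µ/en-dash are interned to the canonical ASCII
    labels. δ13C outside the marine-plausible [-40, 0] per mil band triggers a
    warning, not an error.
    """
    df = _read_csv(path)
    required = {"group", "d13C", "d15N"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError([f"{path}: required columns missing: {sorted(missing)}"])
    if df.empty:
        raise ValidationError([f"{path}: no isotope records"])
    if "sample_id" not in df.columns:
        df.insert(0, "sample_id", [f"S{i}" for i in range(len(df))])
    problems: list[str] = []
    known = set(months) | set(SIZE_CLASSES) | {CONSUMER_GROUP}
    groups = []
    for g in df["group"]:
        g = normalize_text(g)
        groups.append(g)
        if g not in known:
            warnings.warn(f"isotope group {g!r} is not a month, size class or "
                          f"'{CONSUMER_GROUP}'", stacklevel=2)
            known.add(g)
    df["group"] = groups
    for iso in ("d13C", "d15N"):
        df[iso] = [
            _to_number(raw, where=f"sample {sid!r}, {iso}", problems=problems)
            for sid, raw in zip(df["sample_id"], df[iso])
        ]
    if problems:
        raise ValidationError(problems)
    lo, hi = _D13C_PLAUSIBLE
    odd = df.loc[(df["d13C"] < lo) | (df["d13C"] > hi), "sample_id"]
    if len(odd):
        warnings.warn(f"d13C outside [{lo}, {hi}] per mil for samples "
                      f"{list(odd)}", stacklevel=2)
    return IsotopeSampleSet(data=df[["sample_id", "group", "d13C", "d15N"]]
                            .reset_index(drop=True))


def write_isotope_samples(samples: IsotopeSampleSet, path) -> None:
    samples.data.to_csv(path, index=False)


# ---------------------------------------------------------------- fatty acids

def read_fa_profiles(path, months: Sequence[str] = MONTH_ORDER_DEFAULT,
                     strict: bool = False) -> FattyAcidTable:
    """Read wide per-sample FA concentrations (µg per mg dry tissue).

    FA column names are normalized to canonical shorthand (``C18:1(n-9)`` →
    ``C18:1n-9``). Columns that do not parse as FA shorthand are kept but
    flagged in ``unrecognized`` (strict mode raises instead).
    """
    from .fatty_acids import normalize_fa_name

    df = _read_csv(path)
    if "month" not in df.columns:
        raise SchemaError([f"{path}: required column 'month' missing"])
    if df.empty:
        raise ValidationError([f"{path}: no FA records"])
    if "sample_id" not in df.columns:
        df.insert(0, "sample_id", [f"F{i}" for i in range(len(df))])
    for col, default in (("sex", "none"), ("tissue", "soma")):
        if col not in df.columns:
            df[col] = default
    meta = ["sample_id", "month", "sex", "tissue"]
    if "size_class" in df.columns:
        meta.append("size_class")
        df["size_class"] = [normalize_text(v) for v in df["size_class"]]
    problems: list[str] = []
    df["month"] = [normalize_text(m) for m in df["month"]]
    _check_months(df["month"], months, problems)
    raw_fa_cols = [c for c in df.columns if c not in meta]
    if not raw_fa_cols:
        raise SchemaError([f"{path}: no fatty-acid columns found"])
    fa_cols, unrecognized, rename = [], [], {}
    for c in raw_fa_cols:
        try:
            canon = normalize_fa_name(c)
        except ValueError:
            if strict:
                problems.append(f"column {c!r}: unparseable FA shorthand")
            unrecognized.append(c)
            canon = c
        rename[c] = canon
        fa_cols.append(canon)
    df = df.rename(columns=rename)
    for c in fa_cols:
        df[c] = [
            _to_number(raw, where=f"sample {sid!r}, FA {c!r}", problems=problems,
                       nonnegative=True)
            for sid, raw in zip(df["sample_id"], df[c])
        ]
    if problems:
        raise ValidationError(problems)
    return FattyAcidTable(data=df[meta + fa_cols].reset_index(drop=True),
                          fa_columns=tuple(fa_cols),
                          unrecognized=tuple(unrecognized), months=tuple(months))


def write_fa_profiles(table: FattyAcidTable, path) -> None:
    table.data.to_csv(path, index=False)


# ----------------------------------------------------------------- validation

_READERS = {
    "prey": read_prey_counts,
    "env": read_env_availability,
    "isotopes": read_isotope_samples,
    "fa": read_fa_profiles,
}


def validate_file(kind: str, path, months: Sequence[str] = MONTH_ORDER_DEFAULT) -> dict:
    """Run the reader for ``kind`` and return a machine-readable report."""
    if kind not in _READERS:
        raise KeyError(f"unknown input kind {kind!r}; expected one of {sorted(_READERS)}")
    report: dict = {"path": str(path), "kind": kind, "valid": True, "problems": []}
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            _READERS[kind](path, months=months)
        except (ValidationError, FileNotFoundError) as err:
            report["valid"] = False
            report["problems"] = (err.problems if isinstance(err, ValidationError)
                                  else [str(err)])
    report["warnings"] = [str(w.message) for w in caught]
    return report
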