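"""Fatty-acid nomenclature, class totals, and trophic biomarker ratios.

FA shorthand is ``C<carbons>:<double bonds>`` with an optional omega suffix
``n-<x>`` (parenthesized variants like ``C18:1(n-9)`` are tolerated and
normalized). Saturation classes follow the double-bond count: SFA (0),
MUFA (1), PUFA (>=2). Omega-3/omega-6 membership comes from the ``n-x``
suffix only; FAs without one count toward saturation classes but toward
neither omega family.

Biomarker ratios (dimensionless, per sample or per group):

- n3/n6 — omega-3 over omega-6 totals (detritus vs living-plankton signal);
- PUFA/SFA — high values indicate carnivory, low values herbivory/detritivory;
- EPA/DHA — decreases toward higher trophic levels (DHA is conserved up the
  food web; EPA = C20:5n-3, DHA = C22:6n-3).

Zero denominators yield ratios flagged undefined (NaN), never infinities.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import FattyAcidProfile, FattyAcidTable, MONTH_ORDER_DEFAULT

ALIASES: dict[str, str] = {
    "EPA": "C20:5n-3",
    "DHA": "C22:6n-3",
    "AA": "C20:4n-6",
    "palmitic": "C16:0",
}

_FA_RE = re.compile(r"^C(\d{1,2}):(\d)(?:\s*\(?n-?(\d{1,2})\)?)?$")


def normalize_fa_name(name: str, allow_aliases: bool = True) -> str:
    """Canonicalize FA shorthand; resolves common-name aliases unless disabled."""
    from .io import normalize_text

    s = normalize_text(name).replace(" ", "")
    if allow_aliases:
        for alias, canon in ALIASES.items():
            if s.lower() == alias.lower():
                return canon
    m = _FA_RE.match(s)
    if not m:
        raise ValueError(f"unparseable FA shorthand {name!r}")
    carbons, bonds, omega = m.groups()
    canon = f"C{int(carbons)}:{int(bonds)}"
    if omega is not None:
        canon += f"n-{int(omega)}"
    return canon


@dataclass(frozen=True)
class FAClass:
    name: str
    carbons: int
    double_bonds: int
    omega: int | None
    saturation_class: str  # SFA | MUFA | PUFA


def classify_fa(name: str, allow_aliases: bool = True) -> FAClass:
    """Parse FA shorthand into its structural classification."""
    canon = normalize_fa_name(name, allow_aliases=allow_aliases)
    m = _FA_RE.match(canon)
    carbons, bonds, omega = int(m.group(1)), int(m.group(2)), m.group(3)
    sat = "SFA" if bonds == 0 else ("MUFA" if bonds == 1 else "PUFA")
    return FAClass(name=canon, carbons=carbons, double_bonds=bonds,
                   omega=int(omega) if omega is not None else None,
                   saturation_class=sat)


@dataclass
class FASummary:
    """Class totals and biomarker ratios for one FA profile.

    Totals in µg per mg dry tissue; percentages of total; undefined ratios
    (zero denominator) are NaN and listed in ``undefined``.
    """

    total: float
    class_totals: dict[str, float]
    class_pct: dict[str, float]
    n3_total: float
    n6_total: float
    n3_n6: float
    pufa_sfa: float
    epa_dha: float
    undefined: frozenset[str] = field(default_factory=frozenset)


def _safe_ratio(num: float, den: float, name: str, undefined: set[str]) -> float:
    if den == 0.0:
        undefined.add(name)
        return math.nan
    return num / den


def fa_summary(profile: FattyAcidProfile | Mapping[str, float]) -> FASummary:
    """Class totals, percentages and the three biomarker ratios of one sample."""
    conc = (profile.concentrations if isinstance(profile, FattyAcidProfile)
            else dict(profile))
    parsed: list[tuple[FAClass, float]] = []
    for name, value in conc.items():
        v = float(value)
        if v < 0:
            raise ValueError(f"negative concentration for {name!r}")
        try:
            parsed.append((classify_fa(name), v))
        except ValueError:
            warnings.warn(f"skipping unclassifiable FA column {name!r}", stacklevel=2)
    total = sum(v for _, v in parsed)
    if total <= 0:
        raise ValueError("all-zero FA profile")
    class_totals = {c: 0.0 for c in ("SFA", "MUFA", "PUFA")}
    n3 = n6 = epa = dha = 0.0
    for fac, v in parsed:
        class_totals[fac.saturation_class] += v
        if fac.omega == 3:
            n3 += v
        elif fac.omega == 6:
            n6 += v
        if fac.name == ALIASES["EPA"]:
            epa += v
        elif fac.name == ALIASES["DHA"]:
            dha += v
    undefined: set[str] = set()
    return FASummary(
        total=total,
        class_totals=class_totals,
        class_pct={c: 100.0 * t / total for c, t in class_totals.items()},
        n3_total=n3, n6_total=n6,
        n3_n6=_safe_ratio(n3, n6, "n3_n6", undefined),
        pufa_sfa=_safe_ratio(class_totals["PUFA"], class_totals["SFA"],
                             "pufa_sfa", undefined),
        epa_dha=_safe_ratio(epa, dha, "epa_dha", undefined),
        undefined=frozenset(undefined),
    )


_STATS = ("total", "SFA_pct", "MUFA_pct", "PUFA_pct", "n3_n6", "pufa_sfa", "epa_dha")


def _summary_row(s: FASummary) -> dict[str, float]:
    return {"total": s.total, "SFA_pct": s.class_pct["SFA"],
            "MUFA_pct": s.class_pct["MUFA"], "PUFA_pct": s.class_pct["PUFA"],
            "n3_n6": s.n3_n6, "pufa_sfa": s.pufa_sfa, "epa_dha": s.epa_dha}


def fa_group_stats(table: FattyAcidTable | Iterable[FattyAcidProfile],
                   by: Sequence[str] = ("month", "sex", "tissue"),
                   months: tuple[str, ...] = MONTH_ORDER_DEFAULT,
                   ) -> pd.DataFrame:
    """Mean +/- SE per group of totals, class percentages and ratios.

    NaN ratios (undefined in a sample) are excluded from that ratio's group
    statistic. Groups appear in calendar order on the month key.
    """
    profiles = (table.profiles() if isinstance(table, FattyAcidTable)
                else list(table))
    if isinstance(table, FattyAcidTable):
        months = table.months
    rows = []
    for prof in profiles:
        key = {k: getattr(prof, k) for k in by}
        rows.append({**key, **_summary_row(fa_summary(prof))})
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no FA profiles to summarize")
    grouped = df.groupby(list(by), dropna=False, sort=False)
    out_rows = []
    for key, g in grouped:
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(by, key))
        row["n"] = len(g)
        for stat in _STATS:
            vals = g[stat].dropna().astype(float)
            row[f"{stat}_mean"] = float(vals.mean()) if len(vals) else math.nan
            row[f"{stat}_se"] = (float(vals.std(ddof=1) / math.sqrt(len(vals)))
                                 if len(vals) > 1 else 0.0)
        row["se_defined"] = len(g) > 1
        out_rows.append(row)
    out = pd.DataFrame(out_rows)
    if "month" in by:
        order = {m: i for i, m in enumerate(months)}
        out = out.sort_values(by=list(by),
                              key=lambda s: (s.map(order) if s.name == "month" else s),
                              kind="stable").reset_index(drop=True)
    return out


def gonad_soma_contrast(table: FattyAcidTable | Iterable[FattyAcidProfile],
                        months: tuple[str, ...] = MONTH_ORDER_DEFAULT,
                        ) -> pd.DataFrame:
    """Gonad-to-soma mean total FA ratio per (month, sex) plus overall row."""
    stats = fa_group_stats(table, by=("month", "sex", "tissue"), months=months)
    rows = []
    for (month, sex), g in stats.groupby(["month", "sex"], sort=False):
        idx = g.set_index("tissue")
        if {"gonad", "soma"} <= set(idx.index):
            rows.append({"month": month, "sex": sex,
                         "gonad_total": float(idx.loc["gonad", "total_mean"]),
                         "soma_total": float(idx.loc["soma", "total_mean"]),
                         "ratio": float(idx.loc["gonad", "total_mean"]
                                        / idx.loc["soma", "total_mean"])})
    df = pd.DataFrame(rows)
    if len(df):
        overall = {"month": "all", "sex": "all",
                   "gonad_total": df["gonad_total"].mean(),
                   "soma_total": df["soma_total"].mean(),
                   "ratio": df["gonad_total"].mean() / df["soma_total"].mean()}
        df = pd.concat([df, pd.DataFrame([overall])], ignore_index=True)
    return df
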