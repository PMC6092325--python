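"""Prey electivity: Pearre's index C with an ordinary chi-square test.

The diet margin of the 2x2 table is the pooled integer prey count over all
predators of a month; the environment margin is the net-haul densities turned
into integer pseudo-counts under a configurable policy (chi-square needs
counts, and the published record does not state an environment sample size).

For a focal taxon with diet counts (a_d, b_d) and environment counts
(a_e, b_e), Pearre's electivity index is::

    C = (a_d*b_e - b_d*a_e) / sqrt((a_d+a_e)(b_d+b_e)(a_d+b_d)(a_e+b_e))

which satisfies chi2 = n * C**2 with the ordinary (uncorrected) 2x2
chi-square on the same table, n = a_d+b_d+a_e+b_e, 1 degree of freedom.
C ranges over [-1, 1]; positive C means the taxon is over-represented in the
diet relative to the environment (positive selection).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import EnvAvailabilityTable, PreyCountTable


class DegenerateTableError(ValueError):
    """A margin of the 2x2 table is entirely zero; C is undefined."""


@dataclass(frozen=True)
class Contingency2x2:
    """Diet-vs-environment counts for one focal taxon.

    a_d/b_d: focal and other-taxa counts in the diet margin;
    a_e/b_e: same split in the environment margin.
    """

    a_d: int
    b_d: int
    a_e: int
    b_e: int

    @property
    def n(self) -> int:
        return self.a_d + self.b_d + self.a_e + self.b_e

    def __post_init__(self):
        for name in ("a_d", "b_d", "a_e", "b_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n == 0:
            raise DegenerateTableError("all four cells are zero")


@dataclass(frozen=True)
class SelectivityScore:
    C: float
    chi2: float
    p: float
    direction: str  # "+", "-", "0"


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(np.int64)


def build_contingency(taxon: str, diet: PreyCountTable, env: EnvAvailabilityTable,
                      month: str, env_pseudo_n: str | int = "volume") -> Contingency2x2:
    """Pool the month's stomach counts and environment densities into a 2x2 table.

    ``env_pseudo_n`` policies for converting densities to integer counts:

    - ``"raw"``: densities rounded half-up as-is;
    - ``"volume"``: densities x volume_sampled when the env table has volumes,
      else fall back to ``"match"``;
    - ``"match"``: density proportions x the month's pooled diet total;
    - an integer: density proportions x that pseudo-n.
    """
    if taxon not in set(diet.taxa) | set(env.taxa):
        raise KeyError(f"taxon {taxon!r} unknown to both diet and environment tables")
    diet_month = diet.month_slice(month)  # KeyError if absent
    dens = env.month_densities(month)     # KeyError if absent

    diet_counts = diet_month[list(diet.taxa)].sum(axis=0)
    a_d = int(diet_counts.get(taxon, 0))
    b_d = int(diet_counts.sum()) - a_d

    dens = dens.astype(float)
    total_dens = float(dens.sum())
    if total_dens <= 0 and (a_d + b_d) == 0:
        raise DegenerateTableError(f"month {month!r}: all-zero diet and environment")

    if env_pseudo_n == "raw":
        env_counts = _round_half_up(dens.values)
    else:
        if env_pseudo_n == "volume":
            sub = env.data[env.data["month"].astype(str) == month]
            if env.has_volume and sub["volume_sampled"].notna().all():
                vol = float(sub["volume_sampled"].astype(float).mean())
                env_counts = _round_half_up(dens.values * vol)
            else:
                env_pseudo_n = "match"
        if env_pseudo_n == "match":
            pseudo_n = a_d + b_d
            env_counts = (_round_half_up(dens.values / total_dens * pseudo_n)
                          if total_dens > 0 else np.zeros(len(dens), dtype=np.int64))
        elif isinstance(env_pseudo_n, (int, np.integer)):
            if total_dens <= 0:
                raise DegenerateTableError(f"month {month!r}: all-zero environment")
            env_counts = _round_half_up(dens.values / total_dens * int(env_pseudo_n))
    env_series = pd.Series(env_counts, index=dens.index)
    a_e = int(env_series.get(taxon, 0))
    b_e = int(env_series.sum()) - a_e
    if a_d + a_e == 0:
        raise DegenerateTableError(
            f"taxon {taxon!r} absent from both diet and environment in {month!r}")
    return Contingency2x2(a_d=a_d, b_d=b_d, a_e=a_e, b_e=b_e)


def pearre_index(t: Contingency2x2, alpha: float = 0.05) -> SelectivityScore:
    """Pearre's C with its chi-square significance (df=1, no continuity correction)."""
    margins = (t.a_d + t.a_e, t.b_d + t.b_e, t.a_d + t.b_d, t.a_e + t.b_e)
    if any(m == 0 for m in margins):
        raise DegenerateTableError(
            f"zero margin in table {(t.a_d, t.b_d, t.a_e, t.b_e)}; C undefined")
    num = t.a_d * t.b_e - t.b_d * t.a_e
    C = num / math.sqrt(math.prod(float(m) for m in margins))
    chi2 = t.n * C * C
    p = float(stats.chi2.sf(chi2, df=1))
    if p <= alpha and C > 0:
        direction = "+"
    elif p <= alpha and C < 0:
        direction = "-"
    else:
        direction = "0"
    return SelectivityScore(C=C, chi2=chi2, p=p, direction=direction)


def monthly_selectivity(diet: PreyCountTable, env: EnvAvailabilityTable,
                        alpha: float = 0.05, env_pseudo_n: str | int = "volume",
                        ) -> pd.DataFrame:
    """One selectivity score per (month, taxon); degenerate cells flagged.

    Returns a tidy frame with columns month, taxon, diet_mean, diet_se,
    a_d..b_e, C, chi2, p, direction, testable. Cells where the focal taxon is
    absent from both margins (or a margin is all zero) get testable=False.
    """
    taxa = [t for t in diet.taxa if t in env.taxa] + \
           [t for t in diet.taxa if t not in env.taxa] + \
           [t for t in env.taxa if t not in diet.taxa]
    months_present = [m for m in diet.months
                      if m in set(diet.data["month"].astype(str))
                      and m in set(env.data["month"].astype(str))]
    per_taxon = diet_totals(diet)["per_taxon"]
    rows = []
    for month in months_present:
        for taxon in taxa:
            row = {"month": month, "taxon": taxon}
            stat = per_taxon[(per_taxon["month"] == month) &
                             (per_taxon["taxon"] == taxon)]
            row["diet_mean"] = float(stat["mean"].iloc[0]) if len(stat) else 0.0
            row["diet_se"] = float(stat["se"].iloc[0]) if len(stat) else 0.0
            try:
                tab = build_contingency(taxon, diet, env, month, env_pseudo_n)
                score = pearre_index(tab, alpha=alpha)
                row.update(a_d=tab.a_d, b_d=tab.b_d, a_e=tab.a_e, b_e=tab.b_e,
                           C=score.C, chi2=score.chi2, p=score.p,
                           direction=score.direction, testable=True)
            except (DegenerateTableError, KeyError):
                row.update(a_d=np.nan, b_d=np.nan, a_e=np.nan, b_e=np.nan,
                           C=np.nan, chi2=np.nan, p=np.nan,
                           direction="", testable=False)
            rows.append(row)
    return pd.DataFrame(rows)


def per_sample_selectivity(diet: PreyCountTable, env: EnvAvailabilityTable,
                          alpha: float = 0.05, env_pseudo_n: str | int = "match",
                          ) -> pd.DataFrame:
    """Per-predator (unpooled) variant; chi-square is fragile at stomach-scale counts."""
    rows = []
    for _, pred in diet.data.iterrows():
        month = str(pred["month"])
        if month not in set(env.data["month"].astype(str)):
            continue
        one = PreyCountTable(data=pred.to_frame().T.reset_index(drop=True),
                             taxa=diet.taxa, months=diet.months)
        for taxon in diet.taxa:
            try:
                tab = build_contingency(taxon, one, env, month, env_pseudo_n)
                score = pearre_index(tab, alpha=alpha)
                rows.append({"predator_id": pred["predator_id"], "month": month,
                             "taxon": taxon, "C": score.C, "chi2": score.chi2,
                             "p": score.p, "direction": score.direction,
                             "testable": True})
            except (DegenerateTableError, KeyError):
                rows.append({"predator_id": pred["predator_id"], "month": month,
                             "taxon": taxon, "C": np.nan, "chi2": np.nan,
                             "p": np.nan, "direction": "", "testable": False})
    return pd.DataFrame(rows)


def diet_totals(diet: PreyCountTable) -> dict[str, pd.DataFrame]:
    """Mean +/- SE of prey per medusa, per month, overall and per taxon.

    ``totals``: month, n, mean, se, se_defined — mean over predators of their
    summed stomach counts, SE = sample SD / sqrt(n) (0 with se_defined=False
    when n = 1). ``per_taxon``: the same statistic per taxon.
    """
    counts = diet.counts()
    months = diet.data["month"].astype(str)
    totals_rows, taxon_rows = [], []
    for month in [m for m in diet.months if m in set(months)]:
        block = counts[months == month]
        n = len(block)
        if n == 0:
            raise ValueError(f"month {month!r} has no predators")
        tot = block.sum(axis=1).astype(float)
        se_defined = n > 1
        totals_rows.append({
            "month": month, "n": n, "mean": float(tot.mean()),
            "se": float(tot.std(ddof=1) / math.sqrt(n)) if se_defined else 0.0,
            "se_defined": se_defined,
        })
        for taxon in diet.taxa:
            col = block[taxon].astype(float)
            taxon_rows.append({
                "month": month, "taxon": taxon, "n": n, "mean": float(col.mean()),
                "se": float(col.std(ddof=1) / math.sqrt(n)) if se_defined else 0.0,
                "se_defined": se_defined,
            })
    return {"totals": pd.DataFrame(totals_rows), "per_taxon": pd.DataFrame(taxon_rows)}
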