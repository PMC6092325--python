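"""δ notation and trophic-level estimation from nitrogen isotope enrichment.

Isotope ratios R = heavy/light are expressed in per-mil deviation from an
international standard (Vienna Pee Dee Belemnite for C, atmospheric N2 for N)::

    delta = (R_sample / R_standard - 1) * 1e3

Trophic level follows the standard baseline construction: consumers enrich in
15N by a fixed amount per trophic step (default 3.2 per mil), so

    TL = (d15N_consumer - d15N_baseline) / enrichment + TL_baseline

with mesozooplanktonic calanoid copepods as the baseline at TL 2. δ13C is
carried through all summaries for source tracing (its ~2 per mil per-step
fractionation feeds the mixing model's TEF), but TL itself is N-based.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .datamodel import IsotopeSampleSet, MONTH_ORDER_DEFAULT

#: Per-trophic-level enrichments (per mil) and the copepod baseline level.
ENRICHMENT_N = 3.2
ENRICHMENT_C = 2.0
TL_REF = 2.0


@dataclass(frozen=True)
class TrophicEstimate:
    group: str
    TL: float
    d15N_f: float
    d15N_ref: float
    TL_ref: float
    enrichment: float


def delta_value(R_sample: float, R_standard: float) -> float:
    """Per-mil δ of a raw isotope ratio against its standard."""
    if R_standard <= 0:
        raise ValueError(f"R_standard must be positive, got {R_standard}")
    if R_sample < 0:
        raise ValueError(f"R_sample must be >= 0, got {R_sample}")
    return (R_sample / R_standard - 1.0) * 1e3


def ratio_from_delta(delta: float, R_standard: float) -> float:
    """Inverse of :func:`delta_value`: recover R_sample from δ (per mil)."""
    if R_standard <= 0:
        raise ValueError(f"R_standard must be positive, got {R_standard}")
    return (delta / 1e3 + 1.0) * R_standard


def trophic_level(d15N_f: float, d15N_ref: float, TL_ref: float = TL_REF,
                  enrichment: float = ENRICHMENT_N, group: str = "consumer",
                  ) -> TrophicEstimate:
    """Trophic level of a consumer δ15N against a baseline organism's δ15N."""
    if enrichment <= 0:
        raise ValueError(f"enrichment must be positive, got {enrichment}")
    TL = (d15N_f - d15N_ref) / enrichment + TL_ref
    return TrophicEstimate(group=group, TL=TL, d15N_f=d15N_f, d15N_ref=d15N_ref,
                           TL_ref=TL_ref, enrichment=enrichment)


def group_summary(samples: IsotopeSampleSet, by: str = "group",
                  months: tuple[str, ...] = MONTH_ORDER_DEFAULT) -> pd.DataFrame:
    """Mean +/- SE of δ13C and δ15N per group, in calendar order where groups
    are months. Single-sample groups report SE 0 with se_defined=False."""
    df = samples.data
    labels = list(dict.fromkeys(df[by].astype(str)))
    ordered = [m for m in months if m in labels] + [g for g in labels if g not in months]
    rows = []
    for g in ordered:
        sub = df[df[by].astype(str) == g]
        n = len(sub)
        if n == 0:
            warnings.warn(f"group {g!r} empty; skipped", stacklevel=2)
            continue
        row = {"group": g, "n": n, "se_defined": n > 1}
        for iso in ("d13C", "d15N"):
            vals = sub[iso].astype(float)
            row[f"{iso}_mean"] = float(vals.mean())
            row[f"{iso}_se"] = (float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def monthly_trophic_levels(samples: IsotopeSampleSet,
                           baseline: Mapping[str, float] | float,
                           TL_ref: float = TL_REF,
                           enrichment: float = ENRICHMENT_N,
                           months: tuple[str, ...] = MONTH_ORDER_DEFAULT,
                           ) -> pd.DataFrame:
    """Monthly consumer TL from group mean δ15N and a per-month (or global,
    scalar) copepod baseline δ15N."""
    summ = group_summary(samples, months=months)
    rows = []
    for _, r in summ.iterrows():
        g = r["group"]
        ref = baseline.get(g) if isinstance(baseline, Mapping) else float(baseline)
        if ref is None:
            warnings.warn(f"no baseline δ15N for group {g!r}; TL skipped", stacklevel=2)
            continue
        est = trophic_level(float(r["d15N_mean"]), float(ref), TL_ref, enrichment, group=g)
        rows.append({"group": g, "n": int(r["n"]), "d15N_mean": est.d15N_f,
                     "d15N_ref": est.d15N_ref, "TL": est.TL,
                     "d13C_mean": float(r["d13C_mean"])})
    return pd.DataFrame(rows)
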