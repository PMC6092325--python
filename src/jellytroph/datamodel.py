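"""Core data containers and run configuration.

All tabular data are carried as pandas DataFrames wrapped in thin dataclasses
that pin down the schema: identifier/grouping columns first, then the
measurement columns (prey taxa, isotopes, or fatty acids). Validation happens
at construction via :mod:`jellytroph.io`; the wrappers themselves only hold
already-validated frames plus the metadata the downstream statistics need
(month calendar, taxon vocabulary, FA panel).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: The sampling calendar: months with successful jellyfish collections,
#: in field order (no Oct, Jan, Mar — weather and absence from surface waters).
MONTH_ORDER_DEFAULT: tuple[str, ...] = (
    "Nov", "Dec", "Feb", "Apr", "May", "Jun", "Jul", "Sep",
)

#: Canonical plankton size-class labels used as isotope mixing sources.
SIZE_CLASS_MICRO = "<200 um"
SIZE_CLASS_MESO = "200-1000 um"
SIZE_CLASS_MACRO = ">1000 um"
SIZE_CLASSES: tuple[str, ...] = (SIZE_CLASS_MICRO, SIZE_CLASS_MESO, SIZE_CLASS_MACRO)
CONSUMER_GROUP = "consumer"

ISOTOPES: tuple[str, ...] = ("d13C", "d15N")


class ValidationError(ValueError):
    """Raised when a table violates its schema; carries *all* offending rows."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


class SchemaError(ValidationError):
    """Required columns missing or mis-typed at the header level."""


def month_categorical(values, months: Sequence[str] = MONTH_ORDER_DEFAULT) -> pd.Categorical:
    return pd.Categorical(values, categories=list(months), ordered=True)


@dataclass
class PreyCountTable:
    """Per-predator integer prey counts by taxon, with a month label per row.

    ``data`` columns: ``predator_id``, ``month``, then one integer column per
    taxon. A taxon absent from a stomach is a structural zero, never missing.
    """

    data: pd.DataFrame
    taxa: tuple[str, ...]
    months: tuple[str, ...] = MONTH_ORDER_DEFAULT

    def counts(self) -> pd.DataFrame:
        """Taxon count block, indexed like ``data``."""
        return self.data[list(self.taxa)]

    def month_slice(self, month: str) -> pd.DataFrame:
        if month not in set(self.data["month"].astype(str)):
            raise KeyError(f"month {month!r} has no predators")
        return self.data[self.data["month"].astype(str) == month]


@dataclass
class EnvAvailabilityTable:
    """Environmental zooplankton densities (individuals m^-3) per taxon.

    ``data`` columns: ``sample_id``, ``month``, optional ``volume_sampled``
    (m^3), then one non-negative real column per taxon.
    """

    data: pd.DataFrame
    taxa: tuple[str, ...]
    months: tuple[str, ...] = MONTH_ORDER_DEFAULT

    @property
    def has_volume(self) -> bool:
        return "volume_sampled" in self.data.columns

    def month_densities(self, month: str) -> pd.Series:
        """Mean density per taxon over the month's net hauls."""
        sub = self.data[self.data["month"].astype(str) == month]
        if sub.empty:
            raise KeyError(f"month {month!r} has no environmental samples")
        return sub[list(self.taxa)].mean(axis=0)


@dataclass
class IsotopeSampleSet:
    """δ13C/δ15N records (per mil) with a group label per record.

    Groups are either months (consumer time series) or source classes
    (plankton size fractions) plus the literal ``"consumer"`` label.
    """

    data: pd.DataFrame  # columns: sample_id, group, d13C, d15N

    def group(self, label: str) -> pd.DataFrame:
        sub = self.data[self.data["group"].astype(str) == label]
        if sub.empty:
            raise KeyError(f"group {label!r} has no isotope records")
        return sub

    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.data["group"].astype(str)))


@dataclass
class FattyAcidProfile:
    """One sample's FA concentration profile (µg per mg dry tissue)."""

    sample_id: str
    month: str
    sex: str  # male | female | none
    tissue: str  # gonad | soma | plankton
    concentrations: dict[str, float]
    size_class: str | None = None


@dataclass
class FattyAcidTable:
    """Wide per-sample FA concentrations keyed by month, sex and tissue.

    ``data`` columns: ``sample_id``, ``month``, ``sex``, ``tissue``, optional
    ``size_class``, then one non-negative column per FA (canonical shorthand
    ``C<carbons>:<double bonds>n-<omega>``). ``unrecognized`` lists columns
    kept verbatim because their names did not parse as FA shorthand.
    """

    data: pd.DataFrame
    fa_columns: tuple[str, ...]
    unrecognized: tuple[str, ...] = ()
    months: tuple[str, ...] = MONTH_ORDER_DEFAULT

    def profiles(self) -> list[FattyAcidProfile]:
        out = []
        for _, row in self.data.iterrows():
            out.append(
                FattyAcidProfile(
                    sample_id=str(row["sample_id"]),
                    month=str(row["month"]),
                    sex=str(row.get("sex", "none")),
                    tissue=str(row.get("tissue", "soma")),
                    size_class=(str(row["size_class"]) if "size_class" in row.index
                                and pd.notna(row["size_class"]) else None),
                    concentrations={fa: float(row[fa]) for fa in self.fa_columns},
                )
            )
        return out


@dataclass
class MCMCConfig:
    chains: int = 4
    iterations: int = 20_000
    burnin: int = 10_000
    thin: int = 5
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.iterations <= self.burnin:
            problems.append("iterations must exceed burn-in")
        if self.chains < 1:
            problems.append("need at least one chain")
        if self.thin < 1:
            problems.append("thin must be >= 1")
        if problems:
            raise ValidationError(problems)


@dataclass
class AnalysisConfig:
    """Knobs shared across pipeline stages.

    Units: enrichments in per mil per trophic level; TEF entries are
    (mean, sd) per isotope; alpha is a two-sided significance level.
    """

    alpha: float = 0.05
    enrichment_n: float = 3.2
    enrichment_c: float = 2.0
    tl_ref: float = 2.0
    tef: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"d13C": (2.0, 0.3), "d15N": (3.2, 0.1)}
    )
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    n_permutations: int = 999
    transform: str = "log1p"  # log1p | none
    env_pseudo_n: str | int = "volume"  # volume | match | raw | <int>
    months: tuple[str, ...] = MONTH_ORDER_DEFAULT

    def validate(self) -> None:
        problems = []
        if not 0.0 < self.alpha < 1.0:
            problems.append(f"alpha must be in (0,1), got {self.alpha}")
        if self.enrichment_n <= 0:
            problems.append("enrichment_n must be positive")
        if self.n_permutations < 99:
            problems.append("n_permutations must be >= 99")
        if self.transform not in ("log1p", "none"):
            problems.append(f"unknown transform {self.transform!r}")
        if problems:
            raise ValidationError(problems)
        self.mcmc.validate()

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        d = dict(d)
        if "mcmc" in d and isinstance(d["mcmc"], Mapping):
            d["mcmc"] = MCMCConfig(**d["mcmc"])
        if "months" in d:
            d["months"] = tuple(d["months"])
        if "tef" in d and isinstance(d["tef"], Mapping):
            d["tef"] = {k: tuple(v) for k, v in d["tef"].items()}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise SchemaError([f"unknown config keys: {sorted(unknown)}"])
        cfg = cls(**d)
        cfg.validate()
        return cfg
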