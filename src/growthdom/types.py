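"""Core domain types shared across the pipeline stages."""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .errors import ValidationError

#: Column order of the delimited census format read/written by the package.
CENSUS_COLUMNS = ("plot_id", "tree_id", "census_date", "dbh_cm", "species", "status")

VALID_STATUS = frozenset({"live", "dead", "thinned"})
VALID_VARIABLES = ("diameter", "basal_area", "stem_mass")


@dataclass(frozen=True)
class TreeRecord:
    """One tree's contribution to a single growth interval.

    ``size`` and ``growth`` share a dimension family chosen by the caller
    (diameter cm, basal area m2 or stem mass kg); ``weight`` is the
    per-hectare representation factor (1 for fixed-area plots).
    """

    tree_id: str
    size: float
    growth: float
    species: str = "other"
    status: str = "live"
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.size > 0:
            raise ValidationError(
                f"tree {self.tree_id!r}: size must be > 0, got {self.size}"
            )
        if not self.weight > 0:
            raise ValidationError(
                f"tree {self.tree_id!r}: weight must be > 0, got {self.weight}"
            )
        if self.status not in VALID_STATUS:
            raise ValidationError(
                f"tree {self.tree_id!r}: status {self.status!r} not in {sorted(VALID_STATUS)}"
            )


@dataclass(frozen=True)
class PartitionResult:
    """A growth-partitioning index value with its provenance."""

    value: float
    index_kind: str  # "DC" | "SGR"
    variable: str  # "diameter" | "basal_area" | "stem_mass"
    n_trees: int
    plot_id: Optional[str] = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.index_kind not in ("DC", "SGR"):
            raise ValidationError(f"unknown index_kind {self.index_kind!r}")
        if self.variable not in VALID_VARIABLES:
            raise ValidationError(f"unknown variable {self.variable!r}")
        min_n = 2 if self.index_kind == "SGR" else 1
        if self.n_trees < min_n:
            raise ValidationError(
                f"{self.index_kind} requires n_trees >= {min_n}, got {self.n_trees}"
            )


@dataclass(frozen=True)
class AllometryCoefficients:
    """Power-law stem-mass coefficients: mass_kg = multiplier * dbh_cm**exponent."""

    multiplier: float
    exponent: float
    species: str = "*"

    def __post_init__(self) -> None:
        if not self.multiplier > 0:
            raise ValidationError(f"allometry multiplier must be > 0, got {self.multiplier}")
        if not self.exponent > 0:
            raise ValidationError(f"allometry exponent must be > 0, got {self.exponent}")


@dataclass
class PlotCensus:
    """A plot's tree list at one census, plus stand-level descriptors.

    ``data`` holds one row per tree with at least the columns
    ``tree_id, dbh_cm, species, status, weight``; synthetic stands add a
    ``growth_cm_yr`` baseline-increment column.
    """

    plot_id: str
    data: pd.DataFrame
    census_date: Optional[_dt.date] = None
    structure: Optional[str] = None  # "even_aged" | "selection"
    stand_type: Optional[str] = None  # "beech_dominated" | "beech_admixed"
    stand_basal_area: Optional[float] = None  # m2/ha when weighted

    def live_trees(self) -> pd.DataFrame:
        return self.data[self.data["status"] == "live"]

    @property
    def n_trees(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class Period:
    """A named growth period spanning whole growing seasons."""

    label: str
    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        if self.end_year < self.start_year:
            raise ValidationError(
                f"period {self.label!r}: end_year {self.end_year} < start_year {self.start_year}"
            )

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1


#: The seven growth periods of the drought analysis, in calendar order.
DEFAULT_PERIODS: tuple[Period, ...] = (
    Period("1984-1994", 1984, 1994),
    Period("1995-2004", 1995, 2004),
    Period("2005-2009", 2005, 2009),
    Period("2010-2017", 2010, 2017),
    Period("2018", 2018, 2018),
    Period("2019", 2019, 2019),
    Period("2020", 2020, 2020),
)
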