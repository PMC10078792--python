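"""Seeded synthetic stands and longitudinal inventories.

Two stand structures are emulated: even-aged stands with truncated-normal
(unimodal) diameter distributions, and single-tree-selection stands with
shifted-exponential (reverse-J) distributions.  All draws respect the 12-cm
census threshold.  Baseline annual diameter growth follows

    g = max(0, alpha + beta * dbh**gamma + eps),   eps ~ Normal(0, sigma^2)

so gamma > 1 yields convex (dominance-favouring) size-growth laws and the
additive noise is clamped before it can produce negative increments, the
same policy the index module applies.

Longitudinal series superimpose a drought scenario: per growth period and
species class a growth multiplier in (0, 1] that interpolates linearly
between a small-tree and a large-tree value over the within-plot size
percentile.  Multipliers of 1 everywhere give a null (no-drought) series.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .types import DEFAULT_PERIODS, Period, PlotCensus

MIN_DBH_CM = 12.0

_BEECH = "beech"
_OTHER = "other"


@dataclass(frozen=True)
class StandConfig:
    """Parameters of one synthetic plot."""

    structure: str  # "even_aged" | "selection"
    n_trees: int
    # even-aged diameter law: truncated normal, lower bound MIN_DBH_CM
    dbh_mean: float = 30.0
    dbh_sd: float = 8.0
    # selection diameter law: MIN_DBH_CM + Exp(rate), truncated above
    dbh_rate: float = 0.08  # per cm
    dbh_max: float = 90.0
    # growth law g = max(0, alpha + beta*d**gamma + eps)
    alpha: float = 0.05
    beta: float = 0.02
    gamma: float = 1.0
    sigma: float = 0.0
    beech_fraction_ba: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.structure not in ("even_aged", "selection"):
            raise ValidationError(f"unknown structure {self.structure!r}")
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")
        if self.structure == "even_aged" and not self.dbh_sd > 0:
            raise ValidationError("dbh_sd must be > 0")
        if self.structure == "selection":
            if not self.dbh_rate > 0:
                raise ValidationError("dbh_rate must be > 0")
            if not self.dbh_max > MIN_DBH_CM:
                raise ValidationError(f"dbh_max must exceed {MIN_DBH_CM} cm")
        if self.beta < 0:
            raise ValidationError("beta must be >= 0")
        if not self.gamma > 0:
            raise ValidationError("gamma must be > 0")
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")
        if not 0.0 <= self.beech_fraction_ba <= 1.0:
            raise ValidationError("beech_fraction_ba must be in [0, 1]")


@dataclass(frozen=True)
class DroughtScenario:
    """Ordered growth periods plus per-period growth multipliers.

    ``multipliers`` maps period label -> species class ("beech"/"other")
    -> (small-tree multiplier, large-tree multiplier); missing entries
    default to 1.  The effective multiplier at within-plot size percentile
    ``p`` is ``m_small + (m_large - m_small) * p``.
    """

    periods: tuple[Period, ...] = DEFAULT_PERIODS
    multipliers: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=dict
    )
    drought_year: int = 2018

    def __post_init__(self) -> None:
        if len(self.periods) == 0:
            raise ValidationError("scenario must define at least one period")
        for prev, cur in zip(self.periods, self.periods[1:]):
            if cur.start_year != prev.end_year + 1:
                raise ValidationError(
                    f"periods must be contiguous and ordered: {prev.label} -> {cur.label}"
                )
        labels = {p.label for p in self.periods}
        for label, by_class in self.multipliers.items():
            if label not in labels:
                raise ValidationError(f"multiplier for unknown period {label!r}")
            for cls, (m0, m1) in by_class.items():
                if cls not in (_BEECH, _OTHER):
                    raise ValidationError(f"unknown species class {cls!r}")
                for m in (m0, m1):
                    if not 0.0 < m <= 1.0:
                        raise ValidationError(
                            f"multiplier {m} for {label}/{cls} outside (0, 1]"
                        )

    def multiplier(self, label: str, species: str, size_percentile) -> np.ndarray:
        cls = _BEECH if species == _BEECH else _OTHER
        m0, m1 = self.multipliers.get(label, {}).get(cls, (1.0, 1.0))
        p = np.asarray(size_percentile, dtype=float)
        return m0 + (m1 - m0) * p

    def census_dates(self) -> list[_dt.date]:
        """Census dates bracketing the periods.

        Multi-year periods are closed by a spring measurement the following
        year (the previous growing season is the last one represented);
        single-year periods are closed by a late-season measurement in
        September of the same year.
        """
        dates = [_dt.date(self.periods[0].start_year, 4, 15)]
        for p in self.periods:
            if p.n_years > 1:
                dates.append(_dt.date(p.end_year + 1, 4, 15))
            else:
                dates.append(_dt.date(p.end_year, 9, 15))
        return dates


def null_scenario(periods: tuple[Period, ...] = DEFAULT_PERIODS) -> DroughtScenario:
    """All multipliers 1: growth identical across periods."""
    return DroughtScenario(periods=periods)


def default_scenario(periods: tuple[Period, ...] = DEFAULT_PERIODS) -> DroughtScenario:
    """Drought scenario: 2018 suppresses large-tree growth, the post-drought
    years suppress large beech trees hardest.  Magnitudes are illustrative,
    chosen for reliable direction recovery at ~200 plots, not calibrated to
    any real inventory."""
    return DroughtScenario(
        periods=periods,
        multipliers={
            "2018": {_BEECH: (0.95, 0.55), _OTHER: (1.0, 0.80)},
            "2019": {_BEECH: (0.90, 0.25), _OTHER: (0.95, 0.75)},
            "2020": {_BEECH: (0.90, 0.25), _OTHER: (0.95, 0.75)},
        },
    )


# ---------------------------------------------------------------------------
# stand generation


def _draw_diameters(config: StandConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_trees
    if config.structure == "even_aged":
        a = (MIN_DBH_CM - config.dbh_mean) / config.dbh_sd
        return stats.truncnorm.rvs(
            a, np.inf, loc=config.dbh_mean, scale=config.dbh_sd, size=n, random_state=rng
        )
    # shifted exponential truncated at dbh_max, by CDF inversion
    u = rng.uniform(size=n)
    span_mass = 1.0 - np.exp(-config.dbh_rate * (config.dbh_max - MIN_DBH_CM))
    return MIN_DBH_CM - np.log(1.0 - u * span_mass) / config.dbh_rate


def baseline_growth(
    dbh: np.ndarray, config: StandConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Annual diameter increment (cm/yr) under the stand's growth law."""
    g = config.alpha + config.beta * np.asarray(dbh, dtype=float) ** config.gamma
    if config.sigma > 0:
        if rng is None:
            raise ValidationError("sigma > 0 requires an rng")
        g = g + rng.normal(0.0, config.sigma, size=np.shape(dbh))
    return np.clip(g, 0.0, None)


def _assign_species(
    ba: np.ndarray, target: float, rng: np.random.Generator, tol: float = 0.05
) -> np.ndarray:
    """Randomized greedy species labels hitting the beech basal-area share.

    Trees are taken in random order until the beech share first reaches the
    target; the best of several permutations is kept.  Raises when no
    permutation lands within ``tol`` (e.g. one tree holds > tol of the
    stand's basal area and n is tiny).
    """
    n = ba.size
    if target <= 0.0:
        return np.array([_OTHER] * n)
    if target >= 1.0:
        return np.array([_BEECH] * n)
    total = ba.sum()
    best_dev, best_mask = np.inf, None
    for _ in range(64):
        order = rng.permutation(n)
        share = np.cumsum(ba[order]) / total
        k = int(np.searchsorted(share, target) + 1)
        dev = abs(share[min(k - 1, n - 1)] - target)
        if dev < best_dev:
            best_dev = dev
            best_mask = order[:k]
        if dev <= 1e-9:
            break
    if best_dev > tol:
        raise ValidationError(
            f"cannot realize beech basal-area share {target:.2f} +/- {tol} "
            f"with {n} trees (best deviation {best_dev:.3f})"
        )
    species = np.array([_OTHER] * n)
    species[best_mask] = _BEECH
    return species


def generate_stand(
    config: StandConfig,
    plot_id: str = "P1",
    census_date: _dt.date | None = None,
) -> PlotCensus:
    """One seeded plot: diameters, baseline annual growth, species labels.

    Deterministic for a given config (seed included); the realized beech
    basal-area share is within 5 percentage points of the target.
    """
    rng = np.random.default_rng(config.seed)
    dbh = _draw_diameters(config, rng)
    growth = baseline_growth(dbh, config, rng if config.sigma > 0 else None)
    ba = np.pi * (dbh / 200.0) ** 2
    species = _assign_species(ba, config.beech_fraction_ba, rng)
    data = pd.DataFrame(
        {
            "tree_id": [f"T{i + 1:04d}" for i in range(config.n_trees)],
            "dbh_cm": dbh,
            "growth_cm_yr": growth,
            "species": species,
            "status": "live",
            "weight": 1.0,
        }
    )
    beech_share = float(ba[species == _BEECH].sum() / ba.sum()) if ba.sum() > 0 else 0.0
    return PlotCensus(
        plot_id=plot_id,
        data=data,
        census_date=census_date,
        structure=config.structure,
        stand_type="beech_dominated" if beech_share >= 0.5 else "beech_admixed",
        stand_basal_area=float(ba.sum()),
    )


# ---------------------------------------------------------------------------
# longitudinal series


def generate_inventory_series(
    config: StandConfig,
    scenario: DroughtScenario,
    plot_id: str = "P1",
) -> pd.DataFrame:
    """Long census table (one row per tree per census) under a scenario.

    Censuses bracket every scenario period; per-interval diameter increments
    are the baseline law evaluated at the interval's starting diameter,
    scaled by the scenario multiplier and the interval length in growing
    seasons.  No mortality or recruitment is simulated.
    """
    stand = generate_stand(config, plot_id=plot_id)
    dates = scenario.census_dates()
    dbh = stand.data["dbh_cm"].to_numpy().copy()
    species = stand.data["species"].to_numpy()
    tree_ids = stand.data["tree_id"].to_numpy()
    n = dbh.size

    frames = []

    def snapshot(date: _dt.date, d: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "plot_id": plot_id,
                "tree_id": tree_ids,
                "census_date": date.isoformat(),
                "dbh_cm": d.copy(),
                "species": species,
                "status": "live",
            }
        )

    frames.append(snapshot(dates[0], dbh))
    for k, period in enumerate(scenario.periods):
        rng = np.random.default_rng([config.seed, 7919, k])
        g = baseline_growth(dbh, config, rng if config.sigma > 0 else None)
        if n > 1:
            pct = stats.rankdata(dbh, method="average") - 1.0
            pct /= n - 1
        else:
            pct = np.zeros(1)
        mult = np.where(
            species == _BEECH,
            scenario.multiplier(period.label, _BEECH, pct),
            scenario.multiplier(period.label, _OTHER, pct),
        )
        dbh = dbh + g * mult * period.n_years
        frames.append(snapshot(dates[k + 1], dbh))
    return pd.concat(frames, ignore_index=True)


def generate_plot_network(
    n_plots: int,
    scenario: DroughtScenario,
    base_config: StandConfig,
    seed: int,
    beech_dominated_fraction: float = 0.5,
    dominated_share: float = 0.7,
    admixed_share: float = 0.15,
) -> pd.DataFrame:
    """Census tables for a network of plots, half beech-dominated by default.

    Plot seeds are derived from ``seed``; structures alternate between
    even-aged and selection.  Returns the concatenated long census table.
    """
    if n_plots < 1:
        raise ValidationError("n_plots must be >= 1")
    frames = []
    n_dom = int(round(n_plots * beech_dominated_fraction))
    for i in range(n_plots):
        cfg = replace(
            base_config,
            structure="even_aged" if i % 2 == 0 else "selection",
            beech_fraction_ba=dominated_share if i < n_dom else admixed_share,
            seed=seed * 1_000_003 + i,
        )
        frames.append(
            generate_inventory_series(cfg, scenario, plot_id=f"P{i + 1:04d}")
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# climate


def generate_climate(
    site_seed: int,
    years: range,
    mean_annual_temp: float = 8.0,
    seasonal_amplitude: float = 9.0,
    temp_noise_sd: float = 1.0,
    precip_mean: float = 100.0,
    precip_sd: float = 30.0,
    srad_mean: float = 180.0,
    srad_amplitude: float = 80.0,
    site_id: str = "S1",
) -> pd.DataFrame:
    """Monthly climate table: sinusoidal seasonality plus seeded noise.

    Temperature peaks in July; precipitation is clamped at zero.  Columns
    match the delimited climate format (site_id, year, month, temp_c,
    precip_mm, srad_wm2).
    """
    years = list(years)
    if not years:
        raise ValidationError("years range is empty")
    rng = np.random.default_rng(site_seed)
    rows = []
    for year in years:
        for month in range(1, 13):
            phase = -np.cos(2 * np.pi * (month - 1) / 12.0)
            temp = mean_annual_temp + seasonal_amplitude * phase
            if temp_noise_sd > 0:
                temp += rng.normal(0.0, temp_noise_sd)
            precip = max(0.0, rng.normal(precip_mean, precip_sd))
            srad = max(0.0, srad_mean + srad_amplitude * phase + rng.normal(0.0, 5.0))
            rows.append((site_id, year, month, temp, precip, srad))
    return pd.DataFrame(
        rows, columns=["site_id", "year", "month", "temp_c", "precip_mm", "srad_wm2"]
    )
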