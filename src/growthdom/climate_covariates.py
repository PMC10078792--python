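"""Site and climate predictors for the dominance coefficient.

Implements the classic 1948 Thornthwaite monthly potential
evapotranspiration with the standard day-length correction, seasonal
aggregation of monthly climate (summer Jun-Aug, autumn Sep-Nov, winter
Dec-Feb spanning the year boundary, spring Mar-May), a greedy pairwise
collinearity screen at |r| > 0.50, and an AICc-ranked all-subsets mixed
model comparison for DC with Akaike weights and marginal/conditional R2.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .errors import ValidationError

DAYS_IN_MONTH = np.array([31, 28.25, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
#: Mid-month day of year used for the solar-declination day-length term.
MID_MONTH_DOY = np.array([15, 45, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349])

SEASON_MONTHS = {
    "spring": (3, 4, 5),
    "summer": (6, 7, 8),
    "autumn": (9, 10, 11),
    "winter": (12, 1, 2),  # Dec of the previous calendar year
}
GROWING_SEASON_MONTHS = (3, 4, 5, 6, 7, 8)  # March-August


# ---------------------------------------------------------------------------
# Thornthwaite PET


def day_length_hours(latitude_deg: float, month: int) -> float:
    """Mean astronomical day length (h) at mid-month for a latitude."""
    phi = np.deg2rad(latitude_deg)
    delta = 0.4093 * np.sin(2 * np.pi * MID_MONTH_DOY[month - 1] / 365.0 - 1.405)
    cos_omega = np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0)
    return float(24.0 * np.arccos(cos_omega) / np.pi)


def _heat_index(temps: np.ndarray) -> float:
    t = np.clip(temps, 0.0, None)
    return float(np.sum((t[t > 0] / 5.0) ** 1.514))


def _pet_unadjusted(t: float, heat_index: float, a: float) -> float:
    if t <= 0.0:
        return 0.0
    if t >= 26.5:
        return -415.85 + 32.24 * t - 0.43 * t * t
    return 16.0 * (10.0 * t / heat_index) ** a


def thornthwaite_pet(series: pd.DataFrame, latitude_deg: float) -> pd.DataFrame:
    """Monthly PET (mm) from monthly mean temperature.

    ``series`` needs columns ``year, month, temp_c`` with all 12 months for
    each year used.  The annual heat index is computed per calendar year;
    years in which every month is at or below 0 degC yield PET = 0 for all
    months and are flagged.  The unadjusted value is scaled by the standard
    day-length/month-length correction for the latitude.
    """
    required = {"year", "month", "temp_c"}
    if not required <= set(series.columns):
        raise ValidationError(f"climate series needs columns {sorted(required)}")
    out_frames = []
    for year, g in series.groupby("year"):
        months = sorted(g["month"].tolist())
        if months != list(range(1, 13)):
            raise ValidationError(f"year {year}: incomplete months {months}")
        g = g.sort_values("month")
        temps = g["temp_c"].to_numpy(dtype=float)
        heat = _heat_index(temps)
        flags = ""
        if heat == 0.0:
            pet = np.zeros(12)
            flags = "all_months_below_zero"
        else:
            a = (
                6.75e-7 * heat**3
                - 7.71e-5 * heat**2
                + 1.792e-2 * heat
                + 0.49239
            )
            unadj = np.array([_pet_unadjusted(t, heat, a) for t in temps])
            corr = np.array(
                [
                    day_length_hours(latitude_deg, m) / 12.0 * DAYS_IN_MONTH[m - 1] / 30.0
                    for m in range(1, 13)
                ]
            )
            pet = unadj * corr
        frame = g[["year", "month"]].copy()
        frame["pet_mm"] = pet
        frame["flags"] = flags
        out_frames.append(frame)
    return pd.concat(out_frames, ignore_index=True)


# ---------------------------------------------------------------------------
# seasonal aggregation


def seasonal_aggregates(
    series: pd.DataFrame,
    latitude_deg: float = 47.0,
    window: tuple[int, int] = (1981, 2018),
) -> dict[str, float]:
    """Seasonal and annual climate summaries averaged over a year window.

    Temperatures are averaged and precipitation summed within each season;
    winter attaches December to the *following* year's winter (winter 2018
    = Dec 2017 + Jan/Feb 2018), so the first winter of the record is
    incomplete and excluded from averaging.  PET is summed within seasons.
    Solar radiation is averaged over the March-August growing season.
    Returns one flat mapping of predictor name to value.
    """
    df = series.copy()
    lo, hi = window
    pet = thornthwaite_pet(df, latitude_deg)
    df = df.merge(pet[["year", "month", "pet_mm"]], on=["year", "month"])
    # season year: December rolls into the next year's winter
    df["season_year"] = np.where(df["month"] == 12, df["year"] + 1, df["year"])

    out: dict[str, float] = {}
    annual = df[(df["year"] >= lo) & (df["year"] <= hi)]
    if annual.empty:
        raise ValidationError(f"no climate rows inside window {window}")
    out["temp_annual"] = float(annual.groupby("year")["temp_c"].mean().mean())
    out["precip_annual"] = float(annual.groupby("year")["precip_mm"].sum().mean())
    out["pet_annual"] = float(annual.groupby("year")["pet_mm"].sum().mean())
    if "srad_wm2" in df.columns:
        gs = annual[annual["month"].isin(GROWING_SEASON_MONTHS)]
        out["srad_growing_season"] = float(gs.groupby("year")["srad_wm2"].mean().mean())

    for season, months in SEASON_MONTHS.items():
        year_col = "season_year" if season == "winter" else "year"
        sub = df[df["month"].isin(months)].copy()
        sub = sub[(sub[year_col] >= lo) & (sub[year_col] <= hi)]
        complete = sub.groupby(year_col).filter(lambda g: len(g) == 3)
        if complete.empty:
            warnings.warn(f"season {season}: no complete season inside window")
            out[f"temp_{season}"] = np.nan
            out[f"precip_{season}"] = np.nan
            out[f"pet_{season}"] = np.nan
            continue
        by_year = complete.groupby(year_col)
        out[f"temp_{season}"] = float(by_year["temp_c"].mean().mean())
        out[f"precip_{season}"] = float(by_year["precip_mm"].sum().mean())
        out[f"pet_{season}"] = float(by_year["pet_mm"].sum().mean())
    return out


def site_predictor_table(
    climate_by_site: pd.DataFrame,
    sites: pd.DataFrame,
    window: tuple[int, int] = (1981, 2018),
) -> pd.DataFrame:
    """Join per-site climate aggregates with the static site table.

    ``sites`` needs columns ``site_id, ph, whc_mm, elevation_m, slope_pct,
    latitude``.
    """
    rows = []
    for site_id, g in climate_by_site.groupby("site_id"):
        lat = float(sites.loc[sites["site_id"] == site_id, "latitude"].iloc[0])
        agg = seasonal_aggregates(g, latitude_deg=lat, window=window)
        agg["site_id"] = site_id
        rows.append(agg)
    clim = pd.DataFrame(rows)
    return sites.merge(clim, on="site_id")


# ---------------------------------------------------------------------------
# collinearity screening


@dataclass
class PredictorSet:
    """Retained predictors plus the audit trail of exclusions."""

    retained: list[str]
    audit: pd.DataFrame  # predictor, action, reason, partner, r

    def frame(self, predictors: pd.DataFrame) -> pd.DataFrame:
        return predictors[self.retained]


def screen_collinear(
    predictors: pd.DataFrame, threshold: float = 0.50
) -> PredictorSet:
    """Greedy pairwise collinearity elimination.

    While any retained pair has |Pearson r| above the threshold, the member
    of the worst pair with the larger mean |r| to all other retained
    predictors is dropped; ties fall back to the declared column order
    (the later column is dropped).  Constant predictors are dropped first
    with their own reason code.  Idempotent on an already-screened set.
    """
    if predictors.shape[1] < 1:
        raise ValidationError("need at least one candidate predictor")
    audit_rows = []
    cols = list(predictors.columns)
    retained = []
    for c in cols:
        if predictors[c].nunique() <= 1:
            audit_rows.append(
                {"predictor": c, "action": "dropped", "reason": "constant", "partner": "", "r": np.nan}
            )
        else:
            retained.append(c)
    while len(retained) >= 2:
        corr = predictors[retained].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = float(corr.values.max())
        if worst <= threshold:
            break
        # first pair (in declared order) attaining the worst correlation
        pair = None
        for a, b in itertools.combinations(retained, 2):
            if np.isclose(corr.loc[a, b], worst):
                pair = (a, b)
                break
        a, b = pair
        mean_r = {
            c: corr.loc[c, [x for x in retained if x != c]].mean() for c in (a, b)
        }
        drop = b if mean_r[b] >= mean_r[a] else a
        audit_rows.append(
            {
                "predictor": drop,
                "action": "dropped",
                "reason": f"|r|>{threshold}",
                "partner": a if drop == b else b,
                "r": worst,
            }
        )
        retained.remove(drop)
    for c in retained:
        audit_rows.append(
            {"predictor": c, "action": "retained", "reason": "", "partner": "", "r": np.nan}
        )
    audit = pd.DataFrame(
        audit_rows, columns=["predictor", "action", "reason", "partner", "r"]
    )
    return PredictorSet(retained=retained, audit=audit)


# ---------------------------------------------------------------------------
# AICc model selection


@dataclass
class ModelSelectionReport:
    """Ranked candidate models and coefficient tables (Table-2 layout)."""

    ranking: pd.DataFrame  # terms, k, aicc, delta, weight
    best_terms: tuple[str, ...]
    best_table: pd.DataFrame
    full_table: pd.DataFrame
    best_aicc: float
    full_aicc: float
    best_r2: dict[str, float] = field(default_factory=dict)
    full_r2: dict[str, float] = field(default_factory=dict)


def _aicc(llf: float, k: int, n: int) -> float:
    aic = -2.0 * llf + 2.0 * k
    if n - k - 1 <= 0:
        return np.inf
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def _fit_candidate(data: pd.DataFrame, terms: Sequence[str]):
    rhs = " + ".join(terms) if terms else "1"
    model = smf.mixedlm(f"dc ~ {rhs}", data, groups=data["plot_id"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                return model.fit(reml=False, method=method, maxiter=200)
            except (np.linalg.LinAlgError, ValueError):
                continue
        return model.fit(reml=False, maxiter=200)


def _r2_nakagawa(fit) -> dict[str, float]:
    """Marginal/conditional R2 by variance partitioning (fixed-effect
    variance over fixed + random-intercept + residual variance)."""
    X = fit.model.exog
    var_f = float(np.var(X @ np.asarray(fit.fe_params)))
    var_a = float(np.asarray(fit.cov_re).ravel()[0]) if fit.cov_re.size else 0.0
    var_e = float(fit.scale)
    denom = var_f + var_a + var_e
    return {
        "marginal_r2": var_f / denom if denom > 0 else np.nan,
        "conditional_r2": (var_f + var_a) / denom if denom > 0 else np.nan,
    }


def _coef_table(fit, alpha: float = 0.05) -> pd.DataFrame:
    k = len(fit.fe_params)
    se = np.asarray(fit.bse)[:k]
    pvals = np.asarray(fit.pvalues)[:k]
    return pd.DataFrame(
        {
            "term": list(fit.fe_params.index),
            "estimate": np.asarray(fit.fe_params),
            "se": se,
            "p_value": pvals,
            "star": ["*" if p < alpha else "" for p in pvals],
        }
    )


def dc_climate_model_selection(
    dc_table: pd.DataFrame,
    predictors: pd.DataFrame,
    max_terms: int = 4,
    alpha: float = 0.05,
    collinearity_threshold: float = 0.50,
) -> ModelSelectionReport:
    """All-subsets AICc comparison of DC mixed models.

    ``dc_table`` needs columns ``plot_id, dc`` (repeated measures per plot)
    plus one column per candidate predictor, or the predictors are merged
    in from ``predictors`` on ``plot_id``.  Candidates are all subsets of
    the collinearity-screened predictors up to ``max_terms`` plus the full
    screened model; each is a linear mixed model with a plot random
    intercept fitted by maximum likelihood, ranked by AICc with Akaike
    weights.  Candidates with more parameters than observations are skipped
    with a reason.
    """
    data = dc_table.merge(predictors, on="plot_id") if "plot_id" in predictors else dc_table
    cand_cols = [c for c in predictors.columns if c not in ("plot_id", "site_id")]
    if cand_cols:
        screened = screen_collinear(data[cand_cols], threshold=collinearity_threshold)
        terms_pool = screened.retained
    else:
        terms_pool = []  # intercept-only report
    n = len(data)

    candidates: list[tuple[str, ...]] = [()]
    for size in range(1, min(max_terms, len(terms_pool)) + 1):
        candidates.extend(itertools.combinations(terms_pool, size))
    full_terms = tuple(terms_pool)
    if full_terms not in candidates:
        candidates.append(full_terms)

    rows, fits = [], {}
    for terms in candidates:
        k = len(terms) + 3  # intercept + RE variance + residual variance
        if k + 1 >= n:
            rows.append(
                {"terms": "+".join(terms) or "1", "k": k, "aicc": np.nan,
                 "delta": np.nan, "weight": np.nan, "skipped": "k>=n"}
            )
            continue
        fit = _fit_candidate(data, terms)
        fits[terms] = fit
        rows.append(
            {"terms": "+".join(terms) or "1", "k": k,
             "aicc": _aicc(float(fit.llf), k, n), "delta": np.nan,
             "weight": np.nan, "skipped": ""}
        )
    ranking = pd.DataFrame(rows)
    ok = ranking["aicc"].notna()
    best_aicc = float(ranking.loc[ok, "aicc"].min())
    ranking.loc[ok, "delta"] = ranking.loc[ok, "aicc"] - best_aicc
    w = np.exp(-0.5 * ranking.loc[ok, "delta"])
    ranking.loc[ok, "weight"] = w / w.sum()
    ranking = ranking.sort_values("aicc", kind="mergesort").reset_index(drop=True)

    fitted_terms = list(fits.keys())
    best_terms = fitted_terms[
        int(np.argmin([_aicc(float(fits[t].llf), len(t) + 3, n) for t in fitted_terms]))
    ]
    best_fit = fits[best_terms]
    full_fit = fits.get(full_terms) or _fit_candidate(data, full_terms)
    return ModelSelectionReport(
        ranking=ranking,
        best_terms=best_terms,
        best_table=_coef_table(best_fit, alpha),
        full_table=_coef_table(full_fit, alpha),
        best_aicc=_aicc(float(best_fit.llf), len(best_terms) + 3, n),
        full_aicc=_aicc(float(full_fit.llf), len(full_terms) + 3, n),
        best_r2=_r2_nakagawa(best_fit),
        full_r2=_r2_nakagawa(full_fit),
    )
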