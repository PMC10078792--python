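"""Drought-response analysis on nested-plot inventories.

Stages: per-hectare expansion weights for the two-circle nested design
(200 m2 for d >= 12 cm, 500 m2 for d >= 36 cm), annualization of basal-area
increments, mapping census pairs onto the seven growth periods, the
>=8-tree plot filter, per-period dominance coefficients, and linear mixed
models with the 2018 drought period as reference level followed by
Tukey-adjusted pairwise period comparisons within each stand type.

Model fitting is delegated to statsmodels MixedLM; this module owns the
design construction, reference coding, contrast matrices and compact
letter display.
"""

from __future__ import annotations

import datetime as _dt
import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from patsy import build_design_matrices
from scipy import stats

from .errors import UndefinedResultError, UnmappedIntervalError, ValidationError
from .partition_indices import basal_area, dc_value
from .types import DEFAULT_PERIODS, Period

MIN_DBH_CM = 12.0
OUTER_DBH_CM = 36.0
INNER_AREA_M2 = 200.0
OUTER_AREA_M2 = 500.0

STAND_TYPES = ("beech_dominated", "beech_admixed")


# ---------------------------------------------------------------------------
# elementary operations


def expansion_weight(diameter_cm):
    """Per-hectare representation factor from the nested-circle design.

    Trees of 12 <= d < 36 cm are recorded on the inner 200-m2 circle
    (factor 50); trees of d >= 36 cm on the 500-m2 circle (factor 20); the
    36-cm boundary belongs to the outer circle.
    """
    d = np.asarray(diameter_cm, dtype=float)
    if np.any(d < MIN_DBH_CM):
        raise ValidationError(
            f"diameter below the {MIN_DBH_CM}-cm census threshold"
        )
    out = np.where(d >= OUTER_DBH_CM, 10_000.0 / OUTER_AREA_M2, 10_000.0 / INNER_AREA_M2)
    return float(out) if np.isscalar(diameter_cm) else out


def annualize(increment, interval_years: float):
    """Per-year increment; intervals of at most one year pass through."""
    if not interval_years > 0:
        raise ValidationError(f"interval_years must be > 0, got {interval_years}")
    if interval_years <= 1.0:
        return increment
    return increment / interval_years


def _last_growing_season(date: _dt.date) -> int:
    """Last completed growing season represented by a measurement date.

    Spring measurements (before August) close the previous season; late
    season measurements (August onwards) include the current one.
    """
    return date.year - 1 if date.month < 8 else date.year


def assign_period(
    date_start: _dt.date,
    date_end: _dt.date,
    periods: Sequence[Period] = DEFAULT_PERIODS,
) -> tuple[str, int]:
    """Map a census pair to its growth period label and length in seasons."""
    if date_end <= date_start:
        raise ValidationError(f"census dates not ordered: {date_start} >= {date_end}")
    first = _last_growing_season(date_start) + 1
    last = _last_growing_season(date_end)
    if last < first:
        raise UnmappedIntervalError(
            f"interval {date_start}..{date_end} spans no completed growing season"
        )
    for p in periods:
        if p.start_year <= first and last <= p.end_year:
            return p.label, last - first + 1
    raise UnmappedIntervalError(
        f"interval {date_start}..{date_end} (seasons {first}-{last}) "
        "does not fall inside any configured period"
    )


def classify_stand_type(trees: pd.DataFrame, beech_share_threshold: float = 0.5) -> str:
    """Beech-dominated when the weighted beech basal-area share is >= 50%."""
    live = trees[trees["status"] == "live"] if "status" in trees else trees
    if len(live) == 0:
        raise ValidationError("cannot classify a plot with no live trees")
    ba = basal_area(live["dbh_cm"].to_numpy(dtype=float))
    w = live["weight"].to_numpy(dtype=float) if "weight" in live else np.ones_like(ba)
    total = float((w * ba).sum())
    beech = float((w * ba)[(live["species"] == "beech").to_numpy()].sum())
    return "beech_dominated" if beech / total >= beech_share_threshold else "beech_admixed"


def filter_plots(
    plot_tables: dict[str, pd.DataFrame], min_trees: int = 8
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Drop plots with fewer than ``min_trees`` live trees; log exclusions."""
    kept, log_rows = {}, []
    for plot_id, table in plot_tables.items():
        n_live = int((table["status"] == "live").sum()) if "status" in table else len(table)
        if n_live >= min_trees:
            kept[plot_id] = table
        log_rows.append(
            {"plot_id": plot_id, "n_live": n_live, "retained": n_live >= min_trees}
        )
    if not plot_tables:
        warnings.warn("filter_plots received no plots")
    log = pd.DataFrame(log_rows, columns=["plot_id", "n_live", "retained"])
    return kept, log


# ---------------------------------------------------------------------------
# interval construction


def build_interval_table(
    census: pd.DataFrame,
    periods: Sequence[Period] = DEFAULT_PERIODS,
    weighted: bool = True,
    min_trees: int = 8,
) -> pd.DataFrame:
    """Tree-level growth intervals from a long census table.

    Pairs consecutive censuses per plot, keeps trees live at both ends,
    annualizes basal-area increments, attaches nested-design weights (start
    diameter), the start-census stand basal area and stand type, and the
    growth-period label.  Plots with fewer live trees than ``min_trees`` at
    the start census contribute no intervals for that pair.
    """
    df = census.copy()
    df["census_date"] = pd.to_datetime(df["census_date"]).dt.date
    df = df.sort_values(["plot_id", "tree_id", "census_date"], kind="mergesort")

    grp = df.groupby(["plot_id", "tree_id"], sort=False)
    df["dbh_prev"] = grp["dbh_cm"].shift()
    df["date_prev"] = grp["census_date"].shift()
    df["status_prev"] = grp["status"].shift()

    iv = df[
        df["dbh_prev"].notna()
        & (df["status"] == "live")
        & (df["status_prev"] == "live")
    ].copy()
    if iv.empty:
        raise ValidationError("no growth intervals found (need >= 2 censuses per plot)")

    # period labels: few unique date pairs, resolve once
    pairs = iv[["date_prev", "census_date"]].drop_duplicates()
    label_map, years_map = {}, {}
    for d0, d1 in pairs.itertuples(index=False):
        label, yrs = assign_period(d0, d1, periods)
        label_map[(d0, d1)] = label
        years_map[(d0, d1)] = yrs
    key = list(zip(iv["date_prev"], iv["census_date"]))
    iv["period"] = [label_map[k] for k in key]
    iv["interval_years"] = [years_map[k] for k in key]

    iv["ba_start"] = basal_area(iv["dbh_prev"].to_numpy(dtype=float))
    ba_end = basal_area(iv["dbh_cm"].to_numpy(dtype=float))
    iv["bai_annual"] = (ba_end - iv["ba_start"]) / np.maximum(iv["interval_years"], 1.0)
    iv["weight"] = (
        expansion_weight(iv["dbh_prev"].to_numpy(dtype=float)) if weighted else 1.0
    )

    # start-census stand descriptors
    iv["wba"] = iv["weight"] * iv["ba_start"]
    g = iv.groupby(["plot_id", "period"], sort=False)
    iv["stand_ba"] = g["wba"].transform("sum")
    beech_wba = iv["wba"].where(iv["species"] == "beech", 0.0)
    iv["beech_share"] = beech_wba.groupby(
        [iv["plot_id"], iv["period"]], sort=False
    ).transform("sum") / iv["stand_ba"]
    iv["stand_type"] = np.where(
        iv["beech_share"] >= 0.5, "beech_dominated", "beech_admixed"
    )
    iv["n_trees"] = g["tree_id"].transform("count")
    iv = iv[iv["n_trees"] >= min_trees]

    cols = [
        "plot_id",
        "tree_id",
        "period",
        "interval_years",
        "species",
        "dbh_prev",
        "ba_start",
        "bai_annual",
        "weight",
        "stand_ba",
        "stand_type",
    ]
    return iv[cols].reset_index(drop=True)


def dc_by_period(
    interval_table: pd.DataFrame, weighted: bool = True
) -> pd.DataFrame:
    """Per (plot, period) dominance coefficient on basal area vs annual BAI.

    Negative increments are clamped to zero (the package default policy);
    plot-periods whose total growth is zero are dropped with a warning.
    """
    rows, dropped = [], 0
    for (plot_id, period), g in interval_table.groupby(["plot_id", "period"], sort=False):
        w = g["weight"].to_numpy() if weighted else np.ones(len(g))
        try:
            value = dc_value(
                g["ba_start"].to_numpy(),
                np.clip(g["bai_annual"].to_numpy(), 0.0, None),
                w,
                g["tree_id"].to_numpy(),
            )
        except UndefinedResultError:
            dropped += 1
            continue
        rows.append(
            {
                "plot_id": plot_id,
                "period": period,
                "stand_type": g["stand_type"].iloc[0],
                "dc": value,
                "n_trees": len(g),
                "weighted": weighted,
            }
        )
    if dropped:
        warnings.warn(f"dropped {dropped} plot-period(s) with zero total growth")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mixed models, Tukey contrasts, letters


@dataclass
class PeriodEffects:
    """Cell means, pairwise Tukey comparisons and letters for one response."""

    response: str
    means: pd.DataFrame  # period, stand_type, estimate, se, letters
    pairwise: pd.DataFrame  # stand_type, period_a, period_b, diff, se, q, p_adj
    model: object = field(repr=False, default=None)


def _fit_mixedlm(formula: str, data: pd.DataFrame, groups: str, vc_formula=None):
    model = smf.mixedlm(formula, data, groups=data[groups], vc_formula=vc_formula)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(method="lbfgs", maxiter=200)
        except Exception:
            fit = model.fit(maxiter=200)
    return fit


def _cell_design(fit, cells: pd.DataFrame) -> np.ndarray:
    design_info = fit.model.data.design_info
    (X,) = build_design_matrices([design_info], cells)
    return np.asarray(X)


def _cell_means(fit, periods: Sequence[str], stand_types: Sequence[str]):
    cells = pd.DataFrame(
        [(p, s) for s in stand_types for p in periods],
        columns=["period", "stand_type"],
    )
    X = _cell_design(fit, cells)
    k_fe = len(fit.fe_params)
    beta = np.asarray(fit.fe_params)
    vcov = np.asarray(fit.cov_params())[:k_fe, :k_fe]
    cells["estimate"] = X @ beta
    cells["se"] = np.sqrt(np.einsum("ij,jk,ik->i", X, vcov, X))
    return cells, X, vcov


_TUKEY_GRID_DF = 1000.0
_tukey_interp_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _tukey_sf(q: float, k: int, df_resid: float) -> float:
    """Studentized-range survival function, interpolated for large df.

    Exact evaluation is expensive; for df > 500 the distribution is close
    to its df = 1000 shape, so a cached fixed-grid interpolant is used
    (absolute error < 1e-3, immaterial at the 0.05 decision level).
    """
    if df_resid <= 500:
        return float(stats.studentized_range.sf(q, k, df_resid))
    if k not in _tukey_interp_cache:
        grid = np.linspace(0.0, 12.0, 121)
        _tukey_interp_cache[k] = (
            grid,
            stats.studentized_range.sf(grid, k, _TUKEY_GRID_DF),
        )
    grid, sf = _tukey_interp_cache[k]
    if q >= grid[-1]:
        return 0.0
    return float(np.interp(q, grid, sf))


def tukey_within_stand_type(
    fit, periods: Sequence[str], stand_types: Sequence[str], df_resid: float
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tukey-adjusted pairwise period contrasts within each stand type.

    Adjustment uses the studentized range with k = number of periods, the
    lsmeans-style convention: q = |diff| / se_diff * sqrt(2).
    """
    cells, X, vcov = _cell_means(fit, periods, stand_types)
    k = len(periods)
    rows = []
    for s_idx, stype in enumerate(stand_types):
        base = s_idx * k
        for i, j in itertools.combinations(range(k), 2):
            c = X[base + i] - X[base + j]
            diff = float(c @ np.asarray(fit.fe_params))
            se = float(np.sqrt(c @ vcov @ c))
            if se == 0:
                continue
            q = abs(diff) / se * np.sqrt(2.0)
            p = _tukey_sf(q, k, df_resid)
            rows.append(
                {
                    "stand_type": stype,
                    "period_a": periods[i],
                    "period_b": periods[j],
                    "diff": diff,
                    "se": se,
                    "q": q,
                    "p_adj": p,
                }
            )
    return cells, pd.DataFrame(rows)


def compact_letters(
    labels: Sequence[str],
    estimates: Sequence[float],
    pairwise: pd.DataFrame,
    alpha: float = 0.05,
) -> dict[str, str]:
    """Compact letter display from an adjusted p-value table.

    Two labels share a letter iff they belong to a common maximal clique of
    the not-significantly-different graph, so the letters are transitive-
    consistent with the pairwise decisions.
    """
    g = nx.Graph()
    g.add_nodes_from(labels)
    for row in pairwise.itertuples(index=False):
        if row.p_adj > alpha:
            g.add_edge(row.period_a, row.period_b)
    est = dict(zip(labels, estimates))
    cliques = sorted(nx.find_cliques(g), key=lambda c: (min(est[x] for x in c), sorted(c)))
    letters: dict[str, list[str]] = {lab: [] for lab in labels}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for idx, clique in enumerate(cliques):
        for lab in clique:
            letters[lab].append(alphabet[idx % len(alphabet)])
    return {lab: "".join(sorted(v)) for lab, v in letters.items()}


def _period_order(data: pd.DataFrame, periods: Sequence[Period]) -> list[str]:
    present = set(data["period"])
    return [p.label for p in periods if p.label in present]


def _check_cells(data: pd.DataFrame, periods: list[str], stand_types: list[str]):
    """Drop unestimable period x stand-type cells, warn about them."""
    counts = data.groupby(["period", "stand_type"]).size()
    missing = [
        (p, s)
        for p in periods
        for s in stand_types
        if (p, s) not in counts.index
    ]
    if missing:
        warnings.warn(f"unestimable cells dropped from the design: {missing}")
        bad_p = {p for p, _ in missing}
        data = data[~data["period"].isin(bad_p)]
        periods = [p for p in periods if p not in bad_p]
    return data, periods


def fit_dc_period_model(
    dc_table: pd.DataFrame,
    periods: Sequence[Period] = DEFAULT_PERIODS,
    reference: str = "2018",
    alpha: float = 0.05,
) -> PeriodEffects:
    """DC ~ period x stand_type with a plot random intercept.

    The 2018 drought period is the reference level; Tukey multiple
    comparisons are run within each stand type and summarized as letters.
    """
    data = dc_table.dropna(subset=["dc"]).copy()
    period_labels = _period_order(data, periods)
    if len(period_labels) < 2:
        raise ValidationError("DC period model needs >= 2 periods with data")
    counts = data.groupby("period")["plot_id"].nunique()
    if (counts < 3).any():
        warnings.warn(f"periods with < 3 plots: {counts[counts < 3].index.tolist()}")
    stand_types = [s for s in STAND_TYPES if s in set(data["stand_type"])]
    data, period_labels = _check_cells(data, period_labels, stand_types)
    ref = reference if reference in period_labels else period_labels[-1]
    if len(stand_types) > 1:
        formula = f"dc ~ C(period, Treatment('{ref}')) * C(stand_type)"
    else:
        formula = f"dc ~ C(period, Treatment('{ref}'))"
    fit = _fit_mixedlm(formula, data, groups="plot_id")
    df_resid = max(float(len(data) - len(fit.fe_params)), 2.0)
    cells, pairwise = tukey_within_stand_type(fit, period_labels, stand_types, df_resid)
    letter_col = []
    for stype in stand_types:
        sub = cells[cells["stand_type"] == stype]
        pw = pairwise[pairwise["stand_type"] == stype]
        lett = compact_letters(
            sub["period"].tolist(), sub["estimate"].tolist(), pw, alpha
        )
        letter_col.extend(lett[p] for p in sub["period"])
    cells = cells.copy()
    cells["letters"] = letter_col
    return PeriodEffects(response="dc", means=cells, pairwise=pairwise, model=fit)


def fit_bai_period_model(
    interval_table: pd.DataFrame,
    periods: Sequence[Period] = DEFAULT_PERIODS,
    reference: str = "2018",
    alpha: float = 0.05,
) -> PeriodEffects:
    """Annual BAI ~ period x stand_type with trees nested within plots."""
    data = interval_table.dropna(subset=["bai_annual"]).copy()
    if data.empty:
        raise ValidationError("empty interval table")
    period_labels = _period_order(data, periods)
    if len(period_labels) < 2:
        raise ValidationError("BAI period model needs >= 2 periods with data")
    stand_types = [s for s in STAND_TYPES if s in set(data["stand_type"])]
    data, period_labels = _check_cells(data, period_labels, stand_types)
    ref = reference if reference in period_labels else period_labels[-1]
    data["period"] = data["period"].astype(str)
    data["tree_uid"] = data["plot_id"].astype(str) + ":" + data["tree_id"].astype(str)
    if len(stand_types) > 1:
        formula = f"bai_annual ~ C(period, Treatment('{ref}')) * C(stand_type)"
    else:
        formula = f"bai_annual ~ C(period, Treatment('{ref}'))"
    fit = _fit_mixedlm(
        formula, data, groups="plot_id", vc_formula={"tree": "0 + C(tree_uid)"}
    )
    df_resid = max(float(len(data) - len(fit.fe_params)), 2.0)
    cells, pairwise = tukey_within_stand_type(fit, period_labels, stand_types, df_resid)
    letter_col = []
    for stype in stand_types:
        sub = cells[cells["stand_type"] == stype]
        pw = pairwise[pairwise["stand_type"] == stype]
        lett = compact_letters(sub["period"].tolist(), sub["estimate"].tolist(), pw, alpha)
        letter_col.extend(lett[p] for p in sub["period"])
    cells = cells.copy()
    cells["letters"] = letter_col
    return PeriodEffects(response="bai_annual", means=cells, pairwise=pairwise, model=fit)


def size_and_density_slopes(
    interval_table: pd.DataFrame,
    periods: Sequence[Period] = DEFAULT_PERIODS,
    min_cell: int = 10,
) -> pd.DataFrame:
    """Per (period, stand_type) slopes of annual BAI on tree and stand BA.

    One mixed model per cell, ``bai_annual ~ ba_start + stand_ba`` with a
    plot random intercept, reporting both slopes with standard errors plus
    the simple-regression R2 of BAI on tree basal area.  Cells with fewer
    than ``min_cell`` trees, a single plot, or a failed fit are flagged.
    """
    rows = []
    period_labels = [p.label for p in periods]
    for (period, stype), g in interval_table.groupby(["period", "stand_type"]):
        row = {
            "period": period,
            "stand_type": stype,
            "n_trees": len(g),
            "n_plots": g["plot_id"].nunique(),
            "size_slope": np.nan,
            "size_se": np.nan,
            "density_slope": np.nan,
            "density_se": np.nan,
            "r2_size": np.nan,
            "flags": "",
        }
        if len(g) < min_cell:
            row["flags"] = "too_few_trees"
            rows.append(row)
            continue
        use_density = g["stand_ba"].nunique() > 1
        formula = "bai_annual ~ ba_start + stand_ba" if use_density else "bai_annual ~ ba_start"
        try:
            if g["plot_id"].nunique() > 1:
                fit = _fit_mixedlm(formula, g, groups="plot_id")
                with warnings.catch_warnings():
                    # boundary variance estimates make some bse entries NaN
                    warnings.simplefilter("ignore", RuntimeWarning)
                    params, bse = fit.fe_params, fit.bse_fe
            else:
                ols = smf.ols(formula, g).fit()
                params, bse = ols.params, ols.bse
                row["flags"] = "single_plot_ols"
        except Exception:
            row["flags"] = "fit_failed"
            rows.append(row)
            continue
        row["size_slope"] = float(params["ba_start"])
        row["size_se"] = float(bse["ba_start"])
        if use_density:
            row["density_slope"] = float(params["stand_ba"])
            row["density_se"] = float(bse["stand_ba"])
        else:
            row["flags"] = (row["flags"] + ";no_density_variation").strip(";")
        x, y = g["ba_start"], g["bai_annual"]
        if x.nunique() > 1 and y.var() > 0:
            row["r2_size"] = float(stats.pearsonr(x, y).statistic ** 2)
        rows.append(row)
    out = pd.DataFrame(rows)
    out["period"] = pd.Categorical(out["period"], categories=period_labels, ordered=True)
    return out.sort_values(["stand_type", "period"]).reset_index(drop=True)
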