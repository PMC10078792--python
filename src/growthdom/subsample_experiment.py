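"""Sample-size and size-range sensitivity experiments.

For each plot the partitioning index computed from all trees is compared
with the index computed from random subsamples on a ladder of sample sizes
(default 5, 8, 10, 20, 30, 50, 100); agreement is summarized as the Pearson
correlation across plots, averaged over seeded replicates.  A second
experiment removes the largest 10 and 20 trees from 100-tree samples and
tests the paired shift in the dominance coefficient with a two-sided
Wilcoxon signed-rank test.

Subsampling is keyed to sorted tree ids plus the seed, so sample membership
is invariant to the row order of the input table.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateFitError, SubsampleSkip, UndefinedResultError, ValidationError
from .partition_indices import derive_size_growth, dc_value, sgr_value
from .types import PartitionResult, PlotCensus

DEFAULT_LADDER = (5, 8, 10, 20, 30, 50, 100)


@dataclass(frozen=True)
class RemovalTestResult:
    """Paired full-sample vs largest-trees-removed DC comparison."""

    n_removed: int
    pairs: pd.DataFrame  # columns plot_id, dc_full, dc_reduced
    statistic: float
    p_value: float
    n_decreased: int
    flags: tuple[str, ...] = ()


def _plot_arrays(plot: PlotCensus, variable: str):
    """Live-tree (ids, size, growth, weight) in the requested variable."""
    live = plot.live_trees()
    if len(live) == 0:
        raise ValidationError(f"plot {plot.plot_id}: no live trees")
    dbh = live["dbh_cm"].to_numpy(dtype=float)
    # baseline annual increment in cm drives all three variable families
    g_cm = live["growth_cm_yr"].to_numpy(dtype=float)
    size, growth = derive_size_growth(dbh, dbh + g_cm, variable)
    ids = live["tree_id"].astype(str).to_numpy()
    weight = live["weight"].to_numpy(dtype=float) if "weight" in live else np.ones_like(size)
    return ids, size, growth, weight


def _index_value(index_kind: str, size, growth, weight, ids) -> float:
    if index_kind == "DC":
        return dc_value(size, np.clip(growth, 0.0, None), weight, ids)
    if index_kind == "SGR":
        return sgr_value(size, growth, weight)
    raise ValidationError(f"unknown index_kind {index_kind!r}")


def _sample_rng(seed: int, plot_id: str, n: int, replicate: int) -> np.random.Generator:
    return np.random.default_rng(
        [seed, zlib.crc32(str(plot_id).encode()), n, replicate]
    )


def subsample_index(
    plot: PlotCensus,
    n: int,
    index_kind: str = "DC",
    variable: str = "basal_area",
    seed: int = 0,
    replicate: int = 0,
) -> PartitionResult:
    """Index from a seeded simple random sample of ``n`` live trees.

    Sampling is without replacement and keyed to sorted tree ids, so the
    same (seed, plot, n, replicate) always selects the same trees no matter
    how the input rows are ordered.  Raises :class:`SubsampleSkip` when the
    plot holds fewer than ``n`` live trees.
    """
    ids, size, growth, weight = _plot_arrays(plot, variable)
    if n > ids.size:
        raise SubsampleSkip(
            f"plot {plot.plot_id}: requested n={n} but only {ids.size} live trees"
        )
    order = np.argsort(ids)
    rng = _sample_rng(seed, plot.plot_id, n, replicate)
    pick = order[rng.choice(ids.size, size=n, replace=False)]
    value = _index_value(index_kind, size[pick], growth[pick], weight[pick], ids[pick])
    return PartitionResult(
        value=value,
        index_kind=index_kind,
        variable=variable,
        n_trees=n,
        plot_id=plot.plot_id,
        flags=("subsample",),
    )


def full_plot_index(
    plot: PlotCensus, index_kind: str = "DC", variable: str = "basal_area"
) -> PartitionResult:
    ids, size, growth, weight = _plot_arrays(plot, variable)
    value = _index_value(index_kind, size, growth, weight, ids)
    return PartitionResult(
        value=value,
        index_kind=index_kind,
        variable=variable,
        n_trees=ids.size,
        plot_id=plot.plot_id,
    )


def sensitivity_analysis(
    plots: Sequence[PlotCensus],
    ladder: Sequence[int] = DEFAULT_LADDER,
    index_kind: str = "DC",
    variable: str = "basal_area",
    replicates: int = 25,
    seed: int = 0,
) -> pd.DataFrame:
    """Pearson correlation of full-plot vs subsample indices by sample size.

    One row per (structure, index_kind, variable, sample_size) with the
    correlation averaged over ``replicates`` independent draws per plot.
    Cells with an undefined correlation (zero variance, too few plots) are
    reported with a NaN value and a reason flag rather than dropped.
    Plots that cannot supply a sample or whose subsample index is undefined
    are excluded pairwise and counted in the flags.
    """
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    by_structure: dict[str, list[PlotCensus]] = {}
    for p in plots:
        by_structure.setdefault(p.structure or "unknown", []).append(p)

    rows = []
    for structure, group in sorted(by_structure.items()):
        full = {}
        for p in group:
            try:
                full[p.plot_id] = full_plot_index(p, index_kind, variable).value
            except (DegenerateFitError, UndefinedResultError):
                continue
        if len(full) < len(group):
            warnings.warn(
                f"{structure}: {len(group) - len(full)} plot(s) with undefined "
                f"full-plot {index_kind} excluded"
            )
        if len(full) < 3:
            warnings.warn(f"{structure}: only {len(full)} usable plots (low power)")
        for n in ladder:
            r_reps, n_pairs, n_skipped = [], 0, 0
            for rep in range(replicates):
                xs, ys = [], []
                for p in group:
                    if p.plot_id not in full:
                        continue
                    try:
                        sub = subsample_index(p, n, index_kind, variable, seed, rep)
                    except SubsampleSkip:
                        n_skipped += 1
                        continue
                    except (DegenerateFitError, UndefinedResultError):
                        continue
                    xs.append(full[p.plot_id])
                    ys.append(sub.value)
                n_pairs = max(n_pairs, len(xs))
                if len(xs) >= 3 and np.std(xs) > 0 and np.std(ys) > 0:
                    r_reps.append(float(stats.pearsonr(xs, ys).statistic))
            flags = []
            if n_skipped:
                flags.append("some_plots_skipped")
            if not r_reps:
                flags.append("correlation_undefined")
                r_mean = np.nan
            else:
                r_mean = float(np.mean(r_reps))
                if len(r_reps) < replicates:
                    flags.append("some_replicates_undefined")
            if 0 < n_pairs < 3:
                flags.append("low_power")
            rows.append(
                {
                    "structure": structure,
                    "index_kind": index_kind,
                    "variable": variable,
                    "sample_size": n,
                    "pearson_r": r_mean,
                    "n_plots": n_pairs,
                    "replicates": len(r_reps),
                    "flags": ";".join(flags),
                }
            )
    return pd.DataFrame(rows)


def largest_tree_removal_test(
    plots: Sequence[PlotCensus],
    base_n: int = 100,
    removals: Iterable[int] = (10, 20),
    variable: str = "basal_area",
    seed: int = 0,
) -> list[RemovalTestResult]:
    """Paired DC comparison after dropping the largest trees.

    For each plot one random ``base_n``-tree sample is drawn (shared by
    both arms), DC is computed on the full sample and after removing the
    ``k`` largest trees by size, and the paired values are tested with a
    two-sided Wilcoxon signed-rank test pooled across plots.
    """
    removals = sorted(set(int(k) for k in removals))
    for k in removals:
        if k <= 0 or k >= base_n:
            raise ValidationError(f"removal {k} must be in (0, base_n={base_n})")
    results = []
    for k in removals:
        recs = []
        for plot in plots:
            try:
                ids, size, growth, weight = _plot_arrays(plot, variable)
            except ValidationError:
                continue
            if ids.size < base_n:
                raise SubsampleSkip(
                    f"plot {plot.plot_id}: {ids.size} trees < base_n={base_n}"
                )
            order = np.argsort(ids)
            rng = _sample_rng(seed, plot.plot_id, base_n, 0)
            pick = order[rng.choice(ids.size, size=base_n, replace=False)]
            s, g, w, i = size[pick], growth[pick], weight[pick], ids[pick]
            dc_full = dc_value(s, np.clip(g, 0, None), w, i)
            keep = np.argsort(s)[: base_n - k]  # drop the k largest
            dc_red = dc_value(s[keep], np.clip(g[keep], 0, None), w[keep], i[keep])
            recs.append({"plot_id": plot.plot_id, "dc_full": dc_full, "dc_reduced": dc_red})
        pairs = pd.DataFrame(recs).sort_values("plot_id").reset_index(drop=True)
        diffs = pairs["dc_reduced"] - pairs["dc_full"]
        flags: tuple[str, ...] = ()
        if np.allclose(diffs, 0.0):
            stat, pval = np.nan, np.nan
            flags = ("degenerate_all_differences_zero",)
        else:
            test = stats.wilcoxon(
                pairs["dc_full"], pairs["dc_reduced"], alternative="two-sided"
            )
            stat, pval = float(test.statistic), float(test.pvalue)
        results.append(
            RemovalTestResult(
                n_removed=k,
                pairs=pairs,
                statistic=stat,
                p_value=pval,
                n_decreased=int((diffs < 0).sum()),
                flags=flags,
            )
        )
    return results
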