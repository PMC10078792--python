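"""Growth-partitioning indices: growth dominance coefficient and
size-growth relationship slope.

The growth dominance coefficient (DC) is computed from the piecewise-linear
curve of cumulative proportional growth against cumulative proportional
size, with trees arranged in ascending order of size:

    DC = 1 - sum_i (s_i - s_{i-1}) * (D_i + D_{i-1})

where ``s_i`` is the cumulative proportional size of tree ``i`` and
``D_i`` the cumulative proportional growth, ``s_0 = D_0 = 0``.  DC lies in
[-1, 1] whenever all growths are non-negative: 0 means growth proportional
to size, positive values mean large trees contribute disproportionately to
stand growth, negative values the opposite.

The size-growth relationship (SGR) is the ordinary-least-squares slope of
proportional individual growth on proportional individual size; growth
proportional to size gives a slope of exactly 1.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DegenerateFitError,
    UndefinedResultError,
    ValidationError,
)
from .types import AllometryCoefficients, PartitionResult, TreeRecord

TreesLike = Union[Sequence[TreeRecord], pd.DataFrame]

NEGATIVE_GROWTH_POLICIES = ("clamp_to_zero", "keep")


# ---------------------------------------------------------------------------
# input coercion


def _as_arrays(trees: TreesLike):
    """Return (tree_id, size, growth, weight) arrays from records or a frame."""
    if isinstance(trees, pd.DataFrame):
        if len(trees) == 0:
            raise ValidationError("empty tree table")
        ids = trees["tree_id"].astype(str).to_numpy()
        size = trees["size"].to_numpy(dtype=float)
        growth = trees["growth"].to_numpy(dtype=float)
        if "weight" in trees.columns:
            weight = trees["weight"].to_numpy(dtype=float)
        else:
            weight = np.ones_like(size)
    else:
        trees = list(trees)
        if not trees:
            raise ValidationError("empty tree collection")
        ids = np.array([str(t.tree_id) for t in trees])
        size = np.array([t.size for t in trees], dtype=float)
        growth = np.array([t.growth for t in trees], dtype=float)
        weight = np.array([t.weight for t in trees], dtype=float)
    bad = np.flatnonzero(~(size > 0))
    if bad.size:
        raise ValidationError(
            f"non-positive size for tree(s) {ids[bad[:5]].tolist()} (size must be > 0)"
        )
    bad_w = np.flatnonzero(~(weight > 0))
    if bad_w.size:
        raise ValidationError(
            f"non-positive weight for tree(s) {ids[bad_w[:5]].tolist()}"
        )
    return ids, size, growth, weight


def _apply_policy(growth: np.ndarray, policy: str) -> tuple[np.ndarray, tuple[str, ...]]:
    if policy not in NEGATIVE_GROWTH_POLICIES:
        raise ValidationError(
            f"negative_growth_policy must be one of {NEGATIVE_GROWTH_POLICIES}, got {policy!r}"
        )
    flags: tuple[str, ...] = ()
    if np.any(growth < 0):
        if policy == "clamp_to_zero":
            growth = np.clip(growth, 0.0, None)
            flags = ("negative_growth_clamped",)
        else:
            flags = ("negative_growth_kept",)
    return growth, flags


# ---------------------------------------------------------------------------
# growth dominance coefficient


def dc_value(
    size: np.ndarray,
    growth: np.ndarray,
    weight: np.ndarray | None = None,
    tree_id: np.ndarray | None = None,
) -> float:
    """Trapezoid-rule DC on pre-validated arrays.

    Trees are sorted ascending by size, ties broken by ascending growth then
    tree id so the cumulative curve is deterministic.  Weights multiply both
    the size and growth contributions in the cumulative sums.
    """
    size = np.asarray(size, dtype=float)
    growth = np.asarray(growth, dtype=float)
    if weight is None:
        weight = np.ones_like(size)
    if tree_id is None:
        tree_id = np.arange(size.size)
    order = np.lexsort((np.asarray(tree_id), growth, size))
    ws = weight[order] * size[order]
    wg = weight[order] * growth[order]
    total_growth = wg.sum()
    if not total_growth > 0:
        raise UndefinedResultError(
            f"total weighted growth is {total_growth}; DC is undefined for non-positive totals"
        )
    s = np.concatenate(([0.0], np.cumsum(ws) / ws.sum()))
    d = np.concatenate(([0.0], np.cumsum(wg) / total_growth))
    return float(1.0 - np.sum(np.diff(s) * (d[1:] + d[:-1])))


def growth_dominance_coefficient(
    trees: TreesLike,
    variable: str = "basal_area",
    negative_growth_policy: str = "clamp_to_zero",
    plot_id: str | None = None,
) -> PartitionResult:
    """Compute the growth dominance coefficient for one stand.

    Parameters
    ----------
    trees
        Sequence of :class:`TreeRecord` or a frame with columns
        ``tree_id, size, growth`` (optional ``weight``); sizes and growths
        must already be expressed in ``variable``'s dimension family.
    variable
        Recorded in the result for provenance only.
    negative_growth_policy
        ``clamp_to_zero`` (default) zeroes shrinking trees before forming
        proportions, preserving the [-1, 1] bound; ``keep`` passes negative
        increments through and flags the result.

    Raises
    ------
    ValidationError
        Empty input or non-positive size/weight.
    UndefinedResultError
        Total growth <= 0 after the policy.
    """
    ids, size, growth, weight = _as_arrays(trees)
    growth, flags = _apply_policy(growth, negative_growth_policy)
    value = dc_value(size, growth, weight, ids)
    return PartitionResult(
        value=value,
        index_kind="DC",
        variable=variable,
        n_trees=size.size,
        plot_id=plot_id,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# size-growth relationship


def sgr_value(
    size: np.ndarray, growth: np.ndarray, weight: np.ndarray | None = None
) -> float:
    """Weighted OLS slope of proportional growth on proportional size."""
    size = np.asarray(size, dtype=float)
    growth = np.asarray(growth, dtype=float)
    if weight is None:
        weight = np.ones_like(size)
    total_g = float(np.sum(weight * growth))
    total_s = float(np.sum(weight * size))
    if not total_g > 0:
        raise UndefinedResultError(
            f"total weighted growth is {total_g}; SGR proportions are undefined"
        )
    # per-tree proportions over weighted stand totals; weights re-enter as
    # regression weights, so integer weights reproduce tree replication
    q = size / total_s
    p = growth / total_g
    wsum = weight.sum()
    qbar = float(np.sum(weight * q) / wsum)
    pbar = float(np.sum(weight * p) / wsum)
    sqq = float(np.sum(weight * (q - qbar) ** 2))
    if sqq <= 0 or not np.isfinite(sqq):
        raise DegenerateFitError("zero variance in proportional size; SGR slope undefined")
    spq = float(np.sum(weight * (q - qbar) * (p - pbar)))
    return spq / sqq


def size_growth_relationship(
    trees: TreesLike,
    variable: str = "basal_area",
    plot_id: str | None = None,
) -> PartitionResult:
    """OLS slope of proportional stand growth on proportional size.

    Requires >= 2 trees with non-identical proportional sizes; a slope of
    1 means growth exactly proportional to size, 0 means equal growth for
    all trees.
    """
    ids, size, growth, weight = _as_arrays(trees)
    if size.size < 2:
        raise ValidationError(f"SGR requires >= 2 trees, got {size.size}")
    value = sgr_value(size, growth, weight)
    return PartitionResult(
        value=value,
        index_kind="SGR",
        variable=variable,
        n_trees=size.size,
        plot_id=plot_id,
    )


# ---------------------------------------------------------------------------
# per-tree derived quantities


def basal_area(diameter_cm):
    """Cross-sectional stem area (m2) at 1.3 m from diameter in cm."""
    d = np.asarray(diameter_cm, dtype=float)
    if np.any(~(d > 0)):
        raise ValidationError("diameter must be > 0")
    out = np.pi * (d / 200.0) ** 2
    return float(out) if np.isscalar(diameter_cm) else out


def resolve_coefficients(
    table: Iterable[AllometryCoefficients] | Mapping[str, AllometryCoefficients],
    species: str,
) -> AllometryCoefficients:
    """Look up species coefficients with wildcard ('*') fallback."""
    if isinstance(table, Mapping):
        entries = table
    else:
        entries = {c.species: c for c in table}
    if species in entries:
        return entries[species]
    if "*" in entries:
        return entries["*"]
    raise ConfigurationError(
        f"no allometry coefficients for species {species!r} and no wildcard entry"
    )


def stem_mass(diameter_cm, coeffs: AllometryCoefficients):
    """Power-law stem mass (kg): multiplier * dbh**exponent.

    Strictly increasing in diameter because both coefficients are positive.
    """
    d = np.asarray(diameter_cm, dtype=float)
    if np.any(~(d > 0)):
        raise ValidationError("diameter must be > 0")
    out = coeffs.multiplier * d ** coeffs.exponent
    return float(out) if np.isscalar(diameter_cm) else out


def derive_size_growth(
    dbh_start,
    dbh_end,
    variable: str,
    coeffs: AllometryCoefficients | None = None,
):
    """Size and increment arrays in the requested dimension family.

    Diameter increments are simple differences; basal-area and stem-mass
    increments are differences of the transformed start/end diameters.
    """
    d0 = np.asarray(dbh_start, dtype=float)
    d1 = np.asarray(dbh_end, dtype=float)
    if variable == "diameter":
        return d0, d1 - d0
    if variable == "basal_area":
        return basal_area(d0), basal_area(d1) - basal_area(d0)
    if variable == "stem_mass":
        if coeffs is None:
            coeffs = AllometryCoefficients(multiplier=0.1, exponent=2.5)
        return stem_mass(d0, coeffs), stem_mass(d1, coeffs) - stem_mass(d0, coeffs)
    raise ValidationError(f"unknown variable {variable!r}")


def results_to_frame(results: Iterable[PartitionResult]) -> pd.DataFrame:
    """Tabulate partition results in the delimited output layout."""
    rows = [
        {
            "plot_id": r.plot_id,
            "index_kind": r.index_kind,
            "variable": r.variable,
            "n_trees": r.n_trees,
            "value": r.value,
            "flags": ";".join(r.flags),
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=["plot_id", "index_kind", "variable", "n_trees", "value", "flags"])
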