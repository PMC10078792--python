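"""Shared fixtures: seeded synthetic plots at the scales the tests need."""

from __future__ import annotations

import numpy as np
import pytest

from growthdom.synthetic_stands import StandConfig, generate_stand


def make_index_study_plots(structure: str, n_plots: int, n_trees: int = 400, seed0: int = 1):
    """Plots with between-plot variation in the size-growth law, so that
    full-plot index values spread out and correlations are informative.

    Even-aged stands span a wide range of growth laws (stage/age variation);
    selection stands are near-steady-state and share similar laws, so their
    between-plot index spread is small relative to subsampling noise --
    the structural asymmetry behind their higher sample-size sensitivity.
    """
    plots = []
    for i in range(n_plots):
        rng = np.random.default_rng([seed0, 77, i])
        if structure == "even_aged":
            gamma = float(rng.uniform(0.7, 1.5))
            alpha = float(rng.uniform(0.0, 0.15))
        else:
            gamma = float(rng.uniform(0.85, 1.05))
            alpha = float(rng.uniform(0.02, 0.08))
        cfg = StandConfig(
            structure=structure,
            n_trees=n_trees,
            dbh_rate=0.06,
            dbh_max=120.0,
            gamma=gamma,
            alpha=alpha,
            beta=0.02,
            sigma=0.12,
            beech_fraction_ba=0.7,
            seed=int(seed0 * 100_000 + i),
        )
        plots.append(generate_stand(cfg, plot_id=f"{structure[:2]}-{i:03d}"))
    return plots


@pytest.fixture(scope="session")
def even_aged_plots():
    return make_index_study_plots("even_aged", 30, n_trees=200)


@pytest.fixture(scope="session")
def selection_plots():
    return make_index_study_plots("selection", 30, n_trees=200)


@pytest.fixture()
def simple_stand():
    """Deterministic proportional-growth stand: DC = 0, SGR = 1."""
    cfg = StandConfig(
        structure="even_aged", n_trees=25, alpha=0.0, beta=0.02, gamma=1.0,
        sigma=0.0, seed=42,
    )
    return generate_stand(cfg, plot_id="prop")
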