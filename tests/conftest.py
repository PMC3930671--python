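"""Shared fixtures: small windows and programmatically built stem maps."""

from __future__ import annotations

import numpy as np
import pytest

from icomosaic.core import PlotWindow, StemMap, TreeRecord


@pytest.fixture
def window200() -> PlotWindow:
    """4-ha square plot with the standard 5 m buffer."""
    return PlotWindow(0.0, 0.0, 200.0, 200.0, buffer_width=5.0)


@pytest.fixture
def window100() -> PlotWindow:
    return PlotWindow(0.0, 0.0, 100.0, 100.0, buffer_width=5.0)


def make_tree(i, x, y, dbh=20.0, species="JP", status="live", crown_radius=None):
    return TreeRecord(id=f"t{i}", x=x, y=y, species=species, dbh=dbh,
                      status=status, crown_radius=crown_radius)


def random_crowned_map(window: PlotWindow, n: int, seed: int,
                       r_lo: float = 1.0, r_hi: float = 5.0) -> StemMap:
    """Uniform random stems with uniform random crown radii."""
    rng = np.random.default_rng(seed)
    trees = [
        make_tree(
            i,
            rng.uniform(window.x_min, window.x_max),
            rng.uniform(window.y_min, window.y_max),
            dbh=float(rng.uniform(6, 80)),
            crown_radius=float(rng.uniform(r_lo, r_hi)),
        )
        for i in range(n)
    ]
    return StemMap(window, trees, site_label="random")


@pytest.fixture
def tiny_stemmap(window200) -> StemMap:
    trees = [
        make_tree(0, 10.0, 10.0, dbh=12.5),
        make_tree(1, 100.0, 100.0, dbh=30.0, species="WF",
                  status="snag"),
        make_tree(2, 150.25, 42.75, dbh=81.0),
    ]
    return StemMap(window200, trees, site_label="tiny")
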