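"""Shared fixtures: small seeded panels used across the suite."""

import numpy as np
import pandas as pd
import pytest

import gtwrkit as g


def make_toy_panel(seed: int = 5, n_units: int = 10, n_months: int = 2):
    """A tiny well-conditioned panel with O(1)-scale covariates.

    Used for exact-arithmetic comparisons against brute-force solvers,
    where covariate scaling must keep local systems far from singular.
    """
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, 10, size=(n_units, 2))
    n = n_units * n_months
    frame = pd.DataFrame(
        {
            "unit_id": np.repeat([f"U{i}" for i in range(n_units)], n_months),
            "u": np.repeat(coords[:, 0], n_months),
            "v": np.repeat(coords[:, 1], n_months),
            "t": np.tile(np.arange(n_months), n_units),
            "x1": rng.normal(0, 1, n),
            "x2": rng.normal(0, 1, n),
        }
    )
    frame["response"] = (
        1.0 + 0.5 * frame.x1 - 0.3 * frame.x2 + rng.normal(0, 0.1, n)
    )
    return g.PanelDataset(frame, ("x1", "x2"))


@pytest.fixture(scope="session")
def toy_panel():
    return make_toy_panel()


@pytest.fixture(scope="session")
def small_config():
    """30 units x 12 months: fast but structurally complete."""
    return g.SyntheticConfig(n_units=30, n_months=12, n_stations=15, seed=3)


@pytest.fixture(scope="session")
def small_panel(small_config):
    panel, truth = g.generate_panel(small_config)
    return panel, truth


def constant_surfaces(beta_aqi: float = 0.5):
    return (
        g.CoefficientSurface("intercept", base=1.0),
        g.CoefficientSurface("aqi", base=beta_aqi),
        g.CoefficientSurface("unemployment", base=0.03),
        g.CoefficientSurface("income", base=-0.0003),
    )
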