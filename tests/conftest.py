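"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from equipanel import GeneratorConfig, ResourcePanel, default_scheme, generate_panel


def pairwise_gini(bases, resources) -> float:
    """Independent Gini oracle: weighted pairwise mean difference.

    G = sum_i sum_j w_i w_j |r_i - r_j| / (2 mu) with w the base shares,
    r the per-base densities and mu = sum_i w_i r_i.  Kept deliberately
    independent of the Lorenz-trapezoid code path it cross-checks.
    """
    b = np.asarray(bases, dtype=float)
    r = np.asarray(resources, dtype=float) / b
    w = b / b.sum()
    mu = float(np.sum(w * r))
    return float(np.sum(np.abs(np.subtract.outer(r, r)) * np.outer(w, w)) / (2 * mu))


def equal_density_frame(k: float = 5.0e-4) -> pd.DataFrame:
    """A 31-province one-year panel whose counts are exactly proportional to
    population (per-capita density k) and to area (per-km² density 2k)."""
    scheme = default_scheme()
    provinces = scheme.provinces()
    rng = np.random.default_rng(7)
    pops = rng.integers(3_000_000, 110_000_000, size=len(provinces)).astype(float)
    areas = pops / 100.0  # equal per-km2 density too
    return pd.DataFrame({
        "province": provinces,
        "year": 2018,
        "population": pops,
        "area_km2": areas,
        "institutions": k * pops / 100,
        "beds": k * pops,
        "technicians": k * pops,
        "physicians": k * pops,
    })


@pytest.fixture(scope="session")
def default_panel() -> ResourcePanel:
    return generate_panel(GeneratorConfig(seed=42))


@pytest.fixture()
def equal_density_panel() -> ResourcePanel:
    return ResourcePanel(equal_density_frame())
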