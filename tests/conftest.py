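"""Shared rendered fixtures (session-scoped: renders are reused across tests)."""

from __future__ import annotations

import pytest

from phantomqa import SimConfig, get_layout, register_phantom, render_series


@pytest.fixture(scope="session")
def acr_layout():
    return get_layout("ACR")


@pytest.fixture(scope="session")
def insight_layout():
    return get_layout("INSIGHT")


@pytest.fixture(scope="session")
def insight_ideal():
    """Pristine Insight render: no distortion, blur, noise, or bias."""
    series, truth = render_series(SimConfig(layout="INSIGHT", seed=102))
    return series, truth


@pytest.fixture(scope="session")
def acr_ideal():
    series, truth = render_series(SimConfig(layout="ACR", seed=101))
    return series, truth


@pytest.fixture(scope="session")
def insight_reg(insight_ideal, insight_layout):
    series, _ = insight_ideal
    return register_phantom(series[insight_layout.analysis_slices["grid"]], insight_layout)


@pytest.fixture(scope="session")
def acr_reg(acr_ideal, acr_layout):
    series, _ = acr_ideal
    return register_phantom(series[acr_layout.analysis_slices["geometry"]], acr_layout)
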