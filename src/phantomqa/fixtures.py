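"""Canonical, seeded simulation fixtures for recovery testing.

Each fixture is a named :class:`~phantomqa.simulate.SimConfig` (or a small
family of them) together with the outcomes the analyzers are expected to
recover and the tolerance for each.  Fixtures are regenerated at call time
from their configs - nothing large is stored - and regeneration with the
same name is bit-reproducible because every config carries a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable

from .simulate import DistortionField, GroundTruth, SimConfig, render_series
from .imageio import QASeries

__all__ = ["Fixture", "FixtureSpec", "make_fixture", "fixture_names"]


@dataclass(frozen=True)
class FixtureSpec:
    name: str
    configs: tuple[SimConfig, ...]
    expected: dict[str, Any]  # outcome id -> (value, tolerance) or value


@dataclass(frozen=True)
class Fixture:
    spec: FixtureSpec
    series: tuple[QASeries, ...]
    truths: tuple[GroundTruth, ...]

    @property
    def name(self) -> str:
        return self.spec.name

    @property
    def expected(self) -> dict[str, Any]:
        return self.spec.expected


def _registry() -> dict[str, FixtureSpec]:
    k_radial = -1.0 / 141.42135623730951**2  # -1 mm displacement at the grid corner radius
    return {
        # pristine renders: every geometric error 0, nominal thickness recovered
        "acr_ideal": FixtureSpec(
            "acr_ideal",
            (SimConfig(layout="ACR", seed=101),),
            {
                "path_error_mm": (0.0, 0.2),
                "thickness_mm": (5.0, 0.05),
                "wedge_offset_mm": (0.0, 0.2),
                "piu": (100.0, 0.5),
            },
        ),
        "insight_ideal": FixtureSpec(
            "insight_ideal",
            (SimConfig(layout="INSIGHT", seed=102),),
            {
                "path_error_mm": (0.0, 0.1),
                "thickness_mm": (3.0, 0.05),
                "percent_visible": (100.0, 0.0),
            },
        ),
        # smooth radial contraction, strongest at the periphery
        "insight_distorted": FixtureSpec(
            "insight_distorted",
            (SimConfig(layout="INSIGHT", distortion=DistortionField(radial_k=k_radial), seed=103),),
            {"recovery_tolerance_mm": 0.2},
        ),
        # increasing blur at fixed pattern frequency: MTF must fall monotonically
        "insight_blur_sweep": FixtureSpec(
            "insight_blur_sweep",
            tuple(
                SimConfig(layout="INSIGHT", blur_fwhm=f, seed=104)
                for f in (0.0, 1.5, 3.0, 4.5, 6.0)
            ),
            {"monotone": "non-increasing"},
        ),
        # phantom tilted about the ramp axis: opposed transitions split but
        # the harmonic combination still recovers the true thickness
        "ramp_tilt": FixtureSpec(
            "ramp_tilt",
            tuple(SimConfig(layout="INSIGHT", tilt_deg=t, seed=105) for t in (0.0, 1.0, 2.0)),
            {"thickness_mm": (3.0, 0.05)},
        ),
        # flat field with 5% Gaussian noise: the multi-ROI std metric is a
        # consistent estimator of the noise fraction
        "uniformity_noise": FixtureSpec(
            "uniformity_noise",
            (SimConfig(layout="INSIGHT", noise_sigma=0.05, seed=106),),
            {"avg_std_percent": (5.0, 0.3)},
        ),
        # 4-acquisition marker session with 3 of 40 channels missing: 92.5%
        "markers_partial": FixtureSpec(
            "markers_partial",
            (
                SimConfig(layout="INSIGHT", seed=107),
                SimConfig(layout="INSIGHT", seed=108),
                SimConfig(layout="INSIGHT", seed=109),
                SimConfig(layout="INSIGHT", hidden_markers=("ch_t1", "ch_l2", "ch_r1"), seed=110),
            ),
            {"percent_visible": (92.5, 0.0)},
        ),
    }


def fixture_names() -> list[str]:
    return sorted(_registry())


def make_fixture(name: str) -> Fixture:
    """Render a registered fixture: (series, ground truths, expected outcomes)."""
    reg = _registry()
    if name not in reg:
        raise KeyError(f"unknown fixture {name!r}; known: {', '.join(sorted(reg))}")
    spec = reg[name]
    rendered = [render_series(c) for c in spec.configs]
    return Fixture(
        spec=spec,
        series=tuple(s for s, _ in rendered),
        truths=tuple(t for _, t in rendered),
    )
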