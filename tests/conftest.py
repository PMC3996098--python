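"""Shared fixtures: cached scenario runs on the default heel model.

Transient scenario pairs are expensive relative to unit tests, so they are
computed once per session and shared.  All protocol runs here use the
5-minute recovery window that the diagnostic observables live in; the one
full 30-minute run has its own fixture.
"""

from __future__ import annotations

import pytest

import dtitherm as dt


@pytest.fixture(scope="session")
def short_cfg() -> dt.ProtocolConfig:
    """Default protocol truncated to the 5-minute diagnostic window."""
    return dt.ProtocolConfig(t_end=300.0)


@pytest.fixture(scope="session")
def pair_cache(short_cfg):
    """Memoized (lesion, healthy) scenario pairs on shared meshes."""
    cache: dict = {}

    def get(stage: dt.LesionStage, depth: float):
        key = (stage, depth)
        if key not in cache:
            cache[key] = dt.run_pair(stage, depth, short_cfg)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def healthy_full_run():
    """Healthy scenario over the complete 30-minute recovery."""
    return dt.run_scenario(dt.LesionStage.HEALTHY, None, dt.ProtocolConfig())


@pytest.fixture(scope="session")
def default_model():
    """Default 8 mm ischemia geometry/mesh/layers bundle."""
    return dt.build_model(dt.LesionStage.ISCHEMIA, 0.008)
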