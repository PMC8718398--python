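from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from aonproj import (
    extract_patterns,
    make_fig2_gb1,
    make_fig2_gb2,
    project_monopartite,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def gb1():
    """Two drugs over events A-C: patterns {ABC: 1, AB: 1}."""
    return make_fig2_gb1()


@pytest.fixture
def gb2():
    """Three drugs over events A-E: patterns {AB: 2, ABCDE: 1}."""
    return make_fig2_gb2()


@pytest.fixture
def gb1_patterns(gb1):
    return extract_patterns(gb1)


@pytest.fixture
def gm1(gb1):
    """Triangle A-B-C."""
    return project_monopartite(gb1)


@pytest.fixture
def gb2_patterns(gb2):
    return extract_patterns(gb2)


@pytest.fixture
def gm2(gb2):
    """Complete graph on A-E."""
    return project_monopartite(gb2)
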