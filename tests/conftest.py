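from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def small_config():
    """A scaled-down synthetic study: same structure, desk-size counts."""
    from famexome.synth import SyntheticConfig

    return SyntheticConfig(
        seed=42,
        snv_het_range=(120, 160),
        indel_range=(60, 100),
        n_reads=300,
    )


@pytest.fixture
def small_study(small_config):
    from famexome.synth import gen_family_cohorts

    return gen_family_cohorts(small_config)
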