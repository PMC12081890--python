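import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cytoferm import simulate
from cytoferm.gating import (
    apply_gfp_gate,
    apply_singlet_filter,
    apply_static_filter,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_table():
    """The canonical 5-event fixture: live GFP+/GFP- singlets, a doublet,
    a dead singlet, and one event removed by the static filter."""
    return simulate.make_gate_fixture()


@pytest.fixture
def toy_masks(toy_table):
    """All four masks for the toy table (live threshold between clusters)."""
    return {
        "static": apply_static_filter(toy_table),
        "single": apply_singlet_filter(toy_table, 80.0),
        "gfp_positive": apply_gfp_gate(toy_table, 100.0),
        "live": toy_table.fl3_h < 1000.0,
    }


@pytest.fixture
def live_dead_events():
    """10,000 acquired events, 70% live, well-separated FL3-H modes."""
    spec = simulate.live_dead_spec(live_fraction=0.70)
    return simulate.simulate_events(spec, n=12_000, seed=42)


def true_live_fraction(table) -> float:
    labels = table.labels
    return float(np.isin(labels, list(simulate.LIVE_COMPONENTS)).mean())
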