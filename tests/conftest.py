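"""Shared fixtures: the CPU-scale training experiments are run once per session."""

import pytest

from avisep.experiments import counter_comparison, separation_recovery


@pytest.fixture(scope="session")
def recovery():
    """End-to-end separation recovery experiment (tiny model, 30 epochs)."""
    return separation_recovery(seed=0)


@pytest.fixture(scope="session")
def counter_cmp():
    """Improved vs. baseline counter heads on 2-vs-3-source mixtures."""
    return counter_comparison(seed=0)
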