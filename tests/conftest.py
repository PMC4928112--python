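import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make _oracles importable

from netclass import DirectedNetwork

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover - hypothesis is a test dependency
    pass


@pytest.fixture
def path3() -> DirectedNetwork:
    """A -> B -> C."""
    return DirectedNetwork.from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def cycle3() -> DirectedNetwork:
    """A -> B -> C -> A."""
    return DirectedNetwork.from_edges([("A", "B"), ("B", "C"), ("C", "A")])


@pytest.fixture
def diamond() -> DirectedNetwork:
    """A -> {B, C} -> D."""
    return DirectedNetwork.from_edges([("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")])
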