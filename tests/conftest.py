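import numpy as np
import pytest

from seqimp import Alphabet, MISSING, SequencePanel, generate_panel, preset
from seqimp.synthgen import GeneratorSpec


def panel_from_strings(rows, states=("A", "B", "C", "D"), **kw):
    """Build a panel from strings like 'AAB.BA' ('.' = missing)."""
    states = tuple(states)
    lookup = {s: i for i, s in enumerate(states)}
    data = np.array([[MISSING if ch == "." else lookup[ch] for ch in row]
                     for row in rows], dtype=np.int32)
    used = max(2, int(data.max()) + 1)
    return SequencePanel(data, Alphabet(states[:used]), **kw)


@pytest.fixture
def make_panel():
    return panel_from_strings


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def markov_panel():
    """Stationary first-order Markov panel with a known transition matrix."""
    P = np.array([[0.8, 0.15, 0.05],
                  [0.1, 0.8, 0.1],
                  [0.05, 0.15, 0.8]])
    # stationary distribution
    w, v = np.linalg.eig(P.T)
    pi = np.real(v[:, np.argmin(np.abs(w - 1))])
    pi = pi / pi.sum()
    spec = GeneratorSpec(n=5000, T=8, states=("A", "B", "C"), init=pi,
                         transition=P)
    panel = generate_panel(spec, np.random.default_rng(777))
    panel.transition_matrix = P
    panel.stationary = pi
    return panel


@pytest.fixture
def small_panel():
    return generate_panel(preset("small_template", n=300),
                          np.random.default_rng(42))
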