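import numpy as np
import pytest

from scriptsurp.synthetic_data import NoiseSpec, ScriptGraph


@pytest.fixture
def pasta_graph() -> ScriptGraph:
    """Small pasta-cooking script network with one branch point and a terminal."""
    return ScriptGraph(
        states=("put water", "turn stove", "boil water", "pour pasta"),
        transition_matrix=np.array(
            [
                [0.0, 0.8, 0.2, 0.0, 0.0],
                [0.0, 0.0, 0.9, 0.1, 0.0],
                [0.0, 0.0, 0.0, 0.85, 0.15],
                [0.0, 0.0, 0.0, 0.0, 1.0],
            ]
        ),
        start_distribution=np.array([0.9, 0.1, 0.0, 0.0]),
    )


@pytest.fixture
def zero_noise() -> NoiseSpec:
    return NoiseSpec(seed=0)


@pytest.fixture
def toy_sequences() -> list[list[str]]:
    """Hand-countable bigram corpus: p(b|a)=1, p(c|b)=2/3, p(d|b)=1/3."""
    return [["a", "b", "c"], ["a", "b", "d"], ["a", "b", "c"]]
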