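import numpy as np
import pytest

from repeatphylo import pipeline, trees


@pytest.fixture(scope="session")
def tree10():
    """Ten species in four clades: the standard synthetic study tree."""
    return trees.clade_tree(pipeline.default_clades())


@pytest.fixture(scope="session")
def tree13():
    """Fixed 13-tip tree with deep shared history, used for λ recovery."""
    clades = {
        "A": ["a1", "a2", "a3"],
        "B": ["b1", "b2", "b3"],
        "C": ["c1", "c2", "c3"],
        "D": ["d1", "d2", "d3", "d4"],
    }
    return trees.clade_tree(clades, crown_depth=0.05, backbone_start=0.2)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def study_result():
    """Full synthetic study at the standard scale; shared across tests."""
    return pipeline.run_study(pipeline.StudyConfig(seed=1))
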