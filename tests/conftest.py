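import numpy as np
import pytest

from cohmap import GeneratorConfig, make_corpus_and_space, make_transcripts
from cohmap.semantic_space import SemanticSpace


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced synthetic cohort (8 controls, 12 patients) with its space;
    session-scoped because the space build dominates the cost."""
    cfg = GeneratorConfig(seed=7, n_controls=8, n_patients=12)
    _, space = make_corpus_and_space(cfg)
    records, truth = make_transcripts(cfg)
    return cfg, space, records, truth


@pytest.fixture
def toy_space():
    """Hand-set 3-word, 3-dim orthonormal space for arithmetic checks."""
    return SemanticSpace(
        words=["tea", "kettle", "boy"],
        matrix=np.eye(3),
        provenance="hand-built toy",
    )
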