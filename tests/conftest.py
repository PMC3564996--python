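import os
import sys

import numpy as np
import pytest

sys.path.insert(0, os.path.dirname(__file__))

from alleleflow.pipeline import run_pipeline
from alleleflow.simulate import SimulationConfig, score_against_truth, simulate_dataset


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


@pytest.fixture(scope="session")
def study_run():
    """One full pipeline run under the standard study conditions.

    8 diploid individuals in two groups, 150 single-copy loci plus 25
    two-copy paralog families at 6% divergence, 1% allelic divergence,
    90% haplotype capture, no sequencing errors, seed 42.  Shared by the
    end-to-end tests; runs once per session (~1 minute).
    """
    config = SimulationConfig(seed=42)
    library, truth = simulate_dataset(config)
    result = run_pipeline(library)
    metrics = score_against_truth(result, truth)
    return library, truth, result, metrics
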