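import numpy as np
import pytest

from crisprembryo.reads import CcsRead
from crisprembryo.synthetic import make_amplicon


@pytest.fixture(scope="session")
def amplicon():
    """A 400-bp reference amplicon with the guide at offset 180
    (cut site at 197)."""
    return make_amplicon(seed=1, length=400, guide_offset=180)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture(scope="session")
def study_run():
    """One full simulated study (60 embryos, 3 loci x 2 reagent arms,
    depth 500, default error model) pushed through the whole pipeline.
    Session-scoped: several recovery tests share it."""
    from crisprembryo.pipeline import run_study_pipeline
    from crisprembryo.synthetic import simulate_study

    scenario = simulate_study(seed=1, n_per_group=10, depth=500)
    result = run_study_pipeline(scenario.reads, scenario.sheet, scenario.amplicons)
    return scenario, result


def make_read(
    read_id="r0", sequence="ACGT" * 25, passes=9, accuracy=0.999, qual=40
):
    return CcsRead(
        read_id=read_id,
        sequence=sequence,
        qualities=[qual] * len(sequence),
        passes=passes,
        predicted_accuracy=accuracy,
    )
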