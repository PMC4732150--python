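import numpy as np
import pytest

from fallkit.records import ADL, FALL, RECORD_LEN, Record
from fallkit.synthetic import GeneratorConfig, generate_dataset


def make_record(values=None, label=ADL, subject="S", at=None):
    """Record from a (3, 51) array, or a zero record with a scalar placed
    at samples[0, 0] so distances reduce to 1-D absolute differences."""
    if values is None:
        values = np.zeros((3, RECORD_LEN))
        if at is not None:
            values[0, 0] = at
    return Record(subject, label, np.asarray(values, dtype=float))


def line_records(positions, label=ADL):
    """Degenerate records embedded on a line: pairwise distances equal the
    absolute coordinate differences."""
    return [make_record(at=p, label=label) for p in positions]


@pytest.fixture(scope="session")
def small_dataset():
    """Seeded 4-subject cohort, big enough for CV but fast."""
    return generate_dataset(
        GeneratorConfig(n_subjects=4, adl_per_subject=40,
                        falls_per_subject=12, seed=7)
    )


@pytest.fixture(scope="session")
def random_records():
    """50 i.i.d. Gaussian records for oracle comparisons."""
    rng = np.random.default_rng(11)
    return [
        make_record(rng.normal(size=(3, RECORD_LEN))) for _ in range(50)
    ]
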