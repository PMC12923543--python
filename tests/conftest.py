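import numpy as np
import pytest

from nanochop.io_fastq import ReadRecord
from nanochop import simulate as S


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def fast_body_model():
    """Short bodies so end-to-end tests stay quick."""
    return S.BodyModel(length_distribution=("lognormal", {"median": 150, "sigma": 0.4}))


def make_record(read_id="r1", sequence="ACGT", quality=30):
    quals = np.full(len(sequence), quality, dtype=np.int64)
    return ReadRecord(read_id, sequence, quals)


@pytest.fixture
def two_record_fastq(tmp_path):
    text = (
        "@read1\nACGTN\n+\n!I5+~\n"
        "@read2 with description\nTTTT\n+\nIIII\n"
    )
    path = tmp_path / "fixture.fastq"
    path.write_text(text)
    return path, text
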