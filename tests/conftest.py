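import numpy as np
import pytest

from hmannot.io_formats import BlastHit


def make_hit(query="q", subject="s", evalue=1e-10, bit_score=100.0, **kw):
    """BlastHit with sensible defaults for the non-essential columns."""
    defaults = dict(
        pct_identity=90.0,
        aln_length=100,
        mismatches=10,
        gap_opens=0,
        q_start=1,
        q_end=100,
        s_start=1,
        s_end=100,
    )
    defaults.update(kw)
    return BlastHit(query_id=query, subject_id=subject, evalue=evalue, bit_score=bit_score, **defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def hit_factory():
    return make_hit
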