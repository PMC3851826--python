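import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from homeosplit import ContigCounts, questionable_set_from_sites

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_contig(cell_counts, contig_id="c", ref=None):
    """Build a ContigCounts from an (M, N, 4) nested list/array."""
    counts = np.asarray(cell_counts, dtype=np.int64)
    m, n, _ = counts.shape
    if ref is None:
        ref = "A" * n
    return ContigCounts(
        contig_id=contig_id,
        accession_ids=[f"a{i + 1}" for i in range(m)],
        ref_seq=ref,
        counts=counts,
    )


@pytest.fixture
def fig2_contig():
    """Two accessions with opposite expression bias over two sites.

    Accession 1 carries the "CA" copy at ~1/4 of its reads (5/20 and
    10/42), accession 2 at ~4/5; pooled, the second site is nearly
    balanced (A:43 vs G:44), so the global majority blurs the signal.
    """
    counts = np.zeros((2, 2, 4), dtype=np.int64)
    counts[0, 0] = [15, 5, 0, 0]
    counts[0, 1] = [10, 0, 32, 0]
    counts[1, 0] = [4, 16, 0, 0]
    counts[1, 1] = [33, 0, 12, 0]
    contig = make_contig(counts, contig_id="fig2", ref="CG")
    qset = questionable_set_from_sites(contig, [0, 1])
    return contig, qset
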