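import numpy as np
import pytest

from selratio.genomic_io import GenomicInterval
from selratio.neutral_model import AncestralRepeat
from selratio.synthetic_data import make_worked_fixtures


@pytest.fixture(scope="session")
def worked_fixtures(tmp_path_factory):
    return make_worked_fixtures(tmp_path_factory.mktemp("fixtures"))


def make_ar(ar_id, chrom, coords, seq_ref=None, seq_other=None, **kwargs):
    """AncestralRepeat with attached pairwise alignment at given ref coords."""
    coords = np.asarray(coords, dtype=np.int64)
    n = len(coords)
    seq_ref = seq_ref or "A" * n
    seq_other = seq_other or "A" * n
    defaults = dict(family="L2a", repeat_class="LINE/L2", divergence=30.0,
                    lineage="shared")
    defaults.update(kwargs)
    ar = AncestralRepeat(
        interval=GenomicInterval(chrom, int(coords[0]), int(coords[-1]) + 1, "+", ar_id),
        ar_id=ar_id,
        **defaults,
    )
    ar.attach_alignment(seq_ref, seq_other, coords)
    return ar
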