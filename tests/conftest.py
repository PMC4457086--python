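import numpy as np
import pytest

import rnetseq as r
from rnetseq import experiments as X
from rnetseq.io import AlignedRead


@pytest.fixture(scope="session")
def wt_small():
    """Moderate WT dataset shared by unit tests (20 kb, 40 sites, 3e4 reads)."""
    return X.strain_dataset("WT", 30_000, seed=7)


@pytest.fixture(scope="session")
def dgre_small():
    return X.strain_dataset("dGreAB", 30_000, seed=9)


@pytest.fixture(scope="session")
def tiny_genome():
    genome, genes, tss = r.generate_genome(5000, 0.5, 4, seed=3)
    return genome, genes, tss


def make_read(
    start,
    length,
    strand="+",
    seq=None,
    ref=None,
    read_id="x",
    replicon="simchr",
    mapq=42,
    n_hits=1,
):
    """Hand-built substitution-only alignment for toy pileups."""
    ref = ref if ref is not None else "A" * length
    seq = seq if seq is not None else ref
    return AlignedRead(
        read_id=read_id,
        replicon=replicon,
        strand=strand,
        ref_start=start,
        ref_end=start + length,
        mapq=mapq,
        ref_bases=ref,
        read_bases=seq,
        n_hits=n_hits,
    )
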