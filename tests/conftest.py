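import numpy as np
import pytest

from mrpipe.gwas_io import (HarmonizedInstrumentSet, HarmonizedRecord,
                            SummaryStatsSet, VariantAssociation)


def va(snp_id, *, chrom="1", pos=1000, ea="A", oa="G", eaf=0.3,
       beta=0.1, se=0.01, pval=1e-9, n=100_000.0):
    return VariantAssociation(snp_id=snp_id, chrom=chrom, pos=pos,
                              effect_allele=ea, other_allele=oa, eaf=eaf,
                              beta=beta, se=se, pval=pval, n=n)


def sumset(name, records):
    return SummaryStatsSet(name, list(records))


def hset(bx, sx, by, sy, px=None, py=None, ids=None):
    """Build a HarmonizedInstrumentSet directly from effect arrays."""
    j = len(bx)
    ids = ids or [f"rs{i + 1}" for i in range(j)]
    px = px if px is not None else [1e-9] * j
    py = py if py is not None else [0.5] * j
    recs = [HarmonizedRecord(snp_id=ids[i], beta_exp=bx[i], se_exp=sx[i],
                             p_exp=px[i], beta_out=by[i], se_out=sy[i],
                             p_out=py[i]) for i in range(j)]
    log = [(i, "kept", "as_is") for i in ids]
    return HarmonizedInstrumentSet("exp", "out", recs, log)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
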