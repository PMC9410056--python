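import numpy as np
import pytest
from hypothesis import settings

from mrkit.sumstats_io import GwasRecord, HarmonizedInstrument

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_record(snp_id="rs1", ea="A", oa="G", eaf=0.3, beta=0.1, se=0.02,
                pvalue=1e-9, n=1000) -> GwasRecord:
    return GwasRecord(snp_id=snp_id, effect_allele=ea, other_allele=oa,
                      eaf=eaf, beta=beta, se=se, pvalue=pvalue, n=n)


def make_instruments(bx, by, sy, sx=None, eaf=0.3, n_exp=997, n_out=184_305):
    """Build harmonized instruments from effect/SE arrays."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sy = np.asarray(sy, dtype=float)
    sx = np.full_like(bx, 0.02) if sx is None else np.asarray(sx, dtype=float)
    return [
        HarmonizedInstrument(
            snp_id=f"snp{j + 1:03d}", effect_allele="A", other_allele="G",
            eaf_exposure=eaf,
            beta_exposure=float(bx[j]), se_exposure=float(sx[j]),
            pvalue_exposure=1e-9, n_exposure=n_exp,
            beta_outcome=float(by[j]), se_outcome=float(sy[j]),
            pvalue_outcome=0.5, n_outcome=n_out,
        )
        for j in range(len(bx))
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
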