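import numpy as np
import pandas as pd
import pytest

from ivmr.sumstats import HarmonizedInstrument, SummaryStatRecord


def make_instruments(gamma, Gamma, se_Gamma, se_gamma=None, ids=None):
    """Build harmonized instruments from parallel arrays."""
    gamma = np.asarray(gamma, dtype=float)
    Gamma = np.asarray(Gamma, dtype=float)
    se_Gamma = np.asarray(se_Gamma, dtype=float)
    se_gamma = (
        np.full_like(gamma, 0.01) if se_gamma is None else np.asarray(se_gamma, float)
    )
    ids = ids or [f"rs{j}" for j in range(len(gamma))]
    return [
        HarmonizedInstrument(i, g, sg, G, sG)
        for i, g, sg, G, sG in zip(ids, gamma, se_gamma, Gamma, se_Gamma)
    ]


def make_record(snp="rs1", ea="A", oa="G", beta=0.1, se=0.01, eaf=None, **kw):
    return SummaryStatRecord(
        snp_id=snp, effect_allele=ea, other_allele=oa, beta=beta, se=se, eaf=eaf, **kw
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def exact_fit_instruments():
    """Instruments satisfying Gamma = 0.3 * gamma exactly."""
    g = np.array([0.02, 0.03, 0.05, 0.04, 0.025])
    return make_instruments(g, 0.3 * g, np.full(5, 0.01))


def write_sumstats_tsv(path, rows, columns=None):
    cols = columns or ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
    return path
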