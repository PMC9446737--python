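import numpy as np
import pytest

from targetmr import (
    GeneRegion,
    HarmonizedPair,
    SummaryRecord,
    SyntheticConfig,
)


def make_record(
    vid="rs1",
    chrom="10",
    pos=115_803_625,
    ea="A",
    oa="G",
    beta=0.1,
    se=0.01,
    pval=1e-10,
    n=100_000,
    eaf=0.3,
):
    return SummaryRecord(
        variant_id=vid, chrom=chrom, pos=pos, effect_allele=ea, other_allele=oa,
        beta=beta, se=se, pval=pval, n=n, eaf=eaf,
    )


@pytest.fixture
def adrb1_region():
    return GeneRegion("ADRB1", "10", 115_803_625, 115_806_663)


@pytest.fixture
def mr_sim_config():
    """Twenty independent causal instruments, continuous exposure in mmHg,
    binary outcome on the log-odds scale — the recovery-test conditions."""
    return SyntheticConfig(
        seed=0,
        m_snps=20,
        ld_decay=0.0,
        causal_index=tuple(range(20)),
        causal_beta=0.5,
        theta=0.05,
        n_exposure=500_000,
        n_outcome=100_000,
        outcome_type="case_control",
        case_fraction=0.05,
    )


def pair_from_truth(exposure, outcome):
    """Aligned HarmonizedPair straight from simulated records (same alleles
    by construction, so no drops)."""
    return HarmonizedPair.from_arrays(
        [r.beta for r in exposure],
        [r.se for r in exposure],
        [r.beta for r in outcome],
        [r.se for r in outcome],
        [r.variant_id for r in exposure],
    )


def rng_spawn(seed, n):
    """Independent child seeds below 2**31 derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]
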