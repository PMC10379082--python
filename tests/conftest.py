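import numpy as np
import pytest

import radsweep as rs


@pytest.fixture(scope="session")
def bn_two_pops():
    """Two moderately diverged populations, small enough for fast tests."""
    cfg = rs.SimulationConfig(
        seed=42, n_pops=2, samples_per_pop=20, n_chrom=2,
        chrom_length_bp=500_000, n_snps=2_000, drift_f=0.1, missing_rate=0.02,
    )
    return rs.simulate_balding_nichols(cfg)


@pytest.fixture(scope="session")
def bn_structured():
    """Strongly diverged pair (drift F = 0.3) for structure tests."""
    cfg = rs.SimulationConfig(
        seed=7, n_pops=2, samples_per_pop=30, n_chrom=4,
        chrom_length_bp=500_000, n_snps=2_000, drift_f=0.3, missing_rate=0.02,
    )
    return rs.simulate_balding_nichols(cfg)


def make_vt(pos, chrom=None, qd=None, fs=None, **kw):
    """Build a minimal VariantTable around integer positions."""
    pos = np.asarray(pos, dtype=np.int64)
    n = len(pos)
    return rs.VariantTable(
        chrom=np.array(chrom if chrom is not None else ["chr1"] * n, dtype=object),
        pos=pos,
        ref=np.array(["A"] * n, dtype=object),
        alt=np.array(["T"] * n, dtype=object),
        qd=np.array(qd if qd is not None else [20.0] * n),
        fs=np.array(fs if fs is not None else [1.0] * n),
        site_id=np.arange(n),
        **kw,
    )


def make_gm(dosages, depths=None):
    dosages = np.asarray(dosages, dtype=np.int8)
    return rs.GenotypeMatrix(
        samples=[f"s{i}" for i in range(dosages.shape[0])],
        dosages=dosages,
        depths=depths,
    )
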