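import numpy as np
import pandas as pd
import pytest

import tetrasweep as ts


@pytest.fixture(scope="session")
def small_sim():
    """Two-chromosome panel with one strong shared sweep on Chr1."""
    cfg = ts.SimConfig(
        n_chromosomes=2,
        chrom_length_bp=5_000_000,
        snps_per_mb=100.0,
        n_samples_per_group={"A": 40, "B": 60},
        missing_rate=0.05,
        sweep_specs=(ts.TruthSweep("Chr1", 1_500_000, 3_000_000, "all", 0.9),),
        seed=11,
    )
    return ts.simulate_panel(cfg)


@pytest.fixture(scope="session")
def null_sim():
    """Sweep-free single-group panel (background only)."""
    cfg = ts.SimConfig(
        n_chromosomes=2,
        chrom_length_bp=4_000_000,
        snps_per_mb=100.0,
        n_samples_per_group={"P": 80},
        missing_rate=0.05,
        group_divergence=0.0,
        seed=7,
    )
    return ts.simulate_panel(cfg)


def toy_windows(chrom, firsts, lasts, mids=None):
    """Hand-built window frame for caller/band unit tests."""
    firsts = np.asarray(firsts)
    lasts = np.asarray(lasts)
    if mids is None:
        mids = firsts
    return pd.DataFrame(
        {
            "chromosome": [chrom] * len(firsts),
            "first": firsts,
            "last": lasts,
            "start_bp": np.asarray(mids),
            "end_bp": np.asarray(mids),
            "mid_bp": np.asarray(mids),
            "n_loci": lasts - firsts + 1,
        }
    )
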