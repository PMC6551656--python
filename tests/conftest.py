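import numpy as np
import pandas as pd
import pytest

import methylotype as mt


@pytest.fixture(scope="session")
def small_cohort():
    """8 vs 10 samples, 500 probes, planted delta 0.2 at 10% of probes."""
    return mt.simulate_cohort(8, 10, 500, frac_dmp=0.1, delta=0.2, dispersion=0.02, seed=11)


@pytest.fixture(scope="session")
def small_manifest():
    return mt.simulate_manifest(
        500,
        seed=12,
        sex_fraction=0.05,
        mask_fractions={"cross_reactive": 0.03, "snp_overlap": 0.03},
    )


@pytest.fixture(scope="session")
def canyon_sim():
    """Coupled track + manifest + cohort with a planted 0.014 canyon shift."""
    return mt.simulate_canyon_cohort(
        n_wt=14, n_mut=28, n_probes=2000, chrom_length=120_000, n_canyons=3, seed=13
    )


@pytest.fixture(scope="session")
def reference():
    return mt.simulate_reference(
        samples_per_stage=3, n_probes=1500, within_stage_sd=0.02, seed=14
    )
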