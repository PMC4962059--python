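import warnings

import pytest

from lncraft import DEFilterParams, HomologyEngine, SimConfig, run_pipeline, simulate


@pytest.fixture()
def engine():
    return HomologyEngine()


def small_config(seed: int) -> SimConfig:
    """Scaled-down study conditions for randomized sweeps."""
    return SimConfig(
        seed=seed,
        n_chrom=1,
        chrom_len=400_000,
        n_coding=10,
        n_j_isoforms=2,
        n_o_overlap=1,
        n_lincrna=6,
        n_linc_perfect_target=2,
        n_linc_near_target=2,
        n_nat_coding=3,
        n_nat_decoy=2,
        n_nat_nat_pairs=1,
        n_nat_sirna=1,
        n_sirna=5,
        n_te_hc=3,
        n_te_pr=3,
        n_u_chains=2,
        n_u_isolated=3,
        n_dup_ref_pairs=1,
        n_short_novel=2,
        n_est=2,
        te_lib_n=8,
        smallrna_lib_n=8,
        n_protein_decoys=5,
        n_de_features=20,
    )


@pytest.fixture(scope="session")
def default_sim():
    """One full-size synthetic dataset shared across tests."""
    return simulate(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_pipeline(default_sim):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(
            default_sim.genome,
            default_sim.annotation,
            default_sim.libraries,
            est_set=default_sim.est_set,
            de_records=default_sim.de_records,
            de_params=DEFilterParams(exclusion_region=default_sim.exclusion_region),
        )
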