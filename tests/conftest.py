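import pytest

from pancyan.pangenome import PresenceAbsenceMatrix, cluster_families
from pancyan.synthetic_data import SimParams, generate_pangenome


@pytest.fixture(scope="session")
def small_params() -> SimParams:
    """Six-genome pan-genome with a 3-genome anchor subset.

    Two planted co-occurring families (one adjacent pair) and two
    confounders each leaking into one non-anchor genome.
    """
    return SimParams(
        n_genomes=6,
        n_core_families=20,
        n_dispensable_families=15,
        singleton_rate=3,
        gene_length_mean=120,
        gene_length_sd=15,
        divergence=0.02,
        anchor_subset_size=3,
        n_planted_cooccurring=2,
        adjacent_pairs=1,
        n_confounders=2,
        leak_count=1,
        enriched_target_size=40,
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def small_sim(small_params):
    return generate_pangenome(small_params)


@pytest.fixture(scope="session")
def small_families(small_sim):
    _, annotations, _ = small_sim
    return cluster_families(annotations, 0.70)


@pytest.fixture(scope="session")
def small_matrix(small_sim, small_families):
    genomes, _, _ = small_sim
    return PresenceAbsenceMatrix.from_family_table(
        small_families, [g.genome_id for g in genomes]
    )


@pytest.fixture(scope="session")
def truth_matrix(small_sim):
    """Presence/absence matrix built straight from the truth ledger."""
    import pandas as pd

    genomes, _, truth = small_sim
    gids = [g.genome_id for g in genomes]
    fids = sorted(truth.carriers)
    df = pd.DataFrame(
        [[g in truth.carriers[f] for f in fids] for g in gids],
        index=gids, columns=fids,
    )
    return PresenceAbsenceMatrix(df)


@pytest.fixture(scope="session")
def colinear_pair():
    """Two genomes with identical family content, divergence 0.02.

    No accessory content, so the contigs are equal-length and
    positionally alignable — the setting for positional ANI oracles.
    """
    params = SimParams(
        n_genomes=3,
        n_core_families=40,
        n_dispensable_families=0,
        singleton_rate=0,
        anchor_subset_size=0,
        n_planted_cooccurring=0,
        adjacent_pairs=0,
        n_confounders=0,
        leak_count=0,
        gene_length_mean=150,
        gene_length_sd=10,
        divergence=0.02,
        rng_seed=3,
    )
    genomes, _, _ = generate_pangenome(params)
    return genomes[0], genomes[1]
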