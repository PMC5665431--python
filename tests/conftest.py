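import numpy as np
import pytest

from hapfine import simdata
from hapfine.cluster_eval import ClusterModel
from hapfine.painting import CoancestryMatrix


@pytest.fixture(scope="session")
def two_cluster_dataset():
    """Two drifted clusters, 1 chromosome, enough windows for binning."""
    cfg = simdata.SimConfig(
        n_clusters=2, n_per_cluster=[30, 30], n_chrom=1, snps_per_chrom=400,
        drift_f=[0.03, 0.03], seed=11,
    )
    return simdata.simulate_haplotypes(cfg)


@pytest.fixture(scope="session")
def two_cluster_model(two_cluster_dataset):
    ds = two_cluster_dataset
    return ClusterModel(dict(zip(ds.individual_ids, ds.population_labels)))


@pytest.fixture(scope="session")
def simulated_coancestry():
    """Three donor clusters, one admixed target, moderate chunk noise."""
    return simdata.simulate_coancestry(
        [20, 20, 20], [[0.3, 0.7, 0.0]], 10_000, noise_seed=7, n_per_target=25,
    )


def coancestry_from_sim(sim):
    total = CoancestryMatrix(sim.values, sim.recipient_ids, sim.donor_ids)
    per = [CoancestryMatrix(m, sim.recipient_ids, sim.donor_ids)
           for m in sim.per_chromosome]
    return total, per, ClusterModel(dict(sim.assignment))
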