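import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from fullorf import (
    ESTRecord,
    ESTSet,
    CloneRecord,
    End,
    LibraryParams,
    Population,
    simulate_clone_library,
    simulate_gene_set,
)


def make_est(est_id, seq, end=End.FIVE_PRIME, clone_id=None,
             population=Population.ATLANTIC, library_id="libA"):
    return ESTRecord(
        est_id=est_id,
        clone_id=clone_id or est_id.rsplit(".", 1)[0],
        end=end,
        library_id=library_id,
        population=population,
        sequence=seq,
    )


def estset_from_reads(reads):
    """Build an ESTSet (with clone records) from ESTRecords."""
    clones = {}
    for est in reads:
        rec = clones.setdefault(
            est.clone_id, CloneRecord(clone_id=est.clone_id, est5_id="x")
        )
        if est.end is End.FIVE_PRIME:
            rec.est5_id = est.est_id
        else:
            rec.est3_id = est.est_id
    for rec in clones.values():
        if rec.est5_id == "x":
            rec.est5_id = None
    return ESTSet(reads, clones.values())


def random_seq(rng, n):
    return "".join(np.array(["A", "C", "G", "T"])[rng.integers(0, 4, n)])


@pytest.fixture(scope="session")
def clean_library():
    """Error-free full-length clone library over 3 plain genes."""
    genome, specs, gene_truth = simulate_gene_set(3, seed=42)
    params = LibraryParams(
        n_clones_per_gene=8, rt_dropoff_p=0.0, error_rate=0.0,
        read_len_mean=800, read_len_sd=40, seed=43,
    )
    ests, clone_truth = simulate_clone_library(specs, params)
    return {
        "genome": genome,
        "specs": specs,
        "gene_truth": gene_truth,
        "ests": ests,
        "clone_truth": clone_truth,
    }


@pytest.fixture(scope="session")
def noisy_library():
    """Library with RT drop-off and sequencing errors over 6 genes."""
    genome, specs, gene_truth = simulate_gene_set(6, seed=7, sl_genes=1)
    params = LibraryParams(
        n_clones_per_gene=15, rt_dropoff_p=0.0005, error_rate=0.01, seed=8,
    )
    ests, clone_truth = simulate_clone_library(specs, params)
    return {
        "genome": genome,
        "specs": specs,
        "gene_truth": gene_truth,
        "ests": ests,
        "clone_truth": clone_truth,
    }
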