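import numpy as np
import pytest

from thaploseq.genome_model import ReferenceLocus
from thaploseq.simulator import SimulationConfig, run_simulation


def write_fasta(path, name, seq, width=60):
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")
    return str(path)


def write_bed(path, rows, chrom="locus"):
    with open(path, "w") as fh:
        for row in rows:
            fh.write(chrom + "\t" + "\t".join(str(x) for x in row) + "\n")
    return str(path)


@pytest.fixture
def random_sequence():
    rng = np.random.default_rng(42)
    return "".join(rng.choice(list("ACGT"), size=5000))


@pytest.fixture(scope="session")
def tiny_sim():
    """Small but complete simulated experiment shared across tests."""
    cfg = SimulationConfig.fast(
        seed=7,
        locus_length=200_000,
        n_fragments=60_000,
        lfr_n=500,
        n_genes=5,
        planted_error_fraction=0.1,
    )
    return run_simulation(cfg)


@pytest.fixture(scope="session")
def fast_sim():
    """Fast-profile (1 Mb) simulation with planted reported-truth errors."""
    return run_simulation(SimulationConfig.fast(seed=1, planted_error_fraction=0.1))


@pytest.fixture
def toy_locus():
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), size=3000))
    return ReferenceLocus("toy", seq, repeats=[(500, 700), (1500, 1600)])
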