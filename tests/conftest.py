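import numpy as np
import pytest

from iesbounds.simulate import SimConfig, simulate_experiment

WT = ("CU427", "CU428", "BII")
MUT = ("3-1", "4-1", "27-2")


def random_dna(rng: np.random.Generator, n: int, p_gc: float = 0.25) -> str:
    p = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


@pytest.fixture(scope="session")
def wt_experiment():
    """Three wild-type strains, motif at every locus, default jitter."""
    cfg = SimConfig(seed=11, n_ies=30, strains=WT)
    return cfg, simulate_experiment(cfg)


@pytest.fixture(scope="session")
def contrast_experiment():
    """Six strains (3 WT + 3 mutant), motif at half the loci."""
    cfg = SimConfig(
        seed=19,
        n_ies=60,
        n_contigs=2,
        contig_length=300_000,
        motif_fraction=0.5,
        strains=WT + MUT,
        mut_strains=MUT,
    )
    return cfg, simulate_experiment(cfg)
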