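import numpy as np
import pytest

from resectra import GenomeModel, SimParams, make_genome


@pytest.fixture
def small_genome() -> GenomeModel:
    """200 kb circular chromosome, DSB at 50 kb, chi every 5 kb left /
    20 kb right in the attenuating orientation."""
    return make_genome(
        length=200_000, dsb=50_000,
        chi_layout={"left_spacing": 5_000, "right_spacing": 20_000},
    )


@pytest.fixture
def chi_free_genome() -> GenomeModel:
    return make_genome(length=200_000, dsb=50_000,
                       chi_layout={"forward": [], "reverse": []})


@pytest.fixture
def fast_params() -> SimParams:
    return SimParams(onset_rate=0.4, k_fast=400.0, p_chi=0.23, k_slow=340.0,
                     k_off=0.0, t_total=3600.0, n_cells=2_000, seed=7)


def brute_force_scan(sequence: str, motif: str, circular: bool):
    """O(n*m) two-strand sliding-window oracle for motif occurrence."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[c] for c in reversed(motif))
    n, m = len(sequence), len(motif)
    fwd, rev = [], []
    limit = n if circular else n - m + 1
    for i in range(max(limit, 0)):
        window = "".join(sequence[(i + j) % n] for j in range(m))
        if window == motif:
            fwd.append(i)
        if window == rc:
            rev.append(i)
    return sorted(set(fwd)), sorted(set(rev))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
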