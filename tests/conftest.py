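import numpy as np
import pytest
from hypothesis import settings

from crenadelim.io_model import AlleleFreqProfile
from crenadelim.synthetic_data import make_paper_like_scenario, simulate_allozymes

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def random_profile(
    rng: np.random.Generator,
    group: str,
    n_loci: int = 5,
    max_alleles: int = 4,
    two_n: int = 20,
) -> AlleleFreqProfile:
    """Random allele-frequency profile over loci L1..Ln (shared allele pool)."""
    freqs = {}
    copies = {}
    for i in range(n_loci):
        locus = f"L{i + 1}"
        k = int(rng.integers(1, max_alleles + 1))
        alleles = list("abcd"[:max_alleles])
        chosen = rng.choice(alleles, size=k, replace=False)
        raw = rng.dirichlet(np.ones(k))
        freqs[locus] = {a: float(p) for a, p in zip(sorted(chosen), raw)}
        copies[locus] = two_n
    return AlleleFreqProfile(group, freqs, copies)


@pytest.fixture(scope="session")
def paper_like():
    """One paper-like simulated dataset (seed 1), shared across tests."""
    spec = make_paper_like_scenario(1)
    gt, truth = simulate_allozymes(spec)
    return spec, gt, truth
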