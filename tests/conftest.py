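import numpy as np
import pytest

from xnacall.alphabet import make_alphabet
from xnacall.kmer_model import KmerModel, KmerStats
from xnacall.simulate import synthetic_model


@pytest.fixture(scope="session")
def pz_model():
    """Random synthetic model over A,T,G,C + the P:Z pair (768 kmers)."""
    return synthetic_model(alphabet=make_alphabet([("P", "Z")]), seed=11)


@pytest.fixture(scope="session")
def full_model():
    """Random synthetic model over the full 12-letter alphabet."""
    return synthetic_model(seed=11)


def build_heptamer_model(mu_by_kmer: dict[str, float], sigma: float = 0.4) -> KmerModel:
    """Explicit model from kmer->mu, common sigma (global == sigma)."""
    entries = {
        k: KmerStats(kmer=k, mu=mu, sigma=sigma, n_obs=100, min=mu - 1, max=mu + 1,
                     median=mu, iqr=sigma)
        for k, mu in mu_by_kmer.items()
    }
    return KmerModel(k=4, entries=entries)


def separated_pg_model(deltas, sigma: float = 0.4, base_mu: float = 0.0) -> KmerModel:
    """Model for the AAA(P|G)AAA heptamer with controlled per-kmer mean
    separations ``deltas`` between the P and G hypotheses."""
    p_kmers = ["AAAP", "AAPA", "APAA", "PAAA"]
    g_kmers = ["AAAG", "AAGA", "AGAA", "GAAA"]
    mus = {k: base_mu + d for k, d in zip(p_kmers, deltas)}
    mus.update({k: base_mu for k in g_kmers})
    return build_heptamer_model(mus, sigma)
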