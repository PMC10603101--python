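"""Monte-Carlo simulation of reads from a kmer level model, and
synthetic models for dependency-free testing.

Simulated "reads" mirror the decomposition-recompilation scheme of the
level model itself: for each heptamer NNN-X-NNN the four covering kmers
are identified and one level per kmer is drawn from Normal(mu_k,
sigma_g) with a fixed global sigma_g = 0.4 by default; the draws are
recompiled into a sequence-signal pair. Full-length squiggle features
(event durations, correlated noise) are out of scope. The three heptamer
positions outside the focal window carry a 0.0 placeholder level, which
no downstream computation reads.

Seeding uses one root seed with per-heptamer child streams, so any
subset of heptamers reproduces identically regardless of iteration
order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .alphabet import STANDARD_LETTERS, Alphabet, enumerate_xna_kmers, twelve_letter_alphabet
from .kmer_model import CoverageError, KmerModel, KmerStats, decompose
from .levels_io import LevelTable

__all__ = [
    "SimConfig",
    "all_heptamers",
    "simulate_code",
    "simulate_heptamer_levels",
    "synthetic_model",
    "theoretical_recall",
    "theoretical_auc_single_kmer",
]

#: Default per-heptamer read count and global model sigma.
DEFAULT_N_READS = 1000
DEFAULT_SIGMA_G = 0.4

FLANK = 3  # bases on each side of the focal position
FOCAL_POS = FLANK  # focal index within a heptamer
HEPTAMER_LEN = 2 * FLANK + 1


@dataclass(frozen=True)
class SimConfig:
    """Simulation conditions: reads per heptamer, global sigma, seed."""

    n_reads_per_heptamer: int = DEFAULT_N_READS
    sigma_g: float = DEFAULT_SIGMA_G
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads_per_heptamer < 1:
            raise ValueError("n_reads_per_heptamer must be >= 1")
        if self.sigma_g <= 0:
            raise ValueError("sigma_g must be > 0")


def all_heptamers(focal_base: str, flank_letters: Sequence[str] = STANDARD_LETTERS) -> list[str]:
    """All NNN-X-NNN heptamers with canonical flanks: 4^6 = 4096 per base."""
    out = []
    for left in itertools.product(flank_letters, repeat=FLANK):
        for right in itertools.product(flank_letters, repeat=FLANK):
            out.append("".join(left) + focal_base + "".join(right))
    return out


def _focal_mus(model: KmerModel, heptamer: str) -> np.ndarray:
    kmers = [kmer for _, kmer in decompose(heptamer, FOCAL_POS, model.k)]
    missing = [k for k in kmers if k not in model]
    if missing:
        raise CoverageError(f"model does not cover kmer(s) {sorted(set(missing))}")
    return np.array([model.mu(k) for k in kmers])


def simulate_heptamer_levels(
    model: KmerModel, heptamer: str, n: int, sigma_g: float, rng: np.random.Generator
) -> np.ndarray:
    """(n, 4) focal-kmer levels for one heptamer, drawn from the model."""
    mus = _focal_mus(model, heptamer)
    return rng.normal(mus, sigma_g, size=(n, mus.size))


def simulate_code(
    model: KmerModel,
    substitution_base: str,
    config: SimConfig = SimConfig(),
    heptamers: Sequence[str] | None = None,
) -> LevelTable:
    """Simulate reads for every heptamer of one substitution base.

    For each of the 4096 NNN-X-NNN heptamers (X = ``substitution_base``),
    ``n_reads_per_heptamer`` reads are generated, each carrying one level
    per covering kmer sampled from Normal(mu_k, sigma_g). At the default
    n = 1000 this yields 4,096,000 reads per substitution base.

    Simulated reads carry q_score 12 and match_score 1 so that the
    standard read filter passes them through.
    """
    if heptamers is None:
        heptamers = all_heptamers(substitution_base)
    n = config.n_reads_per_heptamer
    children = np.random.SeedSequence(config.seed).spawn(len(heptamers))
    total = len(heptamers) * n
    levels = np.zeros((total, HEPTAMER_LEN))
    for h, (hept, child) in enumerate(zip(heptamers, children)):
        rng = np.random.default_rng(child)
        draws = simulate_heptamer_levels(model, hept, n, config.sigma_g, rng)
        # kmer at offset o models the level at FOCAL_POS - o, offsets +2..-1
        levels[h * n : (h + 1) * n, FOCAL_POS - 2 : FOCAL_POS + 2] = draws
    seq_col = np.repeat(np.asarray(heptamers, dtype=object), n)
    df = pd.DataFrame(
        {
            "read_id": np.char.add("sim", np.arange(total).astype(str)),
            "reference_name": seq_col,
            "reference_seq": seq_col,
            "q_score": np.full(total, 12.0),
            "match_score": np.full(total, 1.0),
        }
    )
    return LevelTable(df, levels)


def synthetic_model(
    k: int = 4,
    alphabet: Alphabet | None = None,
    seed: int = 0,
    mu_range: tuple[float, float] = (-2.5, 2.5),
    sigma: float = DEFAULT_SIGMA_G,
) -> KmerModel:
    """A reproducible random kmer model for testing.

    Every canonical k-mer and every single-XNA k-mer of the alphabet gets
    a level mean drawn uniformly from ``mu_range`` (the normalized-level
    scale) and the common ``sigma``.
    """
    lo, hi = mu_range
    if not np.isfinite([lo, hi]).all():
        raise ValueError("mu_range must be finite")
    alphabet = alphabet or twelve_letter_alphabet()
    kmers = ["".join(t) for t in itertools.product(STANDARD_LETTERS, repeat=k)]
    if alphabet.xna_letters:
        kmers += enumerate_xna_kmers(k, alphabet.xna_letters)
    rng = np.random.default_rng(seed)
    mus = rng.uniform(lo, hi, size=len(kmers))
    entries = {
        kmer: KmerStats(
            kmer=kmer,
            mu=float(mu),
            sigma=sigma,
            n_obs=DEFAULT_N_READS,
            min=float(mu - 3 * sigma),
            max=float(mu + 3 * sigma),
            median=float(mu),
            iqr=float(1.349 * sigma),
        )
        for kmer, mu in zip(kmers, mus)
    }
    return KmerModel(k=k, entries=entries)


def theoretical_recall(
    model: KmerModel,
    heptamer: str,
    base_i: str,
    base_j: str,
    sigma: float | None = None,
) -> float:
    """Closed-form per-read correct-call probability for truth ``base_i``
    against alternative ``base_j``.

    With levels drawn at the base_i model and an LLR decision at
    threshold 0, the probability of calling base_i is
    Phi(sqrt(sum_k Delta_k^2) / (2 sigma)) with Delta_k the per-kmer mean
    difference. Serves as the analytic oracle for simulated recall.
    """
    sigma = sigma if sigma is not None else model.global_sigma
    hep_i = heptamer[:FOCAL_POS] + base_i + heptamer[FOCAL_POS + 1 :]
    hep_j = heptamer[:FOCAL_POS] + base_j + heptamer[FOCAL_POS + 1 :]
    delta = _focal_mus(model, hep_i) - _focal_mus(model, hep_j)
    sep = float(np.sqrt((delta**2).sum()))
    return float(norm.cdf(sep / (2.0 * sigma)))


def theoretical_auc_single_kmer(delta: float, sigma: float) -> float:
    """Binormal ROC closed form for one kmer: AUC = Phi(|delta|/(sigma sqrt(2)))."""
    return float(norm.cdf(abs(delta) / (sigma * np.sqrt(2.0))))
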