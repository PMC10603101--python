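"""Alternative-hypothesis basecalling of XNA positions.

Calling is framed as model refinement, not de novo decoding: the
reference sequence and the position of the putative XNA are known, and
the question is whether the observed current levels better match the
XNA-containing kmers or kmers with an alternative base substituted.

For a focal position the heptamer context NNN-X-NNN decomposes into four
4-mers, each with an observed level I_k. Per kmer, the log-likelihood
ratio between candidate bases i and j is

    LLR_k = log10 P(I_k | mu_ki) - log10 P(I_k | mu_kj),

and the heptamer LLR is the sum over the four kmers. The outlier-robust
variant damps each term by its distance from the two-model midpoint and
rescales by the model separation:

    Sc_diff  = I_k - (mu_ki + mu_kj) / 2
    ORLLR_k  = exp(-Sc_diff^2 / (Sf sigma^2)) * LLR_k
               / (sigma^2 * |mu_ki - mu_kj|^Sp * Sf2)

with scaling parameters Sf = 4, Sf2 = 3, Sp = 0.3 (the Tombo defaults).
A positive statistic means base i is more likely than base j; the default
decision rule is agnostic maximum likelihood at threshold 0.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabet import STANDARD_LETTERS, Alphabet, twelve_letter_alphabet
from .kmer_model import CoverageError, KmerModel, decompose, level_log10_pdf
from .levels_io import LevelTable, ReadLevelRecord

logger = logging.getLogger(__name__)

__all__ = [
    "OrllrParams",
    "CallResult",
    "ConsensusCall",
    "sequence_log10_likelihood",
    "llr",
    "orllr",
    "call_position",
    "consensus_call",
    "statistic_scores",
    "call_table",
    "focal_xna_position",
    "candidates_for",
]

_LOG10E = math.log10(math.e)


@dataclass(frozen=True)
class OrllrParams:
    """ORLLR scaling parameters (Tombo defaults)."""

    sf: float = 4.0
    sf2: float = 3.0
    sp: float = 0.3

    def __post_init__(self) -> None:
        if self.sf <= 0 or self.sf2 <= 0 or self.sp < 0:
            raise ValueError("require sf > 0, sf2 > 0, sp >= 0")


DEFAULT_ORLLR_PARAMS = OrllrParams()


@dataclass(frozen=True)
class CallResult:
    """Outcome of one per-read hypothesis test at one position.

    ``statistic_values`` maps each alternative candidate to its
    candidate-vs-null statistic (positive favors the candidate);
    ``total_log10`` gives the multi-way total log10 likelihood of every
    base considered (null included) for likelihood ranking.
    """

    read_id: str
    reference_name: str
    position: int
    null_base: str
    called_base: str
    statistic: str
    statistic_values: dict[str, float]
    total_log10: dict[str, float]


@dataclass(frozen=True)
class ConsensusCall:
    """Majority vote over per-read calls at one reference position."""

    reference_name: str
    position: int
    null_base: str
    called_base: str | None
    n_reads: int
    votes: dict[str, int]


def _substitute(seq: str, pos: int, base: str) -> str:
    return seq[:pos] + base + seq[pos + 1 :]


def _focal_levels_and_kmers(
    record: ReadLevelRecord, pos: int, base: str, model: KmerModel
) -> tuple[np.ndarray, list[str]]:
    """Levels and kmers for the 4 kmers covering ``pos`` with ``base``
    substituted. The kmer at offset o models the level at pos - o."""
    seq = _substitute(record.reference_seq, pos, base)
    pairs = decompose(seq, pos, model.k)
    levels = np.array([record.levels[pos - off] for off, _ in pairs])
    return levels, [kmer for _, kmer in pairs]


def sequence_log10_likelihood(
    record: ReadLevelRecord,
    candidate_seq: str,
    model: KmerModel,
    window: tuple[int, int] | None = None,
) -> float:
    """Total log10 likelihood that the observed levels came from
    ``candidate_seq``.

    Individual per-kmer log probabilities are added over every kmer fully
    inside ``window`` (default: the whole sequence). A kmer starting at
    position s models the level at s + 1.
    """
    if len(candidate_seq) != len(record.levels):
        raise ValueError("candidate sequence length does not match levels")
    lo, hi = window if window is not None else (0, len(candidate_seq))
    total = 0.0
    missing = []
    for start in range(max(lo, 0), min(hi, len(candidate_seq)) - model.k + 1):
        kmer = candidate_seq[start : start + model.k]
        if kmer not in model:
            missing.append(kmer)
            continue
        mu = model.mu(kmer)
        sigma = model.sigma_for(kmer)
        total += level_log10_pdf(record.levels[start + 1], mu, sigma)
    if missing:
        raise CoverageError(f"model does not cover kmer(s) {sorted(set(missing))}")
    return total


def _llr_terms(
    record: ReadLevelRecord,
    pos: int,
    base_i: str,
    base_j: str,
    model: KmerModel,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-kmer (llr_term, level, mu_i, mu_j, sigma) arrays over the 4
    covering kmers."""
    levels, kmers_i = _focal_levels_and_kmers(record, pos, base_i, model)
    _, kmers_j = _focal_levels_and_kmers(record, pos, base_j, model)
    missing = [k for k in kmers_i + kmers_j if k not in model]
    if missing:
        raise CoverageError(f"model does not cover kmer(s) {sorted(set(missing))}")
    mu_i = np.array([model.mu(k) for k in kmers_i])
    mu_j = np.array([model.mu(k) for k in kmers_j])
    sigma = np.array([model.sigma_for(k) for k in kmers_i])
    terms = level_log10_pdf(levels, mu_i, sigma) - level_log10_pdf(levels, mu_j, sigma)
    return terms, levels, mu_i, mu_j, sigma


def llr(
    record: ReadLevelRecord, pos: int, base_i: str, base_j: str, model: KmerModel
) -> float:
    """Heptamer log-likelihood ratio of base_i over base_j at ``pos``:
    the sum over the four covering kmers of the per-kmer log10 density
    ratios. Positive favors base_i."""
    terms, *_ = _llr_terms(record, pos, base_i, base_j, model)
    return float(terms.sum())


def _orllr_terms(
    terms: np.ndarray,
    levels: np.ndarray,
    mu_i: np.ndarray,
    mu_j: np.ndarray,
    sigma: np.ndarray,
    params: OrllrParams,
) -> np.ndarray:
    sc_diff = levels - (mu_i + mu_j) / 2.0
    mu_diff = np.abs(mu_i - mu_j)
    out = np.zeros_like(terms)
    ok = mu_diff > 0  # degenerate mu_i == mu_j kmers contribute 0
    damp = np.exp(-(sc_diff[ok] ** 2) / (params.sf * sigma[ok] ** 2))
    out[ok] = damp * terms[ok] / (sigma[ok] ** 2 * mu_diff[ok] ** params.sp * params.sf2)
    return out


def orllr(
    record: ReadLevelRecord,
    pos: int,
    base_i: str,
    base_j: str,
    model: KmerModel,
    params: OrllrParams = DEFAULT_ORLLR_PARAMS,
) -> float:
    """Outlier-robust LLR of base_i over base_j at ``pos``, applied per
    kmer and summed over the four covering kmers."""
    terms, levels, mu_i, mu_j, sigma = _llr_terms(record, pos, base_i, base_j, model)
    return float(_orllr_terms(terms, levels, mu_i, mu_j, sigma, params).sum())


def candidates_for(
    null_base: str,
    mode: str = "standard",
    alphabet: Alphabet | None = None,
    substitution: Mapping[str, str] | None = None,
) -> list[str]:
    """Alternative candidate sets for a null XNA base.

    ``standard`` — the single most-similar canonical base (the
    substitution map); ``canonical`` — all four canonical bases;
    ``all`` — every other letter of the alphabet.
    """
    alphabet = alphabet or twelve_letter_alphabet()
    if mode == "standard":
        sub = dict(substitution) if substitution else dict(alphabet.substitution)
        if null_base in STANDARD_LETTERS:
            raise ValueError(f"{null_base!r} is already canonical")
        return [sub[null_base]]
    if mode == "canonical":
        return [b for b in STANDARD_LETTERS if b != null_base]
    if mode == "all":
        return [b for b in alphabet.letters if b != null_base]
    raise ValueError(f"unknown candidate mode {mode!r}")


def call_position(
    record: ReadLevelRecord,
    pos: int,
    null_base: str,
    candidates: Sequence[str],
    model: KmerModel,
    statistic: str = "llr",
    threshold: float = 0.0,
    orllr_params: OrllrParams = DEFAULT_ORLLR_PARAMS,
) -> CallResult:
    """Score each candidate against the null and call the position.

    The null (the XNA in the reference) is retained unless some candidate
    achieves candidate-vs-null statistic > ``threshold``; otherwise the
    maximal candidate wins, with deterministic alphabetical tie-break.
    """
    if record.reference_seq[pos] != null_base:
        raise ValueError(
            f"reference has {record.reference_seq[pos]!r} at {pos}, not {null_base!r}"
        )
    if not candidates:
        raise ValueError("candidates must be nonempty")
    if statistic not in ("llr", "orllr"):
        raise ValueError(f"unknown statistic {statistic!r}")
    values: dict[str, float] = {}
    for cand in candidates:
        if cand == null_base:
            logger.warning("candidate %r equals the null base; skipped", cand)
            continue
        if statistic == "llr":
            values[cand] = llr(record, pos, cand, null_base, model)
        else:
            values[cand] = orllr(record, pos, cand, null_base, model, orllr_params)
    exceeding = {c: v for c, v in values.items() if v > threshold}
    if not exceeding:
        called = null_base
    else:
        best = max(exceeding.values())
        called = min(c for c, v in exceeding.items() if v == best)  # alphabetical tie-break
    total = {}
    win = (pos - model.k + 1, pos + model.k)
    for base in [null_base, *values]:
        total[base] = sequence_log10_likelihood(
            record, _substitute(record.reference_seq, pos, base), model, window=win
        )
    return CallResult(
        read_id=record.read_id,
        reference_name=record.reference_name,
        position=pos,
        null_base=null_base,
        called_base=called,
        statistic=statistic,
        statistic_values=values,
        total_log10=total,
    )


def consensus_call(
    results: Iterable[CallResult], min_reads: int = 10
) -> ConsensusCall:
    """Majority vote over per-read calls at one reference position.

    Groups smaller than ``min_reads`` and vote ties yield a no-call
    (``called_base is None``).
    """
    results = list(results)
    if not results:
        raise ValueError("empty call group")
    keys = {(r.reference_name, r.position, r.null_base) for r in results}
    if len(keys) != 1:
        raise ValueError(f"call group mixes positions/references: {sorted(keys)}")
    (name, pos, null_base), = keys
    votes = Counter(r.called_base for r in results)
    called: str | None
    if len(results) < min_reads:
        called = None
    else:
        ranked = votes.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            logger.info("consensus tie at %s:%d", name, pos)
            called = None
        else:
            called = ranked[0][0]
    return ConsensusCall(
        reference_name=name,
        position=pos,
        null_base=null_base,
        called_base=called,
        n_reads=len(results),
        votes=dict(votes),
    )


def focal_xna_position(seq: str) -> int | None:
    """Position of the single XNA letter in ``seq``, or None if absent.

    Raises if more than one XNA is present (multi-XNA sequences are
    called per position by the caller, one heptamer window each).
    """
    positions = [i for i, l in enumerate(seq) if l not in STANDARD_LETTERS]
    if not positions:
        return None
    if len(positions) > 1:
        raise ValueError(f"sequence has {len(positions)} XNA positions; call them individually")
    return positions[0]


def statistic_scores(
    table: LevelTable,
    pos: int,
    base_i: str,
    base_j: str,
    model: KmerModel,
    statistic: str = "llr",
    orllr_params: OrllrParams = DEFAULT_ORLLR_PARAMS,
) -> np.ndarray:
    """Vectorized per-read base_i-vs-base_j statistic at ``pos`` for a
    table of same-length reads (e.g. simulated heptamers).

    Equivalent to calling :func:`llr`/:func:`orllr` per read; grouped by
    reference sequence so per-group work is a handful of array ops.
    """
    if statistic not in ("llr", "orllr"):
        raise ValueError(f"unknown statistic {statistic!r}")
    mat = table.levels_matrix()
    seqs = table.frame["reference_seq"].to_numpy()
    out = np.empty(len(table))
    k = model.k
    col = np.arange(pos - k + 2, pos + 2)  # level columns for the 4 kmers
    for seq in pd.unique(seqs) if len(seqs) else []:
        idx = np.flatnonzero(seqs == seq)
        kmers_i = [kmer for _, kmer in decompose(_substitute(seq, pos, base_i), pos, k)]
        kmers_j = [kmer for _, kmer in decompose(_substitute(seq, pos, base_j), pos, k)]
        mu_i = np.array([model.mu(kk) for kk in kmers_i])
        mu_j = np.array([model.mu(kk) for kk in kmers_j])
        sigma = np.array([model.sigma_for(kk) for kk in kmers_i])
        levels = mat[np.ix_(idx, col)]  # level at pos - offset == kmer_start + 1
        terms = level_log10_pdf(levels, mu_i, sigma) - level_log10_pdf(levels, mu_j, sigma)
        if statistic == "orllr":
            sc = levels - (mu_i + mu_j) / 2.0
            mu_diff = np.abs(mu_i - mu_j)
            scaled = np.zeros_like(terms)
            ok = mu_diff > 0
            damp = np.exp(-(sc[:, ok] ** 2) / (orllr_params.sf * sigma[ok] ** 2))
            scaled[:, ok] = damp * terms[:, ok] / (
                sigma[ok] ** 2 * mu_diff[ok] ** orllr_params.sp * orllr_params.sf2
            )
            terms = scaled
        out[idx] = terms.sum(axis=1)
    return out


def call_table(
    table: LevelTable,
    model: KmerModel,
    statistic: str = "orllr",
    candidate_mode: str = "standard",
    threshold: float = 0.0,
    alphabet: Alphabet | None = None,
    orllr_params: OrllrParams = DEFAULT_ORLLR_PARAMS,
) -> list[CallResult]:
    """Call every XNA position of every read in ``table``.

    XNA positions are taken from each read's reference sequence; each is
    called independently from its own heptamer window.
    """
    alphabet = alphabet or twelve_letter_alphabet()
    results = []
    for record in table:
        positions = [i for i, l in enumerate(record.reference_seq) if l not in STANDARD_LETTERS]
        for pos in positions:
            null_base = record.reference_seq[pos]
            cands = candidates_for(null_base, candidate_mode, alphabet)
            results.append(
                call_position(
                    record, pos, null_base, cands, model,
                    statistic=statistic, threshold=threshold, orllr_params=orllr_params,
                )
            )
    return results
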