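"""Supernumerary DNA alphabets.

Standard DNA uses four letters paired A:T and G:C. Synthetic xenonucleotides
(XNAs) add up to four orthogonal pairs — B:S, P:Z, X:K and J:V — giving
alphabets of 4, 6, 8, 10 or 12 letters. Some letters denote more than one
chemical variant (S may be Sn or Sc; X is Xt; K is Kn); the sequence letter
stays single-character and the variant is carried as metadata that selects
which kmer level model applies at analysis time.

This module defines the alphabet objects, base-pair complementation, the
canonical-substitution map used to push XNA references through standard
aligners, and the combinatorial enumerations (XNA kmer sets, codon-space
sizes, information content) that size every downstream dataset.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "AlphabetError",
    "XenoBase",
    "Alphabet",
    "XnaSequence",
    "STANDARD_LETTERS",
    "XNA_LETTERS",
    "XNA_PAIRS",
    "CANONICAL_SUBSTITUTION",
    "MEASURED_VARIANTS",
    "twelve_letter_alphabet",
    "make_alphabet",
    "reverse_complement",
    "substitute_canonical",
    "enumerate_xna_kmers",
    "bits_per_base",
    "codon_space_size",
]


class AlphabetError(ValueError):
    """A sequence or letter is not valid over the active alphabet."""


STANDARD_LETTERS = ("A", "T", "G", "C")

#: Unordered complementary pairs beyond Watson-Crick.
XNA_PAIRS = (("B", "S"), ("P", "Z"), ("X", "K"), ("J", "V"))

XNA_LETTERS = tuple(l for pair in XNA_PAIRS for l in pair)

#: Canonical base that minimizes level variance when an XNA must be
#: represented over {A,T,G,C} for alignment (empirically determined;
#: override via ``Alphabet.with_substitution``).
CANONICAL_SUBSTITUTION = {
    "B": "A",
    "S": "A",  # both Sn and Sc variants
    "P": "G",
    "Z": "C",
    "X": "A",
    "K": "G",
    "J": "C",
    "V": "G",
}

#: The nine chemically distinct measured XNA bases, as variant tokens.
#: S has two variants (Sn, Sc); X and K each have a single named variant.
MEASURED_VARIANTS = ("B", "Sn", "Sc", "P", "Z", "Xt", "Kn", "J", "V")

_PAIR_MAP = {"A": "T", "T": "A", "G": "C", "C": "G"}
for _a, _b in XNA_PAIRS:
    _PAIR_MAP[_a] = _b
    _PAIR_MAP[_b] = _a

#: Deterministic letter ordering: canonical A<C<G<T, then XNA letters.
_LETTER_ORDER = {l: i for i, l in enumerate("ACGT" + "".join(sorted(XNA_LETTERS)))}


def _letter_key(token: str) -> tuple[int, str]:
    # variant tokens ("Sn") sort by their leading letter, then the tag
    return (_LETTER_ORDER.get(token[0], len(_LETTER_ORDER)), token)


@dataclass(frozen=True)
class XenoBase:
    """One letter of a supernumerary alphabet.

    ``variant`` distinguishes chemical variants sharing a sequence letter
    (e.g. ``Sn`` vs ``Sc`` for S); it never appears in sequence strings.
    """

    letter: str
    variant: str | None = None

    def __post_init__(self) -> None:
        if len(self.letter) != 1 or self.letter not in _PAIR_MAP:
            raise AlphabetError(f"unknown base letter {self.letter!r}")
        if self.variant is not None and not self.variant.startswith(self.letter):
            raise AlphabetError(
                f"variant {self.variant!r} does not tag letter {self.letter!r}"
            )

    @property
    def is_standard(self) -> bool:
        return self.letter in STANDARD_LETTERS

    @property
    def complement_letter(self) -> str:
        return _PAIR_MAP[self.letter]

    @property
    def canonical_substitute(self) -> str:
        if self.is_standard:
            return self.letter
        return CANONICAL_SUBSTITUTION[self.letter]


@dataclass(frozen=True)
class Alphabet:
    """An even-sized supernumerary alphabet with a perfect pairing.

    ``substitution`` maps each XNA letter to the canonical base used when
    the sequence must be expressed over {A,T,G,C}.
    """

    bases: tuple[XenoBase, ...]
    substitution: dict[str, str] = field(default_factory=lambda: dict(CANONICAL_SUBSTITUTION))

    def __post_init__(self) -> None:
        letters = self.letters
        if len(set(letters)) != len(letters):
            raise AlphabetError("duplicate letters in alphabet")
        if len(letters) % 2 or not 4 <= len(letters) <= 12:
            raise AlphabetError(f"alphabet size {len(letters)} not in {{4,6,8,10,12}}")
        for l in letters:
            if _PAIR_MAP[l] not in letters:
                raise AlphabetError(f"letter {l} lacks its pairing partner in the alphabet")

    @property
    def letters(self) -> tuple[str, ...]:
        return tuple(b.letter for b in self.bases)

    @property
    def xna_letters(self) -> tuple[str, ...]:
        return tuple(b.letter for b in self.bases if not b.is_standard)

    @property
    def pairs(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset((l, _PAIR_MAP[l])) for l in self.letters)

    def __len__(self) -> int:
        return len(self.bases)

    def __contains__(self, letter: str) -> bool:
        return letter in self.letters

    def complement(self, letter: str) -> str:
        self.validate(letter)
        return _PAIR_MAP[letter]

    def validate(self, seq: str) -> None:
        bad = set(seq) - set(self.letters)
        if bad:
            raise AlphabetError(
                f"letters {sorted(bad)} not in alphabet {''.join(self.letters)}"
            )

    def with_substitution(self, override: dict[str, str]) -> "Alphabet":
        """Return a copy with some canonical substitutions overridden."""
        sub = dict(self.substitution)
        sub.update(override)
        return Alphabet(self.bases, sub)


def make_alphabet(
    xna_pairs: Sequence[Sequence[str]] = XNA_PAIRS,
    variants: dict[str, str] | None = None,
) -> Alphabet:
    """Build an alphabet from the standard four plus the given XNA pairs.

    Parameters
    ----------
    xna_pairs
        Complementary XNA letter pairs to include (subset of B:S, P:Z,
        X:K, J:V).
    variants
        Optional ``letter -> variant tag`` choices (e.g. ``{"S": "Sc"}``)
        selecting which chemical variant's kmer model applies.
    """
    variants = variants or {}
    bases = [XenoBase(l) for l in STANDARD_LETTERS]
    for a, b in xna_pairs:
        for l in (a, b):
            if frozenset((a, b)) not in frozenset(map(frozenset, XNA_PAIRS)):
                raise AlphabetError(f"unknown XNA pair {a}:{b}")
            bases.append(XenoBase(l, variants.get(l)))
    return Alphabet(tuple(bases))


def twelve_letter_alphabet(variants: dict[str, str] | None = None) -> Alphabet:
    """The full 12-letter alphabet (A,T,G,C + B:S, P:Z, X:K, J:V)."""
    return make_alphabet(XNA_PAIRS, variants)


@dataclass(frozen=True)
class XnaSequence:
    """A sequence over a supernumerary alphabet.

    ``variant_map`` optionally tags positions whose letter admits several
    chemical variants (position -> variant token).
    """

    letters: str
    alphabet: Alphabet = field(default_factory=twelve_letter_alphabet)
    variant_map: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.alphabet.validate(self.letters)
        for pos, tag in self.variant_map.items():
            if not 0 <= pos < len(self.letters):
                raise AlphabetError(f"variant position {pos} out of range")
            if not tag.startswith(self.letters[pos]):
                raise AlphabetError(
                    f"variant {tag!r} at {pos} does not match letter {self.letters[pos]!r}"
                )

    def __len__(self) -> int:
        return len(self.letters)

    def __str__(self) -> str:
        return self.letters


def _as_letters(seq: "str | XnaSequence") -> str:
    return seq.letters if isinstance(seq, XnaSequence) else seq


def reverse_complement(seq: "str | XnaSequence", alphabet: Alphabet | None = None) -> str:
    """Base-paired sequence read 5'->3' on the opposite strand.

    XNA letters complement within their orthogonal pair (B<->S, P<->Z,
    X<->K, J<->V), exactly as A<->T and G<->C.
    """
    letters = _as_letters(seq)
    alphabet = alphabet or (seq.alphabet if isinstance(seq, XnaSequence) else twelve_letter_alphabet())
    alphabet.validate(letters)
    return "".join(_PAIR_MAP[l] for l in reversed(letters))


def substitute_canonical(
    seq: "str | XnaSequence", substitution: dict[str, str] | None = None
) -> tuple[str, list[int]]:
    """Replace each XNA letter with its canonical stand-in.

    Returns the {A,T,G,C} sequence together with the 0-based positions of
    the replaced letters, ascending. The default map is the empirically
    determined minimum-variance substitution (B->A, S->A, P->G, Z->C,
    X->A, K->G, J->C, V->G).
    """
    letters = _as_letters(seq)
    sub = substitution if substitution is not None else CANONICAL_SUBSTITUTION
    out = []
    positions = []
    for i, l in enumerate(letters):
        if l in STANDARD_LETTERS:
            out.append(l)
        elif l in sub:
            out.append(sub[l])
            positions.append(i)
        else:
            raise AlphabetError(f"letter {l!r} has no canonical substitute")
    return "".join(out), positions


def enumerate_xna_kmers(k: int, xna_letters: Iterable[str]) -> list[str]:
    """All kmers containing exactly one XNA letter.

    Each element of ``xna_letters`` may be a plain letter (``"P"``) or a
    variant token (``"Sn"``); variant tokens are treated as distinct
    symbols, so the nine measured bases yield 9 * k * 4^(k-1) kmers at any
    k. Output is deduplicated and sorted with canonical letters before
    XNA letters.

    For k=4 this gives 256 kmers per xenonucleotide, 512 per pair, and
    2304 across the nine measured bases.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    tokens = list(dict.fromkeys(xna_letters))
    if not tokens:
        raise ValueError("xna_letters must be nonempty")
    for t in tokens:
        if t[0] in STANDARD_LETTERS:
            raise ValueError(f"{t!r} is a standard base, not an XNA letter")
    seen = set()
    for token in tokens:
        for pos in range(k):
            for fill in itertools.product(STANDARD_LETTERS, repeat=k - 1):
                kmer = fill[:pos] + (token,) + fill[pos:]
                seen.add(kmer)
    return ["".join(t) for t in sorted(seen, key=lambda t: tuple(map(_letter_key, t)))]


def bits_per_base(alphabet_size: int) -> float:
    """Information content of one base: log2 of the alphabet size.

    4 letters carry 2 bits per base; the full 12-letter alphabet carries
    log2(12) = 3.58 bits per base.
    """
    if alphabet_size < 1:
        raise ValueError("alphabet size must be >= 1")
    return math.log2(alphabet_size)


def codon_space_size(n_xna_pairs: int, max_xna_per_codon: int = 1) -> int:
    """Number of codon-anticodon pairs with expanded alphabets.

    Counts, by explicit enumeration, all length-3 codons over the four
    canonical letters plus ``n_xna_pairs`` orthogonal XNA pairs, allowing
    at most ``max_xna_per_codon`` XNA letters per codon. Each additional
    pair contributes 96 codons beyond the canonical 64, reaching 448 with
    all four pairs.
    """
    if not 0 <= n_xna_pairs <= len(XNA_PAIRS):
        raise ValueError(f"n_xna_pairs must be in [0, {len(XNA_PAIRS)}]")
    letters = list(STANDARD_LETTERS)
    xna = [l for pair in XNA_PAIRS[:n_xna_pairs] for l in pair]
    count = 0
    for codon in itertools.product(letters + xna, repeat=3):
        if sum(l in xna for l in codon) <= max_xna_per_codon:
            count += 1
    return count
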