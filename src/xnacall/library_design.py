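"""Barcoded hairpin libraries and ground-truth reference sets.

Kmer models are trained on ligation libraries built from two pools of
blunt-end hairpin oligos. Each hairpin carries an 8-nt pool barcode
(decoding which xenonucleotide was tailed), a 24-nt triplet barcode
mapped 1:1 to the 3-nt sequence at its blunt 3' end, and that terminal
triplet itself. Tailing one pool with an XNA x and the other with its
partner x', then ligating complementary single-base overhangs, joins the
pools into duplexes whose top strand reads

    armA + x + reverse_complement(armB),

placing the XNA in a NNN-x-NNN heptamer: 64 triplets per pool give
64 x 64 = 4096 unique contexts covering all 512 XNA-containing 4-mers of
the pair (256 per strand). A smaller validation design replaces the
triplet enumeration with uniform-random 20-nt variable regions, 10 per
pool, yielding 100 products.

Reference sets for signal-to-sequence mapping enumerate not only the
desired hetero-ligations but every plausible side product: within-pool
mismatch homo-ligations, blunt-end ligations lacking the inserted pair,
and N-1 (pyrophosphorolysis) products missing one terminal base.

Scaffold sequences default to synthetic placeholders; counts and kmer
coverage, not the exact bases, carry the design guarantees.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alphabet import (
    STANDARD_LETTERS,
    XNA_PAIRS,
    AlphabetError,
    reverse_complement,
    substitute_canonical,
)

__all__ = [
    "DesignError",
    "HairpinTemplate",
    "ValidationHairpin",
    "ReferenceSet",
    "NnnLibrary",
    "ValidationLibrary",
    "design_nnn_library",
    "design_validation_library",
    "enumerate_ligation_products",
    "xna_kmer_coverage",
    "passes_structure_filter",
]

#: Synthetic placeholder scaffolds and pool barcodes.
DEFAULT_SCAFFOLD = "TCAGGTACCTGATTGCAGTC"
DEFAULT_POOL_BARCODES = ("AACGTACG", "TTGCATGC")

PROVENANCE_TAGS = ("desired", "homo_mismatch", "blunt_gap", "pyrophosphorolysis")

_PAIR_OF = {a: b for a, b in XNA_PAIRS} | {b: a for a, b in XNA_PAIRS}


class DesignError(ValueError):
    """A library design constraint is violated."""


@dataclass(frozen=True)
class HairpinTemplate:
    """One barcoded hairpin oligo of an NNN pool.

    ``arm`` is the top-strand sequence read 5'->3' up to the blunt 3'
    terminal triplet, the junction-adjacent end that receives the XNA
    tail.
    """

    name: str
    pool_barcode: str
    triplet_barcode: str
    terminal_triplet: str
    scaffold: str

    def __post_init__(self) -> None:
        if len(self.pool_barcode) != 8:
            raise DesignError(f"{self.name}: pool barcode must be 8 nt")
        if len(self.triplet_barcode) != 24:
            raise DesignError(f"{self.name}: triplet barcode must be 24 nt")
        if len(self.terminal_triplet) != 3:
            raise DesignError(f"{self.name}: terminal triplet must be 3 nt")
        for part in (self.pool_barcode, self.triplet_barcode, self.terminal_triplet, self.scaffold):
            if set(part) - set(STANDARD_LETTERS):
                raise DesignError(f"{self.name}: hairpin parts must be canonical DNA")

    @property
    def arm(self) -> str:
        return self.scaffold + self.pool_barcode + self.triplet_barcode + self.terminal_triplet


@dataclass(frozen=True)
class ValidationHairpin:
    """One validation-pool hairpin: a uniform-random variable region
    replaces the triplet-barcode scheme."""

    name: str
    pool_barcode: str
    variable_region: str
    scaffold: str

    @property
    def arm(self) -> str:
        return self.scaffold + self.pool_barcode + self.variable_region


@dataclass
class ReferenceSet:
    """Named reference sequences with per-record provenance tags."""

    records: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def add(self, name: str, seq: str, tag: str) -> None:
        if tag not in PROVENANCE_TAGS:
            raise DesignError(f"unknown provenance tag {tag!r}")
        if name in self.records:
            raise DesignError(f"duplicate record name {name!r}")
        self.records[name] = seq
        self.provenance[name] = tag

    def __len__(self) -> int:
        return len(self.records)

    def by_tag(self, tag: str) -> dict[str, str]:
        return {n: s for n, s in self.records.items() if self.provenance[n] == tag}

    def deduplicate(self) -> "ReferenceSet":
        """Drop records whose sequence already appeared (first name wins)."""
        out = ReferenceSet()
        seen: set[str] = set()
        for name, seq in self.records.items():
            if seq in seen:
                continue
            seen.add(seq)
            out.add(name, seq, self.provenance[name])
        return out

    def canonical_substituted(self) -> "ReferenceSet":
        """Copy with every XNA replaced by its canonical stand-in, for
        use as an alignment reference."""
        out = ReferenceSet()
        for name, seq in self.records.items():
            canon, _ = substitute_canonical(seq)
            out.add(name, canon, self.provenance[name])
        return out

    def write(self, fasta_path: str | Path, manifest_path: str | Path | None = None) -> None:
        from .fasta import write_xna_fasta

        write_xna_fasta(self.records.items(), fasta_path)
        if manifest_path is not None:
            pd.DataFrame(
                {
                    "name": list(self.records),
                    "provenance": [self.provenance[n] for n in self.records],
                    "length": [len(s) for s in self.records.values()],
                }
            ).to_csv(manifest_path, index=False)


@dataclass(frozen=True)
class NnnLibrary:
    """The two 64-hairpin pools of one XNA letter plus the 4096 joined
    target sequences (name -> extended-alphabet sequence)."""

    xna_letter: str
    pool1: tuple[HairpinTemplate, ...]
    pool2: tuple[HairpinTemplate, ...]
    joined: dict[str, str]


@dataclass(frozen=True)
class ValidationLibrary:
    xna_letter: str
    pool1: tuple[ValidationHairpin, ...]
    pool2: tuple[ValidationHairpin, ...]
    joined: dict[str, str]


def passes_structure_filter(seq: str, max_homopolymer: int = 4, min_selfcomp: int = 10) -> bool:
    """Crude secondary-structure screen for variable regions.

    Rejects homopolymer runs longer than ``max_homopolymer`` and any
    ``min_selfcomp``-nt substring whose reverse complement also occurs in
    the sequence (a hairpin-competent self-complementarity).
    """
    for letter in set(seq):
        if letter * (max_homopolymer + 1) in seq:
            return False
    for i in range(len(seq) - min_selfcomp + 1):
        sub = seq[i : i + min_selfcomp]
        if reverse_complement(sub) in seq:
            return False
    return True


def _random_barcodes(n: int, length: int, rng: np.random.Generator) -> list[str]:
    letters = np.array(list(STANDARD_LETTERS))
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        bc = "".join(rng.choice(letters, size=length))
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def _check_xna_letter(xna_letter: str) -> str:
    if xna_letter not in _PAIR_OF:
        raise AlphabetError(f"{xna_letter!r} is not an XNA letter")
    return _PAIR_OF[xna_letter]


def design_nnn_library(
    xna_letter: str,
    pool_barcodes: Sequence[str] = DEFAULT_POOL_BARCODES,
    scaffold: str = DEFAULT_SCAFFOLD,
    seed: int = 0,
) -> NnnLibrary:
    """Design the two 64-member NNN pools for one XNA letter and
    enumerate the 4096 joined targets.

    Each pool enumerates all 4^3 = 64 terminal triplets, each linked
    injectively to a 24-nt triplet barcode. Joined target i,j places the
    XNA between pool-1 triplet i and the reverse complement of pool-2
    triplet j, so all 512 XNA 4-mers of the pair are covered across the
    two strands.
    """
    _check_xna_letter(xna_letter)
    if len(set(pool_barcodes)) != 2:
        raise DesignError("need two distinct pool barcodes")
    if set(scaffold) - set(STANDARD_LETTERS):
        raise DesignError("scaffold must contain no XNA letters")
    rng = np.random.default_rng(seed)
    triplets = ["".join(t) for t in itertools.product(STANDARD_LETTERS, repeat=3)]
    pools = []
    for p, pool_bc in enumerate(pool_barcodes, start=1):
        barcodes = _random_barcodes(len(triplets), 24, rng)
        pools.append(
            tuple(
                HairpinTemplate(
                    name=f"{xna_letter}{p}-{trip}",
                    pool_barcode=pool_bc,
                    triplet_barcode=bc,
                    terminal_triplet=trip,
                    scaffold=scaffold,
                )
                for trip, bc in zip(triplets, barcodes)
            )
        )
    joined = {
        f"{a.name}+{b.name}": a.arm + xna_letter + reverse_complement(b.arm)
        for a in pools[0]
        for b in pools[1]
    }
    return NnnLibrary(xna_letter=xna_letter, pool1=pools[0], pool2=pools[1], joined=joined)


def design_validation_library(
    n_per_pool: int = 10,
    variable_len: int = 20,
    seed: int = 0,
    xna_letter: str = "P",
    pool_barcodes: Sequence[str] = DEFAULT_POOL_BARCODES,
    scaffold: str = DEFAULT_SCAFFOLD,
    max_attempts: int = 10_000,
) -> ValidationLibrary:
    """Design validation pools with uniform-random variable regions.

    Variable regions are drawn with a uniform prior per base and screened
    by :func:`passes_structure_filter`; joining the two pools yields
    n_per_pool^2 products, each containing a single XNA pair position.
    Identical seeds give identical libraries.
    """
    if n_per_pool < 1:
        raise DesignError("n_per_pool must be >= 1")
    _check_xna_letter(xna_letter)
    rng = np.random.default_rng(seed)
    letters = np.array(list(STANDARD_LETTERS))
    pools = []
    for p, pool_bc in enumerate(pool_barcodes[:2], start=1):
        members = []
        attempts = 0
        while len(members) < n_per_pool:
            attempts += 1
            if attempts > max_attempts:
                raise DesignError("structure filter rejected too many candidates")
            var = "".join(rng.choice(letters, size=variable_len))
            if not passes_structure_filter(var):
                continue
            members.append(
                ValidationHairpin(
                    name=f"Val{p}-{len(members):02d}",
                    pool_barcode=pool_bc,
                    variable_region=var,
                    scaffold=scaffold,
                )
            )
        pools.append(tuple(members))
    joined = {
        f"{a.name}+{b.name}": a.arm + xna_letter + reverse_complement(b.arm)
        for a in pools[0]
        for b in pools[1]
    }
    return ValidationLibrary(xna_letter=xna_letter, pool1=pools[0], pool2=pools[1], joined=joined)


def enumerate_ligation_products(
    poolA: Sequence["HairpinTemplate | ValidationHairpin"],
    poolB: Sequence["HairpinTemplate | ValidationHairpin"],
    xna_pair: tuple[str, str] = ("P", "Z"),
) -> ReferenceSet:
    """Enumerate every ligation product class as an alignment reference
    set.

    Emits (i) desired hetero-ligations A_i(+x)-B_j(+x'); (ii) within-pool
    mismatch homo-ligations A_i(+x)-A_j(+x) and B_i(+x')-B_j(+x');
    (iii) blunt-gap products (no inserted pair) for A-B, A-A and B-B;
    (iv) N-1 pyrophosphorolysis products lacking one terminal base, on
    either joining partner. Top-strand representation throughout; use
    :meth:`ReferenceSet.canonical_substituted` for aligner input and
    :meth:`ReferenceSet.deduplicate` before writing.
    """
    x, xp = xna_pair
    if _PAIR_OF.get(x) != xp:
        raise DesignError(f"{x}:{xp} is not a complementary XNA pair")
    refs = ReferenceSet()

    def join(a, b, insert: str) -> str:
        return a.arm + insert + reverse_complement(b.arm)

    for a, b in itertools.product(poolA, poolB):
        refs.add(f"{a.name}+{b.name}", join(a, b, x), "desired")
    for pool, insert in ((poolA, x), (poolB, xp)):
        for a, b in itertools.product(pool, pool):
            refs.add(f"{a.name}+{b.name}|homo", join(a, b, insert), "homo_mismatch")
    for left, right in ((poolA, poolB), (poolA, poolA), (poolB, poolB)):
        for a, b in itertools.product(left, right):
            refs.add(f"{a.name}+{b.name}|blunt", join(a, b, ""), "blunt_gap")
    for a, b in itertools.product(poolA, poolB):
        short_a = a.arm[:-1] + x + reverse_complement(b.arm)
        short_b = a.arm + x + reverse_complement(b.arm[:-1])
        refs.add(f"{a.name}-1+{b.name}", short_a, "pyrophosphorolysis")
        refs.add(f"{a.name}+{b.name}-1", short_b, "pyrophosphorolysis")
    return refs


def xna_kmer_coverage(sequences: Iterable[str], k: int = 4) -> set[str]:
    """Distinct XNA-containing k-mers observable from a sequence set,
    counting both strands (each duplex is read in both orientations)."""
    out: set[str] = set()
    for seq in sequences:
        for oriented in (seq, reverse_complement(seq)):
            for i in range(len(oriented) - k + 1):
                kmer = oriented[i : i + k]
                if any(l not in STANDARD_LETTERS for l in kmer):
                    out.add(kmer)
    return out
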