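"""Extended FASTA: standard records whose sequences may contain XNA letters.

The 12-letter alphabet cannot be expressed in IUPAC codes, so records are
plain FASTA with B,S,P,Z,X,K,J,V allowed in sequence lines. A sidecar
token in the description (``variant=Sc``) records which chemical variant a
shared letter denotes; the sequence itself stays single-character.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import Alphabet, AlphabetError, XnaSequence, twelve_letter_alphabet

__all__ = ["read_xna_fasta", "write_xna_fasta"]

_VARIANT_TOKEN = re.compile(r"\bvariant=(\w+)\b")


def read_xna_fasta(
    path: str | Path,
    alphabet: Alphabet | None = None,
    strict: bool = True,
) -> dict[str, XnaSequence]:
    """Read extended FASTA into named :class:`XnaSequence` objects.

    In strict mode any character outside the alphabet raises
    :class:`AlphabetError`; otherwise offending records are skipped.
    Variant tokens (``variant=Sc``) in the description apply to every
    position holding that variant's letter.
    """
    alphabet = alphabet or twelve_letter_alphabet()
    out: dict[str, XnaSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        try:
            alphabet.validate(seq)
        except AlphabetError:
            if strict:
                raise AlphabetError(f"record {rec.id!r}: invalid letters for alphabet")
            continue
        variant_map: dict[int, str] = {}
        for tag in _VARIANT_TOKEN.findall(rec.description or ""):
            letter = tag[0]
            variant_map.update({i: tag for i, l in enumerate(seq) if l == letter})
        out[rec.id] = XnaSequence(seq, alphabet, variant_map)
    return out


def write_xna_fasta(records: "dict[str, XnaSequence] | Iterable[tuple[str, str]]", path: str | Path) -> None:
    """Write sequences as extended FASTA, emitting variant sidecar tokens."""
    if isinstance(records, dict):
        items = records.items()
    else:
        items = records
    seq_records = []
    for name, seq in items:
        desc = ""
        if isinstance(seq, XnaSequence) and seq.variant_map:
            tags = sorted(set(seq.variant_map.values()))
            desc = " ".join(f"variant={t}" for t in tags)
        seq_records.append(SeqRecord(Seq(str(seq)), id=name, description=desc))
    SeqIO.write(seq_records, str(path), "fasta")
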