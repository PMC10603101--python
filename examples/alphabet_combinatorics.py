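"""Supernumerary alphabet: pairing, substitution, and what 12 letters buy.

Builds the full 12-letter alphabet, complements and canonically
substitutes an XNA-containing sequence, and enumerates the kmer and
codon spaces the expanded alphabet opens up.
"""

from xnacall import (
    bits_per_base,
    codon_space_size,
    enumerate_xna_kmers,
    reverse_complement,
    substitute_canonical,
)

seq = "AGTBCCT"
print(f"sequence          : {seq}")
print(f"reverse complement: {reverse_complement(seq)}  (B pairs with S)")
canon, positions = substitute_canonical(seq)
print(f"canonical stand-in: {canon}, XNA at positions {positions}")
print()

print(f"4-mers with one P            : {len(enumerate_xna_kmers(4, ['P']))}")
print(f"4-mers for the P:Z pair      : {len(enumerate_xna_kmers(4, ['P', 'Z']))}")
nine = ["B", "Sn", "Sc", "P", "Z", "Xt", "Kn", "J", "V"]
print(f"4-mers over 9 measured bases : {len(enumerate_xna_kmers(4, nine))}")
print()

# Information density and codon space grow with each orthogonal pair:
print(f"bits per base, 4 letters : {bits_per_base(4):.2f}")
print(f"bits per base, 12 letters: {bits_per_base(12):.2f}")
for n in range(5):
    print(f"codon-anticodon pairs with {n} XNA pair(s): {codon_space_size(n)}")
# Each pair adds 96 codons (3 positions x 2 letters x 16 canonical fills)
# on top of the canonical 64, reaching 448 with all four pairs.
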