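"""Design the barcoded libraries behind model building and validation.

Generates the two 64-hairpin NNN pools for P, checks that the joined
4096 contexts cover all 512 P/Z 4-mers, then builds a 10x10 validation
library and its full alignment reference set including ligation side
products.
"""

from xnacall import (
    design_nnn_library,
    design_validation_library,
    enumerate_ligation_products,
    xna_kmer_coverage,
)

lib = design_nnn_library("P", seed=0)
print(f"NNN library for P: {len(lib.pool1)} + {len(lib.pool2)} hairpins, "
      f"{len(lib.joined)} joined contexts")
coverage = xna_kmer_coverage(lib.joined.values())
print(f"distinct XNA 4-mers covered (both strands): {len(coverage)}")
# 64 x 64 = 4096 heptamer contexts; 256 kmers per strand = 512 for the pair.

val = design_validation_library(n_per_pool=10, variable_len=20, seed=1, xna_letter="P")
print(f"\nvalidation library: {len(val.joined)} products "
      f"({len(val.pool1)} x {len(val.pool2)} hairpins)")

refs = enumerate_ligation_products(val.pool1, val.pool2, ("P", "Z")).deduplicate()
for tag in ("desired", "homo_mismatch", "blunt_gap", "pyrophosphorolysis"):
    print(f"  {tag:18s}: {len(refs.by_tag(tag))} reference records")
# The side-product classes let signal-to-sequence mapping assign reads to
# blunt or N-1 ligations instead of forcing them onto the desired product.
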