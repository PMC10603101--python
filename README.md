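# xnacall

Expanded-alphabet (XNA) nanopore basecalling from segmented current
levels.

Synthetic xenonucleotides extend DNA beyond A:T and G:C with up to four
orthogonal base pairs — B:S, P:Z, X:K and J:V — lifting the information
content from log₂(4) = 2 to log₂(12) ≈ 3.58 bits per base. Standard
nanopore basecallers only emit the four canonical letters, so XNA
positions have to be recovered from the raw current signal. `xnacall`
implements the signal-level route: it consumes the tabular product of
signal-to-sequence mapping (one median-normalized current level per
reference base, per read), models each 4-nt kmer's level as a normal
distribution, and decides each putative XNA position by alternative-
hypothesis testing against candidate substitutions.

The package is aimed at people developing or benchmarking expanded-
alphabet sequencing: it covers the full in-silico path — alphabet
combinatorics, barcoded library and reference-set design, kmer-model
fitting (mean / median / KDE estimators with the Silverman bandwidth
rule), LLR/ORLLR basecalling, recall/specificity/ROC benchmarking, and
a Monte-Carlo read simulator that doubles as the test oracle's
counterpart.

## The model and test statistics

Each reference base sits at the center of a heptamer NNN·**X**·NNN that
decomposes into four 4-mers covering it (offsets +2, +1, 0, −1). A kmer
model assigns every kmer *k* a level mean µ_k and standard deviation
σ_k; observed levels are modeled as

P(I) = 1/(σ√2π) · exp(−(I−µ_k)²/(2σ²)),

with σ by default the *global* sigma — the average of the per-kmer
standard deviations (≈ 0.4 on the normalized scale). For candidate
bases *i*, *j* at a position, the per-kmer log-likelihood ratio

LLR_k = log₁₀ P(I_k|µ_ki) − log₁₀ P(I_k|µ_kj)

is summed over the four covering kmers. The outlier-robust variant
damps each term by its distance from the two-model midpoint,
Sc_diff = I_k − (µ_ki+µ_kj)/2, and rescales by the model separation:

ORLLR_k = exp(−Sc_diff²/(Sf·σ²)) · LLR_k / (σ²·|µ_ki−µ_kj|^Sp·Sf₂),

with Sf = 4, Sf₂ = 3, Sp = 0.3. A positive statistic favors base *i*;
calling uses agnostic maximum likelihood at threshold 0, per read, as a
majority-vote consensus over ≥ 10 reads, or on position-averaged levels
(per sequence). Recall = TP/(TP+FN) and specificity = 1 − FP/(FP+TN)
benchmark call sets, with ROC curves sweeping the statistic threshold.

## Worked example

`examples/simulate_and_call.py` builds a model in which P and G differ
by 0.35 normalized-level units at each of the four covering kmers
(σ = 0.4), simulates 10,000 reads of one heptamer, and calls each read:

```
per-read recall (llr): 81.0%
per-read recall (orllr): 79.1%
Gaussian oracle Phi(sqrt(sum d^2)/(2 sigma)): 80.9%
consensus recall (n=11 majority): 99.2% (binomial prediction 99.1%)
```

The LLR decision at threshold 0 is the likelihood-ratio test between
two Gaussian product models, so its per-read recall has the closed form
Φ(√(Σ_k Δ_k²)/(2σ)) — here Φ(0.7/0.8) ≈ 80.9%, matched by the
simulation within Monte-Carlo noise. Majority voting over 11 reads
lifts ~81% per-read recall above 99%, the exact binomial-majority
value. The other examples cover alphabet combinatorics
(`alphabet_combinatorics.py`: 256/512/2304 kmers, 448 codon-anticodon
pairs), library design (`design_library.py`: 64-hairpin pools, 4096
joined contexts covering all 512 pair kmers, 100 validation products
plus ligation side-product references) and model fitting
(`fit_model.py`: recovery of generating kmer means at ~10³
observations per kmer).

A thin CLI wraps the same functions (`xnacall design|sim|model|levels|
morph|stats`); run `xnacall --help`. Raw-signal preprocessing
(basecalling, resquiggling, normalization) is out of scope — `xnacall
preprocess` documents the level-CSV input contract instead.

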