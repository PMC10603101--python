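# Methods

## Signal model

Nanopore current is summarized per reference base as a median-normalized
level assigned by an upstream signal-to-sequence mapping step; `xnacall`
begins at that table. Levels are modeled at kmer resolution: a length-4
window determines the expected level, and a base at position *p* is
covered by the four 4-mers starting at *p−3 … p* (offset labels +2, +1,
0, −1 give the focal base's index within the kmer relative to the kmer
center). The level associated with a kmer starting at position *s* is
the one observed at *s+1*; for a heptamer NNN·X·NNN this places the four
informative levels at positions *p−2 … p+1*.

Observed levels for kmer *k* are treated as Normal(µ_k, σ). k = 4 is
the default because a complete single-XNA model (512 kmers per pair) is
measurable from one small flow-cell run; the structures support other
k. The model is assumed stationary across reads and positions, levels
conditionally independent given the sequence — both idealizations of
pore data, which carries event-duration effects and correlated noise.

### Sigma policy

Three policies are exposed: `global` (default) uses the mean of the
per-kmer sample standard deviations for every kmer; `per_kmer` uses
each kmer's own σ_k; `manual` takes a user value. The global policy is
the default because a shared σ makes the likelihood-ratio decision
depend only on mean separations and empirically outperforms per-kmer
choices. The global σ is always computed from the loaded model rather
than fixed; on real normalized data it comes out near 0.4, which is
therefore the simulator's default σ_g.

### Estimators and the KDE question

µ_k can be summarized as the sample mean, sample median, or from a
Gaussian KDE built with the Silverman rule-of-thumb bandwidth

    A = 0.9 · min(IQR/1.34, σ_k),  BW = A · n_k^(−1/5),

with a flagged fallback to BW = 10⁻³ for constant data. Two KDE
summaries are exposed: `kde` takes the argmax of the density on a
512-point grid spanning the data range ± 3·BW, and `kde-mean` takes the
density-weighted grid mean. For a symmetric kernel the KDE mean tracks
the sample mean and is √n-consistent; the grid argmax is a *mode*
estimator whose sampling SD at the density-optimal bandwidth scales as
σ·n^(−1/5) — about 0.036 at n = 10⁴, σ = 0.4 (measured over 40
replicate draws). Tests therefore hold the mean-type estimators to
CLT-scale tolerances (≈ 3σ/√n, and 0.02 for the KDE mean at n = 10⁴)
but the KDE mode only to ≈ 3× its own sampling SD (0.11). For Gaussian
level distributions all estimators target the same value, so estimator
choice is not expected to matter beyond noise — which is also why all
are kept available.

### Density

The per-level density is the standard normal pdf with the chosen µ and
σ; log₁₀ densities are summed over kmers to give sequence likelihoods.
σ ≤ 0 is a domain error; a kmer absent from the model raises a coverage
error naming the kmer rather than silently skipping it.

## Hypothesis testing

Calling is refinement, not decoding: the reference sequence and the
putative XNA position are given. For candidates *i* vs *j* the heptamer
LLR is the sum of the four per-kmer log₁₀ density ratios; the
outlier-robust LLR multiplies each term by exp(−Sc_diff²/(Sf·σ²)) and
divides by σ²·|µ_ki−µ_kj|^Sp·Sf₂ (Sf = 4, Sf₂ = 3, Sp = 0.3). ORLLR is
applied per kmer and summed; when µ_ki = µ_kj the term is defined as 0
(the |µ|^Sp denominator would otherwise be singular, and an
uninformative kmer should contribute nothing). Every scale factor is
positive, so each kmer's ORLLR term keeps its LLR sign; aggregate
four-kmer decisions may still differ between the two statistics.

Decision rule: each alternative candidate gets a candidate-vs-null
statistic; the null (the XNA) is retained unless some candidate exceeds
the threshold (default 0), in which case the maximal candidate is
called, with an alphabetical tie-break. With two candidates, LLR and
threshold 0, this is exactly the total-likelihood argmax. Candidate
sets: the single most-similar canonical base (the empirical
substitution map B→A, S→A, P→G, Z→C, X→A, K→G, J→C, V→G), all four
canonical bases, or every letter of the active alphabet. A multi-way
total-likelihood ranking is reported alongside. Multi-XNA sequences are
called position by position from each position's own heptamer window;
overlapping windows containing two XNAs would need multi-XNA kmers and
raise a coverage error, matching the single-insertion model scope.

Consensus calling majority-votes per-read calls at one position,
requiring ≥ 10 reads by default; smaller groups and exact ties are
no-calls. For per-read accuracy r > 0.5 and odd n, consensus accuracy
is the binomial majority probability, which exceeds r — the property
the consensus tests check exactly.

## Metrics

Recall = TP/(TP+FN) with the XNA as the positive class. Specificity is
1 − FP/(FP+TN); the FP/(FP+TN) quantity is called FDR in this method's
own convention (elsewhere the false-positive rate) and is the x-axis of
the ROC, built on scikit-learn's `roc_curve`/`auc` with trapezoidal
integration. A precision-based FP/(FP+TP) variant is exposed under a
distinct name and never used by default.

## Simulation

The simulator mirrors the decomposition-recompilation scheme: for each
of the 4096 heptamers of a substitution base, n reads (default 1000,
i.e. 4,096,000 reads per base) each draw one level per covering kmer
from Normal(µ_k, σ_g), σ_g = 0.4. Only the four focal positions carry
modeled levels; the three edge positions hold a 0.0 placeholder that no
computation reads (levels are required finite). No clipping to an
observed level range is applied. Seeding uses one root `SeedSequence`
with per-heptamer spawned child streams, so a heptamer's draws depend
only on its index in the enumeration. Levels are stored columnar (one
2-D array per table), which keeps the full-scale simulation in the
hundreds of MB and seconds range.

Synthetic models for testing draw each kmer mean uniformly from
[−2.5, 2.5] — the span of the normalized-level scale — with a common
σ = 0.4. What the simulator deliberately omits: segmentation errors,
event-duration information, level autocorrelation, q-score/match-score
structure (simulated reads carry passing QC values), and multi-read
coverage bias. Tests passing on simulated data therefore validate the
statistical machinery (estimators, statistics, decision rules, metric
definitions) — not robustness to real-pore artifacts.

### Analytic oracles

Under the model, the per-read LLR decision between truth *i* and
alternative *j* is correct with probability Φ(√(Σ_k Δ_k²)/(2σ)),
Δ_k = µ_ki − µ_kj; for a single informative kmer the score ROC has
AUC = Φ(|Δ|/(σ√2)); consensus recall is an exact binomial sum. These
closed forms are derived independently of the implementation and the
end-to-end pipeline is required to reproduce them within Monte-Carlo
error (3 binomial SEs, plus a one-read discreteness allowance in the
randomized property test where the expected recall can sit near 1).

## Library design

The NNN design enumerates all 64 terminal triplets per pool, pairs each
injectively with a random 24-nt triplet barcode, and joins pools as
armA + x + revcomp(armB): 4096 contexts covering all 512 pair kmers
across the two strands (verified exhaustively). Validation pools use
uniform-random 20-nt variable regions screened by a simple secondary-
structure filter (homopolymer runs ≤ 4; no 10-nt self-complementary
substring) standing in for an external screening tool. Scaffolds and
pool barcodes are synthetic placeholder constants — counts, coverage
and barcode decodability are the guaranteed properties, not particular
bases. Reference sets enumerate desired hetero-ligations, within-pool
homo-mismatch ligations, blunt-gap products without the inserted pair,
and N−1 products lacking one terminal base on either partner
(which partner loses the base is unspecified upstream, so both variants
are emitted — a superset is safe for alignment references). Top-strand
representation throughout; homo-mismatch products are sequence-
identical in form to desired ones and distinguished by provenance tags.

## Degenerate inputs and numerical choices

Constant level vectors: flagged small-positive KDE bandwidth. σ_k = 0
(single observation): recorded as 0 but never used for likelihoods
under the global policy. Duplicate read ids, level-count/sequence-
length mismatches and non-finite levels are format errors with line
numbers. Model files reject duplicate kmer rows and missing required
columns, and preserve unknown extra columns. All enumerations
(kmers, codons, heptamers) are explicit products in deterministic
lexicographic order with XNA letters after the canonical four; variant
tokens (Sn, Sc, Xt, Kn) sort by leading letter then tag.

## Problem sizes in tests

The default suite simulates at 10³–10⁴ reads per check and one
full-scale 4,096,000-read generation; parameter-recovery runs use 16
reads per heptamer, giving ~1024 observations for each of the 256
focal kmers. These sizes put Monte-Carlo noise well below the tested
tolerances while keeping the suite in the tens of seconds.

## Known limitations

No raw-signal handling (FAST5/POD5, segmentation, normalization); no
HMM/Viterbi decoding or de novo calling; kmer models longer than 4 nt
are supported structurally but not shipped; multi-XNA kmers are out of
model scope; the S/X/K variant distinction lives in metadata and model
choice, never in sequence strings.
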