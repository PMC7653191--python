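# Methods

## Classification model

The classifier maps a one-hot encoded DNA sequence of fixed length
L = 200 (columns A, C, G, T; N encodes as the all-zero row, so padding
injects no base evidence) to a probability of G-quadruplex formation.

Architecture, in forward order, for filter counts (16, 8, 4, 3):

    [conv1d(kernel 8, same padding, ReLU) → batch normalization
     → max-pool(2) → dropout(0.3)] × 4
    → flatten → dense(32, ReLU) → dense(1, sigmoid)

Training uses Adam (learning rate 0.001, β₁ = 0.9, β₂ = 0.99, ε = 1e-7)
on binary cross-entropy, 15 epochs, batch size 32, no early stopping, no
class weights, no schedule. Weight init is Glorot-uniform; weight init,
shuffling and dropout masks all derive from `NetworkConfig.seed`.

Choices the architecture description leaves open, fixed here and exposed
in `NetworkConfig`: ReLU as the convolution activation, "same" padding
(so four pool-2 stages fit: 200 → 100 → 50 → 25 → 12), pool size 2 and
dense width 32. Batch normalization uses ε = 1e-3 and running-stat
momentum 0.9 (an internal constant; 0.9 lets the inference statistics
settle well within a 15-epoch run). Sequences shorter than L are
random-N-padded and longer ones center-cropped before scoring, so the
predictor accepts arbitrary-length input; the padding seed is a
`predict` argument, making inference deterministic.

The network is implemented directly on numpy (im2col convolutions,
hand-derived backprop through batch-norm/pool/dropout, Adam). At this
size a framework adds nothing; the numpy stack keeps inference
dependency-free, makes every random stream explicit, and is validated by
a finite-difference gradient check in the test suite.

**Fast occlusion inference.** Randomized-window mutagenesis rescans the
same sequence ~16,000 times with only a 40-nt window changed, so the
model also exposes a strip-update forward: per-layer activations of the
base sequence are cached and only the receptive-field strip of each
layer (window ± kernel reach, shrinking through the pooling stages, with
a rank-one correction at the dense layer) is recomputed per variant.
This is arithmetically the same computation restricted to the affected
columns; a test asserts agreement with the naive full forward to float
precision.

## Dataset construction

Intervals are BED-convention (0-based, half-open); minus-strand
intervals are extracted as reverse complements, so every sequence reads
5'→3' on its annotated strand. Standardization to 200 nt: longer
sequences keep the central window starting at floor((len−200)/2) (the
extra base is lost on the right — a deterministic tie-break); shorter
sequences receive their deficit of Ns split uniformly at random between
the flanks.

Negatives: for each sampled positive, k negatives of the positive's
pre-padding length are drawn on the plus strand, uniformly over the
genome (chromosome chosen proportionally to its count of valid start
positions), rejection-sampled against an interval tree of the *full*
positive set. Negatives are not screened for N content or for motif
matches — random genomic coordinates legitimately contain both. Ratios
1:k are exact: totals must divide by k+1. Positives are sampled without
replacement; multiple positive BED files are pooled by concatenation
without deduplication. The train/eval split is stratified (default 10 %
held out).

## Baselines

The regex baseline is the canonical motif
`(G{3,}[ATGCN]{1,7}){3,}G{3,}`, a boolean per sequence. G4Hunter is
re-implemented from its scoring rule: per-base ±min(run length, 4) for
G/C runs, 0 for A/T/N; per-sequence score is the maximum mean over
25-nt windows (stride 1; a single whole-sequence window when the input
is shorter), reported only if it strictly exceeds the threshold
(default 0), else 0. Window means are computed from integer window sums
divided by the window size, so results are bit-reproducible and
identical to naive enumeration. No merging of overlapping
above-threshold regions is performed — the tool is used as a
per-sequence scorer.

## Evaluation conventions

A call is positive iff score ≥ threshold (so a score of exactly 0.85 is
"precise"-positive). Precision is defined as 0 when no positives are
called. PR curves enumerate distinct score values as thresholds; tied
items enter the confusion counts together. AUPRC is the step-function
average precision Σ (R_i − R_{i−1})·P_i over descending thresholds, not
a trapezoid — well-defined under ties and equal to prevalence for a
constant scorer at any class ratio. The F1-vs-threshold scan uses a
0.00–1.00 grid in steps of 0.01 and returns the smallest maximizing
threshold on ties.

## Synthetic data generator

Positives are 200-nt i.i.d. background sequences (default 40 % GC,
roughly genomic; P(G)=P(C)=gc/2) with a planted canonical motif:
`n_tracts` = 4 G-tracts of length 3–5 joined by loops of 1–7 nt. Loop
bases are drawn from {A, C, T}: allowing G in loops can merge or extend
adjacent tracts, which would corrupt both the tract-count property and
the planted-interval ground truth that the interpretation experiments
score against. Negatives are pure background, by default
rejection-sampled until regex-free so labels are clean; the screen can
be disabled to emulate unscreened genomic negatives. The generator also
plants motifs into a whole synthetic genome (disjoint slots, half on the
minus strand, variable peak-interval lengths) to exercise the
BED-driven dataset builder end to end.

What this emulates — and does not. The fixture reproduces the
*structure* of the problem: a localized G-tract motif against background
at controlled prevalence. It does not reproduce real genomes:
non-canonical G4s (long loops, bulged tracts, two-quartet structures),
repeat structure, GC heterogeneity, assembly gaps, or noisy G4-seq
labels. Consequently the planted task is much easier than the genomic
one — near-ceiling AUPRC on the synthetic ladder shows the pipeline
learns and ranks the motif correctly under imbalance, not that genomic
performance would be comparable. In particular the canonical regex is a
*perfect* classifier of this fixture by construction (every positive
contains the motif, screened negatives never do), whereas on real
G4-seq data it misses the large non-canonical fraction.

## Interpretation

For every window start (window 40 nt, all L − 40 + 1 = 161 positions),
the window is replaced by `n_random` = 100 i.i.d. uniform A/C/G/T
stretches — replacements never insert N, which is reserved for padding —
and importance is the original score minus the mean variant score.
"Most important" subsequences are selected greedily in decreasing drop
with mutual non-overlap enforced (otherwise top-k returns shifted copies
of one peak); ties break toward the smaller start. For negative
examples the same drop statistic is used by default; ranking by
absolute change is available (`mode="abs"`). Windows overlapping flank
padding are randomized like any other — padding is part of the model
input. Export sorts samples by their best window's drop and writes the
top subsequences as FASTA for external motif discovery.

A closed form anchors the statistic: for a scorer returning the G
fraction of the sequence, randomizing a w-window keeps each G with
probability 1/4, so the expected drop is (G_w − w/4)/L for a window
containing G_w guanines — (w/L)·(3/4) on an all-G sequence. Tests check
empirical convergence to this at n_random up to 1,000.

## Experiment orchestration and problem sizes

`workbench.run_experiment` chains simulate → train → evaluate →
interpret. All stage seeds derive from one global seed as
blake2s("`<seed>:<stage>`") mod 2³¹, so evaluation seeds are disjoint
from training seeds by construction; reports (TSV + JSON + per-ratio
score tables + log) are stamped with a hash of the full configuration.

Default experiment sizes — chosen so a complete run is a
few-minutes-on-one-CPU affair while keeping every estimate's sampling
error small relative to the effects measured: 10,000 balanced training
sequences (10 % validation split), evaluation sets of 2,000 (1:1),
2,000 (1:9), 5,000 (1:99) and 10,000 (1:999), and 100–200 positives for
interpretation profiling. The imbalance-degradation property is tested
with nested evaluation sets (fixed positives, negatives accumulated
from one background distribution), the construction under which AUPRC
is guaranteed non-increasing; independent per-ratio redraws obey the
trend only in expectation and can wiggle at the ceiling.

## Known limitations

* Training determinism across platforms is not promised (BLAS summation
  order); inference given fixed weights and padding seed is.
* The classifier scores the central 200 nt only; genome-wide scanning
  (tiling, overlap resolution) is out of scope.
* G4Hunter region refinement, external tool wrappers and motif
  discovery itself are out of scope; extracted subsequences are exported
  for external tools.
* The sensitive/precise thresholds are conventions carried with the
  model, not re-derived per dataset; `f1_vs_threshold` supports
  re-deriving an operating point when label composition differs.
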