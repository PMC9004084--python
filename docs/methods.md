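# Methods

`diffmotif` reimplements a differential-binding motif-discovery pipeline for
transcription-factor (TF) ChIP-seq: given peaks and read counts from a
wild-type TF and a DNA-binding-domain (DBD) mutant, it labels peaks that are
significantly stronger in the wild-type, trains a convolutional network to
predict that label from sequence alone, attributes the network's predictions
back to individual bases with the Rescale rule, aggregates high-attribution
subsequences ("seqlets") into motifs, and runs the downstream motif analyses
(trimming, mega-motif assembly, PWM scanning, SELEX read scoring,
peak-strength association). A seeded synthetic-data generator reproduces the
statistical structure of such a study so the whole chain is testable without
any external data.

## Differential peak labeling (`diffbind`)

Summit peaks from all datasets are merged by single-linkage chaining of
summits within 50 bp; the merged summit is the rounded mean of member
summits. Read 5' ends are shifted by half the fragment length — to the right
on the + strand and, by default, to the left on the − strand
(`strand_aware=False` reproduces a literal shift-right for both strands) —
and counted per summit-centered window.

The differential test is a deliberately transparent stand-in for a
negative-binomial GLM package: median-of-ratios size factors; per-peak
log2FC = log2((μ_mut + 0.5) / (μ_WT + 0.5)) of normalized condition means
(mutant over wild-type, so "stronger in wild-type" means log2FC < 0);
method-of-moments NB dispersions pooled across peaks in 20 mean-rank bins
and floored at 1e-8; a Wald z with a delta-method standard error; two-sided
normal p; BH q over non-zero peaks. Within each bin the dispersion is the
ratio of summed excess variance to summed squared means — a per-peak
median is biased low at 3-vs-3 (the per-peak estimate is right-skewed) and
inflates the null rejection rate to ~0.075; the ratio-of-sums form restores
~0.05. An external differential table (e.g. from DESeq2) can be ingested in
place of the built-in test; labels follow the rule: positive
iff q < 0.05 and log2FC < −1, negative iff log2FC ≥ 0, else excluded.

## The network (`convnet`)

The architecture is fixed: three valid (unpadded) convolutions — 60 filters
of 4×15, 60 of 1×15, 15 of 1×15, each followed by ReLU and dropout 0.2 —
then max-pooling of width and stride 35 (the final partial window dropped)
and a single sigmoid unit. Inputs are 4×L one-hot matrices (rows A,C,G,T; N
is an all-zero column); every peak contributes a forward and a
reverse-complement example, and the per-peak score is the mean of the two.

Training: SGD with Nesterov momentum 0.85, learning rate 0.01, batch size
200, weighted binary cross-entropy with class weights equal to the fraction
of peaks in the other class; a pretraining phase from He-normal
initialization on a class-balanced subsample (negatives down-sampled to the
number of positives), then the full training set; both phases stop after
three consecutive epochs without improvement in validation recall at 80%
precision (defined as 0 when no threshold reaches the floor) and restore the
best-validation weights, with ties broken toward the lower training loss.
The chromosome split is train = chr3–7, chr10–19, chrX; validation = chr8–9;
test = chr1–2.

The network is implemented directly in NumPy. Convolutions (forward,
input-gradient and weight-gradient passes) are computed through real FFTs
with padding past the wrap-around lags; this was chosen over im2col because
the pipeline targets single-CPU, bandwidth-limited hosts, where the K-fold
patch duplication dominates runtime. Forward passes preserve float64 inputs
end-to-end, which the finite-difference oracle tests rely on; training runs
in float32. Training is bit-reproducible given a seed.

## Attribution (`attribution`)

Rescale-rule attribution assigns each input entry a share of the difference
in a readout between the input and a reference (the all-zero "sequence of
Ns"). Multipliers pass through linear layers via the transposed weights and
through each ReLU as Δoutput/Δinput, falling back to the gradient when
|Δinput| < 1e-7; max-pooling (when on the attribution path) routes credit to
the argmax unit of the actual input. Contributions satisfy completeness
(they sum to the readout difference) and, for this ReLU stack with a zero
reference, equal input × gradient. Hypothetical scores extend the observed
contributions to all four bases per position by applying the same
multipliers to each substituted one-hot difference; the observed base's
hypothetical entry equals its actual contribution.

Two readouts are provided: the summed post-ReLU output of the final
convolutional layer, and the pre-sigmoid logit. The pipeline attributes the
logit: the final-conv sum mixes all 15 filters regardless of their weight in
the decision, and in practice its attributions are dominated by
non-discriminative sequence signal, whereas the logit readout concentrates
attribution on the label-discriminative motif.

## Motif discovery (`motifdisco`)

A transparent stand-in for seqlet-based aggregation tools: per-position
importance is the summed absolute contribution; 21-bp windows are scored by
summed importance and thresholded at empirical FDR ≤ 0.2 against a null from
per-peak position shuffling in blocks of two (preserving adjacent-pair
coupling); each passing window is re-centered on its importance centroid
(window sums are flat-topped around a compact motif, so the raw offset is a
tie-break artifact) and overlapping windows are resolved by greedy
non-maximum suppression (>50% overlap suppressed). Pairwise seqlet
similarity is the overlap-fraction-weighted cosine of hypothetical-score
matrices, maximized over relative offsets within ±width/2 and both
orientations. Greedy leader clustering on descending total attribution
assigns each seqlet to the first leader with similarity above threshold;
clusters below `min_seqlets` are dropped and the rest are ranked by size.
Aggregation averages aligned one-hots (the motif PFM) and hypothetical
scores (the importance matrix) in a width-50 frame.

Defaults are FDR 0.2, final width 50 and a minimum of 200 supporting
seqlets; the desk-scale pipeline passes `min_seqlets=20` (a few hundred
validation true-positives cannot support 200) and a leader-similarity
threshold of 0.6 — with 21-bp seqlets on a ~6-bp motif the overlap-fraction
weighting caps off-register alignments near 0.76, so the library's stricter
0.8 default would shatter genuine clusters. `DiscoveredMotif.to_pfm` exports
only columns covered by at least half the peak seqlet coverage: edge columns
averaged over a handful of members are far too noisy for the
probability-threshold trimming rules. Discovered motifs carry no intrinsic
strand; the pipeline canonicalizes orientation by a 0.25-centered sliding
dot product against the known core motif (centering keeps background
columns from outvoting a truncated match) and then extracts the downstream
element with the downstream trim rule — the same orient-then-trim procedure
the analyses are designed around. No claim of output-level fidelity to
TF-MoDISco is made: the gapped-k-mer embedding and graph-clustering phases
are intentionally replaced by this exhaustive, testable equivalent.

## Motif operations (`motifops`) and scanning (`scanner`)

Trimming removes degenerate flanks by scanning the per-column maximum
probability: the kept region starts at the first position (or first of two
consecutive positions) above the cutoff and ends either before the second
degenerate position encountered (one interior degenerate position is
tolerated) or before a position whose maximum probability drops by more than
a threshold relative to the previous kept position. Three standard
parameterizations are exported as constants (0.60 one-position; 0.40
two-consecutive; 0.35 scanning upstream from the downstream end with a
>0.35 drop stop). Boundary semantics are strict (> cutoff, > drop).

Mega-motifs concatenate motif parts with background-probability spacer
columns; the six presets are core, upstream, downstream, upstream + 7 bp +
core, core + 2 bp + downstream, and all three combined. The SELEX query for
20-bp reads is the downstream-most 10 bp of the core, 2 background columns,
and the upstream-most 4 bp of the downstream motif (width 16). Backgrounds
come from both-strand base and dinucleotide counts with a 0.1 pseudocount
(order 0 and order 1); "G/C content" spacers default to GC = 0.42. PWMs are
log2-odds with a 0.001 pseudocount weighted by the background.

The scanner computes, for each PWM, the exact null score distribution under
the strand-symmetrized order-0 background: by direct enumeration of all 4^W
sums (vectorized outer addition) for W ≤ 10, and by an integer-lattice
dynamic program (1000 bins over the total score range) with queries scored
on the same lattice for wider motifs, so table lookups are internally
consistent and the discretization error is bounded by width × range / bins.
Both strands are scanned; q-values are BH across all retained hits of one
scan. Per-sequence best-hit features: −log10 of the
smallest q if below 0.5 else 0, or −log10 of the smallest p with p = 1 when
a sequence has no hit. Order-1 backgrounds are reduced to their order-0
marginals for p-value computation; higher-order scoring is out of scope.

## Statistics (`stats`) and analyses (`analyses`)

Wilcoxon rank-sum tests use exact enumeration for tie-free samples with
n1 + n2 ≤ 12 and otherwise the normal approximation with midranks, tie
correction and continuity correction (via scipy). BH is statsmodels'
step-up. Fisher's r-to-z comparison uses the independent-samples formula
z = (atanh r1 − atanh r2) / sqrt(1/(n1−3) + 1/(n2−3)); the correlations it
compares share the peak-strength variable, so the independence assumption is
an approximation, as in the original analysis. Bonferroni multiplies by m
(default 6) and clips at 1.

SELEX read scoring is the maximum dot product of the one-hot read (either
orientation) with the query PFM over all full-overlap alignments; pools are
compared by a one-sided rank-sum test. Aggregate hit logos average one-hot
read segments at hits passing each q cutoff (0.05, 0.01, 0.005, 0.001),
reverse-complementing minus-strand hits. Peak partitions follow the
strict/relaxed reference rule: overlapping means ≥1 bp overlap with the
strict set; non-overlapping means zero overlap with the relaxed set; peaks
matching neither rule are excluded. Peak strength is ln of the narrowPeak
signal column; group comparisons are two-sided rank-sum tests with
Bonferroni ×6; correlation comparisons use all peaks with the no-hit feature
set to 0. The logistic baseline is scikit-learn logistic regression with
inverse-regularization C = 1.0 (solver tolerance 1e-8), fit on the train +
validation chromosomes and scored by AUPRC on the test chromosomes.

## Synthetic data (`synthetic`)

The generator emulates the statistical structure of such an experiment,
not its raw reads: 20 chromosomes named chr1..chr19 + chrX (75 kb each by default) of
i.i.d. bases at GC 0.42; 4000 summit-spaced peaks; every peak carries a
19-bp sharpened-consensus core motif within ±10 bp of its summit; positive
peaks (fraction 0.3) additionally carry a GAGCCA downstream motif 2 bp
after the core (or at a uniform 2–12 bp spacing in variable-spacing mode).
Counts are gamma-Poisson (NB) with mean 200, dispersion 0.05, a log-normal
per-peak baseline (sd 0.5), log-uniform [0.5, 2] size factors, 3 replicates
per condition, and a planted log2FC of −2 on positive peaks. SELEX pools
are 20-bp background reads; the enriched cycle carries query-PFM samples at
uniform offsets and random orientation in 30% of reads. All outputs are
pure functions of (config, seed).

What this does not emulate: dinucleotide or repeat structure, chromatin
accessibility, fragment-level coverage shape, PCR duplicates, or motif
grammar beyond the planted elements. Passing tests therefore demonstrate
that the machinery recovers planted structure under the model's own
assumptions, not performance on real ChIP-seq.

Windows are 2 × flank = 200 bp by default (flank is configurable; planted
motifs sit within ±10 bp of the summit, so 200 bp amply covers them at
desk scale). Problem sizes used by the test suite and the reproduction
script: 4000 peaks for the full-chain and model-vs-baseline runs (the
model-vs-baseline comparison needs the resulting ~400-peak validation split
so that recall-at-80%-precision is fine-grained enough for the patience-3
early stop to act on real improvements), 2000 peaks for differential-test
calibration, 5000 reads for SELEX power, 1e5 positions for scanner
calibration.

## Known limitations

- The differential test is a calibrated stand-in, not a DESeq2
  reimplementation (no shrinkage, no covariates, no independent filtering).
- Scanner p-values are order-0 exact; FIMO's order-1 scoring mode is not
  reproduced.
- Seqlet clustering is leader-based; motif estimates depend on the leader's
  registration, and rare co-occurring motifs below `min_seqlets` are lost.
- Numerical agreement with historical Keras/Theano-era DeepLIFT
  implementations is not claimed anywhere; the contracts tested are mathematical
  (completeness, exactness, calibration), not bit-compatibility.
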