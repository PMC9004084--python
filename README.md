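# diffmotif

Differential-binding motif discovery for transcription-factor ChIP-seq.

When a DNA-binding-domain (DBD) mutant of a transcription factor loses
binding at a subset of its wild-type sites, the sequence features enriched in
the *lost* peaks reveal what the mutated domain was reading. `diffmotif`
implements that whole inference chain for desk-scale analysis:

1. **Label** peaks: merge summit peaks across datasets (summits within
   50 bp, merged summit = mean), count fragment-shifted read 5' ends, run a
   negative-binomial Wald test of wild-type vs mutant counts (median-of-ratios
   size factors, pooled method-of-moments dispersions), and call a peak
   *positive* (stronger in wild-type) iff q < 0.05 and log2FC < −1, *negative*
   iff log2FC ≥ 0.
2. **Learn**: train a fixed convolutional network — three valid convolutions
   (60 filters 4×15, 60 of 1×15, 15 of 1×15, ReLU + dropout 0.2 each),
   max-pool 1×35/35, one sigmoid unit — on 1-hot windows around the merged
   summits (forward + reverse-complement examples; SGD, Nesterov momentum
   0.85, lr 0.01, batch 200, class weights = fraction of the other class;
   balanced pretraining; early stop on validation recall at 80% precision).
3. **Interpret**: Rescale-rule attributions and hypothetical scores
   (reference = all-N, i.e. the zero one-hot matrix), satisfying completeness
   Σᵢ contribᵢ = f(x) − f(ref).
4. **Discover**: extract high-attribution 21-bp seqlets at empirical FDR
   0.2, cluster by offset/orientation-maximized cosine similarity of their
   hypothetical-score matrices, and average each cluster into a width-50
   motif (PFM + importance matrix) ranked by seqlet support.
5. **Analyze**: degenerate-flank trimming (three parameterized rules),
   mega-motif assembly with background spacers, FIMO-style PWM scanning with
   *exact* order-0 p-values and BH q-values, max-dot-product SELEX read
   scoring with rank-sum enrichment tests, peak-overlap partitions, and
   ln-peak-strength association tests (Wilcoxon, Bonferroni ×6, Fisher
   r-to-z correlation comparisons).

A seeded generator (`diffmotif.synthetic`) simulates matching experimental conditions —
summit-centered peaks on 20 chromosomes, a core motif in every peak, a
GAGCCA element 2 bp downstream of the core in positive peaks only, NB counts
with planted log2FC = −2, and 20-bp SELEX pools — so the entire chain runs
and is tested with no downloads. The network and attribution engine are pure
NumPy (FFT-based convolutions, hand-written gradients), so there is no deep
learning framework dependency.

## Worked example

Run the full chain on simulated data (4000 peaks, ~4 minutes on one CPU):

```bash
diffmotif run-all --seed 1 --outdir out/
```

```
{
  "label_counts": {"negative": 2508, "positive": 1179, "excluded": 313},
  "val_auprc": 0.965918623364811,
  "test_auprc": 0.9897573613194507,
  "n_motifs": 4,
  "top_motif_seqlets": 215,
  "trimmed_consensus": "GAGCCAAA",
  "recovered_gagcca": true
}
```

Reading this: of 4000 simulated peaks, 1179 were labeled significantly
stronger in the wild-type (the simulation planted 1200 at log2FC −2), 2508
negative, 313 excluded by the q/log2FC rules. The network separates held-out
test-chromosome peaks at AUPRC 0.99. Seqlet clustering of the Rescale
attributions yields 4 motifs; the top-ranked one (215 supporting seqlets)
spans the planted core + 2 bp + GAGCCA arrangement, and orienting it against
the core and trimming its downstream element recovers the planted GAGCCA
(plus two weak flanking columns) — the analysis finds the mutated domain's
motif from sequence alone. `out/` also contains the labels, the per-epoch
training log, and the motifs in MEME format.

Every stage is an ordinary library call (see `diffmotif.pipeline` for the
chain wiring) and has a CLI subcommand: `simulate`, `merge`, `count`,
`diff`, `label`, `train`, `attribute`, `discover`, `trim`, `megamotif`,
`scan`, `selex`, `overlap-compare`, `strength`, `baseline`, `run-all`.

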