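# Methods

This note records the model, the protocol, and every place where the
design was genuinely open, so that results produced by the test suite
and `scripts/acceptance.py` can be read with the right caveats.

## Problem setting

Per-residue binary classification: each residue of a protein sequence is
either intrinsically disordered (1) or structured (0).  The predictor
does not see the sequence itself; its inputs are the per-residue scores
of four component disorder predictors (channels D, I, V, E after the
roles DisEMBL, IUPred, VSL2 and ESpritz play), each scoring disorder
high on its own scale.  Channels are accepted on their native scales —
thresholds are learned per channel, so no rescaling is needed and only
finiteness is validated.

## Threshold selection by information gain

For a labelled training set and channel scores *s*, the information
gain of the split "s ≥ x" is the parent label entropy minus the
size-weighted entropies of the two groups, in bits, with 0·log 0 = 0.
IG is computed on an evenly spaced grid (default 201 points) over the
observed score range.  Properties relied on elsewhere: IG is invariant
under strictly monotone transforms applied jointly to scores and
threshold; for equal-variance label-conditional Gaussians its maximizer
converges to the Bayes boundary.

The IG curve of an informative channel is single-peaked.  The dual
thresholds are band edges of that peak: the step-*k* true/false cutoffs
are the outermost grid points, walking out contiguously from the peak,
where IG ≥ `step_k_frac` · IG(peak).  Step 1 uses the lower fraction
(default 0.6), so its band is wider and a step-1 vote requires a score
beyond the far shoulder of the high-IG region — the stringent setting;
step 2 uses 0.9 and is laxer.  This fixes the ordering
`t1_true ≥ t2_true ≥ peak ≥ t2_false ≥ t1_false`.  The fractional-height
construction is this package's own operationalization of "stringent
first, lax second"; no closed form for the pairs exists in the
literature the method descends from.  Ties at the grid maximum break
toward the smaller score for determinism; a channel whose peak IG falls
below 1e-6 bits is rejected as degenerate rather than silently encoded.

An earlier variant derived the bands from complementary heights
(IG ≥ (1 − frac)·peak).  It satisfies the same ordering but makes the
default abstention bands so wide that roughly half of all residues
encode to the zero vector, capping the meta-predictor below its best
component; it was discarded.

## The voting tree and its encoding

Votes at step *k*: TRUE iff score ≥ `tk_true`, FALSE iff score ≤
`tk_false`, else ABSTAIN (boundary scores count as votes).  The tree:
step-1 majority decides; a tie falls to the step-2 majority; a second
tie goes to significance voting, comparing d_T = Σ (score − t2_true)
over step-2 TRUE voters with d_F = Σ (t2_false − score) over step-2
FALSE voters.  The all-abstain case is a 0–0 tie with d_T = d_F = 0 and
encodes as the zero vector rather than erroring.

Three points were open and are fixed as follows:

* The tree emits no label.  Its branch determines the encoding only;
  the network makes the final call.
* The 10 network inputs are a1 (4), a2 (4), d_T, d_F — the only
  quantity set whose cardinality matches the ten input nodes.  The vote
  counts N_T/N_F are implied by the sign pattern of the a-values and
  are not separate inputs.  For a channel voting TRUE at step *k*,
  a_k = score − tk_true ≥ 0; FALSE, a_k = score − tk_false ≤ 0;
  ABSTAIN, a_k = 0.
* Distance sums always use the step-2 (lax) thresholds, so that more
  channels contribute, and are computed on every branch so the network
  sees the distance evidence even when a majority decided.

The encoding is deliberately normalization-free: scaling one channel's
scores and thresholds by c > 0 scales its contributions by c, and
raising a score never lowers that channel's a-values or d_T.  An
exhaustive 5⁴-point grid test pins the implementation against an
independent scalar re-implementation of the tree.

## Network

Fixed architecture 10-20-20-2, fully connected; hyperbolic tangent on
all nodes including the output pair, whose activations are then passed
through a softmax to form (P(structured), P(disordered)).  Loss is
(optionally class-weighted) cross-entropy.  Since no training scheme is
prescribed by the method's origin, standard choices are used and
exposed: mini-batch gradient descent with momentum (defaults lr 0.01,
momentum 0.9, batch 128), uniform fan-in-scaled weight initialization,
and early stopping on a dedicated stop set with patience (default 50,
capped at the epoch budget), returning the snapshot with the best
stop-set loss.  Encoder features are standardized with training-fold
means/sds stored in the model — the a/d features have heterogeneous
scales.  Analytic gradients are verified against central differences;
identical seed, data and config give bit-identical weights.

## Evaluation

Confusion-derived metrics use the textbook formulas; balanced accuracy
is exactly (Sens+Spec)/2.  Any metric with a zero denominator is carried
as an explicit NaN marker and excluded from aggregation — coercing to 0
would visibly distort small groups such as single terminal positions.
ROC/PR curves come from scikit-learn's threshold sweep (ties collapse to
single steps); ROC AUC is the trapezoid, PR AUC the interpolation-free
step sum, and both are cross-checked against an O(n²) concordance
oracle in the tests.  Pairwise overlap/coverage and all-coverage follow
the set definitions on true-positive/true-negative sets per class.
Grouped balanced accuracy supports amino-acid, terminal-distance
(distances 5–25, pooled across sequences rather than averaged per
sequence) and per-sequence groupings; no smoothing is applied to the
terminal curves.

## Experimental protocol

Splits are by sequence, never by residue, to avoid within-sequence
leakage.  ~20% of sequences form an independent test set, accepted by
rejection resampling until the disordered:structured residue ratio of
test and training sides agrees within 10% relative (up to 1000
attempts, then a hard error reporting the best ratio achieved).  The
remaining sequences form five folds; rotation *i* validates on fold
*i*, early-stops on fold (*i*+1) mod 5 and trains on the rest, so every
fold serves every role exactly once over one fixed assignment per seed.
Thresholds are re-derived from each rotation's training folds only.
Summaries are mean ± sd across rotations, with NaN-marked metrics
excluded.  Independent-test evaluation applies all five rotation models
and averages; any id overlap between test set and folds is a hard
error.

Terminal regions: the 25 residues nearest each terminus form the N/C
regions, the rest the middle; for sequences shorter than 50 residues,
positions claimed by both termini go to the nearer one, ties to the N
side, so the three regions always partition the sequence.  Region
experiments re-derive thresholds and re-train the network per region.

## Synthetic data generator

The generator emulates the statistical regime the meta-strategy
assumes, not protein biology.  Per sequence (default 300 sequences of
80–400 residues): alternating structured/disordered segments with
geometric lengths (means 36 and 14, stationary disorder fraction 0.28,
matching the ~2.5:1 structured:disordered imbalance typical of curated
disorder datasets).  Per residue, a latent standard normal shared
across channels (weight √ρ, default ρ = 0.5) plus independent channel
noise is mapped through the normal CDF and label-conditional Beta
quantiles: label 1 ~ Beta(c, 2), label 0 ~ Beta(2, c), with c =
3.1226, 3.3647, 3.5032, 3.8320 solved numerically so the analytic
P(score₁ > score₀) equals 0.78, 0.82, 0.84, 0.88 — the component-AUC
spread the method targets.  Because the copula preserves marginals, the
per-channel AUC is independent of ρ.

The optional terminal effect (within 25 residues of either end, active
when `terminal_noise_sd` > 0) is signal attenuation plus jitter:
score′ = 0.5 + 0.5·(score − 0.5) + N(0, sd), clipped to [0, 1].  Pure
zero-mean jitter was tried first and degrades terminal AUC, but leaves
the optimal decision rule nearly unchanged, so region-specific
retraining cannot beat a global model trained on seven times the data;
attenuation emulates what window-based predictors actually do at
sequence ends — lose discriminative signal, scores regressing toward
mid-scale — and is exploitable by re-derived thresholds, which is the
phenomenon the region experiments study.

What the generator does *not* emulate: amino-acid-composition
dependence of disorder, terminal enrichment of disorder, sequence
autocorrelation of scores beyond segment structure, or
predictor-specific score dialects.  Passing tests therefore demonstrate
the pipeline's correctness and its capacity to exploit ensemble
structure of this kind, not performance on curated experimental data.

## Benchmark studies and problem sizes

Both studies (`disvote.experiments`) train with 60 epochs, patience 10,
batch 256 — the network converges well before that on these data — and
class weights (1, 2.57) inverting the residue imbalance, since balanced
accuracy is the headline metric and unweighted training trades
sensitivity for specificity at the 0.5 call cutoff.

* Meta vs best channel: five seeds; per seed a fresh 300-sequence
  dataset, full five-rotation cross-validation; baseline = per-channel
  validation AUC on raw scores and balanced accuracy at the channel's
  training-fold IG peak; win = meta mean exceeds the best channel.
* Region vs global: five seeds with `terminal_noise_sd` = 0.2; per seed
  the mean over all five rotations of terminal-residue balanced
  accuracy on the validation fold, comparing one global model against
  N-/C-region models stitched per residue.  Rotation averaging is used
  because the paired adaptation effect (~+0.005 balanced accuracy) is
  comparable to single-rotation training noise.

## Known limitations

* The network trainer is plain NumPy and single-threaded; it is sized
  for the benchmark datasets, not proteome-scale training.
* Threshold selection assumes a single-peaked IG curve; multi-modal
  curves take the contiguous band around the global peak and ignore
  secondary peaks.
* The CASP-style output writer and the ablation switches for
  alternative encodings are intentionally minimal.
* Undefined-metric propagation means downstream consumers must treat
  NaN as "no data", not zero.
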