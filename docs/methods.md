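# Methods

This note documents the model, the numerical and design choices behind
`clipbind`, what the synthetic data generator does and does not emulate,
and the package's known limitations.

## Model and assumptions

`clipbind` is a binary sequence classifier with an interpretable output
layer.  The core assumption is that protein–RNA binding is driven by
short, degenerate sequence elements whose effect depends on their local
context: the convolution bank detects candidate elements, and the
bidirectional LSTM (BLSTM) integrates them with the surrounding sequence
before a per-base verdict is made.  The model compares each sequence
against the *genomic background* it was trained against, not against an
absolute binding free energy; scores are only comparable between
sequences of similar length scored by the same model.

Pipeline per sequence (length L, filters of sizes m ∈ {4,…,8} by
default):

1. **Encoding.**  One-hot over (A, C, G, U), zero-padded with a symmetric
   margin of m_max − 1 columns so the largest filter can run full
   convolutions, and right-padded within a batch to a common length.  A
   validity mask separates real bases from padding.  Ambiguity codes
   (N, R, Y, …) encode as all-zero columns with mask 1: they are real
   positions that contribute no evidence, which the bias-free network
   treats as exactly neutral.
2. **Convolution bank.**  One filter per size, no bias, rectifier
   activation, stride of one whole base.  Initial weights are the
   constant 0.01; the bank starts symmetric and is differentiated by the
   gradients flowing back from the (randomly initialised) BLSTM.
3. **WTA enhancement.**  Per filter, the single maximum score is doubled
   (first occurrence on ties) and the whole vector squared.  The
   subgradient at the winner is taken through the doubled branch.
4. **Track reconstruction.**  The enhanced value assigned to base j is
   the score of the placement whose *first* position is j (the margins
   guarantee such a placement exists for every real base).  An
   alternative rule — the maximum over all placements covering j — is
   available via `build_tracks(..., assignment="max_cover")` for
   sensitivity analysis; the default is the simplest rule consistent
   with rebuilding the one-hot pattern from the enhanced vector.
5. **BLSTM.**  Standard gate equations (input, forget, modulatory,
   output gates; σ and tanh activations), hidden state initialised to
   zero, 20 units per direction by default.  The hidden size is a free
   architectural parameter (not dictated by the method); 20 keeps
   desk-scale training fast while being ample for short motifs, and it
   is exposed in `TrainConfig`.
6. **Masked recurrence.**  Padded time steps are *skipped*: hidden and
   cell state carry through unchanged.  This is the property that makes
   profiles and scores exactly invariant to how much padding surrounds a
   sequence — with non-zero trained gate biases, running the recurrence
   over zero inputs would instead let the amount of padding leak into
   the hidden state at the sequence boundary.  Backpropagation treats the
   carry as an identity connection.
7. **Output.**  Profile value at base t = row sum of H_t; padding rows
   are zeroed and removed; score = σ(1.0 · Σ profile) through a fixed,
   bias-free node.  The weight is stored but excluded from optimisation
   by construction (it is not an optimiser slot), so "frozen after any
   number of updates" holds identically.

## Training

* Loss: mean binary cross-entropy.  ADAM with α = 0.0002, β₁ = 0.9,
  β₂ = 0.999, ε = 1e−8.
* Initialisation: convolution weights constant 0.01; BLSTM weights and
  biases from N(0, 0.01²).
* Dropout 10% on the elements of H only (applied after the BLSTM, so
  recurrent connections are unaffected), with inverted scaling so
  inference needs no rescaling.
* Batches of 64, reshuffled each epoch; the last partial batch is kept.
* Model selection: after every epoch the selection metric (validation
  AUROC by default; validation loss as the alternative) is evaluated
  with dropout off; the best-so-far parameters are retained, keeping the
  *first* best on exact ties.  Early stopping after `patience` epochs
  without improvement; `patience` defaults to ceil(0.10 · max_epochs).
* Splits: 80/10/10 stratified per class, validation and test each taking
  floor(n/10) per class and the remainder training.  10-fold CV shuffles
  indices into 10 near-equal bins; fold k tests on bin k and validates
  on bin (k+1) mod 10 — the pairing of validation bins to folds is a
  free choice; this one makes every bin validation exactly once.  CV
  fold plans are built per class and paired bin-by-bin so every fold
  sees both classes; test predictions are pooled across folds before a
  single AUROC is computed.
* All randomness in a run (splitting, initialisation, epoch shuffling,
  dropout masks) flows from one seed, so runs are bit-for-bit
  reproducible in single-threaded NumPy.
* Classes are assumed balanced (the background generator produces one
  background per peak); imbalance triggers a warning, not reweighting.

The whole network, including gradients, is implemented in NumPy: batched
backpropagation-through-time for both LSTM directions, the track/WTA/
convolution chain, and the masked carries.  The gradient code is checked
element-wise against central finite differences and the forward pass
against an independent straight-line scalar implementation in the test
suite.

## Background generation

Given positive peaks (BED) and gene spans (BED6), each peak is assigned
the gene with the largest overlap (ties: first in annotation order) and
one background interval of identical width is rejection-sampled
uniformly inside that gene (default 1,000 tries), subject to overlapping
no positive peak and no previously placed background.  Peaks are
processed in input order — feasibility is order-dependent in tightly
packed genes — and infeasible peaks are skipped with a warning, never
dropped silently.  Placement ignores strand; the sequence is extracted
on the peak's strand.  Because accepted draws come from a uniform
proposal filtered by a fixed legality predicate, placements are uniform
over the legal set, which the tests verify against exhaustive
enumeration and a 3σ frequency band.  Alternatively, class-0 sequences
can be made by scrambling the positives (mononucleotide permutation by
default; a dinucleotide-preserving Eulerian-walk shuffle is available
behind a flag).  Peaks can be pre-expanded by a fixed flank and/or
recentred to a fixed width (left-biased midpoint on odd adjustments).

## Pseudo-PFMs

For motif extraction the top-1000 sequences by classification score
(ties by input order; alternatively all sequences above a score
threshold such as 0.5) are scanned with each filter.  A placement
contributes its covered k-mer weighted by the *square of its own raw
(pre-WTA) rectified convolution score*, provided the placement lies
entirely in the real region and every covered base has binding-profile
value strictly greater than 0 — regions the BLSTM associates with the
unbound class are zeroed out.  Weighting per placement (rather than by
the sequence's maximum filter score) attributes the weight to the
convolutional layer that produced it; the per-sequence-maximum reading
is available via `weighting="seq_max"`.  No pseudocounts are added;
filters with no contributing placement yield an explicitly empty PFM.
PFMs are ranked by mean per-column information content,
IC = 2 + Σ_b f_b log₂ f_b bits against a uniform background, and
exported as MEME minimal motifs plus a full-precision counts TSV.

## Applied prediction modes

* **Variant scoring** reports Δ = score(mut) − score(wt) and, for
  length-matched pairs, the per-base profile difference.  Substitutions
  within one maximal filter width of a sequence end trigger a warning:
  edge positions lack full context and their profile values are
  unreliable.
* **Long-sequence profiling** slides a window (default: the model's
  training maximum, forced odd by subtracting one; step 1) and stitches
  the central-nucleotide profile values.  The first/last half-window
  positions copy their values from the first/last full window — a
  simple, documented edge rule consistent with the edge-effect caveat
  above; no reflection or missing values.
* **Site calling** finds all 9-nt windows with mean profile strictly
  greater than 0.3, merges *overlapping* (not merely adjacent)
  qualifying windows into maximal intervals, and recomputes each merged
  site's mean over the merged interval.  Coordinates are 0-based
  half-open on the query.
* **Region aggregation** extracts anchored sub-regions around exon
  boundaries (first/last 25 exonic nt, 50 nt intronic flanks by
  default) from many full-length profiles and reports the per-offset
  mean with a normal-approximation 95% CI (1.96·s/√n).

## Synthetic data

`simulate.generate_dataset` plants one motif instance — sampled
column-wise from a user PFM — at a uniformly random offset in each
positive (overwriting background bases so lengths stay fixed), with
composition-matched i.i.d. negatives; a truth table records every
planted offset.  The default study conditions used throughout the tests
and the acceptance script are a 7-mer point-mass UGUGUGU motif (a
TDP-43-like UG repeat), sequences of length 40, 1000 positives and 1000
negatives, uniform background, occurrence rate 1.  `generate_toy_genome`
lays tiled genes on a single chromosome with non-overlapping planted
peaks for exercising the background generator end-to-end.

What the generator does *not* emulate: CLIP protocol biases
(cross-link-induced truncations, uridine enrichment around crosslink
sites), transcript-level coverage structure, degenerate/partial motif
occurrences beyond what the PFM encodes, and RNA secondary structure.
Passing the planted-motif tests therefore demonstrates that the
implementation can learn and localise a sequence signal under clean
conditions — not that any particular real-data accuracy will be
reached.

## Problem sizes

The test suite and acceptance script run the full default fixture
(1000 + 1000 × 40 nt) with up to 30 training epochs — about ten seconds
of training in this implementation — and use smaller instances
(n ≤ 64, hidden ≤ 8) for oracle-equivalence, gradient and determinism
checks, where exhaustive or element-wise comparisons are the point.

## Limitations

* Scores are relative to the training background and not comparable
  across sequences of very different lengths; the architecture sums
  per-base contributions, so longer sequences accumulate more mass.
* The track-reconstruction alignment and the pseudo-PFM placement
  weighting each have one defensible alternative reading; both are
  implemented behind flags and the defaults are stated above.
* Single-threaded NumPy training is desk-scale: datasets of ~10⁴ short
  sequences train in minutes, but this implementation is not intended
  for 10⁶-sequence corpora.
* No RNA structure, no multi-filter-per-size banks, no k-mer embeddings.
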