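# Methods

## Classifier

**Model.** The GR/non-GR decision is a binary classification over protein
sequences. A frozen backend maps a sequence of length L to an L×d matrix
of per-residue embeddings; the trainable head is a transformer encoder
(post-layer-norm: each layer applies multihead self-attention with a
residual connection and layer normalisation, then a position-wise
feed-forward network with a second residual + normalisation), followed by
mean pooling over positions, a single linear unit and a logistic output.
The reference configuration is 12 layers, model dimension 512, 8 heads ×
64 channels, FFN inner dimension 512, dropout 0.4. The backend is never
updated: freezing the feature extractor is what lets a small head train
on modest data without destroying the embedding geometry.

Two points the architecture leaves genuinely open were decided as
follows. The head consumes *per-residue* embedding matrices and pools
*after* the encoder (mean over positions): pooling first would reduce the
encoder to an MLP over a single vector and make the attention layers
vacuous. No positional encodings are added; the stub backend's k-mer
windows already carry local positional information, and the
classification target is position-diffuse. Both choices are configurable
in spirit (the head only assumes an L×d input).

**Implementation.** Forward and backward passes are written in NumPy
(float64). The backward pass is exact (softmax, layer-norm and dropout
gradients derived by hand) and is checked against central finite
differences at rtol 1e-3 in the suite; observed agreement is ~1e-9.
Batches group sequences by length so equal-length inputs run as one (B,
L, d) tensor contraction.

**Training protocol.** Per epoch, the batch pool is every positive
training sequence plus a fresh subsample of the negative pool (default
one negative per positive), drawn without replacement and keyed on
(seed, epoch) so successive epochs see different negatives. The loss is
weighted binary cross-entropy with weight 5 on TF-labeled negatives
(hard negatives: non-GR transcription factors are the class the model
must actually learn to reject) and 1 elsewhere; scores are clamped to
[1e-7, 1-1e-7] inside the loss. Optimisation is AdamW (β = 0.9/0.999,
decoupled weight decay 0.1, biases and normalisation parameters
excluded from decay), linear learning-rate warm-up from 0 to the target
over the first `warmup_batches` batches, and global-L2-norm gradient
clipping at 100. The best checkpoint is selected by validation AUC. The
reference defaults (lr 1e-6, 1,000-batch warm-up) describe
corpus-scale training; at desk scale (a 2-layer, dim-64 head on a few
hundred sequences) the package's own operating point is lr 1e-3 with a
20-batch warm-up and 8–15 epochs, which is the standard regime for a
model of that size — the corpus-scale learning rate would not move a
tiny head in a bounded number of epochs. The decision threshold for
calls defaults to 0.5.

**Splitting.** Whole GR types can be held out: their sequences go 50/50
to validation and test (odd counts: the extra sequence to validation,
a fixed tie-break), and never to training — this is what measures
generalisation to unseen regulator families. Known GR types split
80/10/10 per type; negatives split 8:1:1 stratified within each
negative category. Held-out types must have ≥ 10 sequences. All
splitting is deterministic given a seed. The 5× TF weight applies to the
training loss only; validation metrics are unweighted.

## Exact-p-value PWM scanning

Motif probabilities are regularised with a pseudocount
(p̂ = (p + 0.1·π_b)/(1.1)) and scored as log₂(p̂/π_b). Scores are
quantised to an integer grid with granularity chosen so the
widest-spanning column covers at most 1000 bins (≈ 3 decimal digits of
score resolution); a warning is raised if quantisation merges distinct
column scores. The null distribution of the total window score under the
background model (independent positions) is built by column-wise
convolution of the integer score distributions; a hit's p-value is the
exact tail mass P(S ≥ s). The dynamic program is validated against
exhaustive 4^w enumeration at machine precision for short widths.
P-values clamp to 1 below the support and to the exact mass at the
maximum above it, so they stay in (0, 1]. Reported hit scores are the
quantised values (integer score × granularity), keeping score → p-value
exactly consistent.

Upstream windows are the 400 nt immediately 5′ of the gene start
(strand-corrected; minus-strand genes take the reverse complement of the
region 3′ of their end). Windows truncated by contig edges are flagged
and scanned as-is; both strands are scanned; overlapping windows of
adjacent genes are not trimmed, so one physical site may support two
genes. Ambiguous bases (N) take the minimum score of their column — the
conservative choice, since it can only push a window below threshold.

**Three-tier filtering.** Tier 1 is the raw threshold p ≤ 1e-4. Tier 2
handles extremely short motifs (< 6 bp), whose best possible p-value
(≥ 0.25⁵ ≈ 1e-3) cannot clear a meaningful threshold: it keeps only
hits attaining the maximum achievable score. This operationalises
"maximal stringency" for short motifs — a literal p ≤ 0 admits no hits
at all, and consensus-only matching preserves the evident intent while
remaining non-vacuous. Tier 3 automates the symmetry inspection of
candidate motifs: palindromicity is the fraction of consensus positions
complementary to their mirror position, and motifs below 0.6 are
*flagged* in the QC output rather than removed — a manual-judgment step
should annotate, not silently delete.

## Regulons and networks

Calls aggregate surviving hits per (GR type, genome, gene) with hit
count and best p-value. Genus prevalence uses as denominator every
genome of the genus in the analysed set, not only genomes with calls.
The core-target hierarchy: fraction ≥ 0.5 in a genus (inclusive — a
family in exactly half the genomes qualifies) gives genus-level core;
qualification in ≥ 2 genera gives cross-genus core; only when a GR has
no cross-genus core anywhere does the fallback emit the top 5 families
by overall genome prevalence, ties broken lexicographically. "The same
gene across genomes" means sharing `family_label` — orthology is an
input annotation, not computed here.

The putative-regulator support rule is read literally: ≥ 10 distinct
(genome, gene) targets in total, with calls spanning ≥ 2 genomes (not 10
per genome); both thresholds are parameters.

Network edges A → B count call events on genes encoding another
regulator (the gene → GR-type map is an explicit input). Edge supports
therefore sum exactly to the number of calls landing on GR-encoding
genes. Hub ranking is by support-weighted total degree, ties
lexicographic. Network scope (species- vs phylum-level graphs) is a
genome filter on the same operation.

## Synthetic data generator

The generator emulates the statistical structure the pipeline must
resolve, not biological realism. Proteins: every GR sequence carries a
shared 40-residue core block (point-mutated at 5% per sequence — enough
variation to prevent memorisation, little enough to stay learnable) plus
a 20-residue type-specific conserved block, placed at random offsets in
120-residue sequences with uniform-random filler; TF hard negatives
carry the core with 50% of positions randomised (similar enough to be
the informative negative class, different enough to be separable);
random negatives are pure filler. Defaults: 8 GR types × 30 sequences,
60 TF and 180 random negatives.

Motifs: one per GR type, widths cycling 10–14, columns drawn from
Dirichlet(0.1) — low concentration gives the information-rich columns
(≈ 1.8 bits on average) real regulator motifs have. Genomes: 3 genomes ×
200 genes on uniform-background contigs, genes spaced with 2×-window
gaps so upstream windows never overlap (an overlap mode exists for
testing the untrimmed-window rule). The first genes of each genome
encode the GR proteins themselves. The regulon design gives each type 5
plain target families plus the gene of the next type in a ring (and one
self-loop), so cross-regulation truth is known exactly; motif instances
(consensus by default, PWM-sampled optionally) are planted at uniform
offsets with probability `plant_prob` (default 1) and registered in the
truth manifest. Everything is bit-deterministic under the seed.

What passing on this fixture does *not* show: robustness to homology
between negative and positive sets beyond the designed core degradation,
operon structure and shared promoters, non-uniform genome composition
(the scanner's background model is uniform or user-supplied, never
estimated), or pLM-specific embedding geometry — the k-mer stub shares
the frozen-backend contract, not ESM2's numerics.

## Verification conditions and problem sizes

The suite trains a reduced head (2 layers, dim 64, k-mer stub backend,
dim 32) on the default protein fixture — large enough to exhibit the
seen-type/held-out-type generalisation gap, small enough to converge in
a few hundred optimisation steps. Scanner properties are measured on the
default 3 × 200-gene genomes (≈ 4,800 window–motif scans). Held-out-type
discrimination is tested against a label-permutation null (999
permutations, one-sided).

Network reconstruction is checked at two thresholds. Support
conservation (Σ edge supports = calls on GR-encoding genes) is
structural and holds at the default p ≤ 1e-4. Exact recovery of the
planted cross-regulation design is checked at p ≤ 1e-6: at 1e-4 the
scanner's *site-level* false positives (≈ 0.08 expected chance hits per
400-nt window, what the scanner recovery check measures) necessarily leak
support-1 edges into the graph, so the graph-logic check uses a site
threshold stringent enough that only consensus-grade sites (p ≤ 0.25¹⁰
≈ 9.5e-7 for the narrowest planted motifs) enter. This separates the
two error sources instead of conflating them.

## Known limitations

- The head is CPU/NumPy; it is meant for desk-scale corpora, not the
  multi-million-sequence regime (no GPU kernels, no mixed precision).
- Background nucleotide composition is uniform or user-supplied; no
  genome-specific background estimation, and no multiple-testing
  correction across windows (raw exact p-values with tiered filtering).
- Gene starts stand in for transcription start sites; operons and
  internal promoters are not modelled.
- GR-type assignment of predicted positives is out of scope (the
  classifier is binary); type attribution would be a downstream
  comparative step.
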