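# Methods

This note documents the models and procedures implemented in
`markwriter`, the choices made where the design was genuinely open, and
what the synthetic-data tests do and do not establish about real data.

## Coordinates and regions

All internal coordinates are 0-based half-open (BED convention);
1-based inputs must be converted at the boundary. Anchor regions are
built from the gene-boundary coordinate of the anchor — TSS at `start`
(+ strand) or `end` (−), TTS symmetric — and extend
upstream/downstream in the reading direction, so a spec of (up, down)
always yields an interval of up + down bp before clipping. Regions are
clipped to chromosome bounds, never discarded. The TSS2 region
(+200..+600) is expressed as a negative upstream extent. Summit
*distances* are measured from the anchor base (TSS base = `end − 1` on
the − strand) and signed positive downstream; nearest-anchor matching
ignores strand when locating the anchor but signs by the matched
gene's strand. Under this signing, mirroring the genome (reflecting
coordinates and flipping every strand) leaves all signed distances
invariant — the property test asserts exactly that.

Registered region presets: `TSS_region` (−150/+300), `TTS_region`
(−200/+200), `TSS_region2` (+200/+600), `enhancer_region` (±900).

## Coverage quantification

Single-end reads are extended 3′-wards to 250 bp (configurable) to
represent fragments. A fragment counts once per region when it
overlaps by ≥ 1 bp (bedtools-coverage-like); bedGraph tracks are
integrated as signal area. RPM = raw × 10⁶ / library size; RPKM = RPM
× 10³ / region length. bedGraph library sizes cannot be inferred and
must be supplied when RPM/RPKM is requested. Gene splitting: the gene
body is the transcribed interval minus the intra-genic parts of the
anchor regions (3-region scheme, genes ≥ 500 bp; 4-region scheme adds
TSS2, genes ≥ 800 bp). Gene-body columns carry both RPM and RPKM —
"unnormalized" body values are interpreted as RPM, mirroring the
anchor-region columns, since they are contrasted only with
length-normalized values. An empty body yields zero-valued columns
rather than dropping the gene. Expression enters the feature table as
the mean FPKM of the replicates.

## Random-forest binding model

Bound genes are the top *n* by ranked signal, ties broken by gene id
so labelling is deterministic; negative signals rank normally. Each of
the 5 repeats draws its negatives from the full unbound pool first and
then excludes held-out genes from fitting (so each repeat's balanced
set is exactly n positives + n sampled negatives before holdout
exclusion); ROC/AUC is evaluated on all genes of the held-out
chromosome (unbalanced), or on a seeded stratified fraction in
fraction-holdout mode. Forest hyperparameters are not dictated by the
procedure itself and default to 500 trees, mtry = ⌊√p⌋, unlimited
depth. Per-repeat seeds are `seed + repeat`. Importances are
scikit-learn's Gini importances, which are normalized to sum to 1
within each model; the reference R implementation reports the raw
decrease. Rankings — the quantity every downstream decision uses — are
unaffected; absolute importance values are therefore comparable within
a model, not across packages. Ablation zeroes every column derived
from the named track and uses majority-vote class predictions, since
the lost-gene rule is defined over class predictions, not scores. A
gene is "lost" when at least one repeat flips it from predicted-bound
to predicted-unbound under the ablation. The pairing of repeats is a
deliberate design choice: an unpaired reading ("bound ≥ 1 original
repeat and unbound ≥ 1 ablated repeat") nominates every gene the
repeats merely disagree on, so even a no-op ablation (zeroing an
already-constant column) would return the ~2–3% of boundary genes
whose five repeats split — the paired rule makes the null perturbation
map to the empty set while agreeing with the unpaired one wherever
the original ensemble is unanimous.

## k-mer SVM promoter model

Vectorization is coding-strand only, lexicographic k-mer order,
windows containing non-ACGT skipped; no reverse-complement collapsing
(promoter architecture is directional). The training pool excludes the
held-out chromosome. Five CV trials partition the positives into five
folds; each trial trains on 4/5 of the positives plus an equally sized
negative sample drawn independently (without replacement within a
trial) and validates on the held-out fold (balanced with unused
negatives). The regularization parameter C ∈ {0.01, 0.1, 1, 10} is
chosen by mean validation accuracy; the final ensemble is the five
fold models refit at that C, which keeps the ensemble diverse even
when the unbound pool is no larger than the bound pool. Count vectors
are standardized per model on its training rows only (zero-variance
k-mers get sd := 1); holdout rows are transformed with the stored
parameters — the tests assert this hygiene by recomputation. Averaged
weights over the five models rank k-mers; rank labels follow |weight|.

Similarity levels between 6-mers are ordinal — reverse complement >
1-nt offset > 1-nt offset on the opposite strand > none — with display
scores 1, 2/3, 1/3 for graph export; a self-reverse-complement 6-mer
forms no self edge, and a pair satisfying several tests reports the
highest level. Flanking-context matrices use all coding-strand
occurrences with complete, N-free 3-bp flanks in the designated
sequence set (bound promoters for positive k-mers, unbound for
negative, all promoters for near-zero/random — the last choice is the
package's reading of an underspecified point). Motif families are
exact 6-mer catalogs (GAGA, TATA, telobox, ARGCCCAWT). Conservation
per k-mer averages a per-base score track over all occurrence bases,
dropping occurrences with undefined scores.

## Mutant, spike-in and correlation statistics

Loss profiles split TSS→TTS into 6 bins with boundaries ⌊iL/6⌋,
ordered 5′→3′; per-bin WT − mutant RPM differences are standardized
per gene with sample SD (n − 1), constant rows becoming all-zero.
Mutants are clustered on Euclidean distances between vectorized bin
matrices with average linkage (UPGMA; configurable — the distance, not
the linkage, is dictated by the procedure). The spike-in statistic
R = target-genome reads / spike-in reads is a within-sample ratio,
hence invariant to sequencing depth; the actual/expected ratio
R_mut,mark / (R_wt,mark · R_mut,H3 / R_wt,H3) estimates the mutant's
remaining global mark level. Overlap tests are exact hypergeometric
tails (under: P(X ≤ obs); over: P(X ≥ obs)). Mark–transcription
correlation is Spearman's ρ (average ranks on ties) of the mark vector
against *each* expression replicate, over all protein-coding genes
including unexpressed ones; the exported rank table for density plots
excludes unexpressed genes — two deliberately distinct filters.
Genotypes are compared by Welch's t-test on the replicate ρ values,
with degenerate zero-variance cases mapped to p = 1 (equal means) or
p = 0 (unequal).

## Synthetic-data generator

The generator emulates the statistical skeleton the analysis assumes,
at desk scale (defaults: 5 chromosomes of 1.2 Mb, 2000 genes with
log-normal lengths ≥ 500 bp, 300 bound genes; the genome-scale bound
count of 3000 is a config change). Binding propensity follows
logit = β_D·z(driver) + β_M·motif + ε with a bimodal (two-component
Gaussian, modes 0 and 2.5, unit SD) driver, standard-normal noise by
default, and the bound set is the top-n propensity. Feature tracks
carry the driver plus measurement noise (SD 0.2), independent
standard-normal nuisance features, and an RNAP2-like feature ∝
(expression + 0.1)^γ. Expression is log-normal with three
multiplicative-noise replicates and a configurable exactly-zero
fraction (default 10%). Promoters are i.i.d. uniform ACGT with a
single GAGAGAGA insertion at a uniform offset, probability π_bound =
0.6 (bound) vs π_unbound = 0.05 (unbound); when β_M ≠ 0 the logit uses
a latent motif indicator with the genome-wide expected insertion rate
as its prior, while the emitted FASTA plants conditionally on the
realized bound set. Mutant tracks share one per-gene-per-bin
log-normal rate field with WT; a mutant's counts are per-bin binomial
thinnings (multiplier < 1) or Poisson augmentations (> 1) of the WT
fragments on its affected genes, so an identity profile reproduces the
WT track byte-for-byte and profile comparisons share WT sampling
noise. Fragments in mutant tracks are 1-bp points so per-bin counts
partition exactly. Spike-in counts split a fixed read total
binomially, with the mutant mark sample's target share scaled by the
planted remaining mark level f — the actual/expected ratio therefore
recovers f directly. The correlation fixture composes the mark from a
transcription-coupled term ∝ expression^γ and an independent
chromatin-cue term scaled to equal mean contribution; removing either
term moves ρ in the diagnostic direction. Per-stage RNG streams are
derived from the master seed by hashing stage names, so stages can be
regenerated independently and every artifact is byte-deterministic.

What the generator does **not** model: realistic nucleosome
positioning or k-mer composition of real promoters (background is
uniform), GC or mappability bias, read-level errors, replicate
structure in ChIP tracks, or correlated chromatin features. Passing
recovery tests therefore demonstrate that the *procedures* recover
planted structure under their stated assumptions — not that real
ChIP-seq data satisfies those assumptions.

## Problem sizes and numerical notes

Recovery tests sweep 20 seeds at the desk-scale defaults above (SVM
fixture: 600 bound + 600 unbound promoters of 450 bp; clustering
fixture: 400 genes, 100 affected, six mutants with 3′-biased
(1,1,1,0.4,0.4,0.4) vs uniform (0.5,…) profiles; spike-in: 10⁵ reads
per sample). One caveat is worth stating plainly: with a single motif
insertion at π_bound = 0.6 vs π_unbound = 0.05 on a uniform
background, motif presence is the only class signal, which caps any
classifier's holdout AUC near 0.775 (0.6·0.95 + ½·(0.6·0.05 +
0.4·0.95)); the linear SVM lands below that ceiling because ~10³
training rows in 4096 standardized dimensions are linearly separable
and part of the margin fits noise, while fold-averaged weights still
rank the planted k-mers first. Motif *identification* — the scientific
readout — is robust under these conditions; high absolute AUC is not
achievable there and is not evidence the implementation is wrong.
Ties are broken deterministically throughout (gene id in labelling and
ranking, stable sorts in k-mer selection); Spearman uses average
ranks; standardization uses population SD within SVM models and sample
SD for bin profiles, as noted above.
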