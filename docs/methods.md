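# Methods

## Observation model

Raw UMI counts are modelled per gene as a zero-inflated negative binomial:
with probability $\pi$ the observation is a structural zero (dropout), and
otherwise it is a negative binomial with mean $d\mu'$ and dispersion $r$
(variance $m + m^2/r$ at mean $m$). The decoder produces $\mu'$ as a
softmax over genes, so $\mu'$ is a composition summing to 1 and $d\mu'$
matches the cell's observed depth exactly; this makes "sequencing-depth-
corrected mean" concrete and makes predictions directly comparable across
cells of different depths. Dispersion is a free per-gene parameter shared
across cells (one `softplus`-constrained vector), and the dropout logit is
a per-gene decoder head. The likelihood is evaluated in log space using
`softplus`/`logaddexp` identities so it stays finite for arbitrarily large
counts and saturated dropout logits.

## Networks and training

Encoder and decoder are fixed-depth MLPs (two hidden ReLU layers, width 128
by default). The encoder consumes `log1p` of the raw counts concatenated
with the one-hot factor indicators — the likelihood still evaluates raw
counts; the transform only stabilizes conditioning — and emits a diagonal
Gaussian posterior over a latent cell embedding (default dimension 25).
Both the encoder and the decoder condition on species/batch/tissue
indicators; conditioning only the decoder is a viable alternative, but
conditioning both matches the posterior's declared form $q(z|X,b,s,t)$.
Training samples $z$ by reparameterization; prediction uses the posterior
mean with no sampling and no dropout applied, the deterministic choice for
a "denoised" profile. Whether predicted expression should instead be
$(1-\pi)\mu'$ is genuinely open; $\mu'$ is the default and the dropout
parameters remain accessible on the decoded `ZINBParams`.

Optimization is Adam (learning rate $10^{-3}$, minibatch 128). A seeded
uniform split reserves 10% of cells (capped at 20,000) for validation;
training stops when the validation cVAE loss has not improved for 45
consecutive epochs (`patience_epochs`) and the best snapshot is restored.
Validation loss is evaluated at the posterior mean, so early stopping is
deterministic. With the discriminator enabled, each epoch first updates the
single-layer species discriminator on detached sampled embeddings
(cross-entropy), then updates encoder/decoder on
$\mathrm{loss}_{\mathrm{cVAE}} - \lambda\,\mathrm{loss}_{\mathrm{dis}}$
with the discriminator frozen ($\lambda = 1$ by default). All computation
is NumPy float64 through the package's own reverse-mode autodiff engine, so
runs with the same seed are bit-reproducible.

Grid search trains one model per (discriminator, latent dimension) point
and keeps the one maximizing mean validation LISI over species; ties keep
the earlier grid point (discriminator off first, ascending latent size).

## LISI

The local inverse Simpson index uses Gaussian kernel weights over the
$\lceil 3 \times \mathrm{perplexity} \rceil$ Euclidean nearest neighbours,
with the bandwidth calibrated per cell by binary search so the weight
entropy equals $\log(\mathrm{perplexity})$ (default perplexity 30, the
convention of the Harmony line of work; the exact variant the original
analyses used is not stated, so this choice is documented rather than
assumed). Degenerate neighbourhoods where all distances tie fall back to
uniform weights. Scores lie in $[1, k]$ for $k$ label levels.

## Orthology reconciliation

Scored many-to-many ortholog candidates are reduced to one-to-one maps by
greedy matching: edges sorted by decreasing percent identity (ties broken
lexicographically on gene ids, for determinism), accepted iff both
endpoints are free. The hub species (mouse in the motivating three-species
design) is matched against every other species to form the reduced graph
G'. Transitive triangles then link an apex-species gene A to a gene C in a
third species via an intermediate B: the criteria implemented are that A–B
is in G', B–C is in the independently computed one-to-one map of
(s(B), s(C)), C has no apex-species neighbour, and A has no s(C) neighbour.
The literal formulation "G' contains no edge touching C" is unsatisfiable
for hub-containing species pairs — the B–C hub edge itself touches C —
so the condition is operationalized as "A has no ortholog in s(C) yet",
which is what the canonical worked example (human A, mouse B, chicken C
with A lacking any chicken ortholog) describes. Species pairs are scanned
in a declared order (hub pairs first, then non-hub pairs); within a pair,
triangles apply greedily by decreasing B–C score. The apex species defaults
to human when present and otherwise to the hub, since the formal apex
(human) does not exist in the three-species dataset the procedure was
designed around; both modes are supported explicitly. No attempt is made to
keep the result consistent with the species tree.

## Demultiplexing and QC

A cell whose second- plus third-largest per-species read counts are
*strictly* greater than 20% of its total is a species doublet; otherwise it
is labelled with the argmax species, with exact top-two ties flagged
`AMBIGUOUS` rather than resolved arbitrarily. "Expressed" means count > 0.
The QC filter keeps ortholog-covered genes, drops mitochondrial genes, then
iterates the two threshold filters — cells with fewer than 200 total UMIs
and genes expressed in fewer than 50 cells — to a fixed point. The first
iteration is the standard single pass; iterating guarantees the whole
operation is idempotent, because removing sparse genes can push a
borderline cell below the UMI threshold (and vice versa). The report
accumulates removals per step across iterations.

## Evaluation

Pseudobulk is the mean of per-cell profiles rescaled to a fixed library
size of 10,000 (stated once in the disease-transfer analysis and unified
everywhere for consistency); the log variant applies $\log_2(x+1)$ to the
averaged profile, matching the pseudobulk-plus-one convention of the
log2FC analyses. Baselines: the donor baseline averages Pearson
correlations of per-donor log pseudobulk over all donor pairs ("cheating",
an approximate ceiling); the species baseline correlates the
ortholog-translated source profile with the target truth (predicting "no
change across species"); the cell-type baseline picks the nearest source
cell type by Euclidean distance on log pseudobulk and uses its
target-species profile. Relative prediction error is
$|\mathrm{pred}-\mathrm{target}| / |\mathrm{source}-\mathrm{target}|$
per gene, excluding (and counting) genes with zero denominator. The
AD-vs-WT evaluation correlates predicted with observed
$\log_2((\mathrm{AD}+1)/(\mathrm{WT}+1))$ vectors after the 10,000
rescaling. Correlations of constant vectors are reported as missing (NaN)
rather than forced.

## XCU statistics

Predicted per-cell profiles in each species are normalized so the summed
expression of housekeeping genes is 1 per cell (sum-scaling; a
regression-style correction would be the alternative reading of
"normalized based on housekeeping genes"). Per gene, the per-cell
$\log_2$ ratio between the upper and lower species uses a pseudocount of
$10^{-2}$ on the normalized scale to keep fold changes finite (the floor
the original analyses used is unstated; the value is a flag), and the
median across cells is the gene's summary fold change. Group-level tests
are one-sided one-sample Wilcoxon signed-rank tests: upregulation is
H0 median $\le -1$ vs greater; incomplete compensation is H0 median
$\ge 0$ vs less. The null distribution is exact for $n \le 25$ — doubled
midranks are integers, so the distribution of $2W^+$ is built by
subset-sum counting, equivalent to enumerating all sign assignments even
under ties — and a tie-corrected normal approximation with continuity
correction is used above. Zero differences are dropped; an all-zero group
is reported as missing. Multiple testing uses Benjamini–Hochberg (the
specific correction applied originally is unstated). Motif analysis counts
overlapping GGACH occurrences (H ∈ {A, C, T/U}) in CDS and rates per kb;
group shifts are tested with a one-sided Mann–Whitney U.

## Synthetic data

The count generator mirrors the model's generative assumptions so recovery
is well-posed: cell-type centers are standard normal in a true latent space
(dimension 8), cells scatter around their center (s.d. 0.3), and each
species decodes latents through a shared linear map plus a species-specific
perturbation (scale 0.6, large enough that raw counts separate by species)
followed by a softmax into $\mu'$. Depths are uniform on [500, 2000] —
deliberately shallow, in the range of combinatorial-indexing experiments
scaled to a 200-gene vocabulary — dispersions log-uniform on [1, 10], and
per-gene dropout uniform on [0, 0.3]. The last cell type is never emitted
in the last species, giving a held-out-type scenario with known truth: the
expected $\mu'$ of every (type, species) pair is estimated from 400 fresh
latent draws. What this does *not* emulate: real cross-species data have
non-affine expression divergence, unbalanced cell-type compositions,
ambient contamination and batch structure, so passing recovery tests here
demonstrates that the machinery works under its own assumptions, not that
real biological divergence is captured. The barnyard generator mixes
species reads multinomially (pure cells optionally contaminated, doublets
50/50); the orthology generator index-matches genes across species with
true-edge scores in (85, 100], decoys strictly below, and optional deleted
hub–third-species edges to exercise transitive filling.

## Problem sizes and defaults

Recovery experiments run at 2,000 cells × 200 genes, 5 cell types, 2
species, latent dimension 16, 40 epoch cap with patience 10 — small enough
to train in seconds per seed on one CPU while leaving the early-stopping
and selection logic fully exercised. The full-scale defaults
(latent 25/50/100 grid, patience 45, validation cap 20,000) remain the
package defaults and are used unless overridden.

## Known limitations

- The NumPy autodiff engine is single-threaded and eager; it is not
  intended for atlas-scale (>10⁵ cells, >10⁴ genes) training.
- One-to-one orthology discards duplicated genes; lineage-specific
  expansions are invisible to the model.
- The model assumes cell identity is conditionally independent of species;
  cell populations unique to one species violate this and their imputations
  are extrapolations.
- Statistical significance of differential expression on *predicted*
  profiles is out of scope; predictions are denoised continuous values, not
  counts.
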