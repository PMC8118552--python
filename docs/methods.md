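# Methods

## Model overview

The package infers gene-expression dynamics along a *pseudospace* axis — a
virtual cell-state coordinate defined by interpolated conditioning vectors —
rather than a pseudotime ordering of observed cells. Three fitted components
cooperate:

1. a **supervised encoder** that compresses a cell's log2(TPM+1) expression
   profile into a 64-dimensional latent vector while being trained *only* to
   predict the cell's relative isotype expression (its "adjacent
   information");
2. a **decoder** that maps latent vectors back to full expression profiles;
3. a **conditional GAN** whose generator simulates latent vectors for an
   arbitrary isotype profile, including profiles never observed (e.g. 37%
   IgM / 63% IgG1).

Supervision shapes the latent manifold so that position along it tracks the
class-switch coordinate; the GAN turns that manifold into a sampler; the
decoder converts samples into expression. The three are trained in sequence
(encoder, then decoder on the frozen encoder's latents, then the GAN on the
same latents), matching the two-step autoencoder description; a flag to
fine-tune the encoder jointly with the decoder is deliberately absent — the
frozen-encoder reading keeps the latent space fixed for the GAN.

### Assumptions

- The adjacent information is a per-cell simplex vector that varies
  monotonically along the process of interest. Here it is relative isotype
  expression over eight IgH constant-region transcripts; any gene set with
  that property can be substituted.
- Trajectories are linear source -> target interpolations on the simplex.
  Branching topologies are out of scope.
- Expression inputs are log2(TPM+1); for UMI/droplet counts, counts-per-million
  is used as the TPM surrogate since droplet chemistry has no transcript-length
  bias. No further per-gene standardization is applied before the encoder.

## Networks and losses

All networks are plain fully connected stacks implemented in numpy with
hand-written backpropagation (`nn.py`); there is no framework dependency and
every training loop is driven by one `numpy.random.Generator`, so a fixed
seed reproduces training bit-for-bit on a fixed platform.

| component | architecture | loss |
| --- | --- | --- |
| encoder | in -> 512 -> 256 (ReLU, dropout 0.3) -> 64 sigmoid -> 128 (ReLU, dropout) -> 8 softmax | mean KLD(Y‖Ŷ) + λΣ‖W‖² |
| decoder | 64 -> 256 -> 512 (ReLU + batch norm) -> genes linear | mean squared error + λΣ‖W‖² |
| generator | (32 noise + 8 condition) -> 256 -> 512 (ReLU) -> 64 linear | non-saturating: min −mean log D(G(r)) |
| discriminator | (64 latent + 8 condition) -> 512 (ReLU) -> 1 sigmoid | min mean −log D(z) − log(1−D(G(r))) |

Defaults: λ = 1e-5 (weight matrices only; biases and batch-norm parameters
are exempt), Adam with lr 1e-4 (autoencoder) and 5e-5 (GAN), β = (0.9,
0.999), batch size 128. Generator noise is uniform on (−1, 1). The
generator's printed objective `mean log D(G(r))` is the quantity it
maximizes; the implementation minimizes its negation (both appear in the
training log). The generator output layer is linear even though real latents
are sigmoid-bounded; the discriminator penalizes out-of-range samples, and
in practice generated latents land inside (0, 1).

Numerical guards: predicted profiles are clipped to ≥1e-12 inside the KLD
log (observed zeros contribute exactly 0), discriminator probabilities are
clipped to [1e-7, 1−1e-7], and any non-finite loss or gradient aborts
training with diagnostics rather than propagating NaNs.

## Early stopping

10% of the training cells (stratified by dominant isotype, so rare isotypes
are represented; the split is seeded) form a validation set. Only the data
term of the loss — KLD for the encoder, MSE for the decoder — is monitored.
If it has not strictly decreased for 100 consecutive epochs, training stops,
the weights revert to the best-validation snapshot, and training continues
for 5 more epochs on all cells including the validation split. A safety cap
(`max_epochs`, default 10,000) bounds runtime when the plateau never comes.
The stopper itself is a standalone object (`nn.EarlyStopper`) so the
protocol is testable on scripted loss sequences.

GAN training has no validation set; it runs to a loss plateau (relative
change of both losses < 1e-4 across a 500-epoch window) or to `max_epochs`
(default 50,000), with a divergence detector that aborts when losses go
non-finite or the discriminator's accuracy pins at 1.0 for a full window.
"Epoch" means a full pass over the dataset; the update schedule is 1
discriminator step then 1 generator step per minibatch (configurable k:1).
No gradient penalty, spectral norm or other stabilizers are used by default.

## Pseudospace tracing

A trajectory from source channel *s* to target channel *g* with step 0.01
contains 101 profiles `r(t) = (1−t)·e_s + t·e_g`. For each profile the
generator draws 100 replicate latents (fresh uniform noise each), which the
decoder maps to expression, i.e. 10,100 pseudocells per traced pair. The
per-gene summary is the replicate mean at each point with an **empirical
2.5–97.5 percentile band** — distribution-free, which is the natural choice
with 100 draws (a normal ±1.96·SE band is available behind a flag). Z-scoring
is applied to the mean curve across trajectory points, per gene; constant
genes are left at zero. Decoder outputs are reported raw (a flag clips
negatives to zero).

Phase assignment clusters the z-scored mean curves with k-means (k = 3,
10 restarts, seeded); clusters are named early/middle/late by the axis
position of their centroid's peak, so labels are deterministic up to k-means
convergence. Hierarchical clustering of profiles elsewhere in the package
uses average linkage on Euclidean distance with a deterministic leaf order —
a documented stand-in for a legacy clustergram default.

## Synthetic data

`simulate_csr_dataset` generates the structure the method assumes, with full
ground truth:

- **Cells.** Each cell has a trajectory coordinate *t* on an IgM -> target
  axis. Stable cells sit at an endpoint (default dominance fractions 0.30 /
  0.14 / 0.10 / 0.05 / 0.09 / 0.06 / 0.05 / 0.03 across the eight isotypes);
  18% are transitioning with *t* ~ U(0,1) toward IgG1/IgG2b/IgG3 (a beta
  option models sparse intermediate sampling).
- **Isotype genes.** Log-scale means are `B·w` where `w = (1−t, t)` on the
  two active channels and B = 18 log2 units — isotype transcripts are among
  the most abundant in switched B cells, which is also what makes the
  planted profile recoverable from counts at 10x-like depth.
- **Modules.** Three gene modules follow Gaussian response curves in *t*
  peaking at 0.1 / 0.5 / 0.9 (width 0.18, amplitude ≈ 3 log2 units) — the
  planted early/middle/late phases.
- **Confounder.** A rank-2 oscillation `sin/cos(φ)` with random gene
  loadings, independent of *t*, emulates the cell cycle; at high strength it
  dominates PC1 of the expression matrix, reproducing the failure mode of
  unsupervised projections.
- **Noise.** Gamma-Poisson (negative binomial, dispersion 0.1) counts at a
  mean library size of 50,000, with dropout probability `exp(−μ)` per entry.

What the simulator does **not** model: batch effects, doublets, gene-length
bias, transcriptional bursting beyond NB dispersion, and somatic-hypermutation
lineage structure. Tests passing on these data therefore show the machinery
recovers planted structure under the method's own assumptions, not that it
resolves every artefact of real experiments.

Fixture presets: `tiny` (200×300, seconds to train, used throughout the test
suite), `small` (1000×2000), `paper_scale` (7065×6617, matching the scale of
the motivating germinal-center dataset).

## Problem sizes used in tests and the acceptance script

Training-based tests run on the `tiny` simulated dataset with the published
hyperparameters but reduced epoch caps (encoder/decoder ≤ 1500 epochs, GAN
≤ 4500 epochs to its plateau, cross-validation folds capped at 300 epochs,
sample-size sweep at a fixed 120-epoch budget); these sizes were chosen so
the full pipeline trains in minutes on one CPU while every recovery property
(channel correlation ≥ 0.8, |Spearman ρ| ≥ 0.9 monotonicity, discriminator
equilibrium) is still met with margin. The sample-size sweep keeps the
500/1000/5000-cell design of the original analysis, at 300 genes.

## Design choices where the design was open

- **Zero-denominator cells** (no isotype transcript detected) receive the
  uniform profile with a warning, never NaN, so the simplex invariant holds
  for every cell.
- **Variable-gene metric**: plain variance on the log scale (a dispersion
  option exists); "most variable" is read literally.
- **MSE reduction**: mean over all (cell, gene) entries, so the loss scale
  is gene-count-free; a per-cell-sum convention is available.
- **Validation split stratification** by dominant isotype prevents rare
  isotypes from vanishing from small validation sets.
- **Isotype genes stay in the encoder input** (they are genes like any
  other); an exclusion flag exists.
- **Distribution-match checking** for the GAN compares per-dimension means
  and standard deviations of generated vs real latents per condition on the
  unit (0,1) latent scale (means within 0.2 for ≥90% of dimensions,
  standard deviations for ≥80%, over the most abundant conditions);
  ratio-relative comparison is ill-defined for sigmoid-saturated dimensions,
  and a vanilla conditional GAN leaves a few high-variance dimensions of
  smaller condition groups slightly under-dispersed at any feasible
  training length.

## Known limitations

- Vanilla GAN training is delicate; the divergence detector and plateau
  monitor make failure loud, but hard datasets may need the (off-by-default)
  stabilizer flags or longer training.
- The decoder's reconstruction quality is bounded by count noise: genes
  observed at a few counts per cell cannot exceed r ≈ 0.8 against their own
  resampled values, which is a property of the data, not the model.
- Pseudospace positions are conditioning values, not calendar time; equal
  steps in the profile are not equal durations.
- Per-gene confidence bands reflect generator noise only — they quantify the
  variability of simulated cells at a fixed conditioning, not posterior
  uncertainty about the underlying biology.
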