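# Methods

## The model

`sigxae` extracts single-base-substitution (SBS) mutational signatures from
catalogues of somatic mutation counts. A catalogue is a matrix
`C ∈ ℕ^{m×96}`: for each of `m` tumour genomes, the number of mutations in
each of the 96 channels (6 pyrimidine-centred substitution types × 16
trinucleotide contexts). A signature is a probability distribution over the
96 channels; an exposure is the number of mutations a signature contributes
to a genome.

The factorization is learned by a hybrid autoencoder:

* **Encoder** `f`: three dense hidden layers (default widths 128/64/32),
  each followed by batch normalization and a softplus activation, then a
  latent layer of width `k` with a non-negative activation. The latent
  vector `z = f(x)` holds the genome's exposures.
* **Decoder** `g`: a single linear map `x̂ = z Wᵀ` with `W ∈ ℝ^{96×k}`
  constrained elementwise non-negative and no bias. The columns of `W` are
  the signatures.

The loss treats counts as Poisson draws and regularizes the decoder towards
a minimum-volume solution:

```
L(x, x̂) = Σ ( −x·log x̂ + x̂ )  +  β·log det(W Wᵀ + I),   W ≥ 0
```

The log-determinant is evaluated on the k×k Gram matrix `WᵀW + I_k`
(Cholesky); by Sylvester's determinant identity this equals the 96×96 form,
so the choice of identity dimension is immaterial (verified in the tests).
Non-negativity of `W` is enforced by projection (clipping at zero) after
every optimizer step. Optimization is minibatch Adam with early stopping on
a held-out fraction of rows; the parameters of the best monitored epoch are
restored.

A nonlinear encoder can capture interactions that a purely linear
factorization cannot, while the linear non-negative decoder keeps the
signatures interpretable as additive, non-negative spectra.

### Numerical choices in the network

These choices are not part of the conceptual model but matter in practice;
all are config flags.

* **Burden-scaled latent** (`burden_scaled_latent`, default on). The latent
  activation output is multiplied by the sample's total mutation burden
  `N_g`, so the encoder codes *relative* signature activities of order
  `1/k` and `z Wᵀ` sits on the count scale from the first epoch. Without
  this, a generic initialization starts the Poisson means orders of
  magnitude below the data and Adam spends most of its budget inflating
  scales.
* **Latent activation**: softplus. A hard ReLU latent can put a sample in a
  zero-gradient dead zone permanently (observed in practice: the refit of a
  small cohort stalls with one genome assigned zero everywhere); softplus
  has the same non-negativity contract without the dead zone. When a
  rectified-linear latent is explicitly requested (`latent_activation =
  "relu"` without latent batch norm), the latent bias is initialized at
  +0.5 so no unit is born dead.
* **Latent batch normalization** (`latent_batchnorm`): optional batch norm
  on the latent pre-activation. In multi-restart de novo training it
  prevents collapsed signature columns (a latent unit drifting far negative
  and never recovering) and empirically removed essentially all bad local
  optima in repeated-seed trials; it is on in the fast extraction profile.
  It is *off* during exposure refitting, where forcing each latent
  dimension towards zero mean across the batch fights the count-scale
  coding of exposures.
* **Batch-norm inference statistics** (`bn_inference`, default `"batch"`).
  Evaluation uses the statistics of the evaluated batch (transductive)
  rather than running averages. With short training schedules the running
  averages lag the fast-moving weights, and on degenerate inputs (all rows
  identical, hence zero within-batch variance) the mismatch amplifies
  through the layers and explodes the monitored loss. All package-level
  evaluations operate on whole catalogues, where batch statistics are well
  defined; `"running"` mode is available.
* **Decoder warm start** (`decoder_warm_start`, `"random"` by default,
  `"nmf"` in the extraction profiles). With `"nmf"`, each training run
  seeds its decoder with the profiles from a short Kullback–Leibler NMF
  run (multiplicative updates, default 200 iterations, on at most 2000
  randomly chosen training rows) started from that run's own random state.
  The autoencoder's gradient optimization then refines within the basin.
  The warm start is itself a random restart — different seeds give
  different NMF trajectories — so multi-restart stability selection keeps
  its meaning: above the true `k`, warm starts disagree and the silhouette
  filter still rejects the solution. Without the warm start, a noticeable
  fraction of gradient-only runs stall in poor local optima (mixed or
  duplicated signature columns), which poisons the consensus silhouettes
  at exactly the true `k`.
* **Decoder freeze phase** (`decoder_freeze_epochs`, 30 in the extraction
  profiles). The warm-started decoder is held fixed for an initial phase
  while the randomly initialized encoder learns to invert it; otherwise
  the encoder's arbitrary early latent codes generate gradients that
  destroy the warm start within a few epochs.
* **Poisson log clamp**: `log(x̂ + ε)` with ε = 1e-7.
* **Learning rate**: constant by default. A cosine-decay option exists but
  is not used by the extraction profiles: multi-restart runs escape poor
  early basins late in training at a constant rate, and decaying the rate
  measurably increased the frequency of bad restarts.

## De novo extraction (model selection)

`DeNovoSignatureModel(catalogue, config).fit()` runs the NMFk-style
procedure:

1. **Bootstrap augmentation.** Each genome `g` with burden `N_g` and channel
   frequencies `p_g` is resampled `t` times from `Multinomial(N_g, p_g)`.
   This multiplies the effective training-set size and injects exactly the
   sampling noise the Poisson model assumes.
2. **Multi-restart training.** For each candidate `k` in `k_range`, `n`
   models are trained from independent initializations on the augmented
   catalogue. Each run keeps its decoder `W_i^k` and the Frobenius
   reconstruction error `E_rec = ‖C − Ĉ‖_F` measured on the *original*
   catalogue.
3. **K-means with matching.** The `n·k` signature estimates are grouped
   into `k` clusters of exactly `n` members: centroids start from the
   lowest-error run; each iteration solves, per run, the k×k linear
   assignment problem (Jonker–Volgenant, `scipy.optimize.
   linear_sum_assignment`) minimizing total `1 − cosine`, then recomputes
   centroids as normalized means, until assignments stabilize. Consensus
   signatures are the centroids, renormalized to sum 1.
4. **Silhouette filter.** Cluster quality is measured by silhouettes with
   distance `1 − cosine`. A solution passes when the average silhouette
   exceeds `th_avg` (default 0.9) and the minimum per-cluster mean
   silhouette exceeds `th_min` (default 0.7). For `k = 1` (one cluster,
   silhouette undefined) the score is one minus the mean intra-cluster
   cosine distance — 1 for identical restarts, decreasing with spread.
5. **Selection.** Among the passing solutions, `K*` minimizes the mean of
   the `n` per-run reconstruction errors, ties towards smaller `k`
   (parsimony). If nothing passes, the result is flagged unstable and falls
   back to the highest-average-silhouette `k`.

Design points that the procedure leaves open, resolved here: the per-`k`
error entering selection is the **mean** over the `n` runs (robust to a
single bad restart, per-run values retained); centroids initialize from the
lowest-error run (deterministic and quality-biased); columns are
L2-normalized for the cosine geometry of clustering and the final consensus
is sum-normalized (probability convention).

### Scale profiles

`ExtractionConfig()` defaults to the production setting `t = 100`,
`n = 100`. `ExtractionConfig.fast_profile()` is the desk-scale profile used
by the test suite and the acceptance script: `t = 10`, `n = 15`,
`k ∈ 1..8`, batch size 256, learning rate 7e-3, at most 120 epochs with
patience 30, latent batch norm on. These sizes were chosen so a full
selection sweep trains a few hundred networks in minutes on a single CPU
core while still recovering planted signature sets reliably.

## Exposure refitting (assignment)

Given fixed signatures `S`, `ExposureModel(catalogue, S, config).fit()`
normalizes `S` column-wise, loads it into the decoder, freezes the decoder
(bit-identical on return, asserted in tests), and trains only the encoder
under the Poisson likelihood plus two L1 penalties: `l1_weights` (default
1e-4) on the final encoder layer's weights and `l1_activity` (default
1e-3) on the non-negative latent output. The penalties push genomes to use
few signatures, countering over-assignment. Because the frozen profiles are
column-stochastic, `z Sᵀ` has the same row sums as `z`, so the latent lives
on the mutation-count scale; `rescale_rows` (default off) additionally
forces each genome's exposures to sum exactly to its observed burden.
Early stopping watches the training loss (the refit data are the data of
interest; no validation split), patience 50. The minimum-volume term is
dropped — with `W` frozen it is an exact constant.

## Synthetic cohorts

The simulator draws, per sample: a total burden from a log-normal (default
log-mean `ln 3000`, log-sd 1.0 — the scale of whole-genome SBS burdens);
an active-signature set by independent Bernoulli draws from the subcohort's
prevalences (a sample that switches nothing on falls back to its
subcohort's most prevalent signature); relative activities from a Dirichlet
proportional to the subcohort's burden weights (concentration 1.0,
uninformative); integer exposures as a multinomial split of the burden; and
channel counts as the sum of per-signature multinomial draws (or Poisson
with matching means). Ground truth (profiles, exposures, labels) is
recorded exactly as drawn.

Five templates (`scenario1` … `scenario5`) mirror the standard benchmark
designs for extraction tools: a single-cancer-type cohort with 11
signatures; a flat-signature two-subcohort mix (11); an
overlapping-signature mix (11); a two-subcohort design with only 3
signatures in total; and a nine-type pan-cancer style cohort with 21
signatures (300 samples per type). Reference signature sets (e.g. COSMIC)
are not bundled — they require download and carry licence terms — so
well-separated random profiles from `generate_signatures` (rejection
sampling of sparsified Dirichlet draws under a pairwise-cosine cap) stand
in by default, and any 96×k signature TSV can be supplied instead. What the
templates therefore do **not** emulate is the exact spectral shape of
specific catalogued signatures (e.g. the near-flat or strongly overlapping
profiles of the real flat-signature designs); the similarity structure is
approximated through the pairwise-cosine cap (0.8 for the flat and
overlapping designs, 0.6 elsewhere). Passing recovery tests on these
cohorts demonstrates the machinery end to end under the model's own
assumptions — multinomial channel noise, exact low-rank structure, no
sequencing artefacts or strand bias — and is not evidence about any
particular real signature.

## Evaluation harness

Extracted profiles are matched one-to-one to ground truth by the Hungarian
algorithm on cosine similarity (`min(k_est, k_true)` pairs). At a threshold
τ, a matched pair with cosine ≥ τ is a true positive; remaining truth
columns are false negatives and remaining estimates false positives, so
`TP+FN = k_true` and `TP+FP = k_est` at every τ. Precision, sensitivity and
F1 are computed on a grid over [0.8, 1] (default step 0.01) and summarized
by the trapezoidal area under each curve divided by the grid width
(perfect recovery ⇒ 1). F1 is defined as 0 when precision and sensitivity
are both 0. An exact cosine of 1 is compared with a 1e-12 tolerance so that
identical profiles count as recovered at τ = 1.

Exposure usefulness is quantified by tumour-type classification: classes
with fewer than 10 samples are dropped, then a random forest (500 trees,
class-balanced weights) is evaluated under stratified 5-fold
cross-validation, reporting Matthews correlation, Cohen's kappa and
balanced accuracy (mean ± SD over folds). The forest settings are explicit
stand-ins, configurable.

## Problem sizes

The acceptance script (`scripts/acceptance.py`) recomputes three
quantities from scratch: the Monte-Carlo random-cosine baseline (10,000
pairs); `K*` on a 400-sample two-subcohort cohort with 3 planted signatures
(`t=10, n=15, k ∈ 1..8`); and `K*` on a 500-sample cohort with 11 planted
signatures (`t=10, n=10, k ∈ 5..15`). These sizes train ~230 networks in
total and complete on one CPU core in well under half an hour. The
production profile (`t = n = 100`, wider `k` ranges) is the setting
intended for real cohorts and scales linearly in `t·n·|k_range|`.

## Using external benchmark and reference data

Nothing external is required to build or test the package, but the same
harness runs unchanged on real data when it is available locally:

* a real benchmark cohort (e.g. the published synthetic-scenario catalogues
  distributed with other extraction tools) can replace a simulated one —
  `sigxae extract --input <catalogue.tsv>` accepts any SBS-96 TSV, and
  `sigxae evaluate --estimated <extracted.tsv> --truth <known.tsv>`
  scores the result against the scenario's known signature file;
* a reference signature set (COSMIC- or Signal-style 96×k TSV) can be
  passed to `sigxae simulate --signatures` to plant real profiles instead
  of random ones, or used as the `--truth` side of `evaluate` to match de
  novo extractions against the catalogued signatures;
* full-scale cohort extractions use the default production profile
  (`t = n = 100`) rather than `--profile fast`.

These full-size runs are hours-long, full-cohort computations and are not
part of the test suite; the desk-scale acceptance targets stand in for
them.

## Known limitations

* The simulator's noise model matches the extractor's likelihood; real
  catalogues contain contamination, sequencing artefacts and
  signature-profile drift the benchmark cannot probe.
* Silhouette thresholds (0.9/0.7) are conventions, not estimates; cohorts
  with genuinely unstable processes may yield a flagged fallback selection
  rather than a confident `K*`.
* Training is single-threaded numpy; very large cohorts (tens of
  thousands of augmented rows) are feasible but slow compared to a GPU
  implementation.
* Exposure refitting returns a point estimate; no uncertainty is attached
  to per-genome attributions.
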