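# sigxae

De novo extraction of mutational signatures from SBS-96 cancer mutation
catalogues with an **explainable autoencoder**: a nonlinear encoder over a
linear, non-negative, minimum-volume-regularized decoder, trained under a
Poisson likelihood, with multinomial-bootstrap data augmentation and
consensus-clustering model selection. The package also refits exposures
onto a fixed signature set with sparsity penalties, simulates benchmark
cohorts with known ground truth, and scores signature recovery and
exposure-based tumour classification.

**Who it is for.** Cancer-genomics analysts who have an SBS-96 count matrix
(samples × 96 trinucleotide-context channels, COSMIC-style TSV) and want
(1) the number and profiles of the mutational processes active in the
cohort, (2) per-genome attributions (exposures), and (3) a way to benchmark
the whole procedure on simulated cohorts where the truth is known.

## The model

A genome's 96-channel count vector `x` is encoded to a non-negative latent
vector `z` (the exposures) by a three-hidden-layer network (batch norm +
softplus) and decoded linearly, `x̂ = z Wᵀ`, with `W ≥ 0` (96 × k); the
columns of `W` are the signatures. Training minimizes

    L(x, x̂) = Σ( −x·log x̂ + x̂ ) + β·log det(W Wᵀ + I),   W ≥ 0,

i.e. a Poisson negative log-likelihood for the counts plus a minimum-volume
penalty that favours tight, identifiable signature simplices. The number of
signatures K\* is selected NMFk-style: the catalogue is augmented by
multinomial bootstrap (factor `t`), the model is trained `n` times per
candidate k, the n·k decoder columns are clustered into k equal-size
clusters by linear-assignment matching on cosine distance, solutions whose
silhouettes fall below thresholds are discarded, and K\* is the surviving k
with the lowest mean reconstruction error on the original catalogue. See
`docs/methods.md` for the full procedure and all numerical choices.

## Worked example

Simulate a two-subcohort cohort from three planted, well-separated
signatures, then extract de novo:

```python
import numpy as np
from sigxae import (DeNovoSignatureModel, generate_cohort,
                    generate_signatures, match_signatures, scenario_template)
from sigxae.extraction import ExtractionConfig

signatures = generate_signatures(3, max_pairwise_cosine=0.6, seed=11)
spec = scenario_template("scenario4", scale=0.4, seed=5)   # 2 x 200 samples
catalogue, truth = generate_cohort(spec, signatures)

model = DeNovoSignatureModel(catalogue,
                             ExtractionConfig.fast_profile(base_seed=1))
result = model.fit()
print(result.summary())
```

```
De novo signature extraction
==============================
 k silhouette_avg silhouette_min mean_erec  passes_filter  selected
 1         0.9999         0.9999  13632.21           True     False
 2         0.9999         0.9997   6147.29           True     False
 3         0.9086         0.8139   2365.57           True      True
 4         0.5728        -0.6580   2516.89          False     False
 5         0.3266        -0.6923   3483.88          False     False
 6         0.1632        -0.7252   4142.62          False     False
 7         0.1085        -0.6182   5056.81          False     False
 8        -0.0016        -0.5647   5713.54          False     False
Selected K* = 3 (stable; thresholds avg>0.9, min>0.7)
```

Reading the table: k = 1..3 give highly stable consensus clusters
(silhouettes near 1) because the data really contain three processes;
k ≥ 4 restarts disagree (low/negative silhouettes) and are filtered out.
Among the stable candidates, k = 3 has the lowest reconstruction error on
the original catalogue, so K\* = 3 — the planted number. The consensus
profiles match the planted ones almost exactly:

```python
match = match_signatures(result.signatures, truth.signatures)
print([round(c, 3) for _, _, c in match.pairs])   # [1.0, 0.998, 0.999]
```

Exposures for the selected signatures are then refit with a frozen decoder
and sparsity penalties:

```python
from sigxae import ExposureModel
exposures = ExposureModel(catalogue, result.signatures).fit().exposures
```

## Command line

Each subcommand honours `--seed` and writes a JSON run manifest next to its
outputs:

```sh
sigxae simulate --template scenario4 --scale 0.4 --seed 5 --out sim/
sigxae extract  --input sim/catalogue.tsv --profile fast --seed 1 --out ex/
sigxae assign   --input sim/catalogue.tsv --signatures ex/signatures.tsv --out as/
sigxae evaluate --estimated ex/signatures.tsv --truth sim/true_signatures.tsv --out ev/
sigxae classify --exposures as/exposures.tsv --labels sim/labels.tsv --out cl/
```

`--profile fast` uses the desk-scale extraction setting (t=10, n=15); the
default profile is the production setting (t=100, n=100).

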