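# seqlift

**Lifting landmark expression profiles to RNA-seq-like full transcriptomes.**

High-throughput perturbational screens measure only ~1000 "landmark" genes
per profile (the L1000 assay), while most downstream analysis — signature
search, pathway enrichment, cross-study integration — wants full-genome
RNA-seq-scale profiles. `seqlift` implements a two-step deep-learning
pipeline that bridges that gap **without any paired training samples**,
together with the baselines, metrics, signature tools and synthetic
benchmarks needed to validate it:

1. **Domain translation (CycleGAN).** Two generators
   *G*: X→Y and *F*: Y→X map landmark-space profiles between the
   L1000-like domain X and the RNA-seq-like domain Y, trained against two
   least-squares discriminators *D_X*, *D_Y* on *unpaired* pools under

   *L* = *L*<sub>GAN</sub>(G, D_Y) + *L*<sub>GAN</sub>(F, D_X)
   + λ<sub>cyc</sub> *L*<sub>cyc</sub>(G, F)
   + λ<sub>identity</sub> *L*<sub>identity</sub>(G, F),

   with λ<sub>cyc</sub> = λ<sub>identity</sub> = 10, MSE-form cycle and
   identity penalties, Adam, and ReLU on the generator outputs so
   expression never goes negative.

2. **Full-genome extrapolation (FCNN).** A fully connected network takes
   RNA-seq-like landmark profiles and predicts every remaining gene
   (MSE objective, Adam at 2·10⁻⁴, batch 100, early stopping with
   patience 3, rectified output), exploiting the strong gene–gene
   correlation structure of transcriptomes.

Around the core: GCT 1.2 / GMT / TSV readers and writers, count
filtering + log2 + quantile normalization, ratio-scaling and
linear-regression baselines, sample-/gene-wise PCC–SCC–RMSE benchmarking
with random-pairing nulls, PCA domain embedding,
characteristic-direction (CD) and fold-change signatures computed per
batch, bridge-walk gene-set enrichment with permutation p-values, and a
gene-centric reverse search over signature collections. A seeded
synthetic-data module generates cross-platform worlds with known ground
truth so every claim is testable at desk scale. The neural networks are
implemented directly on numpy — at these dimensions explicit matrix
backpropagation on a CPU is fast and bit-reproducible.

## Worked example

```python
from seqlift import (CycleGANConfig, paired_metrics, random_pairing_metrics,
                     simulate_world, train_translator, translate)

world = simulate_world(n_genes=300, n_landmark=50, n_factors=10,
                       n_train_per_domain=1000, n_paired=200,
                       noise_sd=0.1, distortion_strength=1.0, seed=7)
y_pool = world.y_train.subset_genes(world.landmark_ids, space="landmark")
model = train_translator(world.x_train, y_pool,
                         CycleGANConfig(hidden_units=128, epochs=60, seed=7))
translated = translate(model, world.paired_eval_x)
truth = world.paired_eval_y_landmark
print(paired_metrics(translated, truth, "sample_wise").summary["pcc_mean"])
print(paired_metrics(world.paired_eval_x, truth, "sample_wise").summary["pcc_mean"])
print(random_pairing_metrics(translated, truth, "sample_wise", seed=1)
      .summary["pcc_mean"])
```

prints (seed 7, 60 epochs):

```
0.9653567538848091   # translated vs paired truth
0.7524852187914496   # raw platform-distorted input vs truth
0.8208044417350231   # translated vs randomly re-paired truth
```

The translated profiles recover the paired ground truth far better than
the raw input (mean sample-wise Pearson r 0.97 vs 0.75) and better than
a random-pairing null (0.82) — the translator has learned to invert the
per-gene platform distortion from unpaired data alone. The
`examples/` directory contains one short script per capability
(preprocessing, translation, extrapolation, signatures + bridge walks,
reverse search), each printing the numbers it computes.

A thin CLI mirrors the library:
`seqlift simulate | preprocess | train-translator | translate |
train-extrapolator | extrapolate | baseline | evaluate | pca |
signatures | bridge | gene-search` (see `seqlift --help`).

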