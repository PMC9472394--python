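"""Compute differential-expression signatures and bridge-walk enrichment.

Simulates a batched perturbation study in which treatment samples gain
+2 log2 units on a 20-gene target set, computes per-batch
characteristic-direction signatures (treatment vs same-batch controls),
and walks the top-ranked genes against the true target set and against
size-matched random sets.
"""

import numpy as np

from seqlift import (batch_signatures, bridge_null, simulate_perturbation_study,
                     simulate_world)

world = simulate_world(n_genes=300, n_landmark=50, n_factors=10,
                       n_train_per_domain=100, n_paired=50,
                       noise_sd=0.1, distortion_strength=1.0, seed=7)
study = simulate_perturbation_study(world, n_batches=5, treat_per_batch=5,
                                    control_per_batch=5, target_set_size=20,
                                    effect_size=2.0, seed=9)

signatures = batch_signatures(study.profiles, study.metadata, "drugA",
                              method="cd")
print(f"{len(signatures)} batch signatures computed")

ranked = signatures[0].ranked_genes()
observed = bridge_null(ranked, study.target_set, n_permutations=200, seed=3)
print(f"target set : bridge peak = {observed.peak:.3f}, "
      f"permutation p = {observed.p_value:.4f}")

rng = np.random.default_rng(5)
random_ps = []
for _ in range(10):
    rand_set = set(rng.choice(world.full_truth.gene_ids, 20, replace=False))
    random_ps.append(bridge_null(ranked, rand_set, n_permutations=200,
                                 seed=3).p_value)
print(f"random sets: median permutation p = {np.median(random_ps):.3f}")
# A peak near 1 means the spiked genes crowd the very top of the CD
# ranking; the permutation p-value confirms the enrichment is far beyond
# chance, while size-matched random sets stay at chance level.
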