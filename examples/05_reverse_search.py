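"""Gene-centric reverse search: which perturbations move my gene?

Builds a signature collection in which exactly one batch up-regulates
the query gene, then asks the reverse search to find it. The search
ranks signatures by a rank-sum over three criteria: the gene's log2
fold change, its CD coefficient and its within-signature rank.
"""

from seqlift import (batch_signatures, reverse_search,
                     simulate_perturbation_study, simulate_world)

world = simulate_world(n_genes=200, n_landmark=30, n_factors=8,
                       n_train_per_domain=50, n_paired=30,
                       noise_sd=0.1, distortion_strength=1.0, seed=7)

# background: four null batches; foreground: one batch spiking 5 genes
null_study = simulate_perturbation_study(world, n_batches=4, treat_per_batch=5,
                                         control_per_batch=5,
                                         target_set_size=0, effect_size=0.0,
                                         seed=11)
active_study = simulate_perturbation_study(world, n_batches=1,
                                           treat_per_batch=5,
                                           control_per_batch=5,
                                           target_set_size=5, effect_size=2.0,
                                           seed=12)

signatures = batch_signatures(null_study.profiles, null_study.metadata, "drugA")
active = batch_signatures(active_study.profiles, active_study.metadata, "drugA")
active[0].signature_id = "drugA_active_batch"
signatures += active

query = sorted(active_study.target_set)[0]
up, down, volcano = reverse_search(query, signatures, top_k=3)

print(f"query gene: {query}")
print("top up-regulating signatures:")
print(up[["signature_id", "log2fc", "cd_coefficient", "rank"]].to_string(index=False))
print(f"\nvolcano coordinates (x = log2FC, y = |CD|), "
      f"{int(volcano.discordant.sum())} sign-discordant signatures")
# The spiked batch tops the up-table: the query gene has the largest fold
# change, the largest CD coefficient and the best within-signature rank
# there, so the rank-sum places it first.
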