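"""Generate a small planted dataset, score every pair, rank candidates.

The generator plants matched miRNA/disease blocks: associations are common
inside a matched block and rare outside, and the four similarity kernels
are noisy reflections of the same blocks. A good score should push a
disease's unverified same-block miRNAs to the top of its candidate list.
"""

import mirfusion as mf

spec = mf.SyntheticSpec(n_mirna=30, n_disease=20, n_groups=4, seed=7)
assoc, kernels = mf.generate(spec)
print(f"dataset: {assoc.n_mirna} miRNAs x {assoc.n_disease} diseases, "
      f"{assoc.n_associations} known associations")

# reference weights (alpha=beta=0.02, gamma=0.27) with the neighbor count
# scaled to the instance: k must be well below the matrix dimension for the
# sparse kernels and agreement weights to do any pruning
cfg = mf.ModelConfig(fusion=mf.FusionConfig(k_neighbors=8))
scores = mf.predict_full(assoc, kernels, cfg)

disease = assoc.disease_names[0]
top = mf.rank_candidates(scores, disease, top_n=5)
print(f"\ntop 5 candidate miRNAs for {disease} (known pairs excluded):")
for mirna, score in top:
    group = (assoc.mirna_names.index(mirna)) % spec.n_groups
    print(f"  {mirna}  score={score:.4f}  block={group}")
print(f"\n{disease} sits in block 0; same-block candidates at the top mean "
      "the planted structure was recovered.")
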