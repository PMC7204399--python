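"""Leave-one-association-out cross-validation with a permutation null.

Each known association is masked in turn; the whole pipeline (Hamming
kernels, fusion, weighted networks, projections) is recomputed on the
masked data and the held-out pair's score is pooled against all unknown
pairs. The AUC is compared with a 200-replicate label-permutation null: a
method with no signal lands inside the null band around 0.5.
"""

import numpy as np

import mirfusion as mf

assoc, kernels = mf.generate(mf.SyntheticSpec(n_mirna=30, n_disease=20, seed=7))
# neighbor count scaled to the instance (see example 01)
cfg = mf.ModelConfig(fusion=mf.FusionConfig(k_neighbors=8))

report = mf.loocv(assoc, kernels, cfg)
null = mf.permutation_null(report, n_replicates=200, seed=8)
lo, hi = np.percentile(null, [2.5, 97.5])

print(f"LOOCV over {len(report.fold_records)} folds")
print(f"pooled AUC          : {report.auc:.4f}")
print(f"permutation null    : [{lo:.4f}, {hi:.4f}] (95% band)")
print(f"signal recovered    : {report.auc > hi}")
print("\nAn AUC above the null band means held-out associations outrank "
      "unknown pairs more often than label-shuffled chance allows.")
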