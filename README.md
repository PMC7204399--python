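# mirfusion

Ranking candidate miRNA–disease associations by multi-kernel similarity
fusion and bipartite space projection.

Experimentally verified miRNA–disease links are sparse: most pairs in a
curated catalog are simply untested. `mirfusion` is for computational
biologists who want to prioritize which untested pairs to validate next,
given (a) a Boolean association matrix **MD** (n_m miRNAs × n_d diseases)
and (b) precomputed similarity kernels — miRNA functional and sequence
similarity, disease semantic and functional similarity — as produced by
standard resources. No negative training samples are needed, and entities
with no known associations (new miRNAs, isolated diseases) can be scored.

## The model

Per side, three kernels (the two supplied ones plus a Hamming kernel
computed from association profiles, `DDhs(i,j) = 1 − Hamming(MD(·,i),
MD(·,j))/n_m`) are fused by sparse-kernel cross-diffusion: each kernel is
restricted to k-nearest-neighbor support and row-normalized (P), each is
ratio-normalized against the sum of all three, and for t rounds each
diffuses through its own sparse kernel against the average of the other
two,

    S_x ← δ · P_x ((S_y + S_z)/2) P_xᵀ + (1−δ)(S̄_y⁰ + S̄_z⁰)/2.

The rounds' average, sharpened by a mutual-neighbor agreement weight
(1 / 0.5 / 0), gives the integrated kernels MM* and DD*. These reweight the
Boolean network,

    MDm(i,j) = MD(i,j) + α Σ_{k≠i} MM*(i,k) MD(k,j),
    MDd(i,j) = MD(i,j) + β Σ_{k≠j} MD(i,k) DD*(k,j),

and each pair is scored by projecting the enriched profiles onto the
similarity spaces:

    Fpf = (1−γ) Fpmᵀ + γ Fpd,   Fpm(i,j) = ⟨MDdᵀ(i,·), MM*(·,j)⟩/‖MM*(·,j)‖,
                                Fpd(i,j) = ⟨MDm(i,·), DD*(·,j)⟩/‖DD*(·,j)‖.

Defaults α=β=0.02, γ=0.27, k=36, t=10, δ=0.1. See `docs/methods.md` for
assumptions, evaluation protocols, and limitations.

## Worked example

`examples/01_simulate_and_score.py` plants block structure (matched
miRNA/disease groups with common within-block associations and kernels
correlated with the blocks), scores all pairs, and ranks candidates:

```
dataset: 30 miRNAs x 20 diseases, 67 known associations

top 5 candidate miRNAs for d001 (known pairs excluded):
  m001  score=1.4895  block=0
  m029  score=1.4476  block=0
  m017  score=1.3868  block=0
  m023  score=0.4127  block=2
  m019  score=0.3190  block=2
```

Disease `d001` belongs to planted block 0; its three top-ranked unverified
candidates are exactly the block-0 miRNAs, with a clear score gap to
out-of-block candidates — the planted structure was recovered.
`examples/02_cross_validation.py` masks each known association in turn,
recomputes the whole pipeline per fold, and pools one ROC:

```
LOOCV over 67 folds
pooled AUC          : 0.8475
permutation null    : [0.4197, 0.5638] (95% band)
signal recovered    : True
```

An AUC of 0.85 against a label-permutation null band around 0.5 means
held-out associations outrank unknown pairs far more often than chance.
The other examples cover the new-miRNA / isolated-disease protocols and
parameter sweeps.

The same operations are exposed as a CLI for file-based workflows:

```sh
mirfusion simulate --out-dir data --seed 7
mirfusion loocv --data-dir data --out-dir report
mirfusion rank --data-dir data --disease d003 --top 50 --out top50.tsv
```

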