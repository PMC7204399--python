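# Methods

`mirfusion` ranks candidate miRNA–disease associations from a Boolean
bipartite association matrix **MD** (n_m miRNAs × n_d diseases) and four
externally supplied similarity kernels: miRNA functional and sequence
similarity, disease semantic and functional similarity. A fifth kernel per
side — Hamming similarity of association profiles — is computed internally.
The model has three stages: multi-kernel fusion, weighted-network
construction, and space projection.

## Hamming similarity

For two diseases i, j with profile columns MD(·,i), MD(·,j), the Hamming
similarity is

    DDhs(i,j) = 1 − #{k : MD(k,i) ≠ MD(k,j)} / n_m,

and symmetrically for miRNAs on rows of MD. Mismatch counts are accumulated
in integer arithmetic so the kernel is exact and exactly symmetric. Two
all-zero profiles (which arise whenever an entity's associations are fully
masked) have similarity 1 — the formula's verdict, kept deliberately.
Because the Hamming kernels are functions of MD, they are **recomputed
inside every cross-validation fold** from the masked matrix; this is the
reference protocol (see Evaluation).

## Multi-kernel fusion

Three kernels per side are fused by sparse-kernel cross-diffusion:

1. **Sparse kernel.** For each entity i, the neighbor set N_i holds the k
   entities with the largest similarity to i (self always included; ties at
   the k-th rank broken by ascending entity index so results are
   platform-independent). Then P(i,j) = S(i,j) / Σ_{l∈N_i} S(i,l) on N_i
   and 0 elsewhere; a zero-mass row falls back to P(i,i)=1.
2. **Initial status.** Each kernel is ratio-normalized entrywise against
   the sum of all three: S̄_x(i,j) = S_x(i,j) / (S_a+S_b+S_c)(i,j). Where
   the three-way sum is zero all three outputs are 0 (no similarity is
   invented; the alternative, 1/3, would create mass where none exists).
3. **Cross-diffusion.** For t rounds, each kernel x with companions y, z is
   updated as

       next_x = δ · P_x ((cur_y + cur_z)/2) P_xᵀ + (1−δ) (init_y + init_z)/2,

   with all three next-states computed from the same previous states
   (Jacobi-style), so the result does not depend on an update order. The
   three kernels play fully symmetric roles, which also makes the fusion
   invariant to the order kernels are passed in. δ=0 is a useful limit:
   every kernel collapses to the constant average of the other two initial
   statuses after one round.
4. **Agreement weighting.** The three diffused kernels are averaged into
   S_temp, and a weight matrix W — computed from S_temp's k-nearest
   neighborhoods — is applied elementwise: W(i,j)=1 for mutual neighbors,
   0 when neither is a neighbor of the other, 0.5 one-sided. S* = S_temp ∘ W.
   S_temp is the natural neighborhood authority here because the three
   pre-fusion kernels each carry incompatible neighborhoods of their own.

Defaults: k=36 neighbors (applied to both sides, clamped to the matrix
dimension on small instances), t=10 rounds, δ=0.1. t counts update rounds
performed before the averaging in step 4.

## Weighted networks and space projection

With fused kernels MM* (miRNA) and DD* (disease):

    MDm(i,j) = MD(i,j) + α Σ_{k≠i} MM*(i,k) MD(k,j)
    MDd(i,j) = MD(i,j) + β Σ_{k≠j} MD(i,k) DD*(k,j)

propagate each entity's neighbors' associations into the Boolean network
(self-terms excluded; α=0 or β=0 returns MD exactly). Scores project these
enriched profiles onto the opposite similarity space:

    Fpm(i,j) = ⟨MDdᵀ(i,·), MM*(·,j)⟩ / ‖MM*(·,j)‖      (disease × miRNA)
    Fpd(i,j) = ⟨MDm(i,·),  DD*(·,j)⟩ / ‖DD*(·,j)‖      (miRNA × disease)
    Fpf      = (1−γ) Fpmᵀ + γ Fpd.

The norm is Euclidean (the natural reading of an unannotated vector norm);
a zero-norm similarity column scores 0 rather than dividing by zero — it
cannot occur with positive fused diagonals but degenerate synthetic inputs
must not crash. Fpf is affine in γ; γ=0 keeps only the miRNA-space
projection, γ=1 only the disease-space projection. Scores are **not**
zeroed at known-association positions; the score matrix carries the MD it
was computed from (`known_mask`) so that ranking and evaluation exclude
verified pairs without redefining the score.

Defaults α=β=0.02, γ=0.27 — the operating point at which the method was
originally calibrated on curated human data.

## Evaluation protocols

All protocols are **global**: positives and their candidate scores from all
folds are pooled into one threshold-sweep ROC, and AUC is the trapezoidal
area (identical to the tie-aware Mann–Whitney statistic, a property the
test suite asserts by brute force). Per-fold records (held-out identity,
score, number of outranking candidates) are retained so local variants can
be derived.

* **Pair LOOCV** masks each known pair in turn, recomputes Hamming kernels,
  fusion, weighted networks and scores on the masked matrix, and pools the
  held-out score against the scores of every pair unknown in the original
  data, rescored in the same fold. A `fast_loocv` flag skips the per-fold
  kernel/fusion recomputation (recomputing only the networks and
  projections); it is clearly non-reference and agrees with the reference
  exactly only when masking cannot alter the fused kernels.
* **New miRNA / isolated disease** mask a whole row/column, recompute
  everything, and score the entity's true associations against its own
  unknown pairs.
* **Parameter sweep** reruns pair LOOCV over an (α=β, γ) grid (α and β tied
  by default, the way the weighting parameters were originally explored);
  an untied product grid is available.

Candidate negatives are always pairs unknown in the *original* data, and
they are rescored within each fold — the conservative reading when the
alternative (scoring negatives once on full data) is also defensible. The
input association matrix is restored after every protocol; tests assert
this and that masking a pair really changes that fold's Hamming kernel.

## Synthetic data

The generator plants matched blocks: miRNAs and diseases are assigned
round-robin to g groups; MD(i,j) ~ Bernoulli(p_in) when groups match, else
Bernoulli(p_out). Each external kernel is
`kernel_signal · block_indicator + (1 − kernel_signal) · 0.5` plus
symmetric Gaussian noise (sd `noise_sd`), symmetrized before clipping to
[0,1] so symmetry is exact, diagonal forced to 1. The background constant
0.5 keeps unrelated-pair similarities mid-scale, where the ratio
normalization treats all three kernels comparably. Defaults: 60×40, 4
groups, p_in=0.4, p_out=0.02, kernel_signal=0.7, noise_sd=0.1 — sized so
full-recompute LOOCV (~270 folds) runs in a few seconds. `p_in = p_out` is
allowed and expresses the no-signal null used in calibration checks.

The generator emulates block-structured association preferences and
correlated kernels; it does **not** reproduce real degree distributions,
ontology-induced similarity structure, or the sparsity (~2.9%) of curated
human data. Passing signal-recovery tests therefore demonstrates that the
pipeline extracts planted structure under noise, not that it attains any
particular accuracy on real catalogs.

## Numerical choices

* Canonical entity order is lexicographic over identifiers; all matrices
  are stored and processed in that order, making every run deterministic
  and file outputs byte-identical across repeats.
* Kernel files failing symmetry by more than 1e-8 are rejected (never
  silently averaged); diagonal drift within 1e-8 is snapped to 1.
* Score tables are written with shortest round-trip float representation
  and read back with round-trip parsing, so write→read is bit-exact.
* Neighbor ties, score ties in ranking (score desc, then identifier asc),
  and AUC ties (0.5 credit) all have fixed documented rules.

## Known limitations

* The cross-kernel ratio normalization compresses magnitude information:
  where all three kernels agree, the normalized entries approach 1/3
  regardless of how similar the pair actually is. Raw-kernel structure
  re-enters only through the sparse kernels (weight δ) and the agreement
  matrix W. Consequently, when k is close to the matrix dimension W prunes
  almost nothing and the fused kernel flattens. At the default acceptance
  conditions (40 diseases, k=36) this leaves isolated-disease ranking near
  chance while pair LOOCV and new-miRNA retain clear signal; with k well
  below the dimension (examples, k=8 at 30×20) both entity protocols
  recover the planted structure, the isolated-disease protocol remaining
  the weaker of the two. Choose k ≪ n when applying the model to small
  matrices.
* Full-recompute LOOCV is O(#associations) pipeline runs; use
  `fast_loocv` only when the fused kernels are insensitive to single-pair
  masking, and expect it to diverge from the reference otherwise.
* Scores are unbounded above (they are norm-scaled inner products, not
  probabilities) and are comparable within a run, not across datasets.
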