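# Methods

## Model and assumptions

`mvhknn` is a lazy binary classifier for numeric feature vectors. For a
query `x ∈ R^d` and each class `c` it collects the K Euclidean-nearest
class-`c` training points (ties broken by lower training index), stacks
them as columns of `V_c ∈ R^{d×K}`, and minimizes

    LH_c(α) = λ_r ||α||²
            + (1/λd) Σ_{j=1}^d exp{ λ [1 − κ_σ(x_j − V_{c,j} α)]^{p/2} }
            + μ α^T L*(β) α

over the reconstruction weights `α ∈ R^K`, assigning the class with the
smaller final objective (ties to the lower label). The middle term is
the kernel risk-sensitive mean p-power error (KRP) of the per-dimension
reconstruction residuals, with Gaussian kernel `κ_σ(e) = exp(−e²/2σ²)`.
It is bounded in `[1/λ, e^λ/λ]` and its derivative decays to zero for
large residuals, so grossly corrupted feature dimensions saturate
instead of dominating — the robustness mechanism that motivates the
model. The hyperplane is the *linear* span of the neighbours (no
affine/sum-to-one constraint on `α`), which is why the ridge term
matters: without it the span is scale-unbounded.

The graph term penalizes reconstruction weights that differ across
similar neighbours. Three similarity views — RBF `exp(−γ||x_i−x_j||²)`,
cosine, and Pearson correlation — each induce a graph on the K
neighbours in which an edge (f, g) exists only when f and g are mutual
K-nearest neighbours (judged over the whole class-`c` training subset by
default; a `mutual_scope="neighborhood"` flag restricts the pool to the
K neighbours themselves). Negative cosine/Pearson similarities are
clamped to zero so degrees stay non-negative, the diagonal is forced to
zero, and each view is normalized to `L_ij = −W_ij/√(D_ii D_jj)` with
unit diagonal on non-isolated nodes — a symmetric PSD operator with
spectrum in [0, 2]. The views are fused as `L*(β) = Σ_v β_v^ρ L_v` with
simplex weights `β`.

## The alternating fit

Per (query, class):

1. build the m view Laplacians once;
2. initialize `α ~ N(0, 1/K²)` entrywise under the run seed and
   `β = 1/m`;
3. per round: fuse `L*(β)`; compute the half-quadratic diagonal
   `Λ_jj = exp{λ[1−κ]^{p/2}} [1−κ]^{(p−2)/2} κ` at the current residuals;
   solve `(λ₁I + V^TΛV + λ₂L*) α = V^TΛx` with `λ₁ = 4σ²dλ_r/p`,
   `λ₂ = 4σ²dμ/p`; update
   `β_v ∝ trace(α^T L_v α)^{−1/(ρ−1)}`.

The linear solve is exactly the stationarity condition of `LH_c` at
frozen Λ and `L*`, so a fixed point of the alternation is a stationary
point of the objective (verified against finite differences and a
multi-restart general-purpose optimizer in the test suite). The scheme
is not provably monotone; empirically the final objective is at or below
the initial one in ≥ 95% of random fits, which the suite checks, and the
per-round objective trace is retained in the solver state for
inspection.

Two Λ variants exist. The `derivative_consistent` form above is the one
whose assembled gradient matches the true gradient of the KRP term (the
suite verifies this to 1e−5 against central differences). A variant
with middle exponent `p/2` instead of `(p−2)/2` circulates in the
literature; the two differ by a factor `(1−κ)` at every `p`, and the
variant is kept available as `lambda_mode="as_printed"` for comparison
only. At `p = 2` the consistent form has exponent zero, so exact
reconstructions need no special handling; for `p < 2` the factor
`(1−κ)` is floored at 1e−12 before the negative exponent to keep the
update finite at exact reconstruction.

## Parameters

| name | meaning | default | rationale |
|---|---|---|---|
| `λ_r` | ridge weight on `||α||²` | 0.01 | mild shrinkage; enters the solve as `λ₁ = 4σ²dλ_r/p` |
| `λ` (lam) | KRP risk sensitivity | 1 | canonical curve of the loss family |
| `σ` | KRP kernel bandwidth (units of one feature coordinate) | 1 | matches unit within-class noise; should be rescaled to the residual scale of real features |
| `p` | KRP power | 2 | the exponent at which the loss is smoothest to optimize |
| `μ` | graph-penalty weight | 0.01 | mild smoothing; `λ₂ = 4σ²dμ/p` |
| `ρ` | fusion exponent | 2 | smallest integer satisfying the ρ > 1 requirement of the β update |
| `γ` | RBF similarity width | 1/d | scale-free default |
| `K` | neighbourhood size | 5 | small enough that d > K holds for the intended feature scales |
| `iterations` | alternation rounds | 3 | the fixed point is reached quickly in practice and early stopping curbs overfitting; configurable, with an optional `alpha_tol` early stop (off by default) |
| `views` | similarity views | rbf, cosine, pearson | the three defined views, m = 3 |

`d > K` is required for the closed-form update to be well-posed and is
enforced as an error by default (`enforce_d_gt_K=False` demotes it to a
warning). Degenerate cases are handled deterministically: singular
linear systems fall back to the least-norm solution with a
`SingularSystemWarning`; a vanishing `trace(α^T L_v α)` caps that view's
unnormalized weight at 1e12 (the maximally smooth view dominates without
infinities); exactly equal traces return the uniform β exactly; MCC with
a zero marginal is reported as 0 with a `MetricWarning`; argmin ties in
classification and majority-vote ties in KNN resolve to the lowest class
label.

## Evaluation

ACC, SN, SP and MCC follow the standard confusion-matrix formulas; ROC
and AUC use the threshold sweep whose AUC equals Mann–Whitney pairwise
concordance with half credit for ties (cross-checked against an O(n²)
oracle in the tests). Cross-validation is stratified with a seeded
shuffle; the primary metrics pool out-of-fold confusion counts (per-fold
reports are retained) because pooling is deterministic and stable for
small folds. The ablation runner evaluates all four rungs — KNN, HKNN,
HKNN(KRP) (`μ = 0`), MvHKNN(KRP) — on identical fold assignments so rung
differences are paired. The binary ROC score is `LH_0 − LH_1` (class-1
vote fraction for KNN, score difference for squared-loss HKNN).

## Synthetic data: what it does and does not show

The generator produces two balanced isotropic Gaussian classes in `R^d`,
means `separation · within_sd` apart along a random direction and
symmetric about the origin; contamination displaces an exact count of
samples by `outlier_scale · within_sd` along random directions and/or
flips an exact count of labels (disjoint index sets, all recorded in
metadata). The default fixture — 100 samples per class, d = 50,
separation 6 — is an easy, high-dimensional problem on which the whole
ablation runs in seconds.

This emulates only the gross statistical shape of embedding feature
tables (balanced classes, high dimension, roughly isotropic noise). It
does not reproduce the anisotropic, heavy-tailed, strongly correlated
geometry of real learned embeddings, and the origin-symmetric placement
is mildly adversarial for linear-span hyperplanes (each class's span
contains scaled negatives of its points). Passing benchmarks here
demonstrates the machinery is correct and well-behaved, not that the
model ranks the same way on real peptide data.

One consequence measured by `scripts/acceptance.py` deserves emphasis:
with the default contamination (10% of samples displaced by 10 sd in
d = 50), displaced points land about as far away as the *typical*
nearest-neighbour distance of the clean cloud, so Euclidean neighbour
selection almost never admits them into a K = 5 neighbourhood. The
robust loss then has no corruption to suppress, while its boundedness
slightly compresses decision margins at σ = 1; the squared-loss HKNN can
come out marginally ahead on this benchmark. The KRP advantage is
expected in regimes where contamination actually reaches the
neighbourhoods (milder displacements, harder class overlap, or
bandwidths tuned to the residual scale) — a regime the default
benchmark, by construction, does not occupy.

## Problem sizes

The shipped test suite and acceptance script run the benchmark at the
default 200-sample scale: five-fold cross-validated ablation per seed,
five seeds for the clean benchmark, and twenty paired seeds of the
contamination experiment (100 training + 25 held-out samples per class
per seed). Unit and property tests use smaller instances (d ≤ 20,
n ≤ 100) chosen so each oracle comparison stays exact and the whole
suite completes in well under a minute per module.

## Known limitations

- Binary focus: multi-class inputs classify by per-class argmin, but the
  ROC score and the contamination tooling assume two classes.
- Lazy learning: every query costs O(nd) neighbour search plus O(dK²)
  per solver round and per class; no tree or approximate index is used.
- The alternation carries no descent guarantee; pathological
  objective/graph combinations could cycle (none observed in testing).
- `σ` is not auto-scaled to the data; features whose residuals are far
  from O(σ) put the loss in its saturated (uninformative) or quadratic
  (non-robust) regime.
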