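# Methods

`cmot` infers the unmeasured omics modality of single cells. The setting:
a set of *source* cells is profiled in two modalities X and Y (e.g.,
chromatin accessibility and gene expression), possibly with only partial
cell-to-cell correspondence between the two profiles; a set of *target*
cells is profiled only in modality Y. The goal is an inferred matrix X̂
giving each target cell's missing X profile. The pipeline has three
stages.

## Stage A — manifold alignment of the source modalities

When the two source profiles are not fully paired, X and Y cells are
embedded jointly on a shared d-dimensional manifold. Within-modality
geometry is captured by binary K-nearest-neighbor graphs W_X and W_Y
(Euclidean distances, symmetrized by max(A, Aᵀ), ties to the lower cell
index); known pairings enter as a binary correspondence matrix W. The
embedding minimizes

    μ Σ ||φ_X(x_i) − φ_X(x_k)||² W_X[i,k]
  + μ Σ ||φ_Y(y_j) − φ_Y(y_m)||² W_Y[j,m]
  + (1−μ) Σ ||φ_X(x_i) − φ_Y(y_j)||² W[i,j]

subject to PᵀDP = I, where P stacks both coordinate blocks and D is the
degree diagonal of the joint graph. This is the generalized eigenproblem
L v = γ D v on the joint Laplacian L = D − W_joint, solved densely
(`scipy.linalg.eigh`), which returns D-orthonormal eigenvectors so the
constraint holds to machine precision. Eigenvalues below a relative
threshold of 1e-9 are the per-component null directions and are dropped;
the next d eigenvectors form the embedding, with each eigenvector's sign
fixed so its first nonzero coordinate is positive. μ defaults to 0.5,
weighting geometry preservation and correspondence equally.

After alignment each Y cell borrows the X profile of its nearest X cell
in embedding space (ties to the lower index). Under full correspondence
the stage is skipped and X rows are used directly.

Two spectral caveats, reflected in how the package is tested: exact
co-location of corresponding cells under identical inputs holds when the
data lie on a smooth low-dimensional manifold, so the retained
symmetric modes fall below the cheapest antisymmetric joint-graph mode;
on unstructured (expander-like) inputs it can fail, which is a property
of the objective, not of the solver. Likewise, twin vertices (cells with
identical graph neighborhoods) receive identical embedding coordinates,
making nearest-neighbor matching between them arbitrary.

## Stage B — regularized optimal transport on the shared modality

Source cells Y and target cells Ŷ (matched features) are coupled by a
transport plan π minimizing

    ⟨π, C⟩_F − λ Ω_s(π) + η Ω_c(π)

over couplings with uniform marginals a = 1/s_Y, b = 1/s_Ŷ. C is the
pairwise squared-Euclidean cost divided by its maximum (scale-free,
entries in [0,1]). Ω_s is the transport entropy −Σ π log π; the entropic
problem is solved by Sinkhorn scaling. Ω_c = Σ_j Σ_c ||π(I_c, j)||₁^q
(q = 0.5) is a group-lasso penalty over source-class row blocks I_c that
pushes each target cell to draw its mass from a single class; classes
are prior cell types or, absent those, two Ward-linkage hierarchical
clusters of the source cells. The concave group penalty is handled by
majorization–minimization: each outer iteration adds its linearization
η·q·(||π_prev(I_c, j)||₁ + 1e-16)^(q−1) to the cost and re-solves the
entropic problem (default 10 outer iterations, inner Sinkhorn budget
1000, tolerance 1e-9 on the marginal residual). η = 0 short-circuits to
plain Sinkhorn, bitwise.

Parameter convention: the user-facing λ is a *sharpness* — the solver's
internal entropic weight is ε = 1/λ, so λ = 200 yields a near-LP, close
to sparse coupling while small λ gives the smooth high-entropy regime.
ε can be set directly (`epsilon=`) when the raw entropic weight is
wanted. When ε < 1e-2·mean(C) the scaling iterations run in the log
domain (logsumexp updates) to avoid underflow; the plan records which
path ran.

Mass-inconsistency note: with unit-vector marginals the printed
constraint set is infeasible for s_Y ≠ s_Ŷ; the package uses normalized
uniform marginals (standard discrete OT) and the barycentric map
row-normalizes, Y⁽ᵗ⁾ = diag(π1)⁻¹ π Ŷ, which reduces to π Ŷ exactly in
the unit-row convention. Each transported source cell is thus a convex
combination of target cells.

**Outlier screen.** Target cells from populations absent in the source
map poorly. The screen forms P = πᵀ ∘ Cᵀ (each target row holds the
cost it actually pays, weighted by received mass), projects P onto the
principal components explaining ≥ 95% of variance, and runs a seeded
isolation forest on the projection. Flagged cells stay in the output but
are marked, and a warning reports the flagged percentage. Fewer than 5
target cells: the screen is skipped (an ensemble on so few rows is
meaningless).

## Stage C — weighted kNN inference

For each target cell ŷ_j, its k nearest transported source cells S_j are
found by Euclidean distance (optionally restricted to a caller-chosen
feature subset such as the top highly variable genes; ties to the lower
source index). Neighbor l gets raw weight exp(−dist); weights are
normalized to sum to one so

    x̂_j = Σ_l w_j^l · x_{S_j[l]}

is a convex combination — every inferred value stays inside the source
hull per feature. exp(−√(‖·‖²)) is written as exp(−‖·‖), which is the
same quantity. Defaults (K = 5, d = 20, λ = 200, η = 1, k = 600) follow
a typical high-dimensional chromatin/expression configuration; k is
clamped to the number of source cells on small data, with a run-log
notice.

## Preprocessing

Deterministic, tool-free versions of the usual transforms: highly
variable feature selection by variance of log1p counts (count-like
modalities only; ties broken lexicographically by feature id; a
selection computed on a reference dataset can be re-applied to another
by id), TF-IDF for peak matrices (TF = count/rowsum,
IDF = log(1 + n_cells/(1 + df))), per-cell centered log-ratio for
protein counts (log1p then row-center, rows sum to zero), library-size
log-normalization (target sum 10⁴), inclusive-≥ binarization with a
strict-> mode, and a generic min-cells feature filter. The HVG criterion
is plain variance rather than a fitted dispersion model, so selections
can differ from pipelines that use variance-stabilizing regressions.

## Evaluation metrics

Cell-wise and feature-wise Pearson r (zero-variance rows/columns are
reported as missing, with counts, and excluded from medians); one-sided
Wilcoxon rank-sum p (normal approximation with tie and continuity
correction); one-vs-all AUPRC by a descending-threshold sweep with step
interpolation, with baseline = positives/total; per-peak AUROC via the
rank statistic U/(n₁n₀); and the silhouette score
S(m) = (E(m) − e(m))/max(E(m), e(m)) with e(m) the mean intra-cluster
distance and E(m) the mean distance to the closest other cluster,
singleton clusters scored 0.

## Synthetic generator

`cmot.synthetic` draws cells from a shared latent manifold with cluster
structure: cluster centers at scale `cluster_sep` (default 5) in a
`latent_dim`-dimensional space (default 4), per-cell latents Gaussian
around their center, and each modality observing a fixed random linear
map of a pointwise nonlinearity (default tanh) of the latents plus
Gaussian noise (default sd 0.1). Defaults are 200 source and 100 target
cells, 2 clusters, 30 features per modality. Target cells come from the
same process with one modality held out as ground truth, giving an
exact end-to-end accuracy readout. `plant_outliers` replaces a fraction
of target rows with amplitude-scaled noise to exercise the outlier
screen. All randomness uses the counter-based Philox generator, so
fixtures are bit-reproducible across platforms.

What the generator does *not* emulate: count statistics (negative
binomial sampling, library-size variation), sparsity patterns of real
chromatin data beyond an optional uniform dropout, batch effects, or
imbalanced or hierarchical cell-type composition. Passing tests on this
generator demonstrate correctness of the algorithms under the model's
own assumptions, not performance on any particular real dataset.

## Numerical and design choices

- Dense eigensolver for alignment: exact, deterministic, and cheap at
  the cell counts the tests use (hundreds); a sparse Lanczos path would
  be the natural extension for much larger data.
- Sinkhorn convergence is declared when the worst marginal residual
  drops below `tol` (default 1e-9); plans carry the residual, iteration
  count and log-domain flag for inspection.
- All stochastic components (correspondence subsampling, isolation
  forest, generator) take explicit seeds; the pipeline is bit-
  deterministic for a fixed config and seed.
- Benchmark problem sizes in the test-bench (200 + 100 cells, 20
  replicate seeds, 5×5 LP-oracle instances) keep every independent
  oracle exact while exercising all code paths.

## Known limitations

- Reported λ/η values from external studies may map differently onto
  this solver's internal scale; the `epsilon` override exists for
  matching a specific regularization level.
- Alignment quality degrades when the subsampled correspondence leaves
  the joint graph disconnected (very small p); the package warns and
  drops the extra null directions, but embeddings of unlinked
  components are not mutually comparable.
- The outlier screen's contamination defaults to the isolation forest's
  automatic threshold; heavily contaminated target sets may need an
  explicit fraction.
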