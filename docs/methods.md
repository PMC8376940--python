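# Methods

`ppiforest` predicts whether two proteins interact using only their
sequences, via evolutionary profiles. The pipeline has four stages:
profile descriptors, an unsupervised linear embedding, pair features,
and a tree-ensemble classifier, evaluated under stratified
cross-validation.

## Profile descriptors

Each protein is represented by a position-specific scoring matrix
(PSSM): a T x 20 matrix P of log-odds substitution scores, one row per
residue, produced by iterative profile search (PSI-BLAST, inclusion
e-value 0.001, 3 iterations; the library only constructs the command
and parses its ASCII output — it never runs the search). Of the 40
numeric columns in the ASCII file, only the 20 substitution-score
columns are used; the weighted-percentage block is discarded.

Because T varies, the PSSM is summarized into a fixed-length vector
before any projection:

    F = P'^T P' / T,    P' = sigmoid(P) elementwise,

a 20 x 20 matrix of inter-amino-acid co-occurrence, flattened row-major
to 400 entries. F is symmetric, has entries in (0, 1], is invariant to
row order and to duplicating the sequence, and preserves the
column-wise evolutionary covariation that the raw profile carries. The
logistic squashing keeps extreme log-odds scores from dominating the
cross products. Applying the summary per protein (rather than embedding
individual PSSM rows) is a design choice: it makes every protein a
point in one common 400-dimensional space, which is what a linear
projection fitted across the dataset requires.

## Orthogonal locality preserving projections

The 400-dim descriptors are reduced by OLPP, a linear manifold-learning
method. Locality preserving projections minimize
`sum_ij (y_i - y_j)^2 W_ij` over a neighborhood graph, i.e. directions
in which near neighbors stay near; the solution is the smallest
generalized eigenvector of `X L X^T w = lambda X D X^T w` with
`L = D - W` the graph Laplacian and `D` the degree matrix. The
orthogonal variant extracts d directions one at a time, each the
smallest eigenvector of a deflated operator constructed so that every
new direction is exactly orthogonal (in the Euclidean sense) to all
previous ones. The whole procedure runs inside a PCA pre-projection
that removes near-null covariance directions first.

Numerical choices:

* **Graph**: OR-symmetrized k-nearest-neighbour graph, Euclidean
  metric, default `n_neighbors = 5`. An epsilon-ball rule would be the
  alternative; KNN is used because it has no scale-dependent free
  parameter.
* **Weights**: heat kernel `exp(-||x_i - x_j||^2 / t)` on edges, zero
  elsewhere. Default `t = "auto"` sets t to the mean squared distance
  over edges, making the weights scale-free; a fixed positive t can be
  supplied.
* **PCA cutoff**: components with eigenvalue below `1e-9` times the
  largest are discarded (`pca_tol`).
* **Ridge**: `1e-8 * trace(XDX^T)/r` is added to the diagonal of
  `XDX^T` before inversion, guarding rank deficiency without visibly
  perturbing well-conditioned problems.
* **Deflation**: the deflated operator is non-symmetric, so its
  eigenpairs are computed with a dense general eigensolver; eigenpairs
  with non-negligible imaginary parts are discarded, and (because the
  deflated operator's null space can contain spurious directions that
  violate the orthogonality constraint) the smallest-eigenvalue
  eigenvector satisfying the constraint is selected, then polished by
  one Gram-Schmidt pass so pairwise inner products stay below 1e-8.
* **Signs**: every basis vector and PCA component is flipped so its
  largest-magnitude entry is positive — output is then identical
  across eigensolver implementations.
* **Embedding dimension**: `embed_dim = 50` by default. The dimension
  is a free parameter of the method; 50 keeps roughly an order of
  magnitude of compression from the 400-dim descriptor while leaving
  the downstream classifier enough coordinates, and keeps the
  per-dimension deflation loop cheap. If `embed_dim` exceeds the PCA
  rank the model clamps it (with a warning) rather than failing.
* **No leakage**: inside cross-validation the projection is fitted on
  descriptors of proteins appearing in training pairs only; held-out
  proteins are embedded with the fitted transform.

The first extracted direction is verified in the test suite against an
independent dense generalized-eigensolver solution, and the second
against a brute-force grid minimization of the constrained Rayleigh
quotient.

## Pair features and Rotation Forest

A pair (A, B) is represented by concatenating the two embeddings
(A then B, 2d entries). Concatenation is the simplest order-preserving
merge; element-wise difference or product would impose a symmetry the
data may not have.

The classifier is a from-scratch Rotation Forest of L = 35 CART trees
with K = 10 feature subsets (the published operating point of the
method this package implements; a K x L grid search utility is
provided). For each tree: the features are randomly split into K
disjoint subsets (a random permutation cut into contiguous chunks,
remainders going to the first chunks); for every subset, PCA is
estimated on a bootstrap resample — drawn with replacement, size
ceil(0.75 N) — of just those columns, and **all** principal-axis
coefficient vectors form one diagonal block of a sparse n x n rotation
matrix (entries outside the blocks are exactly zero). The tree trains
on the full training set rotated by that matrix; resampling perturbs
only the PCA estimate, which is the ensemble's diversity mechanism.
Prediction averages the trees' leaf class-frequency probabilities and
takes the highest-confidence class, ties toward the lower class index.
Zero-variance subsets get an identity block with a warning instead of
crashing. The classical class-subset elimination step before PCA is
intentionally not implemented.

## Evaluation

Metrics on the 2 x 2 confusion table (positive class = interacting):
accuracy, precision, sensitivity, and Matthews correlation coefficient
in their standard closed forms. A zero denominator reports that metric
as 0 with an explicit degenerate flag. AUC is the rank-form
Mann-Whitney statistic (ties count one half), invariant under monotone
score transforms; ROC points are swept over unique thresholds with
(0,0) and (1,1) included, using the forest's interacting-class
confidence as the score. Cross-validation is stratified five-fold with
a fixed shuffle seed; the report carries per-fold values, their mean,
and the sample standard deviation (ddof = 1) over folds.

## Synthetic data generator

Real interaction benchmarks require database-scale profile searches, so
the generator emulates the data's structure instead: uniform random
sequences (length 50-150 by default, mirroring the usual
fragment-length filter), integer profiles in which each residue's own
column scores high (+3..+7) against a centered background in [-5, 5],
and labeled pair sets with a planted class signal.

The signal emulates the co-evolution rationale for sequence-based
interaction prediction: a fixed latent "interaction direction" u in
descriptor space (RMS-1 entries), with every interacting pair receiving
one shared perturbation `c * effect * sd * u` — the same vector added
to both partners, `c ~ N(1, 0.25)` a per-pair amplitude, `sd` the
overall descriptor standard deviation. Every pair member, interacting
or not, additionally carries independent Gaussian noise with per-entry
sd `noise_sd * sd` (default 0.5). `effect` and `noise_sd` are therefore
directly comparable per-entry scales: at `effect = 2.0` the planted
signature dominates the geometry and the pipeline recovers it almost
perfectly, at `effect = 0` interacting and non-interacting pairs are
identically distributed and the pipeline sits at chance AUC, and AUC
rises monotonically in between (all three statements are asserted by
the test suite). Each pair gets its own perturbed instance descriptors
(ids `pairNNNN.A/.B`), so the class signal lives exactly in the pair
feature where the classifier looks.

What the generator does **not** emulate: homology between proteins,
realistic amino-acid composition or profile structure, hub proteins
shared across many pairs, or database redundancy filtering. Passing
tests therefore demonstrate that the pipeline's machinery recovers a
planted pairwise signal of known strength — not that it attains any
particular accuracy on real interaction data.

## Problem sizes and defaults

The standard study conditions used by the tests and the acceptance
script are 400 pairs (balanced labels, 100 base proteins, 800 instance
descriptors), OLPP with 5 neighbours and d = 50, Rotation Forest with
K = 10 and L = 35, five-fold CV; smaller variants (80-120 pairs, d = 8)
are used where a property needs several repetitions across seeds.

## Known limitations

* The descriptor discards positional (sequence-order) information; two
  sequences with permuted residues share a descriptor.
* OLPP is unsupervised: a class signal that is geometrically negligible
  in descriptor space can be projected away regardless of its
  predictive value.
* The deflation loop costs one dense r x r eigendecomposition per
  embedding dimension; for r ~ 400 and d in the hundreds this becomes
  the dominant cost.
* Model serialization of the forest uses joblib (trees are sklearn
  objects); the OLPP model serializes to portable JSON.
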