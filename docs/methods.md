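# Methods

## Model and decision rule

The classifier assumes each class of feature vectors is well approximated
by sparse combinations of class-specific exemplars. Training vectors (or
their blocks) are used directly as dictionary atoms; no generative model
is fit. For a test block `y` and a dictionary `D` whose atoms carry class
labels, the sparse code is the solution of basis pursuit denoising in
constrained form,

    min ‖x‖₁  s.t.  ‖y − D x‖₂ ≤ ε,

and classification compares how well each class's atoms alone reconstruct
the block: `r_c = ‖y − D δ_c(x)‖₂`, where `δ_c` zeroes the coefficients
of the other class. The block score `LLS = −(log r_m − log r_n)` is the
log-ratio of the two reconstruction errors; averaging over blocks gives
the ensemble score ELLS, and its sign gives the prediction (positive →
malignant). Averaging before taking the sign is deliberate: taking the
sign per block and voting would discard score magnitude, and the mean is
what makes the ensemble score usable as a confidence value.

Assumptions worth keeping in mind: the two classes must differ in which
low-dimensional structures they occupy, not merely in scale; residuals
are compared through a log-ratio, so the method is insensitive to the
absolute reconstruction level but sensitive to class imbalance in the
atom pool (both classes contribute all their training samples as atoms).

## Tunable parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `s` | block length (components) | 64 | with `l = 256` gives 4 blocks — enough ensemble members while keeping each dictionary overcomplete |
| `ε` | BPDN noise margin | 0.05·‖y‖₂ per block | relative margin makes the solver scale-free; 5% absorbs modest noise without destroying sparsity |
| `normalize` | unit-L2 dictionary atoms | on | L1/residual trade-offs are scale dependent; normalization makes atom selection depend on direction only. A raw-scale mode is kept behind the flag |
| `folds` | CV folds | 10 | standard for datasets of a few hundred samples |
| K-SVD `atoms_per_class` | learned dictionary size | ⌈k/2⌉ | compresses the training set about 2:1 |
| K-SVD `T0` | OMP sparsity while learning | 5 | small relative to the atom count |
| K-SVD `iterations` | coding/update alternations | 30 | planted-atom recovery saturates well before this on clean data |

Residuals are floored at 1e−12 before the log so exact one-class
reconstructions produce large finite scores rather than infinities.
`sgn(0)` is resolved to benign, deterministically, and logged; a test
vector that both classes explain equally well carries no evidence of
malignancy.

## BPDN solver

The constrained problem is solved on the lasso penalty path. The lasso
solution is piecewise linear in the penalty, so the residual norm is
piecewise quadratic and monotone; the solver computes the path (LARS)
and finds, in closed form inside one segment, the penalty at which the
residual first equals ε — which is where the constrained optimum sits
whenever ‖y‖₂ > ε. If the path computation degenerates (exactly
collinear atoms), the solver falls back to coordinate-descent lasso with
bisection on the penalty (feasibility band 1e−5 relative, duality-gap
tolerance 1e−8). ε = 0 is the basis-pursuit linear program, solved as an
LP on split variables. `‖y‖₂ ≤ ε` returns x = 0 immediately. A margin
below the least-squares residual of y on the column space of D is
unattainable; the best iterate is returned flagged `infeasible`.
Converged solutions satisfy the constraint within 1e−6 relative slack.
The strict inequality sometimes written for the constraint is
implemented as ≤ (a measure-zero distinction).

An independent oracle (`bpdn_oracle`, tests only, ≤ 12 atoms) solves the
same convex program by sequential quadratic programming on split
variables x = u − v. Across seeded random instances the two routes agree
on the minimal L1 norm to ~1e−11 relative; the test suite asserts 1e−3.

Test blocks are not normalized before coding; instead ε is taken
relative to ‖y‖₂, which achieves the same scale-freedom without
distorting the block geometry.

## K-SVD

Per class, the dictionary is initialized with a seeded random subset of
training columns and refined by alternating OMP coding (sparsity `T0`)
with sequential rank-1 atom updates via the leading singular pair of the
restricted residual. Two safeguards depart from the textbook loop:

* greedy OMP has no descent guarantee, so a signal keeps its previous
  code whenever the fresh code reconstructs it worse — this makes the
  recorded objective Σ‖y − Dx‖² non-increasing by construction;
* an atom whose coherence with an earlier atom exceeds 0.99 transfers
  its coefficients to the twin and is re-seeded with the currently
  worst-explained signal (applied after the objective is recorded), which
  rescues initializations that sampled one latent direction twice.

Dead atoms (no users) are likewise re-seeded. Given the seed the whole
procedure is bit-reproducible. For the label-specific variants the
learned class dictionaries are concatenated and their atoms labeled by
class; learning is per block for the block modes (whether whole-vector
learning would behave differently is untested here and left open).

## Cross-validation harness

Folds are stratified on the class label and shuffled with a fixed seed;
class imbalance otherwise makes fold metrics noisy. All fitted artifacts
— dictionaries, PCA bases, K-SVD atoms — are computed from each fold's
training portion only, and a hash-comparison test verifies that
perturbing held-out samples cannot change them. Confusion counts are
pooled across folds; AUC is computed on the pooled continuous ensemble
scores (micro), with per-fold values also reported, since with ~20 test
samples per fold a per-fold ROC is unstable. TPR/TNR are reported as
absent (not 0) when their denominator class is missing from a test set.

The per-component KL divergence diagnostic histograms both classes on 32
shared equal-width bins over the pooled range with 1e−10 smoothing mass
per bin; constant components return 0 by convention. KL estimates from
binned data depend on the binning, so these values are comparative
diagnostics, not calibrated divergences.

## Synthetic data

The generator emulates exactly the structure the classifier assumes:
unit-norm latent dictionaries per class (a leading fraction optionally
shared between classes), t-sparse coefficients bounded away from zero
(|N(0,1)| + 0.5, so planted supports are identifiable), additive
isotropic Gaussian noise. Default conditions: 100 samples per class,
l = 256, 16 atoms per class, t = 3, σ = 0.01, disjoint subspaces. One
master seed fans out to independent per-stage streams so stages can be
regenerated independently.

What the generator does **not** emulate: real deep features are
non-negative after ReLU, heavy-tailed, and correlated across components
in ways unrelated to a low-dimensional union-of-subspaces model; class
overlap in real mammography features is far larger than any σ used here.
Passing tests on this generator therefore demonstrate correctness of the
pipeline and its behavior under controlled difficulty (noise, subspace
overlap), not clinical-grade accuracy on real data.

## Problem sizes and numerical choices

The evaluation runs use 200 samples of length 256 (4 blocks of 64 in
BlockBoost; 720-atom pooled dictionary per fold in PatchSample), chosen
so a full 10-fold evaluation completes in well under a minute per
configuration on one CPU while keeping every dictionary overcomplete.
The K-SVD recovery study uses 200 exact 1-sparse signals over 8 planted
atoms in 16 dimensions. Ties among duplicated atoms in BPDN are
degenerate by symmetry; any L1-optimal split is accepted.

## Limitations

* Binary classification only; the residual log-ratio does not extend
  directly to more than two classes.
* ELLS is a score, not a calibrated probability.
* The noise margin ε is the one influential free parameter; the
  evaluation module exposes it as a sweep axis precisely because the
  classification can be sensitive to it.
* Feature extraction from images is out of scope: the package consumes
  feature vectors through a file contract (CSV/NPZ), not images.
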