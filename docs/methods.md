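# Methods

`seatsom` classifies sitting postures from 32×32 seat-pressure images using a
six-node self-organizing map (SOM) and an improved variant (ISOM) that prunes
poorly differentiated training samples and retrains. This note documents the
model, the numerical choices, and what the synthetic data generator does and
does not emulate.

## Sensor model

Each of the 1024 cells of the flexible resistive array is read through a
voltage divider,

    u_o = V_ref · R_ij / (R_ij + R_IM),    V_ref = 5 V, R_IM = 200 kΩ,

and pressure is recovered from the empirical calibration fit
`p = 1690/R − 3.379` with R in kΩ. The fit's units are left abstract ("fit
units"): the downstream pipeline is scale-invariant because every feature
vector is L2-normalized. The fit goes negative for unloaded cells
(R → ∞ gives −3.379); we clamp to 0 so frames satisfy the non-negativity
contract. The acquisition threshold that suppresses seat-foam deformation is
a configurable field with default 0 (no filtering), since no concrete value
is available; tests would otherwise be silently lossy.

## Per-frame PCA reduction and its mirror degeneracy

A frame `P` (32×32) is reduced by treating its 32 columns as variables
observed over 32 rows: the sample covariance `R` (divisor 31) is
eigendecomposed, the top 8 eigenvectors form `A` (32×8), and `P_r = P·A` is
flattened row-major into a 256-element feature vector. Eigenvector sign is
fixed by making each column's largest-magnitude entry positive, and
eigenvalue ties break by original index order, so reduction is a
deterministic function of the frame. Rank-deficient covariances still return
8 orthonormal columns (the eigensolver completes the basis) with a warning.

A consequence of reducing every frame in its own basis deserves emphasis:
**per-frame reduction is exactly invariant to left-right mirroring.**
Mirroring the columns of `P` by the reversal permutation `J` conjugates the
covariance (`Cov(PJ) = J·Cov(P)·J`), so if `φ` is an eigenvector of `Cov(P)`
then `Jφ` is an eigenvector of `Cov(PJ)` with the same eigenvalue, and
`(PJ)(Jφ) = Pφ`. A left-leaning frame and its mirror image therefore map to
*identical* features, making mirrored posture pairs (lean left / lean right,
left / right cross-legs) inseparable by any downstream classifier. A unit
test freezes this property. For this reason the end-to-end pipeline defaults
to a **pooled** basis — the average of per-frame column covariances over the
training set, eigendecomposed once — which preserves lateral information.
Per-frame mode remains the reducer's literal default and is available in the
pipeline via `reduction_mode: per-frame`.

## SOM classifier

The output layer is a 2×3 hexagonal lattice: row r, column i sits at
`(i + 0.5·(r mod 2), r·√3/2)`, so all lattice neighbours are exactly one
unit apart. Inputs and the six 256-element weight vectors are L2-normalized.
Training is classic online competitive learning: for sample `x` at
presentation `t`, the best-matching unit (BMU) `c` minimizes `‖x − w_j‖`
(ties to the lowest index), and every node within lattice distance
`min(N_c(0), σ(t))` of `c` moves by

    w_j ← w_j + η(t) · exp(−D_cj² / (2σ(t)²)) · (x − w_j),

with `σ(t) = σ₀·e^{−t/τ_σ}` and `η(t) = η₀·e^{−t/τ_η}`. Defaults (the
method's tuned values): η₀ = 0.6, τ_η = 1000, σ₀ = 10, τ_σ = 2, N_c(0) = 3,
six nodes. Weights are renormalized after every update; the update rule
alone would let norms drift, and the BMU distance computation presumes unit
weights. Samples are presented in seeded per-epoch shuffles until
`max_iters = 5000` presentations or `η(t) < 10⁻³` (≈ 6400 presentations),
whichever comes first.

Two constants are in visible tension: τ_σ = 2 collapses the neighbourhood to
the winner alone within about five presentations, while τ_η = 1000 keeps the
learning rate high for a thousand. We keep both as documented defaults
rather than "fixing" them; the practical consequence is that training is
winner-take-all for almost its entire duration, i.e. close to online
k-means on the unit sphere. `σ(t)` underflows to floating-point zero near
t ≈ 1500; the update handles this by giving the winner (distance 0) kernel
value 1 and flushing all other kernels to 0.

Because winner-take-all dynamics with one node per class are sensitive to
initialization (a node that never wins is permanently dead), two choices
were made here:

* **Initialization** defaults to `maximin` — a farthest-point draw of six
  training samples (a random seed sample, then greedily the sample farthest
  from the chosen set). Random unit vectors in 256 dimensions are nearly
  orthogonal to the data manifold and routinely leave dead nodes (median
  held-out accuracy ≈ 0.82 in our experiments); `random` and uniform
  `sample` init remain available.
* **Restart selection**: `n_restarts = 5` independent fits (consecutive
  seeds) are run and the one with the lowest quantization error (mean
  sample-to-BMU distance) is kept. Single fits fall into a local optimum
  that splits one wide posture cloud across several nodes on roughly a
  third of seeds; quantization error separates such solutions cleanly
  (≈ 0.23 vs ≈ 0.19 on the default data). Everything is deterministic
  given the top-level seed.

After unsupervised training, each node is labeled by majority vote of the
training samples it wins (vote ties break by the fixed class order LC, RC,
LL, LR, WB, SS; an unhit node inherits the label of the lattice-nearest
labeled node). Prediction maps a frame's feature vector to its BMU's label.

## Differentiation filter (ISOM)

With the first fit's weights frozen, every training sample `i` is scored
against its BMU `j` and rival `k` — the hex-adjacent node of `j` closest to
the sample (`rival="all"` instead evaluates every adjacent pair and keeps
the worst case):

    e_jk = d_ij − d_ik,    r_jk = |e_jk| / (d_ij + d_ik) ∈ [0, 1].

`r_jk` is 0 for a sample equidistant between the two nodes and 1 for a
sample lying on its winner. Samples with `r_jk < r_min` (default 0.15) are
removed and the map is retrained from scratch on the survivors (same seed
policy, fresh schedules; a warm start from the first weights is optional).
`e_jk` is kept signed in the filter report (negative when the BMU is
genuinely closer); the degree uses its magnitude. If `d_ij + d_ik = 0` the
sample is maximally ambiguous and scores 0. Filtering applies to training
data only.

If the filter would empty an entire class, the guard re-admits that class's
best-differentiated samples (top 10% by `r_jk`, at least one) so every
posture can still claim a node; `strict_paper_mode=True` disables the guard
and performs exactly one unguarded filter-retrain pass. The removal count is
monotone in `r_min` by construction.

## Evaluation layer

Confusion matrices are 6×6, rows = actual, columns = predicted, in the fixed
class order. Per-class precision and recall come from the one-vs-rest
reduction (TP on the diagonal, FN the rest of the row, FP the rest of the
column, TN the remainder); overall accuracy is trace/total; macro averages
are unweighted class means. On class-balanced data overall accuracy equals
macro recall. Zero-denominator metrics report 0 and flag the class rather
than returning NaN. Percentages print at two decimals, rounded half-up. The
55/45 stratified train/test split (seeded, via scikit-learn) is the method's
evaluation protocol. `seatsom.reference` ships two published benchmark
confusion matrices; pushing them through this layer reproduces every printed
percentage exactly, which is the package's worked example and regression
anchor.

## Synthetic data generator

No pressure recordings are publicly available, so the generator emulates the
qualitative structure of real seat maps: two sharp ischial peaks plus two
broader thigh regions, rendered as anisotropic 2-D Gaussian load components
whose amplitudes are relative load shares (summing to 1). Class templates
encode the standard clinical picture — symmetric pattern for standard
sitting; a 4-cell lateral shift with load transfer for the leans; thigh
lift-off, pelvic tilt and contralateral ischial loading for the cross-leg
postures (the mirrored pair is an exact reflection); a 5-cell forward shift
with tighter, thigh-heavy load for the waist bow. Subject weight is drawn
uniformly from 45–80 kg and scales total frame load linearly
(`load_per_kg = 5` fit units/kg). Per-frame variability: whole-pattern
translation jitter (σ = 0.5 cells), independent per-component jitter
(σ = 0.25 cells), log-normal spread and amplitude jitter (σ = 0.06). Ideal
pressures are pushed through the electrical chain (pressure → resistance →
divider voltage + Gaussian noise of 5 mV → pressure, clamped at 0), so
noise enters where a real ADC would see it. `inject_midpoint_frames` salts a
dataset with cell-wise means of two frames from different classes, labeled
as one parent — the boundary samples the differentiation filter targets.

What the generator does *not* emulate: inter-subject anatomy (the same
template geometry serves all "subjects"), temporal correlation between
consecutive frames of one sitter, sensor cross-talk, hysteresis and
drift, and seat-dependent baseline deformation. Passing tests therefore
demonstrate that the pipeline recovers well-separated posture classes under
realistic noise — not that it reaches any particular accuracy on real
hardware data.

## Problem sizes and defaults used in the shipped experiments

The default experiment uses 100 frames per class (600 total) with the 55/45
split, ten seeds per study; these sizes keep the full synthetic study and
the test suite comfortably fast while leaving per-seed test sets of 270
frames. With these defaults the plain SOM reaches a median held-out accuracy
of ≈ 0.99 with all six postures on distinct nodes, and with 10% injected
midpoint samples the filtered variant matches or exceeds the plain one's
accuracy and spreads its node weights further apart on ≥ 9/10 seeds,
removing ≈ 5% of training samples at r_min = 0.15.

## Known limitations

* The pooled-basis default departs from the literal per-frame formulation;
  the mirror-invariance proof above is the reason, and per-frame mode is one
  flag away.
* With six nodes there is no redundancy: a posture that loses its node
  (e.g. under strict filtering of a heavily ambiguous class) costs all its
  recall at once.
* The filter runs exactly one pass by design; iterated filtering is out of
  scope.
* Hex-grid sizes other than 2×3 are supported by the lattice code but
  untested against the classification contract (node labeling assumes at
  least as many nodes as classes to be useful).
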