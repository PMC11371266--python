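# Methods

## Problem and model

`sparl` reconstructs a real image `x ∈ R^N` from linear measurements
`y = Hx + n` by solving a *sequence* of convex, spatially re-weighted
L1-analysis problems

    x_{k+1} = argmin_{x ∈ X}  ½‖Hx − y‖² + λ Σ_c ⟨Λ_c(x_k), |W_c x|⟩ ,

where the `W_c` are learned zero-mean convolution filters and the masks
`Λ_c(x_k)` are per-channel, per-pixel weights regenerated from the previous
solution.  Intuitively, the filters respond both to noise and to genuine
image structure; the masks progressively dampen the penalty where structure
has emerged, so edges and texture survive while noise keeps being removed.

Two mask generators are implemented:

* **MMR** (majorization-minimization regularization):
  `Λ_c(x) = B_cᵀ ψ'_c(B_c |W_c x|)` with nonnegative, kernel-normalized
  averaging filters `B_c` and concave-potential derivative profiles
  `ψ'_c(t) = clip_[0,1](σ_c(r_c t))`, `σ_c` a learned non-increasing linear
  spline with `σ_c(0) = 1`.  These masks are exactly the linearization
  weights of the concave energy
  `f(x) = ½‖Hx − y‖² + λ Σ_c ⟨1, ψ_c(B_c|W_c x|)⟩`, so each re-weighted
  problem is a *majorization* of `f` that is tight at `x_k`; the sequence
  `f(x_k)` is therefore non-increasing, which the tests check directly.
* **SAFI** (solution-adaptive fixed-point iterations):
  `Λ̃_c(x) = ϕ_{3,c}(B̂_c ϕ₂(B̃ ϕ₁(W̃x)))`, a 3-layer convolutional network
  with free per-channel linear-spline activations and a spline+logistic
  output, so masks lie in (0, 1).  There is no associated energy, but for
  invertible `H` the update operator maps into the ball of radius
  `2‖y‖/σ_min`, hence admits a fixed point; the iterations are observed to
  converge and the radius is asserted in the tests.

## Solvers

Each convex subproblem is solved by accelerated forward-backward splitting
(FBS) with step `1/‖H‖₂²` and inertial rule `t₁ = 1`, `t_{k+1} = (k+5)/3`,
momentum `(t_k − 1)/t_{k+1}`.  For denoising (`H = Id`, step size exactly 1)
a single FBS step lands exactly on the proximal map of the measurements, so
the FBS loop runs one iteration there.

The weighted-L1 prox `prox_{γ‖L·‖₁}` is evaluated through its dual: an
accelerated projected-gradient iteration on the analysis-domain variable
`u`, initialized at `Lz`, with the box constraint `‖u‖_∞ ≤ γ` enforced by
clipping and the primal recovered as `Proj_X(z − Lᵀu)`.  Within one FBS
solve the dual variable is carried from step to step (warm start); each
dual problem is still solved to its scheduled tolerance, so the computed
minimizers are unchanged while repeated from-scratch dual solves are
avoided.  The dual gradient
step uses the direction `L·Proj_X(Lᵀv − z)`; a finite-difference check on
the dual objective is part of the test suite.  For `L = Id` the solver
reduces to soft-thresholding; for dense `L` it is validated against a
bound-constrained least-squares oracle (`scipy.optimize.lsq_linear` on the
dual), solved by an entirely different algorithm.

Iteration budgets default to 10 outer refinements, 1 (identity `H`) or 1000
FBS steps, and 500 dual steps.  Inner tolerances follow closed-form
schedules that tighten with the outer counter: loose solves early, near
machine precision late.  A negative tolerance is the training sentinel: it
disables early stopping entirely so that a fixed number of steps is
unrolled.

Numerical choices worth noting:

* Step sizes use exact squared spectral norms where available (identity,
  dense via SVD, unitary-Fourier subsampling = 1).  Power-iteration
  estimates are inflated by 1.01 so a step never exceeds the admissible
  `1/‖·‖₂²`; during training the bound `‖L‖ ≤ ‖W‖` (masks never exceed 1)
  with an extra 1.1 margin replaces per-sample estimates.
* The outer relative error `e_k = ‖x_{k+1} − x_k‖/‖x_k‖` falls back to the
  absolute norm when `‖x_k‖ = 0` (the zero initialization).
* When an explicit initialization is supplied, it seeds the *first mask*;
  the default start is `x₁ = 0` with the unweighted operator (the plain
  convex problem), matching the robustness-study protocol.
* k-space column selection keeps `⌊width/M_acc⌋` columns: a centered
  low-frequency block of `round(center_fraction·width)` columns plus a
  uniform random draw of the rest.  The randomization is this package's
  choice; only the kept-column proportion `1/M_acc` is inherent.
* The antiderivative `ψ` is fixed by `ψ(0) = 0` and evaluated in closed
  form (the integrand is a clipped linear spline, so three-segment
  trapezoids over its crossing points are exact).

## Training

The denoiser `D^{n1,1,n3}` is the scheme unrolled for `n1` outer steps, one
FBS step each, and `n3` dual steps, all tolerances disabled.  Training
minimizes `½Σ‖D(x + noise) − x‖²` with Adam (lr 1e-3, standard moments) on
noisy/clean patch pairs, drawing `(n1, n3)` uniformly from {4,5,6} ×
{1,…,10} per batch; the randomized depth regularizes toward fixed-point
behaviour.  Constraints are re-established by projection after every step:
kernels of `W` to zero mean, kernels of `B` onto the simplex via
`|b|/Σ|b|`, profile knots through the monotone projection
`S·clip_(−∞,0](Dd) + 1` (non-increasing, first value exactly 1), scales
`r_c` enter as `|r_c|`, and `λ` (initialized at 1e-4) is clamped positive.
Projection lands in the same feasible set as the reparameterizations it
replaces and keeps the forward pass a plain function of the parameters,
which makes the finite-difference gradient check exact.

Gradients are computed by a small reverse-mode tape over numpy arrays
(`sparl._ad`) that covers exactly the primitives the unrolled solver needs:
convolution and its exact adjoint, uniform-grid spline evaluation (input and
knot gradients), clip (including taped bounds, so `λ` receives gradient
through the dual box), `|·|`, the logistic function and arithmetic.  Every
primitive is validated against central finite differences.  Two quantities
are deliberately treated as constants of the graph: the dual step size
`1/‖L‖²` (estimated by power iteration on detached values) and the momentum
coefficients.  Subgradient conventions: `sign(0) = 0` for `|·|`, and clip
passes the gradient on the closed interval; at parameter points where a
spline sits exactly on a clipping boundary over a set of positive measure
(e.g. the canonical profile initialization, which is 0 beyond the first
knot), the loss is genuinely non-differentiable and finite differences
disagree with any subgradient choice — the gradient tests therefore probe
generic, strictly-decreasing profiles.

After training, the regularization strength is re-tuned for the evaluation
configuration (full fixed-point iterations) by a coarse-to-fine grid search
on validation PSNR: the coarse argmax is refined with a 5-point geometric
grid between its neighbours.

## Synthetic data

The generators supply every input the package needs without downloads:

* *Patches*: random-ellipse cartoons plus `1/f`-filtered texture, clipped to
  [0, 1].  They reproduce the statistic the prior exploits — heavy-tailed
  finite-difference distributions (positive excess kurtosis is asserted) —
  but not the semantic content of photographic training corpora, so
  reduced-scale training results demonstrate that the pipeline learns and
  that masking helps, not the denoising PSNR attainable on natural images.
* *Phantoms*: the modified ellipse-table head phantom (checked against an
  independent per-pixel oracle), random ellipse overlays, and piecewise
  polynomial tilings.
* *MRI instances*: column-undersampled unitary Fourier measurements of a
  phantom with complex Gaussian noise of standard deviation 2e-3 per
  real/imaginary component (per-component is this package's reading;
  only "standard deviation" is inherent), acceleration factor 4 by default.

## Reduced problem sizes

The test suite and the acceptance script run the full pipeline at sizes a
laptop handles comfortably, chosen once: 8 channels, one 5×5 layer and
16×16 patches for training (full-scale 64 channels / two 7×7 layers / 40×40
remain configurable), 64×64 images for denoising and MRI studies, 2000
patches and 2 epochs for the efficacy study, 4-channel random generators
for the descent and fixed-point properties.  The structural guarantees
(majorization, descent, prox optimality, radius bound, schedule closed
forms, gradient correctness) are size-independent, so desk scale checks
them exactly; only absolute PSNR numbers would change at full scale.

## Known limitations

* Multi-coil MRI (sensitivity maps) and non-Cartesian sampling are out of
  scope; the measurement model is single-coil Cartesian column masking.
* Convergence of the SAFI iteration is encouraged (randomized unrolling
  depth), not proven; the package asserts the fixed-point radius and
  observed stability, not a convergence theorem.
* The training path runs on CPU in double precision; it is meant for
  reduced-scale studies, not for reproducing full-scale benchmark tables.
* Mask generators are not Lipschitz-constrained.
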