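# Methods

## The model

`purist` addresses the two-population deconvolution problem for bulk tumour
mRNA abundance data: each tumour sample is a mixture of cancer cells and
normal (healthy) cells, and we want both the cancer fraction and the
expression profile the cancer cells alone would have produced.

For patient *n* with observed tumour profile **t**_n, the decomposition is

    t_n = alpha_n * c_n + sum_r theta_{n,r} * b_r + e_n ,
    alpha_n + sum_r theta_{n,r} = 1 ,

where **c**_n is the patient's cancer profile, **b**_1..**b**_R are
*unmatched* healthy reference profiles (no paired normal sample is needed),
alpha_n is the cancer-cell fraction, and the theta weights express the
patient's healthy component as a convex combination of the references.

For inference the profiles become probability distributions over
transcripts and the data become counts:

    x_n      ~ Multinomial(depth_n, xhat_n),  xhat_n = B theta_n + alpha_n c_n
    theta_n  ~ Dirichlet(nu)
    c_n      ~ Dirichlet(kappa_n * m)
    m        ~ Dirichlet(kappa' * B omega)

**m** is a shared reference cancer profile; its prior mean **B omega** lies
in the convex hull of the healthy panel (cancers largely resemble the
tissue they arise from), and the c_n prior shrinks each patient profile
toward **m** (patients of one cancer subtype resemble each other). The
tumour matrix is discretized to integer counts (round half away from zero),
so each column total acts as that sample's multinomial size.

Fitting maximizes the complete joint log-density (MAP) in two stages:

* **CPE** (cancer profile estimation): every c_n is tied to m; estimates
  m, theta (hence alpha), and the hyper-parameters nu, omega, kappa'.
* **PPE** (patient profile estimation): alpha_n is frozen at its CPE value
  bit-for-bit; estimates each c_n, its prior strength kappa_n, the
  remaining healthy weights on the simplex of mass 1 - alpha_n, and a
  re-estimated shared nu. One nu is shared across patients (the model has
  a single theta prior).

The multinomial combinatorial coefficient is constant in every parameter
and is omitted from the optimization objective (an option restores it for
reporting proper log-likelihoods).

## Optimization

Both stages use block coordinate descent: sweeps over
{theta} -> m -> nu -> omega -> kappa' (CPE) and
{c_n} -> theta -> kappa_n -> nu (PPE), each block minimized by a
Polak-Ribiere nonlinear conjugate-gradient routine with a Wolfe-Powell
line search using quadratic/cubic interpolation and extrapolation.
Defaults: sufficient-decrease 0.1, curvature 0.05, extrapolation capped at
3x the current step, at most 20 evaluations per line search, 100
evaluations per block per sweep, at most 35 sweeps, convergence when the
relative change of the complete log-likelihood between sweeps falls below
1e-7. All are configurable (`FitOptions`).

Because every block objective contains exactly the likelihood terms that
depend on that block, each accepted line-search step can only increase the
complete log-likelihood; the drivers assert this after every block update
(relative tolerance 1e-6) and abort if it fails — a violation indicates a
gradient or reparametrization bug, never expected behaviour.

Line-search comparisons are NaN-tolerant: a comparison involving NaN
reports false, so a trial step outside the objective's domain (infinite or
NaN value/derivative) simply fails the acceptance tests and the search
contracts toward the last good point. A line search that fails twice in a
row terminates the block's optimization at the best point found.

### Unconstrained reparametrization

Simplex blocks (theta rows, m, c_n, omega) are optimized through a softmax
with the last logit pinned to zero — positivity and sum-to-one hold by
construction, and the pinned logit removes the shift ambiguity. Strictly
positive scalars/vectors (nu, kappa', kappa_n) use `minimum + exp(y)`.
All gradients are analytic, chained through these maps, and are verified
against central finite differences in the test suite.

In the PPE stage the frozen alpha_n is removed from the coordinates
entirely: the R healthy weights are a softmax scaled by (1 - alpha_n), so
the freeze holds exactly rather than via a penalty. With R = 1 the scaled
simplex is a single point and the theta block is skipped.

### Prior floors and caps

Dirichlet log-densities are unbounded above when any concentration entry
drops below one (density spikes at the simplex boundary). The mixing
prior's nu is therefore floored at 1 + 1e-6. For the profile priors the
concentration *vector* is floored elementwise:

    a = max(strength * mean_profile, 1)

so transcripts the mean profile deems absent get a flat — not spiked —
prior, while the global strengths kappa' and kappa_n keep weak absolute
floors (2.0). The alternative, raising the global strength until the
smallest entry reaches one, scales like 1/min(mean profile) and makes the
prior overwhelm the data for long-tailed profiles. Strengths are capped
at 1e9 and nu at 1e6 so a profile sitting exactly on its prior mean cannot
drive a concentration to floating-point overflow; trial points beyond a
cap evaluate to +inf and are rejected by the line search.

All densities are computed as sums of logarithms; products of
per-transcript probabilities are never formed.

### Initialization

Seeded and deterministic: theta rows from a flat Dirichlet; m from the
healthy-panel column mean with 5% seeded Dirichlet noise; nu just above
its floor (weak, near-flat mixing prior); omega uniform; kappa' at ten
times its floor; in PPE, c_n starts at m and kappa_n at the CPE kappa'
(so profiles start at the shared estimate). Optional seeded random
restarts for the hyper-parameter blocks (`hyper_restarts`, default 0) keep
the best of the restarted fits.

## The synthetic generator

`purist.simulate.generate` draws cohorts from the model's own generative
process, so estimation quality is measurable against ground truth without
any external dataset. Defaults define the reference study conditions:

* `profile_roughness = 0.5` — per-transcript Dirichlet concentration of
  the reference and shared cancer profiles; values below one give the
  sparse, long-tailed abundance spectra typical of expression data.
* `patient_divergence = 2e4` — total concentration of c_n ~
  Dirichlet(divergence * m); at the reference size (G = 2000) this gives
  roughly 20-30% per-transcript variation of a patient's profile around
  the subtype mean, a plausible within-subtype spread.
* `background = 0.02` — each profile is mixed with 2% uniform mass,
  emulating the nonspecific/optical background of intensity measurements.
  This bounds the dynamic range the way real microarray data is bounded;
  without it, Dirichlet draws carry probabilities down to ~1e-20 whose
  transcripts receive zero counts at any realistic depth and are therefore
  unidentifiable on the log scale.
* `alpha ~ Uniform(0.3, 0.9)`, `depth = 1e6` counts per sample.
* The healthy matrix is emitted noiselessly (the true panel scaled to
  depth) so estimation error is not confounded with reference noise;
  `noisy_reference=True` switches to multinomial-sampled references.

What the generator does **not** emulate: probe effects, saturation,
between-array normalization artefacts, RNA-Seq overdispersion beyond the
multinomial, and more than two cell populations. Passing recovery tests
therefore demonstrate correctness of the inference under the model's own
assumptions, not performance on real arrays.

## Known limitations

* **Intrinsic alpha bias.** The likelihood is exactly invariant under the
  one-parameter family m' ∝ m + gamma*B w, alpha'_n = alpha_n (1 + gamma),
  theta'_n,r = theta_n,r - alpha_n gamma w_r (any simplex direction w):
  moving healthy mass into the shared cancer profile while inflating every
  cancer fraction leaves every xhat_n unchanged. The MAP location along
  this ridge is decided by the priors and by the theta >= 0 boundary, so
  estimated fractions carry a small systematic excess (about +0.03 to
  +0.08 under the reference conditions) while their ranking is essentially
  exact (Spearman rho >= 0.99). Interpret absolute purities accordingly.
* Transcripts with (near-)zero counts in a patient are determined by the
  prior, not the data; their log-profile values are regularized toward the
  shared profile.
* The two-population assumption ignores stromal/immune substructure; the
  single shared m assumes one cancer subtype per cohort.
* Inputs must be linear-scale abundances. A matrix whose maximum is below
  30 triggers a log-scale warning (typical log2 microarray ceiling) but is
  not rejected.
* Block coordinate descent finds a local MAP; different seeds can reach
  different (near-equivalent) optima. Fixed seeds make any single run
  bit-reproducible on one platform.

## Problem sizes used in the checks

The self-checks run at desk scale, chosen to exercise every code path with
comfortable statistical margins: gradient checks on 100 random instances
(G=50, N=4, R=3); monotonicity on ten cohorts (G=500, N=10, R=3, depth
1e5); recovery on three cohorts (G=2000, N=20, R=5, depth 1e6); degenerate
mixing limits at G=200. The full test suite and the acceptance script each
complete in well under a minute on one CPU.
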