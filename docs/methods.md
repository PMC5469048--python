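# Methods

## Task model

The environment is one-dimensional.  Screen positions live in coordinates
where the 53-cm display spans [−5, 5] (so 1 unit = 5.3 cm; centimetres are
display-only).  Joystick position *j* ∈ [−1, 1] maps to cursor position
*c* = m·j + s.  Blocks are drawn by sampling the *policy* parameters
uniformly — w\* = 1/m ~ U(0.25, 1.75), b\* = −s/m ~ U(−0.25, 0.25) — which
induces m ∈ [4/7, 4] and s ∈ [−1, 1].  Targets are uniform on
[−0.4286, 0.4286], the largest symmetric range reachable under every
admissible mapping.  The constant is stored as the printed, operative value
0.4286; the analytic bound (1 − 0.25)/1.75 = 0.428571… is exposed separately
(`TARGET_BOUND_ANALYTIC`).  The 2.9×10⁻⁵ excess of the rounded bound means
the worst-corner optimal action can overshoot |j| = 1 by ~5×10⁻⁵; simulations
treat the linear law as valid there rather than modelling saturation, and
`apply_mapping` (the physical-joystick surface) enforces |j| ≤ 1.

A subject's protocol is 6 warmup blocks (generated, flagged, excluded from
analysis), 24 test blocks of 15 shots, and one 100-shot long block run after
test block 14.

## Learners

All learners share the policy j = w·x + b plus Gaussian noise, and clip
(w, b) to the hypothesis-space box after every update.

**Zeroth order (node perturbation).**  The noise g ~ N(0, σ_g²) is the probe;
after each shot w ← w − η(L − L_prev)·g·x and b ← b − η(L − L_prev)·g with
L = e².  Shot 1 performs no update: L_prev is undefined before two losses
exist, so it is seeded with the first loss and the first update follows
shot 2.  The current shot's g is paired with (L − L_prev).  A
three-hyperparameter variant (separate η_w, η_b) is available; in our
simulations it is reproducibly a few percent *better* than the shared-η form
(the w update is scaled by |x| ≤ 0.43 and prefers a larger rate), without
changing any qualitative outcome.

**First order (LMS).**  The learner runs LMS on the forward model
c = m_est·j + s_est.  Because the action is chosen so that the predicted
cursor equals the target (m_est·j + s_est = x when the policy is the exact
inverse of the estimate), the shooting error e = c − x *is* the model's
prediction error, and the gradient step is m_est ← m_est + η_m·e·j,
s_est ← s_est + η_s·e — the same +e innovation the RLS rule uses.  (Writing
the rule with a minus sign requires the error as x − c; with e = c − x the
minus-form is the anti-gradient and diverges, which we verified by
simulation.)  The policy follows as w = 1/m_est, b = −s_est/m_est; after
clipping w, b the estimates are back-corrected (m_est = 1/w, s_est = −b/w).

**Second order (RLS).**  Gain matrix P initialized to I, forgetting factor
μ ∈ (0, 1]: y = (j, 1)ᵀ, v = P y, k = vᵀ/(μ + yᵀv), P ← P − v k, then
m_est ← m_est + e·k₁, s_est ← s_est + e·k₂ and the same clip/back-correct
step.  The P update is used exactly in this form; the conventional variant
that additionally rescales P by 1/μ is available as
`SecondConfig(textbook_update=True)` (the two coincide at μ = 1).  At μ = 1
and σ_r = 0 the recursion equals batch ridge regression with prior P₀ = I
(verified against the closed form to 10⁻¹⁰).  A consequence worth noting:
at μ = 1 the ridge prior under-excites the magnification direction (the
regressor (j, 1) varies little in j over the narrow target range), so the
noiseless μ = 1 learner levels off near 0.06 mean error by shot 15; with an
*optimized* μ (heavy forgetting, typically μ ~ 10⁻²–10⁻¹) the noiseless
learner is near-perfect (< 10⁻² by shot 15), which is the regime all fitted
doppelgangers occupy.

Two implementations exist deliberately: scalar per-shot reference operations
that transcribe the rules literally, and a vectorized engine that runs
repetitions×blocks lanes in parallel (how 10⁴–10⁶-repetition contests stay
cheap).  A test drives both with the same noise stream and requires
agreement to 10⁻¹².

## Calibration

Each doppelganger is matched to its subject in two scalars.

**Initial policy.**  (w₀, b₀) must reproduce the subject's mean unsigned
shot-1 error over the 24 test blocks.  One constraint, two unknowns: we fix
b₀ = 0 (the centre of its range) and solve for w₀ by root-finding on the
error profile, which is convex in w₀ (a mean of |affine| terms), preferring
the branch right of the minimizer.  If the target lies below the b₀ = 0
floor — possible because the target is a 24-shot sample mean, and because a
subject's own bias can beat any zero-bias start on its design — (w₀, b₀) is
moved jointly along the segment from the design's two-parameter least-error
point to the b₀ = 0 minimizer, where the convex profile crosses the target
uniquely.  Targets below even the joint floor raise `InfeasibleTargetError`
(library default) or clamp to the least-error point with a warning (what the
pipeline does; the residual mismatch is a few percent at worst).  Shot-1
error includes the learner's own noise (g or r) via common-random-numbers
Monte Carlo, since the contest's first shot is noisy.

**Response noise.**  σ_r (first/second order) is fitted so the simulated
median unsigned error over shots 51–100 of the subject's own long block —
learning on, same mapping and targets — matches the subject's, by Brent
root-finding on a common-random-numbers profile (monotone in σ_r).  At
convergence with m = 1 the closed form median|e| = σ_r·Φ⁻¹(0.75) holds and is
used both as a test oracle and as the initial guess.

**Alternation.**  σ_r conditions the hyperparameter optimum and vice versa,
so `Doppelganger.fit` alternates: optimize hyperparameters at the current
σ_r, refit σ_r at the new hyperparameters, recalibrate w₀ at the learner's
own noise level — two rounds by default, after which movement is under 1%.

## Hyperparameter optimization

Hyperparameters (σ_g, η for zeroth; η_m, η_s for first; μ for second)
minimize the mean unsigned shot-15 error over 2000 fresh task-distribution
blocks.  The stochastic objective uses common random numbers — mappings,
targets and noise draws fixed at construction, noise rescaled by the
candidate σ — so Nelder-Mead sees a deterministic surface.  Search runs in
log coordinates (logit for μ) with 5 starts: one fixed
(σ_g = 0.05, η = 1; η_m = η_s = 0.1; μ = 0.9) plus 4 random log-uniform
draws.  The LMS rates are bounded by 2 because |1 − η·j²| ≤ 1 for the
physical |j| ≤ 1 range guarantees per-shot contraction; without that cap the
optimizer occasionally picks rates that limit-cycle (bounded by clipping) on
long blocks, which poisons the σ_r fit.  A design-locked mode (optimize on
the subject's fixed 24 blocks instead of fresh draws) is available; the
default follows the task distribution.

## Synthetic cohort

No raw human data is deposited, so the cohort is generated.  Default
surrogate: a first-order learner with rates degraded by
eta_scale ~ U(0.4, 0.9) from reference values (η_m = 2.0, η_s = 0.18, a
one-off constrained optimization at the cohort-mean noise), response noise
σ_r ~ U(0.0481, 0.0942) (the reported human range, mean ≈ 0.071), and an
initial policy drawn near the naive identity guess
(w₀ ~ U(0.6, 1.45), b₀ ~ U(−0.1, 0.1)).  A first-order surrogate is the
natural choice because human performance sits nearest the first-order curve;
a mechanism-free alternative (`parametric_curve`: exponential decay to a
noise-floor asymptote) is provided for robustness.  What the generator does
*not* emulate: reaction times, fatigue, any across-block meta-learning, and
any sex or age structure; per-subject error-curve shapes beyond the σ_r range
and the level-off pattern cannot be validated against the original cohort, so
passing tests certify the pipeline's statistics, not human realism.

## Contest statistics

The early error is the mean of the per-shot curve over shots 3–7, the window
where the three orders are most separated.  `brute_force_p` counts
repetitions with doppelganger early error ≤ the human's (ties favour the
doppelganger; they have probability zero for continuous errors); a zero
count is reported as the bound p < 1/n_reps, never as 0.  The complementary
tail (`p_loss`, repetitions ≥ the human's) quantifies human losses.  Group
contests compare cross-subject means per repetition.  Robustness tools:
per-shot contests for shots 2–15, variability scaling (σ_r × 1.2, × 1.35
without re-optimizing hyperparameters — the scaling is a perturbation of the
fitted learner), a 9-shot centred running average (window truncated
symmetrically at the series ends), and a two-sided Wilcoxon signed-rank test
(exact null for n ≤ 25) comparing early errors in the first six versus final
six test blocks as a meta-learning check.  For the ordering of *mean* early
errors across learner orders we use a one-sided Monte-Carlo permutation test
on the difference of means (5000 label permutations), which tests the stated
hypothesis directly and is robust to per-repetition dispersion.

Default problem sizes: 12 subjects, 10⁴ contest repetitions (configurable to
10⁶; the vectorized engine makes 10⁶ a minutes-scale run), 2000
common-random-number blocks per objective evaluation, 2000 Monte-Carlo
repetitions for calibration profiles.  These are the package's desk-scale
defaults; every count is a parameter.

## Determinism

All randomness descends from one root seed through named
`numpy.random.SeedSequence` children (stage names hashed with CRC32, so
streams are stable across processes and platforms).  Two runs of the same
configuration produce byte-identical reports; the output directory path is
excluded from the report for that reason.

## Known limitations

* The cohort is synthetic; cohort-level p-values characterize the generator,
  not human subjects.  The per-subject p-values of the original study are not
  reproducible from public data.
* With 10⁴ repetitions the smallest reportable p is 10⁻⁴ (bounds); the
  original million-repetition bounds of 10⁻⁶ require `--reps 1000000`.
* (w₀, b₀) identification is under-determined; the b₀ = 0 convention is a
  choice, recorded per fit, and other conventions matching the same first-shot
  error could shift per-subject results slightly.
* The RLS-as-printed update (no 1/μ rescale of P) and the textbook variant
  genuinely differ for μ < 1; we default to the printed form and expose the
  flag without asserting which the original implementation used.
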