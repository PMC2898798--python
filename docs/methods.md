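# Methods

## Empirical pAUC

For control scores s⁰ (n₀ of them) and case scores s¹ (n₁), positivity is
`score ≥ threshold` with the Heaviside convention H(0) = 1. Attainable
FPRs are multiples of 1/n₀; given a window (α₁, α₂) the package picks the
attained levels k₁/n₀ and k₂/n₀ nearest the targets (distance ties go to
the smaller FPR — the more specific threshold, which is the conservative
choice for screening). The empirical pAUC is the pairwise count over the
controls whose attained FPR lies in (k₁/n₀, k₂/n₀]:

    pAUC = (1/(n₀n₁)) Σᵢ Σ_{j in window} H(s¹ᵢ − s⁰ⱼ),

which equals the Riemann sum of the ROC staircase over those levels. For
α₁ = 0 the upper threshold sits infinitesimally above the top control
score; this is realized by a strict comparison, never by perturbing data.
Consequences of these conventions worth knowing:

* with (α₁, α₂) = (0, 1) and no ties the value is the Mann–Whitney AUC;
* a constant score attains only FPRs {0, 1}, so its empirical pAUC at
  (0, 0.1) is 0 (the nearest attainable level to 0.1 is 0, an empty
  window), while at (0, 1) every case–control tie counts under H(0) = 1
  and the value is 1 — the smoothed version gives the more meaningful ½;
  a binary marker identical to the label likewise scores 0 at (0, 0.1)
  because no threshold attains an FPR near 0.1;
* the attained upper edge can differ from α₂ by up to half a grid step
  when α₂n₀ is not an integer, so the sharp bound pAUC ≤ α₂ − α₁ holds
  exactly when α₂n₀ is integral.

## Smoothed (approximate) pAUC

The empirical pAUC is a step function of the score coefficients, so the
optimizer works on a smoothed surrogate: every Heaviside is replaced by
Φ(z/σ). Writing the pAUC as the level sum above, the smoothed version
keeps the level grid but solves each level's threshold from the
*smoothed* FPR equation

    (1/n₀) Σⱼ Φ((s⁰ⱼ − c_k)/σ) = (k − ½)/n₀,

and sums the smoothed TPR (1/n₁)ΣᵢΦ((s¹ᵢ − c_k)/σ) over the levels. The
half-step target makes c_k converge to the k-th largest control score as
σ → 0 (that control contributes exactly Φ(0) = ½ at the root), so the
smoothed value hardens into the empirical one. Three properties drive
this design, and property tests pin all of them:

* **differentiability** in any coefficient entering the score linearly,
  with analytic first and second derivatives when thresholds are frozen;
* **null behavior**: a score collapsing to a constant has value
  (α₂² − α₁²)/2, the diagonal-ROC pAUC;
* **scale monotonicity**: multiplying the whole score by γ (equivalently
  shrinking σ) moves the value monotonically from the null value toward
  the empirical pAUC. This is what lets σ stay fixed at 1 while the
  coefficient scale remains free — the objective only depends on
  (scale × 1/σ) — and it is the limit property that justifies optimizing
  the surrogate at all.

Two plausible alternatives fail these requirements and are deliberately
not used. Smoothing only the pairwise comparisons while keeping hard
order-statistic thresholds gives a near-zero score the value
Φ(0)·(window width) = 0.05 at (0, 0.1) — far above anything attainable on
weak-signal data — so maximizing it shrinks the score and the fit stalls.
Smoothing the thresholds but keeping a hard in-window control subset
leaves a fresh unit-scale score with an empty window and a zero gradient,
so boosting cannot start. The level form avoids both.

At large n₀ the level grid may be subsampled (`max_levels`) to a fixed
quadrature grid; the value is window-width × mean smoothed TPR, so the
scale is unchanged. The Monte-Carlo scale-monotonicity check uses 64
levels at n₀ = n₁ = 50 000.

## Weak learners

Continuous markers get the m-function natural cubic spline basis (default
m = 5) on knots at equally spaced quantiles of the observed values —
standard additive-model practice, robust to outliers; there is no single
canonical knot count for this objective, so m is exposed in the
configuration. The basis is the truncated-power construction with the two
natural constraints absorbed (linear outside the boundary knots). The
roughness penalty Ω_ab = ∫N_a''N_b'' is exact: second derivatives of
natural cubic splines are piecewise linear between knots and zero
outside, so the product integrates in closed form per interval. Constant
and linear basis elements span the nullspace of Ω and are never
penalized. Each element is standardized by Z = max over training samples
of |N(x)|, putting all learners on the height scale max|f| = 1; the
intercept element, constant on training data, is dropped from the
boosting dictionary because the ROC curve is invariant to adding a
constant.

Discrete markers get threshold stumps at midpoints between consecutive
unique values (both orientations, output {0, 1}); categorical markers get
one-vs-rest stumps. Stumps contribute nothing to the penalty.

## Boosting loop

Iteration t (all candidates = dictionary elements, each kept alive with a
positive-start and a negative-start coefficient stream, initialized ±1):

1. per candidate f, compute the smoothed band of the provisional score
   F_{t−1} + β_{t−1}(f)·f;
2. one Newton–Raphson step on β against the penalized smoothed pAUC with
   the band frozen (the penalty derivative of λ(v + βe_l)'Ω̃(v + βe_l) is
   included analytically); where the surrogate is locally non-concave the
   step falls back to 0.1·sign(gradient); steps are clipped to
   `step_cap`;
3. the candidate whose updated score maximizes the penalized smoothed
   pAUC at its *own* fresh thresholds is selected (deterministic
   tie-break by marker, basis element, sign) and added:
   F_t = F_{t−1} + β·f.

An optional guard (on by default) stops the run rather than accept an
update that lowers the penalized training objective; fixed-T runs disable
it. With the window (0, 1) every quantity reduces to the AUC and the
procedure is AUC boosting. Fits are deterministic given data and
configuration.

The default step cap is 10; the simulation studies run with `step_cap=1`.
Unit-scale steps make the overall score scale — which plays the role of
1/σ — grow gradually, so the surrogate sharpens like an annealing
schedule instead of saturating on the first selected direction; with
large steps the first (often linear, hence unpenalized) component can
blow up the scale, flattening every other candidate's gradient.

## Tuning, filtering, baselines

pAUC_cv(λ, T) sums the held-out empirical pAUC of the score fitted
without each fold over K stratified folds (stratification is required:
with few cases an unstratified split can leave a fold without cases),
optionally averaged over R repeated fold assignments. The T dimension
truncates a single T_max run per (λ, fold), which is exact because
boosting is forward-stagewise. The argmax is reported; ties prefer
smaller T, then larger λ.

Marker filtering scores each marker by its raw values (both orientations,
better one kept) and ranks by pAUC, ties by AUC then index. P_g(k) is the
fraction of B class-stratified bootstrap resamples (stratified so n₀/n₁
and hence the threshold grid are preserved) in which marker g ranks in
the top k; the same resamples serve every k, making P_g(k) monotone in k.
Selection applies a strict cutoff P_g(k) > threshold.

The SDF comparator searches θ ∈ (−π/2, π/2] on a grid (default 2000
angles) for the empirical-pAUC-maximizing linear score
cos θ·x₂ + sin θ·x₄; positive rescaling leaves the ROC unchanged, so the
angle sweep covers all linear combinations, exactly to grid resolution.
AdaBoost uses the standard exponential-loss reweighting over the stump
dictionary with β_t = ½log((1−ε_t)/ε_t); a zero-error round adds the
perfect stump at a capped coefficient and stops, and a round with no
stump below error ½ stops without adding. The ensemble margin is reused
as a score so both methods are judged on the same pAUC metric.

## Synthetic data

Controls are N(0, 1) throughout. The screening-type case distribution is
the mixture 0.9·N(0,1) + 0.1·N(δ,1) and the two-sided variant
0.9·N(0,1) + 0.05·N(−δ,1) + 0.05·N(δ,1), with δ = 3 control SDs — a
separated case fraction clearly distinguishable from the control bulk, as
the screening setting requires; δ and all component parameters are
provisional defaults exposed on the spec objects. The two-marker designs
draw x₂ (screening-type) and x₄ (two-sided in the nonlinear setting,
screening-type in the linear one) independently given the class; the true
log-likelihood-ratio score is available in closed form for oracle
comparisons.

The gene-block design draws p genes per class from a multivariate normal
with correlation D^{-1/2}(0.95·W + 0.05·I)D^{-1/2}, W ~ Wishart(I, 10 df)
resampled per repetition and per class (rank-deficient at p > 10, which
is what produces off-diagonal correlations spanning roughly ±0.8); 10% of
case samples per gene (chosen independently per gene) are replaced by
N(δ, 1) draws, so every gene is a weak screening-type marker.
Noninformative genes share one correlated distribution across classes.

What the generators do *not* emulate: heavy-tailed or skewed expression
distributions, batch effects, missingness, and marker-count regimes
beyond tens of genes. Passing tests therefore show correctness of the
method and its qualitative behavior (nonlinearity capture, low-FPR focus,
false-discovery resistance), not performance on real arrays.

## Study configurations and sizes

The two-marker comparison fits with λ = 1e-4, T = 50, guard off,
step cap 1, 5 knots, on 50/50 training and 500/500 test draws; the
acceptance script averages 100 repetitions, the test suite 30. The gene-block false-discovery comparison uses
p = 20 informative + 20 noninformative genes, λ = 1e-2, T = 20, guard
off, 20 repetitions — a heavier penalty than the two-marker study because
the candidate set is 20× larger and correlated. The oracle-equivalence
check runs 1000 random instances with n₀, n₁ ≤ 20 against a loop-based
pairwise counter.

## Known limitations

* The one-step Newton coordinate ascent is greedy; on weak-signal data it
  can stop at local maxima below what a global fit of the same additive
  family reaches. The guard trades training-objective monotonicity for
  possibly earlier stops.
* For α₁ > 0 the attained lower edge uses the same nearest-level rule as
  the upper edge; windows narrower than 1/n₀ collapse to an empty level
  set and a zero objective.
* P_g(k) is a stability measure conditional on the observed data; for
  exchangeable null markers it concentrates near k/M only after averaging
  over data draws.
* Spline extrapolation beyond the training range is linear (natural
  boundary); predictions far outside the range follow the boundary slope.
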