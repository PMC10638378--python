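# Methods

## Optimizers

### Standard PSO (`tsdpso.swarm`)

A swarm of `s` particles minimizes an objective on a box. Velocities
follow the canonical three-term rule with inertia `ω`, cognitive and
social coefficients `c1, c2`, and uniform random factors `r1, r2`;
velocities are clamped elementwise to `[−v_max, v_max]`, and positions
are clamped into the box with the offending velocity coordinate zeroed
(a standard, least-surprising boundary rule; the alternative of
reflecting is not provided). The run stops when the global best fitness
reaches `convergence_tolerance` or the iteration budget is exhausted.

Defaults follow the configuration used for SVM tuning throughout the
package: `s = 20`, 500 iterations, `c1 = c2 = 2`, `ω = 0.9`,
`v_max = 4`, tolerance `1e−3`.

**Random-factor granularity.** `r1, r2` are drawn independently per
coordinate per particle per iteration (`r_mode="per_coordinate"`, the
default), with a scalar-per-particle mode available. The scalar form
matches the algebraic notation in which the update is usually written,
but it couples all coordinates of a move through a single random factor
and measurably degrades convergence: under the default settings on the
10-D Sphere, scalar draws leave the swarm stranded around 1e−1 while
per-coordinate draws reach the 1e−3 tolerance on every seed tried.
Per-coordinate draws are also what mainstream PSO implementations do, so
they are the default here.

**Constant inertia.** Standard PSO keeps `ω` fixed at its configured
value. A constant `ω = 0.9` explores well but refines poorly (it
plateaus around 1e−5 on the 2-D Sphere); the adaptive schedule below is
TSDPSO's answer to that, and keeping standard PSO constant preserves the
exact-reduction relationship between the two optimizers.

### TSDPSO (`tsdpso.optimizer`)

Per iteration, after fitness evaluation and pbest/gbest bookkeeping:

1. **Evolution factor.** `d_i` is the mean Euclidean distance from
   particle `i` to all particles (the zero self-term included, so the
   divisor is `s`). With `d_g` the mean distance of the best particle,
   `E_f = (d_g − d_min)/(d_max − d_min) ∈ [0, 1]`. A fully collapsed
   swarm (`d_max = d_min`) is defined to have `E_f = 0`: zero spread is
   the deep-convergence limit.
2. **Inertia.** `ω(E_f) = 0.5 E_f + 0.4`, range `[0.4, 0.9]` — large
   when the swarm is spread (explore), small when collapsed (refine).
3. **State.** Thresholds at 0.25/0.5/0.75 (upper edge inclusive)
   propose one of four states: convergence (1), exploration (2),
   development (3), jump-out (4). The realized state is then sampled
   from the row of a tridiagonal 4×4 transition matrix with persistence
   `x` on the diagonal and the remaining mass split over adjacent
   states (edge rows give `1−x` to their single neighbor). The two
   printed mechanisms — threshold classification and Markov switching —
   are composed proposal-then-sample because no composition is
   specified; a deterministic mode (pure thresholding) exists for
   reproducible unit analysis. `x` defaults to 0.6 (moderate
   persistence; any value in (0,1) preserves the structure), constant
   over time.
4. **Parameters and delays.** `(c1, c2)` per state: (2, 2), (2.1, 1.9),
   (2.2, 1.8), (1.8, 2.2). Delay selection, with `m = min(k, τ_max)`
   and `τ_max = 10`: convergence uses current bests (0, 0); exploration
   delays gbest only (0, U{1..m}); development delays pbest only
   (U{1..m}, 0); jump-out delays both independently. Only qualitative
   guidance exists for these magnitudes; the uniform-draw rule is this
   package's concrete reading and every piece of it is configurable.
   History lookups clamp `k − τ < 0` to iteration 0.
5. **Traction.** A particle whose pbest has not improved for
   `stall_threshold = 10` consecutive iterations receives the additive
   velocity term
   `PO = ((f_i − f_min)/(f_avg − f_min)) · rand · (p_g[k−τ1] − p_i[k−τ1])`.
   When `f_avg = f_min` (degenerate swarm) the traction factor is 0 — a
   fully converged swarm needs no traction, and this avoids the 0/0.
6. **Update.** `v' = ω v + c1 r1 (p_i[k−τ1] − x) + c2 r2 (p_g[k−τ2] − x)
   + PO`, clamped; then the position update as in standard PSO.

Setting `τ_max = 0`, disabling traction, pinning the state to 1 and
freezing the inertia reduces the loop — including the random stream —
exactly to standard PSO; the suite asserts bitwise equality of the
resulting runs.

## SVM tuning (`tsdpso.svm_objective`)

The classifier is an RBF-kernel soft-margin SVM,
`k(x, x') = exp(−γ‖x − x'‖²)` with `γ = 1/(2σ²)`; the dual QP is
delegated to scikit-learn's solver — the package's contribution is the
optimizer and the fitness wrapper, not a QP solver. The tuning fitness
is the mean stratified k-fold misclassification rate (10 folds by
default); mean per-fold AUC is available as a separate diagnostic
(`cv_auc`) but does not drive the search — which functional to minimize
is genuinely open, and CV error is the simpler, threshold-free choice.
The search box is the conventional `log2 C ∈ [−5, 15]`,
`log2 γ ∈ [−15, 3]`; searching in log2 space keeps the box well scaled
for the `v_max = 4` speed cap.

## Preprocessing (`tsdpso.preprocess`)

Cleaning order: coerce string columns to numeric where possible
(entirely unparseable columns raise, naming the column) → drop rows
with missing cells → drop exact-duplicate rows → drop rows with
|z| > 3 in any continuous column (population SD; columns whose values
are a subset of {0, 1} are treated as indicators and exempt). The
report reconciles every dropped row. The 3.0 default is the standard
outlier convention; a stricter cut is a parameter. Note the z-rule is a
fixed-point operation only approximately: removing rows shifts the
column statistics, so re-cleaning can in principle drop more rows when
values sit exactly at the threshold.

Min–max scaling maps each column affinely onto `[0, 1]` or `[−1, 1]`;
constant columns map to the lower bound. The SVM pipeline preset uses
`[−1, 1]`, the usual choice for margin classifiers.

PCA standardizes columns to mean 0, SD 1 (zero-variance columns are
excluded with a warning), eigendecomposes the population covariance
`C = XᵀX/n` — the `1/n` convention, not `1/(n−1)`; the tests verify the
relationship to scikit-learn's PCA up to that factor — and retains the
smallest `m` whose cumulative explained-variance ratio reaches the
`n_components` threshold in `(0, 1]` (threshold 1.0 keeps all
components). The sweep utility evaluates a user-supplied model-error
callable across thresholds, reproducing the error-vs-components
stabilization curve used to pick an operating threshold.

## Evaluation (`tsdpso.evaluation`)

Confusion counts take FRI = 1 as positive. Accuracy, recall
(sensitivity), specificity, FPR and precision are percentages; F1 is in
[0, 1]; zero-denominator metrics are returned as `None`, never silently
0. ROC is a tie-grouped threshold sweep with trapezoid AUC; the PR
curve keeps, per recall level, the best-precision operating point.
Model comparisons convert printed percentages to counts by round-half-up
at the stated group size and apply the Pearson χ² without continuity
correction (1 df) — the uncorrected form is what reproduces the
published comparison statistics, and it equals the squared pooled
two-proportion z-statistic (cross-checked against an independent oracle
on 1 000 random tables).

## Synthetic cohorts (`tsdpso.synthetic`)

The generator emulates the structure of an FRI registry at configurable
scale: balanced classes; 80 binary + 17 continuous features by default
(97 total — the registry reports feature categories, not per-type
counts, so the 80/17 split is an assumption); 22 informative features
(age plus ~2:1 binary:continuous signal carriers, mirroring the
published reduced feature set, with indicator names borrowed from the
published list for realism). The separation dial `δ` shifts continuous
informative means by `δ` SD and separates binary informative rates by
`min(0.2 δ, 0.8)` from a 0.15 base rate — a rate *gap* rather than a
literal `δ` separation, since probabilities cap at 1; `δ = 3` thus
pairs a 3-SD mean shift with a 0.6 rate gap. Default `δ = 1` is a
moderate, realistic signal. Ages are drawn uniformly within three
strata (8–34, 35–65, 66–100) whose per-class totals follow the
published distribution (FRI 864/1766/2131, Non-FRI 921/1842/1998);
other cohort sizes allocate proportionally by largest remainder. Real
marginal rates of the indicators are not published; the defaults are
deliberate, documented choices.

What the generator does *not* emulate: inter-feature correlation
(features are independent given the class), skewed or heavy-tailed
marker distributions, missingness mechanisms other than
missing-completely-at-random, and the real cohort's covariance
spectrum. Passing tests therefore validate the machinery — recovery of
planted structure, chance-level behavior under the null, high AUC under
strong separation — not any claim about real FRI data, whose published
AUC (0.91) is intentionally out of reach of this generator.

The defect injector plants missing cells, appended duplicate rows and
+8σ outlier values at disjoint, returned indices so a cleaning pass can
be audited count-for-count. Exact recovery presumes a base table with
no natural |z| > 3 rows; the fixtures pre-clean at a stricter cut
(z = 2.5) to provide margin against the small statistic shifts the
defects themselves induce.

## Pipeline (`tsdpso.pipeline`)

Stage order: cohort (generated or loaded) → clean → scale to `[−1, 1]`
→ PCA (threshold 0.95 default) → stratified 80/20 split (by class, and
by age band when an age column exists, mirroring per-age-group
analyses) → TSDPSO-SVM tuning → held-out evaluation. Artifacts embed
the seed and a hash of the scientific configuration; a rerun with the
same config is byte-identical. Desk-scale defaults (300 per class, an
8-particle/10-iteration tuning swarm, 5 folds) keep a full run around a
second while exercising every stage; all are configurable upward.

## Numerical conventions and edge cases

- All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; identical inputs give bitwise-identical
  results.
- Non-finite fitness values abort an optimization run with an error
  naming the particle and iteration.
- Transition-matrix rows are validated to sum to 1 within 1e−9.
- Percentages are reported to 2 decimals; implied counts use
  round-half-up.
- PCA orthonormality and variance-conservation identities are asserted
  to 1e−8.

## Known limitations

- The delay-magnitude rule, the state-mechanism composition and the
  persistence value `x = 0.6` are concrete readings of qualitative
  descriptions; alternatives fit the same description and are exposed
  as configuration rather than silently fixed.
- Standard PSO with constant `ω = 0.9` is a deliberately plain baseline;
  it will not refine below ~1e−5 on smooth problems.
- The χ² comparison treats printed percentages as exact; counts implied
  by rounding can shift the statistic by ±0.01 at 2 decimals.
- Single-objective, box-constrained minimization only; no constriction
  factor, no multi-objective variants, no convergence proofs.
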