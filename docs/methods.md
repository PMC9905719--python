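# Methods

This note records the model, the defaults and the judgment calls behind
`watergrade`, at the level of detail a maintainer needs to change them
safely.

## Grading standard

GB3838-2002 defines per-class limits only for DO (lower limits
7.5/6/5/3/1 mg/L for classes I–V), NH₃-N (0.15/0.5/1.0/1.5/2.0), COD_Mn
(2/4/6/10/15) and TDS (150/300/450/550/550); turbidity (≤ 1 NTU,
drinking-water limit) and pH (6–9) are single advisory limits and cannot
map to a class, so `watergrade` exposes them as pass/fail flags only.
Sample labels follow **single-factor assessment**: each limited indicator is
assigned the best class whose limit it satisfies (DO with ≥, the others with
≤), and the sample's class is the worst of these. This rule is standard
practice for the norm, deterministic, and monotone (worsening an indicator
can never improve the class) — the monotonicity is property-tested.

Two quirks are handled explicitly. The TDS limits for classes IV and V
coincide (550 mg/L), so TDS cannot separate those classes; and 550 exceeds
the maximum seen in national monitoring summaries (323.12 mg/L), so the
synthetic generator extends its TDS range to 550 to make the class bands
realizable. Published monitoring tables also list pH and TDS units as
mol/L; these are treated as typos (dimensionless; mg/L).

## Weighted grey relational analysis

Pipeline: min-max normalize each indicator column (Eq. y = (x−min)/(max−min);
constant columns are a hard error so the caller decides), normalize the
class series the same way (`normalize_reference`, default on — the
coefficient mixes both series, so they must share a scale), compute grey
coefficients, weight, rank.

* **Orientation ("leveling").** DO *falls* as pollution worsens, so its
  plain normalization is maximally distant from the class series even though
  it is highly informative. As is usual in grey relational work, cost-type
  series are reversed (y ← 1−y) before comparison; the default orientation
  reverses DO only, and `GreyConfig(orientation={})` disables the step.
* **Coefficient form.** The classical denominator Δ_j(i) + ρ·Δmax is the
  default (`standard`); an alternative without ρ in the denominator
  (`literal`) is kept behind `GreyConfig.denominator_form` for comparison.
  ρ defaults to the conventional 0.5. With Δmin = 0 and ρ = 0.5 the standard
  form is bounded below by 1/3 — a tested invariant.
* **Δ pooling.** Δmin/Δmax are global over all indicators and samples (the
  usual two-level min/max); per-indicator pooling would make coefficients
  incomparable across columns.
* **Degenerate case.** If every series is identical (Δmax = 0) all
  coefficients are 1 by convention.
* **AHP.** Subjective weights are row sums of the comparison matrix over its
  total sum. The consistency ratio uses the principal eigenvalue and
  Saaty's RI table (0.58/0.90/1.12/1.24/1.32 for n = 3..7); CR > 0.1 logs a
  warning but does not abort — the analyst owns the judgments. The
  package's default matrix for the seven indicators encodes one piece of
  domain knowledge: the four standard-regulated indicators (DO, NH₃-N,
  COD_Mn, TDS) are moderately more important (Saaty 3) than the advisory
  ones. It is built as a consistent ratio matrix (CR = 0). This default
  matters: with an all-ones matrix the CRITIC half dominates, and CRITIC
  *structurally favours* indicators that are high-variance and uncorrelated
  with everything — on band-structured data that is exactly the
  uninformative ones (they are uniform over their full range, while
  informative indicators are mutually correlated through the class). A
  subjective prior reflecting the standard's own structure is therefore part
  of the method, not a tuning knob; `ComparisonMatrix.equal(n)` restores
  neutrality when wanted.
* **CRITIC.** σ_j is the sample standard deviation (ddof = 1) of the
  normalized column; r_jl is the inter-indicator Pearson correlation (the
  standard CRITIC reading). Constant columns and the all-correlated case
  (ΣC = 0) are hard errors.
* **Ranking.** Stable sort by descending degree, ties broken by original
  column order; q defaults to 4 selected indicators.

Useful identities (all property-tested): α, β, ω each sum to 1;
s_j(i) ∈ (0,1]; r(j) ≤ ω_j and Σ r(j) ≤ 1; permutation equivariance; scale
invariance under positive affine maps of raw columns; and with ω_j = 1/n,
n·r(j) equals the classical Deng relational degree (checked against an
independently written loop implementation).

## Particle swarm

Canonical global-best PSO, minimization convention. Defaults follow the
published setup: swarm 300, T_max 300, c₁ = 1.6 < c₂ = 2.0 (c₁ > c₂ logs a
warning about local-search trapping), inertia ω(t) = 0.9 − 0.4·t/T_max.
Unspecified mechanics use standard hygiene, chosen once:

* velocities initialized uniformly in ±0.1·(high−low), clamped to
  ±0.5·(high−low);
* positions clipped to the box with the offending velocity component zeroed;
* r₁, r₂ drawn per particle per dimension;
* termination at T_max **or** when the global best improves by less than
  `tol` over a `patience` window (default 20 iterations, tol 1e-12) — the
  operationalization of "precision less than the set error value";
* a non-finite objective value aborts with the offending position.

Identical (objective, config, seed) gives bit-identical trajectories.

## One-vs-one SVM

Features are min-max scaled with parameters fitted on the training split
only; test values may fall outside [0,1] and are not clipped. One
scikit-learn `SVC` per class pair (the binary QP solver is deliberately a
backend detail; construction, scaling, voting and tuning are first-party).
Kernel parameterization is taken literally from the tabulated forms, so the
RBF width r maps to `gamma = 1/r²`, and the polynomial kernel uses
`gamma = 1, coef0 = 1`. Voting: one vote per binary model; ties by largest
summed signed decision value among the tied classes, then lowest class id —
an odd classifier count does *not* eliminate multi-way ties, so a
deterministic rule is mandatory. The voting rule is verified against a
brute-force oracle over randomized decision tables for k = 2..6.

Tuning minimizes the stratified 5-fold cross-validated error rate on the
training split (the tuning objective is otherwise underdetermined, and CV
avoids test leakage), searching log10 C ∈ [−2, 3] and log10 r ∈ [−3, 1].
A search box collapsed to a point short-circuits to that point. Folds whose
training part lacks a class are skipped with a log entry.

## Synthetic generator

The generator emulates the *structure* of national river monitoring data:
indicator ranges from published summaries (DO 0.5–25.67, TEMP 0.04–35.22,
turbidity 0.22–2559.22, NH₃-N 0.02–6.47, COD_Mn 0.25–22.66, pH 6.14–9.98,
TDS 47.43–323.12, extended to 550 as above), six classes, labels induced by
the class limits. For each requested class, informative indicators are
drawn **uniformly inside their class band** (DO in [limit_c, limit_{c−1});
upper-limited indicators in (limit_{c−1}, limit_c]; class 6 beyond the
class-V limit, capped at the range maximum; TDS classes 4–6 share
(450, 550]). Uniform-in-band sampling was chosen over Gaussian noise so the
generated label provably equals the single-factor assessment — testability
over realism. Optional `noise_sd` adds within-band jitter (clipped back
into the band, preserving the labels). Non-informative indicators are
uniform over their full range.

What this does **not** emulate: seasonal/temporal autocorrelation, station
geography, correlated measurement noise, class imbalance, and real data's
smoother within-class distributions. Passing tests therefore demonstrate
the machinery (selection recovers label-determining indicators; the tuned
classifier separates band-structured classes), not field performance on
monitoring data, where class overlap would lower accuracy substantially.

`nonlinear=True` instead places the first two informative indicators on
class-indexed annuli (radius in [2i, 2i+1], unit gaps, angle uniform,
affinely mapped into the indicators' ranges) — radially separable geometry
on which a linear kernel must lose to the RBF, used for kernel-ordering
tests.

## Pipeline

Stage order: clean (row-wise deletion of unparseable rows, counted and
logged — the least-assumption cleaning policy) → stratified seeded split
(default 80/20; the partition depends only on labels and seed, never on
indicator values) → indicator selection on the **training split**
(`select_on_all` restores literal select-before-split for comparison) →
swarm tuning → final training → held-out evaluation. A stage failure aborts
with the stage name; with single-class input this necessarily happens at
feature selection (the class reference series is constant), before training
is ever reached. Each run writes a manifest of all resolved configuration;
replaying a manifest reproduces every report byte-identically (JSON written
with sorted keys, all randomness seeded from the single run seed).

Default run sizes (50-particle, 50-iteration swarm with early stopping) are
the package's desk-scale choice; the published-scale 300 × 300 swarm is a
config change.

## Metrics

Accuracy is total-correct over total (the micro form). Precision and recall
are per-class from the confusion matrix and **macro-averaged** — the
tabulated binary formulas do not specify a multiclass average, macro is the
convention when class balance matters, and micro-precision would merely
duplicate accuracy; both macro and micro are emitted, macro is headline. A
class never predicted gets precision 0 with a log note; classes absent from
both label vectors are excluded from macro averages. RMSE uses the ordinal
encoding I..poor V → 1..6 — the only encoding consistent with the classes'
severity order.

## Known limitations

* The selection stage's subjective default reflects the grading standard's
  structure; for questions where the advisory indicators matter (e.g.
  thermal pollution), supply a different comparison matrix.
* CRITIC weights are anti-correlated with relevance on data containing
  pure-noise columns (see above); weighted GRA inherits this and the
  package makes no attempt to hide it.
* The polynomial kernel's degree is tuned by rounding a continuous swarm
  coordinate — adequate, but coarse.
* Model archives are joblib pickles; they are versioned but not portable
  across major scikit-learn versions.
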