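# Methods

This note documents the models, conventions and numerical choices behind
`looptrax`, and what the synthetic-data generators do and do not emulate.

## Cohort data model

A cohort is a table of individuals with an E9.5 looping class (1–4, or
unknown) and categorical E18.5 anatomical parameters. Controlled
vocabularies live in a JSON schema (`src/looptrax/data/default_schema.json`),
not in code, so mouse and human cohorts with different variable sets share
one reader. Unknown/ambiguous values are a first-class state: they are never
coerced to a category, and each analysis declares which variables must be
known for a record to enter it. Two named analysis sets ship by default: an
11-variable E18.5 set for the MCA (which additionally requires a known
looping class and excludes any record with an unknown/ambiguous value in the
set — no imputation), and a 14-variable superset for classification (which
requires only a known response; a forest can carry "unknown" as a predictor
level). This split reproduces the familiar exclusion pattern in which the
ordination uses slightly fewer individuals than the classifier.

The shipped schema is **illustrative**: variable names follow the anatomy
annotated in heterotaxy studies (ventricle laterality D/L, great-artery
malposition D/L/A, apex position, ventriculo-arterial connection, ventricle
and arterial-trunk hypoplasia, atrial situs, arch side, venous returns,
bronchial isomerism, AVSD, VSD), but a real cohort's table should bring its
own schema file.

## Septum-orientation geometry

Three points on the interventricular-septum plane define its unit normal
(normalized cross product of the two edge vectors). The anatomical frame is
built from two spine points (craniocaudal axis u_cc), two dorsoventral
points orthogonalized against the spine (u_dv, exactly 90° by construction),
and u_lr = u_cc × u_dv (right-handed). The orientation components are the
three dot products; since the frame is orthonormal their Euclidean norm is
1 by construction.

Numerical conventions:

- A normal from three unordered points is sign-ambiguous, so the component
  vector is canonicalized to the hemisphere c_lr ≥ 0, ties broken by
  c_dv ≥ 0 then c_cc ≥ 0 (and `plane_normal` itself makes its
  largest-magnitude coordinate positive, so point relabeling cannot flip
  it). The anatomical meaning of +u_lr (subject's left vs right) is a
  config concern of the consuming pipeline, since scanner axis polarity
  varies.
- Input vectors are checked for unit norm / orthonormality at 1e-6;
  internally constructed frames meet 1e-9.
- The control reference interval is the central empirical interval (default
  coverage 99%) per component, with linear interpolation between order
  statistics; at least 10 controls are required. With ~23 controls the
  0.5%/99.5% quantiles sit essentially at the sample extremes, so the
  interval under-covers slightly — a property of the method itself at that
  control count, visible in the simulations as a handful of
  boundary-spillover calls.
- Classification: inside the interval on every component → normal;
  otherwise the component of largest absolute value decides —
  left-right → strictly left-right ventricles, dorsoventral →
  superoinferior ventricles. A craniocaudal-dominant outlier is recorded as
  `abnormal_other` rather than forced into either class, since the
  dominant-component rule only names those two categories.
- Hypoplasia grading uses configurable reference intervals on the RV/LV
  outer-volume ratio and the aortic/pulmonary valve-diameter ratio (below
  the interval → hypoplastic numerator organ, above → denominator organ);
  the defaults are expected to be learned from controls, and no numeric
  thresholds are hard-coded.

## Trajectory calling and kinetics

Classes 2 and 4 loop rightward, classes 1 and 3 leftward. The congruence
postulate maps rightward → D and leftward → L; mismatches are revertants,
and any unknown input leaves the individual unclassified (excluded from all
fraction denominators, reported separately). Stage kinetics pool
cross-sectional stage cohorts into two epochs around a split stage (default
E13.5, the remodeling window) and compare pooled rightward proportions with
a Pearson χ² test without continuity correction; per-stage standard errors
are binomial √(p(1−p)/n).

## Association statistics

The two-sided Fisher exact p is the sum of probabilities of all
margin-compatible tables as or less probable than the observed one (the
standard convention; stated because alternatives exist). 2×2 tables are
enumerated hypergeometrically. For r×c tables the full fixed-margin table
space is enumerated recursively (probabilities via log-gamma, with a 1e-7
relative tie tolerance) while a cheap product bound keeps the table count
under a budget of 10⁷; beyond it, a Monte Carlo estimate permutes one
margin's labels (default 10⁵ replicates), returns the add-one p
(1+hits)/(R+1), and records replicates, standard error and seed in the
result metadata. Cohorts of ~40 keep essentially every scan on the exact
path. Degenerate tables (an all-zero margin) give p = 1 with a warning.
Pairwise scans drop unknowns pairwise (per test, maximizing usable samples,
with per-test n reported), skip features with fewer than two observed
levels, BH-adjust across the scan (statsmodels), and sort by p.

## Multiple correspondence analysis

Indicator-matrix CA (not Burt): with Z the complete disjunctive matrix over
Q variables and J levels, the standardized residual matrix
S = D_r^{−1/2}(P − rcᵀ)D_c^{−1/2} of P = Z/(nQ) is decomposed by SVD.
Eigenvalues are squared singular values and satisfy Σλ = (J−Q)/Q (checked to
1e-10 in the tests); individuals and levels are reported in principal
coordinates; the contribution of level j to dimension k is
100·c_j·g_jk²/λ_k (summing to 100 per dimension). The v-test of a level is
its carriers' mean individual coordinate scaled by
√(n_j(n−1)/(n−n_j))/σ_k — algebraically √(n_j(n−1)/(n−n_j))·g_jk — which
behaves like a Z score for supplementary-style interpretation; |v| > 2 flags
strong associations. Note that levels which *define* a leading dimension
legitimately score far above 2 even between independent variables when Q is
very small; with realistic Q (≥ 3) planted associations dominate independent
noise levels by an order of magnitude (verified in the tests). Each
dimension's sign is canonicalized so its largest-|coordinate| level is
positive, making runs reproducible.

## Classification and the permutation null

The base learner is a scikit-learn random forest on one-hot encoded
predictors; "mtry" counts original variables sampled per split and is mapped
proportionally onto the encoded columns, and Gini importances are summed
back per original variable. The tuning grid defaults to
mtry ∈ {1, ⌈√p⌉, ⌈p/2⌉, p} × trees ∈ {100, 250, 500} — at n ≈ 40 the LOO
accuracy is insensitive to tree counts beyond a few hundred, so the grid
stops at 500; it is config and recorded in output metadata. LOO-CV scores
every grid point with n single-holdout fits; all grid points tied at the
maximum accuracy are kept and their full-data importance vectors averaged
into the consensus ranking (ties broken stably by variable name).

Accuracy is then measured by an independent LOO pass with a distinct
deterministic sub-seed (the two passes differ by seed, not by partition
scheme — LOO has a single partition). The permutation null replaces, at
every fold, the model's prediction by a label drawn uniformly from the
training fold's n−1 responses, scored against the true held-out label — the
held-out label itself is never a candidate, so there is no leakage, and the
expected null accuracy is Σ_c n_c(n_c−1)/(n(n−1)), the squared training
frequencies. B defaults to 5000. The reported p is the plain empirical
fraction #{null ≥ observed}/B (which can be exactly 0 on separable data),
always accompanied by the conservative add-one variant (1+#)/(B+1). Null
replicates are vectorized (no model refits), so B is cheap; the cost is the
two LOO passes.

## Survival

Kaplan-Meier estimation and the k-group log-rank test are delegated to
lifelines behind a typed surface; Greenwood variance is accumulated from the
risk table (Var S = S²·Σ d_i/(n_i(n_i−d_i))) and the 95% band uses the
log(−log S) scale so it stays inside [0,1]. Ties between deaths and
censorings at the same time follow the standard convention (deaths first).
The module is unit-agnostic in time.

## Synthetic-data generators

The generators define the study conditions for every test and for the
acceptance script:

- **Cohort**: looping class ~ class_probs, default (.225, .275, .225, .275)
  — a 45/55 leftward/rightward split; final laterality flips from the
  congruent one with probability 11/18 after leftward and 1/22 after
  rightward looping (so the analytic revertant mixture is ≈ 0.30 and the
  final D proportion ≈ 0.80); E18.5 features then draw from
  trajectory-group-conditional tables. The shipped tables are
  **illustrative** — real association strengths are a property of the data
  and not published as tables — but plant the structure the analyses look
  for: revertants enriched in abnormal septum orientation and ventricle
  hypoplasia, great-artery malposition tracking final laterality, apex
  position tracking looping direction. Missingness defaults mirror a
  43-individual cohort's exclusion pattern (~2 unknown looping classes, ~1
  unknown laterality, ~3 ambiguous atrial situs). Kinetic stage cohorts
  draw binomially at the looping-direction probability before E13.5 and the
  final-D probability from E13.5 on.
- **Landmarks**: per group, a mean unit septum normal in a common template
  frame; noise is an isotropic tangential Gaussian perturbation of the
  normal (parameterized by angular SD in degrees, default 5°) followed by
  renormalization — simple and oracle-checkable (zero noise reproduces the
  mean exactly; dispersion grows monotonically with σ). The default case
  mixture (27 normal-position, 6 superoinferior, 7 strictly left-right
  generating orientations against 23 controls) mirrors a patient-cohort
  composition.
- **Survival**: exponential event times per group hazard (default hazard
  ratio 2), independent exponential censoring truncated at an
  administrative horizon.

All generators are pure functions of (model, seed); one master seed fans out
into per-stream sub-seeds via `SeedSequence.spawn`, so adding a stream never
perturbs existing ones.

What the generators do **not** emulate: litter/batch structure, correlated
missingness, within-class shape variation at E9.5, non-exponential patient
hazards, and measurement error in landmark placement beyond isotropic
angular noise. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated generative structure, not the effect
sizes of any real cohort.

## Problem sizes

The test suite and the acceptance script run at deliberately modest sizes
chosen as sufficient for their purpose: convergence checks at n = 4000–10⁴
(binomial 3·SE bands), calibration of the permutation test over 200 null
cohorts of n = 40 with B = 500 and a 30-tree forest, log-rank calibration
over 200 replicates at n = 100/group and power at n = 500/group, and the
study-scale pipeline itself at n = 43 with B = 5000. The full Fisher-oracle
sweep covers every 2×2 table with margins ≤ 12 plus 100 random small r×c
tables against an exact-Fraction enumeration oracle.

## Known limitations

- The craniocaudal-dominant abnormal orientation category is reported as
  `abnormal_other`; the dominant-component rule names only the left-right
  and dorsoventral cases.
- The r×c Monte Carlo Fisher p is an estimate; its SE is reported, and the
  exact path covers all realistic cohort sizes here.
- Consensus importances come from full-data fits of the tied-best grid
  points, not from per-fold refits; at LOO scale the difference is
  negligible and the full-data fit is the standard reporting object.
- With very few controls the empirical 99% interval under-covers; a
  parametric (e.g. Gaussian tolerance) interval would trade robustness for
  coverage and is deliberately not the default.
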