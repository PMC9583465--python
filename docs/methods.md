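# Methods

## The measurement and the model

Respiratory oscillometry (the forced oscillation technique, FOT) superimposes
small pressure oscillations on tidal breathing and measures the complex
respiratory impedance Zrs(f) — resistance (real part) and reactance
(imaginary part) — here on the standard clinical grid of multiples of 2 Hz
from 4 to 32 Hz.  This package starts at the impedance level: estimating
Zrs from raw pressure/flow signals is out of scope.

Impedance spectra are interpreted through the extended RIC (eRIC) circuit, a
two-compartment electrical analog: central resistance R in series with
inertance I and a parallel block of peripheral resistance Rp and compliance
C.  Its impedance at angular frequency w = 2*pi*f is

    Z(w) = R + Rp/(1 + (w*Rp*C)^2) + j*( w*I - w*Rp^2*C/(1 + (w*Rp*C)^2) )

with total resistance Rt = R + Rp.  Units are the FOT conventions:
cmH2O.s/L (resistances), cmH2O.s^2/L (inertance), L/cmH2O (compliance).
Setting the imaginary part to zero gives the closed-form resonant frequency

    f_r = (1/2*pi) * sqrt( (Rp^2*C - I) / (I * Rp^2 * C^2) ),

real only when Rp^2*C > I; it is the independent oracle against which the
interpolated resonant-frequency feature is tested.

## Features

Eleven FOT indexes per exam: R0, S and Rm (OLS intercept, slope and mean of
resistance over 4–16 Hz, boundaries inclusive); R4, R20 and R4−R20 (exact
grid lookups); Xm (grid-mean reactance over 4–32 Hz); Fr (zero crossing of
reactance, linearly interpolated between bracketing grid points; when no
crossing is measured below 32 Hz it is linearly extrapolated from the last
two points and capped at 64 Hz); Cdyn = −1/(2*pi*4*X4), reported missing
when X4 ≥ 0; Ax (trapezoidal integral of the negative reactance lobe from
4 Hz to min(Fr, 32 Hz) — only observed signal is integrated, so the area
stops at 32 Hz even when Fr is extrapolated beyond it); and Z4 =
sqrt(R4² + X4²).

Five eRIC components (R, Rp, I, C, Rt) are estimated per exam by bounded
trust-region damped least squares (the bounded counterpart of
Levenberg–Marquardt) on the stacked real/imaginary residuals, both parts
weighted equally.  The loss surface has mirror local minima in the (Rp, C)
split, so a fixed multi-start list is derived from data landmarks — the
low/high-frequency resistances for the R/Rp split, the high-frequency
reactance slope for I, a decade scan for C — and the best residual is kept.
The procedure is deterministic for a given spectrum; a fit that converges
from no start is returned flagged, never raised.  On noiseless 15-point
spectra the estimator recovers parameters to machine precision; under 1%
multiplicative noise the median relative error of every component stays
below 1% (the test suite re-measures both).

Together these form the 16-feature record in fixed column order
R0,S,Rm,R4,R20,R4_R20,Xm,Fr,Cdyn,Ax,Z4,R,Rp,I,C,Rt.

One caution on a tempting "sanity" bound: R0 ≤ Rt does *not* hold in
general.  The OLS intercept overshoots Rt whenever the resistance roll-off
(around 1/(2*pi*Rp*C)) falls inside the 4–16 Hz regression band; overshoots
of ~0.25 cmH2O.s/L occur even under the default cohort distributions.  The
true brackets are R ≤ R0 and R20 ≥ R.

## Synthetic cohort

The clinical dataset that motivated this package (25 healthy controls, 24
sarcoidosis patients with normal spirometry, 23 with altered spirometry;
three replicate exams averaged per subject) is not publicly deposited, so a
generator emulates it.  Per group, eRIC parameters are log-normal —
positivity and the right-skewed, outlier-heavy distributions seen in real
FOT cohorts — with disease encoded as a multiplicative shift of the median.
Defaults (medians; control group): R 2.0, Rp 1.2, I 0.008, C 0.020, with
log-scale s.d. 0.25/0.30/0.25/0.30.  Disease shifts: normal-spirometry
group {R ×1.10, Rp ×1.40, I ×1.05, C ×0.75}; altered-spirometry group
{R ×1.15, Rp ×1.50, I ×1.08, C ×0.70}.  Raising Rp and lowering C raises
Rt, Fr, Ax and Z4 and lowers Cdyn — the direction of effects the emulated
study reports — and the shift sizes were calibrated once, on a
500-per-group draw, so the best univariate feature AUCs sit near 0.80
(normal-spirometry analysis) and 0.86 (altered), the reported regime.

Draws are truncated to the measurable regime: a parameter set whose
noiseless reactance at 4 Hz is non-negative (resonance below the band edge;
~4% of unconstrained draws) is redrawn, because every subject in the
emulated population had Cdyn, Fr and Ax recorded.

Replicate noise is multiplicative Gaussian (default relative s.d. 0.03),
independent per frequency and per part; the stored spectrum is the
arithmetic mean of the replicates.  The level is a free knob, not a claim
about any instrument — the source study reports no within-subject
variability.  What the generator does **not** emulate: demographic
covariates, breathing artifacts, frequency-correlated measurement error,
and any real-data deviation from the eRIC topology itself (every synthetic
spectrum is exactly eRIC plus noise, which makes the inverse fit easier
than on real exams).  Passing tests therefore validate the machinery and
the direction/size of simulated effects, not clinical performance.

## Fuzzification

Each crisp feature X is mapped to three triangular memberships anchored at
the training minimum, midpoint (X_min+X_max)/2 and maximum: X_low falls
1→0 over [min, mid]; X_medium peaks at the midpoint; X_high rises 0→1 over
[mid, max].  X_medium is computed as 1 − X_low − X_high, so the partition
of unity is exact by construction.  Values outside the training support are
clipped to it before evaluation (equivalent, for this triangle family, to
clipping memberships, and easier to reason about); ties with the training
extremes get exact vertex memberships, no epsilon nudging.  Inside
cross-validation the scheme is always fitted on the training fold only.

## Interpretable classifiers

Two expression dialects share one tree type:

* **arithmetic** (z-scored features): add, sub, mul and protected division
  (|denominator| < 1e-6 → 1); terminals are features or constants in
  [−1, 1]; the classifier score is the sigmoid of the tree value.
* **fuzzy** (fuzzy pattern trees, membership features): max, min,
  WA(a,b,r) = r·a + (1−r)·b, OWA(a,b,r) = r·max(a,b) + (1−r)·min(a,b),
  dilator (square root) and concentrator (square).  All operators are
  closed on [0, 1], so the raw tree value is the score.  Generated weights
  r come from {0.1, …, 0.9}, but the evaluator accepts any fuzzy subtree in
  the weight slot — evolved trees can and do use a membership as the weight
  (e.g. WA(Fr_medium, Fr_high, I_medium)).

**Tree GP** evolves these trees directly: ramped half-and-half
initialisation over depth range (2, 6), tournament selection (size 7),
subtree crossover (p = 0.9; a child exceeding the depth cap is replaced by
a copy of its parent), subtree mutation (p = 0.1; grow method within the
remaining depth budget), fitness = training AUC of the scores, and the
best-ever individual tracked across generations (elitism of record, not of
population).  The depth cap defaults to 6 for interpretability.  Crossover
and mutation rates follow classical GP practice; the original experiments
did not publish theirs, nor their exact fitness, so these are documented
substitutes.

**Grammatical evolution** evolves integer-codon genomes (8-bit codons,
length 100) decoded through a BNF grammar by leftmost derivation: at each
rule with n ≥ 2 productions the next codon picks `codon mod n`
(single-production rules consume nothing); the codon stream wraps at most 3
times; a derivation deeper than 12 or left with non-terminals when the
budget is spent is *invalid* — a value, assigned worst fitness, never an
exception.  The two shipped grammars (`grammars/*.bnf`) are reconstructions
that generate exactly the expression families above; the original grammar
figure is not machine-readable, so these are equivalent-by-construction,
not transcriptions.  Both grammars are depth-critical (recursion
probability ½ at the top rule), keeping the invalid fraction of a random
initial population well under 50%.  The GA uses tournament selection,
variable one-point crossover (independent cut points, rate 0.9) and
per-codon mutation (rate 0.01).

Evolved models render to plain prefix text (e.g.
`OWA(concentrator(Rp_medium), Ax_medium, 0.6)`) and parse back for scoring.

## Evaluation protocol

Two analyses per experiment: control vs. disease-with-normal-spirometry and
control vs. disease-with-altered-spirometry.  Three experiments:

1. univariate AUC of each crisp feature, computed on the full analysis
   subset without CV (a lone feature has no fitted parameters), orientation
   corrected to max(AUC, 1−AUC);
2. nested cross-validation: stratified 10-fold outer split; per outer fold,
   z-scoring or fuzzification fitted on the outer-training rows only;
   exhaustive grid search by stratified 5-fold inner CV on AUC (the source
   protocol fixes neither the inner fold count nor the metric; 5/AUC are
   this package's choices), ties broken toward the first option in grid
   order; refit on the full outer-training fold; a single pooled ROC/AUC
   over the concatenated outer test folds;
3. experiment 2 plus recursive feature elimination.  The elimination signal
   is model-agnostic — the inner-CV AUC drop on removal, ties dropping the
   later column — because KNN and SVM have no native importances.  The
   elimination path is computed once per (fold, algorithm) at the
   grid-chosen hyperparameters and the surviving-feature count is then
   selected along that nested path by inner-CV AUC (the RFECV approach;
   re-running the full elimination per candidate count would be
   combinatorially infeasible for the evolutionary learners).  Count
   options: 1–15 (crisp) / 1–47 (fuzzy), reduced to {4, 8, 12} / {12, 24,
   36} for GP and GE.

The default roster has nine score-producing families — KNN, SVM, AdaBoost,
RF, LGBM, XGB, LR, DT and GP — so one experiment enumerates 9 × 2 analyses
× 10 folds = 180 sub-experiments per representation; GE is registered and
swappable for (or addable to) GP.  SVM contributes raw decision values to
the ROC (no probability calibration); the others class-1 probabilities.
The LGBM/XGB grids are shipped in the corrected orientation (estimators
10–400, depth 1–60); the originally printed rows appear swapped and remain
available as `printed_grid`.

Group comparisons use Shapiro–Wilk per feature/group followed by two-sided
Mann–Whitney (the features are non-normal), significance at p ≤ 0.05, no
multiple-testing correction (matching the emulated report); fuzzy features
are compared on their membership values; zero-variance features are
reported with p = 1 and a flag.  Feature selections aggregate into a
selection-frequency table (denominator: algorithms × folds), and absolute
LR weights are averaged across folds for the importance comparison.

## Reproducibility and problem sizes

A single global seed fans out to per-stage seeds by SHA-256 hashing of the
stage name, so stages rerun in isolation see the streams they saw in a full
run.  Simulation, evolution and cross-validation are pure functions of
their seeds; identical seeds give identical champions and byte-identical
result files.

Default problem sizes keep every check desk-scale: the shipped cohort is
72 subjects; evolutionary runs in the harness default to population 100 ×
20 generations; the acceptance script runs the reduced roster LR + DT + GP
for the nested-CV experiments and LR + DT for the feature-selection
experiment.  The full Table-style grids remain available and are the
defaults of the standard learners' registry entries.

## Known limitations

* Real exams deviate from the eRIC topology; the inverse fit's
  near-perfect recovery here reflects the simulator's fidelity to its own
  forward model, not expected real-data accuracy.
* The original initialisation of the reference fitting program is
  undocumented; the multi-start list is a substitute, not a reproduction.
* Univariate AUCs (experiment 1) are in-sample by design and optimistic
  relative to cross-validated estimates.
* The RFE path approximation can differ from per-count re-elimination when
  feature interactions are strong.
* Fr beyond 32 Hz is an extrapolation capped at 64 Hz; Ax integrates only
  the observed band.
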