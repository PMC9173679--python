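# Methods

`myotriage` implements the analysis pipeline behind 0/1h biomarker triage
of suspected non-ST-elevation myocardial infarction (NSTEMI): synthetic
cohort generation, application and grid derivation of rule-out/rule-in
threshold sets, the diagnostic-accuracy statistics used to validate them,
and survival by triage category.  This note records the models, the
parameter choices that matter, and the design decisions taken where the
design was genuinely open.

## The triage model

A 0/1h algorithm maps a patient's biomarker concentration at presentation
(`c0`, ng/L), the concentration one hour later (`c1`), and the chest-pain
onset interval to one of three mutually exclusive categories.  Writing
`Δ = c1 − c0` (signed for cMyC; unsigned magnitude `|c1 − c0|` for the
ESC-style troponin rules), a rule set with slots
(`r_single`, `r_paired`, `δ_out`, `R0`, `δ_in`) is evaluated in order:

1. **rule-in, 0 h**: `c0 ≥ R0`;
2. **rule-out, single sample**: `c0 < r_single` (optionally only when
   onset > 3 h; the cMyC rule applies it irrespective of onset);
3. **rule-in, delta**: `Δ ≥ δ_in`;
4. **rule-out, paired**: `c0 < r_paired` and `Δ < δ_out`;
5. otherwise **observe**.

Rule-out comparisons are strict ("below"), rule-in comparisons inclusive
("at least").  Steps 1–2 use the presentation sample only; a patient
resolved there never consults the delta.  This ordering is one of the few
genuinely open points (the published flow diagrams do not print a
precedence): we place the 0 h criteria first so that the "ruled out
directly at presentation" proportion is well defined, and the order is
configurable (`precedence=`) for sensitivity analyses.  The only patients
the order can move are those qualifying simultaneously for the
single-sample rule-out and the delta rule-in (e.g. `c0 = 9`, `Δ = +16`
under the cMyC thresholds); the default resolves them to rule-out.

A missing 1 h sample yields INDETERMINATE rather than observe, so that
efficacy denominators are explicit.  The dual-marker ("triage-booster")
variant inserts a second marker's 0 h criteria as alternative direct
branches: base 0 h rule-in, booster 0 h rule-in, base single-sample
rule-out (onset-gated), booster single-sample rule-out, then the base
0/1 h logic.  Sentinel booster thresholds (0, ∞) reproduce the base
algorithm exactly, which is property-tested.

The reference cMyC rule set is (10, 18, 4, 140, 15) ng/L with signed
deltas and no onset gate.  Numeric thresholds for the ESC hs-cTnT/I
algorithms ship as *editable templates* that users must verify against the
current guideline; they are configuration, not validated constants.

## Accuracy statistics

Let the triage table have rule-out / observe / rule-in columns split by
adjudicated NSTEMI.  With `P` positives and `N` negatives overall:

- **sensitivity** `= 1 − (ruled-out positives)/P`, i.e. rule-out safety;
  **specificity** `= 1 − (ruled-in negatives)/N`, i.e. rule-in accuracy.
  Both are raw proportions with Wilson score intervals.
- **NPV / PPV** are group-conditional probabilities estimated with a
  Jeffreys Beta(½, ½) prior: posterior mean `(x + 0.5)/(n + 1)` over the
  rule-out (disease-free `x`) or rule-in (diseased `x`) group.  The
  default interval is the equal-tailed posterior credible interval;
  `interval="hpd"` gives the highest-posterior-density interval, which is
  the variant that produces one-sided-looking published intervals such as
  "99.57% (98.88–100)" (the posterior is J-shaped when `x = n − 1` at
  large `n`).  An empty group returns the prior mean 0.5 flagged
  degenerate — never a silent zero.
- **likelihood ratios** `LR+ = sens/(1 − spec)`, `LR− = (1 − sens)/spec`,
  with log-method intervals.
- **efficacy** = proportion triaged to either rule-out or rule-in,
  reported separately for decisions based on the 0 h sample alone and for
  the completed 0/1 h algorithm.

Paired algorithm comparisons on the same patients use McNemar's
chi-square (discordant pairs; `(b − c)²/(b + c)`, continuity correction
off by default) for sensitivity, specificity and triage proportions, and
a **generalized score test** for NPV/PPV.  The score test treats every
group membership (patient ruled out under A and/or under B) as a record
of a marginal identity-link model with a group-effect covariate, evaluates
the score at the pooled null estimate, and uses the empirical cluster-level
variance of the efficient score — patients in both groups form two-record
clusters, which is how the pairing and the membership weights
`n_B/(n_A + n_B)` enter.  Under null simulations (two equal-accuracy rules,
n = 200, 10⁴ replicates) its type-I error is 0.050 at α = 0.05; the test
suite re-runs that calibration and also checks the p-value against a
percentile-bootstrap oracle on a fixed 40-patient dataset.  The
calibration simulations use moderate-accuracy rules (sens = spec = 0.8 at
prevalence 0.3): at triage-like accuracy (sens ≈ 0.99) discordant pairs
are so rare that both tests are degenerate and a calibration check carries
no information.  No multiple-testing adjustment is applied anywhere.

## Threshold derivation

`derive_optimal` searches a candidate grid over the five threshold slots
for combinations meeting pre-defined targets — NPV ≥ 99% and
sensitivity ≥ 99% in the rule-out group, PPV ≥ 70% in the rule-in group —
and returns the feasible combination maximising efficacy (an alternative
`objective="rule_out"` maximises the rule-out count).  Constraint metrics
are computed with the *same* estimators as the reporting layer (Jeffreys
NPV/PPV, raw sensitivity), so the returned rule set re-evaluated on the
same cohort satisfies the targets without drift.  Ties break
deterministically: greater rule-out count, then higher 0 h rule-in
threshold, then lexicographically smallest remaining slots.

The original study's candidate grid is unknown; the default is integer
ng/L steps over [2, 30] for the three rule-out slots, [50, 300] step 10
and [5, 50] step 1 for the rule-in slots (~11.4 million valid
combinations).  Exhaustive enumeration is retained for small grids and as
the test oracle; the production path is an exact decomposition — the
rule-out group depends only on (`r_single`, `r_paired`, `δ_out`), the
rule-in group only on (`r_single`, `R0`, `δ_in`), and the feasibility
constraints are group-local — with precomputed count tables, so the
optimum provably equals brute force (verified on random 3⁵ grids).  An
infeasible search returns an explicit infeasibility result carrying the
per-constraint best achieved values and the unconstrained efficacy
maximiser, never an exception dressed as success.

## The synthetic cohort generator

Patient-level data behind triage studies are not public; the generator
reproduces the *reported statistical structure* so the pipeline can be
exercised and property-tested at scale:

- **Class mixture.** Each patient is NSTEMI with probability 0.17
  (published prevalence); labels are independent Bernoulli draws, so the
  observed fraction varies binomially around the prevalence.
- **Concentrations.** Per class and marker, 0 h concentrations are drawn
  from a quantile-matched distribution pinned to the published per-class
  quartile triplets (cMyC NSTEMI 211 [58; 689] ng/L, non-NSTEMI
  13 [7; 28], and the corresponding hs-cTnT/I anchors).  The public
  `fit_quartile_distribution` primitive interpolates the inverse CDF
  piecewise-linearly between anchors with symmetric exponential tails of
  scale `tail_scale × IQR`.  Inside the generator, concentration anchors
  are interpolated *on the log scale* (still exact quantile matching, not
  a parametric lognormal fit) with asymmetric exponential log-tails:
  lower 0.2 × log-IQR, upper 0.7 × log-IQR for the control class and
  0.3 × log-IQR for NSTEMI.  Rationale: biomarker spread is
  multiplicative; a linear-scale IQR-wide lower tail would put roughly a
  quarter of NSTEMI patients at the assay floor, irreconcilable with the
  release kinetics of a cardiac-restricted protein and with the observed
  ~99% rule-out sensitivity at a 10 ng/L cut-off; and the control class
  (which includes non-coronary myocardial injury) produces occasional
  very high concentrations, reflected in the heavier control upper tail
  (~5% of synthetic controls exceed the 140 ng/L rule-in threshold,
  matching the published order of rule-in false positives).  These
  factors were fixed once from the published tables and physiology.
- **Deltas.** Signed cMyC changes are drawn from their printed signed
  anchors on the linear scale (anchors such as 0 [−2; 2] span zero and
  must not be log-modelled); troponin changes, printed as unsigned
  magnitudes, are drawn as magnitudes with a positive sign probability of
  0.95 (NSTEMI) / 0.70 (control), since triage needs signed series but
  only magnitudes are constrained.  Each linear tail scales with the
  adjacent anchor gap (median − q1 below, q3 − median above): symmetric
  anchors behave as with an IQR-wide scale, while skewed magnitude
  anchors such as 27 [6; 124] keep a sharp left edge instead of piling a
  quarter of their mass onto the zero floor.
  `c1 = max(c0 + Δ, LoD)`; all concentrations are floor-censored at the
  assay LoD of 0.4 ng/L.
- **Dependence.** Within a marker, the 0 h level and the delta (signed
  value or magnitude) are rank-coupled through a Gaussian copula with
  Spearman correlation 0.5 in NSTEMI (rising curves: higher levels go
  with larger rises) and 0 in controls; across markers, 0 h levels share
  a Gaussian factor with loading 0.6, since a patient with high cMyC
  usually has high troponin too — this matters for the paired tests and
  the dual-marker analyses.  The published tables give no joint structure;
  these are configurable defaults.
- **Onset.** Uniform(0, 3] hours with probability 0.38 (the published
  early-presenter fraction, 250/663), else Uniform(3, 12] — the enrolment
  window is 12 h.
- **Survival.** Each patient gets an exponential event time with a
  per-triage-category hazard (rule-out 1 × 10⁻⁵, observe 1 × 10⁻⁴,
  rule-in 4 × 10⁻⁴ per day; ≈ 0.4%, 3.6%, 13.6% one-year mortality),
  administratively censored at 365 days.  The category used for hazard
  assignment is the reference cMyC rule set applied to the patient's own
  synthetic values.  The published mortality figure prints no event
  counts, so the hazards are chosen only to order
  rule-in > observe > rule-out and are not calibration targets; the
  survival module is validated against closed-form and simulation oracles
  instead.
- **Demographics** (age per class from the published quartiles, sex,
  renal disease) exist solely to exercise subgroup filters.

What the generator does *not* emulate: serial 2/3/6 h samples,
assay measurement error beyond LoD censoring, enrolment logistics, and
any residual real-data structure not captured by per-class quartiles plus
the stated copulas.  Consequently the synthetic cohort is *harder* than
the real one in the rule-out direction (the real NSTEMI class evidently
had almost no mass below 18 ng/L at presentation, while any smooth
quantile-matched model keeps a little), so the published threshold set
typically shows ~98–99% sensitivity here rather than 99.1%, and a derived
rule set may pick slightly different cut-offs.  Passing tests therefore
demonstrate that the *machinery* (classification, derivation, estimators,
tests) is correct under realistic structure — not that the generator
recreates the original patients.

## Numerical and interface choices

- Exact quartile reproduction is testable: empirical 25/50/75 percentiles
  of 10⁵ draws must sit within ±2% (relative; ±0.3 ng/L absolute for
  anchors spanning zero) of every anchor used.
- Derivation feasibility comparisons use the identical floating-point
  expressions in both search modes, so exhaustive and decomposed searches
  agree bit-for-bit.
- Rule-set validation allows zero/infinite rule-in sentinels so neutral
  boosters can be expressed; degenerate anchors (q1 = median = q3)
  collapse to a point mass.
- Cohorts travel as plain CSV with a documented column dictionary;
  missing 1 h samples are empty fields, rejected rows are reported with
  1-based file line numbers.  Reports store integer counts next to every
  rendered percentage (one decimal on percentages, two on likelihood
  ratios), and the run manifest records seed, configuration and its hash,
  so a bundle is reproducible byte-for-byte and auditable back to counts.
- The 1:1 derivation/validation split is simple random (unstratified),
  reproducing the published design; `round(ratio × n)` patients go to the
  derivation half.
- Default problem sizes: distribution checks at n = 10⁵ draws; triage
  property sweeps over 10³ random cohorts; derivation oracle equivalence
  on 3⁵ grids with 500-patient cohorts; null calibrations at 10⁴
  replicates; the end-to-end example runs 2 000 patients.  These sizes
  make the Monte-Carlo tolerances quoted above meaningful while keeping a
  full run on one CPU in the minutes range.

## Known limitations

- The weighted generalized score statistic of the originally cited R
  package may weight slightly differently (the exact variant is not
  printed in the source we reproduce); ours is validated by calibration
  and bootstrap agreement, not by output-matching that package.
- The prognosis module truncates at the horizon (administrative
  censoring) for the 30-day log-rank; a study could instead have used a
  separate 30-day dataset.  With no censoring before the horizon the two
  coincide.
- Predictive-value comparisons require both algorithms' groups to be
  non-empty; the error message points to a bootstrap fallback, which is
  not built in.
- Cross-validated or bootstrap-smoothed threshold selection is out of
  scope; the derivation reproduces the single-split published procedure.
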