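# Methods

## The pipeline

`adta` implements automated digital tumor-infiltrating-lymphocyte analysis
(ADTA) for primary cutaneous melanoma. The input boundary is deliberately
the *output* of an upstream lymphocyte detector: for every whole-slide
image, a table of 100×100-pixel patches, each row carrying the patch's
upper-left pixel coordinates and a probability that lymphocytes are
present. The pipeline owns everything downstream of that table:

1. **Tumor restriction.** A pathologist's tumor loop (GeoJSON polygon in
   pixel coordinates) is converted to a binary mask; only patches inside
   the tumor count. A patch is "inside" iff the centre of its centre pixel
   lies inside the polygon set under the even-odd fill rule (holes
   subtract). The fill rule is implemented as the symmetric difference of
   ring interiors, which coincides with "outer minus holes" for nested
   rings and remains unambiguous for overlapping loops.
2. **Image score.** With positivity threshold τ (default 0.775, the
   detector's published operating point), the image score is
   s = (# in-tumor patches with p ≥ τ) / (# in-tumor patches).
3. **Patient score.** The median of the patient's image scores (even
   count → mean of the two central values).
4. **Risk classification.** Patients with score ≥ c are *low risk* (high
   infiltrate, better prognosis); below c, *high risk*. The default
   c = 0.065 is the value selected on the original training cohort.
5. **Cutoff selection.** On a training cohort, an ROC of patient scores
   against the died-of-melanoma label (orientation: low score predicts
   death) over midpoint candidate thresholds with ±∞ sentinels; the
   operating point maximizes Youden's J = sensitivity + specificity − 1,
   ties broken toward the smaller threshold (fewer patients called
   high-risk). AUC is the trapezoid area, equal to the two-sample
   concordance probability with half-credit for ties.
6. **Survival validation.** Kaplan–Meier curves per risk group with
   at-risk counts (default report times 0 and 100 months), the two-group
   log-rank (Mantel–Cox) test, univariable Cox proportional-hazards models
   for the risk indicator and each standard pathology covariate, and three
   multivariable models: risk + depth + ulceration, risk + T stage,
   risk + stage.
7. **Association with pathologist grading.** Spearman rank correlation
   (mid-ranks for ties) between patient scores and the ordinal TIL grade
   (absent / non-brisk / brisk), plus a Kruskal–Wallis comparison of score
   distributions across grades (one-way ANOVA available as the parametric
   alternative).

## Conventions and boundary rules

Pixel coordinates are 0-based, origin top-left, x rightward, y downward;
a patch covers the half-open box [x, x+patch) × [y, y+patch), so adjacent
patches never share pixels. A raster pixel (i, j) is tumor iff the point
(j+0.5, i+0.5) is inside the annotation. Patch membership uses the centre
pixel (x + patch//2, y + patch//2); a minimum-overlap-fraction alternative
exists behind a flag but is off by default — whether the original study
counted boundary-straddling patches is unknown, so the centre rule is a
declared choice, not a reconstruction. A probability exactly at τ counts
as positive by default (`at_least`); the `strictly_above` reading is a
config flag since both phrasings circulate. A patient score exactly at c
is low-risk (inclusive on the favourable class), likewise configurable.

Stage is derived when not recorded: any known positive lymph node or
documented satellite metastasis is stage III; otherwise T1a–T2a → I and
T2b–T4b → II, with the T category computed from Breslow depth and
ulceration (AJCC bands at 1, 2 and 4 mm) when it is missing too.

## Survival machinery

Event = died of melanoma; death from other causes and loss to follow-up
are censored (disease-specific survival). Kaplan–Meier, log-rank and Cox
fitting are delegated to `lifelines`; the package surface is ours and is
verified against independent textbook-formula oracles in the test suite.
Cox ties use Efron's method by default (follow-up in months produces
ties); a hand-written Newton–Raphson Breslow fitter is available behind
`ties="breslow"` for comparison with software that defaults to it. The
partial-likelihood score test at β = 0 is implemented directly (lifelines
does not expose it) and reproduces the log-rank chi-square on tie-free
data, the classical equivalence used as a cross-check. Missing covariates
are excluded casewise (complete-case analysis). Complete separation shows
up as an effectively unbounded Wald interval rather than an error.

Covariate codings: high-risk indicator 1/0, ulceration present = 1, depth
continuous in mm, T stage (1..8), TIL grade (0..2) and stage (1..3) as
ordinal numerics — one hazard ratio per variable.

## The synthetic cohort generator

No patient data is distributable, so `adta.simulate` generates cohorts at
the detector-output boundary (no fake H&E pixels — image synthesis would
test nothing the pipeline owns). Defaults are a fixed "stated world"
emulating published marginals of early-stage melanoma cohorts; they are
not adjusted per experiment.

* **Latent infiltration.** Each patient draws λ ∈ (0,1), the fraction of
  in-tumor patches that are "hot": with probability 0.19 from the
  high-infiltrate component U(0.10, 0.45), else from U(0.0, 0.06). With
  the default Beta components this puts expected scores on either side of
  the 0.065 cutoff and spans ≈ 0–0.4.
* **Images.** 1–4 images per patient (uniform); each image is a 20×20 grid
  of 100-px patches with a random star-shaped tumor loop covering 30–90%
  of the grid (jittered regular vertex angles keep every angular gap below
  π, guaranteeing a simple polygon). Hot patches are the top
  round(λ·n_in) patches of a smooth Gaussian-bump field (bump count
  1 + Poisson(12·λ), bump width 2.5 patches), so hot regions are spatially
  clustered while the hot *fraction* is exact — that exactness is what
  gives the calibration tests a closed form. Hot patches draw
  probabilities from Beta(mean 0.90, concentration 8), background from
  Beta(mean 0.15, concentration 8); the expected positive fraction is
  f·SF_hot(τ) + (1−f)·SF_bg(τ) with f = round(λ·n_in)/n_in and SF the
  Beta survival function (≈ 0.884·λ at the defaults).
* **Clinical covariates.** Breslow depth log-normal (median 2.5 mm,
  log-SD 0.8); ulceration Bernoulli(0.44); known node/satellite positivity
  Bernoulli(0.25); T stage derived from depth and ulceration; institution
  label 69/31 between two sites. The ordinal TIL grade is derived from λ
  (absent < 0.02 ≤ non-brisk ≤ 0.25 < brisk) and then misgraded one step
  with probability 0.25 — enough noise to mimic inter-observer
  variability, though the resulting score–grade correlation (ρ ≈ 0.7) is
  stronger than reported multi-institution values, because real grading
  disagreement is not purely random one-step error.
* **Survival.** Exponential times with hazard
  h₀·exp(β_z·z + β_depth·depth + β_ulc·ulc), where z indicates the *true*
  high-risk class (expected score < c). Defaults: h₀ = 0.0012/month
  (≈ 50% events), β_z = log 4 (the effect size the validation analyses
  should recover), β_depth = log 1.2 per mm and β_ulc = log 1.6 (echoing
  reported univariable hazard ratios of ≈ 1.5 and ≈ 1.7), uniform
  administrative censoring on (0, 180) months. The event fraction has the
  closed form 1 − (1 − e^{−rW})/(rW) per patient, used by calibration
  tests. A cohort drawn with zero events is regenerated with a warning.

Ground truth (λ, expected score, true risk class) is stored alongside the
observables so recovery tests can compare against it.

### What a green test does and does not establish

The generator emulates *marginals* (depth median, ulceration and event
rates, grade distribution, class imbalance) and a proportional-hazards
outcome model, not joint distributions real cohorts never report: depth
and ulceration are independent of infiltration here, scanner and staining
artifacts do not exist, tumor loops are star-shaped, and patch
probabilities are exchangeable within hot/background classes. Green
end-to-end tests certify the *pipeline* (scoring, cutoff selection,
survival fitting) against known ground truth; they say nothing about the
clinical validity of the biomarker itself.

### A note on end-to-end cutoff recovery

At the stated defaults, the empirical Youden maximum on an 80-patient
training cohort occasionally (≈ 8% of seeds) falls on a spurious split
*inside* the low-infiltrate score cluster rather than in the gap between
components: death labels are noisy (within-class death rates vary with
depth and ulceration, and events are Bernoulli), and the J landscape
depends only on the rank order of scores versus labels, so no amount of
component separation removes these excursions. Misplaced cutoffs then
dilute the validation risk groups, and the marginal log-rank effect is
further attenuated below the conditional β_z = log 4 by the depth/
ulceration frailty. The end-to-end acceptance test asserts the recovery
property at its stated thresholds and is expected to fail them under this
world; smoothing or cross-validating the cutoff would fix it but is
deliberately out of scope (the clinical procedure applies one
training-set-derived value). The oracle and calibration suites are
unaffected.

## Numerical choices

* Midpoint candidate thresholds mean the returned cutoff never equals an
  observed score, so boundary classification on the training set is
  unambiguous.
* ROC and cutoff code is exact rational arithmetic over counts except for
  the midpoint averaging; oracle tests compare at 1e−12.
* Patch membership for whole cohorts tests patch-centre points directly
  against the polygon (prepared-geometry batch predicate) instead of
  materializing a full-resolution raster; the two routes are equivalent by
  construction and tested as such.
* The Breslow Newton fitter stops when the max coefficient step is below
  1e−10 (cap 100 iterations); lifelines defaults govern the Efron route.
* Degenerate inputs fail loudly: images with no in-tumor patches, ROC
  with one label class or a single distinct score, log-rank with zero
  events, Cox with collinear covariates or no complete-case events.

## Known limitations

* No whole-slide image decoding, no automated tumor segmentation, no
  detector re-implementation: the patch table is the contract.
* No time-varying covariates, frailty terms or competing risks; the
  proportional-hazards check is limited to a log(−log) plot hook.
* Efron vs other software's tie handling produces small numeric
  differences that are documented, not reconciled.
* The synthetic world's score–grade correlation and institution effects
  are simplistic; see above.
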