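# Methods

## The network impact score

An acute ischemic infarct harms cognition not only through how much tissue
it destroys but through *where* it sits in the brain's structural network.
The network impact score operationalises this with a fixed network atlas:
a parcellation of grey matter into R regions (R = 90 in the reference
atlas) and, per region, a betweenness centrality derived once from a
healthy structural connectome. For a binary lesion mask L in the atlas's
template space,

    p_r   = |L ∩ region r| / |region r|          (proportion lesioned)
    I_r   = p_r · c_r                            (regional impact)
    score = log( max_r I_r )

Betweenness centrality c_r counts the shortest paths between all other
region pairs that pass through r (ties fractionally credited, endpoints
excluded). Hub regions — those relaying many shortest paths — therefore
dominate the maximum whenever a lesion touches them.

### Numerical conventions

* **Unnormalized centrality.** Raw shortest-path counts are used. Any
  positive rescaling of the centrality column (normalization included)
  multiplies the raw score by a constant and therefore adds a constant to
  every log score; odds ratios from the downstream logistic models are
  exactly invariant to this shift (verified by test). The absolute log
  scores reported on synthetic data are consequently on an arbitrary
  scale; only differences between patients carry meaning.
* **Weighted shortest paths** use edge length = 1/weight, the usual
  convention for tractography-derived connection strengths. A binarized
  variant (ignore weights) is available via a flag.
* **Natural log** by default; the base is configurable and only rescales
  regression coefficients.
* **Voxel membership is all-or-none**: proportions are voxel-count ratios
  on the shared grid, with no partial-volume weighting — appropriate for a
  1 mm isotropic template grid where voxels are small relative to regions.
* **Ties in the maximum** are broken toward the smallest region id. This
  affects only the reported argmax region, never the score.
* **Zero-score lesions** (no overlap with any positively weighted region —
  e.g. purely white-matter or infratentorial infarcts, which the atlas does
  not cover) raise a typed `UnscorableLesionError` rather than yielding
  −∞. Batch scoring reports them in an exclusion table; nothing is
  silently dropped.
* **Multiple disjoint infarcts** in one mask are scored as their union:
  one lesion map, one score per patient.

## PSCI classification

Post-stroke cognitive impairment (PSCI) at an assessment means
norm-referenced performance below the 5th percentile (strictly) in at
least one of six domains: attention/executive, processing speed, language,
verbal memory, visuospatial perception/construction, visuospatial memory.
Excluding PSCI requires at least three assessed, unimpaired domains; with
fewer the assessment is *indeterminate* (neither outcome level; such rows
carry no binary outcome and never anchor a transition). MoCA-only cohorts
classify directly on the MoCA percentile with the same cut-off.

Transitions compare the sub-acute baseline — the earliest determinate
assessment before day 90 — with later determinate assessments: recovery is
baseline PSCI followed by any later no-PSCI; decline is the reverse; a
patient with no determinate baseline before 90 days or no determinate
follow-up is not evaluable. Recovery/decline take precedence over the
stable statuses when any qualifying later assessment exists.

Time strata are left-closed day bins: [0, 90), [90, 365), [365, 730),
[730, ∞). Prevalence percentages truncate toward zero (208/522 → 39%), the
convention consistent with all the published fractions this package
reproduces.

## Association models

* **Repeated measures:** marginal binary logistic model fit by GEE with an
  AR(1) working correlation indexed by within-subject visit order (not
  calendar day; visits are irregularly spaced and occasion indexing is the
  conventional choice — independence is available as an option). Robust
  sandwich covariance throughout; Wald 95% CIs on the exponentiated scale.
* **Stratified:** ordinary ML logistic per time stratum, earliest
  assessment per patient within the stratum. Fewer than 10 events warns
  but still fits. Fitting uses IRLS, which tolerates sparse categorical
  cells far better than Newton steps.
* **Transitions:** recovery modelled among baseline-PSCI patients
  (recovery vs stable PSCI), decline among baseline-no-PSCI patients.
* **Covariates:** log score per 1 point, age per decade, male vs female,
  three education indicators vs less-than-high-school, prior stroke,
  infarct volume per 10 mL, and study-site fixed effects with the largest
  site as reference. Rows with missing model covariates are deleted
  listwise and counted on the result object. Indicator columns that are
  constant within a subset (a stratum with no patients from some site or
  education level) are dropped to keep the design full rank. No
  multiple-testing correction is applied.

## The synthetic study

All inputs are generated with known truth, so every stage is testable
without any data download.

* **Geometry:** a 64³ grid of 1 mm voxels holding an ellipsoidal brain
  mask (~64 mL). Grey matter is the outer shell (inner core scaled 0.55);
  the core is background, playing the role of white matter outside the
  atlas. The shell is tessellated into 90 regions by seeded multi-source
  BFS (geodesic Voronoi), guaranteeing contiguous, nonempty regions.
  This brain is miniature relative to a real one (~1300 mL), so lesions of
  realistic absolute volume cover larger regional proportions than in
  template space; scores are shifted accordingly, which the models do not
  feel (translation invariance above).
* **Connectome:** connection probability decays exponentially with
  centroid distance; the 8 nodes nearest the centre of mass are designated
  hubs and receive dense, 5× stronger edges, concentrating betweenness on
  them as in real structural networks. Disconnected draws are retried with
  an incremented sub-seed.
* **Lesions:** per patient a target volume is drawn log-normally with
  median 3.7 mL and IQR ≈ 1.2–16.1 mL (the cohort's infarct volume
  distribution), capped at half the brain mask; the lesion takes the
  target number of mask voxels nearest its random seed voxel under a mild
  random anisotropy (quasi-spherical growth, within ±5 % of target).
  Vascular-territory anatomy is deliberately not simulated.
* **Covariates:** age ~ N(66.7, 11.7²) truncated to [18, 100]; 59.8 %
  male; education 56.7/21.7/7.9/13.8 %; prior stroke 11.3 %; 12 sites with
  uneven sizes and centred Gaussian site effects (SD 0.3). Covariates are
  drawn independently; no correlation structure between them is claimed by
  the emulated study design.
* **Outcomes:** per visit, PSCI ~ Bernoulli under a logistic model in the
  log score (default marginal log-OR 0.239, i.e. OR 1.27), age/decade,
  sex, education, prior stroke, volume/10 mL and site effect. Visit counts
  follow the cohort mixture (52.2 % single visit … 5.6 % six visits);
  first-assessment timing is log-normal with median 104 days (clipped at
  452), later visits 120–540 days apart.
* **Within-subject correlation** comes from a shared subject-level normal
  term (SD 1.481, latent ICC 0.4 on the logistic scale) — an exchangeable
  generative structure even though the fitted working structure is AR(1);
  GEE is robust to this deliberate mismatch. Because a shared random term
  attenuates population-averaged effects, the conditional linear predictor
  is inflated by √(1 + c²σ²) with c = 16√3/(15π), so the *marginal* model
  — what GEE estimates — carries the stated coefficients. Simulation
  confirms mean recovery of the marginal log-OR to within 0.02.
* **Percentiles consistent with status:** impaired visits draw 1 + Bin(5,
  0.3) impaired domains below the 5th percentile, others above; 3 % of
  unimpaired full-battery visits record only two domains (indeterminate
  downstream, exercising that path); a MoCA-only subset (25 % of patients)
  mimics screen-only cohorts.
* **Intercept calibration:** the default marginal intercept (−2.503) was
  set with the provided `calibrate_intercept` helper to a per-visit PSCI
  prevalence of 40 %, the middle of the 28–47 % band observed across
  post-stroke intervals; both generation paths land inside that band.
* Everything is deterministic under a fixed seed; sub-stages use fixed
  offsets of it.

### What passing tests do and do not show

The generator reproduces the study's marginal distributions and its
generative logistic structure, so passing tests demonstrate algorithmic
correctness (scoring arithmetic, classification rules, estimator
behaviour), not clinical validity on real imaging: synthetic lesions are
quasi-spherical rather than vascular, the connectome is schematic, domain
percentiles are conditionally independent given status, and PSCI
probability is time-constant within patient (no recovery drift), so
transition *rates* are emergent rather than matched to the cohort's.

## Problem sizes

Default simulations mirror the cohort (2341 patients, up to six visits).
Statistical validation suites use 1000-patient × 3-visit cohorts (100
replicates) for parameter recovery and 500-patient single-visit cohorts
(200 replicates) for null coverage — sizes at which asymptotic Wald
behaviour is established while the full suite stays quick to run.

## Known limitations

* The atlas normalization and weighting of the original published
  centrality table are unknown; both conventions are exposed, and the
  invariances above make the choice immaterial for association estimates.
* Stratified models use the earliest assessment per patient per stratum;
  other selection rules are defensible.
* CI construction is robust-Wald everywhere; no small-sample corrections.
* Listwise deletion for missing covariates (with mandatory reporting); no
  imputation.
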