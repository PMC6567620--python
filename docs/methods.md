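# Methods

This note documents the models and procedures implemented in `bloomline`,
the assumptions behind them, the defaults of the synthetic cohort generator,
and the numerical and design choices made where more than one construction
was defensible.

## The synthetic cohort generator

The generator (`bloomline.simulate`) exists so the full analysis chain can be
exercised and validated against known, planted effect sizes. It emulates a
three-site (TJL, UM, UT) × two-sex × two-treatment (control vs acarbose)
factorial mouse study with `n_per_cell = 12` mice per cell (144 samples), one
sampled mouse per cage, and sampling ages uniform over 762–973 days.

**Community.** Latent per-OTU densities (16S copies per gram) are log-normal:
OTU-level means are drawn once per cohort around `log_density_mean`
(ln 2·10⁶ copies/g, SD 1.2 between OTUs), shifted by site offsets (SD 0.3),
with mouse-to-mouse variation of SD 0.7 on the log scale. Five dominant OTUs
get fixed means (OTU-1 ~4·10⁷, OTU-2/OTU-3/OTU-4 ~3·10⁷, OTU-5 ~10⁷) so the
rank-abundance profile resembles a mouse gut community dominated by
*Muribaculaceae*, *Lachnospiraceae*, *Ruminococcaceae* and
*Lactobacillaceae*. OTU-4 is site-restricted to UT and essentially absent
elsewhere. Under treatment, the site's designated bloom OTU (OTU-1 at TJL and
UM, OTU-4 at UT) is multiplied by `bloom_fold = 4.3` and the remaining
*Muribaculaceae* by `muribaculaceae_other_fold = 0.5`; both defaults are the
density ratios the emulated study reports. A log-normal baseline is an
assumption of convenience — the study itself fits no generative model — but
it reproduces the right-skewed abundance distributions the downstream
non-parametric tests presuppose.

**Sequencing.** Reads are multinomial at depth 10 000 over endemic copies
(density × weight, weight ~ U(0.02, 0.08) g) plus spike copies
(`spike_copies_per_uL = 2·10⁵` × 10 µL), giving a median spike read fraction
of ~3%, a realistic recovery for a cell spike-in. No FASTQ-level artifacts
(chimeras, PCR bias) are simulated; generation starts at OTU counts.

**Metabolites.** For each compound, log concentration = baseline (set near
the reported control medians, e.g. acetate ~15 µmol/g, propionate
~1.4 µmol/g) + optional design effects + Σ coefficient × log1p(density),
with densities centred *within site*, + Gaussian noise (SD 0.3). Within-site
centring matters: OTU-4 is absent at two sites, and cohort-wide centring
would convert that presence/absence pattern into a large artificial
cross-site offset in propionate rather than a within-site density coupling,
which is the quantity the stratified and design-adjusted analyses measure.
Default couplings: propionate on OTU-1/OTU-4/OTU-5 (0.35/0.35/0.25),
butyrate and acetate on *Lachnospiraceae*/*Ruminococcaceae* OTUs, lactate on
OTU-2, succinate weakly negative on the bloom pair (a consumed precursor),
and a shared latent factor (SD 0.4) for acetate and butyrate so their
positive correlation — the source of the masking phenomenon in the survival
models — is present by construction. The coupling strengths were set, once,
so that the planted propionate producers are identifiable at the study's
sample size, which is the qualitative outcome of the emulated study.
Concentrations below 0.05 µmol/g are reported as 0 (a detection limit, so
the zero-replacement rule is exercised).

**Survival.** Death ages follow a Weibull proportional-hazards model (shape
6, scale 957 days — baseline median ≈ 900 days, lifespan SD ≈ 180 days) with
linear predictor Σ β × standardized SCFA concentration; default β are
ln 0.674, ln 0.586 and ln 1.576 for propionate, butyrate and acetate, the
per-SD hazard ratios the study reports for its joint model. Left truncation
is exact inverse-transform sampling on the conditional survivor function
given survival to the sampling age: with H(t) = (t/λ)ᵏ e^η and E ~ Exp(1),
t = λ((a/λ)ᵏ + E e^{-η})^{1/k}, so no rejection loops and every death age
strictly exceeds the sampling age. Death ages are floored to whole days,
which makes ties certain and keeps the Efron correction honest. Sex and
treatment effects on the hazard are exposed but default to 0, keeping null
mode clean. A cage random effect is exposed (`cage_effect_sd`) but defaults
to 0: with one sampled mouse per cage it is unidentifiable, and no variance
component is available to default it to.

`GeneratorParams.null()` switches every planted effect off (folds 1,
couplings and latent factor 0, hazard βs 0, metabolite design effects 0), so
downstream tests applied to null cohorts should reject at their nominal
level; that property is part of the test suite.

**What passing tests do and do not show.** The generator matches the study's
*statistical* structure (factorial design, overdispersed counts,
compositional bloom, taxon-coupled metabolites, truncated survival), not its
biology: no strain-level variation, no cage effects, no protocol batch
effects, no chimeras, lognormal rather than unknown true abundance law.
Recovery of planted parameters demonstrates the estimators are correct and
calibrated under these conditions; it cannot certify behavior under real
data pathologies the generator does not produce.

## Numerical and procedural choices

* **Chao1** uses the bias-corrected form S_obs + F₁(F₁−1)/(2(F₂+1)), finite
  when F₂ = 0. **Simpson's evenness** is inverse-Simpson over observed
  richness (the convention of the mothur toolchain; the emulated study names
  the index without a formula, and the reported medians cannot
  disambiguate).
* **Rarefaction** is a single seeded realization of sampling without
  replacement (multivariate hypergeometric), not an average, and the depth
  is the cohort minimum endemic count with spike reads removed first. In the
  partitioned procedure the exclusion happens strictly before depth
  equalization; the resulting totals are equal across samples, which is the
  observable contract distinguishing the two orders.
* **PERMANOVA** uses sequential (Type-I) sums of squares via projection
  operators on the Gower-centred matrix, with user-controlled term order —
  order-robustness of conclusions is itself worth checking, so the order is
  never hidden. Permutations are free row permutations (cages are not
  strata: one mouse per cage), and p-values use (1+b)/(1+m) so p is never 0.
  **PERMDISP** measures distances to group *centroids* in the full PCoA
  embedding (positive axes minus the imaginary-part correction), not spatial
  medians — a recorded divergence from the R default, chosen for analytic
  tractability; permutation is of group labels on the distances.
* **Mann-Whitney** is exact by full enumeration when n₁+n₂ ≤ 12 without
  ties (the regime of the worked examples), otherwise a normal approximation
  with tie-corrected variance and continuity correction.
* **Size factors** are median-of-ratios against a geometric-mean reference
  over OTUs positive in all samples, falling back to positive-count-only
  means with a notice. **NB dispersion** is a df-weighted pooled
  method-of-moments estimate within design cells, α̂ = Σ(n_c−1)(v_c−m_c) /
  Σ(n_c−1)m_c², floored at 10⁻⁸. Pooling numerator and denominator before
  the ratio matters: a median (or mean) of per-cell ratios is biased low
  because small-df variance estimates are right-skewed, and underestimated
  dispersion makes every Wald test anticonservative (we measured 23% of null
  OTUs at p < 0.05 with the median version on small cohorts, 7% with the
  pooled version at 48 samples — the residual being the usual asymptotic
  optimism of Wald z at modest n). Empirical-Bayes dispersion shrinkage is
  deliberately not reproduced; the content here is the design and the
  independent-filtering procedure, not any particular shrinkage estimator.
* **Independent filtering**: BH is applied only to OTUs with mean relative
  abundance ≥ 0.01% and detection (count ≥ 1) in ≥ 5% of samples, both
  computed from abundance and never from p-values; each model term is its
  own correction family. "Incidence" is cohort-wide.
* **Standard curves**: WLS with weights 1/c², through the origin except
  propionate; the no-intercept slope has the closed form mean(area/conc),
  which the tests pin. Samples carry their extraction protocol (fixed 200 µL
  vs 1:10 w/v) in metadata; no cross-protocol calibration is attempted since
  extraction order was randomized in the emulated design. All log
  transforms are natural logs (the base cancels in every statistic).
* **Zero spike reads** make the spike-adjusted statistic undefined; such
  samples are returned as missing with a warning, never imputed — a
  pseudo-count would bias density ratios. This is this package's policy; the
  emulated study does not state one (possibly no such sample occurred).
* **LASSO**: predictors are standardized before penalization (penalties are
  meaningless across raw per-gram scales) and coefficients are reported on
  that scale; responses are log concentrations residualized on site, sex and
  treatment. The penalty grid is 100 log-spaced values from λ_max down to
  10⁻⁴λ_max; the final penalty maximizes pooled out-of-bag R² of a seeded
  randomized 10-fold CV on all samples and the reported model is a refit on
  all samples at that penalty. A raw-abundance default with a `log_transform`
  switch is provided; raw abundances proved the stronger default for
  detecting a site-restricted bloom taxon, whose signal is carried by a
  heavy right tail.
* **The validation gate** deserves its own paragraph. The natural-looking
  gate — Spearman/Student-t on the pooled cross-validation predictions of
  the selected penalty — is badly anticonservative: at this study's
  dimensions (n = 144, ~150 filtered predictors, 10 folds) it "validates"
  30–35% of models when the response is pure noise. Two mechanisms drive
  this: CV predictions are cross-correlated through shared training
  responses (even a fixed-penalty pooled gate rejects ~13%), and penalty
  selection latches onto whatever chance predictor–response alignment the
  data contain — an alignment that, being a property of the samples rather
  than the fold split, survives any re-splitting of the same data (a
  fresh-split gate still rejects ~25%). The only construction that gives the
  Student-t reference its meaning is a response vector never seen by any
  selection or fitting step. `lasso_cv` therefore sets aside a seeded outer
  holdout (25% of samples), reruns penalty selection and fitting from
  scratch on the remainder, and computes the gate (Spearman rank
  correlation, Student-t, P < 0.05) on the holdout. Measured null validation
  rate: 2.5–3% (slightly conservative, because null selections often
  collapse to the all-zero model, whose constant predictions are flagged
  rather than tested). The reported coefficients still come from the
  full-data CV + refit, so the gate costs no estimation efficiency — only
  gate power, which is the price of a gate that means something.
* **Cox regression** maximizes the delayed-entry partial likelihood with
  Efron tie handling by Newton–Raphson with step-halving (acceptance
  threshold relative to |loglik| so float noise near the optimum cannot
  reject a full Newton step), convergence at gradient norm < 10⁻⁸, explicit
  errors after 50 iterations or when coefficients diverge (monotone
  likelihood / perfect separation is reported, never silently returned).
  Standard errors come from the inverse observed information.
  Standardization of SCFA columns uses the analysis cohort's own mean and SD
  after exclusions; sampling age enters only through delayed entry, never as
  a covariate. With no ties, the Efron and Breslow constructions coincide
  exactly (tested).
* **KM medians** use the step-function convention: the smallest observed
  death time at which the survivor function is ≤ 0.5. The log-rank test is
  delegated to lifelines; lifelines' Cox implementation serves only as an
  independent cross-check of this package's engine in the test suite.

## Problem sizes used in validation

Simulation-based checks use sizes chosen to put each asymptotic procedure in
its working regime while keeping the suite quick: planted-effect recovery at
the study's own 144 samples; joint Cox hazard-ratio recovery at ~2000 mice
(where per-SD log-HR standard errors are ~0.03); Wald-interval coverage over
500 simulated cohorts of 144; null error rates over 200 replicates — 48
samples per cohort for the OTU-level FDR check (the smallest size at which
the NB Wald approximation is honest) and 24 for the Mann-Whitney and
ANOVA-interaction checks, whose small-sample behavior is exact or nearly so.

## Known limitations

* The NB Wald stage is asymptotic; at a few dozen samples its raw p-values
  run ~1–2 percentage points hot at the 5% level even with pooled
  dispersion. The filtered-BH layer absorbs this in practice (null discovery
  rates ≪ 1%), but single-OTU p-values near the threshold deserve caution.
* The LASSO gate trades power for calibration; with moderate couplings and
  144 samples it validates roughly half of genuinely coupled metabolites.
  Support recovery by the full-data model is unaffected.
* PERMDISP with centroids can differ from median-based implementations on
  strongly non-Euclidean dissimilarities.
* The generator's null mode is exactly exchangeable across treatment; real
  studies have cage, batch and protocol structure the error-rate guarantees
  here do not cover.
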