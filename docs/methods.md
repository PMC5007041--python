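# Methods

`cookin` implements a complete dyadic analysis chain for the question *is
the acoustic structure of individually distinctive contact calls predicted
by kinship, by familiarity, or by age?* — together with a synthetic-data
generator that produces colonies with known ground truth, so every stage of
the chain can be validated end to end. This note records the models, the
default parameter choices and their rationale, the numerical decisions, and
the known limitations.

## 1. The synthetic colony

### Demography

`generate_population` builds a three-generation pedigree: a founder
(grandparental) cohort with unknown parents, a parental cohort, and the
focal adult females. Defaults mirror a well-studied provisioned macaque
colony: 67 focal females in 4 social groups and 7 matrilines (nested in
groups), ages uniform on 4–24 years, 4–14 calls per female. Each focal
female has an identified dam, sire and four grandparents.

Kin structure arises from three mechanisms, all configurable:

* **Paternal sibships.** Focal sires come from a colony-wide pool
  (default `n_females // 3` males) sampled with geometrically decaying
  weights controlled by `sire_skew` (default 0.15). Zero skew cycles
  through the pool so paternity is maximally diverse (used to construct
  provably all-non-kin colonies); skew 1 assigns a single dominant male.
* **Maternal sibships and cousins.** Each matriline has `0.7 k` parental
  dams for `k` focal females (some full/maternal sibs) descending from a
  small founder-dam set (maternal cousins), and focal maternal sibs reuse
  their elder sib's sire with probability 1/2 (mate fidelity across
  seasons), so full sibs exist at a realistic rate.
* **Founder pair-bonds.** Founder dams keep a primary mate (80% of their
  daughters are full sisters), which produces the r = 0.125 cousin class.

Under the defaults a 67-female colony yields roughly 400–550 kin dyads
among the 2211 total, with r spread over {0.0625, 0.125, 0.1875, 0.25,
0.3125, 0.375, 0.5} in proportions comparable to the published dyad
contingency of the study system. The generated pedigree is complete, so no
dyads are excluded for unknown ancestors; the exclusion rules are exercised
by hand-built pedigrees in the test suite instead.

### Heritable latent traits

Each individual carries four independent latent channels (`g`, `g2`, `g3`,
`g4`), one per acoustic signature parameter. Founders draw each channel
N(0, 1); offspring receive the midparent value plus segregation noise of
variance 1/2 (the additive infinitesimal model), so the latent correlation
of two relatives equals their relatedness r, channel by channel. Four
*independent* channels rather than one shared factor is a deliberate
choice: distinct acoustic parameters (source frequency, temporal control,
contour shape, spectral envelope) rest on distinct anatomical and neural
substrates, and a single shared factor would impose a rank-1 genetic
architecture in which one unlucky colony-level genotype draw erases the
entire kin signal. With four channels the realized kin contrast averages
over four independent segregation histories, which is both more plausible
and far more stable across colony realizations.

### From effects to acoustics

Each female has four signature parameters: an F0 offset (SD
`sd_individual` = 30 Hz), a log-duration factor, an arch-depth factor and a
spectral-tilt offset. Each is built as

    signature = (z + h2_weight * g_channel) / sqrt(1 + h2_weight**2)

so total signature variance is independent of `h2_weight` and kin
signatures correlate at `h2_weight**2 r / (1 + h2_weight**2)`.

**Familiarity** is modeled as vocal accommodation toward a *vocal
tradition*: every group and every matriline-within-group draws a tradition
offset (scaled to the signature SD), and each female's signature is pulled
toward `0.7 * (group + matriline)` tradition with weight `fam_weight`.
Dyads of the same group — and more strongly of the same group *and*
matriline — thereby become more similar in every signature dimension.
(A pure shrink-to-the-group-mean formulation was rejected: the mean of ~17
i.i.d. signatures is O(sigma/4), so group-level similarity would hinge on a
vanishing quantity; traditions give the group target its own scale, which
is also how accommodation is usually conceived — convergence toward a
shared group norm, not toward the sample average of idiosyncrasies.)

**Age** enters F0 linearly (`age_slope`, Hz/year, centered at the mean
age).

Calls are rendered at 44.1 kHz as a raised-cosine F0 arch (endpoints at the
per-call base F0, peak at `1 + arch_depth` times it), `n_harmonics = 6`
harmonics decaying at `spectral_tilt_db = -6` dB per harmonic, cosine
on/offset ramps, and white noise at `snr_db = 30` dB. Per-call variation:
3% F0 jitter, 12% duration CV, 12% arch jitter, 0.8 dB tilt jitter. These
levels were chosen so that caller identity is strong but not trivial —
the stepwise DFA assigns calls to the correct female at roughly 35–55%
(resubstitution) against a 1.49% chance level, i.e. the same order of
individual distinctiveness reported for real coo calls, rather than the
~100% a noiseless generator produces.

### Scenarios

* `paper_like` — `h2_weight = 0`, `fam_weight = 0.6`, `age_slope = 3`
  Hz/yr: familiarity and age structure but no heritable component.
* `kin_effect` — `h2_weight = 5` (kin signature correlation 0.96 r),
  no familiarity, no age trend. Five was chosen as the operational meaning
  of a *large* heritable effect: a truth-level power analysis showed that
  per-colony sensitivity saturates once the heritable share dominates,
  because the limiting factor is the realized genetic sampling among ~20
  paternal clusters in a 67-female colony, not the effect size.
* `null` — individual signatures only.

## 2. Acoustic features

Recordings are decimated from 44.1 kHz to 11.05 kHz behind a sharp
linear-phase FIR low-pass (2047 taps, cutoff just under the target
Nyquist), then analysed with a 1024-point Hamming-windowed FFT every 32
samples: 10.79 Hz bins over a 5.525 kHz band, 2.896 ms frame spacing.

Each frame's normalized autocorrelation is scanned for local maxima above
0.4 in the lag band corresponding to 150–1500 Hz. No peaks → *noisy*;
peaks whose lags deviate more than 15% from integer multiples of the
highest peak's lag → *complex*; otherwise *tonal*, with F0 from the
parabolic-interpolated best lag and HNR = 10 log10(r/(1−r)) at the
interpolated peak height r. The tonal F0 track is median-filtered and
frames deviating more than 40% in lag are snapped back (automatic
octave-jump suppression in place of interactive correction). Thresholds
are exposed on `SpectroParams`.

Framewise energy descriptors use the *linear amplitude* spectrum: quartile
k is the first bin where the cumulative amplitude reaches k/4 of the frame
total; peak frequency is the argmax bin.

The per-call catalogue is a fixed, versioned manifest of 112 named
features: 10 summary statistics (mean, min, max, start, end, range, SD,
slope, location of max/min) for each of 7 framewise tracks (F0, HNR, peak
frequency, q1–q3, energy), 7 mean absolute frame-to-frame deltas, and 35
call-level descriptors (duration, frame-class fractions, tonal-segment
geometry, F0-to-harmonic amplitude ratios, call-average-spectrum peak/
range/quartiles, global energy peaks above a configurable prominence,
spectral centroid, and local slopes). Calls with no tonal frame get their
tonal-dependent features imputed from the within-female mean (else the run
mean) and are flagged.

## 3. Stepwise DFA and acoustic distance

Selection is driven by Wilks' lambda: at each step the candidate with the
smallest partial lambda enters if its F-to-enter (df = (g−1, N−g−p)) has
p ≤ 0.05; after every entry, included features whose F-to-remove has
p ≥ 0.10 leave. Determinants are computed by `slogdet` on scatter-matrix
blocks; candidates whose residual within-group variance falls below a
tolerance of 1e−7 of their marginal variance are skipped as collinear, and
features with pooled within-group variance below 1e−12 are excluded up
front with a warning. Ties enter the lowest column index, making the
selection path reproducible bit for bit.

Callers are classified by minimal Mahalanobis distance to class centroids
under the pooled within-group covariance (equal priors); both
resubstitution and leave-one-call-out accuracy are reported (the
leave-one-out variant uses rank-one downdates of the scatter matrix).
The acoustic distance between callers i and j is the classical
pairwise-group F,

    F_ij = n_i n_j (N - g - p + 1) / ((n_i + n_j) p (N - g)) * D2_ij,

with D2 the Mahalanobis distance between centroids; in the two-group case
this is exactly the Hotelling T² F statistic, which the test suite verifies
against an independent implementation to 1e−8 relative error.

## 4. Relatedness and dyad classification

Relatedness is Wright's path counting truncated at the grandparental
generation: every contribution runs through a common ancestor at most two
meiotic steps above each member, contributing (1/2)^(steps_a + steps_b),
with no individual repeated within a path and ancestors assumed
non-inbred. r values are therefore *minimum* estimates. An optional
founder-kinship table quantifies the truncation error: declaring two
otherwise-unlinked grandparents related at 0.5 raises the dyad's r by
exactly 0.5 × (1/2)^4 = 0.03125.

The test suite proves equivalence with the recursive tabular additive
relationship on randomized layered pedigrees. (Equivalence requires
layering: with cross-generation matings a node can be a parent of one
focal and a grandparent of the other, and a jointly truncated tabular
computation counts depth-3 chains that the per-side grandparent rule
deliberately excludes.)

Dyads are classified *kin* (≥ 10 of 12 ancestors known, ≥ 1 shared),
*non-kin* (all 12 known, none shared) or *excluded*. The familiarity
factor has three levels (same group & same matriline, same group &
different matriline, different group & different matriline); dyads in the
theoretically possible but unmodeled same-matriline/different-group cell
are labeled "other" and excluded. Age difference is the absolute
birth-year difference.

## 5. The dyadic mixed model

The response is sqrt(F) for each analysed dyad. Continuous predictors —
relatedness and sqrt(age difference) — are z-scored over the analysed
dyads (after exclusion, since the model never sees excluded dyads). Fixed
effects: the two gm dummies (reference: different group & different
matriline), the two z-scored covariates, and all two- and three-way
products — 11 terms plus intercept, so the full-vs-null LRT has df = 11
and dropping the three-way interaction (two product terms) has df = 2.

Both dyad members enter as crossed random factors. The `slopes` structure
adds one independent variance component per covariate to each factor
(random intercepts and slopes, intercept–slope correlations suppressed);
`matched` gives each model family slopes for its own covariates (the
reduced model then carries slopes for its four terms); `intercepts` fits
crossed intercepts only. Fitting is delegated to `lme4::lmer` through a
batch Rscript bridge (uncorrelated slopes via the double-bar formula,
nloptwrap/BOBYQA on the profiled deviance at default tolerances —
benchmarking showed loosened optimizer tolerances bias log-likelihoods by
~1 unit, enough to corrupt LRTs, so accuracy is never traded for speed).
LRTs always compare ML fits with identical random structure; reported
coefficient tables are REML. The `none` option collapses to OLS, used to
verify the fixed-effects machinery against least squares.

The reduction procedure tests the three-way interaction, then each two-way
block against the all-two-ways model, then reads the per-term LRTs off the
main-effects model, with the three pairwise gm contrasts obtained by
releveling and refitting (df = 1 each). All interaction screens are
computed and reported, but a chance-significant two-way does not *block*
the main-effect readout: with five interaction tests at alpha = 0.05, a
strict sequential gate would abandon the main-effects readout in a
substantial fraction of healthy datasets; the report instead records
`reduction_clean` so the user can see whether the textbook path was clean.

Diagnostics: leave-one-subject-out refits, random member-slot reassignment
(fixed estimates are invariant up to optimizer tolerance), and generalized
VIFs from a main-effects OLS design, reported as GVIF^(1/(2 df)). The
unrelated-only analysis re-runs the familiarity model on the r = 0 subset,
with the gm × age interaction LRT at df = 2.

## 6. Validation suites and problem sizes

The simulation-based checks run at the study's own scale — 67 females, 4
groups, 7 matrilines, 4–14 calls each (~600 calls, 2211 dyads) — over 12
fixed seeds per scenario, requiring the injected truth to be recovered in
at least 80% of seeds:

* `paper_like` must yield relatedness non-significant and age difference
  plus group-matrilineal membership significant (observed: 11/12);
* `kin_effect` must yield relatedness significant (observed: 10/12).

These scenario LRTs are read off the main-effects model with its matched
random slopes. Type-I calibration of the relatedness LRT is established
separately under the global null: 500 replicates of 200 dyads drawn from
the crossed-random-intercepts generative model, fitted with the matching
intercepts structure; the empirical rejection rate at alpha = 0.05 must
lie inside the binomial 95% interval.

A sensitivity ceiling is worth stating plainly: even at maximal
heritability the per-colony power of the relatedness test saturates near
0.85, because the realized kin contrast depends on the genetic sampling of
a few dozen paternal clusters in a single 67-female colony — colonies
exist in which a maximal heritable effect leaves no detectable kin signal.
This is a property of the study size, not of the pipeline.

## 7. What the generator does and does not emulate

It emulates: arched tonal calls with harmonic stacks, individual
signatures of realistic strength, pedigree-structured heritable variation,
group/matriline convergence, age trends, and the study's demography and
dyad-classification rules. It does not emulate: vocal-tract resonances or
formants, call segmentation from continuous field recordings, background
noise scenes, minimum-r censoring from incomplete real pedigrees (the
synthetic pedigree is complete; the exclusion rules are exercised on
hand-built pedigrees in the tests), male calls, or non-stationary
within-call noise. Passing the simulation suites therefore shows the
*pipeline* recovers known structure of the kinds hypothesized; it does not
by itself validate the acoustic realism of any particular feature against
field recordings.
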