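# Methods

This note records the models, parameter choices and numerical decisions
behind `stopnet`, in the order the pipeline runs them.

## Task and race-model behavior

The simulated stop-signal/no-go task presents 360 Go (70%), 80
Stop-Signal (20%) and 40 No-Go (10%) trials, randomly interleaved and
split as evenly as possible across two runs, with a ~2.6 s inter-trial
interval and TR = 2 s.  No-Go trials are treated as stop trials with
SSD = 0.

Behavior follows the independent race model: on each stop trial a go
finishing time and a stop finishing time are drawn independently and a
response occurs iff go < SSD + stop (or the stop process fails to
trigger).  Go finishing times are ex-Gaussian (defaults μ = 450 ms,
σ = 60 ms, τ = 100 ms, i.e. mean Go RT 550 ms); stop latencies are
normal truncated at zero (defaults μ = 180 ms, σ = 30 ms).  Small
omission (2%), choice-error (2%) and, for cohort subjects,
trigger-failure (2%) probabilities produce the rarer outcome
categories.  These are standard race-model parameterizations for
healthy adults; all are exposed in `RaceParams`.

The SSD staircase is 1-up/1-down with 50 ms steps: +step after a
successful stop, −step after any response, clamped to [0, 900] ms,
starting at 250 ms.  This tracker converges to a ~50% response rate;
because it starts below its equilibrium (typically ~330-340 ms for the
default parameters), the realized response rate over 80-1000 trials
sits slightly below one half (~47-48%).

## SSRT by block-based integration

Trials are cut into consecutive blocks of 30 stop trials; with 80 stop
trials this yields blocks of 30/30/20 — a trailing remainder with at
least 15 stop trials forms its own block, otherwise it merges into the
preceding block.  Per block: Go omissions are replaced by the block's
maximum Go RT; correct-Go RTs are ranked; the critical RT is the n-th
ranked RT with n = max(1, round(p·N)) (round half-up) where p is the
premature-response-corrected response rate
(N_stop − N_succ − N_RT<SSD)/(N_stop − N_RT<SSD); block SSRT =
critical RT − mean SSD; the subject's SSRT is the mean over estimable
blocks.  Premature-response trials are excluded from the mean SSD as
well as from p — they carry atypically long SSDs (the response landed
before the signal), and leaving them in systematically deflates the
estimate.

Under the default generative conditions the estimator carries a small
negative bias (≈ −9 ms at a 200 ms true stop latency; per-subject SD
≈ 18 ms) arising from stop-latency variance, the staircase's SSD
spread, and the initial-SSD transient.  This is a property of the
integration method itself, not an implementation artifact, and is well
inside the ±15 ms recovery band the test suite enforces over 100
simulated subjects.

Cohort exclusions mirror common practice: subjects with more than 10
premature-response stop trials (fewer than 70 usable of 80) are
dropped, as are subjects whose mean volume-to-volume RMS displacement
lies ≥ 3.5 SD above the age-adjusted cohort trend (ordinary least
squares of displacement on age, residual SD on the same sample).
Displacement uses the rigid-body difference transform with
sqrt(r²/5 · tr(AᵀA) + tᵀt) on an 80 mm sphere radius (configurable).

## BOLD forward model

Each subject's voxel data are TC·M + motion artifacts + white noise,
on a 12×12×10 voxel lattice with unit-norm Gaussian-blob component
maps (σ = 1.4 voxels, centers kept ≥ 3σ apart).  Component time
courses contain:

- condition-evoked responses: outcome-category onsets convolved with
  the double-gamma HRF (response gamma shape 6, undershoot shape 16,
  undershoot ratio 6, 32 s support, 0.1 s convolution grid) times
  per-condition amplitudes (order ~1 relative to the unit-variance
  intrinsic fluctuations);
- intrinsic fluctuations drawn per volume from a correlation matrix
  that equals I + base coupling outside stop epochs and
  I + base ± modulation/2 inside successful/unsuccessful stop epochs
  (eigenvalue-clipped to stay positive definite).  An epoch is a 4 s
  window from each stop-trial onset;
- optional motion artifacts: z-scored realignment parameters times
  random voxel loadings.

Defaults: voxel noise SD 0.15 (peak-voxel SNR ≈ 1.3, plausible for
spatially smoothed task fMRI), base coupling 0.5/0.4/0.3 on three
component pairs, coupling modulation 0.5 on two pairs (condition-wise
coupling 0.75 vs 0.25 around the 0.5 base).  The modulation magnitude
was set by a power analysis so that the cPPI estimator attains ≥ 80%
single-subject detection power at the task's series length — the
configured-effect convention used throughout the acceptance
properties.  White intrinsic/voxel noise, instantaneous coupling
switches and the absence of vascular or slice-timing structure are
deliberate simplifications: passing tests demonstrate estimator
correctness under the generative model, not robustness to every
real-data nuisance.

Motion is a Gaussian random walk whose step scale grows with a
subject severity factor and with age (1.5%/year around the 53-year
midpoint), emulating the positive age-motion association in adult
cohorts.

## Cohort structure and injected brain-behavior links

Ages are uniform on [18, 88].  Go RT slows by 2 ms/year and SSRT
lengthens by 1 ms/year.  Three unit-variance subject latents drive the
brain ground truth: `z_act` scales the SuccStop−UnsuccStop evoked
contrast, `z_mod` the coupling modulation, `z_spont` the base
coupling (all as 1 + 0.4·z, floored at 0.05; modulation and base
coupling additionally shrink by 30% per unit normalized age).  The
generative SSRT is

    SSRT = 170 + 1.0·(age−53) − 18·z_act − (18 + 18·age_norm)·z_mod + N(0,12)   [ms]

with age_norm = (age−53)/35.  The two brain channels are therefore
independent, equally weighted determinants of SSRT; only the
connectivity channel's weight grows with age (zero link at 18,
double the mean at 88), which is the moderation signature the final
analysis must detect while leaving the activity channel's interaction
null.  `cohort_feature_table` exposes noisy subject-level measurements
of these ground-truth features (noise SD 0.15, matched to the sampling
error of the imaging-stage estimators) for prediction-scale studies
where simulating voxel data for hundreds of subjects adds nothing.

## Preprocessing and group ICA

Voxel data are residualized against the six realignment parameters,
their first derivatives, a linear trend and an intercept before
decomposition (the confound-regression contract; WM/CSF-like signals
can be appended).  Model order is chosen by the classical MDL
criterion on the covariance eigenvalues of the concatenated data
(geometric/arithmetic-mean ratio of trailing eigenvalues plus a
0.5·k·(2p−k)·log N parameter penalty; the smaller matrix dimension is
the candidate-subspace dimension, the larger one the observation
count, with a configurable effective-sample-size factor, default 1).

Group ICA concatenates subjects in time, PCA-whitens to order k, and
runs FastICA from random initializations (default 100 runs; tests use
10-20).  The contrast function is kurtosis ("cube"): spatial sources
are sparse and strongly super-Gaussian, and the tanh contrast
empirically converges to spurious stable rotations on near-exact
mixtures of disjoint sparse sources, while the kurtosis fixed point
recovers them (|r| > 0.99).  Components across runs are clustered by
average linkage on 1 − |spatial correlation| into k clusters; each
cluster's centrotype is the member with the highest within-cluster
similarity, and the stability index is mean within-cluster minus mean
between-cluster |r| — for well-separated sources ~0.9, the residual
offset reflecting genuine background overlap between z-scored blob
maps.  Map signs follow positive skewness (ties: positive peak voxel).
Subject time courses are obtained by spatially regressing each
subject's data on the group maps and z-scoring.

Noise components are labeled by a high/low-frequency spectral power
ratio above 0.9 (cutoff 0.1 Hz — the ratio threshold is a published
convention, the frequency boundary is this package's explicit
configuration) or by best spatial match to a reference map designated
non-neuronal.  Split-half validation reruns the ICA per subgroup,
matches components to the full decomposition by Hungarian assignment
on |r|, and compares Fisher-z similarities and temporal/connectivity
ICCs between subgroups by one-way ANOVA; all averaging of correlations
happens on the Fisher-z scale.

## Activity (component responsivity)

Per session, the design matrix contains one HRF-convolved impulse
regressor per observed outcome category (correct Go, correct No-Go,
SuccStop, UnsuccStop, pooled Go errors, No-Go commissions, early and
wrong-direction stop responses — absent categories are omitted and
logged), six realignment parameters, discrete-cosine drifts up to
1/128 Hz, and an intercept.  Events are modeled with zero duration.
Component responsivity is the OLS β difference SuccStop − UnsuccStop
averaged over sessions.  Group consistency: one-sample t tests with
Benjamini-Hochberg FDR at α = 0.01.  Age effects: robust regression
(Huber ψ, tuning constant 1.345, ≤ 50 iterations) with age as the
dependent variable — the orientation used throughout — with BH-FDR at
α = 0.05 and the equivalent partial correlation reported for
interpretability.

## Connectivity

Context-independent connectivity between components i and j is the
coefficient of TC_j in a regression of TC_i on TC_j plus all task
regressors, motion, drifts and session confounds; the equivalent
partial correlation is reported alongside.  Including the task
regressors removes evoked co-activation, so the estimate tracks the
generative base coupling and is insensitive to evoked-amplitude
changes.

Context-dependent connectivity contrasts coupling between conditions.
For each condition (SuccStop, UnsuccStop) a psychological series marks
a 4 s epoch from each event onset; interaction terms TC·ψ are formed
after the TCs are residualized against the task design and confounds,
both interactions are orthogonalized against Z = {TC_i, TC_j, Ψ, C},
and their Pearson correlation estimates the coupling expressed in that
condition.  The cPPI value is tanh(z_succ − z_unsucc) on the Fisher
scale — bounded in (−1, 1), symmetric, positive when the pair couples
more strongly during successful stopping, and null in expectation when
coupling is strong but condition-constant.  A construction that
correlates the two interaction terms of a single signed contrast
series was evaluated and rejected: it provably inherits the baseline
coupling (measured false-positive rate 1.0 under constant coupling),
so it cannot discriminate context-dependent from spontaneous
connectivity.  The epoch-indicator weighting (rather than HRF
convolution of ψ, available via a flag) matches the BOLD-level epoch
support of the generative modulation; with HRF weighting the
interaction mass is smeared across the session and single-subject
power collapses (0.05 vs 0.92 measured).  Inference combines sessions
by inverse-variance weighting of the Fisher-z difference, with each
condition's effective sample size taken as the Kish size of its ψ²
weights.  Group and age tests reuse the activity-module machinery on
Fisher-z values at the same FDR levels (0.01 group / 0.05 age).

## Prediction and moderation

Shrinkage regression solves ((1−γ)S + γνI)w = cov(X, y) on centered
training data, where S is the sample covariance, ν its mean
eigenvalue, and γ the analytic Ledoit-Wolf intensity (verified
identical to scikit-learn's estimator); weights are finite for any
p, including p > n, and γ = 0 reduces to OLS.

The three-stage CV fits these weights on 9/10 of subjects, applies
them to the held-out fold (subject scores), and correlates assembled
scores with observed SSRT.  Covariates of no interest are residualized
out of y and X with parameters estimated on the training folds only.
Significance comes from permutations of y (covariate rows travel with
y) re-run through all three stages with re-drawn fold partitions
(re-use is available); p = (1 + #{r_perm ≥ r_obs})/(B + 1).
Fold-partition variance is quantified by repeating the CV over random
repartitions; model comparison uses the mean repartition-r difference
against the permuted-label null of the same statistic, with both
models always evaluated on identical partitions (a paired design that
removes partition noise from the difference).  Full-scale settings are
1000 permutations/1000 repartitions; tests and the demo config scale
these down (199/100 and nested 10-repartition nulls), sizes chosen as
the package's desk-scale defaults.

Moderation fits y ~ scores + age + scores×age (+ covariates) with
scores and age mean-centered before forming the product.  Inference
uses HC3 heteroscedasticity-consistent standard errors: a genuine
moderation makes the residual variance age-dependent, and classical
OLS errors were measurably anticonservative for the interaction term
under the generator (rejection 0.09 vs 0.04 at nominal 0.05).
Independence of the activity- and connectivity-based subject scores is
the plain Pearson correlation.

## Pipeline

`stopnet run` executes simulate → behavior → ICA → activity →
connectivity → prediction → moderation from one YAML config, persists
every intermediate table, writes a per-stage manifest (parameters +
file hashes) and a markdown report.  All randomness flows from the
single master seed; identical config + seed reproduces every output
byte for byte.  The default demo cohort is 20 subjects with ~300
volumes across two runs — the scale at which the full chain (ICA map
recovery |r| ≥ 0.99, significant activity-based prediction, null
spontaneous-connectivity model) is demonstrable in under a minute on
one CPU; the prediction-stage properties that need hundreds of
subjects run on the feature-level cohort emulation instead.

## Known limitations

- The generator's intrinsic fluctuations are temporally white; real
  BOLD autocorrelation would widen all parametric confidence bands.
- Coupling modulation switches instantaneously at epoch boundaries
  with a fixed 4 s support; when, within a trial, real connectivity
  modulation arises is unknown, so the epoch window is an explicit
  free parameter, not a claim.
- The exact high/low-frequency boundary in noise classification, the
  n-th-RT rounding convention, and the block-remainder rule are
  documented conventions; alternatives are configurable.
- Single-run demo pipelines at n = 20 are underpowered for the
  moderation contrast by design; the dissociation property is
  established at n = 120 on the feature-level cohort.
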