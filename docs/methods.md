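# Methods

`dreamcatcher` re-implements a staged blinded-analysis protocol for asking
whether dreamful and dreamless NREM sleep can be told apart from 1-minute
polysomnograms alone, together with a synthetic cohort generator that
supplies the data such a protocol needs.  This note documents the models,
the defaults and why they are what they are, and what the passing test suite
does and does not establish.

## The classification problem and the blinding schedule

A cohort is 54 one-minute cases: 9 participants x 3 sessions x 2 report
conditions (dreamful / dreamless), each a 29-channel recording (25 EEG on a
10-10 subset, 2 EOG, 2 EMG).  All identity is replaced by neutral labels
(ID01–ID54, pairs P01–P27, participants S1–S9, participant-condition groups
G01–G18, condition groups C1–C2) and revealed cumulatively over five steps:
nothing, pairs, participants, participant-condition groups, condition
groups.  The condition *names* are never revealed; a sealed scoring oracle
returns only accuracies.  Each step's decisions are scored at their own
granularity (54 cases, 27 pairs, 27 pairs, 9 participants, 1 binary call)
with an exact two-tailed binomial test against chance (point-probability
convention, which for a fair null equals the doubled smaller tail capped at
one).

## Combination clustering

The clustering engine is an evidence-accumulation ensemble adapted to the
known two-equal-cluster structure:

* sub-clusterings are 2-means runs (best of 10 restarts; restart seeds
  derive from the master seed through numpy `SeedSequence` streams) on
  random feature subsets of size 1–9 — small subsets keep each weak learner
  away from the curse of dimensionality;
* each sub-clustering is weighted by its mean silhouette value, clipped at
  zero (weights are tallied as frequencies, so negative weights are not
  meaningful);
* weighted co-association frequencies form a similarity matrix; hierarchical
  clustering (average linkage for the blinder steps, Ward when near-equal
  sizes must be forced) on `1 - similarity` is cut at every possible level,
  and the cut owning the single cluster closest to 27 cases wins (ties go to
  the fewest clusters, i.e. the highest threshold); that cluster becomes
  class 1, everything else class 2.

Ward linkage on `1 - coassoc` treats the dissimilarity as squared-Euclidean,
the standard caveat when Ward is applied to a precomputed matrix; average
linkage is the default.  The reference ensemble on the 2475-feature set runs
2475 singleton + 8 x 10 000 random-subset sub-clusterings = 82 475.  The
inner 2-means is a vectorized Lloyd iteration batched over restarts;
scikit-learn's `KMeans` and `silhouette_score` are used in the tests as
independent oracles of the same quantities.

## Feature sets

PSDs are Welch estimates with 2-s Hann windows and 80% overlap (0.5-Hz
resolution; the window length is our choice, the taper and overlap are part
of the protocol being reproduced); all log transforms are natural logs of
µV²/Hz.  `PowerFine` is the 99-bin (0.5–49.5 Hz) log PSD per EEG channel
(2475 features).  `PowerBand` aggregates the six classical bands.  The
Step-2 composite has exactly 50 features: 19 log-spaced scalp-average PSD
bins (integer bin edges chosen nearest to a geometric progression over the
99 fine bins, repaired to stay strictly increasing, so every bin is
non-empty), 11 regional "hot-zone" features (whole-scalp low/high power over
the final 20 s; parieto-occipital low and frontal high power over the final
20/40/60 s; high power over occipital, temporal and posterior-temporal
electrode groups over the final 20 s; bands 1–12 and 18–50 Hz), and per
modality (EMG, EOG) the 0/25/50/75/100th percentiles of consecutive 1-s RMS
values within each 30-s half (10 features each).  The hot-zone electrode
lists, time windows, and the per-quarter RMS variant used in Step 1 are
documented emulations and are configurable — the original supplementary
definitions are not public.

Entropy features follow the standard conventions: permutation entropy of
order 3, delay 1, ties broken by order of occurrence (nats; ramps give 0,
i.i.d. noise approaches ln 6); approximate entropy with m = 2,
r = 0.2 x SD, Chebyshev distance, self-matches included, computed after
decimation to 64 Hz to keep the quadratic template count tractable at
one-minute lengths.  Autocorrelation summaries (time to 1/e, first zero
crossing, lag-1 value) stand in for the cited autocorrelation method.

Step 5 uses three literature-replication features: `SBP_low` (mean log power
1–4 Hz, parieto-occipital), `SBP_high` (20–50 Hz over parieto-occipital +
lateral-frontal + temporal electrodes) and `Scarpelli` (0.50–4.75 Hz over
left fronto-temporal electrodes F7/FT7/T7).

## Temporal-consistency screening

With no labels at all, feature sets are screened by whether clustering them
is stable over time: each case is split into four 15-s segments, each
segment's cases are clustered independently, and agreement between two
segments is C = 2|pi1 - 1/2|, where pi1 is the fraction of cases keeping
co-membership under one of the two label mappings (pi1 + pi2 = 1, so C is
relabeling-invariant).  The null bound is the Bonferroni-corrected upper
quantile of C under pairs of uniformly random balanced labelings — a
documented simplification, since the original null's cluster-size model is
unspecified; the size profile is configurable.  Binomial p-values count
per-case co-membership agreements under the better mapping (the reading of
"N = 54"; the alternative per-pair counting is noted as ambiguous).  The
report only ranks sets; choosing the working set remains an analyst
decision, and the trend test (late-minus-early permutation p) enumerates all
arrangements exhaustively when feasible.

## Pair geometry (Steps 2–4)

Once pairs are known, each pair yields a difference vector whose
*orientation* (not direction — which member is which condition is unknown)
carries the contrast.  Vectors are canonicalized (first non-zero coordinate
positive) and unit-normalized.  The mean orientation maximizes the mean
absolute cosine similarity; because the objective is non-convex the solver
runs alternating sign-assignment/averaging ascent from the leading
eigenvector of the scatter, from every input vector (small sets), and from
random restarts, then polishes each solution by greedy single-sign-flip
moves.  For up to 15 vectors this reproducibly attains the global optimum of
exhaustive sign enumeration (tested to 1e-9).  A hyperplane through the
origin normal to the orientation splits every pair — pair members never
co-associate by construction; a projection of exactly zero sends the first
member to the positive side and is logged.

Pairwise sub-clusterings over random feature subsets are weighted by their
mean |cos| goodness divided by its Monte-Carlo expectation under uniformly
random orientations of matched count and dimension (cached per (n, dim);
dimension 1 and single-vector cases are exactly 1 and skip simulation).
Step 3 averages four co-association matrices with equal weight — pairwise
splits under the global orientation, pairwise splits under each
participant's own orientation, 2-means sub-clusterings over all cases, and
2-means sub-clusterings within each participant's six cases tallied
globally.  The |cos|-based and silhouette-based weight families are min-max
rescaled to [0, 1] before tallying since their scales are not comparable;
the equal-weight average is a documented default (the original averaging
weights are not public).  Step 4 replaces pair differences with the
difference of each participant's two condition-group means (nine vectors)
and runs the hyperplane ensemble over the 18 group means.

## ICA cleanup (Steps 3–4)

Per participant, the six cases' EEG+EOG channels are concatenated and
decomposed with FastICA (deterministic under seed; rank-deficient data
reduces the component count with a warning; full retention recomposes the
input to numerical tolerance).  Component condition-relevance is scored from
within-pair differences of component log power.  Because each pair's
difference sign is arbitrary, one sign per pair is first chosen by the
mean-orientation sign assignment over the pairs' component-difference
vectors; the score is then |mean difference| / SE under those signs.  A
naive signed mean without this alignment would cancel under the blinding and
score a genuinely condition-coupled component near zero.  Step 4 uses the
revealed condition groups directly: |group-mean contrast| / pooled SE, no
alignment needed.  The default keep rule retains the top half of components
by score; the original selection criterion is not public, so both the score
and the fraction are explicit configuration.

## Labeling rules

Clusters are anonymous, so condition names come from literature-derived
rules.  The spectral rule computes per-bin Cohen's d between clusters on log
PSD features and averages it over a low (1–12 Hz) and a high (18–50 Hz)
band: the cluster with more low-frequency and less high-frequency power is
called dreamless.  When the two band summaries agree in sign (an
inconclusive pattern), the larger-|d| band decides and the conflict is
recorded — the original adjudication in that situation is unstated, so this
precedence is our documented choice.  Step 4 adds a frontal high-frequency
tiebreak (lower frontal high power -> dreamless) used when the spectral rule
is inconclusive.  Step 5 subtracts each participant's mean from each
feature (the groups are balanced over participants, so this removes the
participant random effect exactly), then majority-votes the three feature
contrasts (lower SBP_low, higher SBP_high, lower Scarpelli -> dreamful); a
tied vote is an error rather than a guess.

Cohen's d uses sigma = sqrt((SD1² + SD2²)/2) for summary inputs — the
convention that reproduces both printed worked values (0.56, 0.16) — which
coincides with the standard pooled formula for equal group sizes (used for
raw unequal-n inputs).

## Synthetic cohort generator

The generator emulates the *statistical* structure the analysis faces, not
sleep physiology.  Per EEG channel: 1/f^alpha colored noise (spectral
shaping of white noise; alpha ~ N(2.0, 0.2) per participant; background RMS
30 µV), shared sleep-spindle events (12–15 Hz, ~2/min, central emphasis) and
slow-oscillation bursts (0.6–1.2 Hz, ~6/min, frontal emphasis), plus 1 µV
sensor noise.  Participant identity enters as a log-power offset with SD 0.5
and the participant-specific exponent; each case additionally draws a
log-power offset with SD 0.2 (state variability between awakenings).  EOG
channels carry slow eye-movement events (~3/min, mirrored polarity) with
frontal-EEG crosstalk; EMG is high-frequency-weighted noise at 3 µV RMS.
EOG/EMG are condition-independent by default.

The condition effect is purely spectral: dreamless cases multiply low-band
power by `condition_delta_ratio`^w and dreamful cases multiply 18–50-Hz
power by `condition_high_ratio`^w, with regional weights w peaking
parieto-occipitally for the low band and frontally for the high band.  The
gains act on the rFFT of the composite signal, so Welch band power recovers
the configured log-ratio directly; the low-band gain extends through DC
because the sub-0.5-Hz background otherwise leaks enough power across the
band edge (2-s Hann windows have a main lobe two bins wide) to dilute the
measured ratio.  Default ratios are 1.4 (low) and 1.3 (high), calibrated so
that with participant variability off the per-case parieto-occipital
delta-band log-power d is about 1.5 — deliberately large, for
parameter-recovery testing; the true magnitude of any such effect is
unknown (the study this emulates found none), so the ratios are free
parameters, not claims.

What passing tests on this generator do **not** show: robustness to real
EEG nonstationarity, artifacts, volume conduction, sleep-stage structure, or
any physiological coupling between dreaming and EOG/EMG; the generator's
channels are far better behaved than real recordings.

## Problem sizes and numerical choices

The test suite and analysis scripts run cohorts at 128 Hz (the smallest rate
that carries the 50-Hz band at 0.5-Hz Welch resolution) and reduced
ensembles (typically 500 random subsets per size for Step-1-style runs, 20–
200 for pair ensembles, Monte-Carlo normalizations at 1000 draws); the
package defaults remain 256 Hz and 10 000 subsets.  EDF output is 16-bit
with a per-channel symmetric physical range (round-trip error bounded by the
quantization step, tested against the `mne` reader); the `.npz` + JSON
format is lossless for exact round-trips.  Degenerate inputs are explicit:
all-identical points yield a single cluster with weight zero; a flat
co-association matrix raises rather than splitting arbitrarily;
zero-variance features studentize to zeros with a warning; zero difference
vectors are excluded with a warning; a zero-variance series has approximate
entropy 0 by convention.

## Known limitations

* Several components of the original protocol are not public (hot-zone
  feature definitions, ICA selection criterion, Step-3 averaging weights,
  the null's cluster-size model); each is re-specified here as a documented,
  configurable default, and results that depend on them should be read as
  properties of *this* pipeline.
* The headline accuracies of the original experiment depended on
  never-deposited human data and are not reproducible; the package instead
  reproduces every self-contained printed statistic and demonstrates the
  protocol's behaviour (chance performance under a null effect, recovery of
  large injected effects, the participant-identity failure mode of Step 1)
  on synthetic cohorts.
* Ward-on-precomputed-dissimilarity and the min-max weight rescaling in the
  Step-3 average are pragmatic choices; alternatives (average linkage,
  rank-based weight pooling) are one configuration switch away.
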