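# Methods

This package implements a resting-state EEG analysis chain for small
paired pharmacological studies (a baseline window T0 and a post-dose
window T1 per subject), together with a synthetic-EEG generator that
stands in for clinical recordings that cannot be shared. This note
documents the models, the parameters that matter, the numerical choices,
and the limits of what the synthetic validation shows.

## Signal model and preprocessing

A recording is a channels × samples matrix in µV with a sampling rate, a
channel-label list, and a list of half-open *continuity segments*:
artifact-removal cuts break continuity, and no filter, Welch window, or
phase epoch ever crosses a segment boundary. Filtering is applied per
segment for this reason (a cut is a genuine discontinuity that a
convolution would smear across); segments must exceed 3× the filter order.

Filters are Hamming-window linear-phase FIR designs applied zero-phase by
compensating the group delay (order/2 samples). The standard chain is a
45 Hz low-pass (order 660, 5 Hz transition, −6 dB cutoff convention) at
the acquisition rate, polyphase resampling to 250 Hz (per segment, output
length ⌊n·fs_new/fs⌋), a 0.5 Hz high-pass (order 826, 1 Hz transition),
optional bad-channel repair, and common-average re-referencing. The
high-pass design's stopband leaves ~0.5 % of a DC offset (−46 dB); tests
bound it accordingly. Bad channels are caller-supplied, never
auto-detected, and are repaired by spherical-spline interpolation
(spline order m = 4, 50 Legendre terms, regularization λ = 1e−5 — the
standard CSD-toolbox constants). The same spline kernels drive the
surface Laplacian. Independent-component artifact removal is a manual
step outside this package.

The packaged montage is a 59-channel 10-10 reconstruction — 27 homologous
left/right pairs plus 5 midline channels, positions on the unit sphere —
with homologues derived from label parity (odd digit left, even right,
C3↔C4). Any 10-10 subset with complete pairing is accepted.

## Spectra and symmetry

PSD is a Hamming-window Welch estimate, 2 s windows (500 samples at
250 Hz, 0.5 Hz bins), 50 % overlap, windows tiled within continuity
segments. Relative band power uses an 8-band scheme — delta 1.0–3.5,
theta 4.0–7.5, alpha 8.0–12.5, low/middle/high beta 13.0–15.5 /
16.0–20.5 / 21.0–29.5, broadband beta 13.0–29.5, gamma 30.0–42.0 Hz —
with *inclusive* bin edges (the printed edges only tile the 0.5 Hz grid
that way) and the 1.0–42.0 Hz sum as denominator. The five primary bands
(delta/theta/alpha/beta/gamma) tile the grid exactly, so their fractions
sum to 1 per channel. Global band power is the channel mean of the
fractions; the global relative PSD is the channel-mean PSD normalized to
unit sum over 1–42 Hz.

Two asymmetry summaries are computed from the PSD, both built on the
normalized bin asymmetry |(R−L)/(R+L)| ∈ [0, 1]: the pairwise-derived
index (pdBSI) averages it over homologous pairs and band bins; the
revised index (rBSI) first averages the PSD within each hemisphere and
then averages the asymmetry over bins. Midline channels are excluded;
bins with R+L = 0 are skipped. Both are scale- and mirror-invariant.

## Connectivity

Connectivity uses phase-locking values after a current-source-density
surface Laplacian (reference must be common-average first). Signals are
band-passed into five contiguous bands (delta 1–4, theta 4–8, alpha 8–13,
beta 13–30, gamma 30–42 Hz), the analytic phase extracted per continuity
segment, 10 % of each segment trimmed per side against edge effects, and
2 s non-overlapping epochs tiled from the trimmed start. For channels
i, j over M epochs of N samples:

    PLV_ij = (1/M) Σ_m | (1/N) Σ_n exp(−i (φ_jn − φ_in)) |

The band-pass transition width is low-edge/2 clipped to [1, 2] Hz, with
the order additionally spanning ≥3 cycles of the low edge. The narrow
transitions matter: with wide transitions, a power shift in a
*neighbouring* band changes the filtered signal's effective bandwidth and
thereby the PLV estimator's null bias on **every** edge, which a paired
test then reports as a global connectivity change. Even with narrow
transitions the estimator has a band-dependent null floor (~0.27 in alpha
for 2 s epochs) because it averages per-epoch magnitudes; the floor does
not shrink with more epochs, only its variance does. Consequences: (a)
PLV values are compared between conditions, never against zero; (b)
simulations that plant pure coupling effects hold the band-power recipe
fixed across conditions.

The FCSCC summary is the arithmetic mean of a connectivity matrix over
the edges of a (statistically identified) connected component.

## Microstates

The microstate model treats the average-referenced scalp map as switching
among K = 4 quasi-stable unit-norm template topographies, polarity
ignored throughout (all assignments use |spatial correlation|, the
Pearson correlation across channels of average-referenced maps).

*Peak selection.* GFP is the per-sample population (divide-by-C) standard
deviation across channels — pinned by GFP([1, −1]) = 1. Local GFP maxima
are found within continuity segments; the lowest 15 % of peaks (by GFP,
ties broken by time) are discarded first, then peaks whose GFP exceeds
the survivors' mean by more than 3 standard deviations (so a flat peak
distribution loses nothing to the SD rule and a 10× outlier is removed).

*Clustering.* The modified (polarity-invariant) k-means assigns each map
to the template maximizing the squared spatial correlation and updates
each template as the dominant eigenvector of its assigned maps'
channel-covariance. Convergence is a relative GEV change below 1e−7; the
best of 10 restarts by GEV is kept. Ten restarts are the default because
4-restart runs landed in local optima (GEV 0.67 vs 0.85) in ~7 % of
synthetic recordings; empty clusters are re-seeded from the worst-fit
map. A second-level k-means over the pooled per-recording templates
yields group templates, labelled A–D by a one-to-one Hungarian assignment
of maximal |correlation| against packaged canonical maps. Those canonical
maps are *synthetic* reconstructions of the four classic normative
topographies (two diagonal axes, an anterior–posterior gradient, a
fronto-central focus) — adequate for consistent labelling, not normative
data.

*Back-fitting and smoothing.* Every sample is labelled by the
best-matching template; then, while any non-truncated segment is shorter
than ⌈30 ms · fs / 1000⌉ samples (8 at 250 Hz), the shortest such
segment's samples are reassigned one by one to whichever neighbouring
segment's class correlates better at that sample. This is the
segment-rejection smoother; the first/last segment of each continuity
segment is flagged truncated.

*Features.* Truncated segments are excluded from every segment-based
feature. Per class: mean duration (ms); occurrence (non-truncated
segments per second of labelled time); coverage (fraction of
non-truncated-segment samples, summing to 1); mean interval — the mean
gap between the end of one segment of the class and the start of the
next, within a continuity segment:

    MeanInterval_X = (1/(N−1)) Σ_i (t_s(i+1) − t_e(i))

mean GFP over the class's samples; GEV_X = Σ_{t∈X} (GFP_t · corr_t,X)² /
Σ_t GFP_t² over *all* labelled samples (back-fitting labels every sample,
so GEV is not restricted to peaks); SC_XY, the mean |correlation| of
template X with the maps assigned to class Y; and transition
probabilities TP_XY over consecutive non-truncated segment pairs
(self-transitions impossible; rows sum to 1 where defined). Absent
classes yield NaN, never 0.

## Permutation inference

All tests are two-sided at α = 0.05 with add-one corrections; exhaustive
enumeration is used whenever the group size is ≤ max_perm (default 2000),
else max_perm uniform draws.

*Scalar tests.* Within-subject: sign flips of the paired differences with
the one-sample t statistic; between-subject: label shuffles with the
Welch t; correlation: outcome shuffles with Spearman's ρ (average ranks).
The p-value is (#{|stat_perm| > |stat_obs|} + 1)/(n_perm + 1) over the
full group. For continuous statistics the strict inequality is exactly
compensated by the add-one, the test is calibrated (measured type-I
4.5 % at n = 8 over 200 null replicates), and the attainable floors are
1/17 ≈ 0.059 (n = 4 within), 1/257 ≈ 0.004 (n = 8 within), and 1/71 ≈
0.014 (4-vs-4 between), with 16 = 2⁴ permutations in the n = 4 design.

*NBS.* Edge-wise p-value and sign maps over all C(59,2) = 1,711 edges:
exact-distribution Wilcoxon signed-rank on paired differences (within),
exact rank-sum (between), or Spearman with the t-approximation
(correlation design). The exact null distributions are computed by
generating-function/DP recursions and match scipy's exact mode to 1e−12
at n = 8; mid-rank ties are bracketed by floor/ceil on the integer
support. Significant maps (edge p < 0.05, split by sign of the median
difference) are decomposed into connected components (union-find; size =
edge count). Each permutation contributes the largest positive and
largest negative component size to two null distributions, and each
observed component is scored against its sign-matched null as

    p = min(1, (2 · #{|S_null| ≥ |s_obs|} + 1) / (N + 1))

over the N non-identity permutations. The *weak* inequality is
deliberate: component sizes are small tie-heavy integers, and a strict
inequality collapses the ties and inflates the family-wise error to ~18 %
in null simulations, versus 2 % with the weak form (the strict form is
harmless only for continuous statistics, where the scalar tests keep it).

*NBS sensitivity.* At n = 8 the signed-rank floor is 2/256 ≈ 0.008, so an
edge threshold of 0.05 admits ~4 % of edges by chance. On the full
59-channel graph that is ~60–70 dependent false edges — around the
percolation threshold of a 59-node random graph — so chance components
span tens of edges and small true subnetworks cannot outgrow them at any
effect size. This is a property of the method at this sample size, not of
the implementation; the planted-recovery simulation therefore runs on a
19-channel 10-20-style subset (171 edges, chance components of a few
edges), where a planted 6-edge coupling drop is recovered at p < 0.05.

## Classification and prediction

Features reaching the minimal permutation p (ties included) feed a
standardize → PCA → linear-SVM pipeline fitted strictly inside each
training fold; an inner leave-one-out loop grid-searches C over
{0.01, 0.1, 1, 10, 100} (and ε over {0.01, 0.1, 1} for SVR), and the
outer loop holds out one row (default; 16 folds for 8 paired subjects) or
one subject (both rows; a config switch). Classification keeps 2
principal components and reports the AUC of decision scores pooled over
outer folds; regression keeps 1 component and reports RMSE and the
predicted–actual Pearson correlation, with an optional RMSE excluding
explicitly named outlier subjects (no automatic detection). Note that
pooled-LOOCV AUC is pessimistically biased under label permutations when
folds unbalance the training classes; chance-level checks therefore use
paired label swaps with leave-subject-out folds, which keep training
balanced and centre the null AUC on 0.5.

## Synthetic data: what it emulates, and what it does not

`gen_oscillatory` builds each channel as a sum of five band-limited
Gaussian-noise oscillators (band-pass-filtered white noise, not
sinusoids, so Welch and Hilbert stages face realistic spectra) with
relative-power targets summing to 1; pairwise phase coupling is planted
by mixing a shared narrowband source into both channels with variance
weight equal to the coupling strength (per-channel budgets ≤ 1), giving a
PLV that rises monotonically from the null floor to 1. `gen_microstate_eeg`
emits (active template × smooth positive envelope) + spatially white
noise at a stated signal/noise variance ratio, with gamma-distributed
segment durations (mean 100 ms, hard 40 ms floor) and uniform
class-switching. `gen_paired_study` generates 8 paired subjects (60 s,
250 Hz by default) with a −0.07 theta relative-power shift at T1
(redistributed proportionally), a −0.25 coupling drop on a 6-edge
fronto-central path, and outcome scores linear in each subject's baseline
coupling plus Gaussian noise (σ = 0.5). All draws flow from one seeded
generator; identical seeds give bit-identical output.

Not emulated: 1/f spectral shape, artifacts (blinks, muscle — the ICA
stage is out of scope), non-stationarity beyond the microstate envelope,
volume conduction (coupling is planted at electrode pairs, not sources),
and realistic microstate topography geometry (templates are random smooth
maps). Passing parameter-recovery tests therefore demonstrates that the
estimators recover what they claim from signals obeying their own
assumptions — not that those assumptions hold in patient EEG. Two
consequences surfaced during validation and are worth repeating: the
surface Laplacian, being a spatial filter, dilutes electrode-pair-planted
coupling below the PLV noise floor (the coupling-recovery simulations
bypass it; real source-level coupling projects to many electrodes and
survives CSD differently), and band-power changes adjacent to a band bias
that band's PLV null level unless the band-pass transitions are narrow.

## Problem sizes

The test suite and acceptance script use 10–120 s recordings, 2–59
channels, 8 paired subjects, 200 replicates for scalar-test calibration,
50 for NBS family-wise calibration, and 8–10 seeds for microstate
parameter recovery; the analysis drivers run the full 59-channel,
16-recording study. These sizes were chosen so each check's statistical
resolution comfortably exceeds its tolerance.

## Known limitations

- Spearman edge-wise p-values use the t-approximation (exact permutation
  distributions are reserved for the Wilcoxon stages).
- Mid-rank ties in the exact Wilcoxon lookups are bracketed, not
  enumerated; with continuous data ties are measure-zero.
- The NBS edge threshold is a p-value threshold at the conventional
  0.05; no t-threshold sweep is provided.
- The canonical A–D maps are synthetic stand-ins; A/B labelling relative
  to published normative maps should not be over-interpreted.
- `matrix_text` round-trips bit-exactly but stores no segment table;
  continuity metadata travels in side-channel JSON where needed.
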