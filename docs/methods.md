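# Methods

This note records the models, estimators and numerical choices behind
`hypercoh`, and what the synthetic-data tests do and do not establish
about real recordings.

## Signal model of the simulator

A dyadic session is a pair of hardware-synchronized multichannel
recordings sharing one event-marker table. Each trial adds to both
subjects a Gabor atom — a Gaussian-windowed cosine — at latency 0.6 s
after stimulus onset, carrier 5 Hz (inside the 4–7 Hz ERP band),
envelope σ = 0.12 s, scaled by a per-fairness amplitude and a
centro-parietal topography peaking at Pz (Gaussian falloff over
approximate 10-10 coordinates). Ongoing activity is 1/f (pink) noise of
10 µV RMS plus 2 µV white sensor noise per channel, which puts the
single-trial burst SNR below one — the regime in which trial averaging
is necessary and the run-length null behaves like real ERP data. All
randomness flows from one seeded generator.

The defaults are: 7 blocks × 30 trials (210 trials, 35 per
fairness × agency cell), 250 Hz, amplitudes fair 8 / unfair 5 /
hyperunfair 4 µV. The published study reports no quantitative LPP
amplitudes (figures only), so these amplitudes are plausible
placeholders and marked as such.

### Inter-brain coupling

The receiver's burst phase is stimulus-locked, `N(0, 0.3 rad)` across
trials (a phase-locked component is what makes the trial-averaged ERP
non-zero). The observer's phase adds two components controlled by the
coupling parameter κ ∈ [0, 1]:

- a **per-trial von Mises offset** whose concentration is chosen by
  inverting the Bessel ratio `A(c) = I₁(c)/I₀(c) = κ`, so the mean
  resultant length of the phase-difference distribution equals κ
  (circular variance `1 − κ`);
- a **within-burst Brownian phase drift** of rate `(1 − κ) × 5
  rad/√s`, anchored at the burst center.

Both are needed because smoothed magnitude coherence is mathematically
invariant to a phase offset that is constant over the smoothing window:
a per-trial offset alone leaves trial-averaged coherence unchanged no
matter how the offsets are distributed. The drift term decorrelates the
two bursts *within* the estimator's ~0.2 s smoothing support (drift
s.d. ≈ 2.2 rad at κ = 0, coherent fraction e^{−σ²/2} ≈ 0.08), which is
exactly what the estimator detects; the offset term preserves the
intuitive per-trial phase-difference statistics. Locus coherence is
consequently monotone in κ, which the test suite verifies end to end.

### What the simulator does not emulate

No volume-conducted correlated background between channels, no
eye-movement forward model, no reaction-time or habituation dynamics,
no inter-subject amplitude asymmetries. Passing tests therefore show
that the estimators recover planted effects under realistic SNR and
autocorrelation — not that every property carries over to real data.
One intrinsic estimator property worth knowing: because single-trial
coherence is a low-degrees-of-freedom ratio statistic, a strong burst
elevates locus coherence somewhat above the noise floor even at κ = 0
(amplitude-driven bias). The `power_phase_diagnostic` — a per-time
circular–linear (Mardia) correlation between trial band power and
cross-spectrum phase, with the χ²(2) approximation `n·R²` for p —
exists precisely to separate phase alignment from this amplitude route.

## Preprocessing

Fixed order: band-pass → ocular regression → epoch + baseline →
amplitude rejection → dyad intersection. The band-pass is a zero-phase
Butterworth cascade (separate high- and low-pass sections applied
forward–backward); the order of each section is chosen by `buttord` so
that the cascaded response is down ≥ 40 dB at 0.5·low and 1.2·high,
which a fixed 4th-order section cannot achieve at the high edge.
Zero-phase filtering protects ERP latencies. Ocular decontamination is
least-squares regression of all EEG channels on the demeaned EOG
channels — deterministic and exactly testable, chosen over ICA because
the goal is ocular decontamination, not component decomposition (an ICA
hook can be substituted upstream). Amplitude rejection uses a strict
inequality (a sample at exactly ±80 µV is kept) over EEG channels only,
never modifies data, and edge-truncated trials are flagged rather than
dropped. Sample indexing is 0-based and all windows are half-open.

## Wavelet coherence

The CWT uses the analytic Morlet wavelet with ω₀ = 6 (the standard
admissibility-respecting default) computed in the frequency domain with
zero padding to the next power of two; scale maps to frequency as
`f = ω₀/(2πs)`. The scale grid is 12 voices per octave spanning 4–7 Hz.
Coherence follows the Torrence–Compo/Grinsted convention, including the
`1/s` weighting, with smoothing by a Gaussian in time of standard
deviation equal to the scale and a 0.6-octave boxcar across scales;
without smoothing, single-trial coherence is identically 1, and a
regression test asserts this degenerate behavior so the smoothing can
never silently vanish. The cone of influence uses the √2·s e-folding
time; band collapse is the unweighted mean over in-band scales with
COI-masked cells excluded (edge samples use fewer scales and report how
many; fully masked samples are NaN). Per-trial coherence maps are
averaged arithmetically across trials — not pooled cross-spectra —
matching how trial-wise coherence is averaged in practice. Coherence
values enter the t-tests untransformed; a Fisher-z step was considered
and left out as the default since it changes none of the qualitative
conclusions on bounded [0,1] data at these sample sizes.

## Run-length (Guthrie–Buchwald) statistics

Pointwise paired t-tests (two-sided, df = n−1) are screened by the
longest-run criterion. The null is simulated: each replicate draws
`n_subjects` independent stationary Gaussian AR(1) series with the
given lag-1 coefficient, applies the pointwise test, and records the
longest run of consecutive significant samples L. Two reductions of the
null distribution of L are supported:

- `convention="quantile"` (default): the (1 − α) quantile of L — the
  longest run still compatible with the null. This is how the classic
  graphical run-length tables are read; under the canonical conditions
  (ρ = 0.9, 125 samples, 15 subjects, α = 0.05) it gives the familiar
  9-sample threshold (our 20 000-replicate null has P(L ≤ 9) = 0.954).
- `convention="exceedance"`: the smallest r with P(L ≥ r) ≤ α — one
  grid step more conservative (10 under the same conditions), and the
  variant for which "keep runs ≥ threshold" provably bounds the
  familywise error by α. The quantile default is slightly
  anticonservative (FWER ≈ 0.067 at the canonical null), a property of
  the published procedure itself.

The pointwise level `alpha` and the run-quantile level `run_alpha` are
separate parameters (defaulting to the same value): the threshold is
*increasing* in the pointwise level but *decreasing* in the run level,
so monotonicity statements only make sense with one of them fixed. For
real data the AR(1) coefficient is estimated as the mean lag-1
autocorrelation of the subject difference-waveforms. This AR(1)
surrogate is adequate when the tested series' autocorrelation is
short-range (as for ERP waveforms and band-collapsed coherence at
realistic SNR, ρ ≈ 0.9–0.98); for extremely smooth series whose null
runs outlast anything an AR(1) process produces, no run threshold
controls error correctly — a limitation inherited from the method.

## Split-plot ANOVA

Balanced 2 (ROLE, between) × 2 (AGENCY) × 2 (FAIRNESS) design, one
value per subject × cell. Sums of squares are decomposed into the
between stratum (ROLE vs subjects-within-groups) and three within
strata (each within effect and its ROLE interaction against the
matching effect-by-subject error). The partition identity
ΣSS = SS_total is asserted internally to 1e−9 on every call; unbalanced
input is an explicit error (no Type-III fallback). Degrees of freedom
derive from the data given: 14 + 14 subjects yield (1, 26) for every
effect. Tukey HSD is available through `scipy.stats.tukey_hsd` on cell
values as a post-hoc hook.

## eLORETA

Block-diagonal weights W (3×3 per dipole) solve the fixed point
`W_v = [L_vᵀ (L W⁻¹ Lᵀ + λH)⁺ L_v]^{1/2}` (H the average-reference
operator, ⁺ the pseudoinverse), iterated from identity to relative
change < 1e−6 with a 200-iteration cap and an explicit error on
non-convergence; the inverse operator is `T = W⁻¹Lᵀ(LW⁻¹Lᵀ + λH)⁺`.
Weights depend only on the lead field and λ, never on data. The
defining exact-localization property — a noiseless point source at any
dipole is reconstructed with its power maximum at that dipole at λ = 0
— is verified by brute-force sweep in the tests. λ is chosen by
leave-one-channel-out scalp prediction error on a log grid (the
concrete procedure behind "cross-validation" was left open; LOO-channel
is the common, fully testable choice), computed globally per subject.
Dipole orientation is the leading eigenvector of the 3×3 source
covariance pooled over all kept trials and samples, sign-fixed so the
largest-magnitude component is positive; repeated leading eigenvalues
fall back to the deterministic eigendecomposition order with a warning,
and an average explained-variance below 50% triggers a low-dominance
warning. Each ROI is represented by the scalar series of the
Euclidean-nearest dipole to its MNI centroid (ties → lowest index). The
eight channels absent from the New York Head model (TP9, O9, P11, IO,
TP10, O10, Iz, P12) are dropped before inversion (61 → 53); the actual
New York Head lead field is an external asset behind the `LeadField`
interface — all tests use generated toy models. Source-space coherence
inherits eLORETA's spatial leakage: a coupled source elevates coherence
at nearby reconstructed dipoles too, so ROI contrasts should be read
relative to other ROIs, as the localization test does.

The default 11-ROI table (MPFC, aMCC, sgACC, TPJ, pSTS, temporal pole,
precuneus, SMG, DLPFC, anterior insula, ventral striatum) carries
approximate literature MNI centroids and is explicitly user-editable —
study-specific coordinates should replace it.

## Problem sizes

The test suite runs the full chain at reduced but honest sizes chosen
to keep iteration fast while leaving effects well-resolved: toy lead
fields of 20 channels × 30–50 dipoles; coupling-recovery batteries of
14 dyads × 35 trials per cell over 20 seeds; 20 000-replicate run-length
nulls; 4 000-replicate ANOVA null calibration. The pipeline entry point
scales unchanged to the full 14-dyad, 210-trial, 61-channel session.
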