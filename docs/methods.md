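# Methods

This note documents the models, estimators, numerical choices and
validation logic behind `thetagaze`, in the order data flows through the
package.

## Synthetic sessions as the validation substrate

No patient recordings ship with the package; every statistical property is
instead verified by parameter recovery on sessions from
`thetagaze.synth`, which generates jointly a continuous LFP, a 500 Hz gaze
record, and a trial table with memory-outcome labels.

**LFP model.** The signal is a sum of three components:

- a Gaussian *aperiodic background* with power spectrum
  `P(f) = 10^offset · f^(−χ)`, produced by spectrally shaping white noise
  in the frequency domain (so the log-log slope is exactly −χ);
- a *narrowband theta oscillation* whose instantaneous frequency wanders
  around `theta_freq` (default 5 Hz) as an Ornstein–Uhlenbeck process
  (sd 0.5 Hz, correlation time 0.5 s). Real hippocampal theta is 4–6 Hz
  band activity, not a pure tone, and this matters statistically: with a
  perfect sinusoid, every epoch's theta phase series is identical up to an
  offset, trial-shuffle surrogates then underestimate sampling
  variability, and the coupling z-scores overdisperse (we measured
  sd(MI_Z) ≈ 1.5 under no coupling with a pure tone, ≈ 1.0 with wander).
  The exact phase series is stored as ground truth either way;
- a *gamma carrier* (default 90 Hz) whose envelope follows
  `A_g · (1 + d·cos(θ(t) − φ_c)) / (1 + d)`: `d = coupling_depth ∈ [0,1]`,
  and `d = 1` silences gamma at the anti-preferred phase. The depth may
  differ by trial condition (`coupling_depth_by_condition`), which is what
  lets a condition contrast in coupling exist at all — coupling is a
  property of the continuous signal in time, so it can vary only with
  trial identity, not with fixation target.

Default amplitudes (offset 2.0, χ = 2, theta 0.4, gamma 0.12) put theta at
roughly twice the background power in its band and leave the gamma carrier
near the noise floor away from its center frequency. Both choices are
deliberate: a too-clean signal saturates every z-score and makes
comodulogram localization degenerate (wavelet side-bands of a strong
carrier carry the same relative modulation as the carrier itself, so with
no noise the coupling appears equally at 80 and at 200 Hz).

**Fixation stream.** Fixations are laid down sequentially per trial:
after the previous fixation plus a saccade gap, an exponential wait
elapses; an unlocked class (κ = 0) starts there, while a phase-locked
class draws a target phase from vonMises(μ, κ) and starts at the next
instant theta passes through it. Onset phases therefore follow the von
Mises law *exactly* while waits stay Poisson-like. We first implemented
the textbook alternative — thinning a dense Poisson stream by the von
Mises density — and measured a systematic ≈ −0.2 rad phase bias at κ = 8:
with the dead-time compensation needed to hold the fixation rate, several
accepted candidates fall in each theta cycle and keeping the first one
favors earlier phases. The exact-placement scheme has no such bias
(measured |mean error| < 0.04 rad at κ = 8). Its cost is half a theta
period of expected alignment time per locked fixation, so locked classes
saturate below very high nominal rates; with the default durations the
unlocked default rate of 4 fixations/s is met (60 s sessions yield counts
within Poisson 99% bounds of 240).

Phase-locking parameters are keyed by `"condition"` or
`"condition/roi"`, so e.g. fixations to the original versus the updated
object-location within the same Mismatch trials can lock to different
phases with different concentrations.

**Gaze render.** Fixations hold position with Gaussian jitter (sd 0.02°,
clipped at ±0.07°, well under the 0.15° motion threshold); saccades follow
a raised-cosine velocity profile whose duration grows with amplitude
(14–50 ms), giving peak velocity `2A/T ≥ 100°/s` and peak acceleration
`2πA/T² ≥ 8000°/s²` for every amplitude ≥ ~0.3°; consecutive fixation
positions are kept ≥ 1° apart so every programmed saccade is parseable;
blinks zero the pupil for 100 ms inside long fixations while position is
held (no spurious velocity at dropout edges). The generator does not model
the saccadic main sequence beyond threshold compliance, smooth pursuit,
or tracker noise with heavy tails — parser accuracy numbers on synthetic
gaze are therefore upper bounds for real recordings.

## Eye-event parsing

Velocity and acceleration are estimated by central differences after a
3-sample median filter (the tracker literature rarely states the
differentiation scheme; the median filter suppresses single-sample
dropouts that would otherwise fire the velocity threshold). A candidate
saccade is a run of samples above the 30°/s velocity threshold, extended
backward/forward along the monotone flank of the velocity profile down to
a 10°/s floor (plus one sample, since the ramp crosses the floor inside
the movement); it is accepted only if peak |acceleration| ≥ 8000°/s² *and*
total displacement ≥ 0.15°. Blinks are pupil-dropout runs padded by
±25 ms; everything else is fixation. The three kinds tile the record
exactly. Fixations shorter than 80 ms stay in the event list flagged
`excluded`. On synthetic sessions this parser recovers > 99% of programmed
saccades ≥ 1° with onset error ≤ 4 ms and zero false positives under
sub-threshold jitter.

ROI assignment takes the nearest of the trial's three circular ROIs
within 6°, with exact-distance ties broken by role priority (original
before updated/repeated before other) for determinism. Fixations within
500 ms of trial edges are flagged out of the analysis window (stimulus
onset/offset transients); the novelty contrast ignores this flag since it
targets early fixations.

## Preprocessing

All linear and zero-phase: bipolar referencing (anode − cathode per
adjacent contact pair, exclusion flags propagated), 4th-order Butterworth
band-stop applied forward-backward (default ±2 Hz around the line
frequency; harmonics optional), polyphase resampling with a zero-phase
anti-alias filter. Epochs span the analysis window plus a 1250 ms buffer
per side; the buffer rides through the wavelet transform and is trimmed
afterwards, so convolution edges never touch analyzed samples. Onsets
whose buffered window leaves the recording are dropped and logged.

## Spectral estimation

The Morlet transform correlates each epoch with complex wavelets
`exp(2πift)·exp(−t²/2σ_t²)`, `σ_t = n_cycles/(2πf)` with wave number
(`n_cycles`) 5, support ±3σ_t capped at the epoch length, amplitude
normalization (a unit cosine yields |W| ≈ 1). Two details matter:

- the wavelet is corrected to exactly zero mean. At high center
  frequencies the kernel is short and coarsely sampled; an uncorrected
  residual DC sum copies low-frequency signal into the high-frequency
  amplitude envelope and manufactures phase-amplitude coupling out of
  nothing (we measured MI_Z ≈ +1 to +2.4 at 160–200 Hz in pure 1/f noise
  before the correction, ≈ 0 after);
- phase convention: 0 at a waveform peak, ±π at a trough, increasing in
  time — the convention all phase-locking and coupling code assumes.

The default frequency grid is 30 geometrically spaced frequencies from 1
to 10 Hz inclusive. Multitaper PSDs use DPSS tapers at time-bandwidth 2
(three tapers on ~1 s epochs) via mne.

**Spectral model.** In (log10 f, log10 P) space, the aperiodic component
is a line fit robustly: ordinary least squares, then iterated refits on
points whose positive residual is below one residual SD, so oscillatory
peaks do not drag the exponent. Gaussian peaks (over linear frequency, in
log power) are then fit greedily to the residual, each kept only if it
lowers the residual sum of squares — which guarantees the model-comparison
statistic `F = RSS_aperiodic / RSS_full ≥ 1`. Exponent recovery on
synthetic 1/f spectra is within ±0.1 for χ ∈ [1.5, 2.5].

**Oscillation presence.** Each fixation epoch contributes two versions
of its multitaper log-spectrum: the raw spectrum, and a noise-matched
surrogate built by circularly shifting the epoch's residual (about its
robust aperiodic fit) across frequency after per-frequency
standardization. Both versions get the same deterministic fit — the
aperiodic line plus the best non-negative Gaussian from a fixed
center × width bank around the band — and contribute band residual sums
of squares about the aperiodic-only and the full model. The observed
statistic pools across fixations, `F = Σᵢ RSS_ap,i / Σᵢ RSS_full,i`,
over the raw versions; the null re-pools after randomizing which version
each fixation contributes (a paired label exchange; default 10,000
permutations, each a cheap dot product over precomputed per-epoch pairs).

Getting this null exchangeable took three measured corrections, each
worth recording because each wrong variant *looked* plausible: (i) using
the noiseless aperiodic reconstruction as the exchanged version (false
positives ≈ 11% at α = 0.05 — the surrogate must carry the raw
spectrum's noise); (ii) letting temporally overlapping epochs flip
independently (their spectra share noise; overlapping epochs are grouped
and flip together, with a common shift); (iii) ignoring that raw
residuals are line-fit residuals, hence nearly orthogonal to {1, log f},
while shifted residuals are not — both versions are projected onto the
line-orthocomplement before entering the statistic. With all three in
place the measured false-positive rate is ≈ 4.5–5.5% at α = 0.05 (pure
1/f epochs, overlapping or not), with ~100% detection at theta SNR 2 and
40 epochs. How per-fixation spectra aggregate into an electrode-level
test is not uniquely determined by the model-comparison idea; the pooled
residual-variance ratio is this package's choice.

## Phase-locking statistics

ITC is the mean resultant length of the unit phasors across events. Its
null expectation is `√π/(2√N)` (≈ 0.089 at N = 100), so unequal event
counts bias any ITC comparison; contrasts therefore subsample the larger
condition to the smaller N (averaging over `n_draws` draws, default 100
for standalone use).

Circular means get dispersion-based 95% CIs (circular standard error
`√(δ/n)`, `δ = (1−ρ₂)/(2R²)`); when the sample is nearly uniform
(R < 0.1) a bootstrap CI replaces the unstable formula, and at R ≈ 0 the
CI is flagged undefined. Rayleigh tests go through pingouin. The
Watson–Williams F compares two circular means; significance comes from
shuffling group labels (default 1000 permutations), reported both as the
exceedance p and as `Z_F = (F_obs − mean(F_null))/sd(F_null)`.

**ERP phase reset.** A reset realigns ongoing oscillations to the
fixation, so the across-event average gains post-event oscillatory power.
Pre- (−750 to 50 ms) and post-fixation (−50 to 750 ms) multitaper spectra
of the ERP are contrasted per frequency (log ratio); the null rebuilds the
ERP after circularly shifting each epoch by a random lag — preserving
spectral content, destroying alignment — and the contrast is
cluster-corrected over frequency.

## Phase-amplitude coupling

`MI = D_KL(P, U)/log N` with N = 20 bins of 18°; P is the normalized
mean-amplitude-per-bin distribution, empty bins contribute zero
(0·log 0 = 0). MI is 0 iff P is uniform, 1 when all amplitude sits in one
bin, and exactly scale-invariant.

`MI_Z` standardizes the concatenated-epoch MI against surrogates that
re-pair each amplitude epoch with the phase series of a randomly permuted
epoch (default 1000 surrogates, sd per frequency pair). The surrogate
gather is vectorized: per phase frequency, a one-hot phase-bin tensor is
contracted with the amplitude matrix once, after which every surrogate
pairing is an indexing operation. Under no coupling the measured
calibration is mean(MI_Z) ≈ 0.04, sd ≈ 1.0, |MI_Z| > 1.96 in ≈ 5% of
cells; MI grows strictly with programmed coupling depth over
{0, 0.3, 0.6, 0.9}.

Trial-level MI_Z (for the waveform regressions) pairs each epoch's own
phase and band-averaged gamma amplitude, with surrogates substituting
other epochs' phase series; condition-level MI_Z concatenates epochs.
Both granularities are exposed.

**Waveform confounds.** Non-sinusoidal theta can masquerade as coupling.
Per epoch, the 1–10 Hz band-passed signal (4th-order Butterworth,
zero-phase) yields analytic amplitude/phase via Hilbert transform, peak
and trough sharpness (mean absolute amplitude change 2 ms — one sample at
500 Hz — before and after each extremum), and rise/decay asymmetry.
"Asymmetry" has no standard definition; here it is the log ratio of mean
trough→peak rise time to mean peak→trough decay time, signed so a
slow-rise/fast-fall wave is positive. Event phases enter regressions as
sine and cosine of the deviation from the condition's circular mean
phase. One OLS regression per feature set (Power, Sin, Cos, S_peak,
S_trough, Asym, Full) is reported with its F test; the adjusted coupling
measure is the Full-model residual, which is exactly orthogonal to every
retained regressor. Constant or non-finite columns are dropped with a
warning. Under feature-independent MI_Z each feature test is significant
at the nominal ~5% rate.

## Cluster permutation inference

The per-bin statistic is the across-subject mean condition difference
(or ITC difference) over a time–frequency, time, frequency, or
comodulogram grid. Permutations exchange condition labels of individual
events *within* each subject, never across subjects; when condition is a
property of a coarser unit than the event — the trial a fixation belongs
to — labels are shuffled across whole trials instead, keeping each
trial's events together. This matters because fixation epochs within a
trial overlap in time: event-level shuffling of trial-level conditions
breaks that dependence under the null and produced measured false-flag
rates far above nominal (e.g. coupling contrasts flagged in 6/10 null
sessions) before trial blocking; after it, rates are nominal.

For ITC statistics both conditions are additionally subsampled to a
common N — in the observed statistic and in every permutation, with equal
draw counts (default 3) so observed and null stay exchangeable. Without
this, a count imbalance between conditions shifts the whole observed map
by the ITC bias difference and the test rejects under the null almost
always.

Each bin gets its own cluster-forming threshold from the permutation null
(95th percentile one-tailed; 2.5th/97.5th two-tailed); supra-threshold
bins form clusters by 4-connectivity (adjacency in 1-D); cluster mass is
the summed statistic; `p_FWE = (1 + #{null max-mass ≥ mass})/(n_perm+1)`,
never below `1/(n_perm+1)`. Measured FWE under an exchangeable null
(5 subjects × 2 conditions, 100 events each): 3–5% rejections; an
injected ITC difference of 0.2 over 4–6 Hz × 100–300 ms is found with
≥ 80% cluster overlap in ~100% of runs.

Electrode-proportion summaries use the exact upper-tail binomial
probability at chance rate p₀ = 0.05 (Bonferroni multipliers are the
caller's). Effect sizes are Hedges' g for dependent samples,
`g = J · mean(d)/sd(d)`, `J = 1 − 3/(4(n−1)−1)`; all-zero differences give
g = 0, constant nonzero differences are flagged undefined.

## Pipeline and report

`run_session_report` parses gaze, labels fixations, and runs the contrast
battery — retrieval (original vs. updated location fixations on Mismatch
trials; ITC + phase angle), associative novelty (updated-on-Mismatch vs.
repeated-on-Match, restricted to later-remembered trials; ITC + coupling
in the post-fixation −50 to 750 ms window), and subsequent memory
(original-location fixations by memory outcome; ITC). Every p in the
report carries its permutation count and seed, event accounting satisfies
`events_in = analyzed + Σ excluded-by-reason`, and the whole report is a
deterministic function of the inputs and the seed. Session-level flags
apply Bonferroni correction across the battery's measures (each already
FWE-corrected within its own search space), controlling the probability
of any false flag per report at α.

Coupling-contrast inference permutes class labels (trial-blocked where
applicable) on matched-N modulation-index maps, which is affordable
because per-epoch phase-binned amplitude sums are precomputed once;
surrogate-normalized MI_Z maps per class are optional descriptive output.
Band comparisons (low-theta 1–3, theta 4–6, fast theta/alpha 7–10 Hz)
cluster-test differences of band-maximum MI over amplitude frequencies
against phase-permutation surrogates shared across bands, so identical
bands give exactly zero difference.

## Validation scales and what they show

The acceptance suite (`tests/test_acceptance.py`) and
`scripts/acceptance.py` run everything at desk scale on one CPU: Monte
Carlo batteries of 20–1000 runs per property, sessions of 60–400 s,
permutation counts of 400–2000. The end-to-end check builds 20 seeded
effect sessions (peak-locked original fixations κ = 8, trough-locked
updated fixations κ = 1.2, Mismatch-only coupling depth 0.75) plus 20
matched no-effect sessions, and requires the four programmed effects
flagged and the null session clean in ≥ 95% of runs; because that claim
is a conjunction of four tests and a null session, the report is run at a
session-level α of 0.02. With per-measure false-flag rates at their
nominal ~0.4% and effect p-values at the permutation floor, the expected
pass rate per run is ≈ 98%; over 20 runs the binomial check still fails
occasionally by construction — a run with 19/20 passes.

Passing these tests demonstrates internal statistical correctness —
calibration, bias removal, recovery of programmed effects — on signals
matching the generator's assumptions (stationary 1/f background, a single
narrowband theta, one coupled gamma carrier, clean trial structure). It
does not demonstrate robustness to epileptiform artifacts, electrode
drift, tracker loss, multiple oscillators, or non-stationary coupling,
none of which the generator emulates.
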