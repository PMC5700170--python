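# Methods

This note documents the statistical model behind `syncnet`, the synthetic
cohort generator that serves as its test bed, the numerical choices made
where the procedure left room, and the limitations of both.

## The phase-locking difference statistic

For an electrode pair (p, q), frequency f, and time window t, let
φ_p − φ_q be the across-trial distribution of phase differences (phases
from complex Morlet wavelets, wave number 5; phase differences averaged
within each window by the circular mean — the angle of the mean unit
phasor). The mean resultant vector length

    R̄ = | (1/n) Σ_k exp(i(φ_p − φ_q)_k) |

(the phase-locking value, PLV) measures how concentrated that distribution
is: 1 for a perfectly consistent phase relation, 0 for a uniform one. The
statistic of interest is the condition difference

    D_pq(f, t) = R̄_rem − R̄_nrem,

positive when phase locking is stronger on trials whose word was later
recalled (or, in the retrieval contrast, in pre-vocalization windows vs.
unsuccessful-search windows).

R̄ is biased upward for smaller samples, and remembered trials are usually
the minority. Significance therefore comes from a permutation null: the
trial labels are shuffled 500 times, preserving the group sizes so every
null replicate carries the same sample-size bias, and

    z = (D_true − mean(null)) / sd(null)      (sd with n−1).

Within a subject the same 500 shuffles are applied to every electrode pair
(and to the power-SME statistics), so null replicate r is a coherent "null
network" and any functional applied to the true network can be applied to
each null network identically. Degenerate cells (null sd = 0, possible only
for pathological inputs such as constant phase differences) are flagged and
assigned z = 0.

### Hierarchical pooling

Electrode-pair statistics are pooled to a 74-label ROI vocabulary (37
Talairach-style labels per hemisphere; the packaged default list is a
standard gyrus-level vocabulary and is configurable): D_true is averaged
across all electrode pairs spanning an ROI pair within a subject, the null
distributions are averaged replicate-by-replicate, and both are then
averaged across subjects. The z-score of the pooled true value against the
pooled null is the connection weight. ROI pairs sampled by fewer than 7
subjects are zeroed (configurable). No z threshold is applied before
network statistics.

Band-level networks average true and null D over the band's grid
frequencies (theta 3–8 Hz, 6 wavelets; high gamma 45–100 Hz, 11 wavelets
with 5 Hz spacing except 90→100) and over the eight 200 ms item-presentation
windows (0–1600 ms of the 18-window −1000..2600 ms grid), and re-derive z —
note that the z of an average is not the average of z's, because averaging
rescales the null.

### Network statistics

* **Summed weights**: Σ of positive (or negative) connection weights,
  compared with the same functional on each null network; P by the
  plus-one rank rule P = (1 + #{null ≥ true})/(1 + n_perm), tail by sign.
* **Hubs**: node strength k_i = Σ_j w_ij restricted to positive or negative
  weights; per-ROI P from the null strength distribution, then
  Benjamini–Hochberg across ROIs (positive and negative families corrected
  separately, α = 0.05 by default).
* **Timecourses**: frequency-averaged node strength per 200 ms window vs.
  its null; smoothing is a plotting concern and never enters statistics.

## Power subsequent-memory effect and power–synchrony coupling

Log wavelet power is z-scored per channel and frequency across all samples
of a session, averaged into the same windows, and contrasted between
conditions with Welch's unequal-variance t per (electrode, frequency,
window). The 500 label shuffles yield null t's, pooled exactly like the
synchrony statistics (electrode mean within ROI, then subject mean, then
z).

Power–synchrony coupling is assessed two ways:

* per ROI, the Pearson correlation between the z-scored power map and the
  z-scored node-strength map across high-gamma time–frequency pixels of the
  item-presentation interval, BH-corrected across ROIs;
* across the brain, band-averaged power and strength flattened over
  (ROI × window) — ROI-major, window-minor; ten windows, −200 to 1800 ms —
  and correlated, with significance from a cyclic-shift null: the strength
  vector is rotated against the fixed power vector through all N−1 shifts
  plus all N shifts of its mirror image (2N−1 replicates), preserving the
  spatial and temporal autocorrelation of both maps. Two-tailed comparison
  on |r|.

The "core memory network" split takes the sampled ROIs with no significant
band/time-averaged high-gamma power SME (two-tailed permutation P ≥ 0.05)
as out-of-network and matches them against the equally many significant
ROIs with the largest |z| (ties broken lexicographically; unequal counts
truncated to the smaller side).

## Oscillation detection (BOSC / P_episode)

A channel's background spectrum is a robust linear fit (IRLS, Tukey
bisquare) of log mean wavelet power vs. log frequency, so narrowband peaks
are downweighted. At each frequency the power threshold is the 95th
percentile of the χ²(2) distribution scaled to the fitted mean power, and a
sample counts as oscillatory only within a supra-threshold run lasting at
least three cycles (3f⁻¹ s). P_episode is the flagged fraction of each
200 ms window. The oscillatory SME is a Welch t per pixel on an 18-pixel
log grid, 30–58 Hz, BH-corrected per electrode at the deliberately liberal
α = 0.1; electrodes with any surviving pixel form the oscillatory subset,
whose pairwise synchrony is pooled with the same machinery but no
minimum-subject mask, in the 400–600 ms window, at 50–55 Hz and 65–85 Hz
grid frequencies.

## The synthetic cohort generator

Each subject's recording is a sum of:

* 1/f background (spectrally shaped white noise, power exponent 2) plus a
  white measurement-noise floor (default 0.3 of the background RMS) — real
  recordings never have a noise-free high-frequency band, and without the
  floor any injected gamma component would have unbounded SNR;
* 60 Hz line noise with per-contact phase;
* per-trial condition-dependent components, injected into the first contact
  of each two-contact lead so the bipolar derivation retains them:
  coupling edges (a shared sinusoid per edge; the phase offset between the
  two ROIs drawn per trial from von Mises(lag, κ_cond), giving a
  closed-form handle — the expected measured PLV approaches I₁(κ)/I₀(κ)
  as the sinusoid dominates the band), band-limited power effects
  (RMS = amplitude × gain_cond during 0–1600 ms), and Hann-windowed
  narrowband bursts with per-trial occurrence probability p_cond,
  optionally phase-locked across ROIs.

Trial structure follows the free-recall task: 1600 ms word presentations,
750–1000 ms uniform ISI, per-word Bernoulli recall flags, and per-list 30 s
recall periods with vocalization onsets spaced 3 s apart and a silent tail
≥ 2.5 s. Retrieval-condition effects are injected into the 500 ms windows
before vocalizations (remembered-condition parameters) and into the
unsuccessful-search tiles (not-remembered parameters); the generator calls
the same search-window tiling function the preprocessor uses, so injected
and extracted windows coincide by construction.

### Canned study conditions

`syncnet.studies` fixes the conditions under which the package's
statistical properties are established (shared by the test-suite and
`scripts/acceptance.py`):

* **No-effect calibration cohort** — 8 subjects, 204 trials, 6 ROIs; three
  disjoint ROI pairs carry *equal* condition concentrations
  (κ_rem = κ_nrem = 1.5) at 4, 6, and 8 Hz across the whole epoch. Labels
  are exchangeable by construction, so the edge z-test must be calibrated.
  The concentration level matters for the *shape* of the D null: with
  uniform phase differences D is visibly short-tailed (|z| > 1.96 in
  ~3.3 % of cells instead of 5 %), while moderate common concentration puts
  the statistic in its near-normal regime (~5–6 %). Both regimes are
  conservative, never anticonservative.
* **Theta-pair recovery** — one edge (L hippocampus, L middle frontal,
  κ 8 vs 0.5 at 6 Hz).
* **Cross-band recovery** — 12 ROIs; six non-contiguously indexed "memory"
  ROIs receive high-gamma power gains of graded size (1.5–2.5), high-gamma
  *de*coupling (κ 0.5 vs 8 at 70 Hz) and theta coupling (κ 8 vs 0.5) on a
  ring of edges among them. The gain gradation breaks the cyclic-shift
  symmetry so the power–synchrony correlation has a unique alignment.
* **Burst cohort** — phase-locked 52 Hz bursts (16 cycles, p 0.6 vs 0.1,
  onset in 350–650 ms) between two ROIs, amplitude 2.5. The amplitude
  regime matters physically: a 5-cycle Morlet at 65 Hz has ~13 Hz
  half-bandwidth, so a detectable time-aligned 52 Hz burst unavoidably
  leaks *partial* phase locking into 65–85 Hz; the chosen amplitude keeps
  the 52 Hz band detectable while the leaked 65–85 Hz locking stays below
  the significance level. The band contrast is graded, not absolute.
* **Retrieval cohort** — the theta edge plus recall periods, analyzed with
  two 250 ms windows per 500 ms epoch.

Problem sizes (8 subjects, ~100–200 trials, 3–12 bipolar channels) are the
package's test-bed scale; all pooling machinery is size-agnostic.

### What the generator does not emulate

No biophysical neural-mass dynamics, no epileptiform or movement
artifacts, no volume conduction or shared-reference leakage beyond the
common coupling driver, no electrode-position uncertainty, and no
behavioral recall dynamics (vocalization times are placed, not modeled).
Passing recovery tests therefore show the *estimator chain* is correct and
calibrated — not that real iEEG effects of this size exist.

## Numerical choices

* Wavelet transform via MNE (`tfr_array_morlet`, zero-mean wavelets),
  computed per channel to bound memory; phases stored as unit phasors in
  complex64. Encoding epochs carry 1000 ms buffers, retrieval epochs
  1500 ms (a 5-cycle 3 Hz wavelet is ~2.65 s long), clipped after
  convolution.
* log(0) guarded by flooring power at 1e−30 before the log; zero wavelet
  coefficients get phasor 1+0j (stable, arbitrary).
* Notch: Butterworth band-stop 59–61 Hz of order 4, applied
  forward–backward (zero phase, a necessity for a phase-based analysis).
  Resampling via polyphase filtering with the exact rational rate ratio.
* Bipolar pairs inherit the ROI of their contacts; pairs whose contacts
  disagree are dropped and logged.
* Permutation P-values use the plus-one rule; BH via statsmodels.
  Unbiased (n−1) sd everywhere a null sd is taken.
* The cyclic-shift null is computed by FFT circular cross-correlation;
  P ∈ [1/(2N), 1] with null size exactly 2N−1.
* Determinism: every random draw descends from `SeedSequence([seed, k])`
  with a fixed stage offset k (generator subjects k = subject index;
  analysis shuffles k = 1000 + subject; subnetwork shuffles k = 2000 +
  subject), so identical configurations reproduce byte-identical outputs.

## Known limitations

* The |z| > 1.96 type-I rate of the edge test depends on the concentration
  regime of the phase-difference distributions (short-tailed null under
  uniform phases); it is conservative, never inflated, in all regimes
  tested.
* Adjacent encoding epochs overlap in the continuous recording (trial
  spacing ~2.4 s vs. a 5.6 s buffered epoch), as in the original task
  timing; exchangeability of the label shuffle is unaffected.
* With wave number 5 the frequency resolution at gamma is coarse
  (±f/5 half-bandwidth): neighboring grid frequencies are strongly
  correlated, and narrowband effects bleed across a band — a property of
  the measurement, not a bug of the implementation.
* The 74-label vocabulary ships as a default; analyses are valid for any
  label set with the L-/R- prefix convention.
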