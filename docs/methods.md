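# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the `spectrolaminar` toolkit.

## The spectrolaminar motif and what the toolkit measures

Across cortical areas, the depth profile of LFP power follows a stereotyped
pattern: gamma-band power (50–150 Hz) is strongest in superficial layers
(peaking in layers 2/3), alpha-beta power (10–30 Hz) is strongest in deep
layers (peaking in layers 5/6), and the two relative-power profiles cross
near layer 4. The toolkit turns a multi-channel, multi-trial laminar LFP
recording into a **relative power map**

    RelativePower(c, f) = Power(c, f) / max_c' Power(c', f),

a channels × frequency image in [0, 1] in which the depth of peak power is
visible at every frequency, and extracts laminar landmarks from it.

## Spectral estimation

Power spectra are multitaper estimates (DPSS tapers) computed per trial on
the analysis window and averaged across trials. The spectral half-bandwidth
defaults to 2 Hz; on the standard 1-s window (−500 to +500 ms around
stimulus onset; the full trial when no onsets exist) this is a
time-bandwidth product of 2, i.e. 3 tapers. Spectra are reported on 1-Hz
bins from 1 to 150 Hz; the DC bin is excluded because the recordings the
pipeline targets are AC-coupled. A window too short to populate the
requested bins raises a resolution error rather than silently extrapolating.

Channels whose mean power across 1–150 Hz exceeds the across-channel mean
by more than two standard deviations (population statistics, outliers
included) are replaced by the average of their nearest clean neighbors,
once, before normalization. Note that under this rule at most 20 % of
channels can ever be flagged (Cantelli's inequality), so the additional
"more than half the probe is bad" rejection guard is defensive only.

Depth standardization resamples the channel axis by piecewise-linear
interpolation onto 24 depths spanning the recorded span (no extrapolation),
which puts probes with different contact counts and spacings on a common
grid scaled to cortical thickness. Relative maps are re-normalized per
frequency column afterwards so the max-1 invariant survives interpolation.

## FLIP

FLIP scores a contiguous channel range D_i..D_f by fitting straight lines
to the alpha-beta (10–19 Hz) and gamma (75–150 Hz) band-depth profiles —
computed after re-normalizing each frequency column by its maximum *within
the range* — and combining them into

    G = s_αβ · R²_αβ · R²_γ · f    if the two slopes oppose, else G = 0,
    f = 0.04 · (D_f − D_i) + 0.72,

where s_αβ is the sign of the alpha-beta slope and R² the regression
coefficients. Two points about this formula are deliberate design choices:

* **G is zero for same-sign slopes.** The score quantifies *opposing*
  laminar gradients; a probe whose two band profiles rise together carries
  no crossover information, yet both regressions can have R² ≈ 1 (for
  instance when the two bands sample one monotone gradient). Assigning
  such fits a large score would let them win the search while meaning
  nothing.
* **The sign of G is the sign of the alpha-beta slope.** On a
  superficial→deep axis the canonical motif has rising alpha-beta and
  falling gamma, so G > 0; a negative G means the pattern is inverted,
  i.e. the probe entered the cortical sheet from deep to superficial.
  (A sign convention based on the *product* of the two slope signs cannot
  distinguish upright from inverted, since both are opposing patterns.)

The search enumerates every range spanning at least 7 channel steps
(700 µm at 100-µm spacing) on the 24-channel standardized grid and keeps
the fit with the largest |G|; ties break toward the larger span, then the
more superficial D_i. A probe is **identifiable** when both slope p-values
(two-sided t-test on the OLS slope, α = 0.05) are significant and
|G| > G_t = 0.265.

Landmarks are extracted only for identifiable probes (inverted probes are
mirrored into canonical orientation first, and the landmark channels
mirrored back):

* **Crossover (layer 4):** among the channels inside the winning range
  where sign(P_γ − P_αβ) changes, the one maximizing
  ΔP = Σ_superficial (P_γ − P_αβ) + Σ_deep (P_αβ − P_γ), which is positive
  for the canonical pattern. Crossovers are reported at channel
  resolution; no sub-channel interpolation.
* **Gamma peak (layers 2/3) and alpha-beta peak (layers 5/6):** the local
  maxima of the full-probe band profiles nearest the superficial (D_i) and
  deep (D_f) range limits respectively, inside or outside the range.
  Plateaus collapse to their center channel; a peak that falls on a probe
  boundary of a monotone profile is returned with a boundary flag.

## vFLIP

vFLIP repeats the FLIP core over all frequency-band pairs on a 10-Hz grid
satisfying: low-band upper bound ≤ 70 Hz and below the high-band lower
bound; high-band lower bound above 30 Hz; high-band upper bound fixed at
150 Hz. The pair (plus depth range) with the largest |G| wins, with
opposing-slope fits preferred over same-sign fits for the same reason as
above. The low-band grid starts at 10 Hz by default (configurable); the
frequency axis must reach 150 Hz.

## Current source density

CSD is the standard second spatial difference with the skip-one stencil,

    CSD(c, t) = −σ (V(c−2, t) − 2 V(c, t) + V(c+2, t)) / (2s)²,

with s the contact spacing (µm) and σ the tissue conductivity (default 1,
leaving CSD in relative units — the normalization removes absolute scale
anyway). The two outermost channels on each side are undefined and
reported as NaN rather than padded; padding would fabricate sinks at the
boundaries. Normalization subtracts, per channel, the mean CSD over a
−200..0 ms pre-stimulus baseline and divides by the across-trial s.e.m. at
each channel-time point, yielding z-score-like units; zero-variance points
are flagged, not returned infinite.

`detect_early_sink` scans 0–150 ms post-stimulus for the earliest run of at
least 10 ms during which a valid channel stays below z = −2. Because
ongoing 1/f-dominated background makes the z-map temporally autocorrelated,
the raw threshold alone cannot control false positives — baseline
excursions below −2 can persist for tens of milliseconds. The detector
therefore self-calibrates: the effective threshold is the minimum of the
nominal one and the deepest z observed anywhere in the pre-stimulus
baseline, so an event counts only if it is deeper than anything the same
statistical process produced before the stimulus. The search window,
threshold and persistence are package defaults, not literature values; the
landmark they produce (the input-layer sink) was classically identified by
eye.

## Image similarity

Two standardized relative power maps are compared with the structural
similarity index (SSIM) with the data range pinned to 1.0 (maps are
max-normalized) and standard window/constants (7×7 uniform window). Raw
SSIM lives in [−1, 1]; negative values (anticorrelated structure) are
floored at 0, the "completely dissimilar" end of the IS scale.

Group comparisons use the randomized subgrouping procedure: each group of
probes is randomly halved (odd groups drop one probe at random, seeded);
the IS between a group's two half-averages is a within-group value, the
four cross-pairings of half-averages are between-group values; five
repetitions give 5 within values per group and 20 between values, whose
means are the grand within/between IS. Maps are aligned by their crossover
channel before averaging, shifting rows without wraparound and replicating
edge rows into vacated positions so shapes stay equal.

One subtlety: comparing a group against a *literal copy* of itself makes
between-group half-averages overlap ~50 % in probes while within-group
halves are disjoint, so between-IS systematically exceeds within-IS. The
exchangeability check therefore uses two *independent* populations drawn
with identical parameters, for which within ≈ between genuinely holds.

The channel-shuffle null permutes map rows and reruns FLIP (or vFLIP);
the drop from unshuffled to shuffled identifiability measures how much of
the identification rests on genuine laminar ordering.

## Synthetic laminar LFP

The generator is phenomenological: it reproduces the statistics the
analyses consume, not the biophysics that produce them. Each channel
receives:

* **Shared 1/f^χ background** (χ = 2), one trace per trial common to all
  channels with a mild affine depth gain (superficial end 15 % higher in
  amplitude than the deep end). Sharing mimics volume conduction — and is
  what lets the CSD stencil cancel the background, exactly as on a real
  probe, since affine depth profiles are annihilated by the second
  difference. The depth gain exists because real maps are not flat in
  relative power at non-oscillatory frequencies; a depth-constant
  background would make vFLIP's low-band boundary unidentifiable.
* **Per-channel white sensor noise** (0.3 µV RMS), the uncorrelated
  thermal/electrode component that survives the CSD derivative.
* **Two band-limited oscillations** — 4th-order Butterworth-filtered
  Gaussian noise (zero-phase), coherent across channels — whose power
  follows opposing unimodal depth profiles: gamma (50–150 Hz) peaks at
  depth fraction 0.2 and falls toward both the pial surface (edge level
  0.35) and the depths (trough 1/contrast); the low band (10–30 Hz)
  mirrors it, peaking at 0.8. Between the peaks the profiles are opposing
  ramps through the mid level at the crossover depth. Unimodality matters:
  exactly mirrored full-range ramps would make the two band profiles
  affine functions of each other, so *any* channel permutation would
  produce "opposing" windows and the shuffle null would be grossly
  inflated — a degenerate coupling real recordings do not show. A 5 %
  independent per-channel band-power heterogeneity breaks the residual
  coupling.
* **Optionally a stimulus-evoked dipole** constructed directly in CSD
  space (a Gaussian sink flanked by two sources, peak |CSD| = amplitude)
  and integrated twice along each even/odd channel chain to voltage, so
  the planted sink is exact under the stencil. The time course is a
  sin² pulse (default 40-ms latency, 30-ms duration) with 10 %
  multiplicative trial-to-trial jitter.

**Ground truth.** The recorded crossover truth is *not* the nominal planted
depth: the background adds depth-structured power that shifts the actual
crossing of the relative band profiles. The generator therefore computes
the expected per-bin PSD of its own output analytically (filter |H|⁴
responses, background spectrum with depth gain, sensor noise, the
pipeline's ±2 Hz smoothing window) and records the crossing of the
expected relative band profiles nearest the nominal depth — the value an
infinite-trial run of the same pipeline would converge to.

**Defaults and calibration.** 24 channels at 100 µm, 1 kHz, 1-s trials,
50 trials (≈50 s of data — the regime in which landmark localization
reaches about one interpolated channel, ~100 µm), gradient contrast 5,
SNR 1.5 (peak oscillation RMS relative to unit background RMS). These were
calibrated once, jointly, against the package's stated operating targets —
default populations ~100 % FLIP-identifiable, crossover recovered within
one interpolated channel in ≥95 % of probes, channel-shuffle
identifiability far below threshold (~0.12), flat-gradient probes almost
never identifiable — and then frozen. Populations jitter crossover depth
(±0.1), contrast (±20 %) and SNR (±20 %) per probe.

**What the generator does not emulate.** No biophysics (no compartmental
neurons or conductances), no spiking contamination of the gamma band, no
delta-theta rhythm, no probe drift, no non-stationarity across trials, no
spatially heterogeneous conductivity, and oscillations are perfectly
coherent across channels rather than falling off with distance. Passing
tests therefore demonstrate that the algorithms recover what was planted
under realistic noise statistics — not that they are robust to every
pathology of in-vivo recordings.

## Duration robustness

Mirroring the signal-duration experiment: from one 250-s synthetic session,
random trial subsets of 1, 5, 25 and 200 s are drawn (3 per duration), the
crossover is re-estimated on each subset, and its absolute error against
the full-session estimate is averaged per probe, with the median taken
across 50 sessions. Error declines along the ladder and plateaus near zero
once the estimate stabilizes (estimates are integer channels, so exact
agreement with the reference is common from ~5 s on); the check is
therefore monotone non-increase plus a strict overall decrease — the shape
any consistent estimator's duration curve takes.

## Numerical notes

* OLS fits use closed-form sums; zero-variance profiles get R² = 0,
  p = 1 (non-significant) rather than NaN. Perfect fits (1 − R² below
  1e-12) get p = 0.
* Range-search ties break toward (larger span, more superficial D_i);
  crossover candidates at a sign change without an exact zero take the
  channel with the smaller |P_γ − P_αβ|.
* All randomness flows through `numpy.random.default_rng` from explicit
  seeds; population and repetition sub-seeds are drawn below 2³¹.
* Recordings ingest as channels × samples × trials; `deep_first` inputs
  are flipped to superficial-first and flagged; `unknown` order is left
  for FLIP's G sign to resolve.

## Known limitations

* The 10–19 Hz FLIP subband sees proportionally more 1/f background than
  the full 10–30 Hz alpha-beta band, biasing its crossover estimate
  ~0.1–0.3 interpolated channels superficial on synthetic spectra whose
  in-band power is flat. On real data the subbands were chosen because
  the gradients are steepest there, so the trade-off runs the other way.
* Landmarks are quantized to channels; sub-channel localization error is
  bounded below by ~0.3 channels regardless of data quantity.
* vFLIP's low-band boundaries are only weakly determined when the
  spectrum adjacent to the true band carries little depth structure; the
  upper boundary (adjacent to the planted gradient) is recovered much
  more sharply than the lower one.
* The IS group procedure assumes groups of at least 4 probes and drops
  one probe per repetition from odd-sized groups.
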