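"""Synthetic laminar LFP with a planted spectrolaminar motif.

The generator is phenomenological, not biophysical: each channel receives

* a 1/f^chi background (default chi = 2) that is shared across channels,
  as volume-conducted slow activity is, with a mild affine depth gain
  (low-frequency power is superficially dominant on real probes, and a
  depth-constant background would leave every non-oscillatory frequency
  column flat in relative power — an idealization that makes vFLIP band
  boundaries unidentifiable).  Affine depth profiles are annihilated
  exactly by the CSD stencil, so the spatial coherence that lets the CSD
  spatial derivative cancel the background on a real probe is preserved,
* independent per-channel white sensor noise (thermal/electrode noise),
* two band-limited stochastic oscillations — narrowband-filtered Gaussian
  noise, coherent across channels as volume-conducted rhythms are — whose
  amplitudes follow opposing piecewise-linear depth gradients: the
  high-frequency (gamma) band peaks superficially, the low-frequency
  (alpha-beta) band peaks deep, and their relative band power crosses at a
  configurable depth fraction,
* optionally a stimulus-locked evoked dipole constructed directly in CSD
  space and integrated twice to voltage, so the planted current sink is
  exact under the 5-point CSD stencil.

Band power gradients are specified as relative-power targets: with contrast
``C`` the gamma profile runs 1 -> 1/C from superficial to deep (piecewise
linear with its knee at the crossover depth) and the alpha-beta profile
mirrors it, so the planted crossover is exact by construction.  The
oscillation amplitude at the peak channel has RMS ``snr`` relative to the
unit-RMS background.

Defaults (24 channels at 100 um, 1 kHz, 1-s trials, 50 trials, contrast 5,
chi = 2, snr = 1.5) emulate a good-quality cortical probe recording of
about 50 s — the regime in which landmark localization reaches roughly
one interpolated channel (~100 um) of accuracy.  They were calibrated once
against the package's stated operating targets (near-complete
identifiability of default populations, sub-channel crossover recovery,
a channel-shuffle null well below the identifiability threshold) and are
frozen; single-trial estimates remain visibly noisy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.ndimage import uniform_filter1d

from .errors import ParameterError
from .lfp_io import LaminarRecording

__all__ = [
    "EvokedSpec",
    "SyntheticProbeSpec",
    "generate_probe",
    "generate_evoked",
    "generate_population",
]


@dataclass
class EvokedSpec:
    """Planted stimulus-evoked dipole parameters."""

    sink_depth_fraction: float = 0.5
    latency_ms: float = 40.0
    duration_ms: float = 30.0
    amplitude: float = 2e-4  # peak |CSD| in output units (sigma * uV / um^2)
    trial_jitter: float = 0.1  # multiplicative s.d. of per-trial amplitude


@dataclass
class SyntheticProbeSpec:
    """Ground-truth laminar parameters for one synthetic probe."""

    n_channels: int = 24
    channel_spacing_um: float = 100.0
    sampling_rate_hz: float = 1000.0
    trial_length_ms: float = 1000.0
    n_trials: int = 50
    crossover_depth: float = 0.5  # fraction of span, superficial -> deep
    gamma_band: tuple[float, float] = (50.0, 150.0)
    low_band: tuple[float, float] = (10.0, 30.0)
    gradient_contrast: float = 5.0  # peak-to-trough relative band power
    noise_exponent: float = 2.0  # 1/f^chi shared background
    background_depth_gain: float = 0.15  # superficial-minus-deep amplitude
    sensor_noise: float = 0.3  # per-channel white noise RMS (uV)
    band_heterogeneity: float = 0.05  # per-channel band-power jitter (s.d.)
    snr: float = 1.5  # peak oscillation RMS over background RMS
    orientation: str = "upright"  # upright | inverted
    evoked: EvokedSpec | None = None
    seed: int = 0

    def validate(self) -> None:
        nyq = self.sampling_rate_hz / 2
        for name, band in (("gamma_band", self.gamma_band),
                           ("low_band", self.low_band)):
            if not 0 < band[0] < band[1]:
                raise ParameterError(f"{name} bounds must satisfy 0 < lo < hi")
            if band[1] >= nyq:
                raise ParameterError(f"{name} exceeds Nyquist ({nyq:g} Hz)")
        if not (self.low_band[1] <= self.gamma_band[0]
                or self.gamma_band[1] <= self.low_band[0]):
            raise ParameterError("low_band and gamma_band must not overlap")
        if not 0 < self.crossover_depth < 1:
            raise ParameterError("crossover_depth must lie in (0, 1)")
        if self.gradient_contrast <= 1:
            raise ParameterError("gradient_contrast must be > 1")
        if self.orientation not in ("upright", "inverted"):
            raise ParameterError("orientation must be upright or inverted")
        if self.evoked is not None:
            total = self.evoked.latency_ms + self.evoked.duration_ms
            if total >= self.trial_length_ms / 2:
                raise ParameterError(
                    "evoked response must end before the trial does"
                )


# ---------------------------------------------------------------------------
# signal components
# ---------------------------------------------------------------------------


def _pink_noise(rng: np.random.Generator, n_samples: int,
                chi: float) -> np.ndarray:
    """Unit-RMS 1/f^chi noise trace."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-chi / 2.0)
    shaped = np.fft.irfft(spec * gain, n=n_samples)
    return shaped / shaped.std()


def _band_oscillation(rng: np.random.Generator, n_samples: int, fs: float,
                      band: tuple[float, float]) -> np.ndarray:
    """Unit-RMS narrowband noise (4th-order Butterworth, zero-phase)."""
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n_samples))
    return x / x.std()


_GAMMA_PEAK_DEPTH = 0.2  # fraction of span; ~layers 2/3
_ALPHABETA_PEAK_DEPTH = 0.8  # ~layers 5/6
_EDGE_FLOOR = 0.35  # band power at the pial / white-matter ends


def _gradient_profiles(spec: SyntheticProbeSpec
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Relative band-power targets per channel (gamma, low band).

    Unimodal piecewise-linear profiles, as on a real probe whose contacts
    extend into CSF above and white matter below the cortical sheet: gamma
    peaks in the superficial third and falls off toward both the pial
    surface and the depths; the low band mirrors it, peaking in the deep
    third.  Between the two peaks the profiles are opposing ramps through
    the mid level at the crossover depth, so the planted crossover is exact
    by construction.  (Exactly mirrored full-range ramps would make the two
    band profiles affine functions of each other — a degenerate coupling
    real recordings do not show.)
    """
    x = np.linspace(0.0, 1.0, spec.n_channels)
    x0 = spec.crossover_depth
    trough = 1.0 / spec.gradient_contrast
    mid = (1.0 + trough) / 2.0
    edge = max(_EDGE_FLOOR, trough)
    g_peak = min(_GAMMA_PEAK_DEPTH, x0 - 0.05)
    a_peak = max(_ALPHABETA_PEAK_DEPTH, x0 + 0.05)
    r_gamma = np.interp(x, [0.0, g_peak, x0, 1.0], [edge, 1.0, mid, trough])
    r_low = np.interp(x, [0.0, x0, a_peak, 1.0], [trough, mid, 1.0, edge])
    return r_gamma, r_low


def _background_gain(spec: SyntheticProbeSpec) -> np.ndarray:
    """Affine depth amplitude gain of the shared background (superficial
    end higher); exactly annihilated by the CSD second-difference."""
    d = spec.background_depth_gain
    return np.linspace(1.0 + d / 2.0, 1.0 - d / 2.0, spec.n_channels)


def _expected_band_profiles(spec: SyntheticProbeSpec, r_gamma: np.ndarray,
                            r_low: np.ndarray
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Expected relative band-power depth profiles of the emitted signal.

    The planted amplitude gradients alone do not determine the recording's
    crossover: the shared 1/f background and sensor noise add
    depth-constant power that dilutes each band's relative profile (most
    visibly at low frequencies, where the background is strong).  This
    computes the expected per-bin PSD from the generator's own components —
    oscillation bandpass responses (|H|^4 for the zero-phase filter),
    background spectrum, white sensor noise — and returns the expected
    relative power profiles averaged over each band, exactly as the
    spectral pipeline would measure them on infinite data.
    """
    ns = int(round(spec.trial_length_ms * spec.sampling_rate_hz / 1000.0))
    fs = spec.sampling_rate_hz
    freqs = np.fft.rfftfreq(ns, 1.0 / fs)
    pink = np.zeros_like(freqs)
    pink[1:] = freqs[1:] ** (-spec.noise_exponent)
    pink /= pink.sum()  # unit-RMS trace: variance fraction per bin
    white = np.full_like(freqs, spec.sensor_noise ** 2 / freqs.size)

    def osc_psd(band):
        sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
        _, h = signal.sosfreqz(sos, worN=freqs, fs=fs)
        p = np.abs(h) ** 4  # filtfilt: zero-phase, squared magnitude
        return p / p.sum()

    s_g = osc_psd(spec.gamma_band)
    s_l = osc_psd(spec.low_band)
    snr2 = spec.snr ** 2
    # channels x freq bins expected power
    power = (snr2 * np.outer(r_gamma, s_g) + snr2 * np.outer(r_low, s_l)
             + np.outer(_background_gain(spec) ** 2, pink) + white)
    # the measurement applies +-2 Hz multitaper smoothing; the expected
    # measured spectrum is the true spectrum seen through that window
    df = freqs[1] - freqs[0] if freqs.size > 1 else 1.0
    half_bw_bins = max(int(round(2.0 / df)), 0)
    if half_bw_bins:
        power = uniform_filter1d(power, size=2 * half_bw_bins + 1, axis=1,
                                 mode="nearest")
    rel = power / power.max(axis=0)
    out = []
    for band in (spec.gamma_band, spec.low_band):
        sel = (freqs >= band[0]) & (freqs <= band[1])
        out.append(rel[:, sel].mean(axis=1))
    return out[0], out[1]


def _planted_crossover(spec: SyntheticProbeSpec, r_gamma: np.ndarray,
                       r_low: np.ndarray, nominal: float) -> float:
    """Ground-truth crossover (fractional channel) of the emitted signal:
    the crossing of the expected relative band profiles nearest the nominal
    crossover depth.  Falls back to the nominal position when the profiles
    never cross (flat-gradient probes)."""
    prof_g, prof_l = _expected_band_profiles(spec, r_gamma, r_low)
    diff = prof_g / prof_g.max() - prof_l / prof_l.max()
    crossings = []
    for k in range(diff.size - 1):
        if diff[k] == 0.0:
            crossings.append(float(k))
        elif diff[k] * diff[k + 1] < 0:
            crossings.append(k + diff[k] / (diff[k] - diff[k + 1]))
    if diff[-1] == 0.0:
        crossings.append(float(diff.size - 1))
    if not crossings:
        return nominal
    return min(crossings, key=lambda c: abs(c - nominal))


def _evoked_voltage_profile(spec: SyntheticProbeSpec) -> tuple[np.ndarray, int]:
    """Voltage depth profile whose stencil-CSD is the planted dipole.

    The dipole is built in CSD space (a Gaussian sink flanked by two
    sources) and integrated twice along each even/odd channel chain, so
    ``compute_csd`` recovers it exactly at chain-interior channels.
    """
    ev = spec.evoked
    assert ev is not None
    n = spec.n_channels
    c0 = int(round(2 + ev.sink_depth_fraction * (n - 5)))  # stencil-valid
    c = np.arange(n, dtype=float)
    w = 1.2
    q = (-np.exp(-((c - c0) ** 2) / (2 * w ** 2))
         + 0.55 * np.exp(-((c - c0 - 4.0) ** 2) / (2 * w ** 2))
         + 0.55 * np.exp(-((c - c0 + 4.0) ** 2) / (2 * w ** 2)))
    q *= ev.amplitude / np.abs(q).max()

    s, sigma = spec.channel_spacing_um, 1.0
    target = q * (-((2 * s) ** 2) / sigma)  # per-chain second difference
    v = np.zeros(n)
    for parity in (0, 1):
        idx = np.arange(parity, n, 2)
        t = target[idx]
        m = idx.size
        chain = np.zeros(m)
        for k in range(1, m - 1):
            chain[k + 1] = t[k] + 2 * chain[k] - chain[k - 1]
        v[idx] = chain
    return v, c0


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_probe(spec: SyntheticProbeSpec
                   ) -> tuple[LaminarRecording, dict]:
    """Generate one trial-structured laminar recording plus ground truth.

    Trials are independent given distinct sub-seeds drawn from
    ``spec.seed``.  The ground-truth record carries the planted crossover
    (as a depth fraction, a channel on the generated axis and a channel on
    the standard 24-depth grid), the band definitions and the orientation.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_channels
    ns = int(round(spec.trial_length_ms * spec.sampling_rate_hz / 1000.0))
    r_gamma, r_low = _gradient_profiles(spec)
    # independent per-channel heterogeneity per band: real laminar rhythm
    # generators are not exact mirrors of each other, and a perfectly
    # anti-correlated pair would make any permuted window trivially
    # "opposing", distorting shuffle-null statistics
    h = spec.band_heterogeneity
    r_gamma = np.clip(r_gamma * (1 + h * rng.standard_normal(n)), 0.02, None)
    r_low = np.clip(r_low * (1 + h * rng.standard_normal(n)), 0.02, None)
    amp_gamma = spec.snr * np.sqrt(r_gamma)
    amp_low = spec.snr * np.sqrt(r_low)
    cross_channel = _planted_crossover(spec, r_gamma, r_low,
                                       spec.crossover_depth * (n - 1))

    evoked_profile = None
    sink_channel = None
    onset = ns // 2
    if spec.evoked is not None:
        evoked_profile, sink_channel = _evoked_voltage_profile(spec)
        t_ms = (np.arange(ns) - onset) * 1000.0 / spec.sampling_rate_hz
        ev = spec.evoked
        phase = (t_ms - ev.latency_ms) / ev.duration_ms
        wave = np.where((phase >= 0) & (phase <= 1),
                        np.sin(np.pi * np.clip(phase, 0, 1)) ** 2, 0.0)

    bg_gain = _background_gain(spec)
    voltage = np.empty((n, ns, spec.n_trials))
    for trial in range(spec.n_trials):
        shared = _pink_noise(rng, ns, spec.noise_exponent)
        x = bg_gain[:, np.newaxis] * shared
        x += spec.sensor_noise * rng.standard_normal((n, ns))
        osc_g = _band_oscillation(rng, ns, spec.sampling_rate_hz,
                                  spec.gamma_band)
        osc_l = _band_oscillation(rng, ns, spec.sampling_rate_hz,
                                  spec.low_band)
        x += amp_gamma[:, np.newaxis] * osc_g
        x += amp_low[:, np.newaxis] * osc_l
        if evoked_profile is not None:
            gain = max(0.0, 1.0 + spec.evoked.trial_jitter
                       * rng.standard_normal())
            x += gain * evoked_profile[:, np.newaxis] * wave
        voltage[:, :, trial] = x

    cross_interp = cross_channel * 23.0 / (n - 1)
    if spec.orientation == "inverted":
        voltage = voltage[::-1].copy()
        cross_channel = (n - 1) - cross_channel
        cross_interp = 23.0 - cross_interp
        if sink_channel is not None:
            sink_channel = (n - 1) - sink_channel

    rec = LaminarRecording(
        voltage=voltage,
        sampling_rate=spec.sampling_rate_hz,
        channel_spacing=spec.channel_spacing_um,
        channel_order="unknown",
        stimulus_onset=(np.full(spec.n_trials, onset)
                        if spec.evoked is not None else None),
        probe_id=f"synthetic-{spec.seed}",
    )
    truth = {
        "crossover_depth_fraction": spec.crossover_depth,
        "crossover_channel": cross_channel,
        "crossover_channel_interp24": cross_interp,
        "low_band_hz": list(spec.low_band),
        "gamma_band_hz": list(spec.gamma_band),
        "orientation": spec.orientation,
        "gradient_contrast": spec.gradient_contrast,
        "sink_channel": sink_channel,
        "sink_latency_ms": (spec.evoked.latency_ms
                            if spec.evoked is not None else None),
        "seed": spec.seed,
    }
    return rec, truth


def generate_evoked(spec: SyntheticProbeSpec) -> tuple[LaminarRecording, dict]:
    """Generate a recording with the evoked dipole planted (evoked set)."""
    if spec.evoked is None:
        spec = replace(spec, evoked=EvokedSpec())
    return generate_probe(spec)


def generate_population(n_probes: int,
                        seed: int | np.random.Generator = 0,
                        base: SyntheticProbeSpec | None = None,
                        crossover_jitter: float = 0.1,
                        contrast_jitter: float = 0.2,
                        snr_jitter: float = 0.2,
                        **overrides) -> list[tuple[LaminarRecording, dict]]:
    """Draw a population of probes with jittered laminar parameters.

    Crossover depth, gradient contrast and SNR are jittered uniformly
    around the base spec; keyword overrides (e.g. ``low_band=(30, 50)``)
    define parameter distributions for a whole "area", enabling two-area
    group-IS tests.  Reproducible from ``seed``.
    """
    if n_probes < 1:
        raise ParameterError("n_probes must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    base = base or SyntheticProbeSpec()
    if overrides:
        base = replace(base, **overrides)
    out = []
    for _ in range(n_probes):
        spec = replace(
            base,
            crossover_depth=float(np.clip(
                base.crossover_depth
                + rng.uniform(-crossover_jitter, crossover_jitter),
                0.15, 0.85)),
            gradient_contrast=float(max(1.2, base.gradient_contrast
                                        * (1 + rng.uniform(-contrast_jitter,
                                                           contrast_jitter)))),
            snr=float(max(0.05, base.snr
                          * (1 + rng.uniform(-snr_jitter, snr_jitter)))),
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        )
        out.append(generate_probe(spec))
    return out
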