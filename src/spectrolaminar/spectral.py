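"""Trial-wise multitaper LFP power, relative power maps and depth profiles.

The relative power map is the central object of the spectrolaminar analysis:
for each frequency bin, every channel's trial-averaged power is divided by
the power of the channel with the highest power at that frequency,

    RelativePower(c, f) = Power(c, f) / max_c' Power(c', f),

so a value of 1 marks the laminar location of peak power at each frequency.
Band-depth profiles average these relative values over a frequency band,
yielding the opposing alpha-beta (deep-peaking) and gamma
(superficial-peaking) gradients that FLIP fits.

Spectra are multitaper estimates (DPSS tapers) with a +-2 Hz default
spectral smoothing: on the standard 1-s analysis window this is a
time-bandwidth product of 2, i.e. 3 tapers.  Power is computed per trial and
averaged across trials.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal.windows import dpss

from .errors import (
    BoundsError,
    NormalizationError,
    ParameterError,
    QualityError,
    ResolutionError,
)
from .lfp_io import AnalysisConfig, LaminarRecording

__all__ = [
    "PowerMap",
    "RelativePowerMap",
    "BandProfile",
    "compute_power_map",
    "repair_bad_channels",
    "relative_power",
    "band_profile",
    "standardize_depth",
    "rebin_frequencies",
]


@dataclass
class PowerMap:
    """Trial-averaged power (uV^2/Hz) per channel x frequency bin."""

    power: np.ndarray  # (n_channels, n_freqs), >= 0
    freqs: np.ndarray  # Hz bin centers, strictly increasing
    n_trials_averaged: int = 1

    def __post_init__(self) -> None:
        self.power = np.atleast_2d(np.asarray(self.power, dtype=float))
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.power.shape[1] != self.freqs.size:
            raise ParameterError(
                f"power has {self.power.shape[1]} columns for "
                f"{self.freqs.size} frequency bins"
            )
        if np.any(np.diff(self.freqs) <= 0):
            raise ParameterError("freqs must be strictly increasing")
        if np.any(self.power < 0):
            raise ParameterError("power must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.power.shape[0]


@dataclass
class RelativePowerMap:
    """Per-frequency max-normalized power map; all values in [0, 1]."""

    rel_power: np.ndarray
    freqs: np.ndarray
    aligned_to: str = "none"  # none | crossover

    def __post_init__(self) -> None:
        self.rel_power = np.atleast_2d(np.asarray(self.rel_power, dtype=float))
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.rel_power.shape[1] != self.freqs.size:
            raise ParameterError("rel_power / freqs size mismatch")

    @property
    def n_channels(self) -> int:
        return self.rel_power.shape[0]


@dataclass
class BandProfile:
    """Mean relative power in a band as a function of laminar depth."""

    band: tuple[float, float]
    values: np.ndarray  # per channel, superficial -> deep
    depth_axis: np.ndarray  # channel indices

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.depth_axis = np.asarray(self.depth_axis)


# ---------------------------------------------------------------------------
# multitaper power
# ---------------------------------------------------------------------------


def _analysis_windows(rec: LaminarRecording, cfg: AnalysisConfig) -> np.ndarray:
    """Extract the per-trial analysis window, shape (nc, nwin, ntrials).

    With stimulus onsets the window is ``cfg.analysis_window`` (ms) around
    each onset; without onsets the whole trial is used.
    """
    v = rec.voltage
    if rec.stimulus_onset is None:
        return v
    fs = rec.sampling_rate
    i0 = int(round(cfg.analysis_window[0] * fs / 1000.0))
    i1 = int(round(cfg.analysis_window[1] * fs / 1000.0))
    nwin = i1 - i0
    if nwin < 2:
        raise BoundsError("analysis window shorter than two samples")
    out = np.empty((v.shape[0], nwin, v.shape[2]))
    for t, onset in enumerate(rec.stimulus_onset):
        a, b = onset + i0, onset + i1
        if a < 0 or b > v.shape[1]:
            raise BoundsError(
                f"analysis window [{a}, {b}) outside trial {t} "
                f"(0..{v.shape[1]})"
            )
        out[:, :, t] = v[:, a:b, t]
    return out


def _multitaper_psd(x: np.ndarray, fs: float, half_bandwidth: float):
    """Multitaper PSD of traces along the last axis.

    DPSS tapers with NW = T * half_bandwidth; K = floor(2 NW - 1) tapers
    (at least 1).  Returns one-sided PSD and native frequency grid.
    """
    n = x.shape[-1]
    nw = max(half_bandwidth * n / fs, 1.0)
    k = max(int(2 * nw - 1), 1)
    tapers = dpss(n, nw, Kmax=k)  # (k, n), unit-energy
    spec = np.fft.rfft(x[..., np.newaxis, :] * tapers, axis=-1)
    psd = (np.abs(spec) ** 2).mean(axis=-2) / fs
    psd[..., 1:-1] *= 2.0  # one-sided
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return psd, freqs


def compute_power_map(rec: LaminarRecording, cfg: AnalysisConfig | None = None
                      ) -> PowerMap:
    """Multitaper power spectrum per channel, averaged across trials.

    Power is estimated on the configured analysis window of each trial with
    ``cfg.spectral_smoothing`` Hz half-bandwidth, then averaged over trials
    and binned onto ``cfg.frequency_bin``-wide bins from the bin width up to
    ``cfg.max_frequency`` (the DC bin is excluded: recordings are
    AC-coupled).
    """
    cfg = cfg or AnalysisConfig()
    rec = rec.oriented()
    windows = _analysis_windows(rec, cfg)  # (nc, nwin, ntr)
    x = windows.transpose(0, 2, 1)  # (nc, ntr, nwin)
    psd, native = _multitaper_psd(x, rec.sampling_rate, cfg.spectral_smoothing)
    psd = psd.mean(axis=1)  # average across trials -> (nc, nfreq_native)

    width = cfg.frequency_bin
    centers = np.arange(width, cfg.max_frequency + width / 2, width)
    centers = centers[centers <= rec.sampling_rate / 2]
    power = np.empty((psd.shape[0], centers.size))
    for j, fc in enumerate(centers):
        sel = np.abs(native - fc) <= width / 2
        if not sel.any():
            raise ResolutionError(
                f"analysis window too short: no spectral estimate within "
                f"{width / 2:g} Hz of the {fc:g} Hz bin"
            )
        power[:, j] = psd[:, sel].mean(axis=1)
    return PowerMap(power=power, freqs=centers,
                    n_trials_averaged=rec.n_trials)


# ---------------------------------------------------------------------------
# channel repair and normalization
# ---------------------------------------------------------------------------


def repair_bad_channels(pmap: PowerMap) -> tuple[PowerMap, list[int]]:
    """Interpolate channels with mean power > mean + 2 s.d. of all channels.

    Detection uses the population statistics including the outliers;
    flagged channels are replaced by the average of the nearest non-flagged
    neighbors (one-sided at the edges).  Applied once, not iterated.
    """
    if pmap.n_channels < 3:
        raise QualityError("bad-channel repair needs at least 3 channels")
    mean_power = pmap.power.mean(axis=1)
    thresh = mean_power.mean() + 2.0 * mean_power.std()
    flagged = np.nonzero(mean_power > thresh)[0]
    if flagged.size == 0:
        return pmap, []
    if flagged.size > pmap.n_channels / 2:
        raise QualityError(
            f"{flagged.size}/{pmap.n_channels} channels flagged bad; "
            "probe rejected"
        )
    good = np.setdiff1d(np.arange(pmap.n_channels), flagged)
    power = pmap.power.copy()
    for c in flagged:
        below = good[good < c]
        above = good[good > c]
        neighbors = []
        if below.size:
            neighbors.append(pmap.power[below[-1]])
        if above.size:
            neighbors.append(pmap.power[above[0]])
        power[c] = np.mean(neighbors, axis=0)
    repaired = replace(pmap, power=power)
    return repaired, flagged.tolist()


def relative_power(pmap: PowerMap) -> RelativePowerMap:
    """Divide each frequency column by its across-channel maximum."""
    colmax = pmap.power.max(axis=0)
    zero = np.nonzero(colmax <= 0)[0]
    if zero.size:
        raise NormalizationError(
            f"all-zero power at frequency bin(s) {pmap.freqs[zero].tolist()}"
        )
    return RelativePowerMap(rel_power=pmap.power / colmax, freqs=pmap.freqs)


def band_profile(rmap: RelativePowerMap, band: tuple[float, float]
                 ) -> BandProfile:
    """Per-channel mean of relative power over bins with low <= f <= high."""
    lo, hi = band
    sel = (rmap.freqs >= lo) & (rmap.freqs <= hi)
    if not sel.any():
        raise BoundsError(
            f"band {band} contains no frequency bins of the map "
            f"({rmap.freqs[0]:g}-{rmap.freqs[-1]:g} Hz)"
        )
    values = rmap.rel_power[:, sel].mean(axis=1)
    return BandProfile(band=band, values=values,
                       depth_axis=np.arange(rmap.n_channels))


# ---------------------------------------------------------------------------
# depth standardization and frequency re-binning
# ---------------------------------------------------------------------------


def standardize_depth(m: PowerMap | RelativePowerMap, n_out: int = 24):
    """Linearly interpolate the channel dimension onto ``n_out`` depths.

    The output depths span the first-to-last input channel (no
    extrapolation); the frequency dimension is untouched.  Relative maps are
    re-normalized per column afterwards so the max-1 invariant survives
    interpolation.
    """
    if n_out < 2:
        raise ParameterError("n_out must be >= 2")
    arr = m.rel_power if isinstance(m, RelativePowerMap) else m.power
    n_in = arr.shape[0]
    if n_in < 2:
        raise ParameterError("standardize_depth needs at least 2 channels")
    x_out = np.linspace(0, n_in - 1, n_out)
    x_in = np.arange(n_in)
    out = np.empty((n_out, arr.shape[1]))
    for j in range(arr.shape[1]):
        out[:, j] = np.interp(x_out, x_in, arr[:, j])
    if isinstance(m, RelativePowerMap):
        colmax = out.max(axis=0)
        out = out / np.where(colmax > 0, colmax, 1.0)
        return replace(m, rel_power=out)
    return replace(m, power=out)


def rebin_frequencies(m: PowerMap | RelativePowerMap, bin_width: float = 5.0):
    """Average adjacent frequency bins into non-overlapping wider bins.

    The target width must be an integer multiple of the source width (e.g.
    1 Hz -> 5 Hz for cross-species comparison).  Relative maps are
    re-normalized per column afterwards.
    """
    arr = m.rel_power if isinstance(m, RelativePowerMap) else m.power
    src = np.diff(m.freqs)
    if src.size and not np.allclose(src, src[0]):
        raise ParameterError("re-binning requires uniformly spaced bins")
    src_w = src[0] if src.size else bin_width
    ratio = bin_width / src_w
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise ParameterError(
            f"target width {bin_width} Hz is not an integer multiple of the "
            f"source width {src_w:g} Hz"
        )
    ratio = int(round(ratio))
    n_blocks = arr.shape[1] // ratio
    trimmed = arr[:, : n_blocks * ratio]
    out = trimmed.reshape(arr.shape[0], n_blocks, ratio).mean(axis=2)
    freqs = m.freqs[: n_blocks * ratio].reshape(n_blocks, ratio).mean(axis=1)
    if isinstance(m, RelativePowerMap):
        colmax = out.max(axis=0)
        out = out / np.where(colmax > 0, colmax, 1.0)
        return replace(m, rel_power=out, freqs=freqs)
    return replace(m, power=out, freqs=freqs)
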