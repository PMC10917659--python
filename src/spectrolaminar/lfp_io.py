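"""Data model and file I/O for laminar LFP recordings and derived maps.

A recording is a ``channels x samples x trials`` voltage array plus the
geometry needed downstream: sampling rate, inter-channel spacing ``s`` (the
spacing entering the CSD second-difference), the channel ordering convention
and optional per-trial stimulus-onset indices.

On-disk interchange is deliberately low-tech: a NumPy ``.npy`` container (or
a delimited-text matrix for single-trial data) next to a JSON metadata
sidecar whose field names carry explicit units (``channel_spacing_um``,
``sampling_rate_hz``).  Derived maps are written as TSV tables with a header
row of frequency-bin centers; scalar results as JSON records with
deterministic key ordering.

Channel-depth convention: after ingestion the channel index increases from
superficial to deep whenever the ordering is known; ``deep_first`` inputs are
flipped (and flagged).  ``unknown`` order is allowed — the sign of FLIP's G
resolves orientation downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import FormatError, ParameterError, ValidationError

__all__ = [
    "LaminarRecording",
    "ProbeMetadata",
    "AnalysisConfig",
    "read_recording",
    "write_recording",
    "write_result",
    "read_map",
]

_CHANNEL_ORDERS = ("superficial_first", "deep_first", "unknown")


@dataclass
class LaminarRecording:
    """Multi-channel, multi-trial LFP voltage with probe geometry.

    Parameters
    ----------
    voltage:
        Array ``(n_channels, n_samples, n_trials)`` in microvolts.
    sampling_rate:
        Samples per second (Hz).
    channel_spacing:
        Inter-contact spacing in micrometers.
    channel_order:
        ``superficial_first`` (channel index increases with depth),
        ``deep_first`` or ``unknown``.
    stimulus_onset:
        Optional per-trial sample index of stimulus onset.
    conductivity:
        Tissue conductivity sigma (S/m). The default 1 leaves CSD in
        relative units, which the z-score normalization removes anyway.
    """

    voltage: np.ndarray
    sampling_rate: float
    channel_spacing: float
    channel_order: str = "unknown"
    stimulus_onset: np.ndarray | None = None
    conductivity: float = 1.0
    probe_id: str = ""
    flipped_on_ingest: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.voltage, dtype=float)
        if v.ndim == 2:  # single trial
            v = v[:, :, np.newaxis]
        if v.ndim != 3:
            raise ValidationError(
                f"voltage must be (channels, samples, trials); got ndim={v.ndim}"
            )
        if min(v.shape) < 1:
            raise ValidationError(f"empty voltage array with shape {v.shape}")
        if not np.isfinite(v).all():
            bad = np.unique(np.nonzero(~np.isfinite(v))[0]).tolist()
            raise ValidationError(f"non-finite voltage on channels {bad}")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be > 0")
        if self.channel_spacing <= 0:
            raise ValidationError("channel_spacing must be > 0")
        if self.channel_order not in _CHANNEL_ORDERS:
            raise ValidationError(
                f"channel_order must be one of {_CHANNEL_ORDERS}"
            )
        self.voltage = v
        if self.stimulus_onset is not None:
            onset = np.atleast_1d(np.asarray(self.stimulus_onset, dtype=int))
            if onset.size == 1:
                onset = np.repeat(onset, v.shape[2])
            if onset.size != v.shape[2]:
                raise ValidationError(
                    f"stimulus_onset has {onset.size} entries for "
                    f"{v.shape[2]} trials"
                )
            self.stimulus_onset = onset

    @property
    def n_channels(self) -> int:
        return self.voltage.shape[0]

    @property
    def n_samples(self) -> int:
        return self.voltage.shape[1]

    @property
    def n_trials(self) -> int:
        return self.voltage.shape[2]

    def oriented(self) -> "LaminarRecording":
        """Return a copy with channel index increasing superficial -> deep.

        ``deep_first`` recordings are flipped and flagged; ``unknown`` is
        returned unchanged (FLIP's G sign resolves orientation later).
        """
        if self.channel_order != "deep_first":
            return self
        return replace(
            self,
            voltage=self.voltage[::-1].copy(),
            channel_order="superficial_first",
            flipped_on_ingest=True,
        )


@dataclass
class ProbeMetadata:
    probe_id: str
    area_label: str = ""
    n_contacts: int = 0
    notes: str = ""


@dataclass
class AnalysisConfig:
    """Tunable parameters of the spectrolaminar pipeline.

    Defaults follow the standard analysis: 1-s window around stimulus onset,
    2-Hz multitaper smoothing, 1-Hz bins up to 150 Hz, FLIP subranges
    10-19 Hz (alpha-beta) and 75-150 Hz (gamma), identifiability threshold
    G_t = 0.265, minimum depth-range span of 7 channel steps and depth
    standardization to 24 interpolated channels.
    """

    analysis_window: tuple[float, float] = (-500.0, 500.0)  # ms re stimulus
    spectral_smoothing: float = 2.0  # Hz, multitaper half-bandwidth
    frequency_bin: float = 1.0  # Hz (5 for cross-species comparison)
    max_frequency: float = 150.0  # Hz
    flip_low_band: tuple[float, float] = (10.0, 19.0)
    flip_high_band: tuple[float, float] = (75.0, 150.0)
    g_threshold: float = 0.265
    significance_alpha: float = 0.05
    min_range_channels: int = 7
    n_interp_channels: int = 24
    band_delta_theta: tuple[float, float] = (1.0, 6.0)
    band_alpha_beta: tuple[float, float] = (10.0, 30.0)
    band_gamma: tuple[float, float] = (50.0, 150.0)
    vflip_grid_hz: float = 10.0
    vflip_low_start: float = 10.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("flip_low_band", "flip_high_band", "band_delta_theta",
                     "band_alpha_beta", "band_gamma"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ParameterError(f"{name}: lower bound must be < upper")
        if self.g_threshold <= 0:
            raise ParameterError("g_threshold must be > 0")
        if self.min_range_channels < 2:
            raise ParameterError("min_range_channels must be >= 2")


# ---------------------------------------------------------------------------
# recording container I/O
# ---------------------------------------------------------------------------

_REQUIRED_META = ("sampling_rate_hz", "channel_spacing_um")


def read_recording(path: str | Path, metadata_path: str | Path) -> LaminarRecording:
    """Load a recording from an array container plus JSON metadata sidecar.

    ``.npy`` containers hold the full 3-D array; delimited-text containers
    hold a 2-D ``channels x samples`` matrix (``n_trials = 1`` unless the
    sidecar gives ``n_trials`` for reshaping stacked trials).
    """
    path = Path(path)
    metadata_path = Path(metadata_path)
    try:
        meta = json.loads(metadata_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"metadata sidecar {metadata_path} is not valid JSON: {exc}")
    for key in _REQUIRED_META:
        if key not in meta:
            raise FormatError(f"metadata sidecar missing required field '{key}'")

    if path.suffix == ".npy":
        arr = np.load(path)
    else:
        arr = np.loadtxt(path, delimiter="\t" if path.suffix == ".tsv" else None)
        arr = np.atleast_2d(arr)

    n_trials = int(meta.get("n_trials", 1 if arr.ndim == 2 else arr.shape[2]))
    if arr.ndim == 2 and n_trials > 1:
        nc = int(meta.get("n_channels", 0))
        if nc <= 0 or arr.shape[0] != nc * n_trials:
            raise FormatError(
                "n_trials > 1 for a 2-D container requires 'n_channels' with "
                f"rows = n_channels*n_trials; got {arr.shape[0]} rows"
            )
        arr = arr.reshape(n_trials, nc, arr.shape[1]).transpose(1, 2, 0)
    for dim_key, axis in (("n_channels", 0), ("n_samples", 1), ("n_trials", 2)):
        if dim_key in meta and arr.ndim == 3 and arr.shape[axis] != int(meta[dim_key]):
            raise FormatError(
                f"metadata field '{dim_key}'={meta[dim_key]} contradicts "
                f"container dimension {arr.shape[axis]}"
            )

    onset = meta.get("stimulus_onset_sample")
    rec = LaminarRecording(
        voltage=arr,
        sampling_rate=float(meta["sampling_rate_hz"]),
        channel_spacing=float(meta["channel_spacing_um"]),
        channel_order=meta.get("channel_order", "unknown"),
        stimulus_onset=None if onset is None else np.asarray(onset),
        conductivity=float(meta.get("conductivity_s_per_m", 1.0)),
        probe_id=str(meta.get("probe_id", "")),
    )
    return rec.oriented()


def write_recording(rec: LaminarRecording, path: str | Path,
                    metadata_path: str | Path) -> None:
    """Write a recording to an ``.npy`` container plus JSON sidecar."""
    path = Path(path)
    np.save(path, rec.voltage)
    meta = {
        "probe_id": rec.probe_id,
        "sampling_rate_hz": rec.sampling_rate,
        "channel_spacing_um": rec.channel_spacing,
        "channel_order": rec.channel_order,
        "conductivity_s_per_m": rec.conductivity,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "n_trials": rec.n_trials,
        "stimulus_onset_sample": (
            None if rec.stimulus_onset is None else rec.stimulus_onset.tolist()
        ),
    }
    Path(metadata_path).write_text(json.dumps(meta, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# derived-result I/O
# ---------------------------------------------------------------------------


def write_result(result, path: str | Path) -> None:
    """Serialize a derived result to disk.

    Maps (anything exposing a 2-D array + an axis of bin centers) become TSV
    tables with channels as rows and a ``#`` header row of bin centers;
    scalar results (FLIP results and similar records) become JSON with
    sorted keys.
    """
    path = Path(path)
    record = getattr(result, "to_record", None)
    if record is not None:
        path.write_text(json.dumps(record(), indent=2, sort_keys=True) + "\n")
        return
    arr, axis = _map_payload(result)
    header = "\t".join(f"{x:g}" for x in axis)
    np.savetxt(path, arr, delimiter="\t", header=header, fmt="%.8g")


def _map_payload(result) -> tuple[np.ndarray, np.ndarray]:
    for attr, axis_attr in (("rel_power", "freqs"), ("power", "freqs"),
                            ("csd", "time_axis")):
        arr = getattr(result, attr, None)
        if arr is not None:
            return np.asarray(arr), np.asarray(getattr(result, axis_attr))
    raise FormatError(f"do not know how to serialize {type(result).__name__}")


def read_map(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a TSV map written by :func:`write_result`.

    Returns ``(values, axis)`` where ``axis`` holds the header bin centers.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("#"):
        raise FormatError(f"{path} lacks the '#'-prefixed axis header row")
    axis = np.array([float(x) for x in first[1:].split()])
    values = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
    return values, axis
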