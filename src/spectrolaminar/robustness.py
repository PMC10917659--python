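"""Robustness of landmark localization to recording duration.

Mirrors the signal-duration experiment: from one long session, draw random
subsets of trials amounting to a given analysis duration, rerun the layer
identification on each subset, and measure how far the estimated crossover
lands from the estimate obtained on the entire session.  Short durations
give noisy spectral estimates and hence larger localization error; the
error shrinks as duration grows, approaching zero at the full session by
construction (the reference is the full-session estimate).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .flip_core import flip
from .lfp_io import AnalysisConfig, LaminarRecording
from .spectral import compute_power_map, relative_power, standardize_depth
from .synthetic import SyntheticProbeSpec, generate_probe

__all__ = ["subsample_trials", "crossover_from_recording",
           "duration_robustness"]


def subsample_trials(rec: LaminarRecording, n_trials: int,
                     rng: np.random.Generator) -> LaminarRecording:
    """Random without-replacement subset of a recording's trials."""
    idx = rng.choice(rec.n_trials, size=min(n_trials, rec.n_trials),
                     replace=False)
    onset = (None if rec.stimulus_onset is None
             else rec.stimulus_onset[idx])
    return replace(rec, voltage=rec.voltage[:, :, idx], stimulus_onset=onset)


def crossover_from_recording(rec: LaminarRecording,
                             cfg: AnalysisConfig | None = None
                             ) -> float | None:
    """Crossover channel (interpolated grid) of a recording, or None."""
    cfg = cfg or AnalysisConfig()
    rmap = standardize_depth(relative_power(compute_power_map(rec, cfg)),
                             cfg.n_interp_channels)
    res = flip(rmap, cfg)
    return res.crossover_channel


def duration_robustness(durations_s=(1, 5, 25, 200),
                        n_seeds: int = 50,
                        seed: int = 0,
                        session_s: int = 250,
                        n_reps: int = 3,
                        base: SyntheticProbeSpec | None = None,
                        cfg: AnalysisConfig | None = None) -> dict:
    """Median crossover-localization error per analysis duration.

    Per seed: generate one ``session_s``-second synthetic session (1-s
    trials), take its full-session crossover as the reference, then for
    each duration draw ``n_reps`` random trial subsets of that length and
    average the absolute crossover error against the reference (averaging
    over random subsets is what makes the per-probe error continuous
    rather than an integer channel count).  A subset (or session) without
    a recoverable crossover counts as half the probe span.  Returns
    ``{duration_s: median error in interpolated channels}`` across seeds.
    """
    cfg = cfg or AnalysisConfig()
    base = base or SyntheticProbeSpec()
    rng = np.random.default_rng(seed)
    half_span = cfg.n_interp_channels / 2
    errors: dict[int, list[float]] = {d: [] for d in durations_s}
    for _ in range(n_seeds):
        spec = replace(base, n_trials=session_s,
                       seed=int(rng.integers(0, 2 ** 31 - 1)))
        rec, _truth = generate_probe(spec)
        reference = crossover_from_recording(rec, cfg)
        for d in durations_s:
            errs = []
            for _rep in range(n_reps):
                sub = subsample_trials(rec, d, rng)
                est = crossover_from_recording(sub, cfg)
                if est is None or reference is None:
                    errs.append(half_span)
                else:
                    errs.append(abs(est - reference))
            errors[d].append(float(np.mean(errs)))
    return {d: float(np.median(v)) for d, v in errors.items()}
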