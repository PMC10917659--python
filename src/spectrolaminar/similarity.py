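"""Image-similarity (IS) comparison of relative power maps.

Two relative power maps — channels x frequency images with values in
[0, 1] — are compared with the structural similarity index (SSIM), giving an
IS value between 0 (completely dissimilar) and 1 (identical).  The dynamic
range is pinned to 1.0 since the maps are max-normalized; window size and
stabilization constants are the standard SSIM defaults.

Group comparisons follow the randomized subgrouping procedure: each group
of probes is randomly halved, the half-averages compared within each group
(one within-IS per group per repetition) and across groups (four
between-IS per repetition); five repetitions by default give 5 within
values per group and 20 between values, whose means are the grand within-
and between-group IS.  Maps are aligned by their alpha-beta/gamma crossover
channel before averaging.

The channel-shuffle null destroys laminar structure by permuting channel
rows; the drop in FLIP identifiability between original and shuffled maps
measures how much of the identification rests on genuine laminar ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.metrics import structural_similarity

from .errors import ShapeError, SizeError
from .flip_core import flip, vflip
from .lfp_io import AnalysisConfig
from .spectral import RelativePowerMap

__all__ = [
    "SimilarityResult",
    "image_similarity",
    "align_by_crossover",
    "group_is",
    "shuffle_identifiability",
]


@dataclass
class SimilarityResult:
    """Grand within/between IS with the per-repetition values behind them."""

    grand_within: float
    grand_between: float
    within_a: list[float] = field(default_factory=list)
    within_b: list[float] = field(default_factory=list)
    between: list[float] = field(default_factory=list)
    n_repetitions: int = 0


def _as_array(m: RelativePowerMap | np.ndarray) -> np.ndarray:
    return np.asarray(getattr(m, "rel_power", m), dtype=float)


def image_similarity(map_a: RelativePowerMap | np.ndarray,
                     map_b: RelativePowerMap | np.ndarray) -> float:
    """SSIM between two equally shaped relative power maps, in [0, 1].

    Raw SSIM lives in [-1, 1]; anticorrelated structure (negative values)
    is floored at 0, the "completely dissimilar" end of the IS scale.
    """
    a, b = _as_array(map_a), _as_array(map_b)
    if a.shape != b.shape:
        raise ShapeError(
            f"maps have shapes {a.shape} vs {b.shape}; run standardize_depth "
            "and matching frequency binning first"
        )
    win = min(7, a.shape[0] - (a.shape[0] + 1) % 2,
              a.shape[1] - (a.shape[1] + 1) % 2)
    return float(max(0.0, structural_similarity(a, b, data_range=1.0,
                                                win_size=win)))


def align_by_crossover(maps: list[RelativePowerMap | np.ndarray],
                       crossovers: list[int],
                       reference: int | None = None) -> list[np.ndarray]:
    """Shift each map along depth so its crossover lands on a common row.

    Rows are shifted without wraparound; rows vacated at the edges are
    filled by replicating the nearest remaining row, keeping shapes equal so
    the aligned maps can be averaged and compared.  ``reference`` defaults
    to the median crossover.
    """
    arrays = [_as_array(m) for m in maps]
    if reference is None:
        reference = int(round(np.median(crossovers)))
    out = []
    for arr, c in zip(arrays, crossovers):
        shift = reference - int(c)
        shifted = np.empty_like(arr)
        if shift >= 0:
            shifted[shift:] = arr[: arr.shape[0] - shift]
            shifted[:shift] = arr[0]
        else:
            shifted[:shift] = arr[-shift:]
            shifted[shift:] = arr[-1]
        out.append(shifted)
    return out


def group_is(group_a: list[RelativePowerMap | np.ndarray],
             group_b: list[RelativePowerMap | np.ndarray],
             n_reps: int = 5,
             seed: int | np.random.Generator = 0) -> SimilarityResult:
    """Randomized-subgrouping IS between two groups of (aligned) maps.

    Per repetition: each group is randomly split into two equal halves (odd
    groups drop one random probe), the maps of each half averaged; the
    within-IS of a group compares its two half-averages, and the four
    cross-pairings of half-averages give the between-IS values.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    groups = [[_as_array(m) for m in g] for g in (group_a, group_b)]
    for name, g in zip("AB", groups):
        if len(g) < 4:
            raise SizeError(
                f"group {name} has {len(g)} probes; need >= 4 to halve"
            )
    result = SimilarityResult(0.0, 0.0, n_repetitions=n_reps)
    withins = (result.within_a, result.within_b)
    for _ in range(n_reps):
        halves = []
        for g in groups:
            idx = rng.permutation(len(g))
            if len(g) % 2:
                idx = idx[:-1]
            half = len(idx) // 2
            mean1 = np.mean([g[i] for i in idx[:half]], axis=0)
            mean2 = np.mean([g[i] for i in idx[half:]], axis=0)
            halves.append((mean1, mean2))
        for k in range(2):
            withins[k].append(image_similarity(halves[k][0], halves[k][1]))
        for ha in halves[0]:
            for hb in halves[1]:
                result.between.append(image_similarity(ha, hb))
    result.grand_within = float(np.mean(result.within_a + result.within_b))
    result.grand_between = float(np.mean(result.between))
    return result


def shuffle_identifiability(maps: list[RelativePowerMap],
                            n_shuffles: int = 100,
                            method: str = "flip",
                            seed: int | np.random.Generator = 0,
                            cfg: AnalysisConfig | None = None
                            ) -> tuple[float, list[float]]:
    """Channel-shuffle null for FLIP/vFLIP identifiability.

    Permutes the channel rows of each map ``n_shuffles`` times, reruns the
    chosen method and returns ``(mean identifiable fraction, per-probe
    fractions)``.  The identity permutation (n_shuffles=0 semantics) is the
    unshuffled result.
    """
    cfg = cfg or AnalysisConfig()
    run = {"flip": flip, "vflip": vflip}[method]
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    fractions = []
    for m in maps:
        hits = 0
        for _ in range(n_shuffles):
            perm = rng.permutation(m.n_channels)
            shuffled = replace(m, rel_power=m.rel_power[perm])
            res = run(shuffled, cfg)
            flipres = getattr(res, "flip", res)
            hits += int(flipres.identifiable)
        fractions.append(hits / n_shuffles)
    return float(np.mean(fractions)), fractions
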