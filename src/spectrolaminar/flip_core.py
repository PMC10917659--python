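"""FLIP and vFLIP: automated frequency-based laminar layer identification.

The spectrolaminar motif places gamma power superficially (peaking in layers
2/3), alpha-beta power deep (peaking in layers 5/6) and their relative-power
crossover in layer 4.  FLIP quantifies the motif by fitting, over a
contiguous range of channel depths ``D_i..D_f``, straight lines to the
alpha-beta (10-19 Hz) and gamma (75-150 Hz) band-depth profiles and scoring

    G = s_ab * R2_ab * R2_g * f   (slopes opposing; else G = 0),
    f = 0.04 (D_f - D_i) + 0.72,

where ``s_ab`` is the alpha-beta slope sign and ``R2`` the regression
coefficients.  G is nonzero only when the two band gradients genuinely
oppose; on an axis running superficial -> deep the canonical motif has a
rising alpha-beta profile and a falling gamma profile, so G > 0, while
G < 0 flags an inverted (deep-to-superficial) insertion.  The
regularization ``f`` keeps short
ranges from winning on fit quality alone.  The search maximizes |G| over all
ranges spanning at least 7 channel steps (700 um at 100-um spacing); a probe
is identifiable when both slopes are significant (two-sided t-test,
alpha = 0.05) and |G| exceeds G_t = 0.265.

Landmarks inside the winning range: the alpha-beta/gamma crossover (layer 4)
chosen among sign changes of P_g - P_ab by maximizing

    dP = sum_superficial (P_g - P_ab) + sum_deep (P_ab - P_g),

and the gamma / alpha-beta peaks (layers 2/3 and 5/6) as the local profile
maxima nearest D_i and D_f respectively, inside or outside the range.

vFLIP repeats the search over frequency-band combinations on a 10-Hz grid
(low-band upper bound <= 70 Hz and below the high-band lower bound, which
must exceed 30 Hz; high-band upper bound fixed at 150 Hz) and keeps the pair
with the highest |G|.

Channel indices are 0-based throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats

from .errors import NoCrossoverError, ParameterError, SpanError
from .lfp_io import AnalysisConfig
from .spectral import (
    BandProfile,
    PowerMap,
    RelativePowerMap,
    band_profile,
    relative_power,
    standardize_depth,
)

__all__ = [
    "RangeFit",
    "FlipResult",
    "VFlipResult",
    "goodness_of_fit",
    "find_optimal_range",
    "select_crossover",
    "select_peaks",
    "flip",
    "vflip",
]

_TINY = 1e-12


@dataclass
class RangeFit:
    """Diagnostics of the regularized opposing-gradient fit on one range."""

    d_i: int
    d_f: int
    g: float
    f_reg: float
    r2_alphabeta: float
    r2_gamma: float
    slope_sign_alphabeta: int
    slope_sign_gamma: int
    p_alphabeta: float
    p_gamma: float

    @property
    def span(self) -> int:
        return self.d_f - self.d_i

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_alphabeta < alpha and self.p_gamma < alpha


@dataclass
class FlipResult:
    """Outcome of FLIP on one probe.

    Landmark channels live on the standardized (interpolated) depth grid;
    ``*_original`` map them back to the input channel axis.  Landmarks are
    populated only for identifiable probes.
    """

    best_fit: RangeFit
    identifiable: bool
    orientation: str  # upright | inverted | undetermined
    crossover_channel: int | None = None
    gamma_peak_channel: int | None = None
    alphabeta_peak_channel: int | None = None
    delta_p: float | None = None
    gamma_peak_at_boundary: bool = False
    alphabeta_peak_at_boundary: bool = False
    crossover_channel_original: float | None = None
    gamma_peak_channel_original: float | None = None
    alphabeta_peak_channel_original: float | None = None
    low_band: tuple[float, float] = (10.0, 19.0)
    high_band: tuple[float, float] = (75.0, 150.0)
    n_channels_original: int = 0
    n_channels_interp: int = 24

    def to_record(self) -> dict:
        """Serializable record with deterministic field set."""
        return {
            "G": self.best_fit.g,
            "D_i": self.best_fit.d_i,
            "D_f": self.best_fit.d_f,
            "f_reg": self.best_fit.f_reg,
            "R2_alphabeta": self.best_fit.r2_alphabeta,
            "R2_gamma": self.best_fit.r2_gamma,
            "p_alphabeta": self.best_fit.p_alphabeta,
            "p_gamma": self.best_fit.p_gamma,
            "identifiable": self.identifiable,
            "orientation": self.orientation,
            "crossover_channel": self.crossover_channel,
            "gamma_peak_channel": self.gamma_peak_channel,
            "alphabeta_peak_channel": self.alphabeta_peak_channel,
            "crossover_channel_original": self.crossover_channel_original,
            "gamma_peak_channel_original": self.gamma_peak_channel_original,
            "alphabeta_peak_channel_original": self.alphabeta_peak_channel_original,
            "delta_P": self.delta_p,
            "low_band_hz": list(self.low_band),
            "high_band_hz": list(self.high_band),
            "layer_markers": {
                "layers_2_3": "gamma_peak_channel",
                "layer_4": "crossover_channel",
                "layers_5_6": "alphabeta_peak_channel",
            },
        }


@dataclass
class VFlipResult:
    """FLIP outcome plus the winning frequency-band combination."""

    flip: FlipResult
    low_band: tuple[float, float]
    high_band: tuple[float, float]

    def to_record(self) -> dict:
        rec = self.flip.to_record()
        rec["low_band_hz"] = list(self.low_band)
        rec["high_band_hz"] = list(self.high_band)
        return rec


# ---------------------------------------------------------------------------
# regression machinery
# ---------------------------------------------------------------------------


def _line_stats(y: np.ndarray) -> tuple[float, int, float]:
    """OLS of y on 0..n-1: returns (R^2, slope sign, two-sided slope p).

    Zero-variance profiles give R^2 = 0 with p = 1 (fit non-significant).
    """
    n = y.size
    x = np.arange(n, dtype=float)
    sx = x - x.mean()
    sy = y - y.mean()
    ssx = float(sx @ sx)
    ssy = float(sy @ sy)
    if ssy <= _TINY * max(1.0, float(np.abs(y).max()) ** 2):
        return 0.0, 0, 1.0
    sxy = float(sx @ sy)
    r2 = sxy * sxy / (ssx * ssy)
    sign = 1 if sxy > 0 else (-1 if sxy < 0 else 0)
    dof = n - 2
    if dof <= 0:
        return r2, sign, 1.0
    if r2 >= 1.0 - 1e-12:
        return min(r2, 1.0), sign, 0.0
    t = np.sqrt(r2 * dof / (1.0 - r2))
    p = 2.0 * sp_stats.t.sf(t, dof)
    return r2, sign, float(p)


def f_regularization(span: int) -> float:
    """Span-dependent regularization: f = 0.04 * (D_f - D_i) + 0.72."""
    return 0.04 * span + 0.72


def _fit_from_profiles(p_ab: np.ndarray, p_g: np.ndarray,
                       d_i: int, d_f: int) -> RangeFit:
    r2_ab, s_ab, pv_ab = _line_stats(p_ab)
    r2_g, s_g, pv_g = _line_stats(p_g)
    f_reg = f_regularization(d_f - d_i)
    # G is nonzero only for genuinely opposing slopes; its sign then follows
    # the alpha-beta gradient direction (+: rising toward deep = upright
    # insertion), which is what lets negative G flag inverted insertions.
    g = s_ab * r2_ab * r2_g * f_reg if s_ab * s_g == -1 else 0.0
    return RangeFit(d_i=d_i, d_f=d_f, g=g, f_reg=f_reg,
                    r2_alphabeta=r2_ab, r2_gamma=r2_g,
                    slope_sign_alphabeta=s_ab, slope_sign_gamma=s_g,
                    p_alphabeta=pv_ab, p_gamma=pv_g)


def goodness_of_fit(p_alphabeta: BandProfile | np.ndarray,
                    p_gamma: BandProfile | np.ndarray,
                    d_i: int, d_f: int,
                    min_range_channels: int = 7) -> RangeFit:
    """Regularized opposing-gradient score on channels ``d_i..d_f``.

    The caller is responsible for any within-range re-normalization of the
    underlying map; this function fits the given profiles as-is.
    """
    ab = np.asarray(getattr(p_alphabeta, "values", p_alphabeta), dtype=float)
    g = np.asarray(getattr(p_gamma, "values", p_gamma), dtype=float)
    if ab.size != g.size:
        raise ParameterError("profiles differ in length")
    if not (0 <= d_i < d_f < ab.size):
        raise ParameterError(f"range {d_i}..{d_f} outside profile of {ab.size}")
    if d_f - d_i < min_range_channels:
        raise SpanError(
            f"range span {d_f - d_i} below minimum {min_range_channels}"
        )
    return _fit_from_profiles(ab[d_i:d_f + 1], g[d_i:d_f + 1], d_i, d_f)


def _range_profiles(low_map: np.ndarray, high_map: np.ndarray,
                    d_i: int, d_f: int) -> tuple[np.ndarray, np.ndarray]:
    """Band profiles after re-normalizing each frequency column within the
    range (dividing by the channel with highest power inside D_i..D_f)."""
    out = []
    for band_map in (low_map, high_map):
        sub = band_map[d_i:d_f + 1]
        colmax = sub.max(axis=0)
        out.append((sub / np.where(colmax > 0, colmax, 1.0)).mean(axis=1))
    return out[0], out[1]


def find_optimal_range(p_alphabeta: BandProfile | np.ndarray,
                       p_gamma: BandProfile | np.ndarray,
                       min_span: int = 7,
                       band_maps: tuple[np.ndarray, np.ndarray] | None = None
                       ) -> RangeFit:
    """Exhaustive search over all (D_i, D_f) ranges spanning >= ``min_span``.

    Returns the fit maximizing |G| (sign preserved); ties break toward the
    larger span, then the more superficial D_i.  Fits whose two slopes
    actually oppose (the pattern the method looks for) are preferred over
    same-sign fits regardless of |G| — without this, a probe whose two
    bands share one monotone gradient could score arbitrarily high while
    carrying no crossover information.  When ``band_maps`` (the channels x
    band-bins sub-matrices of the relative power map) is given, profiles
    are recomputed per range with within-range re-normalization — the
    standard FLIP behavior; otherwise the fixed profiles are used.
    """
    ab = np.asarray(getattr(p_alphabeta, "values", p_alphabeta), dtype=float)
    g = np.asarray(getattr(p_gamma, "values", p_gamma), dtype=float)
    n = ab.size
    if n < min_span + 1:
        raise SpanError(f"{n} channels cannot host a span of {min_span}")
    best: RangeFit | None = None
    best_key: tuple[int, float, int, int] | None = None
    for d_i in range(n - min_span):
        for d_f in range(d_i + min_span, n):
            if band_maps is not None:
                pa, pg = _range_profiles(band_maps[0], band_maps[1], d_i, d_f)
            else:
                pa, pg = ab[d_i:d_f + 1], g[d_i:d_f + 1]
            fit = _fit_from_profiles(pa, pg, d_i, d_f)
            opposing = int(fit.slope_sign_alphabeta * fit.slope_sign_gamma == -1)
            key = (opposing, abs(fit.g), fit.span, -d_i)
            if best_key is None or key > best_key:
                best, best_key = fit, key
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------


def select_crossover(p_alphabeta: BandProfile | np.ndarray,
                     p_gamma: BandProfile | np.ndarray,
                     fit: RangeFit) -> tuple[int, float]:
    """Pick the alpha-beta/gamma crossover channel within the fitted range.

    Candidates are the channels where ``sign(P_g - P_ab)`` changes inside
    ``D_i..D_f`` (profiles are assumed oriented canonically: gamma dominant
    superficially).  For each candidate c,

        dP(c) = sum_{D_i..c} (P_g - P_ab) + sum_{c..D_f} (P_ab - P_g),

    and the maximizing candidate is returned with its dP.
    """
    ab = np.asarray(getattr(p_alphabeta, "values", p_alphabeta), dtype=float)
    g = np.asarray(getattr(p_gamma, "values", p_gamma), dtype=float)
    d_i, d_f = fit.d_i, fit.d_f
    diff = g[d_i:d_f + 1] - ab[d_i:d_f + 1]

    candidates: list[int] = []
    for k in range(diff.size):
        if diff[k] == 0.0:
            candidates.append(d_i + k)
        elif k + 1 < diff.size and diff[k] * diff[k + 1] < 0:
            # crossing between k and k+1: take the channel closer to zero
            candidates.append(d_i + (k if abs(diff[k]) <= abs(diff[k + 1])
                                     else k + 1))
    candidates = sorted(set(candidates))
    if not candidates:
        raise NoCrossoverError(
            f"P_gamma - P_alphabeta does not change sign in {d_i}..{d_f}"
        )

    def delta_p(c: int) -> float:
        sup = diff[: c - d_i + 1].sum()  # superficial side: gamma dominant
        deep = -diff[c - d_i:].sum()  # deep side: alpha-beta dominant
        return float(sup + deep)

    scores = [delta_p(c) for c in candidates]
    best = int(np.argmax(scores))
    return candidates[best], scores[best]


def _local_maxima(v: np.ndarray) -> list[tuple[int, bool]]:
    """(channel, at_boundary) for all local maxima; plateaus collapse to
    their center channel; the profile's endpoints count when they top their
    inner neighbor."""
    n = v.size
    out: list[tuple[int, bool]] = []
    k = 0
    while k < n:
        j = k
        while j + 1 < n and v[j + 1] == v[k]:
            j += 1
        left_ok = k == 0 or v[k - 1] < v[k]
        right_ok = j == n - 1 or v[j + 1] < v[k]
        if left_ok and right_ok:
            center = (k + j) // 2
            out.append((center, k == 0 or j == n - 1))
        k = j + 1
    return out


def select_peaks(p_alphabeta: BandProfile | np.ndarray,
                 p_gamma: BandProfile | np.ndarray,
                 fit: RangeFit) -> tuple[int, int, bool, bool]:
    """Gamma and alpha-beta peak channels for the fitted range.

    Among local maxima of the full-probe gamma profile, the one nearest the
    superficial limit D_i is the gamma peak (layers 2/3); among alpha-beta
    local maxima, the one nearest the deep limit D_f is the alpha-beta peak
    (layers 5/6) — either inside or outside the range.  Ties break toward
    the range interior.  Returns ``(gamma_peak, alphabeta_peak,
    gamma_at_boundary, alphabeta_at_boundary)``.
    """
    ab = np.asarray(getattr(p_alphabeta, "values", p_alphabeta), dtype=float)
    g = np.asarray(getattr(p_gamma, "values", p_gamma), dtype=float)

    def nearest(maxima: list[tuple[int, bool]], target: int,
                interior_sign: int) -> tuple[int, bool]:
        # interior_sign: +1 if the range interior lies at larger channel
        # indices than the target, -1 otherwise (used only to break ties)
        best = None
        for ch, boundary in maxima:
            key = (abs(ch - target), -interior_sign * np.sign(ch - target))
            if best is None or key < best[0]:
                best = (key, ch, boundary)
        assert best is not None
        return best[1], best[2]

    gamma_peak, g_bound = nearest(_local_maxima(g), fit.d_i, +1)
    ab_peak, ab_bound = nearest(_local_maxima(ab), fit.d_f, -1)
    return gamma_peak, ab_peak, g_bound, ab_bound


# ---------------------------------------------------------------------------
# end-to-end FLIP / vFLIP
# ---------------------------------------------------------------------------


def _band_submatrix(rmap: RelativePowerMap, band: tuple[float, float]
                    ) -> np.ndarray:
    sel = (rmap.freqs >= band[0]) & (rmap.freqs <= band[1])
    if not sel.any():
        raise ParameterError(f"map has no bins inside band {band}")
    return rmap.rel_power[:, sel]


def _flip_core(rmap: RelativePowerMap, cfg: AnalysisConfig,
               low_band: tuple[float, float],
               high_band: tuple[float, float],
               n_orig: int) -> FlipResult:
    """Range search + identifiability + landmarks on a standardized map."""
    low_map = _band_submatrix(rmap, low_band)
    high_map = _band_submatrix(rmap, high_band)
    prof_ab = low_map.mean(axis=1)
    prof_g = high_map.mean(axis=1)
    fit = find_optimal_range(prof_ab, prof_g, cfg.min_range_channels,
                             band_maps=(low_map, high_map))
    identifiable = (fit.significant(cfg.significance_alpha)
                    and abs(fit.g) > cfg.g_threshold)
    if fit.g > 0:
        orientation = "upright"
    elif fit.g < 0:
        orientation = "inverted"
    else:
        orientation = "undetermined"

    result = FlipResult(best_fit=fit, identifiable=identifiable,
                        orientation=orientation, low_band=low_band,
                        high_band=high_band, n_channels_original=n_orig,
                        n_channels_interp=rmap.n_channels)
    if not identifiable:
        return result

    n = rmap.n_channels
    if fit.g < 0:
        # mirrored axis puts the pattern in canonical orientation
        m_ab, m_g = prof_ab[::-1], prof_g[::-1]
        m_low, m_high = low_map[::-1], high_map[::-1]
        m_fit = RangeFit(**{**fit.__dict__,
                            "d_i": n - 1 - fit.d_f, "d_f": n - 1 - fit.d_i})
        back = lambda c: n - 1 - c  # noqa: E731
    else:
        m_ab, m_g, m_low, m_high, m_fit = prof_ab, prof_g, low_map, high_map, fit
        back = lambda c: c  # noqa: E731

    r_ab, r_g = _range_profiles(m_low, m_high, m_fit.d_i, m_fit.d_f)
    # embed range-renormalized profiles on the full axis for landmark search
    full_ab, full_g = m_ab.copy(), m_g.copy()
    full_ab[m_fit.d_i:m_fit.d_f + 1] = r_ab
    full_g[m_fit.d_i:m_fit.d_f + 1] = r_g
    try:
        cross, dp = select_crossover(full_ab, full_g, m_fit)
    except NoCrossoverError:
        result.identifiable = False
        return result
    g_peak, ab_peak, g_bound, ab_bound = select_peaks(m_ab, m_g, m_fit)

    scale = (n_orig - 1) / (n - 1) if n > 1 else 1.0
    result.crossover_channel = back(cross)
    result.gamma_peak_channel = back(g_peak)
    result.alphabeta_peak_channel = back(ab_peak)
    result.delta_p = dp
    result.gamma_peak_at_boundary = g_bound
    result.alphabeta_peak_at_boundary = ab_bound
    result.crossover_channel_original = back(cross) * scale
    result.gamma_peak_channel_original = back(g_peak) * scale
    result.alphabeta_peak_channel_original = back(ab_peak) * scale
    return result


def _prepare_map(m: PowerMap | RelativePowerMap, cfg: AnalysisConfig
                 ) -> tuple[RelativePowerMap, int]:
    rmap = relative_power(m) if isinstance(m, PowerMap) else m
    n_orig = rmap.n_channels
    if n_orig != cfg.n_interp_channels:
        rmap = standardize_depth(rmap, cfg.n_interp_channels)
    return rmap, n_orig


def flip(m: PowerMap | RelativePowerMap, cfg: AnalysisConfig | None = None
         ) -> FlipResult:
    """Run FLIP end to end on a power or relative power map.

    Standardizes depth to ``cfg.n_interp_channels`` interpolated channels,
    builds the 10-19 Hz and 75-150 Hz band profiles, searches all depth
    ranges, applies the identifiability decision (both slope p-values below
    alpha and |G| > G_t) and extracts the layer landmarks.  Non-identifiable
    probes come back with ``identifiable=False`` and diagnostics, never
    landmarks.
    """
    cfg = cfg or AnalysisConfig()
    rmap, n_orig = _prepare_map(m, cfg)
    return _flip_core(rmap, cfg, cfg.flip_low_band, cfg.flip_high_band, n_orig)


def _vflip_band_pairs(cfg: AnalysisConfig) -> list[tuple[tuple[float, float],
                                                         tuple[float, float]]]:
    """All legal (low, high) band pairs on the vFLIP grid.

    Criteria: boundaries on a 10-Hz grid; low upper bound <= 70 Hz and below
    the high lower bound; high lower bound > 30 Hz; high upper bound fixed
    at 150 Hz.
    """
    step = cfg.vflip_grid_hz
    top = 150.0
    pairs = []
    lo_starts = np.arange(cfg.vflip_low_start, 70.0, step)
    for lo in lo_starts:
        for hi in np.arange(lo + step, 70.0 + step / 2, step):
            for hlo in np.arange(max(hi + step, 40.0), top - step / 2, step):
                if hlo <= 30.0 or hlo <= hi:
                    continue
                pairs.append(((float(lo), float(hi)), (float(hlo), top)))
    if not pairs:
        raise ParameterError("vFLIP grid admits no legal band pair")
    return pairs


def vflip(m: PowerMap | RelativePowerMap, cfg: AnalysisConfig | None = None
          ) -> VFlipResult:
    """Frequency-variable FLIP: search band combinations, keep max |G|.

    Runs the FLIP core for every band pair satisfying the grid criteria and
    returns the pair (plus full FLIP result) with the highest |G|.
    """
    cfg = cfg or AnalysisConfig()
    rmap, n_orig = _prepare_map(m, cfg)
    if rmap.freqs[-1] < 150.0 - cfg.frequency_bin:
        raise ParameterError(
            f"vFLIP needs the frequency axis to reach 150 Hz; map stops at "
            f"{rmap.freqs[-1]:g} Hz"
        )
    best_key = (-1, -1.0)
    best_bands = None
    for low, high in _vflip_band_pairs(cfg):
        low_map = _band_submatrix(rmap, low)
        high_map = _band_submatrix(rmap, high)
        fit = find_optimal_range(low_map.mean(axis=1), high_map.mean(axis=1),
                                 cfg.min_range_channels,
                                 band_maps=(low_map, high_map))
        opposing = int(fit.slope_sign_alphabeta * fit.slope_sign_gamma == -1)
        key = (opposing, abs(fit.g))
        if key > best_key:
            best_key, best_bands = key, (low, high)
    assert best_bands is not None
    best = _flip_core(rmap, cfg, best_bands[0], best_bands[1], n_orig)
    return VFlipResult(flip=best, low_band=best_bands[0],
                       high_band=best_bands[1])
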