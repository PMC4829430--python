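"""Per-track analysis of tubulin-washout time series.

Each track is a multichannel time series from a single microtubule:
plus-end position, optional EB-GFP intensities at the end and on the
lattice, the soluble-tubulin background, and optionally the end-region
orientation.  The analysis follows the washout-experiment logic:

1. the washout time is the inflection point of an error-function fit to
   the background channel;
2. the growth speed is an OLS slope over a 10 s window ending at washout;
3. the catastrophe is located by fitting the post-washout positions with
   the integral of an error-function speed transition between slow
   shrinkage v1 and fast depolymerisation v2;
4. the catastrophe time is where the speed has completed 25% of the
   transition, t_cat = t0 - 2*sigma*erfinv(0.5);
5. shrinkage and intensity metrics are extracted per track, and cohorts
   are aligned at t_cat for averaging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import erf, erfinv

from .exceptions import (
    FitFailureError,
    InsufficientDataError,
    NoCatastropheError,
    NoWashoutError,
    UndefinedFractionError,
)

__all__ = [
    "Track",
    "CatastropheFit",
    "TrackMetrics",
    "AlignedAverage",
    "detect_washout",
    "growth_speed",
    "fit_catastrophe",
    "catastrophe_time",
    "shrinkage_metrics",
    "intensity_metrics",
    "align_and_average",
    "orientation_analysis",
    "analyze_track",
    "analyze_cohort",
    "CohortResult",
]

#: half-transition point of the 25% speed criterion: erfinv(0.5)
_ERFINV_HALF = float(erfinv(0.5))
#: 5-95% span of an erf transition in units of tau: 4*erfinv(0.9)
_EXCHANGE_FACTOR = 4.0 * float(erfinv(0.9))


@dataclass
class Track:
    """One microtubule's multichannel washout time series.

    ``time`` must be uniformly sampled (within 1%) and strictly increasing;
    optional channels may be None.  Positions in nm, time in s, intensities
    in arbitrary units, orientation in degrees.
    """

    time: np.ndarray
    end_pos: np.ndarray
    background: np.ndarray
    gfp_end: Optional[np.ndarray] = None
    gfp_lattice: Optional[np.ndarray] = None
    orientation: Optional[np.ndarray] = None
    id: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.end_pos = np.asarray(self.end_pos, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        n = self.time.size
        if n < 2:
            raise ValueError("a track needs at least 2 samples")
        for name in ("end_pos", "background"):
            ch = getattr(self, name)
            if ch.shape != self.time.shape:
                raise ValueError(f"channel {name} length mismatch")
            if not np.all(np.isfinite(ch)):
                raise ValueError(f"non-finite values in required channel {name}")
        if not np.all(np.isfinite(self.time)):
            raise ValueError("non-finite time values")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if np.ptp(dt) > 0.01 * dt.mean():
            raise ValueError("time must be uniform within 1%")
        for name in ("gfp_end", "gfp_lattice", "orientation"):
            ch = getattr(self, name)
            if ch is not None:
                ch = np.asarray(ch, dtype=float)
                if ch.shape != self.time.shape:
                    raise ValueError(f"channel {name} length mismatch")
                setattr(self, name, ch)

    @property
    def dt(self) -> float:
        return float(np.diff(self.time).mean())


@dataclass(frozen=True)
class CatastropheFit:
    """Fitted erf speed-transition model of the post-washout trace.

    The speed model is ``0.5(v1+v2) + 0.5(v1-v2) erf((t0-t)/(2 sigma))``:
    slow shrinkage v1 long before t0, fast depolymerisation v2 after.
    Speeds are signed (negative = shrinking); positions are fitted with the
    analytic antiderivative of the speed.
    """

    v1: float  # slow shrinkage speed, nm/s, signed
    v2: float  # fast depolymerisation speed, nm/s, signed
    t0: float  # transition centre, s
    sigma: float  # transition width, s
    t_wo: float  # washout time the fit was anchored at, s
    x_wo: float  # fitted position at t_wo, nm
    rss: float  # residual sum of squares, nm^2

    @property
    def t_cat(self) -> float:
        return catastrophe_time(self)

    def position(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the fitted position model at times ``t``."""
        return _erf_position(
            np.asarray(t, float), self.x_wo, self.v1, self.v2, self.t0, self.sigma, self.t_wo
        )


@dataclass
class TrackMetrics:
    """Per-track derived quantities; NaN where a channel was absent."""

    id: str = ""
    t_wo: float = np.nan  # washout time, s
    exchange_90: float = np.nan  # 5-95% buffer exchange interval, s
    v_g: float = np.nan  # growth speed at washout, nm/s
    t_cat: float = np.nan  # catastrophe time, s
    delay: float = np.nan  # t_cat - t_wo, s
    v_s: float = np.nan  # slow shrinkage speed, nm/s, magnitude
    v_f: float = np.nan  # fast depolymerisation speed, nm/s, magnitude
    sigma_cat: float = np.nan  # transition width, s
    L_shrink_meas: float = np.nan  # fitted-position difference washout->cat, nm
    L_shrink_pred: float = np.nan  # v_s * delay, nm
    I_wo: float = np.nan  # end intensity at washout, a.u.
    I_cat: float = np.nan  # end intensity at catastrophe, a.u.
    I_lat: float = np.nan  # lattice intensity (time average), a.u.
    cap_fraction_cat: float = np.nan  # (I_cat - I_lat)/(I_wo - I_lat)
    orient_mean: float = np.nan  # mean pre-washout orientation, deg
    orient_mag: float = np.nan  # |orient_mean - cohort mean|, deg
    low_confidence: bool = False

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


@dataclass
class AlignedAverage:
    """Cohort mean trace on a common grid relative to catastrophe."""

    grid: np.ndarray  # time relative to t_cat, s
    mean: np.ndarray
    sem: np.ndarray
    n_tracks: np.ndarray  # tracks contributing per grid point
    channel: str
    decay_rate: Optional[float] = None  # 1/s, intensity channel only
    decay_amplitude: Optional[float] = None
    decay_offset: Optional[float] = None


# ---------------------------------------------------------------------------
# washout detection


def _erf_background(t, lo, hi, t_wo, tau):
    return lo + 0.5 * (hi - lo) * (1.0 - erf((t - t_wo) / (2.0 * tau)))


def detect_washout(track: Track) -> tuple[float, float]:
    """Locate the washout time from the soluble-tubulin background drop.

    Fits ``I(t) = lo + 0.5 (hi-lo) (1 - erf((t - t_wo)/(2 tau)))`` over the
    full record and returns ``(t_wo, exchange_90)``, where t_wo is the
    inflection point and exchange_90 = 4 tau erfinv(0.9) is the 5-95%
    exchange interval.

    Raises
    ------
    NoWashoutError
        If no transition is present (amplitude below 5x the noise sd,
        estimated from first differences of the early record) or the fit
        fails.
    """
    t, b = track.time, track.background
    n_edge = max(4, t.size // 10)
    hi0 = float(np.mean(b[:n_edge]))
    lo0 = float(np.mean(b[-n_edge:]))
    noise_sd = float(np.std(np.diff(b[:n_edge]))) / math.sqrt(2.0) if n_edge > 2 else 0.0
    amplitude = hi0 - lo0
    if amplitude <= max(5.0 * noise_sd, 1e-12 * max(abs(hi0), 1.0)):
        raise NoWashoutError(
            f"background drop {amplitude:.3g} below 5x noise sd {noise_sd:.3g}"
        )
    mid = lo0 + 0.5 * amplitude
    below = np.nonzero(b < mid)[0]
    t_wo0 = float(t[below[0]]) if below.size else float(t[t.size // 2])
    dt = track.dt
    try:
        popt, _ = optimize.curve_fit(
            _erf_background,
            t,
            b,
            p0=[lo0, hi0, t_wo0, max(0.25 * dt, 0.02)],
            bounds=([-np.inf, -np.inf, t[0], 1e-6], [np.inf, np.inf, t[-1], t[-1] - t[0]]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        raise NoWashoutError(f"background erf fit failed: {exc}") from exc
    lo, hi, t_wo, tau = popt
    if hi - lo <= 5.0 * noise_sd:
        raise NoWashoutError("fitted background amplitude below 5x noise sd")
    return float(t_wo), float(_EXCHANGE_FACTOR * tau)


# ---------------------------------------------------------------------------
# growth speed


def growth_speed(
    track: Track, t_wo: float, window: float = 10.0, shift: float = 0.0
) -> float:
    """OLS growth speed over [t_wo - shift - window, t_wo - shift] (nm/s)."""
    if window <= 0:
        raise InsufficientDataError("window must be positive")
    lo, hi = t_wo - shift - window, t_wo - shift
    if lo < track.time[0] - 0.5 * track.dt or hi > track.time[-1] + 0.5 * track.dt:
        raise InsufficientDataError(
            f"window [{lo:.2f}, {hi:.2f}] s not covered by the record"
        )
    mask = (track.time >= lo) & (track.time <= hi)
    if mask.sum() < 2:
        raise InsufficientDataError("fewer than 2 samples in the speed window")
    res = stats.linregress(track.time[mask], track.end_pos[mask])
    return float(res.slope)


# ---------------------------------------------------------------------------
# catastrophe fit


def _erf_position(t, x_wo, v1, v2, t0, sigma, t_wo):
    """Antiderivative of 0.5(v1+v2) + 0.5(v1-v2) erf((t0-t)/(2 sigma)).

    With u = (t0 - t)/(2 sigma), d/dt of -2 sigma (u erf u + exp(-u^2)/sqrt(pi))
    is erf(u); the position is anchored so x(t_wo) = x_wo.
    """
    c = 2.0 * sigma

    def G(tt):
        u = (t0 - tt) / c
        return -c * (u * erf(u) + np.exp(-np.clip(u * u, 0.0, 700.0)) / math.sqrt(math.pi))

    return x_wo + 0.5 * (v1 + v2) * (t - t_wo) + 0.5 * (v1 - v2) * (G(t) - G(t_wo))


def fit_catastrophe(track: Track, t_wo: float) -> CatastropheFit:
    """Fit the erf speed-transition model to the post-washout positions.

    Multi-start nonlinear least squares (5 starts jittering the transition
    centre by up to +-1 s); initial values follow the most negative 3-frame
    position drop (t0), an OLS slope over the first half of the segment
    (v1) and over the last second (v2).

    Raises
    ------
    InsufficientDataError
        Fewer than 8 post-washout samples.
    FitFailureError
        No start converges.
    NoCatastropheError
        The converged fit has |v2| <= |v1| (no fast phase).
    """
    mask = track.time >= t_wo - 0.5 * track.dt
    t = track.time[mask]
    x = track.end_pos[mask]
    if t.size < 8:
        raise InsufficientDataError(f"only {t.size} post-washout samples (need >= 8)")
    dt = track.dt

    # --- initial values
    d3 = x[3:] - x[:-3]
    i0 = int(np.argmin(d3))
    t0_init = float(t[i0] + 1.5 * dt)
    half = max(2, t.size // 2)
    v1_init = float(stats.linregress(t[:half], x[:half]).slope)
    n_last = max(2, int(round(1.0 / dt)))
    v2_init = float(stats.linregress(t[-n_last:], x[-n_last:]).slope)
    if v2_init >= v1_init:
        v2_init = v1_init - 100.0
    sigma_init = 0.5
    x_wo_init = float(x[0])

    def residuals(theta):
        x_wo, v1, v2, t0, sigma = theta
        return _erf_position(t, x_wo, v1, v2, t0, sigma, t_wo) - x

    lb = [-np.inf, -np.inf, -np.inf, t[0], 1e-3]
    ub = [np.inf, np.inf, np.inf, t[-1] + 1.0, 10.0]
    best = None
    for jitter in (0.0, -1.0, -0.5, 0.5, 1.0):
        t0_start = min(max(t0_init + jitter, lb[3]), ub[3])
        try:
            sol = optimize.least_squares(
                residuals,
                [x_wo_init, v1_init, v2_init, t0_start, sigma_init],
                bounds=(lb, ub),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
            )
        except ValueError:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitFailureError("catastrophe fit did not converge from any start")
    x_wo, v1, v2, t0, sigma = best.x
    if abs(v2) <= abs(v1):
        raise NoCatastropheError(
            f"no fast depolymerisation phase (|v2|={abs(v2):.3g} <= |v1|={abs(v1):.3g})"
        )
    return CatastropheFit(
        v1=float(v1),
        v2=float(v2),
        t0=float(t0),
        sigma=float(sigma),
        t_wo=float(t_wo),
        x_wo=float(x_wo),
        rss=float(2.0 * best.cost),
    )


def catastrophe_time(fit: CatastropheFit) -> float:
    """Catastrophe time by the 25% speed-transition criterion.

    The speed completes 25% of the v1 -> v2 transition where
    erf((t0 - t)/(2 sigma)) = 0.5, i.e. t_cat = t0 - 2 sigma erfinv(0.5);
    independent of v1 and v2.
    """
    return fit.t0 - 2.0 * fit.sigma * _ERFINV_HALF


# ---------------------------------------------------------------------------
# per-track metrics


def shrinkage_metrics(
    track: Track, fit: CatastropheFit, t_wo: float, t_cat: float
) -> tuple[float, float, float, float, bool]:
    """Slow/fast shrinkage speeds and shrinkage lengths.

    Returns ``(v_s, v_f, L_shrink_meas, L_shrink_pred, low_confidence)``:
    v_s is the magnitude of the OLS slope of the raw positions on
    [t_wo, t_cat]; v_f = |v2|; L_shrink_meas is the fitted-model position
    difference x(t_wo) - x(t_cat); L_shrink_pred = v_s (t_cat - t_wo).
    Fewer than 4 samples between washout and catastrophe flags the result
    as low-confidence (v_s then falls back to |v1|).
    """
    if t_cat < t_wo:
        raise ValueError("t_cat precedes t_wo")
    mask = (track.time >= t_wo - 0.5 * track.dt) & (track.time <= t_cat)
    low_confidence = mask.sum() < 4
    if mask.sum() >= 2:
        v_s = abs(float(stats.linregress(track.time[mask], track.end_pos[mask]).slope))
    else:
        v_s = abs(fit.v1)
    v_f = abs(fit.v2)
    L_meas = float(fit.position(np.array([t_wo]))[0] - fit.position(np.array([t_cat]))[0])
    L_pred = v_s * (t_cat - t_wo)
    return v_s, v_f, L_meas, L_pred, low_confidence


def _window_mean(t: np.ndarray, y: np.ndarray, centre: float, width: float) -> float:
    mask = np.abs(t - centre) <= 0.5 * width
    if not mask.any():
        raise InsufficientDataError(f"no samples within {width} s of t={centre:.2f}")
    return float(np.mean(y[mask]))


def intensity_metrics(
    track: Track, t_wo: float, t_cat: float, window: float = 1.0
) -> tuple[float, float, float, float]:
    """EB-GFP intensity metrics: ``(I_wo, I_cat, I_lat, cap_fraction_cat)``.

    I_wo and I_cat are the end intensity averaged over windows (default
    1 s) centred at washout and catastrophe; I_lat is the time-average of
    the lattice channel; the cap fraction remaining at catastrophe is the
    lattice-subtracted ratio (I_cat - I_lat)/(I_wo - I_lat).
    """
    if track.gfp_end is None or track.gfp_lattice is None:
        raise InsufficientDataError("gfp_end and gfp_lattice channels required")
    I_wo = _window_mean(track.time, track.gfp_end, t_wo, window)
    I_cat = _window_mean(track.time, track.gfp_end, t_cat, window)
    I_lat = float(np.mean(track.gfp_lattice))
    if I_wo <= I_lat:
        raise UndefinedFractionError(
            f"I_wo={I_wo:.3g} does not exceed lattice level {I_lat:.3g}"
        )
    return I_wo, I_cat, I_lat, (I_cat - I_lat) / (I_wo - I_lat)


# ---------------------------------------------------------------------------
# cohort-level operations


def align_and_average(
    tracks: Sequence[Track],
    metrics: Sequence[TrackMetrics],
    channel: str = "gfp_end",
    pitch: float = 0.25,
    min_coverage: float = 0.5,
) -> AlignedAverage:
    """Align tracks at their catastrophe times and average a channel.

    Each track is linearly interpolated onto a common grid (default 0.25 s
    pitch) of times relative to its own t_cat; for the position channel the
    traces are additionally aligned at the catastrophe end position.  The
    grid is restricted to times covered by at least ``min_coverage`` of the
    tracks.  For the intensity channel a mono-exponential
    ``c + A exp(-k (t - t_start))`` is fitted to the mean trace between the
    mean washout time and catastrophe and the decay rate recorded.
    """
    pairs = [
        (tr, m)
        for tr, m in zip(tracks, metrics)
        if np.isfinite(m.t_cat) and (channel == "end_pos" or getattr(tr, channel) is not None)
    ]
    if len(pairs) < 5:
        raise InsufficientDataError(f"need >= 5 analysable tracks, got {len(pairs)}")

    rel_lo = min(tr.time[0] - m.t_cat for tr, m in pairs)
    rel_hi = max(tr.time[-1] - m.t_cat for tr, m in pairs)
    grid = np.arange(math.floor(rel_lo / pitch) * pitch, rel_hi + 0.5 * pitch, pitch)

    values = np.full((len(pairs), grid.size), np.nan)
    post_wo = np.full((len(pairs), grid.size), np.nan)  # post-washout samples only
    for i, (tr, m) in enumerate(pairs):
        rel = tr.time - m.t_cat
        y = tr.end_pos if channel == "end_pos" else getattr(tr, channel)
        if channel == "end_pos":
            y = y - np.interp(0.0, rel, y)  # align at catastrophe end position
        inside = (grid >= rel[0]) & (grid <= rel[-1])
        values[i, inside] = np.interp(grid[inside], rel, y)
        decaying = inside & (grid >= m.t_wo - m.t_cat)
        post_wo[i, decaying] = np.interp(grid[decaying], rel, y)

    n_per_point = np.sum(np.isfinite(values), axis=0)
    keep = n_per_point >= max(2, int(math.ceil(min_coverage * len(pairs))))
    if not keep.any():
        raise InsufficientDataError("no grid point covered by enough tracks")
    grid, values, n_per_point = grid[keep], values[:, keep], n_per_point[keep]
    post_wo = post_wo[:, keep]
    mean = np.nanmean(values, axis=0)
    sd = np.nanstd(values, axis=0, ddof=1)
    sem = sd / np.sqrt(n_per_point)

    out = AlignedAverage(
        grid=grid, mean=mean, sem=sem, n_tracks=n_per_point, channel=channel
    )
    if channel != "end_pos":
        # decay fit on the post-washout portion only: before its own washout
        # a track sits on its pre-washout plateau, which is not part of the
        # cap-decay process and would flatten the fitted rate
        t_wo_rel = float(np.mean([m.t_wo - m.t_cat for _, m in pairs]))
        n_decay = np.sum(np.isfinite(post_wo), axis=0)
        decay_mean = np.full(grid.size, np.nan)
        covered = n_decay > 0
        decay_mean[covered] = np.nanmean(post_wo[:, covered], axis=0)
        fit_mask = (grid >= t_wo_rel) & (grid <= 0.0) & (n_decay >= 2)
        if fit_mask.sum() >= 4:
            tt, yy = grid[fit_mask], decay_mean[fit_mask]
            # the offset of the mono-exponential is the lattice intensity;
            # fixing it at the measured cohort mean keeps the short fit
            # window (typically ~1 decay time) well conditioned
            lattice = [
                float(np.mean(tr.gfp_lattice))
                for tr, _ in pairs
                if tr.gfp_lattice is not None
            ]
            c_fixed = float(np.mean(lattice)) if lattice else None
            try:
                if c_fixed is not None:
                    model = lambda t, a, k: c_fixed + a * np.exp(-k * (t - tt[0]))  # noqa: E731
                    popt, _ = optimize.curve_fit(
                        model, tt, yy, p0=[max(yy[0] - c_fixed, 1e-6), 0.3],
                        bounds=([0.0, 1e-4], [np.inf, 20.0]), maxfev=10000,
                    )
                    out.decay_offset = c_fixed
                    out.decay_amplitude, out.decay_rate = map(float, popt)
                else:
                    model = lambda t, c, a, k: c + a * np.exp(-k * (t - tt[0]))  # noqa: E731
                    c0 = float(0.5 * yy.min())
                    popt, _ = optimize.curve_fit(
                        model, tt, yy, p0=[c0, max(yy[0] - c0, 1e-6), 0.3],
                        bounds=([-np.inf, 0.0, 1e-4], [np.inf, np.inf, 20.0]),
                        maxfev=10000,
                    )
                    out.decay_offset, out.decay_amplitude, out.decay_rate = map(float, popt)
            except (RuntimeError, ValueError):
                pass
    return out


def orientation_analysis(
    tracks: Sequence[Track],
    metrics: Sequence[TrackMetrics],
    window: float = 10.0,
) -> Optional[tuple[np.ndarray, np.ndarray, float, float]]:
    """Pre-washout orientation vs delay: is stability orientation-biased?

    For each track, the orientation is averaged over the ``window`` seconds
    before washout; the statistic correlated with delay is the magnitude of
    the deviation from the cohort mean.  Returns
    ``(orient_mean, orient_mag, pearson_r, p)`` or None (with metric fields
    left NaN) when the channel is missing or degenerate.
    """
    means, delays, idx = [], [], []
    for i, (tr, m) in enumerate(zip(tracks, metrics)):
        if tr.orientation is None or not np.isfinite(m.t_wo) or not np.isfinite(m.delay):
            continue
        mask = (tr.time >= m.t_wo - window) & (tr.time <= m.t_wo)
        if not mask.any():
            continue
        means.append(float(np.mean(tr.orientation[mask])))
        delays.append(m.delay)
        idx.append(i)
    if len(means) < 5:
        return None
    means_arr = np.array(means)
    mags = np.abs(means_arr - means_arr.mean())
    for j, i in enumerate(idx):
        metrics[i].orient_mean = means_arr[j]
        metrics[i].orient_mag = mags[j]
    if np.ptp(mags) == 0.0 or np.ptp(delays) == 0.0:
        return None
    r, p = stats.pearsonr(mags, np.array(delays))
    return means_arr, mags, float(r), float(p)


# ---------------------------------------------------------------------------
# whole-track / whole-cohort drivers


def analyze_track(
    track: Track,
    speed_window: float = 10.0,
    intensity_window: float = 1.0,
) -> TrackMetrics:
    """Run the full per-track pipeline and collect TrackMetrics.

    Propagates NoWashoutError / NoCatastropheError / FitFailureError /
    InsufficientDataError; intensity metrics are skipped quietly when the
    GFP channels are absent.
    """
    m = TrackMetrics(id=track.id)
    m.t_wo, m.exchange_90 = detect_washout(track)
    m.v_g = growth_speed(track, m.t_wo, window=speed_window)
    fit = fit_catastrophe(track, m.t_wo)
    m.t_cat = catastrophe_time(fit)
    m.delay = m.t_cat - m.t_wo
    if m.delay <= 0:
        raise NoCatastropheError(f"non-positive delay {m.delay:.3f} s")
    m.sigma_cat = fit.sigma
    m.v_s, m.v_f, m.L_shrink_meas, m.L_shrink_pred, m.low_confidence = shrinkage_metrics(
        track, fit, m.t_wo, m.t_cat
    )
    if track.gfp_end is not None and track.gfp_lattice is not None:
        m.I_wo, m.I_cat, m.I_lat, m.cap_fraction_cat = intensity_metrics(
            track, m.t_wo, m.t_cat, window=intensity_window
        )
    return m


@dataclass
class CohortResult:
    """Outcome of analysing a cohort: analysable tracks and their metrics."""

    tracks: list[Track]
    metrics: list[TrackMetrics]
    frame: pd.DataFrame
    statuses: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_ok(self) -> int:
        return len(self.tracks)


def analyze_cohort(
    tracks: Iterable[Track],
    speed_window: float = 10.0,
    intensity_window: float = 1.0,
) -> CohortResult:
    """Analyse every track; failures are excluded and logged, never dropped.

    ``result.statuses`` lists ``(track_id, status)`` with status 'ok' or
    the failure reason, keeping exclusions auditable.
    """
    metrics: list[TrackMetrics] = []
    statuses: list[tuple[str, str]] = []
    kept_tracks: list[Track] = []
    for track in tracks:
        try:
            m = analyze_track(
                track, speed_window=speed_window, intensity_window=intensity_window
            )
        except (
            NoWashoutError,
            NoCatastropheError,
            FitFailureError,
            InsufficientDataError,
            UndefinedFractionError,
        ) as exc:
            statuses.append((track.id, f"{type(exc).__name__}: {exc}"))
            continue
        metrics.append(m)
        kept_tracks.append(track)
        statuses.append((track.id, "ok"))
    orientation_analysis(kept_tracks, metrics)
    frame = pd.DataFrame([m.as_dict() for m in metrics])
    return CohortResult(tracks=kept_tracks, metrics=metrics, frame=frame, statuses=statuses)
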