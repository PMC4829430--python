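"""Cohort-level correlation statistics and the relative-variance D.

Rank correlations (Spearman) quantify how strongly the delay time after
washout tracks momentary quantities such as the growth speed or the EB end
intensity; re-measuring those quantities in windows shifted away from the
washout point probes the seconds-scale memory of microtubule stability.
The relative variance D = var/mean of an intensity series distinguishes
genuine cap-size variability from measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .exceptions import InsufficientDataError, UndefinedCorrelationError
from .trace_analysis import Track, TrackMetrics, growth_speed, _window_mean

__all__ = [
    "CorrelationResult",
    "spearman",
    "correlation_vs_shift",
    "relative_variance",
    "relative_variance_cohort",
]


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    n: int
    shift: Optional[float] = None  # s, when from a shifted-window analysis
    quantity: str = ""


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with midrank ties and t-approximation p.

    The two-sided p-value comes from t = rho sqrt((n-2)/(1-rho^2)) on n-2
    degrees of freedom (adequate for the cohort sizes used here; an exact
    permutation computation is feasible only for tiny n).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if x.size < 5:
        raise InsufficientDataError(f"need >= 5 pairs, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant input")
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), p=float(p), n=int(x.size))


def correlation_vs_shift(
    tracks: Sequence[Track],
    metrics: Sequence[TrackMetrics],
    quantity: str,
    shifts: Sequence[float],
    speed_window: float = 10.0,
    intensity_window: float = 1.0,
) -> list[CorrelationResult]:
    """Correlation of the delay with a quantity measured in shifted windows.

    ``quantity`` is 'growth_speed' (OLS slope over 10 s windows) or
    'gfp_intensity' (mean end intensity over 1 s windows); each window ends
    ``shift`` seconds before washout.  Tracks whose record does not cover a
    window are dropped for that shift, and the per-shift pair count n is
    reported.
    """
    if quantity not in ("growth_speed", "gfp_intensity"):
        raise ValueError(f"unknown quantity {quantity!r}")
    out: list[CorrelationResult] = []
    for shift in shifts:
        values, delays = [], []
        for tr, m in zip(tracks, metrics):
            if not (np.isfinite(m.t_wo) and np.isfinite(m.delay)):
                continue
            try:
                if quantity == "growth_speed":
                    v = growth_speed(tr, m.t_wo, window=speed_window, shift=shift)
                else:
                    if tr.gfp_end is None:
                        continue
                    centre = m.t_wo - shift - 0.5 * intensity_window
                    if centre - 0.5 * intensity_window < tr.time[0]:
                        continue
                    v = _window_mean(tr.time, tr.gfp_end, centre, intensity_window)
            except InsufficientDataError:
                continue
            values.append(v)
            delays.append(m.delay)
        res = spearman(values, delays)
        out.append(
            CorrelationResult(
                rho=res.rho, p=res.p, n=res.n, shift=float(shift), quantity=quantity
            )
        )
    return out


def relative_variance(series: Sequence[float], min_length: int = 100) -> float:
    """Relative variance D = var/mean of one microtubule's intensity series.

    For a Poisson-distributed photon count D = 1; cap-size fluctuations on
    top of measurement noise inflate D, while a constant-density control
    (e.g. a GTPgammaS lattice) shows only the noise floor.  Scales linearly
    with the intensity: D(cX) = c D(X).
    """
    x = np.asarray(series, float)
    if x.size < min_length:
        raise InsufficientDataError(f"need >= {min_length} frames, got {x.size}")
    mean = float(np.mean(x))
    if mean <= 0:
        raise ValueError(f"non-positive mean {mean:.3g}")
    return float(np.var(x, ddof=1) / mean)


def relative_variance_cohort(
    series_list: Sequence[Sequence[float]], min_length: int = 100
) -> tuple[float, float, np.ndarray]:
    """Per-microtubule D values with their cohort mean and sd."""
    ds = np.array([relative_variance(s, min_length=min_length) for s in series_list])
    sd = float(np.std(ds, ddof=1)) if ds.size > 1 else np.nan
    return float(np.mean(ds)), sd, ds
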