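"""Closed-form kinetics of the EB-binding-site cap after tubulin washout.

A microtubule growing at speed ``v_g`` forms EB binding sites at its end
which mature into ordinary lattice sites at a first-order rate ``k_m``.
Treating the microtubule as an effective one-dimensional filament with
``n_pf`` protofilaments of dimer length ``l_dim``, the linear density of
binding sites behind the end is exponential with comet length
``L_comet = v_g / k_m``.  After sudden tubulin removal the cap decays by two
processes: continued maturation everywhere (rate ``k_m``) and slow shrinkage
of the end at speed ``v_s``, which together give a cap decay rate

    k_cap = k_m * (v_s / v_g + 1).

Catastrophe is modelled as a kinetic threshold: the delay between washout
and catastrophe is the time at which a chosen cap observable (terminal site
density, total site number, or the number of sites within a window ``L`` of
the end) falls to a critical value.  This module provides those closed
forms, their two-step-maturation variants (an extra fast first step
``k_1``), and simple error propagation for delay predictions.

Units are fixed package-wide: nm, s, sites; intensities in arbitrary units
with an explicit proportionality factor ``F`` (a.u. * s / nm).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "KineticParams",
    "ThresholdSpec",
    "CapPrediction",
    "site_density",
    "total_sites",
    "cap_decay_rate",
    "delay_from_intensity_ratio",
    "delay_dispersion",
    "delay_end_density",
    "delay_total_number",
    "sites_in_window",
    "delay_window_L",
    "intensity_predictions",
    "two_step_end_density",
    "two_step_total",
    "delay_two_step",
]

THRESHOLD_MODELS = (
    "end_density",
    "total_number",
    "window_L",
    "end_density_2step",
    "total_number_2step",
)


@dataclass(frozen=True)
class KineticParams:
    """Kinetic state of one growth condition.

    Parameters
    ----------
    v_g : float
        Growth speed before washout (nm/s), > 0.
    v_s : float
        Slow shrinkage speed after washout (nm/s), >= 0.
    k_m : float
        Maturation rate of EB binding sites into lattice (1/s), > 0.
    k_1 : float, optional
        First-step maturation rate for the two-step scheme A -> B -> C
        (1/s); must exceed ``k_m`` when set.
    n_pf : int
        Protofilament count (default 13).
    l_dim : float
        Tubulin dimer length (nm, default 8).
    """

    v_g: float
    v_s: float = 0.0
    k_m: float = 0.16
    k_1: Optional[float] = None
    n_pf: int = 13
    l_dim: float = 8.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.v_g) and self.v_g > 0):
            raise ValueError(f"v_g must be positive and finite, got {self.v_g}")
        if not (np.isfinite(self.v_s) and self.v_s >= 0):
            raise ValueError(f"v_s must be non-negative, got {self.v_s}")
        if not (np.isfinite(self.k_m) and self.k_m > 0):
            raise ValueError(f"k_m must be positive, got {self.k_m}")
        if self.k_1 is not None and not (np.isfinite(self.k_1) and self.k_1 > self.k_m):
            raise ValueError(f"k_1 must exceed k_m, got k_1={self.k_1}, k_m={self.k_m}")
        if self.n_pf <= 0 or self.l_dim <= 0:
            raise ValueError("protofilament geometry must be positive")

    @property
    def n_x0(self) -> float:
        """Maximal linear binding-site density n_pf / l_dim (sites/nm)."""
        return self.n_pf / self.l_dim

    @property
    def comet_length(self) -> float:
        """Spatial decay length of the binding region, v_g / k_m (nm)."""
        return self.v_g / self.k_m

    def with_(self, **kw) -> "KineticParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class ThresholdSpec:
    """Which catastrophe-threshold model applies and its parameter(s).

    Exactly the parameters relevant to ``model`` must be set:

    - ``end_density``: f_crit, the fractional terminal site density.
    - ``total_number``: N_crit, the critical total site number.
    - ``window_L``: L (nm) and NL_crit, the critical number within L.
    - ``end_density_2step``: f_crit (fraction of n_x0 for the A+B density).
    - ``total_number_2step``: N_crit (critical total A+B number).
    """

    model: str
    f_crit: Optional[float] = None
    N_crit: Optional[float] = None
    L: Optional[float] = None
    NL_crit: Optional[float] = None

    _REQUIRED = {
        "end_density": ("f_crit",),
        "total_number": ("N_crit",),
        "window_L": ("L", "NL_crit"),
        "end_density_2step": ("f_crit",),
        "total_number_2step": ("N_crit",),
    }

    def __post_init__(self) -> None:
        if self.model not in THRESHOLD_MODELS:
            raise ValueError(f"unknown threshold model {self.model!r}")
        required = self._REQUIRED[self.model]
        for name in ("f_crit", "N_crit", "L", "NL_crit"):
            value = getattr(self, name)
            if name in required:
                if value is None or not np.isfinite(value) or value <= 0:
                    raise ValueError(f"{self.model} requires positive {name}")
            elif value is not None:
                raise ValueError(f"{name} is not a parameter of {self.model}")
        if self.f_crit is not None and self.f_crit > 1.0:
            raise ValueError("f_crit must lie in (0, 1]")


@dataclass(frozen=True)
class CapPrediction:
    """A predicted washout-to-catastrophe delay and its consequences."""

    delay: float  # s
    shrink_length: float  # nm, = v_s * delay
    decay_rate: float  # 1/s, cap decay rate k_m*(v_s/v_g + 1)
    delay_sd: Optional[float] = None
    shrink_sd: Optional[float] = None


def _check_nonneg(name: str, value: float) -> None:
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be non-negative and finite, got {value}")


def site_density(x: float, t: float, p: KineticParams) -> float:
    """Linear density of EB binding sites (sites/nm).

    ``x`` is the distance behind the (possibly shrinking) cap origin, ``t``
    the time since washout; the density is the exponential comet profile
    decayed uniformly by maturation::

        n(x, t) = n_x0 * exp(-x * k_m / v_g) * exp(-k_m * t)

    Monotone non-increasing in both arguments.
    """
    _check_nonneg("x", x)
    _check_nonneg("t", t)
    return p.n_x0 * math.exp(-x * p.k_m / p.v_g) * math.exp(-p.k_m * t)


def cap_decay_rate(p: KineticParams) -> float:
    """Decay rate of the total cap (and of its terminal density), 1/s.

    Both slow shrinkage (eats sites from the end) and maturation (converts
    sites everywhere) contribute::

        k_cap = k_m * (v_s / v_g + 1)

    Always >= k_m; equality iff v_s = 0.
    """
    return p.k_m * (p.v_s / p.v_g + 1.0)


def total_sites(t: float, p: KineticParams) -> float:
    """Total number of EB binding sites a time ``t`` after washout.

    Integrating the decaying exponential profile from the shrinking front
    (at v_s * t in the lab frame) to infinity gives::

        N(t) = n_x0 * (v_g / k_m) * exp(-k_m * (v_s / v_g + 1) * t)
    """
    _check_nonneg("t", t)
    return p.n_x0 * p.v_g / p.k_m * math.exp(-cap_decay_rate(p) * t)


def delay_from_intensity_ratio(I0: float, Icat: float, k: float) -> float:
    """Delay implied by the cap-intensity ratio at catastrophe vs washout.

    Since the lattice-subtracted cap intensity decays as exp(-k t), the
    time to reach the fraction Icat/I0 of the initial cap is
    -ln(Icat/I0) / k.
    """
    if not (np.isfinite(I0) and np.isfinite(Icat) and I0 > 0 and Icat > 0):
        raise ValueError("intensities must be positive and finite")
    if Icat > I0:
        raise ValueError(f"Icat={Icat} exceeds I0={I0}")
    if not (np.isfinite(k) and k > 0):
        raise ValueError(f"decay rate must be positive, got {k}")
    return -math.log(Icat / I0) / k


def delay_dispersion(
    mean_I0: float,
    sd_I0: float,
    mean_Icat: float,
    sd_Icat: float,
    sd_lattice: float,
    k: float,
    v_s: Optional[float] = None,
) -> tuple[float, Optional[float]]:
    """First-order propagated sd of the predicted delay (and shrinkage).

    The measured sd of the end signal mixes true cap-size variability with
    measurement noise; the lattice-signal sd serves as a noise estimate, so
    the intrinsic cap sd is sqrt(sd^2 - sd_lattice^2) at each time point
    (clamped to 0 with a warning if noise exceeds signal sd).  Propagating
    through T = -ln(Icat/I0)/k::

        sd(T) = (1/k) * sqrt((s0/I0)^2 + (scat/Icat)^2)

    Returns ``(delay_sd, shrink_sd)``; the latter is ``v_s * delay_sd`` or
    None when ``v_s`` is not given.
    """
    for name, val in (("mean_I0", mean_I0), ("mean_Icat", mean_Icat), ("k", k)):
        if not (np.isfinite(val) and val > 0):
            raise ValueError(f"{name} must be positive, got {val}")
    for name, val in (("sd_I0", sd_I0), ("sd_Icat", sd_Icat), ("sd_lattice", sd_lattice)):
        _check_nonneg(name, val)

    def intrinsic(sd: float) -> float:
        if sd < sd_lattice:
            warnings.warn(
                "lattice sd exceeds end-signal sd; intrinsic cap sd clamped to 0",
                RuntimeWarning,
                stacklevel=2,
            )
            return 0.0
        return math.sqrt(sd * sd - sd_lattice * sd_lattice)

    s0 = intrinsic(sd_I0)
    scat = intrinsic(sd_Icat)
    delay_sd = math.sqrt((s0 / mean_I0) ** 2 + (scat / mean_Icat) ** 2) / k
    shrink_sd = None if v_s is None else v_s * delay_sd
    return delay_sd, shrink_sd


def _prediction(p: KineticParams, delay: float) -> CapPrediction:
    return CapPrediction(
        delay=delay, shrink_length=p.v_s * delay, decay_rate=cap_decay_rate(p)
    )


def delay_end_density(p: KineticParams, f_crit: float) -> CapPrediction:
    """Delay until the terminal site density falls to the fraction f_crit.

    The terminal density decays at the cap decay rate, so the delay is
    -ln(f_crit) / (k_m * (v_s/v_g + 1)) — independent of the cap length
    v_g/k_m at fixed decay rate.
    """
    if not (np.isfinite(f_crit) and 0.0 < f_crit <= 1.0):
        raise ValueError(f"f_crit must lie in (0, 1], got {f_crit}")
    return _prediction(p, -math.log(f_crit) / cap_decay_rate(p))


def delay_total_number(p: KineticParams, N_crit: float) -> CapPrediction:
    """Delay until the total site number falls to N_crit.

    Because the initial total N(0) = n_x0 * v_g / k_m grows with cap length,
    this model predicts a steeper increase of delays with growth speed than
    the end-density model.
    """
    N0 = total_sites(0.0, p)
    if not (np.isfinite(N_crit) and 0.0 < N_crit <= N0):
        raise ValueError(f"N_crit must lie in (0, N(0)={N0:.4g}], got {N_crit}")
    return _prediction(p, -math.log(N_crit / N0) / cap_decay_rate(p))


def sites_in_window(t: float, p: KineticParams, L: float) -> float:
    """Number of binding sites within a window of length L behind the end.

    N_L(t) = n_x0 * (v_g/k_m) * (1 - exp(-k_m L / v_g)) * exp(-k_cap t);
    recovers ``total_sites`` as L -> infinity and n_x0 * L as L -> 0.
    """
    if not (np.isfinite(L) and L > 0):
        raise ValueError(f"L must be positive, got {L}")
    _check_nonneg("t", t)
    return (
        p.n_x0
        * p.v_g
        / p.k_m
        * -math.expm1(-p.k_m * L / p.v_g)
        * math.exp(-cap_decay_rate(p) * t)
    )


def delay_window_L(p: KineticParams, L: float, NL_crit: float) -> CapPrediction:
    """Delay until the site number within L of the end falls to NL_crit."""
    NL0 = sites_in_window(0.0, p, L)
    if not (np.isfinite(NL_crit) and 0.0 < NL_crit <= NL0):
        raise ValueError(f"NL_crit must lie in (0, N_L(0)={NL0:.4g}], got {NL_crit}")
    return _prediction(p, -math.log(NL_crit / NL0) / cap_decay_rate(p))


def intensity_predictions(
    F: float, p: KineticParams, L: float, NL_crit: float
) -> tuple[float, float]:
    """Predicted lattice-subtracted cap intensities at washout and catastrophe.

    With a camera proportionality factor F (a.u. * s / nm):

    - at washout the cap intensity is proportional to the total site number,
      I(0) = F * v_g;
    - at the window-L catastrophe time, I(T_L) scales with the critical
      number: I(T_L) = F * NL_crit * (l_dim/n_pf) * k_m / (1 - exp(-k_m L / v_g)).
    """
    if not (np.isfinite(F) and F > 0):
        raise ValueError(f"F must be positive, got {F}")
    if not (np.isfinite(L) and L > 0):
        raise ValueError(f"L must be positive, got {L}")
    I_wo = F * p.v_g
    I_cat = F * NL_crit / p.n_x0 * p.k_m / (-math.expm1(-p.k_m * L / p.v_g))
    return I_wo, I_cat


def _require_two_step(p: KineticParams) -> float:
    if p.k_1 is None:
        raise ValueError("two-step formulas require k_1")
    if p.k_1 == p.k_m:
        raise ValueError("k_1 = k_m is singular; perturb k_1")
    return p.k_1


def two_step_end_density(t: float, p: KineticParams) -> float:
    """Terminal density of A+B sites for two-step maturation (sites/nm).

    With A -> B at k_1 (A: freshly added, not yet EB-binding but
    stabilising; B: EB-binding) and B -> C at k_m, the terminal density of
    stabilising sites is::

        n_AB(t) = n_x0 / (k_1 - k_m) * (k_1 e^{-k_m a t} - k_m e^{-k_1 a t})

    with a = v_s/v_g + 1.  Equals n_x0 at t = 0 and reduces to the one-step
    expression for k_1 >> k_m.
    """
    _check_nonneg("t", t)
    k1 = _require_two_step(p)
    a = p.v_s / p.v_g + 1.0
    return (
        p.n_x0
        / (k1 - p.k_m)
        * (k1 * math.exp(-p.k_m * a * t) - p.k_m * math.exp(-k1 * a * t))
    )


def two_step_total(t: float, p: KineticParams) -> float:
    """Total number of A+B sites for two-step maturation.

    N_AB(t) = n_x0 * v_g / (k_1 - k_m) *
              ((k_1/k_m) e^{-k_m a t} - (k_m/k_1) e^{-k_1 a t}),  a = v_s/v_g + 1.
    """
    _check_nonneg("t", t)
    k1 = _require_two_step(p)
    a = p.v_s / p.v_g + 1.0
    return (
        p.n_x0
        * p.v_g
        / (k1 - p.k_m)
        * (
            (k1 / p.k_m) * math.exp(-p.k_m * a * t)
            - (p.k_m / k1) * math.exp(-k1 * a * t)
        )
    )


def delay_two_step(p: KineticParams, spec: ThresholdSpec) -> CapPrediction:
    """Delay for the two-step threshold models, by bracketed root finding.

    The A+B density/number is strictly decreasing in t for k_1 > k_m, so the
    threshold crossing is unique; it is bracketed on [0, 10/k_m] and solved
    with Brent's method to 1e-6 s.
    """
    _require_two_step(p)
    if spec.model == "end_density_2step":
        threshold = spec.f_crit * p.n_x0
        value = lambda t: two_step_end_density(t, p)  # noqa: E731
    elif spec.model == "total_number_2step":
        threshold = spec.N_crit
        value = lambda t: two_step_total(t, p)  # noqa: E731
    else:
        raise ValueError(f"spec.model must be a 2-step model, got {spec.model!r}")

    v0 = value(0.0)
    if threshold > v0:
        raise ValueError(
            f"threshold {threshold:.4g} exceeds the value at washout {v0:.4g}"
        )
    if threshold == v0:
        return _prediction(p, 0.0)
    t_hi = 10.0 / p.k_m
    if value(t_hi) - threshold > 0:
        raise RuntimeError("no sign change in the root bracket [0, 10/k_m]")
    delay = brentq(lambda t: value(t) - threshold, 0.0, t_hi, xtol=1e-6)
    return _prediction(p, delay)


def delay_for_threshold(p: KineticParams, spec: ThresholdSpec) -> CapPrediction:
    """Dispatch a ThresholdSpec to the matching delay formula."""
    if spec.model == "end_density":
        return delay_end_density(p, spec.f_crit)
    if spec.model == "total_number":
        return delay_total_number(p, spec.N_crit)
    if spec.model == "window_L":
        return delay_window_L(p, spec.L, spec.NL_crit)
    return delay_two_step(p, spec)
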