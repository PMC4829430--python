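"""EB comet profiles: averaging and exponential-convolved-Gaussian fits.

The spatial density of EB binding sites behind a growing end is
exponential with decay length L_comet = v_g / k_m, sitting on a constant
lattice-binding step.  A fluorescence line profile is this density
convolved with the microscope point-spread function, modelled as a
Gaussian.  Fitting the closed-form convolution to an averaged profile
yields L_comet, and with the growth speed the maturation rate
k_m = v_g / L_comet.

Coordinates: x increases from the detected microtubule end toward the
lattice (i.e. backwards along the filament), in nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import erf, erfc, erfcx

from .exceptions import FitFailureError

__all__ = ["CometProfile", "CometFit", "comet_model", "build_average_comet", "fit_comet"]


@dataclass(frozen=True)
class CometProfile:
    """An averaged one-dimensional comet intensity profile."""

    x: np.ndarray  # nm, uniform pitch, increasing toward the lattice
    intensity: np.ndarray  # a.u.
    n_frames: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        if self.x.size < 4 or self.x.shape != self.intensity.shape:
            raise ValueError("profile needs matching x/intensity arrays (>= 4 points)")
        dx = np.diff(self.x)
        if np.any(dx <= 0) or np.ptp(dx) > 1e-6 * dx.mean():
            raise ValueError("x must be uniformly increasing")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    @property
    def pitch(self) -> float:
        return float(np.diff(self.x).mean())


@dataclass(frozen=True)
class CometFit:
    """Fitted comet parameters; ``k_m = v_g / L_comet`` by definition."""

    L_comet: float  # nm
    sigma_psf: float  # nm
    xc: float  # nm, offset of the binding-region start from the detected end
    amp: float  # a.u.
    lattice_level: float  # a.u.
    v_g: float  # nm/s used to convert to a rate
    rss: float = np.nan

    @property
    def k_m(self) -> float:
        return self.v_g / self.L_comet


def comet_model(
    x: np.ndarray,
    amp: float,
    L_comet: float,
    sigma_psf: float,
    xc: float,
    lattice_level: float,
) -> np.ndarray:
    """Closed-form convolution of the comet density with a Gaussian PSF.

    The underlying density is ``amp * exp(-x'/L) * 1{x' >= 0} +
    lattice_level * 1{x' >= 0}`` with x' = x - xc, convolved with a
    unit-area Gaussian of width sigma_psf.  The exponential part is the
    exponentially-modified-Gaussian closed form (written via the scaled
    complementary error function for numerical stability), the lattice part
    an erf step::

        I(x) = amp/2 * erfcx((s/L - z/s)/sqrt(2)) * exp(-z^2/(2 s^2))
             + lattice_level/2 * (1 + erf(z/(s sqrt(2))))

    with z = x - xc, s = sigma_psf.  Asymptotics: 0 as x -> -inf,
    lattice_level as x -> +inf; reduces to the unconvolved profile as
    sigma_psf -> 0.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    z = x - xc
    s = sigma_psf
    if s <= 0 or L_comet <= 0:
        raise ValueError("sigma_psf and L_comet must be positive")
    arg = (s / L_comet - z / s) / math.sqrt(2.0)
    # two numerically stable branches of exp(s^2/2L^2 - z/L) * erfc(arg):
    # erfcx form for arg >= 0 (z small/negative), direct form otherwise
    # (there the plain exponent is negative and cannot overflow)
    emg = np.empty_like(z, dtype=float)
    pos = arg >= 0.0
    emg[pos] = erfcx(arg[pos]) * np.exp(-0.5 * (z[pos] / s) ** 2)
    emg[~pos] = erfc(arg[~pos]) * np.exp(0.5 * (s / L_comet) ** 2 - z[~pos] / L_comet)
    emg *= 0.5 * amp
    step = 0.5 * lattice_level * (1.0 + erf(z / (s * math.sqrt(2.0))))
    return emg + step


def build_average_comet(profile_stack: np.ndarray, x: np.ndarray) -> CometProfile:
    """Average a stack of per-frame line profiles aligned at the end.

    ``profile_stack`` has shape (n_frames, n_pixels); all frames share the
    pixel grid ``x``.
    """
    stack = np.asarray(profile_stack, dtype=float)
    if stack.ndim != 2 or stack.shape[0] < 1:
        raise ValueError("profile_stack must be a non-empty 2-D array")
    x = np.asarray(x, dtype=float)
    if x.shape != (stack.shape[1],):
        raise ValueError("x grid does not match the stack's pixel dimension")
    return CometProfile(x=x, intensity=stack.mean(axis=0), n_frames=stack.shape[0])


def fit_comet(profile: CometProfile, v_g: float) -> CometFit:
    """Fit the convolved comet model; derive k_m = v_g / L_comet.

    Raises FitFailureError on non-convergence, a decay length at its
    bounds, or a profile too flat / too short (the record should span a
    few decay lengths behind the end) to constrain the fit.
    """
    if v_g <= 0:
        raise ValueError("v_g must be positive")
    x, y = profile.x, profile.intensity
    span = x[-1] - x[0]
    n_tail = max(2, x.size // 10)
    lat0 = float(np.mean(y[-n_tail:]))
    peak_idx = int(np.argmax(y))
    amp0 = float(y[peak_idx] - lat0)
    if amp0 <= 0:
        raise FitFailureError("no comet peak above the lattice level")
    # crude decay-length start: area of the lattice-subtracted tail over amp
    tail = np.clip(y[peak_idx:] - lat0, 0.0, None)
    L0 = float(np.trapezoid(tail, x[peak_idx:]) / amp0) if tail.size > 1 else 0.2 * span
    L0 = min(max(L0, 2.0 * profile.pitch), 0.5 * span)
    p0 = [amp0, L0, max(profile.pitch, 0.2 * L0), float(x[peak_idx]), lat0]
    lb = [0.0, 0.5 * profile.pitch, 0.3 * profile.pitch, x[0] - span, -np.inf]
    ub = [np.inf, 5.0 * span, span, x[-1], np.inf]
    try:
        popt, _ = optimize.curve_fit(
            comet_model, x, y, p0=p0, bounds=(lb, ub), maxfev=20000
        )
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(f"comet fit failed: {exc}") from exc
    amp, L, s, xc, lat = map(float, popt)
    if not (lb[1] * 1.5 < L < ub[1] / 1.5):
        raise FitFailureError(f"decay length {L:.3g} nm at fit bounds")
    resid = comet_model(x, *popt) - y
    resid_sd = float(np.std(resid, ddof=min(5, resid.size - 1)))
    if amp <= 5.0 * resid_sd:
        raise FitFailureError("comet amplitude indistinguishable from noise")
    return CometFit(
        L_comet=L,
        sigma_psf=s,
        xc=xc,
        amp=amp,
        lattice_level=lat,
        v_g=float(v_g),
        rss=float(np.sum(resid**2)),
    )
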