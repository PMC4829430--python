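"""Speed-sorted fitting of the catastrophe-threshold models.

Because growth-speed distributions of different conditions overlap, tracks
are sorted by their measured pre-washout speed into equal-size groups and
the models are fitted to the group means (weighted by 1/sem^2), exactly as
the averaged data are fitted rather than individual tracks.  Model
comparison uses the reduced chi-square.

The free parameter of each one-parameter model:

- ``end_density``: f_crit, the critical fraction of terminal site density;
- ``total_number``: N_crit, the critical total site number;
- two-step variants: the same thresholds applied to the A+B observables,
  with the first-step rate fixed at a chosen multiple of k_m.

The window-L model is fitted globally over several datasets at fixed L
(free: one NL_crit per dataset and one camera factor F per intensity
dataset), scanning L to produce a reduced-chi-square curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import cap_models as cm
from .exceptions import FitFailureError, InsufficientDataError

__all__ = [
    "SpeedGroups",
    "FitResult",
    "speed_sort",
    "vs_vg_relation",
    "fit_threshold",
    "global_fit_L",
    "reduced_chi2",
]

VsModel = Union[float, tuple[float, float]]  # fixed v_s, or (a, b) in v_s = a v_g + b


def _vs_at(vs_model: VsModel, v_g: float) -> float:
    if isinstance(vs_model, (tuple, list)):
        a, b = vs_model
        return a * v_g + b
    return float(vs_model)


@dataclass
class SpeedGroups:
    """Group means of speed-sorted per-track metrics (sem-weighted fits)."""

    v_g: np.ndarray  # group mean growth speeds, nm/s, increasing
    v_g_sem: np.ndarray
    delay: np.ndarray  # group mean delays, s
    delay_sem: np.ndarray
    n: np.ndarray  # group sizes
    I_wo: Optional[np.ndarray] = None
    I_wo_sem: Optional[np.ndarray] = None
    I_cat: Optional[np.ndarray] = None
    I_cat_sem: Optional[np.ndarray] = None
    label: str = ""

    @property
    def n_groups(self) -> int:
        return self.v_g.size


@dataclass
class FitResult:
    """A fitted threshold model with goodness of fit."""

    model: str
    params: dict = field(default_factory=dict)
    param_se: dict = field(default_factory=dict)
    chi2_red: float = np.nan
    n_points: int = 0
    n_free: int = 0
    at_bound: bool = False


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, float)
    if x.size < 2:
        return np.nan
    return float(np.std(x, ddof=1) / math.sqrt(x.size))


def speed_sort(metrics: pd.DataFrame, n_groups: int) -> SpeedGroups:
    """Sort tracks by measured v_g into contiguous equal-size groups.

    The remainder (when the track count is not divisible) is distributed to
    the slowest groups; ties in v_g are broken by a stable sort, so the
    grouping is deterministic.  Returns per-group means and sems of v_g,
    delay, and (when present) lattice-subtracted intensities I_wo and
    I_cat.
    """
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    n = len(metrics)
    if n < 2 * n_groups:
        raise InsufficientDataError(f"{n} tracks cannot fill {n_groups} groups of >= 2")
    order = np.argsort(metrics["v_g"].to_numpy(), kind="stable")
    base, rem = divmod(n, n_groups)
    sizes = [base + 1 if g < rem else base for g in range(n_groups)]

    has_intensity = (
        "I_wo" in metrics.columns
        and "I_cat" in metrics.columns
        and "I_lat" in metrics.columns
        and np.isfinite(metrics["I_wo"].to_numpy()).all()
    )
    cols: dict[str, list[list[float]]] = {k: [] for k in ("v_g", "delay", "I_wo", "I_cat")}
    counts = []
    start = 0
    for size in sizes:
        idx = order[start : start + size]
        start += size
        sub = metrics.iloc[idx]
        cols["v_g"].append(sub["v_g"].to_numpy())
        cols["delay"].append(sub["delay"].to_numpy())
        if has_intensity:
            cols["I_wo"].append((sub["I_wo"] - sub["I_lat"]).to_numpy())
            cols["I_cat"].append((sub["I_cat"] - sub["I_lat"]).to_numpy())
        counts.append(size)

    def mean_sem(groups):
        return (
            np.array([np.mean(g) for g in groups]),
            np.array([_sem(g) for g in groups]),
        )

    v_g, v_g_sem = mean_sem(cols["v_g"])
    delay, delay_sem = mean_sem(cols["delay"])
    out = SpeedGroups(
        v_g=v_g, v_g_sem=v_g_sem, delay=delay, delay_sem=delay_sem, n=np.array(counts)
    )
    if has_intensity:
        out.I_wo, out.I_wo_sem = mean_sem(cols["I_wo"])
        out.I_cat, out.I_cat_sem = mean_sem(cols["I_cat"])
    return out


def vs_vg_relation(metrics: pd.DataFrame) -> tuple[float, float]:
    """OLS fit of the slow-shrinkage vs growth-speed relation v_s = a v_g + b."""
    sub = metrics.dropna(subset=["v_g", "v_s"])
    if len(sub) < 10:
        raise InsufficientDataError(f"need >= 10 tracks with v_s and v_g, got {len(sub)}")
    v_g = sub["v_g"].to_numpy()
    if np.ptp(v_g) <= 1e-9:
        raise ValueError("degenerate v_g spread")
    res = stats.linregress(v_g, sub["v_s"].to_numpy())
    return float(res.slope), float(res.intercept)


def reduced_chi2(
    observed: np.ndarray,
    predicted: np.ndarray,
    sems: np.ndarray,
    n_free: int,
) -> float:
    """Sum(((obs - pred)/sem)^2) / (n_points - n_free)."""
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    sems = np.asarray(sems, float)
    if np.any(sems <= 0) or not np.all(np.isfinite(sems)):
        raise ValueError("sems must be positive")
    if observed.size <= n_free:
        raise ValueError("need n_points > n_free")
    return float(np.sum(((observed - predicted) / sems) ** 2) / (observed.size - n_free))


def _delay_predictor(
    model: str, k_m: float, vs_model: VsModel, k1_ratio: float
) -> Callable[[float, float], float]:
    """Return pred(v_g, theta) -> delay for a one-parameter threshold model."""

    def params_at(v_g: float, two_step: bool) -> cm.KineticParams:
        return cm.KineticParams(
            v_g=v_g,
            v_s=max(_vs_at(vs_model, v_g), 0.0),
            k_m=k_m,
            k_1=k1_ratio * k_m if two_step else None,
        )

    if model == "end_density":
        return lambda v_g, f: cm.delay_end_density(params_at(v_g, False), f).delay
    if model == "total_number":
        return lambda v_g, N: cm.delay_total_number(params_at(v_g, False), N).delay
    if model == "end_density_2step":
        return lambda v_g, f: cm.delay_two_step(
            params_at(v_g, True), cm.ThresholdSpec("end_density_2step", f_crit=f)
        ).delay
    if model == "total_number_2step":
        return lambda v_g, N: cm.delay_two_step(
            params_at(v_g, True), cm.ThresholdSpec("total_number_2step", N_crit=N)
        ).delay
    raise ValueError(f"unknown threshold model {model!r}")


def fit_threshold(
    groups: SpeedGroups,
    k_m: float,
    vs_model: VsModel,
    model: str = "end_density",
    maturation: str = "one_step",
    k1_ratio: float = 5.0,
) -> FitResult:
    """Weighted least-squares fit of a one-parameter threshold model.

    Predicted group delays (from the group mean v_g, with v_s supplied by
    ``vs_model`` — a fixed speed or an (a, b) linear relation) are matched
    to the measured group mean delays with weights 1/sem^2.  Multi-start
    over a coarse threshold grid guards against local minima.
    """
    if k_m <= 0:
        raise ValueError("k_m must be positive")
    if maturation not in ("one_step", "two_step"):
        raise ValueError("maturation must be 'one_step' or 'two_step'")
    full_model = model + ("_2step" if maturation == "two_step" else "")
    predictor = _delay_predictor(full_model, k_m, vs_model, k1_ratio)
    param_name = "f_crit" if model == "end_density" else "N_crit"

    v_g = groups.v_g
    sems = np.where(
        np.isfinite(groups.delay_sem) & (groups.delay_sem > 0), groups.delay_sem, 1.0
    )

    if model == "end_density":
        lo, hi = 1e-3, 1.0 - 1e-9
        starts = [0.1, 0.3, 0.5]
    else:
        # N_crit must stay below the smallest initial count over the groups
        n0_min = min(
            cm.total_sites(0.0, cm.KineticParams(v_g=v, v_s=0.0, k_m=k_m)) for v in v_g
        )
        lo, hi = 1e-3, 0.999 * n0_min
        starts = [0.1 * n0_min, 0.3 * n0_min, 0.5 * n0_min]

    def residuals(theta):
        pred = np.array([predictor(v, theta[0]) for v in v_g])
        return (groups.delay - pred) / sems

    best = None
    for s in starts:
        try:
            sol = optimize.least_squares(
                residuals, [s], bounds=([lo], [hi]), xtol=1e-14, ftol=1e-14
            )
        except ValueError:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitFailureError(f"threshold fit ({full_model}) did not converge")
    theta = float(best.x[0])
    n_pts, n_free = v_g.size, 1
    chi2 = reduced_chi2(
        groups.delay, groups.delay - best.fun * sems, sems, n_free
    )
    # 1-sigma parameter error from the Jacobian, scaled by the fit quality
    J = best.jac
    try:
        cov = np.linalg.inv(J.T @ J) * max(chi2, 1.0)
        se = float(np.sqrt(cov[0, 0]))
    except np.linalg.LinAlgError:
        se = np.nan
    at_bound = theta <= lo * 1.01 or theta >= hi * 0.99
    return FitResult(
        model=full_model,
        params={param_name: theta},
        param_se={param_name: se},
        chi2_red=chi2,
        n_points=n_pts,
        n_free=n_free,
        at_bound=at_bound,
    )


@dataclass
class DelayDataset:
    """One speed-sorted delay dataset with its kinetic context."""

    groups: SpeedGroups
    k_m: float
    vs_model: VsModel
    label: str = ""


def global_fit_L(
    delay_datasets: Sequence[DelayDataset],
    intensity_groups: Optional[SpeedGroups],
    L_grid: Sequence[float],
    intensity_dataset_index: int = 0,
    intensity_k_m: Optional[float] = None,
) -> list[FitResult]:
    """Global window-L fits over a grid of fixed window lengths L (nm).

    For each L, all delay datasets are fitted simultaneously with the
    window-L threshold model (one free NL_crit per dataset) and, when
    intensity groups are supplied, the washout/catastrophe intensities are
    fitted with their closed forms (one free camera factor F; the linked
    dataset's NL_crit enters the catastrophe intensity).  Returns one
    FitResult per L with params {'L', 'NL_crit': [...], 'F'} and the
    reduced chi-square, so the chi2(L) curve can be scanned for the
    best-supported window length.
    """
    if len(delay_datasets) < 1:
        raise InsufficientDataError("need at least one delay dataset")
    if any(L <= 0 for L in L_grid):
        raise ValueError("L_grid must be positive")
    use_intensity = intensity_groups is not None and intensity_groups.I_wo is not None
    k_m_int = (
        intensity_k_m
        if intensity_k_m is not None
        else delay_datasets[intensity_dataset_index].k_m
    )

    results: list[FitResult] = []
    for L in L_grid:
        n_ds = len(delay_datasets)

        def nl0_min(ds: DelayDataset) -> float:
            return min(
                cm.sites_in_window(
                    0.0, cm.KineticParams(v_g=v, v_s=0.0, k_m=ds.k_m), L
                )
                for v in ds.groups.v_g
            )

        ubs = [0.999 * nl0_min(ds) for ds in delay_datasets]

        def residuals(theta):
            res = []
            for j, ds in enumerate(delay_datasets):
                NL = theta[j]
                sems = np.where(
                    np.isfinite(ds.groups.delay_sem) & (ds.groups.delay_sem > 0),
                    ds.groups.delay_sem,
                    1.0,
                )
                for v, d_obs, s in zip(ds.groups.v_g, ds.groups.delay, sems):
                    p = cm.KineticParams(
                        v_g=v, v_s=max(_vs_at(ds.vs_model, v), 0.0), k_m=ds.k_m
                    )
                    NL_eff = min(NL, 0.999 * cm.sites_in_window(0.0, p, L))
                    pred = cm.delay_window_L(p, L, NL_eff).delay
                    res.append((d_obs - pred) / s)
            if use_intensity:
                F = theta[n_ds]
                NL = theta[intensity_dataset_index]
                g = intensity_groups
                for i, v in enumerate(g.v_g):
                    p = cm.KineticParams(v_g=v, v_s=0.0, k_m=k_m_int)
                    I_wo_pred, I_cat_pred = cm.intensity_predictions(F, p, L, NL)
                    res.append((g.I_wo[i] - I_wo_pred) / g.I_wo_sem[i])
                    res.append((g.I_cat[i] - I_cat_pred) / g.I_cat_sem[i])
            return np.array(res)

        x0 = [0.3 * ub for ub in ubs]
        lb = [1e-6] * n_ds
        ub_full = list(ubs)
        if use_intensity:
            F0 = float(np.mean(intensity_groups.I_wo / intensity_groups.v_g))
            x0.append(max(F0, 1e-6))
            lb.append(1e-9)
            ub_full.append(np.inf)
        sol = optimize.least_squares(
            residuals, x0, bounds=(lb, ub_full), xtol=1e-12, ftol=1e-12
        )
        if not sol.success:
            raise FitFailureError(f"global window-L fit failed at L={L}")
        n_pts = sol.fun.size
        n_free = len(x0)
        chi2 = float(2.0 * sol.cost / (n_pts - n_free))
        params = {
            "L": float(L),
            "NL_crit": [float(v) for v in sol.x[:n_ds]],
        }
        if use_intensity:
            params["F"] = float(sol.x[n_ds])
        results.append(
            FitResult(
                model="window_L",
                params=params,
                chi2_red=chi2,
                n_points=n_pts,
                n_free=n_free,
            )
        )
    return results
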