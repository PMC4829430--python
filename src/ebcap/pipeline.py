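"""End-to-end pipeline: cohort in, metrics / groups / fits / correlations out.

Thin orchestration over the library stages, so the same sequence the CLI
runs is available programmatically:

    tracks -> per-track analysis -> speed-sorted groups -> threshold fits
           -> shifted-window correlations -> aligned averages

Every table written embeds the seed and config hash.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import io as ebio
from .cohort_stats import correlation_vs_shift
from .exceptions import EbcapError, InsufficientDataError
from .model_fitting import fit_threshold, speed_sort, vs_vg_relation
from .synthetic import SyntheticConfig, generate_cohort
from .trace_analysis import CohortResult, Track, align_and_average, analyze_cohort

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Options for one pipeline run; defaults match the analysis contract."""

    tracks_path: Optional[Union[str, Path]] = None  # read tracks from here ...
    synthetic: Optional[SyntheticConfig] = None  # ... or generate them
    out_dir: Optional[Union[str, Path]] = None
    n_groups: int = 7
    k_m: float = 0.16  # 1/s, from comet analysis
    speed_window: float = 10.0  # s
    intensity_window: float = 1.0  # s
    shifts: Sequence[float] = (0.0, 2.0, 5.0, 10.0, 14.0)
    threshold_models: Sequence[str] = ("end_density", "total_number")
    seed: int = 0

    def validate(self, n_tracks: int) -> None:
        if self.n_groups > max(n_tracks // 2, 1):
            raise ValueError(
                f"n_groups={self.n_groups} too large for {n_tracks} tracks"
            )


@dataclass
class PipelineResult:
    cohort: CohortResult
    groups: object = None
    vs_model: Optional[tuple[float, float]] = None
    fits: dict = field(default_factory=dict)
    correlations: list = field(default_factory=list)
    aligned: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis; write tables when out_dir is set."""
    if config.tracks_path is not None:
        tracks = ebio.read_tracks(config.tracks_path)
        truth = None
        meta = {"seed": config.seed, "source": str(config.tracks_path)}
    elif config.synthetic is not None:
        cfg = config.synthetic
        tracks, truth = generate_cohort(cfg)
        meta = {"seed": cfg.seed, "config_hash": ebio.config_hash(cfg)}
    else:
        raise ValueError("either tracks_path or synthetic config required")
    config.validate(len(tracks))

    cohort = analyze_cohort(
        tracks,
        speed_window=config.speed_window,
        intensity_window=config.intensity_window,
    )
    if cohort.n_ok == 0:
        raise EbcapError("all tracks failed analysis")
    result = PipelineResult(cohort=cohort)

    frame = cohort.frame
    try:
        result.vs_model = vs_vg_relation(frame)
    except (InsufficientDataError, ValueError):
        result.vs_model = None
    try:
        result.groups = speed_sort(frame, config.n_groups)
    except InsufficientDataError:
        result.groups = None

    if result.groups is not None and result.vs_model is not None:
        for model in config.threshold_models:
            try:
                result.fits[model] = fit_threshold(
                    result.groups, config.k_m, result.vs_model, model=model
                )
            except EbcapError:
                pass

    has_gfp = all(t.gfp_end is not None for t in cohort.tracks)
    quantities = ["growth_speed"] + (["gfp_intensity"] if has_gfp else [])
    for q in quantities:
        try:
            result.correlations.extend(
                correlation_vs_shift(
                    cohort.tracks, cohort.metrics, q, config.shifts,
                    speed_window=config.speed_window,
                    intensity_window=config.intensity_window,
                )
            )
        except EbcapError:
            pass

    for channel in ["end_pos"] + (["gfp_end"] if has_gfp else []):
        try:
            result.aligned[channel] = align_and_average(
                cohort.tracks, cohort.metrics, channel=channel
            )
        except InsufficientDataError:
            pass

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ebio.write_table(frame, out / "metrics.csv", meta=meta)
        ebio.write_table(
            pd.DataFrame(cohort.statuses, columns=["id", "status"]),
            out / "statuses.csv",
            meta=meta,
        )
        if truth is not None:
            ebio.write_table(truth, out / "truth.csv", meta=meta)
        if result.groups is not None:
            g = result.groups
            gframe = pd.DataFrame(
                {
                    "v_g": g.v_g,
                    "v_g_sem": g.v_g_sem,
                    "delay": g.delay,
                    "delay_sem": g.delay_sem,
                    "n": g.n,
                }
            )
            ebio.write_table(gframe, out / "groups.csv", meta=meta)
        if result.fits:
            rows = [
                {
                    "model": f.model,
                    **{k: v for k, v in f.params.items()},
                    "chi2_red": f.chi2_red,
                }
                for f in result.fits.values()
            ]
            ebio.write_table(pd.DataFrame(rows), out / "fits.csv", meta=meta)
        if result.correlations:
            cframe = pd.DataFrame(
                [
                    {"quantity": c.quantity, "shift_s": c.shift, "rho": c.rho, "p": c.p, "n": c.n}
                    for c in result.correlations
                ]
            )
            ebio.write_table(cframe, out / "correlations.csv", meta=meta)
        for channel, avg in result.aligned.items():
            aframe = pd.DataFrame(
                {
                    "t_rel_cat_s": avg.grid,
                    "mean": avg.mean,
                    "sem": avg.sem,
                    "n": avg.n_tracks,
                }
            )
            extra = dict(meta)
            if avg.decay_rate is not None:
                extra["decay_rate_per_s"] = f"{avg.decay_rate:.6g}"
            ebio.write_table(aframe, out / f"aligned_{channel}.csv", meta=extra)
    return result
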