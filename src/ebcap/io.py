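"""Delimited-text I/O for tracks, metrics and configuration.

Track tables are plain CSV with the header
``time_s,end_pos_nm,gfp_end,gfp_lattice,background,orientation_deg``;
the optional channels (gfp_end, gfp_lattice, orientation_deg) may be
absent.  Cohorts are one file per microtubule.  Configuration is key-value
YAML; every output table embeds the seed and a config hash in ``#``
comment lines so runs are reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .exceptions import SchemaError
from .synthetic import SyntheticConfig
from .trace_analysis import Track

__all__ = [
    "TRACK_COLUMNS",
    "read_track",
    "read_tracks",
    "write_track",
    "write_cohort",
    "write_table",
    "read_config",
    "config_hash",
]

TRACK_COLUMNS = [
    "time_s",
    "end_pos_nm",
    "gfp_end",
    "gfp_lattice",
    "background",
    "orientation_deg",
]
_REQUIRED = ("time_s", "end_pos_nm", "background")
_OPTIONAL = {"gfp_end": "gfp_end", "gfp_lattice": "gfp_lattice", "orientation_deg": "orientation"}


def read_track(path: Union[str, Path]) -> Track:
    """Read one track table (comma- or tab-separated, '#' comments)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=None, engine="python", comment="#")
    except Exception as exc:  # malformed file
        raise SchemaError(f"{path}: cannot parse track table: {exc}") from exc
    missing = [c for c in _REQUIRED if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    bad = frame[_REQUIRED[0]].isna() | frame["end_pos_nm"].isna() | frame["background"].isna()
    if bad.any():
        lines = (np.nonzero(bad.to_numpy())[0] + 2).tolist()  # 1-based + header
        raise SchemaError(f"{path}: malformed rows at lines {lines[:10]}")
    kwargs = {}
    for col, attr in _OPTIONAL.items():
        if col in frame.columns and frame[col].notna().all():
            kwargs[attr] = frame[col].to_numpy(float)
    try:
        return Track(
            time=frame["time_s"].to_numpy(float),
            end_pos=frame["end_pos_nm"].to_numpy(float),
            background=frame["background"].to_numpy(float),
            id=path.stem,
            **kwargs,
        )
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def read_tracks(path: Union[str, Path], pattern: str = "*.csv") -> list[Track]:
    """Read a cohort: a directory of track tables, or one file."""
    path = Path(path)
    if path.is_dir():
        files = sorted(f for f in path.glob(pattern) if f.name != "truth.csv")
        if not files:
            raise SchemaError(f"no {pattern} track tables in {path}")
        return [read_track(f) for f in files]
    return [read_track(path)]


def _header_lines(meta: Optional[dict]) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def write_track(track: Track, path: Union[str, Path], meta: Optional[dict] = None) -> None:
    path = Path(path)
    cols = {"time_s": track.time, "end_pos_nm": track.end_pos}
    if track.gfp_end is not None:
        cols["gfp_end"] = track.gfp_end
    if track.gfp_lattice is not None:
        cols["gfp_lattice"] = track.gfp_lattice
    cols["background"] = track.background
    if track.orientation is not None:
        cols["orientation_deg"] = track.orientation
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        pd.DataFrame(cols).to_csv(fh, index=False)


def write_cohort(
    tracks: Iterable[Track],
    directory: Union[str, Path],
    truth: Optional[pd.DataFrame] = None,
    meta: Optional[dict] = None,
) -> None:
    """Write one CSV per track (named by id) plus an optional truth table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for track in tracks:
        write_track(track, directory / f"{track.id}.csv", meta=meta)
    if truth is not None:
        write_table(truth, directory / "truth.csv", meta=meta)


def write_table(frame: pd.DataFrame, path: Union[str, Path], meta: Optional[dict] = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        frame.to_csv(fh, index=False)


def config_hash(cfg: Union[SyntheticConfig, dict]) -> str:
    payload = asdict(cfg) if not isinstance(cfg, dict) else cfg
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def read_config(path: Union[str, Path]) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: config must be a key-value mapping")
    return data


def synthetic_config_from_dict(data: dict) -> SyntheticConfig:
    known = set(SyntheticConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise SchemaError(f"unknown synthetic config keys: {sorted(unknown)}")
    return SyntheticConfig(**data)
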