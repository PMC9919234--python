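"""CSV/YAML/JSON interchange formats.

Track CSV: header ``t,x,y,sxx,sxy,syy`` (seconds, metres, covariance
entries); gaps are encoded by absent rows.  Trajectory CSV: ``t,x,y``.
Fused-track CSV: ``t,x,y,vx,vy`` (velocities blank for feedforward
fusers).  All files are UTF-8, comma-separated, dot decimal, with a
mandatory header row.  Scenario and pipeline configuration is YAML.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import ScenarioConfig
from .tracks import FusedTrack, SensorTrack, Trajectory

__all__ = [
    "read_track",
    "write_track",
    "read_trajectory",
    "write_trajectory",
    "read_fused",
    "write_fused",
    "load_scenario",
    "save_scenario",
    "bundled_scenario",
    "list_bundled_scenarios",
]

TRACK_COLUMNS = ["t", "x", "y", "sxx", "sxy", "syy"]


def _read_csv(path, columns: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed CSV ({exc})") from exc
    if list(df.columns) != columns:
        raise ValueError(
            f"{path}: expected header {','.join(columns)}, got {','.join(df.columns)}"
        )
    df = df.apply(pd.to_numeric, errors="coerce")
    bad = df.index[df.isna().any(axis=1)]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise ValueError(f"{path}: non-numeric or missing value at line {bad[0] + 2}")
    return df


def read_track(path, sensor_id: str | None = None) -> SensorTrack:
    df = _read_csv(path, TRACK_COLUMNS)
    n = len(df)
    cov = np.empty((n, 2, 2))
    cov[:, 0, 0] = df["sxx"]
    cov[:, 0, 1] = cov[:, 1, 0] = df["sxy"]
    cov[:, 1, 1] = df["syy"]
    sid = sensor_id or Path(path).stem.split("_")[-1]
    return SensorTrack(
        sensor_id=sid, t=df["t"].to_numpy(), xy=df[["x", "y"]].to_numpy(), cov=cov
    )


def write_track(path, track: SensorTrack) -> None:
    df = pd.DataFrame(
        {
            "t": track.t,
            "x": track.xy[:, 0],
            "y": track.xy[:, 1],
            "sxx": track.cov[:, 0, 0],
            "sxy": track.cov[:, 0, 1],
            "syy": track.cov[:, 1, 1],
        }
    )
    df.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


def read_trajectory(path, walking_speed: float | None = None) -> Trajectory:
    df = _read_csv(path, ["t", "x", "y"])
    return Trajectory(
        t=df["t"].to_numpy(), xy=df[["x", "y"]].to_numpy(), walking_speed=walking_speed
    )


def write_trajectory(path, traj: Trajectory) -> None:
    pd.DataFrame({"t": traj.t, "x": traj.xy[:, 0], "y": traj.xy[:, 1]}).to_csv(
        path, index=False, encoding="utf-8", lineterminator="\n"
    )


def read_fused(path) -> FusedTrack:
    df = _read_csv(path, ["t", "x", "y", "vx", "vy"])
    vel = df[["vx", "vy"]].to_numpy()
    if np.all(np.isnan(vel)):
        vel = None
    return FusedTrack(t=df["t"].to_numpy(), xy=df[["x", "y"]].to_numpy(), vel=vel)


def write_fused(path, track: FusedTrack) -> None:
    vel = track.vel if track.vel is not None else np.full_like(track.xy, np.nan)
    pd.DataFrame(
        {
            "t": track.t,
            "x": track.xy[:, 0],
            "y": track.xy[:, 1],
            "vx": vel[:, 0],
            "vy": vel[:, 1],
        }
    ).to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


def _scenario_from_dict(d: dict) -> ScenarioConfig:
    d = dict(d)
    d["waypoints"] = [tuple(map(float, wp)) for wp in d["waypoints"]]
    if "depth_sensor_position" in d:
        d["depth_sensor_position"] = tuple(map(float, d["depth_sensor_position"]))
    if "obstacle_regions" in d:
        d["obstacle_regions"] = [tuple(map(float, r)) for r in d["obstacle_regions"]]
    known = {f.name for f in dataclasses.fields(ScenarioConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown scenario fields: {sorted(unknown)}")
    return ScenarioConfig(**d)


def load_scenario(path) -> ScenarioConfig:
    with open(path, encoding="utf-8") as fh:
        return _scenario_from_dict(yaml.safe_load(fh))


def save_scenario(path, scenario: ScenarioConfig) -> None:
    d = dataclasses.asdict(scenario)
    d["waypoints"] = [list(wp) for wp in d["waypoints"]]
    d["depth_sensor_position"] = list(d["depth_sensor_position"])
    d["obstacle_regions"] = [list(r) for r in d["obstacle_regions"]]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def list_bundled_scenarios() -> list[str]:
    root = resources.files("gaitfuse") / "scenarios"
    return sorted(p.name[: -len(".yaml")] for p in root.iterdir() if p.name.endswith(".yaml"))


def bundled_scenario(name: str) -> ScenarioConfig:
    """Load one of the scenario files shipped with the package.

    Training shapes: ``rectangle``, ``serpentine``, ``lshape``,
    ``diagonal``; evaluation scenarios: ``exp1`` (occluded serpentine) and
    ``exp2`` (rectangle lap).
    """
    res = resources.files("gaitfuse") / "scenarios" / f"{name}.yaml"
    if not res.is_file():
        raise FileNotFoundError(
            f"no bundled scenario '{name}'; available: {list_bundled_scenarios()}"
        )
    return _scenario_from_dict(yaml.safe_load(res.read_text(encoding="utf-8")))


def training_scenarios(walking_speed: float = 0.7) -> list[ScenarioConfig]:
    """The four bundled training shapes at the given walking speed."""
    out = []
    for name in ("rectangle", "serpentine", "lshape", "diagonal"):
        scen = bundled_scenario(name)
        scen.walking_speed = walking_speed
        out.append(scen)
    return out
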