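"""Session bundles on disk, behavior annotations, and summary writers.

A session bundle is a directory with a ``manifest.json`` naming the arena, the
imaged subject, one trajectory CSV per animal (columns ``frame, t_s, x_cm,
y_cm, head_dir_rad, valid``), the event raster (``raster.npz`` or a wide CSV)
and optional ground-truth / trial-table sidecars.  Loading validates frame
alignment across every channel and raises typed errors naming the offending
file.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import AlignmentError, AnnotationError, ConfigError
from .geometry import ArenaGeometry, Trajectory
from .session import Session

TRAJ_COLUMNS = ["frame", "t_s", "x_cm", "y_cm", "head_dir_rad", "valid"]


def _arena_to_dict(arena: ArenaGeometry) -> dict:
    return {"shape": arena.shape, "size_params": list(arena.size_params)}


def _arena_from_dict(d: dict) -> ArenaGeometry:
    try:
        return ArenaGeometry(d["shape"], tuple(d["size_params"]))
    except (KeyError, TypeError) as e:
        raise ConfigError(f"malformed arena descriptor: {d!r}") from e


def write_session(session: Session, path: str | Path, raster_format: str = "npz"
                  ) -> Path:
    """Write a session bundle; returns the bundle directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "arena": _arena_to_dict(session.arena),
        "subject": session.subject,
        "frame_rate": session.frame_rate,
        "n_frames": session.n_frames,
        "seed": session.seed,
        "metadata": session.metadata,
        "trajectories": {},
        "raster": f"raster.{ 'npz' if raster_format == 'npz' else 'csv' }",
    }
    for name, traj in session.trajectories.items():
        fname = f"trajectory_{name}.csv"
        hd = traj.head_dir if traj.head_dir is not None \
            else np.full(traj.n_frames, np.nan)
        pd.DataFrame(
            {"frame": np.arange(traj.n_frames), "t_s": traj.t,
             "x_cm": traj.pos[:, 0], "y_cm": traj.pos[:, 1],
             "head_dir_rad": hd, "valid": traj.valid.astype(int)}
        ).to_csv(path / fname, index=False, float_format="%.17g")
        manifest["trajectories"][name] = fname
    if raster_format == "npz":
        np.savez_compressed(path / "raster.npz", raster=session.raster.astype(np.uint8))
    else:
        pd.DataFrame(session.raster).to_csv(path / "raster.csv", index=False)
    if session.trial_table is not None:
        session.trial_table.to_csv(path / "trials.csv", index=False)
        manifest["trials"] = "trials.csv"
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def read_session(path: str | Path) -> Session:
    """Load and validate a session bundle."""
    path = Path(path)
    mf = path / "manifest.json"
    if not mf.exists():
        raise ConfigError(f"no manifest.json in {path}")
    manifest = json.loads(mf.read_text())
    for key in ("arena", "subject", "trajectories", "raster"):
        if key not in manifest:
            raise ConfigError(f"manifest missing required key {key!r}")
    arena = _arena_from_dict(manifest["arena"])
    frame_rate = float(manifest.get("frame_rate", 30.0))

    trajectories = {}
    for name, fname in manifest["trajectories"].items():
        df = pd.read_csv(path / fname, float_precision="round_trip")
        missing = [c for c in TRAJ_COLUMNS if c not in df.columns]
        if missing:
            raise ConfigError(f"{fname}: missing columns {missing}")
        hd = df["head_dir_rad"].to_numpy(float)
        trajectories[name] = Trajectory(
            frame_rate=frame_rate,
            t=df["t_s"].to_numpy(float),
            pos=df[["x_cm", "y_cm"]].to_numpy(float),
            head_dir=None if np.isnan(hd).all() else hd,
            valid=df["valid"].to_numpy(bool),
        )

    raster_file = path / manifest["raster"]
    if raster_file.suffix == ".npz":
        raster = np.load(raster_file)["raster"]
    else:
        raster = pd.read_csv(raster_file).to_numpy(np.uint8)

    n_set = {t.n_frames for t in trajectories.values()}
    if len(n_set) != 1 or raster.shape[1] not in n_set:
        raise AlignmentError(
            f"frame counts disagree: trajectories {sorted(n_set)}, "
            f"raster {raster.shape[1]} ({raster_file.name})"
        )

    trial_table = None
    if "trials" in manifest:
        trial_table = pd.read_csv(path / manifest["trials"])

    return Session(
        arena=arena,
        trajectories=trajectories,
        raster=raster,
        subject=manifest["subject"],
        seed=manifest.get("seed"),
        metadata=manifest.get("metadata", {}),
        trial_table=trial_table,
    )


def read_annotations(
    path: str | Path,
    column_map: Optional[dict] = None,
) -> pd.DataFrame:
    """Read a BORIS-style behavior-annotation CSV.

    Returns a frame with columns ``behavior, onset_s, offset_s, category``
    (category in {'social', 'non-social'}).  ``column_map`` renames source
    columns, e.g. ``{"Behavior": "behavior", "Start (s)": "onset_s", ...}``.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    required = ["behavior", "onset_s", "offset_s", "category"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise AnnotationError(f"annotation file missing columns {missing}")
    df = df[required].copy()
    if (df["offset_s"] <= df["onset_s"]).any():
        bad = df.index[df["offset_s"] <= df["onset_s"]].tolist()
        raise AnnotationError(f"intervals with offset <= onset at rows {bad}")
    return df


def interaction_fraction(annotations: pd.DataFrame, duration_s: float) -> float:
    """Percentage of session time covered by the union of social intervals."""
    if (annotations["offset_s"] > duration_s + 1e-9).any() or \
            (annotations["onset_s"] < 0).any():
        raise AnnotationError("annotation interval outside the session duration")
    social = annotations[annotations["category"] == "social"]
    if social.empty:
        return 0.0
    ivs = sorted(zip(social["onset_s"], social["offset_s"]))
    total, cur_lo, cur_hi = 0.0, *ivs[0]
    for lo, hi in ivs[1:]:
        if lo > cur_hi:
            total += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    total += cur_hi - cur_lo
    return 100.0 * total / duration_s
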