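"""Reading and writing the package's text formats.

Track tables use an Imaris-like spot-export dialect: a header row with
columns ``track_id,time_s,x_um,y_um,z_um``, one row per spot, rows
groupable by track and sortable by time within track.  Values are printed
at 6 significant digits, making write→read round trips stable at that
precision.

Motility profiles serialise to JSON (the five multisets plus provenance);
Pareto fronts serialise to CSV with one member per row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .stats import ObjectiveVector, ParetoFront, ParetoMember, lambda_score
from .tracks import MotilityProfile, Track, TrackDataset
from .walkers import MODEL_GENES, WalkerParams

__all__ = [
    "read_tracks",
    "write_tracks",
    "profile_to_dict",
    "write_profile",
    "write_front_csv",
    "read_front_csv",
]

TRACK_COLUMNS = ["track_id", "time_s", "x_um", "y_um", "z_um"]


def read_tracks(path) -> TrackDataset:
    """Parse a track CSV into a validated TrackDataset.

    Rows are sorted by time within each track, so shuffled files load
    identically.  Duplicate time stamps within a track are a parse error
    naming the offending track.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = df[TRACK_COLUMNS[1:]].isna().any(axis=1)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()[:5]  # +2: header + 1-based
        raise ValueError(f"{path}: malformed rows at lines {lines}")
    tracks = []
    for tid, grp in df.groupby("track_id", sort=False):
        grp = grp.sort_values("time_s")
        t = grp["time_s"].to_numpy(dtype=float)
        if len(t) >= 2 and (np.diff(t) <= 0).any():
            raise ValueError(f"{path}: non-monotone time in track {tid!r}")
        dt = float(t[1] - t[0]) if len(t) >= 2 else 0.0
        try:
            tracks.append(
                Track(str(tid), grp[["x_um", "y_um", "z_um"]].to_numpy(dtype=float),
                      dt=dt, times=t)
            )
        except ValueError as e:
            raise ValueError(f"{path}: track {tid!r} invalid: {e}") from e
    return TrackDataset(tracks, label=str(path))


def write_tracks(ds: TrackDataset, path) -> None:
    """Emit the same dialect read_tracks consumes (6 significant digits)."""
    rows = []
    for tr in ds:
        times = tr.time_points
        for t, (x, y, z) in zip(times, tr.positions):
            rows.append((tr.track_id, t, x, y, z))
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6g")


def profile_to_dict(profile: MotilityProfile) -> dict:
    return {
        "pooled_translational_speeds_um_min": profile.pooled_translational_speeds.tolist(),
        "pooled_turn_speeds_deg_min": profile.pooled_turn_speeds.tolist(),
        "meandering_indices": profile.meandering_indices.tolist(),
        "median_track_translational_speeds_um_min":
            profile.median_track_translational_speeds.tolist(),
        "median_track_turn_speeds_deg_min": profile.median_track_turn_speeds.tolist(),
        "provenance": {
            "displacement_filter_um": profile.filter_um,
            "n_tracks_excluded": profile.n_tracks_excluded,
            "n_turn_observations_skipped": profile.n_turns_skipped,
        },
    }


def write_profile(profile: MotilityProfile, path) -> None:
    Path(path).write_text(json.dumps(profile_to_dict(profile), indent=1))


def write_front_csv(front: ParetoFront, path, alpha: float = 1.0) -> None:
    """One row per front member: model, named parameters, the three
    objective scores, Λ (blank in MSD mode) and the origin tag."""
    rows = []
    for m in front:
        p: WalkerParams = m.params
        row = {"model": p.model}
        row.update({f"param_{k}": v for k, v in p.as_dict().items()})
        o = m.objectives.values
        row.update(
            {
                "obj_translation": o[0],
                "obj_turn": o[1],
                "obj_third": o[2],
                "lambda": lambda_score(m, alpha) if m.objectives.ks_based else "",
                "lambda_alpha": alpha if m.objectives.ks_based else "",
                "origin": m.origin,
            }
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_front_csv(path) -> ParetoFront:
    df = pd.read_csv(path)
    members = []
    for i, row in df.iterrows():
        model = row["model"]
        vals = tuple(row[f"param_{g}"] for g in MODEL_GENES[model])
        ks_based = "lambda" in df.columns and not pd.isna(row["lambda"])
        obj = ObjectiveVector(
            (row["obj_translation"], row["obj_turn"], row["obj_third"]),
            ks_based=ks_based,
        )
        members.append(
            ParetoMember(WalkerParams(model, vals), obj, origin=row.get("origin", ""), uid=i)
        )
    return ParetoFront(members)
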