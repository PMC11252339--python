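"""Plain-text (CSV/JSON) and HDF5 serialization of session bundles and maps."""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import TrialRecord
from .rate_maps import ActivityTrain, RateMap, Trajectory
from .synthetic import GroundTruth, SessionBundle, SimConfig


def bundle_tag(bundle: SessionBundle) -> str:
    return f"animal{bundle.animal:02d}_day{bundle.day}"


def write_bundle(bundle: SessionBundle, out_dir: str | Path) -> Path:
    """Write one session as trajectories/events/trials CSVs plus a
    ground-truth JSON, under ``out_dir/<animal>_<day>/``."""
    d = Path(out_dir) / bundle_tag(bundle)
    d.mkdir(parents=True, exist_ok=True)
    traj_rows = []
    for tid, tr in sorted(bundle.trajectories.items()):
        traj_rows.append(pd.DataFrame(
            {"trial_id": tid, "t_s": tr.t, "x_cm": tr.x, "y_cm": tr.y}))
    pd.concat(traj_rows).to_csv(d / "trajectories.csv", index=False)
    ev_rows = []
    for tid, trains in sorted(bundle.activity.items()):
        for cid, act in sorted(trains.items()):
            if len(act.times):
                ev_rows.append(pd.DataFrame(
                    {"trial_id": tid, "cell_id": cid,
                     "t_s": act.times, "weight": act.weights}))
    (pd.concat(ev_rows) if ev_rows else
     pd.DataFrame(columns=["trial_id", "cell_id", "t_s", "weight"])
     ).to_csv(d / "events.csv", index=False)
    pd.DataFrame([
        {"trial_id": t.trial_id, "day": t.day, "context": t.context,
         "orientation_deg": bundle.ground_truth.orientation_by_trial[t.trial_id],
         "dig1": t.dig(1), "dig2": t.dig(2),
         "reward_corner": t.reward_corner,
         "chamber_orientation_deg": t.chamber_orientation_deg}
        for t in bundle.trials
    ]).to_csv(d / "trials.csv", index=False)
    gt = bundle.ground_truth
    with open(d / "ground_truth.json", "w") as fh:
        json.dump({
            "cells": gt.cells.to_dict(orient="records"),
            "orientation_by_trial": {str(k): v for k, v in
                                     gt.orientation_by_trial.items()},
            "applied_rotation": {f"{t}:{c}": v for (t, c), v in
                                 gt.applied_rotation.items()},
            "identity_map": {str(k): v for k, v in gt.identity_map.items()},
        }, fh, indent=1)
    return d


def read_bundle(session_dir: str | Path, config: SimConfig,
                animal: int = 0, day: int = 1) -> SessionBundle:
    """Reassemble a :class:`SessionBundle` written by :func:`write_bundle`."""
    d = Path(session_dir)
    traj_df = pd.read_csv(d / "trajectories.csv")
    ev_df = pd.read_csv(d / "events.csv")
    trials_df = pd.read_csv(d / "trials.csv")
    with open(d / "ground_truth.json") as fh:
        gt_raw = json.load(fh)
    trajectories = {
        int(tid): Trajectory(t=g["t_s"].to_numpy(), x=g["x_cm"].to_numpy(),
                             y=g["y_cm"].to_numpy())
        for tid, g in traj_df.groupby("trial_id")
    }
    cell_ids = sorted({int(c["cell_id"]) for c in gt_raw["cells"]})
    activity: dict[int, dict[int, ActivityTrain]] = {
        tid: {cid: ActivityTrain(cell_id=cid, times=np.array([]))
              for cid in cell_ids}
        for tid in trajectories
    }
    for (tid, cid), g in ev_df.groupby(["trial_id", "cell_id"]):
        activity[int(tid)][int(cid)] = ActivityTrain(
            cell_id=int(cid), times=g["t_s"].to_numpy(),
            weights=g["weight"].to_numpy())
    trials = [
        TrialRecord(trial_id=int(r.trial_id), day=int(r.day), context=r.context,
                    dig_sequence=tuple(x for x in (r.dig1, r.dig2)
                                       if isinstance(x, str)),
                    reward_corner=int(r.reward_corner),
                    chamber_orientation_deg=float(r.chamber_orientation_deg),
                    animal=animal)
        for r in trials_df.itertuples()
    ]
    gt = GroundTruth(
        cells=pd.DataFrame(gt_raw["cells"]),
        orientation_by_trial={int(k): v for k, v in
                              gt_raw["orientation_by_trial"].items()},
        applied_rotation={(int(k.split(":")[0]), int(k.split(":")[1])): v
                          for k, v in gt_raw["applied_rotation"].items()},
        identity_map={int(k): v for k, v in gt_raw["identity_map"].items()},
    )
    return SessionBundle(animal=animal, day=day, config=config, trials=trials,
                         trajectories=trajectories, activity=activity,
                         ground_truth=gt)


def write_bundle_hdf5(bundle: SessionBundle, path: str | Path) -> Path:
    """Single-file HDF5 container with the same groups as the CSV layout."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["animal"] = bundle.animal
        f.attrs["day"] = bundle.day
        for tid, tr in sorted(bundle.trajectories.items()):
            g = f.create_group(f"trials/{tid}/trajectory")
            g.create_dataset("t_s", data=tr.t)
            g.create_dataset("x_cm", data=tr.x)
            g.create_dataset("y_cm", data=tr.y)
        for tid, trains in sorted(bundle.activity.items()):
            for cid, act in sorted(trains.items()):
                g = f.create_group(f"trials/{tid}/activity/{cid}")
                g.create_dataset("t_s", data=act.times)
                g.create_dataset("weight", data=act.weights)
    return path


def write_rate_map_csv(rate_map: RateMap, path: str | Path) -> Path:
    """Small-fixture rate-map export: one row per pixel."""
    rows, cols = np.nonzero(np.ones(rate_map.shape, dtype=bool))
    pd.DataFrame({
        "row": rows, "col": cols,
        "rate": rate_map.rate[rows, cols],
        "occupancy_s": rate_map.occupancy[rows, cols],
        "sampled": rate_map.sampled_mask[rows, cols],
    }).to_csv(path, index=False)
    return Path(path)
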