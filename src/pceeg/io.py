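"""On-disk formats: CSV schedules/ratings, JSON montages and cluster results,
HDF5 epoch and TFR containers."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .design import SCHEDULE_COLUMNS
from .spectral import TFRSet
from .stats import Cluster, PermutationResult
from .synth import EpochsSet, Montage

__all__ = [
    "save_schedule", "load_schedule",
    "save_ratings", "load_ratings",
    "save_montage", "load_montage",
    "save_epochs", "load_epochs",
    "save_tfr", "load_tfr",
    "save_cluster_results", "load_cluster_results",
]


def save_schedule(schedule: pd.DataFrame, path) -> None:
    schedule.to_csv(path, index=False, columns=list(SCHEDULE_COLUMNS))


def load_schedule(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SCHEDULE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"schedule file missing columns {sorted(missing)}")
    df["is_catch"] = df["is_catch"].astype(bool)
    return df


def save_ratings(ratings: pd.DataFrame, path) -> None:
    ratings.to_csv(path, index=False)


def load_ratings(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_montage(montage: Montage, path) -> None:
    payload = {
        "channels": list(montage.channel_names),
        "positions": montage.positions.tolist(),
        "neighbors": {ch: sorted(nbs) for ch, nbs in montage.neighbors.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_montage(path) -> Montage:
    payload = json.loads(Path(path).read_text())
    return Montage(
        tuple(payload["channels"]),
        np.asarray(payload["positions"], dtype=float),
        {ch: frozenset(nbs) for ch, nbs in payload["neighbors"].items()},
    )


def save_epochs(epochs: EpochsSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data.astype(np.float32))
        f.create_dataset("times", data=epochs.times)
        f.create_dataset("schedule_ref", data=epochs.schedule_ref)
        f.create_dataset(
            "channels", data=np.array(epochs.channel_names, dtype=h5py.string_dtype())
        )
        f.attrs["srate"] = epochs.srate
        f.attrs["lock"] = epochs.lock
        f.attrs["subject_id"] = epochs.subject_id


def load_epochs(path) -> EpochsSet:
    with h5py.File(path, "r") as f:
        return EpochsSet(
            data=f["data"][()],
            srate=float(f.attrs["srate"]),
            times=f["times"][()],
            lock=str(f.attrs["lock"]),
            subject_id=str(f.attrs["subject_id"]),
            schedule_ref=f["schedule_ref"][()],
            channel_names=tuple(s.decode() for s in f["channels"][()]),
        )


def save_tfr(tfr: TFRSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("power", data=tfr.power.astype(np.float64))
        f.create_dataset("freqs", data=tfr.freqs)
        f.create_dataset("times", data=tfr.times)
        f.create_dataset("counts", data=tfr.counts)
        f.create_dataset(
            "channels", data=np.array(tfr.channel_names, dtype=h5py.string_dtype())
        )
        f.create_dataset(
            "subjects", data=np.array(tfr.subject_ids, dtype=h5py.string_dtype())
        )
        f.attrs["band"] = tfr.band
        f.attrs["lock"] = tfr.lock
        f.attrs["baselined"] = tfr.baselined
        if tfr.baseline_window is not None:
            f.attrs["baseline_window"] = list(tfr.baseline_window)


def load_tfr(path) -> TFRSet:
    with h5py.File(path, "r") as f:
        bw = f.attrs.get("baseline_window")
        return TFRSet(
            power=f["power"][()],
            freqs=f["freqs"][()],
            times=f["times"][()],
            band=str(f.attrs["band"]),
            lock=str(f.attrs["lock"]),
            baselined=bool(f.attrs["baselined"]),
            baseline_window=tuple(float(x) for x in bw) if bw is not None else None,
            counts=f["counts"][()],
            channel_names=tuple(s.decode() for s in f["channels"][()]),
            subject_ids=tuple(s.decode() for s in f["subjects"][()]),
        )


def _cluster_summary(c: Cluster, tfr: TFRSet | None = None) -> dict:
    ch, fr, ti = c.members.T
    summary = {
        "sign": c.sign,
        "value": c.value,
        "p": c.p,
        "n_members": int(len(c.members)),
        "channel_indices": sorted(int(x) for x in np.unique(ch)),
    }
    if tfr is not None:
        summary["channels"] = [tfr.channel_names[i] for i in np.unique(ch)]
        summary["freq_range_hz"] = [float(tfr.freqs[fr.min()]), float(tfr.freqs[fr.max()])]
        summary["time_range_ms"] = [float(tfr.times[ti.min()]), float(tfr.times[ti.max()])]
    else:
        summary["freq_index_range"] = [int(fr.min()), int(fr.max())]
        summary["time_index_range"] = [int(ti.min()), int(ti.max())]
    return summary


def save_cluster_results(
    result: PermutationResult,
    path,
    band: str | None = None,
    lock: str | None = None,
    tfr: TFRSet | None = None,
    members_path=None,
) -> None:
    """Serialize a permutation-test result as JSON plus a member table.

    The JSON carries the factor, band, lock, threshold, permutation count,
    seed and per-cluster summaries; the full member list (cluster, channel,
    frequency, time indices) goes to ``members_path`` as CSV when given.
    """
    payload = {
        "factor": result.factor,
        "band": band,
        "lock": lock,
        "threshold": result.threshold,
        "df": list(result.stat.df),
        "alpha": result.alpha,
        "tail_mode": result.tail_mode,
        "alpha_per_tail": result.alpha_per_tail,
        "n_perm": result.n_perm,
        "seed": result.seed,
        "add_one": result.add_one,
        "clusters": [_cluster_summary(c, tfr) for c in result.clusters],
    }
    Path(path).write_text(json.dumps(payload, indent=1))
    if members_path is not None:
        frames = []
        for k, c in enumerate(result.clusters):
            frames.append(
                pd.DataFrame(
                    {
                        "cluster": k,
                        "channel": c.members[:, 0],
                        "freq_index": c.members[:, 1],
                        "time_index": c.members[:, 2],
                    }
                )
            )
        table = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["cluster", "channel", "freq_index", "time_index"])
        )
        table.to_csv(members_path, index=False)


def load_cluster_results(path) -> dict:
    return json.loads(Path(path).read_text())
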