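"""File I/O: fixture EEG format, behavioural CSV logs, results serialization.

EEG fixtures are a plain float32 binary matrix (channels x time,
microvolts, C order) with a JSON sidecar describing shape, sampling
rate, channel labels and condition.  BrainVision (.vhdr) and EDF (.edf)
recordings are read through mne.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import KnowledgeLog, RuleLog, TrackLog
from .preprocess import EEGRecording


def save_recording(rec: EEGRecording, path) -> None:
    """Write a recording as <path>.bin (float32 raw) + <path>.json sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = rec.samples.astype(np.float32)
    data.tofile(path.with_suffix(".bin"))
    sidecar = {
        "shape": list(data.shape),
        "dtype": "float32",
        "fs": rec.fs,
        "channel_labels": list(rec.channel_labels),
        "condition": rec.condition,
        "units": "uV",
        "has_eog": rec.eog is not None,
    }
    if rec.eog is not None:
        rec.eog.astype(np.float32).tofile(path.with_suffix(".eog.bin"))
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_recording(path) -> EEGRecording:
    """Read a fixture recording written by :func:`save_recording`."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    data = np.fromfile(path.with_suffix(".bin"), dtype=np.float32)
    data = data.reshape(sidecar["shape"]).astype(float)
    eog = None
    if sidecar.get("has_eog"):
        eog = np.fromfile(path.with_suffix(".eog.bin"), dtype=np.float32).astype(float)
    return EEGRecording(
        samples=data, fs=sidecar["fs"],
        channel_labels=tuple(sidecar["channel_labels"]),
        condition=sidecar.get("condition", ""), eog=eog,
    )


def read_raw(path, condition: str = "") -> EEGRecording:
    """Read a BrainVision (.vhdr) or EDF (.edf) recording via mne, in uV."""
    import mne

    path = Path(path)
    if path.suffix == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    elif path.suffix == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    elif path.suffix == ".json":
        return load_recording(path.with_suffix(""))
    else:
        raise ValueError(f"unsupported EEG format {path.suffix!r}")
    picks = mne.pick_types(raw.info, eeg=True, eog=False)
    eog_picks = mne.pick_types(raw.info, eeg=False, eog=True)
    data = raw.get_data(picks=picks) * 1e6          # volts -> microvolts
    labels = tuple(raw.ch_names[i] for i in picks)
    eog = raw.get_data(picks=eog_picks)[0] * 1e6 if len(eog_picks) else None
    return EEGRecording(samples=data, fs=float(raw.info["sfreq"]),
                        channel_labels=labels, condition=condition, eog=eog)


# ---------------------------------------------------------------------------
# behavioural logs as CSV

def save_log(log, directory, condition: str) -> None:
    """Write a behavioural log under ``directory`` with a documented schema.

    TrackLog -> <cond>_cursor.csv (t,x,y) + <cond>_ideal.csv (x,y);
    RuleLog -> <cond>_rules.csv (slot,kind,outcome,weight);
    KnowledgeLog -> <cond>_knowledge.csv (single row of its fields).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if isinstance(log, TrackLog):
        pd.DataFrame(log.cursor_samples, columns=["t", "x", "y"]).to_csv(
            directory / f"{condition}_cursor.csv", index=False)
        pd.DataFrame(log.ideal_track, columns=["x", "y"]).to_csv(
            directory / f"{condition}_ideal.csv", index=False)
        meta = {"completion_time": log.completion_time}
        (directory / f"{condition}_track.json").write_text(json.dumps(meta))
    elif isinstance(log, RuleLog):
        rows = [{"slot": i, "kind": "turn", "outcome": o, "weight": 1.0}
                for i, o in enumerate(log.turn_outcomes)]
        rows += [{"slot": i, "kind": "alt", "outcome": o, "weight": w}
                 for i, (o, w) in enumerate(zip(log.alt_outcomes, log.alt_weights))]
        pd.DataFrame(rows).to_csv(directory / f"{condition}_rules.csv", index=False)
    elif isinstance(log, KnowledgeLog):
        row = {"variant": log.variant, "t_opt": log.t_opt, "t_cir": log.t_cir,
               "t_ev": log.t_ev, "n_att": log.n_att, "t_used": log.t_used,
               "t_av": log.t_av, "completion_time": log.completion_time}
        pd.DataFrame([row]).to_csv(directory / f"{condition}_knowledge.csv",
                                   index=False)
    else:
        raise TypeError(f"not a behavioural log: {type(log)!r}")


def load_log(directory, condition: str):
    """Read back a behavioural log written by :func:`save_log`."""
    directory = Path(directory)
    cursor = directory / f"{condition}_cursor.csv"
    rules = directory / f"{condition}_rules.csv"
    knowledge = directory / f"{condition}_knowledge.csv"
    if cursor.exists():
        samples = pd.read_csv(cursor).to_numpy()
        ideal = pd.read_csv(directory / f"{condition}_ideal.csv").to_numpy()
        meta = json.loads((directory / f"{condition}_track.json").read_text())
        return TrackLog(cursor_samples=samples, ideal_track=ideal,
                        completion_time=meta["completion_time"])
    if rules.exists():
        df = pd.read_csv(rules)
        turn = tuple(int(v) for v in df[df["kind"] == "turn"]["outcome"])
        alt_df = df[df["kind"] == "alt"]
        return RuleLog(turn_outcomes=turn,
                       alt_outcomes=tuple(int(v) for v in alt_df["outcome"]),
                       alt_weights=tuple(float(v) for v in alt_df["weight"]))
    if knowledge.exists():
        row = pd.read_csv(knowledge).iloc[0]
        if row["variant"] == "K1":
            return KnowledgeLog(variant="K1", t_opt=row["t_opt"],
                                t_cir=row["t_cir"], t_ev=row["t_ev"],
                                completion_time=row["completion_time"])
        return KnowledgeLog(variant="K2", n_att=int(row["n_att"]),
                            t_used=row["t_used"], t_av=row["t_av"],
                            completion_time=row["completion_time"])
    raise FileNotFoundError(f"no behavioural log for {condition!r} in {directory}")


def save_feature_table(table, path) -> None:
    """Write a FeatureTable as long-format CSV (epoch, channel, band, value)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    series = table.to_dataframe().stack(["channel", "band"], future_stack=True)
    series.index.names = ["epoch", "channel", "band"]
    df = series.rename("value").reset_index()
    df["units"] = table.units
    df.to_csv(path, index=False)


def save_gfp(gfp, path) -> None:
    """Write a GFPSeries as long-format CSV (epoch, band, value)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(gfp.values, columns=list(gfp.band_names))
    df.insert(0, "epoch", np.arange(len(df)))
    df = df.melt(id_vars="epoch", var_name="band", value_name="value")
    df.to_csv(path, index=False)


def save_json(obj: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=1, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)!r}")
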