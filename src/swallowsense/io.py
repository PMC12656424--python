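"""Interchange formats: recording directories and clinical tables.

A recording is stored as a directory of inspectable text files:

    meta.json   sampling rates, units, grid geometry, subject/group/task/trial
    semg.csv    samples x 32 matrix, header = channel ids (ch00..ch31)
    acc.csv     samples x 3 matrix, header = axis names (ax,ay,az)
    events.csv  rows of (event, time_s)

Clinical tables are CSV with the header
``id,gender,age,disease_duration,updrs3,updrs_axial,sdq,ledd,group``.
The per-subject demographics and scores of the study cohort (15 PD patients,
7 age-matched controls) ship as packaged fixtures.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError
from .types import EventAnnotations, Recording, N_CHANNELS

_SEMG_COLS = [f"ch{i:02d}" for i in range(N_CHANNELS)]
_ACC_COLS = ["ax", "ay", "az"]

_EVENT_FIELDS = {
    "mastication_start": "mastication_start",
    "mastication_end": "mastication_end",
    "swallow_start": "swallow_start",
    "swallow_end": "swallow_end",
}

CLINICAL_COLUMNS = ["id", "gender", "age", "disease_duration", "updrs3",
                    "updrs_axial", "sdq", "ledd", "group"]
_SCORE_COLUMNS = ["age", "disease_duration", "updrs3", "updrs_axial", "sdq", "ledd"]


def write_recording(rec: Recording, path) -> None:
    """Write ``rec`` to ``path`` (a directory, created if needed).

    The numeric payload round-trips losslessly (shortest-round-trip float
    repr) and two writes of the same recording are byte-identical.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "subject_id": rec.subject_id,
        "group": rec.group,
        "task": rec.task,
        "trial": int(rec.trial),
        "fs_semg_hz": rec.fs_semg,
        "fs_acc_hz": rec.fs_acc,
        "semg_units": "mV",
        "acc_units": "g",
        "grid_rows": rec.grid_rows,
        "grid_cols": rec.grid_cols,
        "left_channels": list(map(int, rec.left_channels)),
        "right_channels": list(map(int, rec.right_channels)),
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    # %.17g round-trips any float64 exactly
    pd.DataFrame(rec.semg, columns=_SEMG_COLS).to_csv(
        path / "semg.csv", index=False, float_format="%.17g")
    pd.DataFrame(rec.acc, columns=_ACC_COLS).to_csv(
        path / "acc.csv", index=False, float_format="%.17g")

    rows = []
    ev = rec.events
    for key, attr in _EVENT_FIELDS.items():
        val = getattr(ev, attr)
        if val is not None:
            rows.append((key, float(val)))
    if ev.intake_interval is not None:
        rows.append(("intake_start", float(ev.intake_interval[0])))
        rows.append(("intake_end", float(ev.intake_interval[1])))
    pd.DataFrame(rows, columns=["event", "time_s"]).to_csv(path / "events.csv", index=False)


def read_recording(path) -> Recording:
    """Read a recording directory written by :func:`write_recording`."""
    path = Path(path)
    for fname in ("meta.json", "semg.csv", "acc.csv", "events.csv"):
        if not (path / fname).exists():
            raise FileNotFoundError(f"recording directory {path} is missing {fname}")
    meta = json.loads((path / "meta.json").read_text())

    semg = pd.read_csv(path / "semg.csv", float_precision="round_trip")
    if semg.shape[1] != N_CHANNELS:
        raise SchemaError(
            f"semg.csv must have {N_CHANNELS} columns, found {semg.shape[1]}")
    acc = pd.read_csv(path / "acc.csv", float_precision="round_trip")
    if acc.shape[1] != 3:
        raise SchemaError(f"acc.csv must have 3 columns, found {acc.shape[1]}")

    ev_df = pd.read_csv(path / "events.csv")
    if list(ev_df.columns) != ["event", "time_s"]:
        raise SchemaError("events.csv must have columns event,time_s")
    ev_map = dict(zip(ev_df["event"], ev_df["time_s"]))
    intake = None
    if "intake_start" in ev_map or "intake_end" in ev_map:
        if not ("intake_start" in ev_map and "intake_end" in ev_map):
            raise ValidationError("intake interval needs both intake_start and intake_end")
        intake = (float(ev_map["intake_start"]), float(ev_map["intake_end"]))
    events = EventAnnotations(
        mastication_start=ev_map.get("mastication_start"),
        mastication_end=ev_map.get("mastication_end"),
        swallow_start=ev_map.get("swallow_start"),
        swallow_end=ev_map.get("swallow_end"),
        intake_interval=intake,
    )

    return Recording(
        subject_id=meta["subject_id"],
        group=meta["group"],
        task=meta["task"],
        trial=int(meta["trial"]),
        semg=semg.to_numpy(dtype=float),
        acc=acc.to_numpy(dtype=float),
        fs_semg=float(meta["fs_semg_hz"]),
        fs_acc=float(meta["fs_acc_hz"]),
        grid_rows=int(meta["grid_rows"]),
        grid_cols=int(meta["grid_cols"]),
        left_channels=tuple(meta["left_channels"]),
        right_channels=tuple(meta["right_channels"]),
        events=events,
    )


def read_clinical_table(path) -> pd.DataFrame:
    """Read a clinical table CSV into a typed, validated DataFrame.

    The ``group`` column may be omitted, in which case it is inferred from
    the id prefix convention (``PT``/``PR`` -> PD, ``HC`` -> HC).
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"clinical table {path} is empty") from exc
    if "id" not in raw.columns:
        raise SchemaError(f"clinical table {path} lacks an 'id' column")

    df = pd.DataFrame({"id": raw["id"].astype(str)})
    df["gender"] = raw.get("gender", pd.Series([""] * len(raw))).astype(str)
    for col in _SCORE_COLUMNS:
        vals = []
        for rid, v in zip(df["id"], raw.get(col, pd.Series([None] * len(raw)))):
            if v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == "":
                vals.append(np.nan)
                continue
            try:
                vals.append(float(v))
            except ValueError as exc:
                raise ParseError(
                    f"non-numeric value {v!r} in column {col!r} for subject {rid}") from exc
        df[col] = vals

    if "group" in raw.columns:
        df["group"] = raw["group"].astype(str)
    else:
        df["group"] = ["HC" if rid.upper().startswith("HC") else "PD" for rid in df["id"]]

    validate_clinical(df)
    return df


def validate_clinical(df: pd.DataFrame) -> None:
    if df["id"].duplicated().any():
        raise ValidationError("duplicate subject ids in clinical table")
    if (df["age"] <= 0).any() or df["age"].isna().any():
        raise ValidationError("all subjects need a positive age")
    pd_rows = df[df["group"] == "PD"]
    for col in ("updrs3", "updrs_axial", "sdq", "ledd", "disease_duration"):
        if pd_rows[col].isna().any():
            missing = pd_rows.loc[pd_rows[col].isna(), "id"].tolist()
            raise ValidationError(f"PD rows missing {col}: {missing}")
    hc_rows = df[df["group"] == "HC"]
    if hc_rows["sdq"].isna().any():
        raise ValidationError("HC rows must carry an SDQ score")


def _fixture_path(name: str):
    return resources.files(__package__) / "data" / name


def load_clinical_pd() -> pd.DataFrame:
    """Packaged study fixture: the 15 PD patients (demographics + scores)."""
    with resources.as_file(_fixture_path("clinical_pd.csv")) as p:
        return read_clinical_table(p)


def load_clinical_hc() -> pd.DataFrame:
    """Packaged study fixture: the 7 healthy controls."""
    with resources.as_file(_fixture_path("clinical_hc.csv")) as p:
        return read_clinical_table(p)


def load_clinical() -> pd.DataFrame:
    """Both cohorts, concatenated (22 subjects)."""
    return pd.concat([load_clinical_pd(), load_clinical_hc()], ignore_index=True)
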