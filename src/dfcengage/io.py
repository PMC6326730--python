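"""File formats: TSV component series, BIDS-style events.tsv, motion tables,
YAML paradigm/config, cohort directory trees."""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .paradigm import BehaviorEvent, Paradigm
from .signal_prep import ComponentTimeSeries
from .synthdata import SubjectRecord

EVENTS_COLUMNS = ["onset", "duration", "trial_type", "response_time", "correct"]


def write_timeseries(ts: ComponentTimeSeries, path: str | Path) -> None:
    pd.DataFrame(ts.data, columns=ts.component_ids).to_csv(
        path, sep="\t", index=False, float_format="%.10g")


def read_timeseries(path: str | Path, tr_seconds: float = 1.5) -> ComponentTimeSeries:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"component time-series file not found: {path}")
    df = pd.read_csv(path, sep="\t")
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values in time-series table")
    return ComponentTimeSeries(data=df.to_numpy(float), tr_seconds=tr_seconds,
                               component_ids=list(df.columns))


def write_events(events: list[BehaviorEvent], path: str | Path,
                 duration_s: float = 0.0) -> None:
    """BIDS events.tsv dialect: onset, duration, trial_type, response_time
    (n/a = miss), correct (0/1, n/a when missed)."""
    rows = []
    for e in events:
        rows.append({
            "onset": e.onset_s,
            "duration": duration_s,
            "trial_type": e.task,
            "response_time": e.rt_s if e.responded else "n/a",
            "correct": int(e.correct) if e.responded else "n/a",
        })
    pd.DataFrame(rows, columns=EVENTS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> list[BehaviorEvent]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"events file not found: {path}")
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    missing = [c for c in EVENTS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing events columns {missing}")
    events = []
    for i, row in df.iterrows():
        rt = row["response_time"]
        responded = not (isinstance(rt, float) and math.isnan(rt))
        try:
            events.append(BehaviorEvent(
                onset_s=float(row["onset"]),
                task=str(row["trial_type"]),
                responded=responded,
                correct=bool(int(row["correct"])) if responded else None,
                rt_s=float(rt) if responded else None,
            ))
        except (ValueError, TypeError) as err:
            raise ValueError(f"{path}:{i + 2}: bad event row ({err})") from err
    return events


def write_motion(motion: np.ndarray, path: str | Path) -> None:
    cols = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    pd.DataFrame(motion, columns=cols).to_csv(path, sep="\t", index=False,
                                              float_format="%.10g")


def read_motion(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"motion file not found: {path}")
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 motion columns, got {df.shape[1]}")
    return df.to_numpy(float)


def write_paradigm(paradigm: Paradigm, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(paradigm.to_dict(), sort_keys=False))


def read_paradigm(path: str | Path) -> Paradigm:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"paradigm file not found: {path}")
    return Paradigm.from_dict(yaml.safe_load(path.read_text()))


def write_cohort(paradigm: Paradigm, subjects: list[SubjectRecord],
                 out_dir: str | Path) -> Path:
    """Write a cohort directory: paradigm.yaml + per-subject sub-*/ tree."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_paradigm(paradigm, out / "paradigm.yaml")
    for rec in subjects:
        sdir = out / rec.subject_id
        sdir.mkdir(exist_ok=True)
        write_timeseries(rec.timeseries, sdir / "timeseries.tsv")
        write_events(rec.events, sdir / "events.tsv")
        write_motion(rec.motion, sdir / "motion.tsv")
        np.savetxt(sdir / "engagement.tsv", rec.engagement.e,
                   header="engagement", comments="", fmt="%.8g")
    return out


def read_cohort(in_dir: str | Path) -> tuple[Paradigm, list[dict]]:
    """Load a cohort directory; returns (paradigm, per-subject dicts with
    keys subject_id, timeseries, events, motion)."""
    in_dir = Path(in_dir)
    paradigm = read_paradigm(in_dir / "paradigm.yaml")
    subjects = []
    for sdir in sorted(in_dir.glob("sub-*")):
        subjects.append({
            "subject_id": sdir.name,
            "timeseries": read_timeseries(sdir / "timeseries.tsv",
                                          tr_seconds=paradigm.tr_seconds),
            "events": read_events(sdir / "events.tsv"),
            "motion": read_motion(sdir / "motion.tsv"),
        })
    if not subjects:
        raise FileNotFoundError(f"no sub-* directories under {in_dir}")
    return paradigm, subjects
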