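"""Block-design task paradigm: block schedule, analysis windows, windowed behavior.

The experiment alternates four conditions (rest, working memory, mental math,
visual search "video"), each presented twice as 120-TR (180 s) blocks separated
by 8-TR instruction periods, with the constraint that a task is never followed
by itself.  Connectivity analysis segments each block into non-overlapping
windows anchored at the block onset plus a hemodynamic shift; behavioral events
are binned into windows by their un-shifted stimulus-onset time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TASKS = ("rest", "memory", "math", "video")
#: active (responded) tasks, i.e. tasks with a behavioral event stream
ACTIVE_TASKS = ("memory", "math", "video")

#: inter-trial interval in seconds for each active task's stimulus grid
TRIAL_SPACING_S = {"memory": 3.0, "math": 5.0, "video": 11.25}


@dataclass(frozen=True)
class TaskBlock:
    task: str
    onset_tr: int          # 0-based TR index of block start
    duration_tr: int

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.duration_tr <= 0:
            raise ValueError("duration_tr must be positive")

    @property
    def end_tr(self) -> int:
        return self.onset_tr + self.duration_tr


@dataclass(frozen=True)
class Paradigm:
    blocks: tuple[TaskBlock, ...]
    tr_seconds: float = 1.5
    instruction_tr: int = 8
    n_trs_total: int = 1020

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        prev = None
        for b in self.blocks:
            if prev is not None:
                if b.onset_tr < prev.end_tr:
                    raise ValueError("blocks overlap or are unsorted")
                if b.task == prev.task:
                    raise ValueError("consecutive blocks share a task")
            prev = b
        if self.blocks and self.blocks[-1].end_tr > self.n_trs_total:
            raise ValueError("blocks extend past n_trs_total")

    @property
    def tasks(self) -> tuple[str, ...]:
        return tuple(sorted({b.task for b in self.blocks}))

    def block_order(self) -> list[str]:
        return [b.task for b in self.blocks]

    def to_dict(self) -> dict:
        return {
            "tr_seconds": self.tr_seconds,
            "instruction_tr": self.instruction_tr,
            "n_trs_total": self.n_trs_total,
            "blocks": [
                {"task": b.task, "onset_tr": b.onset_tr, "duration_tr": b.duration_tr}
                for b in self.blocks
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Paradigm":
        blocks = tuple(
            TaskBlock(b["task"], int(b["onset_tr"]), int(b["duration_tr"]))
            for b in d["blocks"]
        )
        return cls(
            blocks=blocks,
            tr_seconds=float(d["tr_seconds"]),
            instruction_tr=int(d["instruction_tr"]),
            n_trs_total=int(d["n_trs_total"]),
        )


@dataclass(frozen=True)
class Window:
    """Half-open TR span [start_tr, end_tr) of one analysis window.

    ``start_tr``/``end_tr`` index the acquired (hemodynamically delayed) series;
    ``shift_tr`` records the offset used, so the stimulus-time span of the
    window is [start_tr - shift_tr, end_tr - shift_tr).
    """

    index: int
    task: str
    start_tr: int
    end_tr: int
    block_index: int
    shift_tr: int = 0

    @property
    def length_tr(self) -> int:
        return self.end_tr - self.start_tr

    @property
    def stim_start_tr(self) -> int:
        return self.start_tr - self.shift_tr

    @property
    def stim_end_tr(self) -> int:
        return self.end_tr - self.shift_tr


@dataclass(frozen=True)
class BehaviorEvent:
    onset_s: float
    task: str
    responded: bool
    correct: bool | None = None   # defined only if responded
    rt_s: float | None = None     # defined only if responded

    def __post_init__(self) -> None:
        if self.responded:
            if self.rt_s is None or self.rt_s <= 0:
                raise ValueError("responded trial requires rt_s > 0")
            if self.correct is None:
                raise ValueError("responded trial requires correct flag")


def _valid_no_repeat(order: list[str]) -> bool:
    return all(a != b for a, b in zip(order, order[1:]))


def build_paradigm(
    seed: int,
    tasks: tuple[str, ...] = TASKS,
    n_repeats: int = 2,
    block_tr: int = 120,
    instruction_tr: int = 8,
    tr_seconds: float = 1.5,
    tail_tr: int = 4,
    max_tries: int = 10_000,
) -> Paradigm:
    """Randomize the block order so no task directly follows itself.

    Rejection-samples permutations of the task multiset (each task repeated
    ``n_repeats`` times).  Deterministic for a fixed seed.  ``tail_tr`` extra
    TRs are appended after the final block so that a hemodynamically shifted
    segmentation never runs off the end of the series.
    """
    multiset = [t for t in tasks for _ in range(n_repeats)]
    if len(set(tasks)) < 2 and len(multiset) > 1:
        raise ValueError("no valid order exists: need >= 2 distinct tasks")
    rng = np.random.default_rng(seed)
    order = None
    for _ in range(max_tries):
        cand = [str(t) for t in rng.permutation(multiset)]
        if _valid_no_repeat(cand):
            order = cand
            break
    if order is None:
        raise ValueError(f"no valid block order found in {max_tries} tries")

    blocks = []
    onset = 0
    for i, task in enumerate(order):
        blocks.append(TaskBlock(task=task, onset_tr=onset, duration_tr=block_tr))
        onset += block_tr
        if i < len(order) - 1:
            onset += instruction_tr
    return Paradigm(
        blocks=tuple(blocks),
        tr_seconds=tr_seconds,
        instruction_tr=instruction_tr,
        n_trs_total=onset + tail_tr,
    )


def segment_windows(paradigm: Paradigm, wl_tr: int = 30, shift_tr: int = 4) -> list[Window]:
    """Cut each block into floor(block_tr / wl_tr) non-overlapping windows.

    Windows are anchored at the shifted block onset; leftover TRs at block end
    (block_tr mod wl_tr) are discarded.
    """
    if wl_tr < 2:
        raise ValueError("wl_tr must be >= 2")
    if shift_tr < 0:
        raise ValueError("shift_tr must be >= 0")
    windows: list[Window] = []
    idx = 0
    for bi, block in enumerate(paradigm.blocks):
        n_win = block.duration_tr // wl_tr
        if n_win == 0:
            logger.warning(
                "block %d (%s): wl_tr=%d exceeds duration %d TRs; no windows",
                bi, block.task, wl_tr, block.duration_tr,
            )
            continue
        for w in range(n_win):
            start = block.onset_tr + shift_tr + w * wl_tr
            end = start + wl_tr
            if end > paradigm.n_trs_total:
                raise ValueError(
                    f"window [{start},{end}) exceeds series length "
                    f"{paradigm.n_trs_total}; increase tail padding"
                )
            windows.append(
                Window(index=idx, task=block.task, start_tr=start, end_tr=end,
                       block_index=bi, shift_tr=shift_tr)
            )
            idx += 1
    return windows


def window_behavior(
    events: list[BehaviorEvent],
    windows: list[Window],
    paradigm: Paradigm,
    fd: np.ndarray | None = None,
) -> pd.DataFrame:
    """Aggregate trials into per-window behavioral summaries.

    A trial belongs to the window whose *un-shifted* stimulus-time TR span
    contains its onset (the hemodynamic shift aligns signal, not behavior).
    Returns one row per task window: n_trials, mean_rt_s (NaN when every trial
    was missed), accuracy (over responded trials), missing_rate (over all
    trials), and mean_fd over the window's acquired TRs when ``fd`` is given.
    """
    tr = paradigm.tr_seconds
    block_spans = [(b.onset_tr * tr, b.end_tr * tr) for b in paradigm.blocks]
    n_orphan = sum(
        1 for e in events
        if not any(lo <= e.onset_s < hi for lo, hi in block_spans)
    )
    if n_orphan:
        logger.warning("%d events fall outside all task blocks; ignored", n_orphan)

    rows = []
    for w in windows:
        if w.task == "rest":
            continue
        lo = w.stim_start_tr * tr
        hi = w.stim_end_tr * tr
        trials = [e for e in events if e.task == w.task and lo <= e.onset_s < hi]
        n = len(trials)
        responded = [e for e in trials if e.responded]
        rts = [e.rt_s for e in responded]
        rows.append({
            "window": w.index,
            "task": w.task,
            "n_trials": n,
            "mean_rt_s": float(np.mean(rts)) if rts else math.nan,
            "accuracy": (sum(e.correct for e in responded) / len(responded))
                        if responded else math.nan,
            "missing_rate": (n - len(responded)) / n if n else math.nan,
            "mean_fd": float(np.mean(fd[w.start_tr:w.end_tr]))
                       if fd is not None else math.nan,
            "all_missed": n > 0 and not responded,
        })
    return pd.DataFrame(rows)
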