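"""End-to-end orchestration: prep -> windows -> dFC -> states -> markers -> stats.

`analyze_subject` runs the single-subject chain (nuisance regression,
band-pass, shift-anchored windowing, windowed Fisher-z connectivity, QC,
correlation-distance k-means with paradigm labeling, distance-to-centroid
markers, windowed participation) and `run_cohort` assembles the group-level
long table and fits the crossed random-intercept LMEs, the per-task HE-LE
link contrasts, and the clustering-accuracy-versus-behavior Spearman screen.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, dfc, graph, signal_prep, stats
from .config import RunConfig
from .paradigm import ACTIVE_TASKS, BehaviorEvent, Paradigm, \
    segment_windows, window_behavior
from .signal_prep import ComponentTimeSeries

logger = logging.getLogger(__name__)

MARKERS = ("dist_he", "dist_le", "b_t")
OUTCOMES = ("mean_rt_s", "accuracy", "missing_rate")


def derive_seed(master: int, *key: int) -> int:
    """Counter-based child seed below 2**31, stable across runs."""
    ss = np.random.SeedSequence(entropy=master, spawn_key=key)
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class SubjectResult:
    subject_id: str
    stack: dfc.DFCStack
    model: clustering.StateModel | None  # None when QC-flagged
    accuracy: float                      # overall fraction over all windows
    task_accuracy: dict[str, float]      # per-task fraction
    table: pd.DataFrame                  # per task window: markers + behavior
    qc_flagged: bool
    qc_report: dict


@dataclass
class CohortResult:
    long_table: pd.DataFrame
    lme_table: pd.DataFrame
    spearman_table: pd.DataFrame
    contrasts: dict[str, pd.DataFrame]
    subject_results: list[SubjectResult] = field(repr=False, default_factory=list)
    dropped_subjects: list[str] = field(default_factory=list)

    @property
    def mean_clustering_accuracy(self) -> float:
        return float(np.mean([s.accuracy for s in self.subject_results]))


def analyze_subject(
    subject_id: str,
    ts: ComponentTimeSeries,
    events: list[BehaviorEvent],
    motion: np.ndarray,
    paradigm: Paradigm,
    config: RunConfig,
    seed: int,
) -> SubjectResult:
    if config.prep.regress_motion:
        ts = signal_prep.regress_nuisance(
            ts, signal_prep.motion_regressors(motion))
    if config.prep.bandpass:
        ts = signal_prep.bandpass(ts, low_hz=config.prep.low_hz,
                                  high_hz=config.prep.high_hz,
                                  order=config.prep.order)
    windows = segment_windows(paradigm, wl_tr=config.window.wl_tr,
                              shift_tr=config.window.shift_tr)
    stack = dfc.windowed_connectivity(ts, windows)
    flagged, qc_report = dfc.qc_low_variability(
        stack, threshold_r=config.cluster.qc_threshold_r)
    if flagged:
        # no dynamic information: skip state extraction, caller drops subject
        return SubjectResult(subject_id=subject_id, stack=stack, model=None,
                             accuracy=float("nan"), task_accuracy={},
                             table=pd.DataFrame(), qc_flagged=True,
                             qc_report=qc_report)

    model = clustering.kmeans_corr(
        stack.z, k=config.cluster.k, max_iter=config.cluster.max_iter,
        n_init=config.cluster.n_init, seed=derive_seed(seed, 1))
    tasks = stack.tasks
    model = clustering.label_clusters(model, tasks)
    accuracy = clustering.clustering_accuracy(model, tasks)
    task_acc = {}
    for task in sorted(set(tasks)):
        idx = [i for i, t in enumerate(tasks) if t == task]
        task_acc[task] = float(np.mean(
            [model.cluster_tasks[int(model.assignments[i])] == task for i in idx]))

    metrics = clustering.distances_to_centroids(stack, model)
    bt = graph.windowed_participation(
        stack, n_reps=config.graph.n_reps, tau=config.graph.tau,
        gamma=config.graph.gamma, seed=derive_seed(seed, 2))
    fd = np.abs(np.diff(motion, axis=0)).sum(axis=1)
    fd = np.concatenate([[0.0], fd])
    behavior = window_behavior(events, windows, paradigm, fd=fd)

    table = metrics.merge(bt[["window", "b_t", "n_modules", "q"]], on="window")
    table = table.merge(behavior.drop(columns=["task"]), on="window", how="left")
    table.insert(0, "subject", subject_id)
    return SubjectResult(subject_id=subject_id, stack=stack, model=model,
                         accuracy=accuracy, task_accuracy=task_acc,
                         table=table, qc_flagged=flagged, qc_report=qc_report)


def fit_group_stats(
    long_table: pd.DataFrame,
    subject_results: list[SubjectResult],
    config: RunConfig,
    tasks: tuple[str, ...] = ACTIVE_TASKS,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame]]:
    lme_rows = []
    for task in tasks:
        sub = long_table[long_table["task"] == task]
        for marker in MARKERS:
            for outcome in OUTCOMES:
                try:
                    res = stats.fit_lme(sub, outcome=outcome, marker=marker)
                    lme_rows.append({
                        "task": task, "marker": marker, "outcome": outcome,
                        "estimate": res.estimate, "t_value": res.t_value,
                        "df": res.df, "lrt_stat": res.lrt_stat,
                        "p_value": res.p_value, "n_rows": res.n_rows,
                    })
                except ValueError as err:
                    logger.warning("LME %s/%s/%s skipped: %s",
                                   task, marker, outcome, err)
                    lme_rows.append({
                        "task": task, "marker": marker, "outcome": outcome,
                        "estimate": np.nan, "t_value": np.nan, "df": 0,
                        "lrt_stat": np.nan, "p_value": np.nan, "n_rows": 0,
                    })
    lme_table = pd.DataFrame(lme_rows)

    acc_rows = []
    for s in subject_results:
        for task in tasks:
            beh = s.table[s.table["task"] == task]
            acc_rows.append({
                "subject": s.subject_id, "task": task,
                "clustering_accuracy": s.task_accuracy.get(task, np.nan),
                "mean_rt_s": beh["mean_rt_s"].mean(),
                "accuracy": beh["accuracy"].mean(),
                "missing_rate": beh["missing_rate"].mean(),
            })
    try:
        spearman = stats.accuracy_behavior_correlation(pd.DataFrame(acc_rows))
    except ValueError as err:
        logger.warning("accuracy-behavior screen skipped: %s", err)
        spearman = pd.DataFrame(columns=["task", "metric", "spearman_r",
                                         "p_value", "p_fdr"])

    contrasts: dict[str, pd.DataFrame] = {}
    for task in tasks:
        he = np.vstack([s.model.centroid_for_task(task) for s in subject_results])
        le = np.vstack([s.model.centroid_for_task("rest") for s in subject_results])
        try:
            contrasts[task] = stats.he_le_contrast(
                he, le, q_threshold=config.stats.fdr_q)
        except ValueError as err:
            logger.warning("HE-LE contrast for %s skipped: %s", task, err)
            contrasts[task] = pd.DataFrame()
    return lme_table, spearman, contrasts


def run_cohort(
    paradigm: Paradigm,
    subjects: list[dict],
    config: RunConfig,
    tasks: tuple[str, ...] = ACTIVE_TASKS,
) -> CohortResult:
    """Run the full analysis on a cohort.

    ``subjects`` is a list of dicts with keys subject_id, timeseries, events,
    motion (the shape `io.read_cohort` returns).  QC-flagged subjects are
    dropped before group statistics, mirroring the original exclusion of a
    low-variability subject.
    """
    results, dropped = [], []
    for i, rec in enumerate(subjects):
        res = analyze_subject(
            rec["subject_id"], rec["timeseries"], rec["events"], rec["motion"],
            paradigm, config, seed=derive_seed(config.seed, 100, i))
        if res.qc_flagged:
            logger.warning("subject %s dropped by low-variability QC",
                           rec["subject_id"])
            dropped.append(rec["subject_id"])
        else:
            results.append(res)
    if len(results) < 2:
        raise RuntimeError("fewer than 2 subjects survive QC")
    long_table = pd.concat([s.table for s in results], ignore_index=True)
    lme_table, spearman, contrasts = fit_group_stats(long_table, results,
                                                     config, tasks)
    return CohortResult(long_table=long_table, lme_table=lme_table,
                        spearman_table=spearman, contrasts=contrasts,
                        subject_results=results, dropped_subjects=dropped)


def write_results(result: CohortResult, config: RunConfig,
                  out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.long_table.to_csv(out / "long_table.csv", index=False)
    result.lme_table.to_csv(out / "lme_results.csv", index=False)
    result.spearman_table.to_csv(out / "spearman_results.csv", index=False)
    for task, df in result.contrasts.items():
        df.to_csv(out / f"contrast_{task}.csv", index=False)
    acc = pd.DataFrame([
        {"subject": s.subject_id, "clustering_accuracy": s.accuracy,
         **{f"accuracy_{t}": a for t, a in s.task_accuracy.items()},
         "qc_mean_pairwise_r": s.qc_report["mean_pairwise_r"]}
        for s in result.subject_results])
    acc.to_csv(out / "subject_accuracy.csv", index=False)
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "n_subjects_analyzed": len(result.subject_results),
        "dropped_subjects": result.dropped_subjects,
        "mean_clustering_accuracy": result.mean_clustering_accuracy,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
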