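"""Synthetic multi-task cohorts with engagement-coupled connectivity and behavior.

Each simulated subject runs through the block paradigm while a latent
engagement level e(t) in [0, 1] — a logistic-squashed Ornstein-Uhlenbeck
process — evolves on a tens-of-seconds timescale.  During a task block the
component time series are drawn from N(0, Sigma_t) with

    Sigma_t = e(t) * Sigma_task + (1 - e(t)) * Sigma_rest,

so high engagement pulls the windowed connectivity toward the task-specific
covariance state and low engagement back toward the rest state.  The same
e(t) drives behavior: reaction times grow, and misses and errors become more
likely, as (1 - e) rises.  Task states are built more globally integrated
(non-zero between-module correlation) than the strongly modular rest state,
so brainwide integration also tracks engagement.

Emulated acquisition: 61 components (configurable), TR = 1.5 s, 4 tasks x 2
blocks of 120 TRs separated by 8-TR instruction periods, and a 4-TR
hemodynamic delay between stimulus and signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .paradigm import (ACTIVE_TASKS, TRIAL_SPACING_S, BehaviorEvent, Paradigm,
                       Window, build_paradigm)
from .signal_prep import ComponentTimeSeries

__all__ = [
    "StateCovariances", "EngagementParams", "EngagementTrace",
    "BehaviorParams", "SubjectRecord", "make_state_covariances",
    "simulate_engagement", "simulate_subject", "simulate_cohort",
]


def nearest_correlation(mat: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """PSD repair: clip negative eigenvalues at zero, rescale to unit diagonal."""
    sym = (mat + mat.T) / 2.0
    w, v = np.linalg.eigh(sym)
    if w.min() >= -tol:
        out = sym
    else:
        out = (v * np.clip(w, 0.0, None)) @ v.T
    d = np.sqrt(np.diag(out))
    if np.any(d <= 0):
        raise ValueError("matrix not repairable to a correlation matrix")
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


@dataclass(frozen=True)
class StateCovariances:
    """Per-task correlation states plus the shared rest state."""

    task_corr: dict[str, np.ndarray]      # task -> C x C correlation matrix
    rest_corr: np.ndarray
    module_maps: dict[str, np.ndarray]    # task/rest -> module id per component
    n_components: int

    def corr_for(self, task: str) -> np.ndarray:
        return self.rest_corr if task == "rest" else self.task_corr[task]


def _block_corr(modules: np.ndarray, within_r: float, between_r: float) -> np.ndarray:
    same = modules[:, None] == modules[None, :]
    mat = np.where(same, within_r, between_r).astype(float)
    np.fill_diagonal(mat, 1.0)
    return mat


def make_state_covariances(
    n_components: int = 61,
    n_modules: int = 4,
    within_r: float = 0.6,
    between_r: float = 0.35,
    seed: int = 0,
    rest_between_r: float = 0.0,
    rest_within_r: float | None = None,
    tasks: tuple[str, ...] = ACTIVE_TASKS,
) -> StateCovariances:
    """Plant one modular correlation state per task plus a rest state.

    Each task gets its own random partition of the components into
    ``n_modules`` modules (within-module correlation ``within_r``,
    between-module ``between_r``); rest uses contiguous modules with
    ``rest_within_r`` (defaults to ``within_r``) and ``rest_between_r``
    (default 0: maximally segregated, so tasks are the more globally
    integrated states).  Matrices are repaired to nearest correlation if
    indefinite.  Deterministic per seed.
    """
    if rest_within_r is None:
        rest_within_r = within_r
    if not (-1.0 < between_r < within_r < 1.0):
        raise ValueError("require -1 < between_r < within_r < 1")
    if not (-1.0 < rest_between_r < rest_within_r < 1.0):
        raise ValueError("require -1 < rest_between_r < rest_within_r < 1")
    if n_modules < 1 or n_modules > n_components:
        raise ValueError("n_modules must be in [1, n_components]")
    rng = np.random.default_rng(seed)

    rest_modules = np.repeat(np.arange(n_modules),
                             -(-n_components // n_modules))[:n_components]
    rest_corr = nearest_correlation(
        _block_corr(rest_modules, rest_within_r, rest_between_r))

    task_corr: dict[str, np.ndarray] = {}
    module_maps: dict[str, np.ndarray] = {"rest": rest_modules}
    for task in tasks:
        modules = rest_modules[rng.permutation(n_components)]
        task_corr[task] = nearest_correlation(_block_corr(modules, within_r, between_r))
        module_maps[task] = modules
    return StateCovariances(task_corr=task_corr, rest_corr=rest_corr,
                            module_maps=module_maps, n_components=n_components)


@dataclass(frozen=True)
class EngagementParams:
    """Logistic-squashed OU process for the latent engagement level.

    ``x_{t+1} = x_t + theta (mu - x_t) + sigma N(0,1)``; ``e = 1/(1+exp(-x))``.
    Defaults give mean engagement ~0.75 with an autocorrelation time of
    ~20 TRs (30 s), i.e. fluctuations at the tens-of-seconds scale the
    windowed analysis targets.
    """

    mu: float = 0.95
    theta: float = 0.05          # mean reversion per TR
    sigma: float = 0.31          # innovation SD per TR
    subject_mu_sd: float = 0.5   # between-subject spread of mu


@dataclass(frozen=True)
class EngagementTrace:
    e: np.ndarray                # per-TR engagement in [0, 1], stimulus time
    params: EngagementParams
    seed: int

    def __post_init__(self) -> None:
        if np.any(self.e < 0) or np.any(self.e > 1):
            raise ValueError("engagement must lie in [0, 1]")


def simulate_engagement(n_trs: int, params: EngagementParams, seed: int) -> EngagementTrace:
    rng = np.random.default_rng(seed)
    x = np.empty(n_trs)
    sd_stat = params.sigma / np.sqrt(max(2 * params.theta - params.theta**2, 1e-12))
    x[0] = params.mu + sd_stat * rng.standard_normal()
    eps = rng.standard_normal(n_trs - 1) * params.sigma
    for t in range(1, n_trs):
        x[t] = x[t - 1] + params.theta * (params.mu - x[t - 1]) + eps[t - 1]
    e = 1.0 / (1.0 + np.exp(-x))
    return EngagementTrace(e=e, params=params, seed=seed)


@dataclass(frozen=True)
class BehaviorParams:
    """Engagement-to-behavior coupling.

    RT is lognormal noise around ``rt_baseline[task] + beta_rt * (1 - e)``;
    misses and errors are Bernoulli with logit-linear dependence on (1 - e).
    Baselines approximate the observed per-task means (RT ~1.0/2.27/1.34 s,
    missing ~13/2/30 %, accuracy ~93/94/67 % for memory/math/video).
    """

    beta_rt: float = 0.5                      # s per unit (1 - e)
    rt_lognorm_sd: float = 0.15
    rt_baseline: dict[str, float] = field(default_factory=lambda: {
        "memory": 0.85, "math": 2.10, "video": 1.20})
    miss_logit0: dict[str, float] = field(default_factory=lambda: {
        "memory": -2.75, "math": -5.0, "video": -1.65})
    error_logit0: dict[str, float] = field(default_factory=lambda: {
        "memory": -4.3, "math": -4.5, "video": -2.4})
    beta_miss: float = 3.0                    # logits per unit (1 - e)
    beta_error: float = 6.0
    subject_rt_sd: float = 0.2                # between-subject RT offset SD (s)


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    timeseries: ComponentTimeSeries
    events: list[BehaviorEvent]
    motion: np.ndarray               # TRs x 6 rigid-body parameters
    engagement: EngagementTrace
    tr_task: np.ndarray              # per-TR task label in stimulus time ('' = gap)
    delay_tr: int
    rt_offset_s: float = 0.0

    def __post_init__(self) -> None:
        n = self.timeseries.n_trs
        if len(self.engagement.e) != n or len(self.tr_task) != n \
                or self.motion.shape != (n, 6):
            raise ValueError("per-TR arrays must share the TR axis length")

    def framewise_displacement(self) -> np.ndarray:
        """Power-style FD: sum of absolute first differences of the six
        motion parameters (rotations already expressed in mm), leading zero."""
        fd = np.abs(np.diff(self.motion, axis=0)).sum(axis=1)
        return np.concatenate([[0.0], fd])

    def window_truth(self, windows: list[Window]) -> tuple[list[str], np.ndarray]:
        """Ground-truth task label and mean engagement per window
        (stimulus-time span)."""
        tasks, mean_e = [], []
        for w in windows:
            sl = slice(w.stim_start_tr, w.stim_end_tr)
            tasks.append(w.task)
            mean_e.append(float(self.engagement.e[sl].mean()))
        return tasks, np.asarray(mean_e)


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def _simulate_events(paradigm: Paradigm, e: np.ndarray, params: BehaviorParams,
                     rt_offset: float, rng: np.random.Generator) -> list[BehaviorEvent]:
    events: list[BehaviorEvent] = []
    tr = paradigm.tr_seconds
    for block in paradigm.blocks:
        if block.task == "rest":
            continue
        spacing = TRIAL_SPACING_S[block.task]
        n_trials = int(block.duration_tr * tr / spacing)
        for i in range(n_trials):
            onset = block.onset_tr * tr + i * spacing
            e_here = float(e[min(int(onset / tr), len(e) - 1)])
            lapse = 1.0 - e_here
            p_miss = _sigmoid(params.miss_logit0[block.task] + params.beta_miss * lapse)
            if rng.random() < p_miss:
                events.append(BehaviorEvent(onset_s=onset, task=block.task,
                                            responded=False))
                continue
            p_err = _sigmoid(params.error_logit0[block.task] + params.beta_error * lapse)
            correct = rng.random() >= p_err
            loc = params.rt_baseline[block.task] + rt_offset + params.beta_rt * lapse
            rt = max(loc, 0.05) * np.exp(params.rt_lognorm_sd * rng.standard_normal())
            events.append(BehaviorEvent(onset_s=onset, task=block.task,
                                        responded=True, correct=bool(correct),
                                        rt_s=float(rt)))
    return events


def simulate_subject(
    paradigm: Paradigm,
    states: StateCovariances,
    engagement_params: EngagementParams | None = None,
    behavior_params: BehaviorParams | None = None,
    seed: int = 0,
    delay_tr: int = 4,
    noise_sd: float = 0.0,
    ar_rho: float = 0.0,
    rt_offset_s: float = 0.0,
    subject_id: str = "sub-001",
) -> SubjectRecord:
    """Draw one subject: component series, behavioral events, motion trace.

    The observed series at TR t reflects the stimulus state at t - delay_tr
    (hemodynamic lag); instruction gaps and the padding tail use the rest
    covariance.  Optional AR(1) smoothing (``ar_rho``) and white observation
    noise (``noise_sd``) are applied after the state draw.
    """
    engagement_params = engagement_params or EngagementParams()
    behavior_params = behavior_params or BehaviorParams()
    if delay_tr < 0:
        raise ValueError("delay_tr must be >= 0")
    ss = np.random.SeedSequence(seed)
    s_eng, s_ts, s_beh, s_mot = (int(c.generate_state(1)[0] % 2**31)
                                 for c in ss.spawn(4))

    n = paradigm.n_trs_total
    trace = simulate_engagement(n, engagement_params, s_eng)
    tr_task = np.array([""] * n, dtype=object)
    for block in paradigm.blocks:
        tr_task[block.onset_tr:block.end_tr] = block.task

    # per-TR covariance in stimulus time, then delayed by delay_tr
    C = states.n_components
    rng = np.random.default_rng(s_ts)
    raw = np.empty((n, C))
    chol_cache: dict[tuple[str, int], np.ndarray] = {}
    e_q = np.round(trace.e, 3)  # quantize engagement for Cholesky reuse
    for t in range(n):
        t_stim = t - delay_tr
        task = tr_task[t_stim] if t_stim >= 0 else ""
        if task in ("", "rest"):
            key, sigma = ("rest", 0), states.rest_corr
        else:
            ee = e_q[t_stim]
            key = (task, int(ee * 1000))
            sigma = ee * states.task_corr[task] + (1.0 - ee) * states.rest_corr
        if key not in chol_cache:
            chol_cache[key] = np.linalg.cholesky(sigma)
        raw[t] = chol_cache[key] @ rng.standard_normal(C)
    if ar_rho:
        for t in range(1, n):
            raw[t] = ar_rho * raw[t - 1] + np.sqrt(1 - ar_rho**2) * raw[t]
    if noise_sd:
        raw += noise_sd * rng.standard_normal(raw.shape)

    ts = ComponentTimeSeries(
        data=raw, tr_seconds=paradigm.tr_seconds,
        component_ids=[f"IC{i + 1:03d}" for i in range(C)],
    )
    events = _simulate_events(paradigm, trace.e, behavior_params, rt_offset_s,
                              np.random.default_rng(s_beh))
    motion = np.cumsum(
        np.random.default_rng(s_mot).normal(scale=0.02, size=(n, 6)), axis=0)
    return SubjectRecord(subject_id=subject_id, timeseries=ts, events=events,
                         motion=motion, engagement=trace, tr_task=tr_task,
                         delay_tr=delay_tr, rt_offset_s=rt_offset_s)


def simulate_cohort(
    n_subjects: int = 24,
    paradigm: Paradigm | None = None,
    states: StateCovariances | None = None,
    engagement_params: EngagementParams | None = None,
    behavior_params: BehaviorParams | None = None,
    seed: int = 0,
    **subject_kwargs,
) -> tuple[Paradigm, list[SubjectRecord]]:
    """Simulate a cohort sharing one paradigm and one set of covariance states.

    All subjects traverse the same block order (as in the emulated experiment,
    which is what makes 'window' a crossed random effect), while per-subject
    engagement set-points and RT baselines are offset at random to create
    between-subject variance.  Per-subject seeds derive from the master seed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    engagement_params = engagement_params or EngagementParams()
    behavior_params = behavior_params or BehaviorParams()
    ss = np.random.SeedSequence(seed)
    s_par, s_states, s_off, *s_subj = (int(c.generate_state(1)[0] % 2**31)
                                       for c in ss.spawn(3 + n_subjects))
    if paradigm is None:
        paradigm = build_paradigm(seed=s_par)
    if states is None:
        states = make_state_covariances(seed=s_states)
    rng = np.random.default_rng(s_off)
    subjects = []
    for i in range(n_subjects):
        eng_i = replace(engagement_params,
                        mu=engagement_params.mu
                        + engagement_params.subject_mu_sd * rng.standard_normal())
        rt_off = behavior_params.subject_rt_sd * rng.standard_normal()
        subjects.append(simulate_subject(
            paradigm, states, eng_i, behavior_params, seed=s_subj[i],
            rt_offset_s=rt_off, subject_id=f"sub-{i + 1:03d}", **subject_kwargs,
        ))
    return paradigm, subjects
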