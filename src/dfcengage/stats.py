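"""Group-level inference for windowed engagement markers.

The central model is a linear mixed effects model with crossed random
intercepts for subject and window,

    y_sw = b0 + b1 * marker_sw + b2 * FD_sw + u_s + v_w + eps_sw,

u_s ~ N(0, sig_s^2), v_w ~ N(0, sig_w^2), eps ~ N(0, sig_e^2) independent.
All variables are z-scored beforehand.  Fitting is by maximum likelihood
(not REML, so likelihood-ratio tests across fixed-effect specifications are
valid): the marginal Gaussian likelihood with covariance
V = sig_e^2 (I + l_s Zs Zs' + l_w Zw Zw') is profiled over the fixed effects
and sig_e^2 and optimized over the two log variance ratios.  The p value for
a marker is the chi-square(1) likelihood-ratio test of the full model against
the model without the marker; FD stays in both models.  Row counts here are
a few hundred, so dense Cholesky algebra suffices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats
from scipy.optimize import minimize
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot z-score a constant vector")
    return (x - x.mean()) / sd


@dataclass(frozen=True)
class MarginalFit:
    beta: np.ndarray
    se: np.ndarray
    sigma2_subject: float
    sigma2_window: float
    sigma2_resid: float
    loglik: float
    converged: bool


@dataclass(frozen=True)
class LMEResult:
    estimate: float          # fixed-effect coefficient of the marker
    t_value: float
    df: int                  # residual df: rows - fixed effects
    lrt_stat: float
    p_value: float           # chi-square(1) LRT p
    full: MarginalFit
    reduced: MarginalFit
    n_rows: int


def _indicator(codes: np.ndarray) -> np.ndarray:
    levels, idx = np.unique(codes, return_inverse=True)
    Z = np.zeros((len(codes), len(levels)))
    Z[np.arange(len(codes)), idx] = 1.0
    return Z


class _MarginalProblem:
    """Profiled ML for y ~ X beta with V = sigma2 (I + l_s Zs Zs' + l_w Zw Zw').

    The random-effect design has q = n_subjects + n_windows columns, far
    fewer than rows, so the Woodbury identity reduces every likelihood
    evaluation to O(q^3) on precomputed cross-products:
    V0^{-1} = I - U G (I_q + U'U G)^{-1} U',  log|V0| = log|I_q + U'U G|.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, subject: np.ndarray,
                 window: np.ndarray) -> None:
        Zs, Zw = _indicator(subject), _indicator(window)
        U = np.hstack([Zs, Zw])
        self.n, self.p = X.shape
        self.q_s = Zs.shape[1]
        self.UtU = U.T @ U
        self.UtX = U.T @ X
        self.Uty = U.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def nll(self, log_lam: np.ndarray) -> float:
        out = self.solve(log_lam)
        return out[0]

    def solve(self, log_lam: np.ndarray):
        lam_s, lam_w = np.exp(np.clip(log_lam, -30.0, 30.0))
        q = self.UtU.shape[0]
        g = np.concatenate([np.full(self.q_s, lam_s),
                            np.full(q - self.q_s, lam_w)])
        A = np.eye(q) + g[:, None] * self.UtU          # I + G U'U
        sign, logdet = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf, None
        # M'V0^{-1}N = M'N - (U'M)' G (I + U'U G)^{-1} (U'N)
        #            = M'N - (U'M)' solve(A', g * (U'N))   since (I+U'UG)' = A
        gUtX = g[:, None] * self.UtX
        gUty = g * self.Uty
        W = np.linalg.solve(A, np.column_stack([gUtX, gUty]))
        XtVX = self.XtX - self.UtX.T @ W[:, :self.p]
        XtVy = self.Xty - self.UtX.T @ W[:, self.p]
        ytVy = self.yty - self.Uty @ W[:, self.p]
        try:
            c = np.linalg.cholesky(XtVX)
        except np.linalg.LinAlgError:
            return np.inf, None
        beta = np.linalg.solve(XtVX, XtVy)
        rss = ytVy - XtVy @ beta
        if rss <= 0:
            return np.inf, None
        sigma2 = rss / self.n
        nll = 0.5 * (self.n * np.log(2 * np.pi * sigma2) + logdet + self.n)
        cov_beta = sigma2 * np.linalg.inv(XtVX)
        return float(nll), (beta, np.sqrt(np.diag(cov_beta)), float(sigma2),
                            float(lam_s), float(lam_w))


_STARTS = ([-1.0, -1.0], [0.0, 0.0], [-4.0, -4.0], [1.0, -4.0], [-4.0, 1.0])


def _fit_marginal(y: np.ndarray, X: np.ndarray, subject: np.ndarray,
                  window: np.ndarray) -> MarginalFit:
    prob = _MarginalProblem(y, X, subject, window)
    best = None
    for x0 in _STARTS:
        res = minimize(prob.nll, np.array(x0), method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 400})
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun):
        raise RuntimeError(f"LME optimizer failed: {best}")
    nll, (beta, se, sigma2, lam_s, lam_w) = prob.solve(best.x)
    # variance components floored at ~0 by the log parameterization
    return MarginalFit(
        beta=beta, se=se,
        sigma2_subject=sigma2 * lam_s,
        sigma2_window=sigma2 * lam_w,
        sigma2_resid=sigma2,
        loglik=-nll,
        converged=bool(best.success),
    )


def fit_lme(
    table: pd.DataFrame,
    outcome: str,
    marker: str,
    fd_col: str = "mean_fd",
    subject_col: str = "subject",
    window_col: str = "window",
    standardize: bool = True,
) -> LMEResult:
    """Crossed random-intercept LME of a behavioral outcome on a dFC marker.

    Rows with a missing outcome or marker are dropped listwise; outcome,
    marker and FD are z-scored on the retained rows (``standardize=False``
    keeps the original scales, e.g. to read a coefficient in natural units).
    Returns the marker's estimate and t value from the full model and the
    chi-square(1) LRT p value against the reduced model without the marker
    (FD kept in both).
    """
    cols = [outcome, marker, fd_col, subject_col, window_col]
    data = table[cols].dropna(subset=[outcome, marker, fd_col])
    n = len(data)
    if data[subject_col].nunique() < 2 or data[window_col].nunique() < 2:
        raise ValueError("need >= 2 subjects and >= 2 windows")
    scale = zscore if standardize else (lambda v: np.asarray(v, float))
    y = scale(data[outcome].to_numpy())
    m = scale(data[marker].to_numpy())
    fd = scale(data[fd_col].to_numpy())
    subject = data[subject_col].to_numpy()
    window = data[window_col].to_numpy()

    X_full = np.column_stack([np.ones(n), m, fd])
    X_red = np.column_stack([np.ones(n), fd])
    full = _fit_marginal(y, X_full, subject, window)
    reduced = _fit_marginal(y, X_red, subject, window)
    lrt = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    if full.loglik < reduced.loglik - 1e-6:
        logger.warning("nested log-likelihoods out of order by %.2g "
                       "(optimizer tolerance)", reduced.loglik - full.loglik)
    p = float(spstats.chi2.sf(lrt, df=1))
    return LMEResult(
        estimate=float(full.beta[1]),
        t_value=float(full.beta[1] / full.se[1]),
        df=n - X_full.shape[1],
        lrt_stat=float(lrt),
        p_value=p,
        full=full, reduced=reduced, n_rows=n,
    )


def accuracy_behavior_correlation(
    per_subject: pd.DataFrame,
    accuracy_col: str = "clustering_accuracy",
    task_col: str = "task",
    metrics: tuple[str, ...] = ("mean_rt_s", "accuracy", "missing_rate"),
) -> pd.DataFrame:
    """Spearman correlation of per-subject clustering accuracy with mean
    behavior, Benjamini-Hochberg corrected over the (task x metric) family.

    ``per_subject`` has one row per subject x task with the clustering
    accuracy and subject-mean behavioral metrics.  Constant vectors yield a
    missing correlation (excluded from the FDR family).
    """
    rows = []
    for task, sub in per_subject.groupby(task_col):
        if len(sub) < 4:
            raise ValueError(f"need >= 4 subjects per task, got {len(sub)}")
        for metric in metrics:
            pair = sub[[accuracy_col, metric]].dropna()
            x, y = pair[accuracy_col].to_numpy(), pair[metric].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append({"task": task, "metric": metric,
                             "spearman_r": np.nan, "p_value": np.nan})
                continue
            r, p = spstats.spearmanr(x, y)
            rows.append({"task": task, "metric": metric,
                         "spearman_r": float(r), "p_value": float(p)})
    out = pd.DataFrame(rows)
    ok = out["p_value"].notna()
    out["p_fdr"] = np.nan
    if ok.any():
        out.loc[ok, "p_fdr"] = multipletests(out.loc[ok, "p_value"],
                                             method="fdr_bh")[1]
    return out


def he_le_contrast(
    he: np.ndarray,
    le: np.ndarray,
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """Link-wise one-sample one-tailed t tests on per-subject HE - LE patterns.

    ``he`` and ``le`` are (subjects x links) centroid matrices for one task
    and for rest.  For each link the paired difference d = HE - LE is tested
    one-tailed in both directions; p values are BH-adjusted across links
    within each direction and thresholded at q < ``q_threshold``.  Links with
    zero difference variance get p = 1.
    """
    he, le = np.asarray(he, float), np.asarray(le, float)
    if he.shape != le.shape:
        raise ValueError("he and le must have identical shape")
    n_subjects, n_links = he.shape
    if n_subjects < 3:
        raise ValueError("need >= 3 subjects")
    d = he - le
    sd = d.std(axis=0, ddof=1)
    dead = sd == 0
    if dead.any():
        logger.warning("%d links with zero difference variance; p set to 1",
                       int(dead.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = d.mean(axis=0) / (sd / np.sqrt(n_subjects))
    t[dead] = 0.0
    dof = n_subjects - 1
    p_gt = np.where(dead, 1.0, spstats.t.sf(t, dof))     # HE > LE
    p_lt = np.where(dead, 1.0, spstats.t.cdf(t, dof))    # LE > HE
    q_gt = multipletests(p_gt, method="fdr_bh")[1]
    q_lt = multipletests(p_lt, method="fdr_bh")[1]
    return pd.DataFrame({
        "link": np.arange(n_links),
        "t": t,
        "p_he_gt_le": p_gt, "q_he_gt_le": q_gt,
        "sig_he_gt_le": q_gt < q_threshold,
        "p_le_gt_he": p_lt, "q_le_gt_he": q_lt,
        "sig_le_gt_he": q_lt < q_threshold,
    })
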