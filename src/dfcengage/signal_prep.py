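"""Component time-series post-processing: nuisance regression, band-pass, shift.

The processing order is regress -> bandpass -> shift -> segment, and every
step is deterministic.  Band-pass limits default to 1/WL = 1/45 s ~ 0.0222 Hz
(suppressing fluctuations slower than the analysis window) and 0.18 Hz
(below task motor-response rates), applied zero-phase so no extra group delay
is introduced on top of the explicit hemodynamic shift.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComponentTimeSeries:
    """TRs x components activity matrix with sampling metadata."""

    data: np.ndarray
    tr_seconds: float
    component_ids: list[str]

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (TRs x components)")
        if self.data.shape[1] != len(self.component_ids):
            raise ValueError("component_ids length must match data columns")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_trs(self) -> int:
        return self.data.shape[0]

    @property
    def n_components(self) -> int:
        return self.data.shape[1]


def motion_regressors(motion: np.ndarray) -> np.ndarray:
    """Stack motion parameters with their first derivatives (leading zero)."""
    motion = np.asarray(motion, dtype=float)
    deriv = np.vstack([np.zeros((1, motion.shape[1])), np.diff(motion, axis=0)])
    return np.hstack([motion, deriv])


def regress_nuisance(ts: ComponentTimeSeries, regressors: np.ndarray) -> ComponentTimeSeries:
    """Project out [intercept, regressors] from every component (OLS residuals).

    Collinear regressor columns are dropped with a warning (rank-revealing QR
    by column pivoting through numpy's lstsq handles the projection either
    way; the warning flags the redundancy).
    """
    X = np.asarray(regressors, dtype=float)
    if X.ndim != 2 or X.shape[0] != ts.n_trs:
        raise ValueError("regressor rows must align with TRs")
    design = np.hstack([np.ones((ts.n_trs, 1)), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        logger.warning("regressor matrix rank-deficient (%d < %d); "
                       "collinear columns are redundant", rank, design.shape[1])
    beta, *_ = np.linalg.lstsq(design, ts.data, rcond=None)
    resid = ts.data - design @ beta
    return replace(ts, data=resid)


def bandpass(
    ts: ComponentTimeSeries,
    low_hz: float = 0.0222,
    high_hz: float = 0.18,
    order: int = 6,
    pad_len: int = 100,
) -> ComponentTimeSeries:
    """Zero-phase Butterworth band-pass of the given overall order.

    ``order`` is the order of the band-pass filter itself (an order-6
    band-pass corresponds to scipy's N=3), applied forward-backward
    (sosfiltfilt) with reflect padding, so the effective magnitude response
    is squared and phase is zero.
    """
    nyq = 1.0 / (2 * ts.tr_seconds)
    if not (0 < low_hz < high_hz):
        raise ValueError("require 0 < low_hz < high_hz")
    if high_hz >= nyq:
        raise ValueError(f"high_hz {high_hz} must be below Nyquist {nyq:.4g} Hz")
    if order < 2 or order % 2:
        raise ValueError("order must be an even integer >= 2")
    sos = sps.butter(order // 2, [low_hz / nyq, high_hz / nyq],
                     btype="bandpass", output="sos")
    padlen = min(pad_len, ts.n_trs - 1)
    out = sps.sosfiltfilt(sos, ts.data, axis=0, padtype="even", padlen=padlen)
    return replace(ts, data=np.ascontiguousarray(out))


def hemodynamic_shift(ts: ComponentTimeSeries, shift_tr: int = 4) -> ComponentTimeSeries:
    """Re-index the series so sample t is attributed to stimulus time t - shift_tr.

    Returns the series with the first ``shift_tr`` samples dropped; segmenting
    the result with un-shifted windows is identical to segmenting the original
    with shift-anchored windows.
    """
    if shift_tr < 0:
        raise ValueError("shift_tr must be >= 0")
    if shift_tr >= ts.n_trs:
        raise ValueError("shift exceeds series length")
    if shift_tr == 0:
        return ts
    return replace(ts, data=ts.data[shift_tr:])


def preprocess(
    ts: ComponentTimeSeries,
    motion: np.ndarray | None = None,
    low_hz: float = 0.0222,
    high_hz: float = 0.18,
    order: int = 6,
) -> ComponentTimeSeries:
    """Standard prep chain: motion(+derivative) regression then band-pass.

    The hemodynamic shift is left to window segmentation (shift-anchored
    windows), so the TR axis stays aligned with the paradigm.
    """
    if motion is not None:
        ts = regress_nuisance(ts, motion_regressors(motion))
    return bandpass(ts, low_hz=low_hz, high_hz=high_hz, order=order)
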