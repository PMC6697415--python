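"""Raw-recording containers and preprocessing: notch filter, common-average
reference, epoching, and VAR detrending with AIC order selection.

The pipeline mirrors standard intracranial-EEG practice for volatility
modelling: line noise is removed with a zero-phase band-stop filter, channels
are re-referenced to the common average of the montage, the continuous record
is cut into fixed-length encoding epochs, and a low-order vector
autoregression fitted across epochs removes linear autocorrelation so that
what remains is (approximately) serially uncorrelated noise whose
*conditional variance* carries the structure of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "RawSession",
    "EpochedData",
    "notch_filter",
    "common_average_reference",
    "epoch_events",
    "select_var_order_aic",
    "detrend_var",
    "NotchFilter",
    "CommonAverageReference",
    "VARDetrender",
]

REGION_LABELS = ("Hipp", "EC", "PRC", "PHC")
#: hippocampal subfield labels that collapse to "Hipp"
HIPP_SUBFIELDS = ("CA1", "CA3", "DG", "Sub")


def collapse_region(label: str) -> str:
    return "Hipp" if label in HIPP_SUBFIELDS else label


@dataclass
class RawSession:
    """A continuous multichannel recording with event metadata.

    samples : (channels, time) voltage array
    fs : sampling rate in Hz
    channel_meta : DataFrame with columns channel, region, hemisphere
    event_onsets : sample indices of event starts, strictly increasing
    event_labels : DataFrame with columns recalled (bool) and session (id)
    """

    samples: np.ndarray
    fs: float
    channel_meta: pd.DataFrame
    event_onsets: np.ndarray
    event_labels: pd.DataFrame
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.event_onsets = np.asarray(self.event_onsets, dtype=int)
        if self.fs <= 360.0:
            raise ValueError("fs must exceed 360 Hz (2×180 Hz analysis band)")
        if np.any(np.diff(self.event_onsets) <= 0):
            raise ValueError("event onsets must be strictly increasing")
        if "region" not in self.channel_meta.columns:
            raise ValueError("channel_meta must carry a region column")
        missing = self.channel_meta["region"].isna()
        if missing.any():
            ids = self.channel_meta.loc[missing, "channel"].tolist()
            raise ValueError(f"channels without region label: {ids}")
        if len(self.channel_meta) != self.samples.shape[0]:
            raise ValueError("channel_meta length does not match channel count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]


@dataclass
class EpochedData:
    """Epoched observations: data is (events, channels, samples)."""

    data: np.ndarray
    fs: float
    labels: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    channel_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoched data must be (events, channels, samples)")
        if np.isnan(self.data).any():
            raise ValueError("epoched data contains missing values")
        if self.labels is None:
            self.labels = pd.DataFrame({
                "recalled": np.zeros(self.data.shape[0], dtype=bool),
                "session": np.zeros(self.data.shape[0], dtype=int),
            })
        if self.channel_meta is None:
            self.channel_meta = pd.DataFrame({
                "channel": [f"ch{j}" for j in range(self.data.shape[1])],
                "region": ["Hipp"] * self.data.shape[1],
                "hemisphere": ["L"] * self.data.shape[1],
            })

    @property
    def n_events(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


def notch_filter(x: np.ndarray, fs: float, center: float = 60.0,
                 width: float = 5.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-stop around the mains frequency.

    A 4th-order band-stop with a 5 Hz stopband (57.5–62.5 Hz for 60 Hz mains)
    applied forward–backward (``sosfiltfilt``), so the output is free of phase
    distortion that would otherwise corrupt lagged cross-channel structure.
    Operates along the last axis; length is preserved.
    """
    x = np.asarray(x, dtype=float)
    hi = center + width / 2.0
    if fs <= 2.0 * hi:
        raise ValueError(f"fs={fs} too low for a stopband reaching {hi} Hz")
    sos = signal.butter(order, [center - width / 2.0, hi],
                        btype="bandstop", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def common_average_reference(x: np.ndarray) -> np.ndarray:
    """Subtract the across-channel mean at every sample (channels on axis 0)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return x - x.mean(axis=0, keepdims=True)


def epoch_events(session: RawSession, window_s: float = 1.6) -> EpochedData:
    """Cut [onset, onset + round(window_s·fs)) windows, one per event.

    Windows are half-open in 0-based samples; overlapping onsets are allowed
    and simply share samples.  An onset whose window exceeds the recording
    raises an error naming the offending event.
    """
    n = int(round(window_s * session.fs))
    T = session.samples.shape[1]
    epochs = np.empty((len(session.event_onsets), session.n_channels, n))
    for i, onset in enumerate(session.event_onsets):
        if onset < 0 or onset + n > T:
            raise ValueError(
                f"event {i} at sample {onset}: window [{onset}, {onset + n}) "
                f"exceeds recording of length {T}")
        epochs[i] = session.samples[:, onset:onset + n]
    return EpochedData(data=epochs, fs=session.fs,
                       labels=session.event_labels.reset_index(drop=True),
                       channel_meta=session.channel_meta)


def _var_design(data: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Stack lagged design/response across epochs for a VAR(p) fit.

    data : (events, channels, samples).  Returns X of shape (n, J·p + 1)
    (intercept last) and Y of shape (n, J) with n = events·(samples − p).
    """
    E, J, T = data.shape
    Y = data[:, :, p:].transpose(0, 2, 1).reshape(-1, J)
    cols = [data[:, :, p - k:T - k].transpose(0, 2, 1).reshape(-1, J)
            for k in range(1, p + 1)]
    cols.append(np.ones((Y.shape[0], 1)))
    X = np.concatenate(cols, axis=1)
    return X, Y


def _var_fit(data: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Pooled VAR(p) least-squares fit across epochs.

    Returns (coefs of shape (p, J, J), residuals of shape (events, channels,
    samples − p), log-determinant of the residual covariance).
    """
    E, J, T = data.shape
    if p >= T:
        raise ValueError(f"order p={p} requires epochs longer than {p} samples")
    if p == 0:
        mean = data.mean(axis=(0, 2), keepdims=True)
        resid = data - mean
        flat = resid.transpose(0, 2, 1).reshape(-1, J)
        cov = flat.T @ flat / flat.shape[0]
        return np.zeros((0, J, J)), resid, _logdet_psd(cov)
    X, Y = _var_design(data, p)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid_flat = Y - X @ coef
    cov = resid_flat.T @ resid_flat / resid_flat.shape[0]
    A = coef[:-1].reshape(p, J, J).transpose(0, 2, 1)  # A[k][j, :] acts on lag k
    resid = resid_flat.reshape(E, T - p, J).transpose(0, 2, 1)
    return A, resid, _logdet_psd(cov)


def _logdet_psd(cov: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(cov + 1e-300 * np.eye(cov.shape[0]))
    return float(logdet) if sign > 0 else -np.inf


def select_var_order_aic(epochs: EpochedData | np.ndarray, p_max: int = 10) -> int:
    """Pick the VAR order minimizing AIC over p ∈ {0..p_max}, ties to smaller p.

    AIC = ln|Σ̂(p)| + 2(J²p + J)/n with Σ̂ the pooled residual covariance and
    n the number of response rows.  All orders are scored on the same
    response window (dropping p_max leading samples) so likelihoods are
    comparable.
    """
    data = epochs.data if isinstance(epochs, EpochedData) else np.asarray(epochs)
    if data.ndim == 2:
        data = data[None]
    E, J, T = data.shape
    if p_max < 0:
        raise ValueError("p_max must be >= 0")
    if T <= p_max + 1:
        raise ValueError(f"epochs of {T} samples are too short for p_max={p_max}")
    best_p, best_aic = 0, np.inf
    n = E * (T - p_max)
    for p in range(p_max + 1):
        # score on the common window data[:, :, p_max - p:]
        _, _, logdet = _var_fit(data[:, :, p_max - p:], p)
        aic = logdet + 2.0 * (J * J * p + J) / n
        if aic < best_aic - 1e-12:
            best_aic, best_p = aic, p
    return best_p


def detrend_var(epochs: EpochedData, p: int) -> EpochedData:
    """Remove a pooled VAR(p) fit, returning the residual epochs.

    Coefficients are estimated once across all epochs of the session (epochs
    treated as independent realizations of the same process); the first p
    samples of each epoch are dropped.  With p = 0 this is per-channel mean
    removal.
    """
    if p < 0:
        raise ValueError("p must be >= 0")
    if p >= epochs.n_samples:
        raise ValueError(f"p={p} >= epoch length {epochs.n_samples}")
    _, resid, _ = _var_fit(epochs.data, p)
    return replace(epochs, data=resid)


# --- sklearn-style wrappers -------------------------------------------------

from sklearn.base import BaseEstimator, TransformerMixin  # noqa: E402


class NotchFilter(TransformerMixin, BaseEstimator):
    """Transformer wrapper around :func:`notch_filter` (stateless)."""

    def __init__(self, fs: float = 1000.0, center: float = 60.0,
                 width: float = 5.0, order: int = 4):
        self.fs = fs
        self.center = center
        self.width = width
        self.order = order

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return notch_filter(X, self.fs, self.center, self.width, self.order)


class CommonAverageReference(TransformerMixin, BaseEstimator):
    """Transformer wrapper around :func:`common_average_reference`."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return common_average_reference(X)


class VARDetrender(TransformerMixin, BaseEstimator):
    """Select a VAR order by AIC (fit) and return residual epochs (transform)."""

    def __init__(self, p: int | None = None, p_max: int = 10):
        self.p = p
        self.p_max = p_max

    def fit(self, X: EpochedData, y=None):
        self.order_ = self.p if self.p is not None else select_var_order_aic(
            X, self.p_max)
        return self

    def transform(self, X: EpochedData) -> EpochedData:
        return detrend_var(X, self.order_)
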