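"""Synthetic MSV data with known ground truth.

Generates (i) epoched observations drawn exactly from the MSV model, for
sampler and pipeline validation; (ii) condition pairs (recalled vs
non-recalled) whose persistence matrices differ by a planted region-level
contrast, for end-to-end recovery of directional-connectivity effects; and
(iii) raw continuous sessions with 60 Hz line noise, an autoregressive trend
and a common offset, exercising the preprocessing chain.

Events are independent given the parameters (the model shares parameters
across encoding events) and each event's initial latent state is drawn from
the stationary law of the latent VAR(1).  Seeding is counter-based: one
master seed spawns a substream per event, so changing the event count does
not reshuffle earlier events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .core import MSVParams, LatentPaths, stationary_moments, stationarity_check
from .preprocessing import EpochedData, RawSession, collapse_region

__all__ = [
    "SimulationSpec",
    "ConditionPair",
    "simulate_msv",
    "make_condition_pair",
    "make_raw_fixture",
    "default_benchmark_params",
]


@dataclass
class SimulationSpec:
    """Size, parameters and labelling of a synthetic MSV dataset.

    The defaults emulate the structure of list-learning iEEG experiments:
    1.6 s encoding epochs (samples_per_event = round(1.6·fs)) and a few
    dozen events per session.
    """

    n_channels: int
    n_events: int
    samples_per_event: int
    params: MSVParams
    region_labels: list[str] = field(default=None)  # type: ignore[assignment]
    seed: int = 0
    fs: float = 500.0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        if self.samples_per_event < 2:
            raise ValueError("need at least two samples per event")
        if self.region_labels is None:
            self.region_labels = ["Hipp"] * self.n_channels
        if len(self.region_labels) != self.n_channels:
            raise ValueError("region labels must cover every channel")
        if self.params.n_channels != self.n_channels:
            raise ValueError("params dimension does not match n_channels")
        self.params.validate()
        if np.any(self.params.sigma2 < 0):
            raise ValueError("sigma2 must be non-negative")

    def channel_meta(self) -> pd.DataFrame:
        return pd.DataFrame({
            "channel": [f"ch{j}" for j in range(self.n_channels)],
            "region": [collapse_region(r) for r in self.region_labels],
            "hemisphere": ["L"] * self.n_channels,
        })


@dataclass
class ConditionPair:
    """Recalled / non-recalled parameter sets differing only in β."""

    params_R: MSVParams
    params_NR: MSVParams
    delta: pd.DataFrame  # region × region planted contrast (R − NR)

    def __post_init__(self) -> None:
        if not np.array_equal(self.params_R.mu, self.params_NR.mu) or \
                not np.array_equal(self.params_R.sigma2, self.params_NR.sigma2):
            raise ValueError("condition pair must differ only in beta")
        self.params_R.validate()
        self.params_NR.validate()


def _psd_sqrt(V: np.ndarray) -> np.ndarray:
    """Symmetric square root of a PSD matrix, tolerating exact singularity."""
    w, U = np.linalg.eigh((V + V.T) / 2.0)
    return U * np.sqrt(np.clip(w, 0.0, None)) @ U.T


def _event_rng(seed: int, event: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(event,)))


def simulate_msv(spec: SimulationSpec) -> tuple[EpochedData, LatentPaths]:
    """Draw observations and true latent log-volatility from the MSV model.

    Per event: x₀ ~ N(μ, V₀) with V₀ the stationary covariance, then
    x_t = μ + β(x_{t−1} − μ) + ε with ε ~ N(0, diag(σ²)), and
    y_t = exp(x_t/2)·ε^y with ε^y standard normal.  Bit-reproducible for a
    given seed and independent of n_events for earlier events.
    """
    J, T = spec.n_channels, spec.samples_per_event
    mu, V0 = stationary_moments(spec.params)
    S0 = _psd_sqrt(V0)
    sig = np.sqrt(spec.params.sigma2)
    beta = spec.params.beta
    x = np.empty((spec.n_events, J, T))
    y = np.empty_like(x)
    for e in range(spec.n_events):
        rng = _event_rng(spec.seed, e)
        xe = np.empty((T, J))
        xe[0] = mu + S0 @ rng.standard_normal(J)
        innov = rng.standard_normal((T - 1, J)) * sig
        for t in range(1, T):
            xe[t] = mu + beta @ (xe[t - 1] - mu) + innov[t - 1]
        x[e] = xe.T
        y[e] = np.exp(x[e] / 2.0) * rng.standard_normal((J, T))
    labels = pd.DataFrame({"recalled": np.zeros(spec.n_events, dtype=bool),
                           "session": np.zeros(spec.n_events, dtype=int)})
    data = EpochedData(data=y, fs=spec.fs, labels=labels,
                       channel_meta=spec.channel_meta())
    return data, LatentPaths(x=x)


def make_condition_pair(base: MSVParams, delta_spec: dict[tuple[str, str], float],
                        region_labels: list[str]) -> ConditionPair:
    """Plant directed region-level contrasts into the persistence matrix.

    ``delta_spec`` maps ordered region pairs (source I, target J) to the
    contrast Δ_{I→J} added to the recalled-condition β on the block with
    target rows j∈J and source columns i∈I (β[j, i] convention).  The
    non-recalled condition keeps the base β; μ and σ² are shared.
    """
    region_labels = [collapse_region(r) for r in region_labels]
    beta_R = base.beta.copy()
    regions = sorted(set(region_labels))
    delta = pd.DataFrame(0.0, index=regions, columns=regions)
    for (src, tgt), d in delta_spec.items():
        rows = [j for j, r in enumerate(region_labels) if r == tgt]
        cols = [i for i, r in enumerate(region_labels) if r == src]
        if not rows or not cols:
            raise ValueError(f"no electrodes for pair {src}->{tgt}")
        beta_R[np.ix_(rows, cols)] += d
        delta.loc[src, tgt] += d
    if not stationarity_check(beta_R):
        raise ValueError("planted contrast breaks stationarity of beta")
    params_R = MSVParams(base.mu.copy(), beta_R, base.sigma2.copy())
    params_NR = base.copy()
    params_NR.validate()
    return ConditionPair(params_R=params_R, params_NR=params_NR, delta=delta)


def make_raw_fixture(spec: SimulationSpec, line_amp: float = 0.0,
                     ar_coeffs=(), fs: float | None = None,
                     common_offset: float = 0.0, isi_samples: int = 0
                     ) -> RawSession:
    """Build a continuous raw session around MSV epochs.

    MSV innovations fill the event windows (white unit-variance noise fills
    any inter-stimulus gaps); the whole record is passed through an AR filter
    with coefficients ``ar_coeffs`` (trend to be removed by VAR detrending),
    then a 60 Hz sinusoid of amplitude ``line_amp`` and a constant
    across-channel common offset are added.  Ground truth (clean epochs,
    latents, parameters, onsets) is stored for recovery tests.
    """
    fs = float(fs if fs is not None else spec.fs)
    if fs not in (500.0, 1000.0, 1600.0):
        raise ValueError("fs must be one of 500, 1000, 1600 Hz")
    ar = np.asarray(ar_coeffs, dtype=float)
    if ar.size and np.any(np.abs(np.roots(np.r_[1.0, -ar])) >= 1.0):
        raise ValueError("ar_coeffs define an unstable AR filter")
    data, latents = simulate_msv(spec)
    E, J, T = data.data.shape
    total = E * (T + isi_samples)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(1 << 20,)))
    raw = rng.standard_normal((J, total))
    onsets = np.arange(E) * (T + isi_samples)
    for e, onset in enumerate(onsets):
        raw[:, onset:onset + T] = data.data[e]
    clean = raw.copy()
    if ar.size:
        raw = signal.lfilter([1.0], np.r_[1.0, -ar], raw, axis=-1)
    t = np.arange(total) / fs
    raw = raw + line_amp * np.sin(2.0 * np.pi * 60.0 * t) + common_offset
    labels = data.labels.copy()
    return RawSession(
        samples=raw, fs=fs, channel_meta=spec.channel_meta(),
        event_onsets=onsets, event_labels=labels,
        ground_truth={"params": spec.params, "latents": latents,
                      "clean": clean, "epochs": data, "ar_coeffs": ar,
                      "line_amp": line_amp, "common_offset": common_offset})


def default_benchmark_params(J: int = 3, seed: int = 7) -> MSVParams:
    """The standard synthetic benchmark: stationary β with nonzero off-diagonals.

    Diagonal persistence around 0.85 (volatility is highly persistent in both
    neural and financial series), modest directed off-diagonal couplings, and
    volatility-of-volatility σ² = 0.1.
    """
    rng = np.random.default_rng(seed)
    beta = np.diag(np.full(J, 0.85))
    off = 0.08 * np.sign(rng.standard_normal((J, J)))
    off[np.diag_indices(J)] = 0.0
    beta = beta + off
    # shrink until comfortably stationary
    while not stationarity_check(0.999 * beta):
        off *= 0.8
        beta = np.diag(np.full(J, 0.85)) + off
    mu = np.linspace(-0.5, 0.5, J)
    return MSVParams(mu=mu, beta=beta, sigma2=np.full(J, 0.1))
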