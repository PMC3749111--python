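"""Raw multichannel signal -> z-scored band envelopes at 100 Hz.

The chain is: common average reference, a bank of 4th-order Butterworth
bandpasses over the seven sensorimotor bands, full-wave rectification,
2nd-order low-pass smoothing at 2.2 Hz, decimation to 100 Hz, and per-feature
z-scoring.  Filtering is causal (forward-only) by default so every feature
sample depends only on past raw samples — the decoder is then implementable
in real time; a zero-phase mode exists for offline exploration.

Decimation keeps every k-th sample without an extra anti-alias stage: the
2.2 Hz smoother already attenuates content near the 50 Hz output Nyquist by
far more than 40 dB.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .config import PipelineConfig

__all__ = [
    "FeatureSeries",
    "common_average_reference",
    "bandpass_filterbank",
    "envelope",
    "downsample",
    "zscore_normalize",
    "band_envelopes",
    "preprocess",
]

log = logging.getLogger(__name__)


@dataclass
class FeatureSeries:
    """Per-channel, per-band z-scored envelopes on the 100 Hz grid.

    ``envelopes`` has one column per retained (channel, band) pair, ordered
    channel-major.  ``mu`` and ``sigma`` are the normalization constants
    computed on the stats window, stored so held-out data can be normalized
    with training statistics.
    """

    envelopes: np.ndarray                 # time x features, z-scores
    fs: float
    channel_of_feature: np.ndarray        # feature -> channel index
    band_of_feature: np.ndarray           # feature -> band index
    band_names: tuple[str, ...]
    mu: np.ndarray
    sigma: np.ndarray
    channel_labels: list[str] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.envelopes.shape[1]

    def __len__(self) -> int:
        return self.envelopes.shape[0]

    def feature_name(self, j: int) -> str:
        ch = int(self.channel_of_feature[j])
        label = self.channel_labels[ch] if self.channel_labels else f"ch{ch}"
        return f"{label}:{self.band_names[int(self.band_of_feature[j])]}"

    def band_feature_mask(self, band: str) -> np.ndarray:
        """Boolean mask selecting the features of one named band."""
        if band not in self.band_names:
            raise ValueError(f"unknown band {band!r}; have {self.band_names}")
        return self.band_of_feature == self.band_names.index(band)


def common_average_reference(signal: np.ndarray) -> np.ndarray:
    """Subtract the across-channel mean at every sample (CAR re-referencing)."""
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 2 or signal.shape[1] < 2:
        raise ValueError("CAR needs a time x channels matrix with >= 2 channels")
    return signal - signal.mean(axis=1, keepdims=True)


def _apply(sos: np.ndarray, x: np.ndarray, mode: str) -> np.ndarray:
    if mode == "zero_phase":
        return sps.sosfiltfilt(sos, x, axis=0)
    return sps.sosfilt(sos, x, axis=0)


def bandpass_filterbank(
    signal: np.ndarray,
    band_edges: tuple[tuple[float, float], ...],
    order: int,
    fs: float,
    mode: str = "causal",
) -> np.ndarray:
    """Filter each channel through every band; output time x (channels*bands).

    Columns are channel-major: channel c, band b maps to column
    ``c * n_bands + b``.
    """
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    nyq = fs / 2.0
    for lo, hi in band_edges:
        if hi >= nyq or lo <= 0:
            raise ValueError(f"band ({lo}, {hi}) Hz outside (0, Nyquist={nyq}) Hz")
    if order < 1:
        raise ValueError("filter order must be >= 1")
    n_t, n_ch = signal.shape
    n_b = len(band_edges)
    out = np.empty((n_t, n_ch * n_b))
    for b, (lo, hi) in enumerate(band_edges):
        sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
        out[:, b::n_b] = _apply(sos, signal, mode)
    return out


def bandpass_gain(band: tuple[float, float], order: int, freq: float) -> float:
    """Analytic magnitude of the analog Butterworth bandpass prototype at
    ``freq`` Hz — the independent reference the digital filter is checked
    against (valid well below Nyquist, where bilinear warping is negligible)."""
    lo, hi = band
    x = (freq**2 - lo * hi) / (freq * (hi - lo))
    return 1.0 / np.sqrt(1.0 + x ** (2 * order))


def envelope(
    band_signal: np.ndarray,
    lp_cutoff: float,
    lp_order: int,
    fs: float,
    mode: str = "causal",
) -> np.ndarray:
    """Rectify (absolute value) and smooth with a low-pass Butterworth.

    The output tracks the within-band amplitude: a unit sinusoid settles to
    about 2/pi, the mean of a rectified sine, since the smoother passes DC
    with unit gain.
    """
    if lp_cutoff >= fs / 2:
        raise ValueError("lp_cutoff must be below Nyquist")
    sos = sps.butter(lp_order, lp_cutoff, btype="low", fs=fs, output="sos")
    return _apply(sos, np.abs(np.asarray(band_signal, dtype=float)), mode)


def downsample(series: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Decimate by keeping every (fs_in/fs_out)-th sample, starting at 0."""
    ratio = fs_in / fs_out
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9 or k < 1:
        raise ValueError(f"fs_in/fs_out must be a positive integer, got {ratio}")
    return np.asarray(series)[::k]


def zscore_normalize(
    env: np.ndarray,
    stats_window: np.ndarray | None = None,
    strict: bool = False,
    mu: np.ndarray | None = None,
    sigma: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """z = (x - mu) / sigma with statistics from ``stats_window`` rows only.

    Uses the population (1/N) standard deviation.  Returns
    ``(z, mu, sigma, keep)`` where ``keep`` marks features with positive
    variance on the window; zero-variance features are dropped with a
    warning (or raise in strict mode).  Precomputed ``mu``/``sigma`` can be
    supplied to normalize held-out data with training statistics.
    """
    env = np.atleast_2d(np.asarray(env, dtype=float))
    if mu is None or sigma is None:
        if stats_window is None:
            stats_window = np.arange(env.shape[0])
        stats_window = np.asarray(stats_window)
        if stats_window.size == 0:
            raise ValueError("stats_window is empty")
        win = env[stats_window]
        mu = win.mean(axis=0)
        sigma = win.std(axis=0)  # population form
    keep = sigma > 0
    if not np.all(keep):
        msg = f"{int(np.sum(~keep))} zero-variance features"
        if strict:
            raise ValueError(msg)
        log.warning("dropping %s", msg)
    z = (env[:, keep] - mu[keep]) / sigma[keep]
    return z, mu, sigma, keep


def band_envelopes(session, config: PipelineConfig) -> np.ndarray:
    """CAR -> filterbank -> rectify/smooth -> decimate (no normalization).

    Returns the raw envelope matrix on the ``config.fs_out`` grid with
    channel-major (channel, band) columns.  Split out from :func:`preprocess`
    so cross-validation can recompute only the z-scoring per fold.
    """
    car = common_average_reference(session.signal)
    banded = bandpass_filterbank(
        car, config.band_edges, config.bp_order, session.fs_signal, config.filter_mode
    )
    env = envelope(
        banded, config.lp_cutoff, config.lp_order, session.fs_signal, config.filter_mode
    )
    return downsample(env, session.fs_signal, config.fs_out)


def preprocess(
    session,
    config: PipelineConfig,
    stats_window: np.ndarray | None = None,
    envelopes: np.ndarray | None = None,
) -> FeatureSeries:
    """Full chain from a raw session to a :class:`FeatureSeries`.

    ``stats_window`` restricts the normalization statistics to a set of
    100 Hz sample indices (e.g. training-trial samples in cross-validation);
    the default uses the whole session.  A precomputed envelope matrix from
    :func:`band_envelopes` may be passed to skip the filtering stages.
    """
    if envelopes is None:
        envelopes = band_envelopes(session, config)
    n_bands = len(config.band_edges)
    n_ch = envelopes.shape[1] // n_bands
    if envelopes.shape[1] != n_ch * n_bands:
        raise ValueError("envelope column count is not a multiple of the band count")
    z, mu, sigma, keep = zscore_normalize(envelopes, stats_window)
    channel_of = np.repeat(np.arange(n_ch), n_bands)[keep]
    band_of = np.tile(np.arange(n_bands), n_ch)[keep]
    return FeatureSeries(
        envelopes=z,
        fs=config.fs_out,
        channel_of_feature=channel_of,
        band_of_feature=band_of,
        band_names=config.band_names,
        mu=mu[keep],
        sigma=sigma[keep],
        channel_labels=list(getattr(session, "channel_labels", [])),
    )
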