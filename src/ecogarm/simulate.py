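"""Synthetic sessions with the statistical structure the decoder assumes.

Kinematics: repeated block-transport cycles around a 25 cm square — per
trial, three sequential point-to-point transports among the square's
corners with grasp/release dwells, interpolated with minimum-jerk profiles
in joint-angle space between inverse-kinematics key postures (so marker
triples are always consistent with the arm geometry and free of
singularities), separated by rest epochs of exactly zero velocity.

Signal: each channel at 1000 Hz is a sum over bands of a unit-variance
band-limited carrier multiplied by a slowly varying envelope, plus a small
pink-noise floor.  Informative (channel, band) pairs get an envelope that
is a positive affine image of a sparse lagged combination of the kinematic
variables; the rest get envelope noise only.  Multiplicative amplitude
modulation is the generative inverse of rectify-and-low-pass envelope
extraction, so the decoding pipeline is the matched analysis for this
generator.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .config import PipelineConfig
from .io import RawSession, write_edf, write_session
from .kinematics import ArmGeometry, JointAngleSeries, forward_kinematics, inverse_kinematics

__all__ = ["SimulationSpec", "GroundTruth", "simulate_kinematics", "simulate_ecog",
           "simulate_session", "make_benchmark_suite"]

log = logging.getLogger(__name__)

#: Names of the kinematic variables envelope couplings draw from.
COUPLING_POOL = (
    "q1", "q2", "q3", "q4",
    "elbow_x", "elbow_y", "elbow_z", "wrist_x", "wrist_y", "wrist_z",
)


@dataclass
class SimulationSpec:
    """Generator settings; a fixed seed makes every output bit-reproducible."""

    n_channels: int = 60
    n_trials: int = 9
    trial_duration_s: float = 16.0
    rest_duration_s: float = 3.0
    square_side: float = 0.25
    square_center: tuple[float, float, float] = (0.0, 0.28, -0.28)
    lift_height: float = 0.08
    dwell_s: float = 0.4
    informative_fraction: float = 0.3
    true_lag_s: float = 0.15
    envelope_snr: float = 10.0          # var(signal envelope)/var(envelope noise); 0 = no signal
    modulation_depth: float = 0.35
    carrier_type: str = "band_noise"    # or "sinusoid"
    broadband_noise: float = 0.1        # pink-noise amplitude relative to carrier scale
    fs_signal: float = 1000.0
    fs_markers: float = 100.0
    geometry: ArmGeometry = field(default_factory=ArmGeometry)
    bands: tuple[tuple[float, float], ...] = PipelineConfig().band_edges
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.informative_fraction <= 1.0):
            raise ValueError("informative_fraction must lie in [0, 1]")
        if self.envelope_snr < 0:
            raise ValueError("envelope_snr must be >= 0")
        if self.carrier_type not in ("band_noise", "sinusoid"):
            raise ValueError("carrier_type must be 'band_noise' or 'sinusoid'")
        if min(self.n_trials, self.n_channels) < 1 or self.trial_duration_s <= 0:
            raise ValueError("counts and durations must be positive")


@dataclass
class GroundTruth:
    """Everything needed for recovery tests: the generating kinematics, the
    informative (channel, band) pairs with their couplings, and the clean
    (pre-noise) envelopes."""

    angles: JointAngleSeries
    informative: list[tuple[int, int]]
    couplings: dict[tuple[int, int], dict]
    clean_envelopes: dict[tuple[int, int], np.ndarray]
    clipped_samples: int
    trial_bounds: list[tuple[int, int]]   # [start, end) movement epochs, 100 Hz grid


def _min_jerk(q0: np.ndarray, q1: np.ndarray, n: int) -> np.ndarray:
    s = np.linspace(0.0, 1.0, n, endpoint=False)
    h = 10 * s**3 - 15 * s**4 + 6 * s**5
    return q0 + (q1 - q0) * h[:, None]


def _posture_for_wrist(p: np.ndarray, geom: ArmGeometry) -> np.ndarray:
    """Key posture (q1..q4) reaching wrist position ``p`` with the elbow
    hanging on the natural (downward) side of the shoulder-wrist axis."""
    p = np.asarray(p, float)
    d = float(np.linalg.norm(p))
    reach = geom.upper + geom.fore
    if d >= 0.995 * reach or d <= abs(geom.upper - geom.fore) * 1.05:
        raise ValueError(f"wrist target {p} outside comfortable reach (d={d:.3f} m)")
    w = p / d
    # shoulder-interior angle between shoulder->wrist and shoulder->elbow
    cos_a = (geom.upper**2 + d**2 - geom.fore**2) / (2 * geom.upper * d)
    a = np.arccos(np.clip(cos_a, -1.0, 1.0))
    down = np.array([0.0, 0.0, -1.0])
    perp = down - (down @ w) * w
    if np.linalg.norm(perp) < 1e-6:
        perp = np.array([0.0, 1.0, 0.0]) - (np.array([0.0, 1.0, 0.0]) @ w) * w
    n1 = perp / np.linalg.norm(perp)
    elbow = geom.upper * (np.cos(a) * w + np.sin(a) * n1)
    q = inverse_kinematics(np.zeros((1, 3)), elbow[None, :], p[None, :], geom)
    return q.as_array()[0]


def simulate_kinematics(spec: SimulationSpec) -> tuple[JointAngleSeries, np.ndarray, list[tuple[int, int]]]:
    """Generate joint angles, markers and the true movement epochs.

    Returns ``(angles, markers, trial_bounds)`` where markers is time x 9
    (shoulder, elbow, wrist xyz) at ``fs_markers`` and trial_bounds are the
    [start, end) movement epochs on the same grid.
    """
    fs = spec.fs_markers
    geom = spec.geometry
    cx, cy, cz = spec.square_center
    h = spec.square_side / 2.0
    corners = [
        np.array([cx - h, cy - h, cz]),
        np.array([cx + h, cy - h, cz]),
        np.array([cx + h, cy + h, cz]),
        np.array([cx - h, cy + h, cz]),
    ]
    lift = np.array([0.0, 0.0, spec.lift_height])
    rest_wrist = np.array([cx, cy - h - 0.05, cz - 0.05])

    q_rest = _posture_for_wrist(rest_wrist, geom)
    # three transports, clockwise rotation of the vacant corner: visits all 4
    transports = [(2, 3), (1, 2), (0, 1)]
    # (wrist target, dwell after reaching?)
    stops: list[tuple[np.ndarray, bool]] = []
    for i, (src, dst) in enumerate(transports):
        stops.append((corners[src], True))                    # reach + grasp
        stops.append((corners[src] + lift, False))            # lift
        stops.append((corners[dst] + lift, False))            # carry
        stops.append((corners[dst], True))                    # lower + release
    postures = [(_posture_for_wrist(p, geom), dwell) for p, dwell in stops]

    n_dwell = int(round(spec.dwell_s * fs))
    n_rest = int(round(spec.rest_duration_s * fs))
    dwell_total = sum(1 for _, d in postures if d) * spec.dwell_s
    move_time = spec.trial_duration_s - dwell_total
    if move_time <= 0:
        raise ValueError("trial_duration_s too short for the dwell schedule")
    # Segment durations proportional to wrist travel distance, so the peak
    # speed is comparable across long carries and short lifts and no
    # within-trial pause outlasts the dwell.
    path = [rest_wrist] + [p for p, _ in stops] + [rest_wrist]
    dists = np.array([np.linalg.norm(b - a) for a, b in zip(path[:-1], path[1:])])
    n_segs = [
        max(int(round(move_time * d / dists.sum() * fs)), 8) for d in dists
    ]

    chunks: list[np.ndarray] = []
    bounds: list[tuple[int, int]] = []
    pos = 0

    def emit(arr: np.ndarray) -> None:
        nonlocal pos
        chunks.append(arr)
        pos += arr.shape[0]

    emit(np.tile(q_rest, (n_rest, 1)))
    for _ in range(spec.n_trials):
        start = pos
        q_prev = q_rest
        for (q_next, dwell), n_seg in zip(postures, n_segs[:-1]):
            emit(_min_jerk(q_prev, q_next, n_seg))
            if dwell:
                emit(np.tile(q_next, (n_dwell, 1)))
            q_prev = q_next
        emit(_min_jerk(q_prev, q_rest, n_segs[-1]))
        bounds.append((start, pos))
        emit(np.tile(q_rest, (n_rest, 1)))

    qmat = np.vstack(chunks)
    angles = JointAngleSeries(qmat[:, 0], qmat[:, 1], qmat[:, 2], qmat[:, 3], fs=fs)
    elbow, wrist = forward_kinematics(angles, geom)
    shoulder = np.zeros_like(elbow)
    markers = np.hstack([shoulder, elbow, wrist])
    return angles, markers, bounds


_ENVELOPE_NOISE_BW = 2.0  # Hz; envelope noise lives in the envelope band


def _slow_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-variance noise band-limited to the envelope bandwidth, so the
    specified envelope SNR survives the decoding pipeline's smoother."""
    sos = sps.butter(2, _ENVELOPE_NOISE_BW, btype="low", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Approximately 1/f-amplitude noise via spectral shaping, unit variance."""
    white = rng.standard_normal(n)
    spec_ = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    shaped = np.fft.irfft(spec_ / np.sqrt(f), n)
    return shaped / shaped.std()


def simulate_ecog(
    angles: JointAngleSeries,
    markers: np.ndarray,
    spec: SimulationSpec,
    trial_bounds: list[tuple[int, int]] | None = None,
) -> tuple[RawSession, GroundTruth]:
    """Generate the multichannel 1000 Hz signal coupled to the kinematics."""
    rng = np.random.default_rng(spec.seed)
    fs_hi, fs_lo = spec.fs_signal, spec.fs_markers
    up = int(round(fs_hi / fs_lo))
    n_lo = len(angles)
    n_hi = n_lo * up
    n_b = len(spec.bands)
    n_pairs = spec.n_channels * n_b

    # kinematic variables, z-scored for coupling
    variables = {}
    qm = angles.as_array()
    for i, name in enumerate(("q1", "q2", "q3", "q4")):
        variables[name] = qm[:, i]
    for j, name in enumerate(("elbow_x", "elbow_y", "elbow_z", "wrist_x", "wrist_y", "wrist_z")):
        variables[name] = markers[:, 3 + j]
    zvars = {}
    for name, v in variables.items():
        sd = v.std()
        zvars[name] = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    n_inf = int(round(spec.informative_fraction * n_pairs))
    pair_ids = rng.choice(n_pairs, size=n_inf, replace=False) if n_inf else np.array([], int)
    informative = sorted((int(p) // n_b, int(p) % n_b) for p in pair_ids)
    lag = int(round(spec.true_lag_s * fs_lo))

    snr = spec.envelope_snr
    depth = spec.modulation_depth if snr > 0 else 0.0
    noise_sd = (
        spec.modulation_depth / np.sqrt(snr) if snr > 0 else spec.modulation_depth
    )

    inf_set = set(informative)
    couplings: dict[tuple[int, int], dict] = {}
    clean: dict[tuple[int, int], np.ndarray] = {}
    clipped = 0
    t_hi = np.arange(n_hi) / fs_hi
    signal = np.zeros((n_hi, spec.n_channels))

    for ch in range(spec.n_channels):
        pink = _pink_noise(rng, n_hi) * spec.broadband_noise
        acc = pink
        for b, (lo, hi) in enumerate(spec.bands):
            if (ch, b) in inf_set:
                k = int(rng.integers(1, 3))
                names = [str(x) for x in rng.choice(COUPLING_POOL, size=k, replace=False)]
                weights = rng.uniform(0.5, 1.0, size=k) * rng.choice([-1.0, 1.0], size=k)
                s = np.zeros(n_lo)
                for name, w in zip(names, weights):
                    shifted = np.roll(zvars[name], lag)
                    shifted[:lag] = zvars[name][0]
                    s += w * shifted
                sd = s.std()
                s = s / sd if sd > 0 else s
                env_clean = 1.0 + depth * s
                low = env_clean < 0.05
                if np.any(low):
                    clipped += int(low.sum())
                    env_clean = np.where(low, 0.05, env_clean)
                couplings[(ch, b)] = {"variables": names, "weights": weights.tolist(), "lag_s": spec.true_lag_s}
                clean[(ch, b)] = env_clean
            else:
                env_clean = np.ones(n_lo)
            env = env_clean + noise_sd * _slow_noise(rng, n_lo, fs_lo)
            env = np.clip(env, 0.0, None)
            env_hi = np.interp(t_hi, np.arange(n_lo) / fs_lo, env)
            if spec.carrier_type == "sinusoid":
                # Keep the rectification ripple (2*f0) well above the 2.2 Hz
                # envelope smoother: floor the carrier at 3x that cutoff when
                # the band allows, else use the band's upper portion.
                f0 = min(0.9 * hi, max(0.5 * (lo + hi), 6.6))
                carrier = np.sqrt(2.0) * np.sin(2 * np.pi * f0 * t_hi + rng.uniform(0, 2 * np.pi))
            else:
                sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs_hi, output="sos")
                carrier = sps.sosfilt(sos, rng.standard_normal(n_hi))
                carrier = carrier / carrier.std()
            acc = acc + carrier * env_hi
        signal[:, ch] = acc

    session = RawSession(
        signal=signal,
        fs_signal=fs_hi,
        markers=markers,
        fs_markers=fs_lo,
        channel_labels=[f"ch{i:02d}" for i in range(spec.n_channels)],
    )
    truth = GroundTruth(
        angles=angles,
        informative=informative,
        couplings=couplings,
        clean_envelopes=clean,
        clipped_samples=clipped,
        trial_bounds=trial_bounds or [],
    )
    if clipped:
        log.warning("clipped %d negative envelope samples", clipped)
    return session, truth


def simulate_session(spec: SimulationSpec) -> tuple[RawSession, GroundTruth]:
    """Kinematics + signal in one call."""
    angles, markers, bounds = simulate_kinematics(spec)
    return simulate_ecog(angles, markers, spec, trial_bounds=bounds)


#: Benchmark conditions.  "high" pairs a generous envelope SNR with
#: sinusoid carriers, whose amplitude the rectify-and-smooth pipeline
#: recovers without estimation noise — the genuinely high-envelope-SNR
#: regime; "low" uses realistic band-noise carriers at SNR 1.
BENCHMARK_CONDITIONS: dict[str, dict] = {
    "high": {"envelope_snr": 10.0, "carrier_type": "sinusoid"},
    "low": {"envelope_snr": 1.0, "carrier_type": "band_noise"},
}


def make_benchmark_suite(
    out_dir,
    conditions: dict[str, dict] | None = None,
    channel_counts: tuple[int, ...] = (60, 15),
    n_trials: int = 5,
    seed: int = 0,
    edf: bool = False,
) -> list[Path]:
    """Write a grid of fixture sessions (signal CSV or EDF + markers CSV +
    ground-truth JSON) to ``out_dir``; returns the session file paths.

    ``conditions`` maps a condition name to ``SimulationSpec`` overrides
    (default :data:`BENCHMARK_CONDITIONS`).  Includes a 15-channel variant
    mirroring the smallest electrode montage.
    """
    if conditions is None:
        conditions = BENCHMARK_CONDITIONS
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for snr_name, overrides in conditions.items():
        for n_ch in channel_counts:
            spec = SimulationSpec(
                n_channels=n_ch, n_trials=n_trials, seed=seed, **overrides
            )
            session, truth = simulate_session(spec)
            stem = f"session_snr-{snr_name}_ch-{n_ch}"
            if edf:
                sig_path = out_dir / f"{stem}.edf"
                write_edf(session, sig_path)
                write_session(session, out_dir / f"{stem}_unused.csv", out_dir / f"{stem}_markers.csv")
                (out_dir / f"{stem}_unused.csv").unlink()
            else:
                sig_path = out_dir / f"{stem}.csv"
                write_session(session, sig_path, out_dir / f"{stem}_markers.csv")
            truth_payload = {
                "informative": [list(p) for p in truth.informative],
                "couplings": {f"{c}:{b}": v for (c, b), v in truth.couplings.items()},
                "clipped_samples": truth.clipped_samples,
                "trial_bounds": [list(b) for b in truth.trial_bounds],
                "condition": {"name": snr_name, **overrides},
                "seed": seed,
            }
            (out_dir / f"{stem}_truth.json").write_text(json.dumps(truth_payload))
            written.append(sig_path)
    return written
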