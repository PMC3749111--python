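"""Session, model and report I/O.

Signals are read from EDF (via :mod:`mne`, imported lazily) or headered
CSV/TSV; marker trajectories from headered CSV/TSV with columns
``time_s, sx, sy, sz, ex, ey, ez, wx, wy, wz``.  Markers are meters
internally; readers accept a ``units`` argument (mm/cm/m) and convert on
load.  Both streams are taken to start at the common cue (sample-0
time-lock); no cross-correlation alignment is attempted.

Decoder model files are single-file JSON with base64-encoded float64 weight
blocks plus the full preprocessing configuration, so prediction refuses to
run on mismatched preprocessing.
"""

from __future__ import annotations

import base64
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig

__all__ = [
    "RawSession",
    "read_session",
    "write_session",
    "write_edf",
    "save_model",
    "load_model",
    "MODEL_FORMAT_VERSION",
]

log = logging.getLogger(__name__)

MARKER_COLUMNS = ["time_s", "sx", "sy", "sz", "ex", "ey", "ez", "wx", "wy", "wz"]
_UNIT_SCALE = {"m": 1.0, "cm": 0.01, "mm": 0.001}
MODEL_FORMAT_VERSION = 1


@dataclass
class RawSession:
    """A recording session: multichannel signal plus synchronized 3D markers.

    ``signal`` is time x channels at ``fs_signal`` Hz; ``markers`` is
    time x 9 (shoulder, elbow, wrist xyz, meters) at ``fs_markers`` Hz,
    time-locked to sample 0 of the signal.  Marker gaps (occlusion) are NaN
    and flagged at construction, never silently interpolated.
    """

    signal: np.ndarray
    fs_signal: float
    markers: np.ndarray | None = None
    fs_markers: float = 100.0
    channel_labels: list[str] = field(default_factory=list)
    t0_aligned: bool = True

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if np.any(np.isnan(self.signal)):
            raise ValueError("signal contains NaN")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.signal.shape[1])]
        if len(self.channel_labels) != self.signal.shape[1]:
            raise ValueError("channel_labels length != channel count")
        if self.markers is not None:
            self.markers = np.atleast_2d(np.asarray(self.markers, dtype=float))
            if self.markers.shape[1] != 9:
                raise ValueError("markers must have 9 columns (shoulder/elbow/wrist xyz)")
            gaps = int(np.sum(np.any(np.isnan(self.markers), axis=1)))
            if gaps:
                log.warning("markers contain %d gap samples (occlusion); kept as NaN", gaps)

    @property
    def n_channels(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.signal.shape[0] / self.fs_signal

    def marker_xyz(self, joint: str) -> np.ndarray:
        """(n, 3) positions for 'shoulder', 'elbow' or 'wrist'."""
        off = {"shoulder": 0, "elbow": 3, "wrist": 6}[joint]
        if self.markers is None:
            raise ValueError("session has no marker stream")
        return self.markers[:, off : off + 3]

    def validate_rates(self, config: PipelineConfig) -> None:
        highest = max(hi for _, hi in config.band_edges)
        if self.fs_signal <= 2 * highest:
            raise ValueError(
                f"fs_signal={self.fs_signal} Hz must exceed twice the highest "
                f"band edge ({highest} Hz)"
            )


# --------------------------------------------------------------------- read
def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except ValueError as err:
        raise ValueError(f"cannot parse {path}: {err}") from err
    non_num = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_num:
        raise ValueError(f"non-numeric columns in {path}: {non_num}")
    return df

def _read_edf(path: Path) -> tuple[np.ndarray, float, list[str]]:
    try:
        import mne
    except ImportError as err:  # pragma: no cover
        raise ImportError("reading EDF requires mne") from err
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return raw.get_data().T, float(raw.info["sfreq"]), list(raw.ch_names)


def read_session(
    signal_path,
    markers_path=None,
    config: PipelineConfig | None = None,
    fs_signal: float | None = None,
    marker_units: str = "m",
    duration_tolerance_s: float = 0.5,
) -> RawSession:
    """Read a session from an EDF or headered CSV/TSV signal file plus an
    optional marker CSV/TSV.

    For tabular signals the sampling rate comes from a ``time_s`` column if
    present, else ``fs_signal`` must be given.  Signal and marker durations
    must agree within ``duration_tolerance_s``.
    """
    signal_path = Path(signal_path)
    if signal_path.suffix.lower() == ".edf":
        sig, fs, labels = _read_edf(signal_path)
    else:
        df = _read_table(signal_path)
        if "time_s" in df.columns:
            t = df.pop("time_s").to_numpy()
            fs = 1.0 / np.median(np.diff(t))
        elif fs_signal is not None:
            fs = float(fs_signal)
        else:
            raise ValueError("tabular signal needs a time_s column or fs_signal")
        sig, labels = df.to_numpy(dtype=float), list(df.columns)

    markers = None
    fs_markers = 100.0
    if markers_path is not None:
        mdf = _read_table(Path(markers_path))
        missing = [c for c in MARKER_COLUMNS if c not in mdf.columns]
        if missing:
            raise ValueError(f"marker file missing columns: {missing}")
        t = mdf["time_s"].to_numpy()
        fs_markers = 1.0 / np.median(np.diff(t))
        try:
            scale = _UNIT_SCALE[marker_units]
        except KeyError:
            raise ValueError(f"marker_units must be one of {sorted(_UNIT_SCALE)}")
        markers = mdf[MARKER_COLUMNS[1:]].to_numpy(dtype=float) * scale
        dur_sig = sig.shape[0] / fs
        dur_mark = markers.shape[0] / fs_markers
        if abs(dur_sig - dur_mark) > duration_tolerance_s:
            raise ValueError(
                f"signal ({dur_sig:.2f} s) and markers ({dur_mark:.2f} s) "
                f"durations differ beyond {duration_tolerance_s} s"
            )
    session = RawSession(
        signal=sig, fs_signal=fs, markers=markers, fs_markers=fs_markers,
        channel_labels=labels,
    )
    if config is not None:
        session.validate_rates(config)
    return session


# -------------------------------------------------------------------- write
def write_session(session: RawSession, signal_path, markers_path=None) -> None:
    """Write a session as headered CSV/TSV (signal) and CSV (markers, meters)."""
    signal_path = Path(signal_path)
    t = np.arange(session.signal.shape[0]) / session.fs_signal
    df = pd.DataFrame(session.signal, columns=session.channel_labels)
    df.insert(0, "time_s", t)
    sep = "\t" if signal_path.suffix.lower() in (".tsv", ".tab") else ","
    df.to_csv(signal_path, index=False, sep=sep, float_format="%.17g")
    if markers_path is not None:
        if session.markers is None:
            raise ValueError("session has no markers to write")
        tm = np.arange(session.markers.shape[0]) / session.fs_markers
        mdf = pd.DataFrame(session.markers, columns=MARKER_COLUMNS[1:])
        mdf.insert(0, "time_s", tm)
        mdf.to_csv(markers_path, index=False, float_format="%.17g")


def write_edf(session: RawSession, path) -> None:
    """Write the signal stream as a minimal EDF file (16-bit, one data
    record per second).  Amplitudes are quantized to the per-channel range;
    EDF is for interchange — lossless round-trips use CSV."""
    sig = session.signal
    fs = int(round(session.fs_signal))
    if abs(fs - session.fs_signal) > 1e-9:
        raise ValueError("EDF writer needs an integer sampling rate")
    n_ch = sig.shape[1]
    n_rec = sig.shape[0] // fs
    if n_rec < 1:
        raise ValueError("signal shorter than one EDF data record (1 s)")
    data = sig[: n_rec * fs]
    pmin = data.min(axis=0)
    pmax = data.max(axis=0)
    span = np.where(pmax > pmin, pmax - pmin, 1.0)
    dmin, dmax = -32768, 32767
    scaled = (data - pmin) / span * (dmax - dmin) + dmin
    digital = np.clip(np.round(scaled), dmin, dmax).astype("<i2")

    def pad(s: str, width: int) -> bytes:
        b = s.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    hdr = b"".join(
        [
            pad("0", 8), pad("X X X X", 80), pad("Startdate X X X X", 80),
            pad("01.01.00", 8), pad("00.00.00", 8),
            pad(str(256 * (1 + n_ch)), 8), pad("", 44),
            pad(str(n_rec), 8), pad("1", 8), pad(str(n_ch), 4),
        ]
    )
    labels = [pad(lbl, 16) for lbl in session.channel_labels]
    sig_hdr = b"".join(
        [
            b"".join(labels),
            b"".join(pad("", 80) for _ in range(n_ch)),
            b"".join(pad("uV", 8) for _ in range(n_ch)),
            b"".join(pad(f"{v:.6g}", 8) for v in pmin),
            b"".join(pad(f"{v:.6g}", 8) for v in pmax),
            b"".join(pad(str(dmin), 8) for _ in range(n_ch)),
            b"".join(pad(str(dmax), 8) for _ in range(n_ch)),
            b"".join(pad("", 80) for _ in range(n_ch)),
            b"".join(pad(str(fs), 8) for _ in range(n_ch)),
            b"".join(pad("", 32) for _ in range(n_ch)),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(hdr + sig_hdr)
        for r in range(n_rec):
            fh.write(digital[r * fs : (r + 1) * fs].T.tobytes())


# -------------------------------------------------------------------- model
def _encode(a: np.ndarray) -> dict:
    a = np.ascontiguousarray(a)
    return {
        "dtype": str(a.dtype),
        "shape": list(a.shape),
        "data": base64.b64encode(a.tobytes()).decode("ascii"),
    }


def _decode(d: dict) -> np.ndarray:
    raw = base64.b64decode(d["data"])
    a = np.frombuffer(raw, dtype=d["dtype"]).reshape(d["shape"])
    return a.copy()


def save_model(model, path) -> None:
    """Serialize a fitted decoder (see :mod:`ecogarm.decoder`) to JSON."""
    payload = model.to_payload()
    payload["format_version"] = MODEL_FORMAT_VERSION
    for key in list(payload.get("arrays", {})):
        payload["arrays"][key] = _encode(np.asarray(payload["arrays"][key]))
    Path(path).write_text(json.dumps(payload))


def load_model(path):
    """Load a decoder saved by :func:`save_model`; refuses version skew or
    truncated files."""
    from .decoder import ArmTrajectoryDecoderResults

    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as err:
        raise ValueError(f"corrupt model file {path}: {err}") from err
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format version {version} != supported {MODEL_FORMAT_VERSION}"
        )
    payload["arrays"] = {k: _decode(v) for k, v in payload["arrays"].items()}
    return ArmTrajectoryDecoderResults.from_payload(payload)
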