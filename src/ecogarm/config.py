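"""Pipeline configuration: band edges, filters, lags, segmentation and fit options.

Defaults follow the decoding pipeline the package implements: seven
sensorimotor-rhythm bands filtered with 4th-order Butterworth bandpasses,
rectified envelopes smoothed at 2.2 Hz (2nd order), downsampled to 100 Hz,
z-scored, and regressed against kinematics using the past 1 s of features
(m = 100 lags, dt = 0.01 s) with a 5%-of-maximum tangential-velocity trial
rule.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["FitOptions", "PipelineConfig", "DEFAULT_BANDS", "BAND_NAMES"]

#: Canonical sensorimotor bands (Hz).  The delta band has no conventional
#: lower print edge; 0.5 Hz is used to exclude drift while keeping
#: movement-locked slow potentials.
DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (0.5, 4.0),    # delta
    (4.0, 8.0),    # theta
    (8.0, 14.0),   # alpha
    (14.0, 20.0),  # beta1
    (20.0, 30.0),  # beta2
    (30.0, 50.0),  # gamma1
    (50.0, 90.0),  # gamma2
)

BAND_NAMES: tuple[str, ...] = (
    "delta", "theta", "alpha", "beta1", "beta2", "gamma1", "gamma2",
)


@dataclass
class FitOptions:
    """Options for the sparse Bayesian (ARD) regression fit.

    max_iter : hard cap on hyperparameter update iterations.
    prune_threshold : a weight whose relevance precision alpha exceeds this
        is removed from the active set (weight exactly 0).
    validation_fraction : chronological tail fraction of the training rows
        held out to detect over-training; 0 disables early stopping.
    patience : consecutive validation-MSE rises tolerated before stopping.
    tolerance : relative weight-change convergence threshold.
    """

    max_iter: int = 100
    prune_threshold: float = 1e6
    validation_fraction: float = 0.1
    patience: int = 3
    tolerance: float = 1e-5
    update_beta: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.validation_fraction < 0.5):
            raise ValueError("validation_fraction must lie in [0, 0.5)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class PipelineConfig:
    band_edges: tuple[tuple[float, float], ...] = DEFAULT_BANDS
    band_names: tuple[str, ...] = BAND_NAMES
    bp_order: int = 4
    lp_cutoff: float = 2.2
    lp_order: int = 2
    fs_out: float = 100.0
    n_lags: int = 100          # m
    lag_step: float = 0.01     # dt, seconds
    include_current_sample: bool = False
    filter_mode: str = "causal"            # or "zero_phase"
    normalization: str = "foldwise"        # or "session"
    velocity_threshold_fraction: float = 0.05
    velocity_smooth_cutoff: float = 5.0
    min_gap_s: float = 1.5
    min_duration_s: float = 2.0
    train_stride: int = 1
    regression: FitOptions = field(default_factory=FitOptions)
    seed: int = 0

    def __post_init__(self) -> None:
        self.band_edges = tuple(tuple(float(e) for e in b) for b in self.band_edges)
        self.band_names = tuple(self.band_names)
        if len(self.band_names) != len(self.band_edges):
            raise ValueError("band_names and band_edges lengths differ")
        for lo, hi in self.band_edges:
            if not (0 <= lo < hi):
                raise ValueError(f"invalid band edges ({lo}, {hi})")
        if self.filter_mode not in ("causal", "zero_phase"):
            raise ValueError("filter_mode must be 'causal' or 'zero_phase'")
        if self.normalization not in ("foldwise", "session"):
            raise ValueError("normalization must be 'foldwise' or 'session'")
        if not (0 < self.velocity_threshold_fraction < 1):
            raise ValueError("velocity_threshold_fraction must lie in (0, 1)")
        if self.n_lags < 1 or self.train_stride < 1:
            raise ValueError("n_lags and train_stride must be >= 1")
        if isinstance(self.regression, dict):
            self.regression = FitOptions(**self.regression)

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band_edges"] = [list(b) for b in self.band_edges]
        d["band_names"] = list(self.band_names)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        """Load from YAML or JSON (by extension)."""
        path = Path(path)
        text = path.read_text()
        if path.suffix == ".json":
            return cls.from_dict(json.loads(text) or {})
        # YAML 1.1 reads bare scientific notation ("1e-05") as a string
        return cls.from_dict(yaml.safe_load(text) or {})

    def save(self, path: str | Path) -> None:
        p = Path(path)
        if p.suffix == ".json":
            p.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            p.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def content_hash(self) -> str:
        """Stable hash of every numeric setting; stored in model files so a
        decoder refuses to predict from differently-preprocessed features."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
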