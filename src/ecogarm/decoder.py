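"""High-level decoding model: session in, fitted trajectory decoder out.

``ArmTrajectoryDecoder`` is the model object: it owns a raw session, a
pipeline configuration, a trial segmentation and a set of scalar target
series (by default the four joint angles from inverse kinematics plus the
six elbow/wrist coordinates).  ``fit()`` returns
``ArmTrajectoryDecoderResults``, which carries one sparse Bayesian
regression per target together with the feature normalization constants and
the configuration, and can predict new sessions, reconstruct 3D trajectories
from the decoded joint angles through forward kinematics, and summarize
sparsity diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .kinematics import (
    ArmGeometry,
    JointAngleSeries,
    forward_kinematics,
    inverse_kinematics,
    tangential_velocity,
)
from .lagged import build_design, predict_series
from .preprocessing import FeatureSeries, band_envelopes, preprocess
from .segmentation import TrialSet, segment_trials
from .slr import fit_slr, sparsity_report

__all__ = [
    "ArmTrajectoryDecoder",
    "ArmTrajectoryDecoderResults",
    "TargetModel",
    "kinematic_targets",
]

log = logging.getLogger(__name__)

ANGLE_TARGETS = ("q1", "q2", "q3", "q4")
COORD_TARGETS = (
    "elbow_x", "elbow_y", "elbow_z", "wrist_x", "wrist_y", "wrist_z",
)
ALL_TARGETS = ANGLE_TARGETS + COORD_TARGETS


def kinematic_targets(
    session, geometry: ArmGeometry, targets=ALL_TARGETS
) -> dict[str, np.ndarray]:
    """Build the named target series (joint angles via inverse kinematics,
    elbow/wrist coordinates) from the session's marker stream."""
    shoulder = session.marker_xyz("shoulder")
    elbow = session.marker_xyz("elbow")
    wrist = session.marker_xyz("wrist")
    out: dict[str, np.ndarray] = {}
    need_angles = any(t in ANGLE_TARGETS for t in targets)
    if need_angles:
        q = inverse_kinematics(shoulder, elbow, wrist, geometry, fs=session.fs_markers)
        for name in ANGLE_TARGETS:
            if name in targets:
                out[name] = getattr(q, name)
    coords = {"elbow": elbow, "wrist": wrist}
    for name in COORD_TARGETS:
        if name in targets:
            joint, ax = name.split("_")
            out[name] = coords[joint][:, "xyz".index(ax)]
    return out


@dataclass
class TargetModel:
    """Serializable per-target decoder: bias-first weights over the lagged
    design layout."""

    name: str
    coef_full: np.ndarray
    active_set: np.ndarray
    noise_variance: float
    n_iter: int
    early_stop_reason: str
    n_lags: int
    include_current: bool = False

    @property
    def w0(self) -> float:
        return float(self.coef_full[0])

    @property
    def nnz(self) -> int:
        return int(np.sum(self.coef_full != 0))


class ArmTrajectoryDecoder:
    """Decoding model for one session.

    Parameters
    ----------
    session : RawSession
    config : PipelineConfig (defaults reproduce the standard pipeline).
    trials : TrialSet; segmented from elbow tangential velocity if omitted.
    targets : dict name -> 100 Hz series; derived from markers if omitted.
    geometry : ArmGeometry used for inverse/forward kinematics; estimated
        from median marker segment lengths if omitted.
    """

    def __init__(
        self,
        session,
        config: PipelineConfig | None = None,
        trials: TrialSet | None = None,
        targets: dict[str, np.ndarray] | None = None,
        geometry: ArmGeometry | None = None,
    ):
        self.session = session
        self.config = config or PipelineConfig()
        session.validate_rates(self.config)
        if geometry is None and session.markers is not None:
            sh, el, wr = (session.marker_xyz(j) for j in ("shoulder", "elbow", "wrist"))
            geometry = ArmGeometry(
                upper=float(np.median(np.linalg.norm(el - sh, axis=1))),
                fore=float(np.median(np.linalg.norm(wr - el, axis=1))),
            )
        self.geometry = geometry
        if trials is None:
            speed = tangential_velocity(
                session.marker_xyz("elbow"),
                session.fs_markers,
                self.config.velocity_smooth_cutoff,
            )
            trials = segment_trials(
                speed,
                session.fs_markers,
                self.config.velocity_threshold_fraction,
                self.config.min_gap_s,
                self.config.min_duration_s,
            )
        self.trials = trials
        if targets is None:
            targets = kinematic_targets(session, self.geometry)
        self.targets = targets

    # ------------------------------------------------------------------
    def fit(self, band: str | None = None) -> "ArmTrajectoryDecoderResults":
        """Fit one sparse regression per target on all retained trials."""
        cfg = self.config
        env = band_envelopes(self.session, cfg)
        n = env.shape[0]
        mask = self.trials.mask(n)
        stats = np.flatnonzero(mask) if cfg.normalization == "foldwise" else None
        feats = preprocess(self.session, cfg, stats_window=stats, envelopes=env)
        Z = feats.envelopes
        feature_sel = np.arange(feats.n_features)
        if band is not None:
            sel = feats.band_feature_mask(band)
            Z, feature_sel = Z[:, sel], feature_sel[np.flatnonzero(sel)]
        models: dict[str, TargetModel] = {}
        fitinfo: dict[str, object] = {}
        for name, series in self.targets.items():
            design = build_design(
                Z, np.asarray(series, float), mask, m=cfg.n_lags,
                include_current=cfg.include_current_sample,
                row_stride=cfg.train_stride,
            )
            res = fit_slr(design, cfg.regression)
            models[name] = TargetModel(
                name=name,
                coef_full=res.params,
                active_set=res.active_set,
                noise_variance=res.noise_variance,
                n_iter=res.n_iter,
                early_stop_reason=res.early_stop_reason,
                n_lags=cfg.n_lags,
                include_current=cfg.include_current_sample,
            )
            fitinfo[name] = res
            log.info("fitted %s: %d/%d nonzero, %d iters (%s)",
                     name, res.nnz, design.n_columns, res.n_iter, res.early_stop_reason)
        return ArmTrajectoryDecoderResults(
            models=models,
            features=FeatureSeries(
                envelopes=np.empty((0, len(feature_sel))),
                fs=cfg.fs_out,
                channel_of_feature=feats.channel_of_feature[feature_sel],
                band_of_feature=feats.band_of_feature[feature_sel],
                band_names=feats.band_names,
                mu=feats.mu[feature_sel],
                sigma=feats.sigma[feature_sel],
                channel_labels=feats.channel_labels,
            ),
            config=cfg,
            band_condition=band,
            geometry=self.geometry,
            fit_results=fitinfo,
        )


@dataclass
class ArmTrajectoryDecoderResults:
    """Fitted decoders plus everything needed to apply them to new data."""

    models: dict[str, TargetModel]
    features: FeatureSeries          # layout + normalization constants (no data)
    config: PipelineConfig
    band_condition: str | None = None
    geometry: ArmGeometry | None = None
    fit_results: dict = field(default_factory=dict)

    # ------------------------------------------------------------- predict
    def _featurize(self, session) -> np.ndarray:
        from .preprocessing import zscore_normalize

        session.validate_rates(self.config)
        env = band_envelopes(session, self.config)
        n_bands = len(self.config.band_edges)
        cols = self.features.channel_of_feature * n_bands + self.features.band_of_feature
        z, *_ = zscore_normalize(
            env[:, cols], mu=self.features.mu, sigma=self.features.sigma
        )
        return z

    def predict(
        self,
        session=None,
        envelopes: np.ndarray | None = None,
        valid_mask: np.ndarray | None = None,
        config: PipelineConfig | None = None,
    ) -> pd.DataFrame:
        """Decode every target for a session; NaN where lag history is missing.

        If ``config`` is given it must hash-match the training configuration
        (fail-closed on preprocessing mismatch).
        """
        if config is not None and config.content_hash() != self.config.content_hash():
            raise ValueError(
                "preprocessing configuration mismatch: model was trained with "
                f"hash {self.config.content_hash()}, got {config.content_hash()}"
            )
        if envelopes is None:
            if session is None:
                raise ValueError("need a session or a z-scored envelope matrix")
            envelopes = self._featurize(session)
        out = {}
        for name, model in self.models.items():
            out[name] = predict_series(model, envelopes, valid_mask)
        return pd.DataFrame(out)

    def reconstruct_trajectory(
        self, predictions: pd.DataFrame, shoulder: np.ndarray | None = None
    ) -> pd.DataFrame:
        """Render decoded joint angles into 3D elbow/wrist paths through
        forward kinematics — segment lengths hold exactly regardless of
        decoder error.  q4 is clipped into (0, pi]."""
        if self.geometry is None:
            raise ValueError("no arm geometry attached to these results")
        missing = [a for a in ANGLE_TARGETS if a not in predictions]
        if missing:
            raise ValueError(f"predictions lack joint angles: {missing}")
        q = predictions[list(ANGLE_TARGETS)].to_numpy()
        defined = ~np.any(np.isnan(q), axis=1)
        qd = q[defined]
        angles = JointAngleSeries(
            q1=qd[:, 0], q2=qd[:, 1], q3=qd[:, 2],
            q4=np.clip(qd[:, 3], 1e-6, np.pi), fs=self.config.fs_out,
        )
        sh = None if shoulder is None else np.asarray(shoulder, float)[defined]
        elbow, wrist = forward_kinematics(angles, self.geometry, sh)
        out = np.full((len(q), 6), np.nan)
        out[defined] = np.hstack([elbow, wrist])
        return pd.DataFrame(out, columns=list(COORD_TARGETS))

    # ---------------------------------------------------------- diagnostics
    def sparsity(self, target: str) -> pd.DataFrame:
        m = self.models[target]
        return sparsity_report(
            m.coef_full,
            m.n_lags,
            self.features.channel_of_feature,
            self.features.band_of_feature,
            self.features.band_names,
        )

    def summary(self) -> str:
        head = "Arm trajectory decoder"
        if self.band_condition:
            head += f" (band: {self.band_condition})"
        lines = [head, "=" * len(head),
                 f"features: {len(self.features.mu)}  lags: {self.config.n_lags}  "
                 f"config: {self.config.content_hash()}",
                 f"{'target':>10} {'nonzero':>8} {'iters':>6} {'stop':>16} {'noise sd':>10}"]
        for name, m in self.models.items():
            lines.append(
                f"{name:>10} {m.nnz:>8d} {m.n_iter:>6d} {m.early_stop_reason:>16} "
                f"{np.sqrt(m.noise_variance):>10.4g}"
            )
        return "\n".join(lines)

    # -------------------------------------------------------- serialization
    def to_payload(self) -> dict:
        arrays = {
            "channel_of_feature": self.features.channel_of_feature,
            "band_of_feature": self.features.band_of_feature,
            "mu": self.features.mu,
            "sigma": self.features.sigma,
        }
        meta_models = {}
        for name, m in self.models.items():
            arrays[f"coef::{name}"] = m.coef_full
            arrays[f"active::{name}"] = m.active_set
            meta_models[name] = {
                "noise_variance": m.noise_variance,
                "n_iter": m.n_iter,
                "early_stop_reason": m.early_stop_reason,
                "n_lags": m.n_lags,
                "include_current": m.include_current,
            }
        return {
            "config": self.config.to_dict(),
            "config_hash": self.config.content_hash(),
            "band_condition": self.band_condition,
            "band_names": list(self.features.band_names),
            "channel_labels": list(self.features.channel_labels),
            "geometry": None
            if self.geometry is None
            else [self.geometry.upper, self.geometry.fore],
            "models": meta_models,
            "arrays": arrays,
        }

    @classmethod
    def from_payload(cls, payload: dict) -> "ArmTrajectoryDecoderResults":
        arrays = payload["arrays"]
        config = PipelineConfig.from_dict(payload["config"])
        if config.content_hash() != payload["config_hash"]:
            raise ValueError("model file config hash mismatch (corrupt or edited)")
        models = {}
        for name, meta in payload["models"].items():
            models[name] = TargetModel(
                name=name,
                coef_full=arrays[f"coef::{name}"],
                active_set=arrays[f"active::{name}"].astype(int),
                **meta,
            )
        geom = payload.get("geometry")
        return cls(
            models=models,
            features=FeatureSeries(
                envelopes=np.empty((0, len(arrays["mu"]))),
                fs=config.fs_out,
                channel_of_feature=arrays["channel_of_feature"].astype(int),
                band_of_feature=arrays["band_of_feature"].astype(int),
                band_names=tuple(payload["band_names"]),
                mu=arrays["mu"],
                sigma=arrays["sigma"],
                channel_labels=list(payload["channel_labels"]),
            ),
            config=config,
            band_condition=payload.get("band_condition"),
            geometry=None if geom is None else ArmGeometry(*geom),
        )
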