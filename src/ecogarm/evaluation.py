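"""Leave-one-out cross-validation over trials; CC and nRMSE scoring.

One decoder is fitted per target variable (each joint angle and each
elbow/wrist coordinate is a scalar regression).  For every held-out trial,
decoders are trained on all other trials' samples — with normalization
statistics and the early-stopping holdout drawn from the training trials
only — then the held-out trial is predicted and scored with Pearson's
correlation coefficient and the range-normalized RMSE.  Scores are averaged
across trials and reported with the standard error of the mean.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .lagged import build_design
from .preprocessing import band_envelopes, preprocess
from .segmentation import TrialSet
from .slr import fit_slr

__all__ = ["EvaluationReport", "pearson_cc", "nrmse", "loo_cv", "per_band_cv"]

log = logging.getLogger(__name__)


def pearson_cc(pred: np.ndarray, actual: np.ndarray) -> float:
    """Pearson's correlation coefficient between two equal-length series.

    Returns NaN (flagged missing, never 0) if either series is constant.
    """
    pred = np.asarray(pred, dtype=float).ravel()
    actual = np.asarray(actual, dtype=float).ravel()
    if pred.shape != actual.shape or pred.size < 2:
        raise ValueError("series must have equal length >= 2")
    dp = pred - pred.mean()
    da = actual - actual.mean()
    denom = np.sqrt((dp @ dp) * (da @ da))
    if denom == 0:
        return float("nan")
    return float(np.clip((dp @ da) / denom, -1.0, 1.0))


def nrmse(pred: np.ndarray, actual: np.ndarray, normalization: str = "range") -> float:
    """Root-mean-square error normalized by the actual series' spread.

    ``normalization="range"`` (default) divides by max(actual) - min(actual)
    within the compared window — the common convention for trajectory
    decoding; ``"std"`` divides by the sample standard deviation instead.
    Returns NaN when the normalizer is zero (constant actual).
    """
    pred = np.asarray(pred, dtype=float).ravel()
    actual = np.asarray(actual, dtype=float).ravel()
    if pred.shape != actual.shape or pred.size < 2:
        raise ValueError("series must have equal length >= 2")
    rmse = float(np.sqrt(np.mean((pred - actual) ** 2)))
    if normalization == "range":
        denom = float(np.ptp(actual))
    elif normalization == "std":
        denom = float(np.std(actual, ddof=1))
    else:
        raise ValueError("normalization must be 'range' or 'std'")
    if denom == 0:
        return float("nan")
    return rmse / denom


@dataclass
class EvaluationReport:
    """Per-trial and aggregate decoding scores.

    ``per_trial`` has one row per (held-out trial, variable) with CC, nRMSE,
    duration and a hash of the fitted fold model; ``aggregate`` carries the
    per-variable mean and SEM (sample sd / sqrt(n_trials)).
    """

    per_trial: pd.DataFrame
    aggregate: pd.DataFrame
    band_condition: str | None = None
    config: dict = field(default_factory=dict)
    models: dict = field(default_factory=dict)   # (trial, variable) -> SLRResults, optional

    def summary(self) -> str:
        head = "Leave-one-out cross-validated decoding"
        if self.band_condition:
            head += f" (band: {self.band_condition})"
        lines = [head, "=" * len(head)]
        agg = self.aggregate
        lines.append(f"{'variable':>10} {'mean CC':>9} {'SEM':>7} {'mean nRMSE':>11} {'SEM':>7} {'trials':>7}")
        for _, r in agg.iterrows():
            lines.append(
                f"{r['variable']:>10} {r['mean_cc']:>9.3f} {r['sem_cc']:>7.3f} "
                f"{r['mean_nrmse']:>11.3f} {r['sem_nrmse']:>7.3f} {int(r['n_trials']):>7d}"
            )
        return "\n".join(lines)

    def save(self, per_trial_csv, aggregate_json) -> None:
        import json
        from pathlib import Path

        self.per_trial.to_csv(per_trial_csv, index=False)
        payload = {
            "band_condition": self.band_condition,
            "config": self.config,
            "aggregate": self.aggregate.to_dict(orient="records"),
        }
        Path(aggregate_json).write_text(json.dumps(payload, indent=2))


def _aggregate(per_trial: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for var, grp in per_trial.groupby("variable", sort=False):
        cc = grp["cc"].to_numpy(dtype=float)
        nr = grp["nrmse"].to_numpy(dtype=float)
        n = len(grp)
        sem = lambda v: float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else float("nan")
        rows.append(
            {
                "variable": var,
                "mean_cc": float(np.nanmean(cc)) if n else float("nan"),
                "sem_cc": sem(cc[~np.isnan(cc)]),
                "mean_nrmse": float(np.nanmean(nr)) if n else float("nan"),
                "sem_nrmse": sem(nr[~np.isnan(nr)]),
                "n_trials": n,
            }
        )
    return pd.DataFrame(rows)


def _model_hash(results) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(results.params).tobytes())
    h.update(np.ascontiguousarray(results.active_set).tobytes())
    return h.hexdigest()[:16]


def loo_cv(
    session,
    trials: TrialSet,
    targets: dict[str, np.ndarray],
    config: PipelineConfig,
    envelopes: np.ndarray | None = None,
    band: str | None = None,
    keep_models: bool = False,
) -> EvaluationReport:
    """Leave-one-trial-out cross-validated decoding of every target series.

    Parameters
    ----------
    session : RawSession (used to compute band envelopes unless given).
    trials : TrialSet of retained movement trials (>= 2).
    targets : name -> series on the feature (100 Hz) grid.
    envelopes : precomputed raw envelope matrix from
        :func:`~ecogarm.preprocessing.band_envelopes` (computed once here
        otherwise).
    band : restrict the design to one named band's features.
    """
    if trials.n_trials < 2:
        raise ValueError("leave-one-out needs at least 2 trials")
    if envelopes is None:
        envelopes = band_envelopes(session, config)
    n = envelopes.shape[0]
    for name, series in targets.items():
        if len(series) != n:
            raise ValueError(f"target {name!r} not on the feature grid ({len(series)} vs {n})")

    records = []
    models = {}
    for k in range(trials.n_trials):
        train_ids = [i for i in range(trials.n_trials) if i != k]
        train_mask = trials.mask(n, train_ids)
        test_mask = trials.mask(n, [k])
        stats = np.flatnonzero(train_mask) if config.normalization == "foldwise" else None
        feats = preprocess(session, config, stats_window=stats, envelopes=envelopes)
        Z = feats.envelopes
        if band is not None:
            Z = Z[:, feats.band_feature_mask(band)]
        s, e = trials.intervals[k]
        dur = (e - s) / config.fs_out
        for name, series in targets.items():
            series = np.asarray(series, dtype=float)
            try:
                design = build_design(
                    Z, series, train_mask, m=config.n_lags,
                    include_current=config.include_current_sample,
                    row_stride=config.train_stride,
                )
            except ValueError as err:
                log.warning("fold %d target %s: %s; skipped", k, name, err)
                continue
            res = fit_slr(design, config.regression)
            try:
                test = build_design(
                    Z, series, test_mask, m=config.n_lags,
                    include_current=config.include_current_sample,
                )
            except ValueError as err:
                log.warning("fold %d target %s: test trial unusable (%s)", k, name, err)
                continue
            pred = test.X @ res.params
            records.append(
                {
                    "trial": k,
                    "variable": name,
                    "cc": pearson_cc(pred, test.y),
                    "nrmse": nrmse(pred, test.y),
                    "duration_s": dur,
                    "model_hash": _model_hash(res),
                }
            )
            if keep_models:
                models[(k, name)] = res
    per_trial = pd.DataFrame(
        records, columns=["trial", "variable", "cc", "nrmse", "duration_s", "model_hash"]
    )
    return EvaluationReport(
        per_trial=per_trial,
        aggregate=_aggregate(per_trial),
        band_condition=band,
        config=config.to_dict(),
        models=models,
    )


def per_band_cv(
    session,
    trials: TrialSet,
    targets: dict[str, np.ndarray],
    config: PipelineConfig,
    band: str,
    envelopes: np.ndarray | None = None,
) -> EvaluationReport:
    """LOO-CV with the design restricted to a single band's features."""
    if band not in config.band_names:
        raise ValueError(f"unknown band {band!r}; have {config.band_names}")
    return loo_cv(session, trials, targets, config, envelopes=envelopes, band=band)
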