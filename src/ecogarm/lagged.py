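"""Lagged design matrices: the past 1 s of features paired with each target sample.

A target sample at time t is predicted from z_i(t - j*dt) for j = 1..m
(strictly past samples; the current sample is excluded by default).  Rows are
emitted only where the target sample and all m preceding feature samples are
valid — rows never straddle trial boundaries, which would fabricate history.
The design carries an explicit leading constant-1 bias column that the
sparsity prior never prunes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LaggedDesign", "build_design", "predict_series"]


@dataclass
class LaggedDesign:
    """Design matrix for one scalar target.

    X : (n_rows, n_features * m + 1), column 0 is the bias.
    y : (n_rows,) target values at ``sample_times``.
    sample_times : indices of the target samples on the 100 Hz grid.
    Column 1 + i*m + (j-1) holds feature i at lag j.
    """

    X: np.ndarray
    y: np.ndarray
    sample_times: np.ndarray
    n_features: int
    n_lags: int
    include_current: bool = False

    def column_of(self, feature: int, lag: int) -> int:
        """Column index of (feature i, lag j); lag counts from the first used
        lag (0 if the current sample is included, else 1)."""
        j0 = 0 if self.include_current else 1
        if not (j0 <= lag < j0 + self.n_lags):
            raise IndexError(f"lag {lag} outside [{j0}, {j0 + self.n_lags})")
        return 1 + feature * self.n_lags + (lag - j0)

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]


def _valid_rows(valid_mask: np.ndarray, m: int, include_current: bool) -> np.ndarray:
    """Target indices t whose full lag history lies inside the valid set."""
    valid = np.asarray(valid_mask, dtype=bool)
    first = 0 if include_current else 1
    ok = valid.copy()
    for j in range(first, m + first):
        shifted = np.zeros_like(valid)
        if j == 0:
            shifted = valid
        else:
            shifted[j:] = valid[:-j]
        ok &= shifted
    return np.flatnonzero(ok)


def build_design(
    features,
    target: np.ndarray,
    valid_mask: np.ndarray | None = None,
    m: int = 100,
    include_current: bool = False,
    row_stride: int = 1,
) -> LaggedDesign:
    """Assemble the lagged design matrix.

    Parameters
    ----------
    features : FeatureSeries or (time, n_features) array on the target grid.
    target : (time,) series on the same grid.
    valid_mask : boolean series marking usable samples (e.g. trial interiors).
    m : number of lags (each one feature-sampling interval, dt = 1/fs).
    row_stride : keep every ``row_stride``-th valid row (training thinning;
        predictions always use stride 1).
    """
    Z = np.asarray(getattr(features, "envelopes", features), dtype=float)
    Z = np.atleast_2d(Z)
    target = np.asarray(target, dtype=float)
    n_t, n_f = Z.shape
    if target.shape[0] != n_t:
        raise ValueError("target and features must share the time grid")
    if valid_mask is None:
        valid_mask = np.ones(n_t, dtype=bool)
    if m >= n_t:
        raise ValueError(f"m={m} lags >= series length {n_t}: empty design")
    rows = _valid_rows(valid_mask, m, include_current)
    if rows.size == 0:
        raise ValueError("no rows with a full valid lag history")
    if row_stride > 1:
        rows = rows[::row_stride]
    j0 = 0 if include_current else 1
    X = np.empty((rows.size, n_f * m + 1))
    X[:, 0] = 1.0
    for j in range(m):
        lag = j0 + j
        X[:, 1 + j::m] = Z[rows - lag] if lag else Z[rows]
    return LaggedDesign(
        X=X,
        y=target[rows],
        sample_times=rows,
        n_features=n_f,
        n_lags=m,
        include_current=include_current,
    )


def predict_series(
    model,
    features,
    valid_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Evaluate the decoder over a feature series.

    Returns a series on the feature grid with NaN wherever the lag history is
    unavailable — undefined samples are flagged, never zero-filled.  ``model``
    needs ``coef_full`` (bias-first weight vector over the design layout),
    ``n_lags`` and ``include_current`` attributes.
    """
    Z = np.asarray(getattr(features, "envelopes", features), dtype=float)
    n_t, n_f = np.atleast_2d(Z).shape
    w = np.asarray(model.coef_full, dtype=float)
    if w.shape[0] != n_f * model.n_lags + 1:
        raise ValueError(
            f"model layout ({w.shape[0]} columns) does not match features "
            f"({n_f} features x {model.n_lags} lags + bias)"
        )
    design = build_design(
        Z,
        np.zeros(n_t),
        valid_mask,
        m=model.n_lags,
        include_current=model.include_current,
    )
    out = np.full(n_t, np.nan)
    out[design.sample_times] = design.X @ w
    return out
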