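"""Sparse Bayesian linear regression with automatic relevance determination.

The decoder weights are fitted by evidence-approximation ARD: each weight
w_k carries its own Gaussian prior precision alpha_k, and the alphas are
re-estimated by the fixed-point updates

    Sigma = (beta X'X + diag(alpha))^-1,   m = beta Sigma X'y,
    gamma_k = 1 - alpha_k Sigma_kk,
    alpha_k <- gamma_k / m_k^2,            beta <- (N - sum gamma) / ||y - Xm||^2.

Weights whose alpha diverges past a prune threshold are removed from the
active set (exactly zero thereafter), which keeps the linear solves at
active-set size and makes designs with tens of thousands of lagged columns
tractable.  When the active set is larger than the number of training rows
the posterior is computed in the dual (Woodbury) form, so the per-iteration
cost never exceeds O(N^2 K).

Over-training is detected on a chronological validation tail of the training
rows: fitting stops after `patience` consecutive validation-MSE increases and
the best-validation snapshot is returned.  A chronological (not random)
holdout respects the serial correlation of the 100 Hz rows.

The bias column is never penalized and never pruned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .config import FitOptions

__all__ = ["SparseBayesianRegression", "SLRResults", "fit_slr", "sparsity_report"]

log = logging.getLogger(__name__)

_ALPHA_UNPENALIZED = 1e-10  # effectively flat prior on the bias
_ALPHA_CAP = 1e300
_EARLY_STOP_BURN_IN = 10    # MacKay transient; no early stop before this


@dataclass
class _Snapshot:
    coef: np.ndarray
    alpha: np.ndarray
    beta: float
    active: np.ndarray
    iteration: int
    val_mse: float


class SparseBayesianRegression:
    """ARD linear regression model: ``SparseBayesianRegression(y, X).fit()``.

    Parameters
    ----------
    endog : (n,) response vector.
    exog : (n, k) design matrix.  By default the first column is treated as
        an unpenalized bias if it is constant; pass ``unpenalized`` to
        override.
    unpenalized : iterable of column indices exempt from the ARD prior and
        from pruning.
    """

    def __init__(self, endog, exog, unpenalized=None):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("endog and exog row counts differ")
        if self.exog.shape[0] < 2:
            raise ValueError("need at least 2 rows")
        if not (np.all(np.isfinite(self.endog)) and np.all(np.isfinite(self.exog))):
            raise ValueError("design contains NaN or infinite values")
        if unpenalized is None:
            first = self.exog[:, 0]
            unpenalized = [0] if np.ptp(first) == 0 and first[0] != 0 else []
        self.unpenalized = np.asarray(sorted(set(int(i) for i in unpenalized)), dtype=int)

    # ------------------------------------------------------------------
    def fit(
        self,
        options: FitOptions | None = None,
        update_alpha: bool = True,
        alpha_init: float = 1.0,
        damping: float = 0.5,
        **kwargs,
    ) -> "SLRResults":
        """Run the ARD fixed-point iteration.

        Extra keyword arguments override fields of ``options`` (e.g.
        ``max_iter=50``).  ``update_alpha=False`` with a small ``alpha_init``
        freezes the prior flat, reducing the fit to (near-)ridge/OLS — used
        as a correctness reference.
        """
        if options is None:
            options = FitOptions()
        if kwargs:
            options = FitOptions(**{**options.__dict__, **kwargs})
        X, y = self.exog, self.endog
        n, k = X.shape
        n_val = int(np.floor(options.validation_fraction * n))
        n_train = n - n_val
        if n_train < 2:
            raise ValueError("too few training rows after validation split")
        Xt, yt = X[:n_train], y[:n_train]
        Xv, yv = X[n_train:], y[n_train:]

        var_y = float(np.var(yt))
        penalized = np.ones(k, dtype=bool)
        penalized[self.unpenalized] = False
        if var_y == 0.0:
            if np.any(penalized):
                raise ValueError("response has zero variance on the training rows")
            beta0 = 1.0
        else:
            beta0 = 1.0 / var_y

        alpha = np.full(k, float(alpha_init))
        alpha[~penalized] = _ALPHA_UNPENALIZED
        beta = beta0
        active = np.arange(k)
        coef = np.zeros(k)
        evidence_trace: list[float] = []
        val_trace: list[float] = []
        prune_iterations: list[int] = []
        best: _Snapshot | None = None
        rises = 0
        reason = "max_iter"
        n_iter = 0

        for it in range(1, options.max_iter + 1):
            n_iter = it
            Xa = Xt[:, active]
            aa = alpha[active]
            m, diag_sigma, logev = self._posterior(Xa, yt, aa, beta)
            if not (np.all(np.isfinite(m)) and np.isfinite(logev)):
                raise FloatingPointError(f"non-finite posterior at iteration {it}")

            gamma = 1.0 - aa * diag_sigma
            gamma = np.clip(gamma, 1e-12, 1.0)
            resid = yt - Xa @ m
            rss = float(resid @ resid)

            prev = coef
            coef = np.zeros(k)
            coef[active] = m
            evidence_trace.append(logev)

            # --- validation bookkeeping (uses the freshly solved posterior)
            if n_val > 0:
                v = yv - Xv[:, active] @ m
                val_mse = float(v @ v) / n_val
                val_trace.append(val_mse)
                # A "rise" is counted against the best MSE so far, with a
                # margin of one sampling standard deviation of the MSE
                # estimate (relative sd of an MSE over n_val rows ~ sqrt(2/n_val)),
                # so chance fluctuations of a small holdout do not stop the
                # fit.  Within-margin ties go to the later, sparser snapshot.
                margin = 1.0 + max(1e-2, np.sqrt(2.0 / n_val))
                if best is None or val_mse <= best.val_mse * margin:
                    mse = val_mse if best is None else min(val_mse, best.val_mse)
                    best = _Snapshot(coef.copy(), alpha.copy(), beta, active.copy(), it, mse)
                    rises = 0
                elif it > _EARLY_STOP_BURN_IN:
                    rises += 1
                    if rises >= options.patience:
                        reason = "validation_rise"
                        break

            # --- hyperparameter updates
            alpha_moved = 0.0
            if update_alpha:
                pa = penalized[active]
                with np.errstate(divide="ignore", over="ignore"):
                    new_a = gamma[pa] / np.square(m[pa])
                new_a = np.minimum(np.nan_to_num(new_a, nan=_ALPHA_CAP, posinf=_ALPHA_CAP), _ALPHA_CAP)
                old_a = alpha[active][pa]
                # damped update in log space: same fixed points, smoother path
                stepped = old_a * (new_a / old_a) ** damping
                upd = alpha[active].copy()
                upd[pa] = np.minimum(stepped, _ALPHA_CAP)
                alpha[active] = upd
                small = stepped < options.prune_threshold
                if np.any(small):
                    alpha_moved = float(
                        np.max(np.abs(np.log(stepped[small] / old_a[small])))
                    )
            if options.update_beta and rss > 0:
                new_beta = max((n_train - float(np.sum(gamma))) / rss, 1e-12)
                beta = beta * (new_beta / beta) ** damping

            # --- prune diverged weights (never the unpenalized columns)
            keep = ~penalized[active] | (alpha[active] <= options.prune_threshold)
            pruned_now = not np.all(keep)
            if pruned_now:
                prune_iterations.append(it)
                active = active[keep]
                coef_mask = np.zeros(k, dtype=bool)
                coef_mask[active] = True
                coef[~coef_mask] = 0.0

            # --- convergence: weights stable, prior stable, nothing pruned
            denom = max(np.max(np.abs(coef)), 1e-30)
            weight_moved = np.max(np.abs(coef - prev)) / denom
            if it > 1 and not pruned_now and weight_moved < options.tolerance and alpha_moved < 1e-2:
                reason = "converged"
                break

        if best is not None:
            # always return the snapshot that validated best
            coef, alpha, beta, active = best.coef, best.alpha, best.beta, best.active

        alpha_out = alpha.copy()
        pruned = np.ones(k, dtype=bool)
        pruned[active] = False
        alpha_out[pruned & penalized] = np.inf
        return SLRResults(
            model=self,
            params=coef,
            alpha=alpha_out,
            scale_precision=beta,
            active_set=np.sort(active),
            n_iter=n_iter,
            early_stop_reason=reason,
            evidence_trace=np.asarray(evidence_trace),
            validation_trace=np.asarray(val_trace),
            prune_iterations=tuple(prune_iterations),
            options=options,
        )

    # ------------------------------------------------------------------
    @staticmethod
    def _posterior(Xa, y, alpha_a, beta):
        """Posterior mean, marginal variances and log evidence for the
        active columns, choosing the primal or dual (Woodbury) form by size."""
        n, ka = Xa.shape
        if ka <= n:
            P = beta * (Xa.T @ Xa)
            P[np.diag_indices_from(P)] += alpha_a
            jitter = 1e-10 * np.trace(P) / ka
            P[np.diag_indices_from(P)] += jitter
            L = sla.cholesky(P, lower=True)
            m = beta * sla.cho_solve((L, True), Xa.T @ y)
            Linv = sla.solve_triangular(L, np.eye(ka), lower=True)
            diag_sigma = np.sum(Linv**2, axis=0)
            # log|C| = -n log beta - sum log alpha + log|P|; y'C^-1 y = beta(y'y - y'Xm)
            logdet_c = (
                -n * np.log(beta)
                - float(np.sum(np.log(alpha_a)))
                + 2.0 * float(np.sum(np.log(np.diag(L))))
            )
            quad = beta * float(y @ y - y @ (Xa @ m))
        else:
            d = 1.0 / alpha_a
            U = Xa * np.sqrt(d)[None, :]
            C = U @ U.T
            C[np.diag_indices_from(C)] += 1.0 / beta
            jitter = 1e-12 * np.trace(C) / n
            C[np.diag_indices_from(C)] += jitter
            L = sla.cholesky(C, lower=True)
            V = sla.solve_triangular(L, U, lower=True)
            u = U.T @ y
            m = beta * np.sqrt(d) * (u - V.T @ (V @ u))
            diag_sigma = d * np.clip(1.0 - np.sum(V**2, axis=0), 1e-300, None)
            w = sla.solve_triangular(L, y, lower=True)
            logdet_c = 2.0 * float(np.sum(np.log(np.diag(L))))
            quad = float(w @ w)
        logev = -0.5 * (n * np.log(2 * np.pi) + logdet_c + quad)
        return m, diag_sigma, logev


@dataclass
class SLRResults:
    """Fitted ARD regression: weights, relevance precisions and diagnostics."""

    model: SparseBayesianRegression
    params: np.ndarray            # full-layout weights; pruned entries exactly 0
    alpha: np.ndarray             # relevance precisions; inf where pruned
    scale_precision: float        # noise precision beta
    active_set: np.ndarray
    n_iter: int
    early_stop_reason: str
    evidence_trace: np.ndarray
    validation_trace: np.ndarray
    prune_iterations: tuple = ()
    options: FitOptions = field(default_factory=FitOptions)

    @property
    def nnz(self) -> int:
        return int(np.sum(self.params != 0))

    @property
    def noise_variance(self) -> float:
        return 1.0 / self.scale_precision

    def predict(self, exog) -> np.ndarray:
        exog = np.atleast_2d(np.asarray(exog, dtype=float))
        return exog @ self.params

    def summary(self) -> str:
        lines = [
            "Sparse Bayesian Linear Regression (ARD)",
            "=" * 44,
            f"rows:              {self.model.exog.shape[0]}",
            f"columns:           {self.model.exog.shape[1]}",
            f"active weights:    {self.active_set.size}",
            f"nonzero weights:   {self.nnz}",
            f"noise variance:    {self.noise_variance:.6g}",
            f"iterations:        {self.n_iter}",
            f"stop reason:       {self.early_stop_reason}",
            f"log evidence:      {self.evidence_trace[-1]:.6g}"
            if self.evidence_trace.size
            else "log evidence:      n/a",
        ]
        return "\n".join(lines)


def fit_slr(design, options: FitOptions | None = None, **kwargs) -> SLRResults:
    """Fit the ARD regression on a :class:`~ecogarm.lagged.LaggedDesign`
    (bias column 0 unpenalized)."""
    return SparseBayesianRegression(design.y, design.X, unpenalized=[0]).fit(
        options, **kwargs
    )


def sparsity_report(
    weights: np.ndarray,
    n_lags: int,
    channel_of_feature: np.ndarray,
    band_of_feature: np.ndarray,
    band_names: tuple[str, ...],
) -> pd.DataFrame:
    """Absolute-weight mass per (channel, band), sorted nonincreasing.

    ``weights`` is the full design-layout vector (bias first); the bias is
    excluded from the mass.  Fractions sum to 1 unless every weight is zero,
    in which case a zero-mass table is returned with a warning.
    """
    w = np.abs(np.asarray(weights, dtype=float)[1:])
    per_feature = w.reshape(-1, n_lags).sum(axis=1)
    df = pd.DataFrame(
        {
            "channel": np.asarray(channel_of_feature, dtype=int),
            "band": [band_names[int(b)] for b in band_of_feature],
            "mass": per_feature,
        }
    )
    total = df["mass"].sum()
    if total == 0:
        log.warning("sparsity report on an empty active set: all weights zero")
        df["fraction"] = 0.0
    else:
        df["fraction"] = df["mass"] / total
    return df.sort_values("mass", ascending=False, kind="stable").reset_index(drop=True)
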