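"""Parametric empirical-Bayes location-scale batch adjustment (ComBat).

Merging arrays from several platforms or studies leaves each gene with
batch-specific location and scale offsets. The adjustment model writes
the standardised expression of gene g in sample j of batch i as

    Z_gj = gamma_ig + delta_ig * eps_gj,

shrinks the per-batch, per-gene location (gamma) and scale (delta^2)
estimates towards batch-level parametric priors — normal for gamma,
inverse-gamma for delta^2, both moment-matched — and removes the
posterior-mean effects. Shrinkage stabilises the per-gene estimates
when batches are small, which is the regime of a typical microarray
meta-analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .containers import ExpressionMatrix

__all__ = ["CombatAdjuster", "BatchModel", "fit_combat", "adjust_combat"]


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


class CombatAdjuster(TransformerMixin, BaseEstimator):
    """sklearn-style transformer removing batch effects gene-wise.

    Operates on ``X`` of shape (n_samples, n_genes); the batch label of
    each sample is passed as ``y`` to :meth:`fit`. ``transform``
    accepts the same samples (or any samples from already-seen batches
    via ``batches=``).

    Parameters
    ----------
    tol : float
        Convergence tolerance on the empirical-Bayes posterior
        iteration (max absolute change of any posterior parameter).
    max_iter : int
        Iteration cap for the posterior fixed point.

    Attributes
    ----------
    alpha_ : (n_genes,) batch-size-weighted grand means.
    sigma2_ : (n_genes,) pooled variances of the batch-centred data.
    gamma_star_, delta2_star_ : (n_batches, n_genes) posterior
        location and scale effects.
    constant_mask_ : genes with zero pooled variance, left unadjusted.
    identity_ : True when only one batch was seen (no-op transform).
    """

    def __init__(self, tol: float = 1e-4, max_iter: int = 500):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        batches = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples × genes)")
        if len(batches) != X.shape[0]:
            raise ValueError("one batch label per sample required")
        labels, inv = np.unique(batches, return_inverse=True)
        counts = np.bincount(inv)
        self.batch_labels_ = [str(b) for b in labels]
        self.n_features_in_ = X.shape[1]
        if len(labels) == 1:
            self.identity_ = True
            self.alpha_ = X.mean(axis=0)
            self.constant_mask_ = np.zeros(X.shape[1], dtype=bool)
            return self
        if counts.min() < 2:
            small = labels[counts < 2]
            raise ValueError(f"batch(es) with a single sample: {list(small)}")
        self.identity_ = False

        n_batches, n_array = len(labels), X.shape[0]
        D = X.T  # genes × samples
        # per-batch gene means; grand mean weighted by batch size
        batch_means = np.stack([D[:, inv == i].mean(axis=1) for i in range(n_batches)])
        alpha = (counts / n_array) @ batch_means
        resid = D - batch_means[inv].T
        sigma2 = (resid**2).mean(axis=1)
        self.constant_mask_ = sigma2 <= 0
        sigma2_safe = np.where(self.constant_mask_, 1.0, sigma2)

        Z = (D - alpha[:, None]) / np.sqrt(sigma2_safe)[:, None]

        gamma_hat = np.stack([Z[:, inv == i].mean(axis=1) for i in range(n_batches)])
        delta_hat = np.stack([Z[:, inv == i].var(axis=1, ddof=1) for i in range(n_batches)])

        gamma_bar = gamma_hat.mean(axis=1)
        tau2 = gamma_hat.var(axis=1, ddof=1)
        m = delta_hat.mean(axis=1)
        s2 = delta_hat.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a_prior = (2 * s2 + m**2) / s2
            b_prior = (m * s2 + m**3) / s2

        gamma_star = np.empty_like(gamma_hat)
        delta2_star = np.empty_like(delta_hat)
        for i in range(n_batches):
            zi = Z[:, inv == i]
            n_i = counts[i]
            g_old = gamma_hat[i].copy()
            d_old = delta_hat[i].copy()
            for _ in range(self.max_iter):
                g_new = _postmean(gamma_hat[i], gamma_bar[i], n_i, d_old, tau2[i])
                sum2 = ((zi - g_new[:, None]) ** 2).sum(axis=1)
                d_new = _postvar(sum2, n_i, a_prior[i], b_prior[i])
                change = max(
                    np.abs(g_new - g_old).max(initial=0.0),
                    np.abs(d_new - d_old).max(initial=0.0),
                )
                g_old, d_old = g_new, d_new
                if change < self.tol:
                    break
            gamma_star[i] = g_old
            delta2_star[i] = d_old

        if np.any(delta2_star <= 0):
            raise RuntimeError("posterior scale effects must be positive")
        self.alpha_ = alpha
        self.sigma2_ = sigma2
        self.gamma_hat_ = gamma_hat
        self.delta_hat_ = delta_hat
        self.gamma_bar_ = gamma_bar
        self.tau2_ = tau2
        self.a_prior_ = a_prior
        self.b_prior_ = b_prior
        self.gamma_star_ = gamma_star
        self.delta2_star_ = delta2_star
        self._fit_batches = batches
        return self

    def transform(self, X, batches=None):
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        if self.identity_:
            return X.copy()
        if batches is None:
            batches = self._fit_batches
        batches = np.asarray(batches)
        if len(batches) != X.shape[0]:
            raise ValueError("one batch label per sample required")
        label_to_idx = {b: i for i, b in enumerate(self.batch_labels_)}
        try:
            idx = np.array([label_to_idx[str(b)] for b in batches])
        except KeyError as exc:
            raise ValueError(f"unseen batch label: {exc.args[0]!r}") from None

        sigma2_safe = np.where(self.constant_mask_, 1.0, self.sigma2_)
        sd = np.sqrt(sigma2_safe)
        Z = (X - self.alpha_) / sd
        adj = (Z - self.gamma_star_[idx]) / np.sqrt(self.delta2_star_[idx])
        out = adj * sd + self.alpha_
        # constant genes carry no batch information: pass through
        out[:, self.constant_mask_] = X[:, self.constant_mask_]
        return out

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y).transform(X)


@dataclass
class BatchModel:
    """Fitted batch model tying a :class:`CombatAdjuster` to gene ids."""

    estimator: CombatAdjuster
    gene_ids: list[str]
    batch_key: str
    batch_of: dict[str, str] = field(default_factory=dict)

    @property
    def identity(self) -> bool:
        return self.estimator.identity_


def _batch_labels(em: ExpressionMatrix, batch_key: str) -> np.ndarray:
    meta = em.sample_frame()
    if batch_key not in meta.columns:
        raise KeyError(f"batch key {batch_key!r} not in sample metadata")
    return meta[batch_key].astype(str).values


def fit_combat(em: ExpressionMatrix, batch_key: str = "platform_id") -> BatchModel:
    """Fit the empirical-Bayes batch model on a log2 expression matrix."""
    if not em.log2_scale:
        raise ValueError("batch adjustment expects log2-scale data")
    batches = _batch_labels(em, batch_key)
    est = CombatAdjuster().fit(em.values.values.T, batches)
    if est.identity_:
        warnings.warn("single batch: model is the identity", stacklevel=2)
    if getattr(est, "constant_mask_", None) is not None and est.constant_mask_.any():
        n = int(est.constant_mask_.sum())
        warnings.warn(f"{n} constant gene(s) left unadjusted", stacklevel=2)
    return BatchModel(
        estimator=est,
        gene_ids=em.gene_ids,
        batch_key=batch_key,
        batch_of=dict(zip(em.sample_ids, batches)),
    )


def adjust_combat(em: ExpressionMatrix, model: BatchModel) -> ExpressionMatrix:
    """Remove the fitted batch effects from ``em``."""
    if em.gene_ids != model.gene_ids:
        raise ValueError("model was fitted on a different gene universe")
    batches = _batch_labels(em, model.batch_key)
    adj = model.estimator.transform(em.values.values.T, batches=batches).T
    return ExpressionMatrix(
        pd.DataFrame(adj, index=em.values.index, columns=em.values.columns),
        em.log2_scale,
        em.samples,
    )
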