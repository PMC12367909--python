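"""Empirical-Bayes location/scale batch harmonization (ComBat).

Multi-scanner radiomic studies carry scanner-specific additive and
multiplicative shifts in every feature.  The ComBat model estimates
per-(batch, feature) location (gamma) and scale (delta^2) effects on
standardized data, shrinks them across features with an empirical-Bayes
prior (normal on gamma, inverse-gamma on delta^2), and removes them.

Two departures from strict textbook behaviour, both deliberate:

* after adjustment each feature is re-centered to its original column
  mean — harmonization should remove between-batch contrast, not move a
  feature's overall location (the EB shrinkage otherwise shifts it by a
  small amount);
* zero-variance features are passed through untouched with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["BatchModel", "combat_fit_transform"]


@dataclass
class BatchModel:
    """Fitted harmonization parameters (one gamma*, delta*^2 per batch x feature)."""

    batches: list
    feature_names: list[str]
    grand_mean: np.ndarray          # per feature (alpha-hat)
    pooled_var: np.ndarray          # per feature
    gamma_star: np.ndarray          # (n_batches, n_features)
    delta_sq_star: np.ndarray       # (n_batches, n_features), > 0
    parametric: bool = True
    skipped_features: list[str] | None = None


def _postmean(g_hat, g_bar, n, d_star_sq, t2):
    return (t2 * n * g_hat + d_star_sq * g_bar) / (t2 * n + d_star_sq)


def _postvar(sum_sq, n, a, b):
    return (0.5 * sum_sq + b) / (n / 2.0 + a - 1.0)


def _parametric_adjust(Z_b, g_hat, d_hat_sq, g_bar, t2, a, b, tol=1e-6,
                       max_iter=500):
    """Iterative conditional EB updates for one batch (Johnson 2007 style)."""
    n = Z_b.shape[0]
    g_new, d_new = g_hat.copy(), d_hat_sq.copy()
    for _ in range(max_iter):
        g_old, d_old = g_new, d_new
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum_sq = ((Z_b - g_new[None, :]) ** 2).sum(axis=0)
        d_new = _postvar(sum_sq, n, a, b)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        if change < tol:
            break
    return g_new, d_new


def _nonparametric_adjust(Z_b, g_hat, d_hat_sq):
    """Monte-Carlo (empirical prior) EB estimates for one batch.

    For each feature g the posterior weight of every other feature's
    (gamma_hat, delta_hat^2) pair is its likelihood given feature g's
    standardized data.
    """
    n, G = Z_b.shape
    g_star = np.empty(G)
    d_star = np.empty(G)
    for g in range(G):
        others = np.arange(G) != g
        gh, dh = g_hat[others], d_hat_sq[others]
        x = Z_b[:, g]
        sum_sq = ((x[:, None] - gh[None, :]) ** 2).sum(axis=0)
        log_lik = -0.5 * sum_sq / dh - 0.5 * n * np.log(2 * np.pi * dh)
        w = np.exp(log_lik - log_lik.max())
        w_sum = w.sum()
        if w_sum <= 0 or not np.isfinite(w_sum):  # pragma: no cover
            g_star[g], d_star[g] = g_hat[g], d_hat_sq[g]
        else:
            g_star[g] = (w * gh).sum() / w_sum
            d_star[g] = (w * dh).sum() / w_sum
    return g_star, d_star


def combat_fit_transform(
    features: pd.DataFrame,
    batch_labels,
    covariates: pd.DataFrame | None = None,
    parametric: bool = True,
    tol: float = 1e-6,
    ddof: int = 0,
) -> tuple[pd.DataFrame, BatchModel]:
    """Harmonize a patients x features matrix across batches.

    Parameters
    ----------
    features : DataFrame (patients x features), no missing values.
    batch_labels : array-like of batch (scanner) identifiers, one per row.
    covariates : optional design of biological covariates to protect
        during standardization (not protected by default).
    parametric : parametric (normal/inverse-gamma) EB shrinkage if True,
        empirical-prior Monte-Carlo variant otherwise.
    ddof : degrees-of-freedom convention for the per-batch scale estimate.
        The default 0 (population variance) makes harmonization an exact
        identity when batches carry no effect; ``ddof=1`` reproduces the
        reference R implementation (sva::ComBat) bit-for-bit up to the
        re-centering described above.

    Returns the harmonized matrix (same shape/schema) and the fitted
    :class:`BatchModel`.
    """
    X = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) else \
        np.asarray(features, dtype=float)
    if isinstance(features, pd.DataFrame):
        feat_names = list(features.columns)
        index = features.index
    else:
        feat_names = [f"f{i}" for i in range(X.shape[1])]
        index = pd.RangeIndex(X.shape[0])
    if np.isnan(X).any():
        raise ValueError("feature matrix contains missing values")
    batch_labels = np.asarray(batch_labels)
    if len(batch_labels) != X.shape[0]:
        raise ValueError("one batch label per sample is required")
    if pd.isna(batch_labels).any():
        raise ValueError("batch label missing for at least one sample")
    batches = sorted(pd.unique(batch_labels).tolist())
    n, G = X.shape
    n_per = {b: int((batch_labels == b).sum()) for b in batches}
    for b, nb in n_per.items():
        if nb < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 samples")

    # zero-variance features pass through untouched
    sd0 = X.std(axis=0, ddof=0)
    keep = sd0 > 0
    skipped = [feat_names[i] for i in np.where(~keep)[0]]
    if skipped:
        warnings.warn(
            f"{len(skipped)} zero-variance feature(s) passed through unharmonized",
            stacklevel=2,
        )
    Xk = X[:, keep]
    Gk = Xk.shape[1]

    # design: batch one-hot (+ optional protected covariates)
    B = np.column_stack([(batch_labels == b).astype(float) for b in batches])
    if covariates is not None:
        C = covariates.to_numpy(dtype=float) if isinstance(covariates, pd.DataFrame) \
            else np.asarray(covariates, dtype=float)
        design = np.column_stack([B, C])
    else:
        C = None
        design = B
    beta, *_ = np.linalg.lstsq(design, Xk, rcond=None)
    nb_frac = np.array([n_per[b] / n for b in batches])
    alpha = nb_frac @ beta[: len(batches)]          # weighted grand mean
    cov_effect = design[:, len(batches):] @ beta[len(batches):] if C is not None \
        else 0.0
    fitted_means = B @ beta[: len(batches)] + cov_effect
    resid = Xk - fitted_means
    pooled_var = (resid**2).mean(axis=0)
    pooled_sd = np.sqrt(pooled_var)
    Z = (Xk - alpha[None, :] - cov_effect) / pooled_sd[None, :]

    gamma_star = np.empty((len(batches), Gk))
    delta_sq_star = np.empty((len(batches), Gk))
    for bi, b in enumerate(batches):
        rows = batch_labels == b
        Zb = Z[rows]
        g_hat = Zb.mean(axis=0)
        d_hat_sq = Zb.var(axis=0, ddof=ddof)
        d_hat_sq = np.maximum(d_hat_sq, 1e-12)
        if Gk < 2:
            # no cross-feature information: no shrinkage possible
            gamma_star[bi], delta_sq_star[bi] = g_hat, d_hat_sq
            continue
        g_bar = g_hat.mean()
        t2 = g_hat.var(ddof=1)
        v_bar = d_hat_sq.mean()
        s2 = d_hat_sq.var(ddof=1)
        eps = 1e-12
        if parametric:
            if t2 < eps and s2 < eps:
                # no cross-feature spread in either effect: nothing to shrink
                gamma_star[bi], delta_sq_star[bi] = g_hat, d_hat_sq
            elif s2 < eps:
                # degenerate scale hyperprior: shrink locations only
                gamma_star[bi] = _postmean(g_hat, g_bar, Zb.shape[0],
                                           d_hat_sq, t2)
                delta_sq_star[bi] = d_hat_sq
            elif t2 < eps:
                # degenerate location hyperprior: shrink scales only
                a = (v_bar**2 + 2 * s2) / s2
                b_prior = (v_bar**3 + v_bar * s2) / s2
                sum_sq = ((Zb - g_hat[None, :]) ** 2).sum(axis=0)
                gamma_star[bi] = g_hat
                delta_sq_star[bi] = _postvar(sum_sq, Zb.shape[0], a, b_prior)
            else:
                a = (v_bar**2 + 2 * s2) / s2
                b_prior = (v_bar**3 + v_bar * s2) / s2
                gamma_star[bi], delta_sq_star[bi] = _parametric_adjust(
                    Zb, g_hat, d_hat_sq, g_bar, t2, a, b_prior, tol=tol
                )
        else:
            gamma_star[bi], delta_sq_star[bi] = _nonparametric_adjust(
                Zb, g_hat, d_hat_sq
            )
    delta_sq_star = np.maximum(delta_sq_star, 1e-12)

    Z_adj = Z.copy()
    for bi, b in enumerate(batches):
        rows = batch_labels == b
        Z_adj[rows] = (Z[rows] - gamma_star[bi][None, :]) / np.sqrt(
            delta_sq_star[bi][None, :]
        )
    X_adj = Z_adj * pooled_sd[None, :] + alpha[None, :] + cov_effect
    # preserve each feature's overall column mean exactly
    X_adj = X_adj - X_adj.mean(axis=0)[None, :] + Xk.mean(axis=0)[None, :]

    out = X.copy()
    out[:, keep] = X_adj
    full_alpha = np.full(G, np.nan)
    full_alpha[keep] = alpha
    full_pv = np.full(G, np.nan)
    full_pv[keep] = pooled_var
    gs = np.full((len(batches), G), np.nan)
    gs[:, keep] = gamma_star
    ds = np.full((len(batches), G), np.nan)
    ds[:, keep] = delta_sq_star
    model = BatchModel(
        batches=batches,
        feature_names=feat_names,
        grand_mean=full_alpha,
        pooled_var=full_pv,
        gamma_star=gs,
        delta_sq_star=ds,
        parametric=parametric,
        skipped_features=skipped,
    )
    result = pd.DataFrame(out, index=index, columns=feat_names)
    return result, model
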