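"""Parametric empirical-Bayes batch correction (location/scale model).

QMI experiments are run on different days with fresh bead conjugations, which
introduces multiplicative batch effects per interaction.  On the log2 scale
these become additive location shifts plus scale changes.  The model here is
the classic parametric empirical-Bayes location/scale adjustment: per
interaction, fit grand mean + condition effects, standardize by the pooled
residual scale, estimate per-batch per-interaction location (gamma) and scale
(delta^2) parameters, shrink them toward batch-level priors (normal prior for
gamma, inverse-gamma for delta^2, hyperparameters by method of moments,
iterative conditional estimation), then remove the shrunken batch effects and
restore grand mean + condition effects.

The condition design is included as a covariate during standardization so
that condition differences are preserved, provided conditions are not
perfectly confounded with batch.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .datatypes import MFIMatrix
from .errors import ValidationError
from .preprocess import log2_transform

logger = logging.getLogger(__name__)


def _as_series(mapping, sample_ids, what: str) -> pd.Series:
    if isinstance(mapping, pd.Series):
        s = mapping.reindex(sample_ids)
    elif isinstance(mapping, Mapping):
        s = pd.Series({s_: mapping[s_] for s_ in sample_ids if s_ in mapping}).reindex(sample_ids)
    else:
        s = pd.Series(list(mapping), index=sample_ids)
    if s.isna().any():
        missing = list(s.index[s.isna()])
        raise ValidationError(f"{what} missing for samples: {missing}")
    return s.astype(str)


def _mom_inverse_gamma(delta_hat: np.ndarray) -> tuple[float, float]:
    """Method-of-moments hyperparameters (shape, rate) for the inverse-gamma prior."""
    m = float(delta_hat.mean())
    s2 = float(delta_hat.var(ddof=1)) if delta_hat.size > 1 else 0.0
    if s2 <= 0:
        # Degenerate spread: an effectively point prior at m.
        return 3.0, 2.0 * m
    a = (2.0 * s2 + m**2) / s2
    b = (m * s2 + m**3) / s2
    return a, b


def _posterior_batch_params(
    z_batch: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative conditional estimates of shrunken location/scale for one batch.

    ``z_batch`` is (n_b samples x G interactions) of standardized data.
    """
    n_b = z_batch.shape[0]
    gamma_hat = z_batch.mean(axis=0)
    delta_hat = z_batch.var(axis=0, ddof=1)
    g_bar = float(gamma_hat.mean())
    t2 = float(gamma_hat.var(ddof=1)) if gamma_hat.size > 1 else 0.0
    a_prior, b_prior = _mom_inverse_gamma(delta_hat)

    gamma = gamma_hat.copy()
    delta = delta_hat.copy()
    for _ in range(max_iter):
        gamma_new = (n_b * t2 * gamma_hat + delta * g_bar) / (n_b * t2 + delta)
        ss = ((z_batch - gamma_new) ** 2).sum(axis=0)
        delta_new = (b_prior + 0.5 * ss) / (n_b / 2.0 + a_prior - 1.0)
        change = max(
            float(np.max(np.abs(gamma_new - gamma))), float(np.max(np.abs(delta_new - delta)))
        )
        gamma, delta = gamma_new, delta_new
        if change < tol:
            break
    return gamma, np.maximum(delta, 1e-12)


def empirical_bayes_batch_correct(
    matrix: MFIMatrix,
    batches: Mapping[str, str] | pd.Series,
    design: Mapping[str, str] | pd.Series | None = None,
    *,
    tol: float = 1e-4,
    max_iter: int = 500,
    allow_single_sample_batches: bool = False,
) -> MFIMatrix:
    """Remove per-batch location/scale effects from an MFI matrix.

    Parameters
    ----------
    matrix:
        Interactions x samples.  Log2 scale is the model's natural scale; a
        linear matrix is log2-transformed internally and back-transformed so
        the output scale matches the input.
    batches:
        Sample -> batch label.  With a single batch the input is returned
        unchanged.
    design:
        Optional sample -> condition label, preserved during standardization.
    allow_single_sample_batches:
        A batch with one sample has no estimable scale; by default this is an
        error.  If enabled, such a batch keeps unit scale and its location is
        shrunk toward the batch-level prior ("shrink-to-prior-only" mode).

    Returns
    -------
    MFIMatrix with the same dimensions and scale flag as the input.
    """
    input_linear = matrix.scale == "linear"
    work = log2_transform(matrix) if input_linear else matrix
    samples = work.sample_ids
    batch = _as_series(batches, samples, "batch label")
    levels = sorted(batch.unique())
    if len(levels) == 1:
        return matrix.copy()

    counts = batch.value_counts()
    singles = [b for b in levels if counts[b] < 2]
    if singles and not allow_single_sample_batches:
        raise ValidationError(
            f"batch(es) with a single sample (scale not estimable): {singles}; "
            "pass allow_single_sample_batches=True for shrink-to-prior-only mode"
        )

    n = len(samples)
    batch_onehot = np.stack([(batch == b).to_numpy(float) for b in levels], axis=1)
    covar = None
    if design is not None:
        cond = _as_series(design, samples, "condition label")
        cond_levels = list(dict.fromkeys(cond))
        if len(cond_levels) > 1:
            covar = np.stack(
                [(cond == c).to_numpy(float) for c in cond_levels[1:]], axis=1
            )
            full = np.hstack([batch_onehot, covar])
            if np.linalg.matrix_rank(full) < full.shape[1]:
                warnings.warn(
                    "a batch is perfectly confounded with a condition; the correction "
                    "may absorb part of the condition effect",
                    UserWarning,
                    stacklevel=2,
                )

    D = batch_onehot if covar is None else np.hstack([batch_onehot, covar])
    X = work.values.to_numpy().T  # samples x interactions
    beta, *_ = np.linalg.lstsq(D, X, rcond=None)
    n_batches = len(levels)
    batch_sizes = counts.reindex(levels).to_numpy(float)
    grand_mean = (batch_sizes / n) @ beta[:n_batches]  # (G,)
    covar_fit = covar @ beta[n_batches:] if covar is not None else 0.0
    resid = X - D @ beta
    var_pooled = np.maximum((resid**2).mean(axis=0), 1e-12)

    stand_mean = grand_mean[None, :] + covar_fit
    Z = (X - stand_mean) / np.sqrt(var_pooled)

    Z_adj = Z.copy()
    for b in levels:
        rows = (batch == b).to_numpy()
        zb = Z[rows]
        if zb.shape[0] < 2:
            # shrink-to-prior-only: no scale adjustment, location toward prior mean
            gamma_hat = zb.mean(axis=0)
            g_bar = float(gamma_hat.mean())
            t2 = float(gamma_hat.var(ddof=1)) if gamma_hat.size > 1 else 0.0
            gamma = (t2 * gamma_hat + g_bar) / (t2 + 1.0)
            delta = np.ones_like(gamma)
            logger.warning("batch %r has one sample: shrink-to-prior-only adjustment", b)
        else:
            gamma, delta = _posterior_batch_params(zb, tol=tol, max_iter=max_iter)
        Z_adj[rows] = (zb - gamma) / np.sqrt(delta)

    X_adj = Z_adj * np.sqrt(var_pooled) + stand_mean
    out = pd.DataFrame(X_adj.T, index=work.interaction_ids, columns=samples)
    if input_linear:
        return MFIMatrix(np.exp2(out), "linear")
    return MFIMatrix(out, "log2")
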