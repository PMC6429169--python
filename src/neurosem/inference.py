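"""Robust (sandwich) standard errors and Bartlett latent-variable scores.

Genotypes are discrete counts, so the normal-theory standard errors of the
ML fit are not trustworthy for the SNP-weight parameters. The sandwich
estimator used here replaces the normal-theory fourth moments with the
empirical fourth moments of the data (the "MLM"-style robust correction):

    acov = (D'WD)^-1 D'W Gamma W D (D'WD)^-1 / n

with D the Jacobian of the implied-covariance elements w.r.t. the free
parameters, W the normal-theory weight matrix at the optimum, and Gamma the
empirical covariance of the sample-covariance elements. Under exact
normality Gamma collapses to W^-1 and the sandwich reduces to the naive
covariance.

All matrix products are carried out in the d x d "vec" representation, so
no Kronecker products or duplication matrices are ever formed explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy import stats

from .model import (
    FitError,
    FitResult,
    implied_covariance,
    param_derivative_matrices,
    _expected_information,
)


def robust_adjust(fit: FitResult, g: np.ndarray, x: np.ndarray) -> FitResult:
    """Fill ``robust_se``, ``z_robust`` and ``p_robust`` of a fit.

    Parameters
    ----------
    fit : FitResult
        A converged fit.
    g, x : arrays
        The same (centred) data matrices the model was fitted to; the raw
        rows are needed because the correction uses empirical fourth
        moments.

    Returns
    -------
    FitResult
        A copy of ``fit`` with robust standard errors, z statistics and
        two-sided normal-tail p values per free parameter.
    """
    if not fit.converged:
        raise FitError("robust adjustment requires a converged fit")
    spec = fit.spec
    g = np.asarray(g, dtype=float).reshape(len(x), spec.p)
    x = np.asarray(x, dtype=float)
    n, d = x.shape[0], spec.p + spec.q
    X = np.hstack([g, x])
    Xc = X - X.mean(axis=0)

    n_moments = d * (d + 1) // 2
    warns = list(fit.warnings)
    if n <= n_moments:
        warns.append(
            f"n={n} does not exceed the {n_moments} unique second moments; "
            "the empirical fourth-moment matrix is rank deficient"
        )

    sigma = implied_covariance(fit.params, spec).full
    sigma_inv = sla.cho_solve((sla.cholesky(sigma, lower=True), True), np.eye(d))
    dsigma = param_derivative_matrices(fit.params, spec)
    info, M = _expected_information(sigma_inv, dsigma)

    # u[i, k] = x_i' M_k x_i realises vec(M_k)' vec(x_i x_i'); its column
    # mean is tr(M_k S), so centring the columns centres Gamma exactly.
    u = np.stack([((Xc @ Mk) * Xc).sum(axis=1) for Mk in M], axis=1)
    uc = u - u.mean(axis=0)
    meat = 0.25 * (uc.T @ uc) / n

    try:
        with warnings.catch_warnings():
            # near-singular information (e.g. collapsed latents under a
            # misspecified grouping) legitimately yields huge SEs / p ~ 1
            warnings.simplefilter("ignore", sla.LinAlgWarning)
            bread = sla.inv(info)
    except sla.LinAlgError as e:
        raise FitError("expected information is singular") from e
    acov = bread @ meat @ bread / n
    diag = np.diag(acov).copy()
    diag[diag < 0] = np.nan
    robust_se = np.sqrt(diag)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(robust_se > 0, fit.estimates / robust_se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return replace(fit, robust_se=robust_se, z_robust=z, p_robust=p, warnings=warns)


@dataclass
class LatentScores:
    """Per-individual Bartlett estimates of the latent variables.

    ``values`` is n x m, columns ordered and keyed by ``group_ids``.
    """

    values: np.ndarray
    group_ids: tuple

    def to_frame(self, index=None) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.group_ids), index=index)


def bartlett_scores(fit: FitResult, x: np.ndarray) -> LatentScores:
    """Conditionally unbiased latent scores from the measurement model.

    zhat_i = (B' Theta^-1 B)^-1 B' Theta^-1 x_i, using the estimated
    loadings and region residual variances only; the scores satisfy
    E[zhat | z] = z because the projection maps B to the identity.
    """
    spec = fit.spec
    x = np.asarray(x, dtype=float)
    if x.shape[1] != spec.q:
        raise FitError("region matrix width does not match the spec")
    B = fit.params.B
    theta_inv = 1.0 / fit.params.theta_full(spec)
    if not np.all(np.isfinite(theta_inv)):
        raise FitError("non-finite region residual variances")
    BtW = B.T * theta_inv                              # m x q
    gram = BtW @ B
    try:
        proj = sla.solve(gram, BtW, assume_a="pos")
    except sla.LinAlgError as e:
        raise FitError("B' Theta^-1 B is singular") from e
    return LatentScores(values=x @ proj.T, group_ids=spec.group_ids)
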