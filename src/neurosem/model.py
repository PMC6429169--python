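"""Grouped-latent structural equation model: specification, implied
covariance, and maximum-likelihood fitting.

The model links p observed SNPs ``g`` (exogenous, centred) to q observed
brain-region measurements ``x`` (centred, usually scaled) through m latent
variables ``z``, one per region group::

    z = A g + eps        eps ~ N(0, Psi),  Psi diagonal (m x m)
    x = B z + zeta       zeta ~ N(0, Theta), Theta diagonal (q x q)

``B`` is block-structured: each latent loads only on the regions of its own
group, the first region per group (the anchor) has its loading fixed to 1
for scale identifiability, and the residual variances in ``Theta`` are
shared within each group (one free theta per group). The SNP covariance is
exogenous and is fixed at its observed value rather than optimised.

The implied covariance of the observed vector (SNPs first, then regions) is

    Sigma = [[ S_gg,           S_gg A' B'                        ],
             [ B A S_gg,       B A S_gg A' B' + B Psi B' + Theta ]]

and parameters are found by minimising the normal-theory discrepancy

    F = log|Sigma| + tr(S Sigma^-1) - log|S| - (p + q),

which is equivalent to maximising the Gaussian likelihood of the sample
covariance S (divisor n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.optimize import minimize


class SpecError(ValueError):
    """Invalid model specification (grouping, anchors, identifiability)."""


class FitError(RuntimeError):
    """Fitting could not be carried out on the given inputs."""


# ---------------------------------------------------------------------------
# Specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SEMSpec:
    """Structure of the grouped-latent SEM.

    Parameters
    ----------
    snp_ids : tuple of str
        Identifiers of the p exogenous SNPs (may be empty).
    region_ids : tuple of str
        Identifiers of the q observed region measurements, in model order.
    group_ids : tuple of str
        Identifiers of the m region groups / latent variables, in the order
        of first appearance in ``region_ids``.
    membership : mapping region_id -> group_id
        Every region belongs to exactly one group.
    anchor_region : mapping group_id -> region_id
        Region whose loading is fixed to 1; the first region of each group.
    """

    snp_ids: tuple
    region_ids: tuple
    group_ids: tuple
    membership: Mapping
    anchor_region: Mapping

    def __post_init__(self):
        groups = {}
        for r in self.region_ids:
            if r not in self.membership:
                raise SpecError(f"region {r!r} has no group assignment")
            groups.setdefault(self.membership[r], []).append(r)
        if set(groups) != set(self.group_ids):
            raise SpecError("group_ids inconsistent with membership")
        for g, members in groups.items():
            if len(members) < 2:
                raise SpecError(
                    f"group {g!r} has a single region; the residual variance "
                    "and loading of a singleton group are not separable"
                )
            if self.anchor_region[g] not in members:
                raise SpecError(f"anchor of group {g!r} is not a member")

    @property
    def p(self) -> int:
        return len(self.snp_ids)

    @property
    def q(self) -> int:
        return len(self.region_ids)

    @property
    def m(self) -> int:
        return len(self.group_ids)

    @property
    def group_index(self) -> np.ndarray:
        """Length-q vector mapping each region to its group's index."""
        gidx = {g: i for i, g in enumerate(self.group_ids)}
        return np.array([gidx[self.membership[r]] for r in self.region_ids])

    @property
    def anchor_index(self) -> np.ndarray:
        """Length-m vector of region indices of each group's anchor."""
        ridx = {r: i for i, r in enumerate(self.region_ids)}
        return np.array([ridx[self.anchor_region[g]] for g in self.group_ids])

    def members(self, group_id) -> list:
        return [r for r in self.region_ids if self.membership[r] == group_id]

    def free_loading_positions(self) -> list:
        """(region_index, group_index) of every free (non-anchor) loading."""
        anchors = set(self.anchor_index)
        gidx = self.group_index
        return [(r, gidx[r]) for r in range(self.q) if r not in anchors]

    def n_free(self) -> int:
        """Free loadings + A entries + latent and region residual variances."""
        return (self.q - self.m) + self.m * self.p + self.m + self.m

    def loading_pattern(self) -> np.ndarray:
        """Boolean q x m mask of structurally nonzero loadings."""
        pat = np.zeros((self.q, self.m), dtype=bool)
        pat[np.arange(self.q), self.group_index] = True
        return pat


def build_spec(grouping, snp_ids: Sequence = (), region_order: Sequence | None = None) -> SEMSpec:
    """Build a model specification from a region -> group mapping.

    Parameters
    ----------
    grouping : mapping, pandas Series, or DataFrame
        Region-to-group assignment. A DataFrame must have the region ids in
        its first column and group codes in its second.
    snp_ids : sequence of str, optional
        SNP identifiers; an empty sequence yields a pure measurement model.
    region_order : sequence of str, optional
        Order of regions in the model; defaults to the order of appearance
        in ``grouping``. Anchors are the first region per group in this
        order.
    """
    if isinstance(grouping, pd.DataFrame):
        grouping = pd.Series(
            grouping.iloc[:, 1].values, index=grouping.iloc[:, 0].values
        )
    if isinstance(grouping, pd.Series):
        grouping = grouping.to_dict()
    grouping = dict(grouping)
    if region_order is None:
        region_order = list(grouping)
    region_order = list(region_order)
    for r in region_order:
        if r not in grouping or pd.isna(grouping[r]):
            raise SpecError(f"region {r!r} has no group assignment")
    group_ids, anchor = [], {}
    for r in region_order:
        g = grouping[r]
        if g not in anchor:
            group_ids.append(g)
            anchor[g] = r
    return SEMSpec(
        snp_ids=tuple(snp_ids),
        region_ids=tuple(region_order),
        group_ids=tuple(group_ids),
        membership={r: grouping[r] for r in region_order},
        anchor_region=anchor,
    )


# ---------------------------------------------------------------------------
# Parameters and implied covariance
# ---------------------------------------------------------------------------

@dataclass
class SEMParams:
    """Parameter values of a grouped-latent SEM.

    ``theta`` holds one residual variance per group; the full q-vector of
    region residual variances is ``theta[spec.group_index]``.
    """

    A: np.ndarray          # m x p SNP -> latent weights
    B: np.ndarray          # q x m loadings (anchors = 1, off-pattern = 0)
    psi: np.ndarray        # m latent residual variances
    theta: np.ndarray      # m region residual variances (shared per group)
    sigma_gg: np.ndarray   # p x p SNP covariance (fixed)

    def validate(self, spec: SEMSpec) -> None:
        m, p, q = spec.m, spec.p, spec.q
        if self.A.shape != (m, p) or self.B.shape != (q, m):
            raise ValueError("parameter dimensions do not match the spec")
        if self.psi.shape != (m,) or self.theta.shape != (m,):
            raise ValueError("variance vectors must have length m")
        if self.sigma_gg.shape != (p, p):
            raise ValueError("sigma_gg must be p x p")
        if np.any(self.psi <= 0) or np.any(self.theta <= 0):
            raise ValueError("residual variances must be positive")
        if np.any(self.B[~spec.loading_pattern()] != 0):
            raise ValueError("B has entries outside the group pattern")
        if not np.allclose(self.B[spec.anchor_index, np.arange(m)], 1.0):
            raise ValueError("anchor loadings must equal 1")

    def theta_full(self, spec: SEMSpec) -> np.ndarray:
        return self.theta[spec.group_index]


@dataclass(frozen=True)
class ImpliedCovariance:
    """Model-implied covariance of (SNPs, regions), SNPs first."""

    full: np.ndarray
    p: int

    @property
    def sigma_gg(self) -> np.ndarray:
        return self.full[: self.p, : self.p]

    @property
    def sigma_gx(self) -> np.ndarray:
        return self.full[: self.p, self.p:]

    @property
    def sigma_xg(self) -> np.ndarray:
        return self.full[self.p:, : self.p]

    @property
    def sigma_xx(self) -> np.ndarray:
        return self.full[self.p:, self.p:]


def implied_covariance(params: SEMParams, spec: SEMSpec) -> ImpliedCovariance:
    """Assemble the implied covariance from the current parameter values.

    The SNP block is the fixed observed SNP covariance; the cross block is
    ``S_gg A' B'`` and the region block ``B (A S_gg A' + Psi) B' + Theta``.
    """
    params.validate(spec)
    A, B, T = params.A, params.B, params.sigma_gg
    C = A @ T @ A.T + np.diag(params.psi)          # cov of latents
    sigma_xx = B @ C @ B.T + np.diag(params.theta_full(spec))
    sigma_xg = B @ A @ T
    full = np.block([[T, sigma_xg.T], [sigma_xg, sigma_xx]])
    full = 0.5 * (full + full.T)
    return ImpliedCovariance(full=full, p=spec.p)


def ml_discrepancy(params: SEMParams, spec: SEMSpec, S: np.ndarray) -> float:
    """Normal-theory ML discrepancy F between implied and sample covariance.

    F = log|Sigma| + tr(S Sigma^-1) - log|S| - d, nonnegative, zero iff
    Sigma = S. Raises ``FitError`` if S is not symmetric positive definite
    or Sigma is numerically singular.
    """
    d = spec.p + spec.q
    S = np.asarray(S, dtype=float)
    if S.shape != (d, d) or not np.allclose(S, S.T, atol=1e-10):
        raise FitError("S must be a symmetric (p+q) x (p+q) matrix")
    try:
        cho_S = sla.cholesky(S, lower=True)
    except sla.LinAlgError as e:
        raise FitError("sample covariance S is not positive definite") from e
    sigma = implied_covariance(params, spec).full
    try:
        cho = sla.cholesky(sigma, lower=True)
    except sla.LinAlgError as e:
        cond = np.linalg.cond(sigma)
        raise FitError(
            f"implied covariance is singular (condition number {cond:.3g})"
        ) from e
    logdet_sigma = 2.0 * np.sum(np.log(np.diag(cho)))
    logdet_S = 2.0 * np.sum(np.log(np.diag(cho_S)))
    sigma_inv_S = sla.cho_solve((cho, True), S)
    return float(logdet_sigma + np.trace(sigma_inv_S) - logdet_S - d)


# ---------------------------------------------------------------------------
# Free-parameter vectorisation
# ---------------------------------------------------------------------------

class _ParamMap:
    """Maps between SEMParams and the unconstrained optimisation vector.

    Layout: free loadings (region order), A entries (row-major), log psi,
    log theta. Variances are log-parameterised to stay positive.
    """

    def __init__(self, spec: SEMSpec):
        self.spec = spec
        self.free_loadings = spec.free_loading_positions()
        self.n_load = len(self.free_loadings)
        self.n_a = spec.m * spec.p
        self.n = spec.n_free()

    def pack(self, params: SEMParams) -> np.ndarray:
        v = np.empty(self.n)
        for k, (r, l) in enumerate(self.free_loadings):
            v[k] = params.B[r, l]
        v[self.n_load: self.n_load + self.n_a] = params.A.ravel()
        v[self.n_load + self.n_a: self.n_load + self.n_a + self.spec.m] = np.log(params.psi)
        v[self.n_load + self.n_a + self.spec.m:] = np.log(params.theta)
        return v

    def unpack(self, v: np.ndarray, sigma_gg: np.ndarray) -> SEMParams:
        spec = self.spec
        B = np.zeros((spec.q, spec.m))
        B[spec.anchor_index, np.arange(spec.m)] = 1.0
        for k, (r, l) in enumerate(self.free_loadings):
            B[r, l] = v[k]
        A = v[self.n_load: self.n_load + self.n_a].reshape(spec.m, spec.p)
        psi = np.exp(v[self.n_load + self.n_a: self.n_load + self.n_a + spec.m])
        theta = np.exp(v[self.n_load + self.n_a + spec.m:])
        return SEMParams(A=A, B=B, psi=psi, theta=theta, sigma_gg=sigma_gg)

    def bounds(self, var_floor: float = 1e-6) -> list:
        """Box bounds: generous limits on weights, a variance floor on the
        log variances to cut off Heywood-case ridges (variance -> 0 with
        diverging loadings) that otherwise stall the line search."""
        lb = np.full(self.n, -1e4)
        ub = np.full(self.n, 1e4)
        lb[self.n_load + self.n_a:] = np.log(var_floor)
        ub[self.n_load + self.n_a:] = np.log(1e8)
        return list(zip(lb, ub))

    def labels(self) -> list:
        """(name, from, to) label per free parameter, in vector order."""
        spec = self.spec
        out = []
        for r, l in self.free_loadings:
            out.append(("loading", spec.group_ids[l], spec.region_ids[r]))
        for l in range(spec.m):
            for j in range(spec.p):
                out.append(("snp_weight", spec.snp_ids[j], spec.group_ids[l]))
        for l in range(spec.m):
            out.append(("latent_residual_var", spec.group_ids[l], spec.group_ids[l]))
        for l in range(spec.m):
            out.append(("region_residual_var", spec.group_ids[l], spec.group_ids[l]))
        return out


def _discrepancy_and_grad(v, pmap: _ParamMap, S, cho_S_logdet):
    """F and its gradient w.r.t. the packed vector (log-variance chain rule).

    Uses G = Sigma^-1 (Sigma - S) Sigma^-1, for which dF/dtheta_k equals
    tr(G dSigma/dtheta_k).
    """
    spec = pmap.spec
    p, q, m = spec.p, spec.q, spec.m
    params = pmap.unpack(v, S[:p, :p])
    A, B, T = params.A, params.B, params.sigma_gg
    C = A @ T @ A.T + np.diag(params.psi)
    sigma_xx = B @ C @ B.T + np.diag(params.theta_full(spec))
    sigma_xg = B @ A @ T
    sigma = np.block([[T, sigma_xg.T], [sigma_xg, sigma_xx]])
    try:
        cho = sla.cholesky(sigma, lower=True)
    except sla.LinAlgError:
        return np.inf, np.zeros_like(v)
    logdet = 2.0 * np.sum(np.log(np.diag(cho)))
    sigma_inv = sla.cho_solve((cho, True), np.eye(p + q))
    F = logdet + float(np.sum(sigma_inv * S)) - cho_S_logdet - (p + q)

    G = sigma_inv - sigma_inv @ S @ sigma_inv
    Gxg = G[p:, :p]
    Gxx = G[p:, p:]

    grad = np.empty_like(v)
    grad_B = 2.0 * (Gxg @ T @ A.T + Gxx @ B @ C)
    for k, (r, l) in enumerate(pmap.free_loadings):
        grad[k] = grad_B[r, l]
    grad_A = 2.0 * (B.T @ Gxg @ T + (B.T @ Gxx @ B) @ A @ T)
    grad[pmap.n_load: pmap.n_load + pmap.n_a] = grad_A.ravel()
    bgb = B.T @ Gxx @ B
    grad_psi = np.diag(bgb) * params.psi                       # chain: d/dlog
    gxx_diag = np.diag(Gxx)
    grad_theta = np.array(
        [gxx_diag[spec.group_index == l].sum() for l in range(m)]
    ) * params.theta
    grad[pmap.n_load + pmap.n_a: pmap.n_load + pmap.n_a + m] = grad_psi
    grad[pmap.n_load + pmap.n_a + m:] = grad_theta
    return F, grad


# ---------------------------------------------------------------------------
# Fit result
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Outcome of an ML fit, with per-parameter inference.

    ``robust_se``, ``z_robust`` and ``p_robust`` are filled by
    :func:`neurosem.inference.robust_adjust`; until then they are None.
    """

    spec: SEMSpec
    params: SEMParams
    estimates: np.ndarray            # packed free-parameter estimates
    labels: list                     # (name, from, to) per free parameter
    naive_se: np.ndarray
    discrepancy: float
    loglik: float
    n: int
    converged: bool
    n_free: int
    n_restarts: int = 0
    robust_se: np.ndarray | None = None
    z_robust: np.ndarray | None = None
    p_robust: np.ndarray | None = None
    warnings: list = field(default_factory=list)
    sample_cov: np.ndarray | None = None

    def _slice(self, name: str) -> slice:
        idx = [i for i, lab in enumerate(self.labels) if lab[0] == name]
        return np.array(idx, dtype=int)

    def snp_weight_pvalues(self) -> np.ndarray:
        """Robust p values for the A entries, as an m x p matrix."""
        if self.p_robust is None:
            raise FitError("robust p values not computed; run robust_adjust")
        idx = self._slice("snp_weight")
        return self.p_robust[idx].reshape(self.spec.m, self.spec.p)

    def to_frame(self) -> pd.DataFrame:
        """Parameter table: one row per free parameter."""
        df = pd.DataFrame(self.labels, columns=["parameter", "from", "to"])
        df["estimate"] = self.estimates
        df["se_naive"] = self.naive_se
        df["se_robust"] = self.robust_se if self.robust_se is not None else np.nan
        df["z_robust"] = self.z_robust if self.z_robust is not None else np.nan
        df["p_robust"] = self.p_robust if self.p_robust is not None else np.nan
        return df

    def header(self) -> dict:
        return {
            "n": int(self.n),
            "n_free": int(self.n_free),
            "discrepancy": float(self.discrepancy),
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "n_restarts": int(self.n_restarts),
        }


def sample_covariance(*blocks: np.ndarray) -> np.ndarray:
    """ML sample covariance (divisor n) of horizontally stacked data blocks."""
    X = np.hstack([np.asarray(b, dtype=float) for b in blocks])
    Xc = X - X.mean(axis=0)
    return (Xc.T @ Xc) / X.shape[0]


def param_derivative_matrices(fit_params: SEMParams, spec: SEMSpec) -> np.ndarray:
    """Stack of dSigma/dparam (raw scale) per free parameter, n_free x d x d.

    Order matches the packed vector: free loadings, A entries, psi, theta.
    """
    p, q, m = spec.p, spec.q, spec.m
    d = p + q
    A, B, T = fit_params.A, fit_params.B, fit_params.sigma_gg
    C = A @ T @ A.T + np.diag(fit_params.psi)
    AT = A @ T                                     # m x p
    BAT = B @ AT                                   # q x p
    BC = B @ C                                     # q x m
    pmap = _ParamMap(spec)
    out = np.zeros((pmap.n, d, d))
    k = 0
    for r, l in pmap.free_loadings:
        dS = out[k]
        dS[p + r, :p] = AT[l]                      # d(B A T) row r
        dS[:p, p + r] = AT[l]
        row = BC[:, l].copy()
        dS[p + r, p:] += row
        dS[p:, p + r] += row
        k += 1
    for l in range(m):
        for j in range(p):
            dS = out[k]
            dS[p:, :p] += np.outer(B[:, l], T[j])
            dS[:p, p:] += np.outer(T[j], B[:, l])
            u = BAT[:, j]
            dS[p:, p:] += np.outer(B[:, l], u) + np.outer(u, B[:, l])
            k += 1
    for l in range(m):
        out[k, p:, p:] = np.outer(B[:, l], B[:, l])
        k += 1
    gidx = spec.group_index
    for l in range(m):
        members = np.where(gidx == l)[0] + p
        out[k, members, members] = 1.0
        k += 1
    return out


def _expected_information(sigma_inv: np.ndarray, dsigma: np.ndarray):
    """Normal-theory information I_jk = 0.5 tr(Sigma^-1 dS_j Sigma^-1 dS_k)."""
    M = sigma_inv @ dsigma @ sigma_inv          # batched over parameters
    k, d = dsigma.shape[:2]
    # tr(M_a dS_b) = vec(M_a) . vec(dS_b) since both stacks are symmetric
    info = 0.5 * (M.reshape(k, d * d) @ dsigma.reshape(k, d * d).T)
    return info, M


def _projected_gradient(v, grad, lb, ub, eps=1e-9):
    pg = grad.copy()
    pg[(v <= lb + eps) & (grad > 0)] = 0.0
    pg[(v >= ub - eps) & (grad < 0)] = 0.0
    return pg


def _fisher_scoring_refine(v, pmap, S, logdet_S, gtol=1e-6, ftol=1e-10, maxiter=50):
    """Polish an approximate optimum by damped, box-projected Fisher scoring.

    The expected information in the packed parameterisation (chain rule for
    the log variances) gives near-quadratic convergence where first-order
    quasi-Newton steps crawl, e.g. under a misspecified grouping.
    Levenberg-style damping keeps every step a descent step; steps are
    projected onto the parameter box (variance floor included) and
    convergence is judged on the projected gradient.
    """
    spec = pmap.spec
    d = spec.p + spec.q
    eye = np.eye(d)
    bounds = np.array(pmap.bounds())
    lb, ub = bounds[:, 0], bounds[:, 1]
    v = np.clip(v, lb, ub)
    F, grad = _discrepancy_and_grad(v, pmap, S, logdet_S)
    lam = 1e-8
    converged = False
    for _ in range(maxiter):
        if np.abs(_projected_gradient(v, grad, lb, ub)).max() < gtol:
            converged = True
            break
        params = pmap.unpack(v, S[: spec.p, : spec.p])
        sigma = implied_covariance(params, spec).full
        try:
            sigma_inv = sla.cho_solve((sla.cholesky(sigma, lower=True), True), eye)
        except sla.LinAlgError:
            break
        dsigma = param_derivative_matrices(params, spec)
        info, _ = _expected_information(sigma_inv, dsigma)
        chain = np.ones(pmap.n)
        chain[pmap.n_load + pmap.n_a: pmap.n_load + pmap.n_a + spec.m] = params.psi
        chain[pmap.n_load + pmap.n_a + spec.m:] = params.theta
        info = info * np.outer(chain, chain)
        scale = np.diag(info).copy()
        scale[scale <= 0] = 1.0
        improved = None
        for _ in range(12):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", sla.LinAlgWarning)
                    step = sla.solve(info + lam * np.diag(scale), -grad, assume_a="pos")
            except sla.LinAlgError:
                lam = max(lam * 10, 1e-6)
                continue
            v_new = np.clip(v + step, lb, ub)
            F_new, grad_new = _discrepancy_and_grad(v_new, pmap, S, logdet_S)
            if np.isfinite(F_new) and F_new <= F:
                improved = F - F_new
                v, F, grad = v_new, F_new, grad_new
                lam = max(lam / 10, 1e-10)
                break
            lam = max(lam * 10, 1e-6)
        if improved is None or improved < ftol:
            # the discrepancy can no longer be reduced: the F-change
            # convergence criterion
            converged = improved is not None or (
                np.abs(_projected_gradient(v, grad, lb, ub)).max() < gtol
            )
            break
    else:
        converged = np.abs(_projected_gradient(v, grad, lb, ub)).max() < gtol
    return v, F, grad, converged


def fit_sem(
    g: np.ndarray,
    x: np.ndarray,
    spec: SEMSpec,
    start: SEMParams | None = None,
    max_restarts: int = 5,
    gtol: float = 1e-6,
    ftol: float = 1e-10,
    maxiter: int = 1000,
    seed: int | None = None,
) -> FitResult:
    """Fit the SEM by quasi-Newton minimisation of the ML discrepancy.

    Parameters
    ----------
    g : array (n, p)
        Centred genotype matrix (p may be 0).
    x : array (n, q)
        Centred (and usually scaled) region matrix, rows aligned with ``g``.
    start : SEMParams, optional
        Starting values; defaults to anchors/free loadings 1, A = 0, and
        psi = theta = half the mean observed region variance.
    max_restarts : int
        Jittered restarts attempted when the line search fails to converge.

    Notes
    -----
    The SNP covariance block is fixed at its observed value, so only the
    loadings, SNP weights and residual variances are optimised. Naive
    standard errors come from the inverse expected information at the
    optimum.
    """
    g = np.atleast_2d(np.asarray(g, dtype=float))
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if g.size == 0:
        g = g.reshape(n, spec.p)
    if g.shape != (n, spec.p) or x.shape != (n, spec.q):
        raise FitError("data dimensions do not match the spec")
    for name, arr, ids in (("genotype", g, spec.snp_ids), ("region", x, spec.region_ids)):
        sd = arr.std(axis=0)
        if np.any(sd == 0):
            bad = [ids[i] for i in np.where(sd == 0)[0]]
            raise FitError(f"constant {name} column(s): {bad}")
    warns = []
    if n <= spec.n_free():
        warns.append(
            f"sample size n={n} is not larger than the number of free "
            f"parameters ({spec.n_free()}); estimates may be unstable"
        )
        warnings.warn(warns[-1], stacklevel=2)

    S = sample_covariance(g - g.mean(0), x - x.mean(0))
    p, d = spec.p, spec.p + spec.q
    try:
        cho_S = sla.cholesky(S, lower=True)
    except sla.LinAlgError as e:
        raise FitError("sample covariance is not positive definite") from e
    logdet_S = 2.0 * np.sum(np.log(np.diag(cho_S)))

    pmap = _ParamMap(spec)
    if start is None:
        B0 = np.zeros((spec.q, spec.m))
        B0[spec.loading_pattern()] = 1.0
        v0_var = 0.5 * float(np.mean(np.diag(S)[p:]))
        start = SEMParams(
            A=np.zeros((spec.m, spec.p)),
            B=B0,
            psi=np.full(spec.m, v0_var),
            theta=np.full(spec.m, v0_var),
            sigma_gg=S[:p, :p],
        )
    v0 = pmap.pack(start)

    rng = np.random.default_rng(seed)
    best_v, best_F = None, np.inf
    converged = False
    n_restarts = 0
    for attempt in range(max_restarts + 1):
        v_cur = v0 if attempt == 0 else v0 + rng.normal(scale=0.1, size=v0.shape)
        # Alternate quasi-Newton descent with Fisher-scoring polishing.
        # Convergence: projected gradient below gtol, or the relative
        # reduction of F falling below ftol once the quasi-Newton stage
        # starts from an already-polished point -- the same termination
        # rule lavaan-style fitters apply.
        for cycle in range(3):
            res = minimize(
                _discrepancy_and_grad,
                v_cur,
                args=(pmap, S, logdet_S),
                method="L-BFGS-B",
                jac=True,
                bounds=pmap.bounds(),
                options={"maxiter": maxiter, "gtol": gtol, "ftol": ftol},
            )
            v_ref, F_ref, _, ok = _fisher_scoring_refine(
                res.x, pmap, S, logdet_S, gtol=gtol, ftol=ftol
            )
            if np.isfinite(F_ref) and F_ref < best_F:
                best_v, best_F = v_ref, F_ref
            if np.isfinite(F_ref) and (ok or (cycle > 0 and res.success)):
                converged = True
                break
            v_cur = v_ref
        if converged:
            break
        n_restarts += 1
    if not converged:
        warns.append(f"optimizer did not converge after {n_restarts} restarts")

    params = pmap.unpack(best_v, S[:p, :p])
    F = float(best_F)
    loglik = -0.5 * n * (d * np.log(2 * np.pi) + F + logdet_S + d)

    # naive SEs: inverse expected information on the raw parameter scale
    sigma = implied_covariance(params, spec).full
    sigma_inv = sla.cho_solve((sla.cholesky(sigma, lower=True), True), np.eye(d))
    dsigma = param_derivative_matrices(params, spec)
    info, _ = _expected_information(sigma_inv, dsigma)
    naive_se = np.full(pmap.n, np.nan)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", sla.LinAlgWarning)
            acov = sla.inv(info) / n
        diag = np.diag(acov).copy()
        diag[diag < 0] = np.nan
        naive_se = np.sqrt(diag)
    except sla.LinAlgError:
        warns.append("expected information singular; naive SEs unavailable")

    estimates = np.concatenate(
        [
            best_v[: pmap.n_load],
            best_v[pmap.n_load: pmap.n_load + pmap.n_a],
            params.psi,
            params.theta,
        ]
    )
    return FitResult(
        spec=spec,
        params=params,
        estimates=estimates,
        labels=pmap.labels(),
        naive_se=naive_se,
        discrepancy=F,
        loglik=float(loglik),
        n=n,
        converged=converged,
        n_free=pmap.n,
        n_restarts=n_restarts,
        warnings=warns,
        sample_cov=S,
    )
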