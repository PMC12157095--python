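"""Marginal linear model fitting with structured residual covariance.

The model is ``y_i = X_i beta + eps_i`` with ``eps_i ~ N(0, sigma2 *
D^{1/2} R_i(theta) D^{1/2})``.  ``beta`` and ``sigma2`` are profiled out
analytically; the remaining correlation parameters (and optional
per-occasion variance weights) are maximized by quasi-Newton search in an
unconstrained reparameterization that keeps every iterate inside the valid
parameter region:

* AR(p) coefficients through their partial autocorrelations via tanh
  (stationary for any real input);
* the compound-symmetry correlation through a scaled logistic onto
  ``(-1/(T-1), 1)``;
* the continuous-time AR parameter through a logistic onto (0, 1) and
  range parameters through the log;
* the unstructured correlation through the hyperspherical (angle)
  factorization of its Cholesky factor;
* variance weights through the log (reference occasion fixed at 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize
from scipy.special import expit, logit

from .corrstruct import (
    CorrelationStructure,
    StructureKind,
    TimeDomain,
    ar_to_pacf,
    build_correlation_matrix,
    pacf_to_ar,
)
from .diagnose import design_matrix
from .simulate import LongitudinalDataset

__all__ = [
    "MarginalModelSpec",
    "FitResult",
    "neg_log_likelihood",
    "fit_marginal_model",
    "information_criteria",
    "fit_heteroscedastic_pair",
]

_PENALTY = 1e10
_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class MarginalModelSpec:
    """What to fit: mean structure, correlation structure, options."""

    mean_structure: str
    structure: CorrelationStructure
    heteroscedastic: bool = False
    estimation: str = "REML"  # "ML" or "REML"

    def __post_init__(self):
        est = self.estimation.upper()
        if est not in ("ML", "REML"):
            raise ValueError(f"estimation must be ML or REML, got {self.estimation}")
        object.__setattr__(self, "estimation", est)


@dataclass
class FitResult:
    beta: pd.Series
    std_errors: pd.Series
    sigma2: float
    theta: np.ndarray
    variance_weights: np.ndarray          # length T, delta_1 == 1
    loglik: float
    n_obs: int
    n_params: int
    aic: float
    bic: float
    aicc: float
    converged: bool
    structure: CorrelationStructure
    estimation: str
    mean_structure: str
    n_fixed: int
    heteroscedastic: bool
    occasions: np.ndarray
    optimizer_message: str = ""
    n_evaluations: int = 0
    penalty_hits: int = 0

    @property
    def n_eff(self) -> int:
        """Effective sample size for BIC/AICc: N under ML, N - p under REML."""
        return self.n_obs if self.estimation == "ML" else self.n_obs - self.n_fixed

    def label(self) -> str:
        lab = self.structure.label()
        if self.heteroscedastic:
            lab += "+hetero"
        return lab

    def fitted_correlation(self) -> np.ndarray:
        struct = CorrelationStructure(self.structure.kind, tuple(self.theta),
                                      self.structure.time_domain)
        return build_correlation_matrix(struct, self.occasions).values

    def summary(self) -> str:
        lines = [
            f"Marginal linear model ({self.estimation})",
            f"  mean structure : {self.mean_structure}",
            f"  correlation    : {self.label()}  theta={np.round(self.theta, 4).tolist()}",
            f"  sigma2         : {self.sigma2:.6g}",
            f"  logLik         : {self.loglik:.4f}   AIC {self.aic:.2f}  "
            f"BIC {self.bic:.2f}  AICc {self.aicc:.2f}",
            f"  converged      : {self.converged}",
            "",
            "  Fixed effects:",
        ]
        for name in self.beta.index:
            b, s = self.beta[name], self.std_errors[name]
            lines.append(f"    {name:<24s} {b:>12.5g}  (se {s:.4g})")
        if self.heteroscedastic:
            lines.append(f"  variance weights: {np.round(self.variance_weights, 4).tolist()}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "structure": self.structure.to_dict(),
            "label": self.label(),
            "estimation": self.estimation,
            "mean_structure": self.mean_structure,
            "beta": {k: float(v) for k, v in self.beta.items()},
            "std_errors": {k: float(v) for k, v in self.std_errors.items()},
            "sigma2": float(self.sigma2),
            "theta": [float(x) for x in self.theta],
            "variance_weights": [float(x) for x in self.variance_weights],
            "loglik": float(self.loglik),
            "n_obs": int(self.n_obs),
            "n_params": int(self.n_params),
            "aic": float(self.aic),
            "bic": float(self.bic),
            "aicc": float(self.aicc) if np.isfinite(self.aicc) else None,
            "converged": bool(self.converged),
            "heteroscedastic": bool(self.heteroscedastic),
        }


# ---------------------------------------------------------------------------
# unconstrained reparameterizations
# ---------------------------------------------------------------------------

def _angles_to_chol(theta: np.ndarray, T: int) -> np.ndarray:
    """Hyperspherical angles (each in (0, pi)) to the Cholesky factor of a
    unit-diagonal correlation matrix."""
    L = np.zeros((T, T))
    L[0, 0] = 1.0
    idx = 0
    for i in range(1, T):
        prod = 1.0
        for j in range(i):
            a = theta[idx]
            idx += 1
            L[i, j] = math.cos(a) * prod
            prod *= math.sin(a)
        L[i, i] = prod
    return L


def _corr_to_angles(R: np.ndarray) -> np.ndarray:
    T = R.shape[0]
    L = np.linalg.cholesky(R)
    angles = []
    for i in range(1, T):
        prod = 1.0
        for j in range(i):
            c = L[i, j] / prod if prod > 1e-12 else 0.0
            c = min(1.0 - 1e-10, max(-1.0 + 1e-10, c))
            a = math.acos(c)
            angles.append(a)
            prod *= math.sin(a)
    return np.asarray(angles)


class _Reparam:
    """Bijection between the natural parameters of one structure (plus
    optional variance weights) and an unconstrained real vector."""

    def __init__(self, structure: CorrelationStructure, T: int, hetero: bool):
        self.kind = structure.kind
        self.T = T
        self.hetero = hetero
        k = structure.kind
        if k is StructureKind.INDEPENDENT:
            self.n_corr = 0
        elif k is StructureKind.UNSTRUCTURED:
            self.n_corr = T * (T - 1) // 2
        elif k is StructureKind.AR:
            self.n_corr = len(structure.params)
        else:
            self.n_corr = 1
        self.cs_lo = -1.0 / (T - 1) if T > 1 else -0.99
        self.n_weights = (T - 1) if hetero else 0
        self.size = self.n_corr + self.n_weights

    # natural -> unconstrained
    def encode(self, params: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
        k = self.kind
        params = np.atleast_1d(np.asarray(params, dtype=float)) if self.n_corr else np.empty(0)
        if k is StructureKind.CS:
            u = (params[0] - self.cs_lo) / (1.0 - self.cs_lo)
            z = np.array([logit(np.clip(u, 1e-12, 1 - 1e-12))])
        elif k is StructureKind.AR:
            pac = np.clip(ar_to_pacf(params), -1 + 1e-10, 1 - 1e-10)
            z = np.arctanh(pac)
        elif k is StructureKind.CAR1:
            z = np.array([logit(np.clip(params[0], 1e-12, 1 - 1e-12))])
        elif k is StructureKind.UNSTRUCTURED:
            # params are lower-triangle correlations; rebuild matrix -> angles
            R = np.eye(self.T)
            idx = 0
            for i in range(1, self.T):
                for j in range(i):
                    R[i, j] = R[j, i] = params[idx]
                    idx += 1
            ang = _corr_to_angles(R)
            z = logit(np.clip(ang / math.pi, 1e-12, 1 - 1e-12))
        elif k is StructureKind.INDEPENDENT:
            z = np.empty(0)
        else:  # range kinds
            z = np.array([math.log(params[0])])
        if self.hetero:
            w = np.ones(self.T) if weights is None else np.asarray(weights, dtype=float)
            z = np.concatenate([z, np.log(w[1:])])
        return z

    # unconstrained -> natural
    def decode(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        z = np.asarray(z, dtype=float)
        zc, zw = z[: self.n_corr], z[self.n_corr :]
        k = self.kind
        if k is StructureKind.CS:
            params = np.array([self.cs_lo + (1.0 - self.cs_lo) * expit(zc[0])])
        elif k is StructureKind.AR:
            params = pacf_to_ar(np.tanh(zc))
        elif k is StructureKind.CAR1:
            params = np.array([expit(zc[0])])
        elif k is StructureKind.UNSTRUCTURED:
            ang = math.pi * expit(zc)
            L = _angles_to_chol(ang, self.T)
            R = L @ L.T
            params = R[np.tril_indices(self.T, k=-1)]
        elif k is StructureKind.INDEPENDENT:
            params = np.empty(0)
        else:
            params = np.array([math.exp(np.clip(zc[0], -30, 30))])
        weights = np.concatenate([[1.0], np.exp(np.clip(zw, -15, 15))]) \
            if self.hetero else np.ones(self.T)
        return params, weights


# ---------------------------------------------------------------------------
# model data & profiled objective
# ---------------------------------------------------------------------------

class _ModelData:
    """Design/outcome arrays grouped by shared within-subject time grid."""

    def __init__(self, spec: MarginalModelSpec, dataset: LongitudinalDataset):
        struct = spec.structure
        discrete = struct.time_domain is TimeDomain.DISCRETE
        if discrete and struct.kind is not StructureKind.INDEPENDENT:
            dataset.require_balanced()
        X, names = design_matrix(dataset, spec.mean_structure)
        y = dataset.data[dataset.outcome].to_numpy(dtype=float)
        # optimize on a standardized outcome so the search path (and hence
        # theta-hat) is exactly invariant to rescaling y; results are mapped
        # back to the original scale afterwards
        self.y_scale = float(np.std(y)) or 1.0
        y = y / self.y_scale
        subj = dataset.data[dataset.subject].to_numpy()
        times = dataset.data[dataset.time].to_numpy(dtype=float)
        self.names = names
        self.q = X.shape[1]
        self.N = len(y)
        self.occasions = dataset.occasions.astype(float)
        self.T = len(self.occasions)
        occ_index = np.searchsorted(self.occasions, times)
        if spec.heteroscedastic and not np.allclose(self.occasions[occ_index], times):
            raise ValueError("heteroscedastic weights require discrete occasions")

        # group subjects by their time-grid signature
        groups: dict[tuple, list[int]] = {}
        order = []
        starts = np.flatnonzero(np.r_[True, subj[1:] != subj[:-1]])
        stops = np.r_[starts[1:], len(subj)]
        self.blocks = []
        for a, b in zip(starts, stops):
            key = tuple(times[a:b])
            groups.setdefault(key, []).append(len(self.blocks))
            self.blocks.append((a, b))
        self.groups = []
        for key, blk_ids in groups.items():
            t = np.asarray(key)
            idx = np.concatenate([np.arange(*self.blocks[i]) for i in blk_ids])
            n_g = len(blk_ids)
            T_g = len(t)
            Xg = X[idx].reshape(n_g, T_g, self.q)
            yg = y[idx].reshape(n_g, T_g)
            occ_g = occ_index[idx][:T_g]
            self.groups.append((t, occ_g, Xg, yg))
        self.n_subjects = len(self.blocks)


def _profiled(spec: MarginalModelSpec, md: _ModelData, params, weights):
    """Profiled -2*(restricted) log-likelihood pieces at given correlation
    parameters and variance weights.  Returns (neg2ll, beta, cov_chol, sigma2)
    or a penalty if any per-subject covariance fails to factor."""
    struct = CorrelationStructure(spec.structure.kind, tuple(params),
                                  spec.structure.time_domain)
    q, N = md.q, md.N
    A = np.zeros((q, q))
    b = np.zeros(q)
    yy = 0.0
    logdet_C = 0.0
    for t, occ_g, Xg, yg in md.groups:
        R = build_correlation_matrix(struct, t).values
        d = weights[occ_g]
        C = d[:, None] * R * d[None, :]
        L = cholesky(C, lower=True)  # raises LinAlgError when not PD
        n_g, T_g = yg.shape
        logdet_C += 2.0 * n_g * float(np.sum(np.log(np.diag(L))))
        # whiten: solve L Z = M for each subject; stack subjects columnwise
        Xflat = np.moveaxis(Xg, 1, 0).reshape(T_g, n_g * q)
        Xw = solve_triangular(L, Xflat, lower=True).reshape(T_g, n_g, q)
        yw = solve_triangular(L, yg.T, lower=True)  # T_g x n_g
        A += np.einsum("tnq,tnr->qr", Xw, Xw)
        b += np.einsum("tnq,tn->q", Xw, yw)
        yy += float(np.sum(yw * yw))
    La = cholesky(A, lower=True)
    beta = cho_solve((La, True), b)
    rss = max(yy - float(b @ beta), 1e-300)
    if spec.estimation == "ML":
        sigma2 = rss / N
        neg2ll = N * (_LOG2PI + math.log(sigma2)) + logdet_C + N
    else:
        dof = N - q
        sigma2 = rss / dof
        logdet_A = 2.0 * float(np.sum(np.log(np.diag(La))))
        neg2ll = dof * (_LOG2PI + math.log(sigma2)) + logdet_C + logdet_A + dof
    return neg2ll, beta, (La, sigma2, A), sigma2


def neg_log_likelihood(spec: MarginalModelSpec, dataset: LongitudinalDataset,
                       theta_full) -> float:
    """Profiled negative log-likelihood at explicit natural parameters.

    ``theta_full`` concatenates the correlation parameters with the T - 1
    free variance weights (delta_2..delta_T) when the spec is
    heteroscedastic.  A covariance that fails to factor returns a large
    penalty value rather than NaN.
    """
    md = _ModelData(spec, dataset)
    theta_full = np.atleast_1d(np.asarray(theta_full, dtype=float))
    rep = _Reparam(spec.structure, md.T, spec.heteroscedastic)
    params = theta_full[: rep.n_corr]
    weights = (np.concatenate([[1.0], theta_full[rep.n_corr :]])
               if spec.heteroscedastic else np.ones(md.T))
    try:
        neg2ll, *_ = _profiled(spec, md, params, weights)
    except (np.linalg.LinAlgError, ValueError):
        return _PENALTY
    dof = md.N if spec.estimation == "ML" else md.N - md.q
    return 0.5 * (neg2ll + dof * math.log(md.y_scale**2))


def _starting_points(spec: MarginalModelSpec, md: _ModelData,
                     rep: _Reparam) -> list[np.ndarray]:
    """Fixed deterministic multi-start set: null correlation, moderate
    positive, and a profile-informed point from the naive residuals."""
    k = spec.structure.kind
    T = md.T
    starts_nat: list[np.ndarray] = []
    if k is StructureKind.CS:
        starts_nat = [np.array([0.0]), np.array([0.3])]
    elif k is StructureKind.AR:
        p = rep.n_corr
        starts_nat = [np.zeros(p), pacf_to_ar(np.full(p, 0.2))]
    elif k is StructureKind.CAR1:
        starts_nat = [np.array([0.1]), np.array([0.5])]
    elif k in (StructureKind.EXPONENTIAL, StructureKind.GAUSSIAN,
               StructureKind.LINEAR, StructureKind.SPHERICAL,
               StructureKind.RATIONAL_QUADRATIC):
        span = float(md.occasions[-1] - md.occasions[0]) or 1.0
        starts_nat = [np.array([span / 2.0]), np.array([2.0 * span])]
    elif k is StructureKind.UNSTRUCTURED:
        # identity start only: the informed start (sample residual
        # correlation) does the real work and extra cold starts are costly
        # in this many-parameter family
        starts_nat = [np.zeros(T * (T - 1) // 2)]
    elif k is StructureKind.INDEPENDENT:
        starts_nat = [np.empty(0)]

    # profile-informed start from pooled naive residual autocorrelations
    informed = _informed_start(spec, md, rep)
    if informed is not None:
        starts_nat.append(informed)

    out = []
    for nat in starts_nat:
        try:
            z = rep.encode(nat)
            if rep.hetero:
                pass  # encode appended log(1) = 0 weight entries
            out.append(z)
        except (ValueError, np.linalg.LinAlgError):
            continue
    return out


def _informed_start(spec: MarginalModelSpec, md: _ModelData,
                    rep: _Reparam) -> np.ndarray | None:
    """Correlation start estimated from identity-weights (OLS) residuals."""
    k = spec.structure.kind
    try:
        _, beta, _, _ = _profiled(
            MarginalModelSpec(spec.mean_structure,
                              CorrelationStructure(StructureKind.INDEPENDENT),
                              estimation=spec.estimation),
            md, np.empty(0), np.ones(md.T))
    except np.linalg.LinAlgError:
        return None
    # residual matrix only well-defined for the single-group balanced case
    if len(md.groups) != 1:
        return None
    t, occ_g, Xg, yg = md.groups[0]
    E = yg - np.einsum("ntq,q->nt", Xg, beta)
    n, T = E.shape
    if n < 3:
        return None
    Ec = E - E.mean()
    gamma0 = float(np.mean(Ec * Ec))
    if gamma0 <= 0:
        return None
    if k is StructureKind.CS:
        corr = np.corrcoef(E, rowvar=False)
        rho = float(np.mean(corr[np.triu_indices(T, 1)]))
        lo = rep.cs_lo
        rho = min(0.99, max(lo + 0.01 * (1 - lo), rho))
        return np.array([rho])
    if k in (StructureKind.AR, StructureKind.CAR1):
        p = rep.n_corr if k is StructureKind.AR else 1
        p = min(p, T - 1)
        gam = [float(np.sum(Ec[:, : T - j] * Ec[:, j:])) / (n * T)
               for j in range(1, p + 1)]
        rho = np.clip(np.asarray(gam) / gamma0, -0.95, 0.95)
        try:
            from .corrstruct import pacf_from_autocorr
            pac = np.clip(pacf_from_autocorr(rho), -0.95, 0.95)
        except ValueError:
            return None
        if k is StructureKind.CAR1:
            val = pac[0]
            return np.array([min(0.99, max(0.01, val))]) if val > 0 else None
        full_pac = np.zeros(rep.n_corr)
        full_pac[: len(pac)] = pac
        return pacf_to_ar(full_pac)
    if k is StructureKind.UNSTRUCTURED:
        corr = np.corrcoef(E, rowvar=False)
        # shrink slightly toward identity to guarantee positive definiteness
        corr = 0.95 * corr + 0.05 * np.eye(T)
        return corr[np.tril_indices(T, k=-1)]
    if k is StructureKind.EXPONENTIAL:
        g1 = float(np.sum(Ec[:, :-1] * Ec[:, 1:])) / (n * T)
        rho1 = g1 / gamma0
        if rho1 <= 0.01:
            return None
        dt = float(np.mean(np.diff(t)))
        return np.array([max(1e-3, -dt / math.log(rho1))])
    return None


def _count_params(n_fixed: int, rep: _Reparam) -> int:
    # fixed effects + correlation params + free weights + the scale sigma2
    return n_fixed + rep.size + 1


def _ic(loglik: float, k: int, n_eff: int) -> tuple[float, float, float]:
    aic = -2.0 * loglik + 2.0 * k
    bic = -2.0 * loglik + k * math.log(n_eff)
    denom = n_eff - k - 1
    aicc = aic + 2.0 * k * (k + 1) / denom if denom > 0 else float("nan")
    return aic, bic, aicc


def information_criteria(fit: FitResult) -> tuple[float, float, float]:
    """(AIC, BIC, AICc) recomputed from the fit's log-likelihood.

    ``n_eff`` is N under ML and N - p under REML; ``k`` counts every
    estimated parameter (fixed effects, correlation parameters, variance
    weights and the scale).  AICc is NaN when ``n_eff - k - 1 <= 0``.
    """
    return _ic(fit.loglik, fit.n_params, fit.n_eff)


def fit_marginal_model(spec: MarginalModelSpec,
                       dataset: LongitudinalDataset) -> FitResult:
    """Maximize the profiled (RE)ML likelihood over the correlation
    parameters (and variance weights) of the requested structure.

    Deterministic: a fixed multi-start set is polished by L-BFGS-B in the
    unconstrained parameterization; the best objective wins, ties broken by
    smaller parameter norm.  Non-convergence is reported through the
    ``converged`` flag on the best iterate found, never raised.
    """
    md = _ModelData(spec, dataset)
    struct = spec.structure
    if struct.kind is StructureKind.AR:
        p = len(struct.params)
        if p > max(1, md.T - 2):
            raise ValueError(
                f"AR({p}) is not identifiable with T={md.T} occasions "
                f"(max supported order {max(1, md.T - 2)})")
    rep = _Reparam(struct, md.T, spec.heteroscedastic)
    penalty_hits = 0
    n_eval = 0

    def objective(z):
        nonlocal penalty_hits, n_eval
        n_eval += 1
        params, weights = rep.decode(z)
        try:
            neg2ll, *_ = _profiled(spec, md, params, weights)
        except (np.linalg.LinAlgError, ValueError):
            penalty_hits += 1
            return _PENALTY + float(np.sum(z * z))
        if not np.isfinite(neg2ll):
            penalty_hits += 1
            return _PENALTY + float(np.sum(z * z))
        return 0.5 * neg2ll

    if rep.size == 0:
        z_best = np.empty(0)
        converged = True
        message = "closed form (no covariance parameters)"
    else:
        best = None
        converged = False
        message = ""
        # central-difference gradients and tight tolerances for
        # low-dimensional structures (cheap, and makes theta-hat reproducible
        # to ~1e-9); cheaper forward differences for the many-parameter
        # unstructured family where each gradient costs dim+1 evaluations
        if rep.size > 10:
            jac, opts = "2-point", {"maxiter": 500, "ftol": 1e-10, "gtol": 1e-6}
        else:
            jac, opts = "3-point", {"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7}
        for z0 in _starting_points(spec, md, rep):
            res = minimize(objective, z0, method="L-BFGS-B", jac=jac,
                           options=opts)
            key = (round(res.fun, 8), float(np.linalg.norm(res.x)))
            if best is None or key < best[0]:
                best = (key, res)
        res = best[1]
        z_best = res.x
        grad_ok = (res.jac is not None
                   and float(np.max(np.abs(res.jac))) < 1e-3)
        converged = (bool(res.success) or grad_ok) and res.fun < _PENALTY / 2
        message = str(res.message)

    params, weights = rep.decode(z_best)
    neg2ll, beta, (La, sigma2, A), _ = _profiled(spec, md, params, weights)
    # map back from the standardized-outcome scale
    s = md.y_scale
    dof = md.N if spec.estimation == "ML" else md.N - md.q
    loglik = -0.5 * (neg2ll + dof * math.log(s**2))
    beta = s * beta
    sigma2 = s**2 * sigma2
    # GLS covariance of beta at theta-hat
    cov_beta = sigma2 * cho_solve((La, True), np.eye(md.q))
    se = np.sqrt(np.diag(cov_beta))
    k = _count_params(md.q, rep)
    n_eff = md.N if spec.estimation == "ML" else md.N - md.q
    aic, bic, aicc = _ic(loglik, k, n_eff)
    return FitResult(
        beta=pd.Series(beta, index=md.names),
        std_errors=pd.Series(se, index=md.names),
        sigma2=float(sigma2),
        theta=np.asarray(params, dtype=float),
        variance_weights=weights,
        loglik=float(loglik),
        n_obs=md.N,
        n_params=k,
        aic=aic, bic=bic, aicc=aicc,
        converged=converged,
        structure=struct,
        estimation=spec.estimation,
        mean_structure=spec.mean_structure,
        n_fixed=md.q,
        heteroscedastic=spec.heteroscedastic,
        occasions=md.occasions,
        optimizer_message=message,
        n_evaluations=n_eval,
        penalty_hits=penalty_hits,
    )


def fit_heteroscedastic_pair(spec: MarginalModelSpec,
                             dataset: LongitudinalDataset) -> tuple[FitResult, FitResult]:
    """Fit the same correlation structure with and without per-occasion
    variance weights and return (homoscedastic, heteroscedastic)."""
    homo_spec = MarginalModelSpec(spec.mean_structure, spec.structure,
                                  heteroscedastic=False, estimation=spec.estimation)
    het_spec = MarginalModelSpec(spec.mean_structure, spec.structure,
                                 heteroscedastic=True, estimation=spec.estimation)
    return fit_marginal_model(homo_spec, dataset), fit_marginal_model(het_spec, dataset)
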