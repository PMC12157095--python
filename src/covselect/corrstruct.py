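"""Autoregressive process algebra and within-subject correlation matrices.

The residual correlation of a longitudinal outcome is modelled through a
small menu of structures: a single exchangeable correlation (compound
symmetry), autoregressive processes of arbitrary order whose autocorrelation
function is obtained from the Yule-Walker equations, several continuous-time
kinds parameterized by a range, and a fully unstructured correlation.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_toeplitz, toeplitz

__all__ = [
    "ARProcess",
    "StructureKind",
    "TimeDomain",
    "CorrelationStructure",
    "CorrelationMatrix",
    "NonStationaryError",
    "is_stationary",
    "yw_autocorrelations",
    "yw_coefficients",
    "theoretical_pacf",
    "pacf_to_ar",
    "ar_to_pacf",
    "build_correlation_matrix",
]

#: Roots of the AR characteristic polynomial must exceed 1 by this margin.
STATIONARITY_MARGIN = 1e-8


class NonStationaryError(ValueError):
    """Raised when AR coefficients define a non-stationary process."""

    def __init__(self, phi, roots):
        self.phi = np.asarray(phi, dtype=float)
        self.roots = np.asarray(roots)
        bad = self.roots[np.abs(self.roots) <= 1.0 + STATIONARITY_MARGIN]
        super().__init__(
            f"AR coefficients {self.phi.tolist()} are non-stationary: "
            f"characteristic roots {np.round(bad, 6).tolist()} do not lie "
            f"strictly outside the unit circle"
        )


def characteristic_roots(phi) -> np.ndarray:
    """Roots of 1 - phi_1 z - ... - phi_p z^p.

    Trailing zero coefficients are dropped first so that e.g. ``[0.6, 0.0]``
    has the same (single) root as ``[0.6]``.
    """
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    if phi.size == 0:
        return np.empty(0, dtype=complex)
    # strip numerically negligible trailing coefficients: they contribute
    # only enormous extra roots but destroy the conditioning of np.roots
    tol = 1e-12 * max(1.0, float(np.abs(phi).max()))
    nz = np.nonzero(np.abs(phi) > tol)[0]
    if nz.size == 0:
        return np.empty(0, dtype=complex)
    phi = phi[: nz[-1] + 1]
    # numpy expects highest-degree coefficient first
    coeffs = np.concatenate([-phi[::-1], [1.0]])
    return np.roots(coeffs)


def is_stationary(phi) -> tuple[bool, np.ndarray]:
    """Check stationarity (causality) of an AR coefficient vector.

    Returns ``(flag, roots)`` where *flag* is True iff every root of the
    characteristic polynomial has modulus > 1 + margin.  An empty ``phi``
    (white noise) is trivially stationary.
    """
    roots = characteristic_roots(phi)
    if roots.size == 0:
        return True, roots
    flag = bool(np.all(np.abs(roots) > 1.0 + STATIONARITY_MARGIN))
    return flag, roots


@dataclass(frozen=True)
class ARProcess:
    """A stationary AR(p) process: X_t = sum_i phi_i X_{t-i} + eps_t."""

    phi: tuple[float, ...]
    sigma2: float = 1.0

    def __post_init__(self):
        phi = tuple(float(x) for x in self.phi)
        object.__setattr__(self, "phi", phi)
        if self.sigma2 <= 0:
            raise ValueError(f"innovation variance must be > 0, got {self.sigma2}")
        flag, roots = is_stationary(phi)
        if not flag:
            raise NonStationaryError(phi, roots)

    @property
    def order(self) -> int:
        return len(self.phi)


def yw_autocorrelations(process, max_lag: int) -> np.ndarray:
    """Autocorrelations rho_1..rho_max_lag of a stationary AR process.

    For lags k <= p the Yule-Walker relations form a p x p linear system in
    (rho_1, ..., rho_p) which is solved exactly; larger lags are extended by
    the recursion rho_k = sum_i phi_i rho_{k-i}.
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    phi = np.asarray(process.phi if isinstance(process, ARProcess) else process,
                     dtype=float)
    flag, roots = is_stationary(phi)
    if not flag:
        raise NonStationaryError(phi, roots)
    p = len(phi)
    if p == 0:
        return np.zeros(max_lag)
    # A @ rho = b where row k (1-based) encodes rho_k - sum_i phi_i rho_{|k-i|}
    # = phi_k (the rho_0 = 1 terms moved to the right-hand side).
    A = np.eye(p)
    b = phi.copy()
    for k in range(1, p + 1):
        for i in range(1, p + 1):
            lag = abs(k - i)
            if lag > 0:
                A[k - 1, lag - 1] -= phi[i - 1]
    rho_p = np.linalg.solve(A, b)
    rho = np.empty(max_lag)
    m = min(p, max_lag)
    rho[:m] = rho_p[:m]
    rho_full = np.concatenate([[1.0], rho_p])
    for k in range(p + 1, max_lag + 1):
        val = float(sum(phi[i] * rho_full[k - 1 - i] for i in range(p)))
        rho_full = np.append(rho_full, val)
        rho[k - 1] = val
    if np.any(np.abs(rho) >= 1.0):
        raise ValueError(f"invalid autocorrelations {rho} for phi={phi.tolist()}")
    return rho


def yw_coefficients(rho) -> np.ndarray:
    """Solve the Yule-Walker matrix system R phi = gamma for the coefficients.

    ``rho`` holds rho_1..rho_p; the Toeplitz matrix R is built from
    rho_0..rho_{p-1} with rho_0 = 1 and must be positive definite.
    """
    rho = np.atleast_1d(np.asarray(rho, dtype=float))
    p = len(rho)
    if p == 0:
        return np.empty(0)
    col = np.concatenate([[1.0], rho[: p - 1]])
    R = toeplitz(col)
    eigmin = float(np.linalg.eigvalsh(R).min())
    if eigmin <= 1e-12:
        raise ValueError(
            f"autocorrelation matrix not positive definite "
            f"(min eigenvalue {eigmin:.3e}); autocorrelations inconsistent"
        )
    return solve_toeplitz((col, col), rho)


def theoretical_pacf(process, max_lag: int) -> np.ndarray:
    """Partial autocorrelations alpha_1..alpha_max_lag by Durbin-Levinson.

    For an AR(p) process the PACF cuts off: alpha_k = 0 for k > p.
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    phi = np.asarray(process.phi if isinstance(process, ARProcess) else process,
                     dtype=float)
    if len(phi) == 0:
        return np.zeros(max_lag)
    rho = yw_autocorrelations(phi, max_lag)
    return pacf_from_autocorr(rho)


def pacf_from_autocorr(rho) -> np.ndarray:
    """Durbin-Levinson: map autocorrelations rho_1..rho_m to PACF values."""
    rho = np.asarray(rho, dtype=float)
    m = len(rho)
    pacf = np.empty(m)
    phi_prev = np.empty(0)
    for k in range(1, m + 1):
        if k == 1:
            a = rho[0]
        else:
            num = rho[k - 1] - float(phi_prev @ rho[k - 2 :: -1][: k - 1])
            den = 1.0 - float(phi_prev @ rho[: k - 1])
            if den <= 0:
                raise ValueError("autocorrelation sequence is not positive definite")
            a = num / den
        pacf[k - 1] = a
        if k < m:
            phi_new = np.empty(k)
            phi_new[:-1] = phi_prev - a * phi_prev[::-1]
            phi_new[-1] = a
            phi_prev = phi_new
    return pacf


def ar_to_pacf(phi) -> np.ndarray:
    """Map AR coefficients to their partial autocorrelations (inverse of
    :func:`pacf_to_ar`); the process must be stationary."""
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    p = len(phi)
    if p == 0:
        return np.empty(0)
    return theoretical_pacf(phi, p)


def pacf_to_ar(pacf) -> np.ndarray:
    """Levinson step-up: partial autocorrelations (each in (-1,1)) to AR
    coefficients.  Any such vector yields a stationary process, which makes
    this the natural unconstrained-optimization parameterization."""
    pacf = np.atleast_1d(np.asarray(pacf, dtype=float))
    if np.any(np.abs(pacf) >= 1.0):
        raise ValueError("partial autocorrelations must lie in (-1, 1)")
    phi = np.empty(0)
    for a in pacf:
        phi_new = np.empty(len(phi) + 1)
        phi_new[:-1] = phi - a * phi[::-1]
        phi_new[-1] = a
        phi = phi_new
    return phi


class StructureKind(str, enum.Enum):
    CS = "cs"
    AR = "ar"
    CAR1 = "car1"
    EXPONENTIAL = "exponential"
    GAUSSIAN = "gaussian"
    LINEAR = "linear"
    SPHERICAL = "spherical"
    RATIONAL_QUADRATIC = "rational_quadratic"
    UNSTRUCTURED = "unstructured"
    INDEPENDENT = "independent"


class TimeDomain(str, enum.Enum):
    DISCRETE = "discrete_equispaced"
    CONTINUOUS = "continuous"


_CONTINUOUS_KINDS = frozenset({
    StructureKind.CAR1,
    StructureKind.EXPONENTIAL,
    StructureKind.GAUSSIAN,
    StructureKind.LINEAR,
    StructureKind.SPHERICAL,
    StructureKind.RATIONAL_QUADRATIC,
})

_RANGE_KINDS = frozenset({
    StructureKind.EXPONENTIAL,
    StructureKind.GAUSSIAN,
    StructureKind.LINEAR,
    StructureKind.SPHERICAL,
    StructureKind.RATIONAL_QUADRATIC,
})

_DEFAULT_DOMAIN = {
    StructureKind.CS: TimeDomain.DISCRETE,
    StructureKind.AR: TimeDomain.DISCRETE,
    StructureKind.UNSTRUCTURED: TimeDomain.DISCRETE,
    StructureKind.INDEPENDENT: TimeDomain.DISCRETE,
}


@dataclass(frozen=True)
class CorrelationStructure:
    """Tagged correlation-structure family with its parameter vector.

    Parameter meaning by kind: ``cs`` -> (rho,); ``ar`` -> phi_1..phi_p;
    ``car1`` -> (phi,) with phi in (0,1); range kinds -> (r,) with r > 0;
    ``unstructured`` -> the T(T-1)/2 correlations in row-major lower-triangle
    order; ``independent`` -> empty.
    """

    kind: StructureKind
    params: tuple[float, ...] = ()
    time_domain: TimeDomain | None = None

    def __post_init__(self):
        kind = StructureKind(self.kind)
        object.__setattr__(self, "kind", kind)
        object.__setattr__(self, "params", tuple(float(x) for x in self.params))
        domain = self.time_domain
        if domain is None:
            domain = (TimeDomain.CONTINUOUS if kind in _CONTINUOUS_KINDS
                      else _DEFAULT_DOMAIN[kind])
        domain = TimeDomain(domain)
        if kind in _CONTINUOUS_KINDS and domain is not TimeDomain.CONTINUOUS:
            raise ValueError(f"{kind.value} requires continuous time_domain")
        if kind in (StructureKind.AR,) and domain is not TimeDomain.DISCRETE:
            raise ValueError(f"{kind.value} requires discrete equispaced time")
        object.__setattr__(self, "time_domain", domain)
        self._validate_params()

    def _validate_params(self):
        k, p = self.kind, self.params
        if k is StructureKind.INDEPENDENT:
            if p:
                raise ValueError("independent structure takes no parameters")
        elif k is StructureKind.CS:
            if len(p) != 1:
                raise ValueError("cs takes a single correlation parameter")
            if not -1.0 < p[0] < 1.0:
                raise ValueError(f"cs correlation must be in (-1, 1), got {p[0]}")
        elif k is StructureKind.AR:
            flag, roots = is_stationary(p)
            if not flag:
                raise NonStationaryError(p, roots)
        elif k is StructureKind.CAR1:
            if len(p) != 1 or not 0.0 < p[0] < 1.0:
                raise ValueError(f"car1 parameter must be in (0, 1), got {p}")
        elif k in _RANGE_KINDS:
            if len(p) != 1 or p[0] <= 0:
                raise ValueError(f"{k.value} range must be > 0, got {p}")
        # unstructured validity is dimension-dependent; checked at build time

    @property
    def order(self) -> int:
        """AR order (0 for non-AR kinds)."""
        return len(self.params) if self.kind is StructureKind.AR else 0

    @property
    def n_params(self) -> int:
        return len(self.params)

    def label(self) -> str:
        if self.kind is StructureKind.AR:
            return f"AR({len(self.params)})"
        return {
            StructureKind.CS: "CS",
            StructureKind.CAR1: "ContinuousAR1",
            StructureKind.EXPONENTIAL: "Exponential",
            StructureKind.GAUSSIAN: "Gaussian",
            StructureKind.LINEAR: "Linear",
            StructureKind.SPHERICAL: "Spherical",
            StructureKind.RATIONAL_QUADRATIC: "RationalQuadratic",
            StructureKind.UNSTRUCTURED: "Unstructured",
            StructureKind.INDEPENDENT: "Independent",
        }[self.kind]

    # -- plain-text config round trip -------------------------------------
    def to_dict(self) -> dict:
        return {
            "kind": self.kind.value,
            "params": list(self.params),
            "time_domain": self.time_domain.value,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CorrelationStructure":
        return cls(
            kind=StructureKind(d["kind"]),
            params=tuple(d.get("params", ())),
            time_domain=TimeDomain(d["time_domain"]) if "time_domain" in d else None,
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "CorrelationStructure":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class CorrelationMatrix:
    """A validated T x T correlation matrix tied to its occasion coordinates."""

    values: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        V = np.asarray(self.values, dtype=float)
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "values", V)
        object.__setattr__(self, "times", t)
        if V.ndim != 2 or V.shape[0] != V.shape[1] or V.shape[0] != len(t):
            raise ValueError("values must be square and match times")
        if not np.allclose(V, V.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(V), 1.0, atol=1e-12):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(np.abs(V) > 1.0 + 1e-12):
            raise ValueError("correlation entries must lie in [-1, 1]")
        eigmin = float(np.linalg.eigvalsh(V).min())
        if eigmin <= 0:
            raise ValueError(
                f"correlation matrix not positive definite "
                f"(min eigenvalue {eigmin:.3e})"
            )

    @property
    def dim(self) -> int:
        return self.values.shape[0]


def _unstructured_from_params(params, T: int) -> np.ndarray:
    expected = T * (T - 1) // 2
    if len(params) != expected:
        raise ValueError(
            f"unstructured needs {expected} parameters for T={T}, got {len(params)}"
        )
    R = np.eye(T)
    idx = 0
    for i in range(1, T):
        for j in range(i):
            R[i, j] = R[j, i] = params[idx]
            idx += 1
    return R


def build_correlation_matrix(structure: CorrelationStructure, times) -> CorrelationMatrix:
    """Construct the correlation matrix of a structure on given occasions.

    Discrete kinds require equispaced occasions; continuous kinds accept any
    strictly increasing time grid (entries depend on pairwise distances).
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    T = len(times)
    if T < 1:
        raise ValueError("times must be non-empty")
    if T == 1:
        return CorrelationMatrix(np.ones((1, 1)), times)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    kind, params = structure.kind, structure.params

    if (structure.time_domain is TimeDomain.DISCRETE
            and kind is not StructureKind.INDEPENDENT):
        steps = np.diff(times)
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise ValueError(
                f"{kind.value} requires equispaced occasions; got spacings "
                f"{np.round(steps, 6).tolist()} (consider a continuous-time kind)"
            )

    d = np.abs(times[:, None] - times[None, :])

    if kind is StructureKind.INDEPENDENT:
        R = np.eye(T)
    elif kind is StructureKind.CS:
        rho = params[0]
        lo = -1.0 / (T - 1)
        if not lo < rho < 1.0:
            raise ValueError(f"cs correlation must be in ({lo:.4f}, 1) for T={T}")
        R = np.full((T, T), rho)
        np.fill_diagonal(R, 1.0)
    elif kind is StructureKind.AR:
        rho = yw_autocorrelations(np.asarray(params), T - 1)
        rho_full = np.concatenate([[1.0], rho])
        lag = np.rint(d / np.diff(times)[0]).astype(int)
        R = rho_full[lag]
    elif kind is StructureKind.CAR1:
        R = params[0] ** d
    elif kind is StructureKind.EXPONENTIAL:
        R = np.exp(-d / params[0])
    elif kind is StructureKind.GAUSSIAN:
        R = np.exp(-((d / params[0]) ** 2))
    elif kind is StructureKind.LINEAR:
        R = np.where(d < params[0], 1.0 - d / params[0], 0.0)
    elif kind is StructureKind.SPHERICAL:
        u = d / params[0]
        R = np.where(d < params[0], 1.0 - 1.5 * u + 0.5 * u**3, 0.0)
    elif kind is StructureKind.RATIONAL_QUADRATIC:
        u2 = (d / params[0]) ** 2
        R = 1.0 - u2 / (1.0 + u2)
    elif kind is StructureKind.UNSTRUCTURED:
        R = _unstructured_from_params(params, T)
    else:  # pragma: no cover
        raise ValueError(f"unknown structure kind {kind}")

    np.fill_diagonal(R, 1.0)
    R = (R + R.T) / 2.0
    return CorrelationMatrix(R, times)
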