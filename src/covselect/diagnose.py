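"""Residual diagnostics for choosing a candidate correlation structure.

The diagnostic stage fits the mean structure alone (generalized least
squares with identity weights, i.e. ordinary least squares), reshapes the
residuals into a subject-by-occasion matrix, and characterizes the leftover
correlation two ways: the lag profile (means of the off-diagonals of the
residual correlation matrix) and a pooled partial autocorrelation function
whose cutoff indicates an autoregressive order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from patsy import dmatrix

from .corrstruct import pacf_from_autocorr
from .simulate import LongitudinalDataset

__all__ = [
    "NaiveFit",
    "LagProfile",
    "PACFResult",
    "StructureSuggestion",
    "fit_naive",
    "residual_correlation",
    "lag_profile",
    "pooled_pacf",
    "suggest_structure",
    "export_diagnostics",
]

DEFAULT_FLATNESS_TOL = 0.05


@dataclass
class NaiveFit:
    """OLS fit of the mean structure with residuals in long and matrix form."""

    coefficients: pd.Series
    std_errors: pd.Series
    residuals: np.ndarray
    residual_matrix: np.ndarray  # n_subjects x T
    occasions: np.ndarray
    formula: str
    sigma2_ols: float

    @property
    def n_subjects(self) -> int:
        return self.residual_matrix.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.residual_matrix.shape[1]


@dataclass
class LagProfile:
    lags: np.ndarray
    mean_correlation: np.ndarray
    n_pairs: np.ndarray

    def is_flat(self, tol: float = DEFAULT_FLATNESS_TOL) -> bool:
        dev = np.abs(self.mean_correlation - self.mean_correlation.mean())
        return bool(dev.max() < tol)

    def flatness(self) -> float:
        """Max absolute deviation of the profile from its own mean."""
        return float(np.abs(self.mean_correlation - self.mean_correlation.mean()).max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag": self.lags,
                             "mean_correlation": self.mean_correlation,
                             "n_pairs": self.n_pairs})


@dataclass
class PACFResult:
    lags: np.ndarray
    pacf: np.ndarray
    significance_band: float
    suggested_order: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag": self.lags, "pacf": self.pacf,
                             "band": np.full(len(self.lags), self.significance_band)})


@dataclass
class StructureSuggestion:
    kind: str                 # "INDEPENDENT" | "CS" | "AR(p)"
    order: int                # AR order; 0 for CS/INDEPENDENT
    flatness: float
    flatness_tol: float
    suggested_order: int
    significance_band: float

    def label(self) -> str:
        return self.kind

    def to_dict(self) -> dict:
        return {"kind": self.kind, "order": self.order,
                "flatness": self.flatness, "flatness_tol": self.flatness_tol,
                "pacf_suggested_order": self.suggested_order,
                "significance_band": self.significance_band}


def design_matrix(dataset: LongitudinalDataset, mean_structure: str):
    """Patsy design matrix for the right-hand-side mean structure."""
    dm = dmatrix(mean_structure, dataset.data, return_type="dataframe")
    X = dm.to_numpy()
    names = list(dm.columns)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify collinear columns by QR pivoting
        _, _, piv = scipy.linalg.qr(X, pivoting=True, mode="economic")
        bad = [names[j] for j in piv[rank:]]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    return X, names


def fit_naive(dataset: LongitudinalDataset, mean_structure: str) -> NaiveFit:
    """Fit the fixed effects alone by OLS and reshape residuals by subject.

    GLS with identity weights coincides with ordinary least squares, so the
    normal equations are solved directly.  Requires complete balanced data
    (the subject-by-occasion residual matrix needs a full grid).
    """
    dataset.require_balanced()
    X, names = design_matrix(dataset, mean_structure)
    y = dataset.data[dataset.outcome].to_numpy()
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n, p = X.shape
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    occ = dataset.occasions
    resid_mat = resid.reshape(dataset.n_subjects, len(occ))
    return NaiveFit(
        coefficients=pd.Series(beta, index=names),
        std_errors=pd.Series(se, index=names),
        residuals=resid,
        residual_matrix=resid_mat,
        occasions=occ,
        formula=mean_structure,
        sigma2_ols=sigma2,
    )


def residual_correlation(fit: NaiveFit) -> tuple[np.ndarray, np.ndarray]:
    """Across-subject sample correlation (and covariance) of the occasion
    residuals; entry (s, t) is the Pearson correlation between occasion-s and
    occasion-t residuals over subjects."""
    E = fit.residual_matrix
    if E.shape[0] < 3:
        raise ValueError("need at least 3 subjects to estimate residual correlation")
    sd = E.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        bad = np.nonzero(sd <= 0)[0]
        raise ValueError(f"zero-variance residual column(s) at occasion index {bad.tolist()}")
    cov = np.cov(E, rowvar=False, ddof=1)
    corr = cov / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    return corr, cov


def lag_profile(corr: np.ndarray) -> LagProfile:
    """Means of the off-diagonals of a T x T correlation matrix by lag."""
    corr = np.asarray(corr, dtype=float)
    T = corr.shape[0]
    if T < 2:
        raise ValueError("need at least 2 occasions")
    lags = np.arange(1, T)
    means = np.array([np.diagonal(corr, offset=k).mean() for k in lags])
    n_pairs = T - lags
    return LagProfile(lags=lags, mean_correlation=means, n_pairs=n_pairs)


def pooled_autocovariance(E: np.ndarray, max_lag: int) -> np.ndarray:
    """Pooled autocovariances gamma_0..gamma_max_lag across subject series.

    Cross-products at each lag are summed over all subjects and divided by
    the fixed total count n*T (the biased-but-positive-semidefinite
    convention), after demeaning by the pooled residual mean.
    """
    n, T = E.shape
    Ec = E - E.mean()
    denom = n * T
    gamma = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        gamma[k] = float(np.sum(Ec[:, : T - k] * Ec[:, k:])) / denom
    return gamma


def pooled_pacf(fit: NaiveFit, max_lag: int | None = None,
                alpha_z: float = 1.96) -> PACFResult:
    """Pooled PACF of the residual series with a pointwise significance band.

    The band is ``alpha_z / sqrt(n*T)`` — an approximate 95% null bound
    treating the n*T pooled residuals as the effective sample size.  The
    suggested order is the largest lag whose |PACF| strictly exceeds the
    band (a value exactly on the band is non-significant).
    """
    E = fit.residual_matrix
    n, T = E.shape
    if max_lag is None:
        max_lag = min(T - 1, 10)
    if not 1 <= max_lag <= T - 1:
        raise ValueError(f"max_lag must be in [1, T-1] = [1, {T - 1}], got {max_lag}")
    gamma = pooled_autocovariance(E, max_lag)
    if gamma[0] <= 0:
        raise ValueError("degenerate residuals: zero pooled variance")
    rho = gamma[1:] / gamma[0]
    pacf = pacf_from_autocorr(rho)
    band = alpha_z / np.sqrt(n * T)
    sig = np.abs(pacf) > band
    order = int(np.nonzero(sig)[0][-1] + 1) if sig.any() else 0
    return PACFResult(lags=np.arange(1, max_lag + 1), pacf=pacf,
                      significance_band=float(band), suggested_order=order)


def suggest_structure(profile: LagProfile, pacf: PACFResult,
                      flatness_tol: float = DEFAULT_FLATNESS_TOL) -> StructureSuggestion:
    """Decision rule mapping the two diagnostics to a candidate structure.

    No significant PACF lag -> independent residuals; a single significant
    lag with a flat lag profile -> compound symmetry; a single lag with a
    decaying profile -> AR(1); p >= 2 significant lags -> AR(p).
    """
    p = pacf.suggested_order
    flat = profile.flatness()
    if p == 0:
        kind, order = "INDEPENDENT", 0
    elif p == 1 and flat < flatness_tol:
        kind, order = "CS", 0
    elif p == 1:
        kind, order = "AR(1)", 1
    else:
        kind, order = f"AR({p})", p
    return StructureSuggestion(kind=kind, order=order, flatness=flat,
                               flatness_tol=flatness_tol, suggested_order=p,
                               significance_band=pacf.significance_band)


def export_diagnostics(profile: LagProfile, pacf: PACFResult, out_dir,
                       render_plots: bool = False) -> dict:
    """Write lag-profile and PACF tables as tidy CSV; optionally render PNGs.

    Plot rendering is a convenience layer (requires matplotlib); the CSV
    tables are the tested artifact.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    lp_path = out / "lag_profile.csv"
    profile.to_frame().to_csv(lp_path, index=False)
    paths["lag_profile"] = lp_path
    pacf_path = out / "pacf.csv"
    pacf.to_frame().to_csv(pacf_path, index=False)
    paths["pacf"] = pacf_path
    if render_plots:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        axes[0].plot(profile.lags, profile.mean_correlation, "o-")
        axes[0].axhline(0.0, color="grey", lw=0.8)
        axes[0].set(xlabel="lag", ylabel="mean off-diagonal correlation",
                    title="Residual lag profile")
        axes[1].stem(pacf.lags, pacf.pacf)
        for s in (pacf.significance_band, -pacf.significance_band):
            axes[1].axhline(s, color="red", ls="--", lw=0.8)
        axes[1].set(xlabel="lag", ylabel="PACF", title="Pooled residual PACF")
        fig.tight_layout()
        png = out / "diagnostics.png"
        fig.savefig(png, dpi=120)
        plt.close(fig)
        paths["plot"] = png
    return paths
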