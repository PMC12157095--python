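"""End-to-end pipeline: load -> naive fit -> diagnostics -> candidate fits
-> comparison table -> report."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .corrstruct import CorrelationStructure, StructureKind
from .diagnose import (
    StructureSuggestion,
    fit_naive,
    lag_profile,
    pooled_pacf,
    residual_correlation,
    suggest_structure,
)
from .fitmm import FitResult, MarginalModelSpec, fit_marginal_model
from .simulate import LongitudinalDataset, read_dataset

__all__ = [
    "ComparisonTable",
    "AnalysisReport",
    "default_candidates",
    "compare_structures",
    "run_pipeline",
    "write_report",
]

CRITERIA = ("aic", "bic", "aicc")


@dataclass
class ComparisonTable:
    """Fit results for the candidate structures with best-by-criterion flags."""

    fits: list[FitResult]
    criterion: str = "bic"
    suggestion: StructureSuggestion | None = None
    all_failed: bool = False
    best: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.fits:
            raise ValueError("empty candidate list")
        converged = [f for f in self.fits if f.converged]
        self.all_failed = not converged
        pool = converged or self.fits
        self.best = {}
        for crit in CRITERIA:
            vals = [(getattr(f, crit), f.n_params, f.label()) for f in pool]
            finite = [(v, k, lab) for v, k, lab in vals if np.isfinite(v)]
            if not finite:
                self.best[crit] = None
                continue
            # ties: fewer parameters, then lexicographic label
            self.best[crit] = min(finite)[2]
        order = np.argsort([getattr(f, self.criterion) for f in self.fits],
                           kind="stable")
        self.fits = [self.fits[i] for i in order]

    def selected(self) -> FitResult:
        """Headline winner under the table's criterion (among converged fits)."""
        lab = self.best.get(self.criterion)
        for f in self.fits:
            if f.label() == lab:
                return f
        return self.fits[0]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.fits:
            row = {
                "structure": f.label(),
                "k": f.n_params,
                "loglik": f.loglik,
                "aic": f.aic,
                "bic": f.bic,
                "aicc": f.aicc,
                "converged": f.converged,
            }
            for crit in CRITERIA:
                row[f"best_{crit}"] = (f.label() == self.best[crit])
            rows.append(row)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "criterion": self.criterion,
            "best": self.best,
            "all_failed": self.all_failed,
            "rows": [f.to_dict() for f in self.fits],
            "suggestion": self.suggestion.to_dict() if self.suggestion else None,
        }


def default_candidates(T: int, suggested_order: int,
                       balanced: bool = True,
                       irregular: bool = False) -> list[CorrelationStructure]:
    """Candidate set: CS, AR(1)..AR(cap), unstructured; continuous kinds when
    the time grid is irregular.  The AR order is capped at
    min(suggested_order + 1, T - 2) to keep every candidate identifiable."""
    cands: list[CorrelationStructure] = []
    if balanced:
        cands.append(CorrelationStructure(StructureKind.CS, (0.0,)))
        cap = max(1, min(suggested_order + 1, T - 2))
        for p in range(1, cap + 1):
            cands.append(CorrelationStructure(StructureKind.AR, (0.0,) * p))
        cands.append(CorrelationStructure(
            StructureKind.UNSTRUCTURED, (0.0,) * (T * (T - 1) // 2)))
    if irregular or not balanced:
        cands.append(CorrelationStructure(StructureKind.CAR1, (0.5,)))
        cands.append(CorrelationStructure(StructureKind.EXPONENTIAL, (1.0,)))
        cands.append(CorrelationStructure(StructureKind.GAUSSIAN, (1.0,)))
        cands.append(CorrelationStructure(StructureKind.LINEAR, (1.0,)))
    return cands


def compare_structures(dataset: LongitudinalDataset, mean_structure: str,
                       candidates: list[CorrelationStructure],
                       estimation: str = "REML",
                       heteroscedastic: bool = False,
                       criterion: str = "bic",
                       suggestion: StructureSuggestion | None = None) -> ComparisonTable:
    """Fit every candidate structure and tabulate the information criteria.

    Non-converged fits stay in the table but are excluded from best-flagging.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    if criterion not in CRITERIA:
        raise ValueError(f"criterion must be one of {CRITERIA}")
    fits = []
    for cand in candidates:
        spec = MarginalModelSpec(mean_structure, cand,
                                 heteroscedastic=heteroscedastic,
                                 estimation=estimation)
        fits.append(fit_marginal_model(spec, dataset))
    return ComparisonTable(fits=fits, criterion=criterion, suggestion=suggestion)


@dataclass
class AnalysisReport:
    dataset_summary: dict
    naive_coefficients: dict
    diagnostics: dict
    comparison: dict
    selected: dict
    metadata: dict

    def to_dict(self) -> dict:
        return {
            "dataset_summary": self.dataset_summary,
            "naive_coefficients": self.naive_coefficients,
            "diagnostics": self.diagnostics,
            "comparison": self.comparison,
            "selected": self.selected,
            "metadata": self.metadata,
        }

    def to_json(self) -> str:
        # canonical: sorted keys, fixed separators, no volatile fields
        return json.dumps(self.to_dict(), sort_keys=True, indent=2,
                          allow_nan=False, default=_jsonify)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisReport":
        return cls(dataset_summary=d["dataset_summary"],
                   naive_coefficients=d["naive_coefficients"],
                   diagnostics=d["diagnostics"],
                   comparison=d["comparison"],
                   selected=d["selected"],
                   metadata=d["metadata"])


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _round_floats(obj, ndigits=12):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        v = float(obj)
        return None if not np.isfinite(v) else float(f"{v:.{ndigits}g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_pipeline(dataset, mean_structure: str,
                 subject: str = "subject", time: str = "time",
                 outcome: str = "outcome",
                 estimation: str = "REML",
                 heteroscedastic: bool = False,
                 criterion: str = "bic",
                 candidates: list[CorrelationStructure] | None = None,
                 max_lag: int | None = None,
                 log=lambda msg: None) -> AnalysisReport:
    """Execute the five analysis stages in order and assemble the report.

    ``dataset`` may be a path to a long-format CSV or an in-memory
    :class:`LongitudinalDataset`.  Every number in the report derives
    deterministically from the inputs, so identical runs give identical
    reports.
    """
    # stage 1: load
    if isinstance(dataset, (str, Path)):
        ds = read_dataset(dataset, subject=subject, time=time, outcome=outcome)
    else:
        ds = dataset
    occ = ds.occasions
    T = len(occ)
    log(f"load: {ds.n_subjects} subjects x {T} occasions")

    # stage 2: naive fixed-effects fit
    naive = fit_naive(ds, mean_structure)
    log(f"naive fit: {len(naive.coefficients)} coefficients, "
        f"residual sigma2 {naive.sigma2_ols:.4g}")

    # stage 3: residual diagnostics
    corr, _ = residual_correlation(naive)
    profile = lag_profile(corr)
    pacf = pooled_pacf(naive, max_lag=max_lag)
    suggestion = suggest_structure(profile, pacf)
    log(f"diagnostics: suggested {suggestion.label()} "
        f"(pacf order {pacf.suggested_order}, flatness {profile.flatness():.3f})")

    # stage 4: candidate fits + comparison
    balanced = ds.is_balanced()
    steps = np.diff(occ)
    irregular = not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12)
    if candidates is None:
        candidates = default_candidates(T, pacf.suggested_order,
                                        balanced=balanced, irregular=irregular)
    table = compare_structures(ds, mean_structure, candidates,
                               estimation=estimation,
                               heteroscedastic=heteroscedastic,
                               criterion=criterion, suggestion=suggestion)
    log(f"comparison: best-by-{criterion} = {table.best[criterion]}")

    # stage 5: report assembly
    selected = table.selected()
    agrees = suggestion.label() == selected.label()
    report = AnalysisReport(
        dataset_summary={
            "n_subjects": int(ds.n_subjects),
            "n_occasions": int(T),
            "occasions": [float(t) for t in occ],
            "n_obs": int(len(ds.data)),
            "balanced": bool(balanced),
            "variables": list(ds.data.columns),
            "roles": {"subject": ds.subject, "time": ds.time,
                      "outcome": ds.outcome},
        },
        naive_coefficients={
            "estimate": {k: float(v) for k, v in naive.coefficients.items()},
            "std_error": {k: float(v) for k, v in naive.std_errors.items()},
        },
        diagnostics={
            "lag_profile": _round_floats(profile.to_frame().to_dict("list")),
            "pacf": _round_floats(pacf.to_frame().to_dict("list")),
            "suggestion": _round_floats(suggestion.to_dict()),
        },
        comparison=_round_floats(table.to_dict()),
        selected={
            "structure": selected.label(),
            "criterion": criterion,
            "agrees_with_suggestion": bool(agrees),
            "fit": _round_floats(selected.to_dict()),
            "summary_text": selected.summary(),
        },
        metadata={
            "package_version": __version__,
            "estimation": estimation,
            "criterion": criterion,
            "mean_structure": mean_structure,
            "heteroscedastic": bool(heteroscedastic),
        },
    )
    # round every float so that JSON text is reproducible across platforms
    report.naive_coefficients = _round_floats(report.naive_coefficients)
    return report


def write_report(report: AnalysisReport, path, fmt: str = "json") -> list[Path]:
    """Serialize a report as canonical JSON, a CSV bundle, or markdown.

    All formats are views of the same in-memory report; nothing is
    recomputed.  Returns the list of files written.
    """
    path = Path(path)
    if fmt == "json":
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(report.to_json() + "\n")
        return [path]
    if fmt == "csv-bundle":
        path.mkdir(parents=True, exist_ok=True)
        written = []
        tables = {
            "naive_coefficients": pd.DataFrame(report.naive_coefficients),
            "lag_profile": pd.DataFrame(report.diagnostics["lag_profile"]),
            "pacf": pd.DataFrame(report.diagnostics["pacf"]),
            "comparison": pd.DataFrame([
                {"structure": r["label"], "k": r["n_params"],
                 "loglik": r["loglik"], "aic": r["aic"], "bic": r["bic"],
                 "aicc": r["aicc"], "converged": r["converged"]}
                for r in report.comparison["rows"]]),
        }
        for name, df in tables.items():
            p = path / f"{name}.csv"
            df.to_csv(p, index=True if name == "naive_coefficients" else False)
            written.append(p)
        return written
    if fmt == "markdown":
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(render_markdown(report))
        return [path]
    raise ValueError(f"unknown report format {fmt!r} "
                     f"(expected json, csv-bundle or markdown)")


def render_markdown(report: AnalysisReport) -> str:
    ds = report.dataset_summary
    sug = report.diagnostics["suggestion"]
    lines = [
        "# Longitudinal covariance-structure analysis",
        "",
        f"- subjects: {ds['n_subjects']}",
        f"- occasions: {ds['n_occasions']} ({ds['occasions']})",
        f"- observations: {ds['n_obs']} (balanced: {ds['balanced']})",
        f"- mean structure: `{report.metadata['mean_structure']}`",
        f"- estimation: {report.metadata['estimation']}",
        "",
        "## Diagnostics",
        "",
        f"Suggested structure: **{sug['kind']}** "
        f"(PACF order {sug['pacf_suggested_order']}, "
        f"lag-profile flatness {sug['flatness']:.3f})",
        "",
        "## Model comparison",
        "",
        "| structure | k | logLik | AIC | BIC | AICc | converged |",
        "|---|---|---|---|---|---|---|",
    ]
    for r in report.comparison["rows"]:
        aicc = "n/a" if r["aicc"] is None else f"{r['aicc']:.2f}"
        lines.append(
            f"| {r['label']} | {r['n_params']} | {r['loglik']:.2f} | "
            f"{r['aic']:.2f} | {r['bic']:.2f} | {aicc} | {r['converged']} |")
    sel = report.selected
    lines += [
        "",
        "## Selected model",
        "",
        f"Best by {sel['criterion'].upper()}: **{sel['structure']}** "
        f"({'agrees' if sel['agrees_with_suggestion'] else 'disagrees'} "
        f"with the residual diagnostics suggestion)",
        "",
        "```",
        sel["summary_text"],
        "```",
        "",
    ]
    return "\n".join(lines)
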