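"""Orchestration of the full method comparison.

One config describes the input (a synthetic design or file paths), the
methods to run, their parameters and a seed; :func:`run_comparison` executes
every requested method on the same gene-matched data, labels unsupervised
components against the ground truth, evaluates each estimate and writes the
per-method tables plus one cross-method summary. A method that fails is
recorded and the remaining methods still run; the whole run is deterministic
under a fixed config and seed (wall times are logged, never written into
the summary tables).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .core import (
    DeconvolutionResult,
    ExpressionMatrix,
    MixDeconError,
    ProportionMatrix,
    SignatureMatrix,
    match_genes,
)
from . import io as mio
from .evaluate import EvaluationReport, build_report
from .simulate import MixtureDesign, SignatureDesign, make_dataset
from .supervised import (
    MrnaScalingFactors,
    SvrConfig,
    alts_deconvolve,
    nnls_deconvolve,
    rlm_deconvolve,
    svr_deconvolve,
)
from .unsupervised import assign_components, ica_deconvolve, linseed_deconvolve

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ComparisonSummary", "load_or_simulate", "run_comparison"]

SUPERVISED = ("nnls", "svr", "rlm", "alts")
UNSUPERVISED = ("ica", "linseed")
ALL_METHODS = SUPERVISED + UNSUPERVISED


@dataclass
class RunConfig:
    """Validated description of one comparison run."""

    methods: tuple[str, ...] = ALL_METHODS
    seed: int = 0
    output_dir: str | None = None
    # exactly one input branch
    synthetic: dict | None = None          # {"signature": {...}, "mixture": {...}}
    bulk_path: str | None = None
    signature_path: str | None = None
    true_proportions_path: str | None = None
    n_cell_types: int | None = None
    method_params: dict = field(default_factory=dict)
    exclude_types: tuple[str, ...] = ()
    unlog: bool = False

    def __post_init__(self) -> None:
        self.methods = tuple(self.methods)
        unknown = [m for m in self.methods if m not in ALL_METHODS]
        if unknown:
            raise MixDeconError(f"unknown methods {unknown}; choose from {ALL_METHODS}")
        if not self.methods:
            raise MixDeconError("no methods requested")
        if (self.synthetic is not None) == (self.bulk_path is not None):
            raise MixDeconError("exactly one of a synthetic design or a bulk file is required")
        if self.bulk_path is not None:
            if any(m in SUPERVISED for m in self.methods) and self.signature_path is None:
                raise MixDeconError("supervised methods require a signature file")
            if any(m in UNSUPERVISED for m in self.methods) and self.n_cell_types is None:
                raise MixDeconError("unsupervised methods require n_cell_types")
        bad = [m for m in self.method_params if m not in ALL_METHODS]
        if bad:
            raise MixDeconError(f"method_params for unknown methods {bad}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise MixDeconError(f"config {path} must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise MixDeconError(f"unknown config keys {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


@dataclass
class ComparisonSummary:
    """Cross-method metrics for one run."""

    table: pd.DataFrame                      # method, status, metrics, winner flags
    reports: dict[str, EvaluationReport]
    results: dict[str, DeconvolutionResult]
    failures: dict[str, str]
    runtimes: dict[str, float]               # seconds; logged, not part of the table


def load_or_simulate(config: RunConfig) -> tuple[
    ExpressionMatrix, SignatureMatrix | None, ProportionMatrix | None, dict | None
]:
    """Materialize the run's inputs from files or the synthetic generator."""
    if config.synthetic is not None:
        design = dict(config.synthetic)
        sig_kwargs = dict(design.get("signature", {}))
        mix_kwargs = dict(design.get("mixture", {}))
        if "cell_types" in sig_kwargs:
            sig_kwargs["cell_types"] = tuple(sig_kwargs["cell_types"])
        sig_kwargs.setdefault("seed", config.seed)
        mix_kwargs.setdefault("seed", config.seed + 1)
        ds = make_dataset(SignatureDesign(**sig_kwargs), MixtureDesign(**mix_kwargs))
        return ds.B, ds.S_true, ds.P_true, dict(ds.marker_truth)
    B = mio.read_expression(config.bulk_path, unlog=config.unlog)
    S = mio.read_signature(config.signature_path) if config.signature_path else None
    P = (
        mio.read_proportions(config.true_proportions_path)
        if config.true_proportions_path
        else None
    )
    if P is None:
        logger.info("no known proportions supplied; evaluation stages will be skipped")
    return B, S, P, None


def _run_method(
    method: str,
    B: ExpressionMatrix,
    S: SignatureMatrix | None,
    P_true: ProportionMatrix | None,
    c: int,
    seed: int,
    params: dict,
) -> DeconvolutionResult:
    params = dict(params)
    if method == "nnls":
        return nnls_deconvolve(B, S)
    if method == "svr":
        cfg = SvrConfig(
            nu_grid=tuple(params.pop("nu_grid", SvrConfig.nu_grid)),
            C=params.pop("C", SvrConfig.C),
            standardize=params.pop("standardize", SvrConfig.standardize),
        )
        return svr_deconvolve(B, S, cfg)
    if method == "rlm":
        alphas = params.pop("alphas", None)
        if isinstance(alphas, dict):
            alphas = MrnaScalingFactors(alpha=alphas)
        return rlm_deconvolve(B, S, alphas=alphas)
    if method == "alts":
        result, _ = alts_deconvolve(B, S, **params)
        return result
    if method == "ica":
        _, result = ica_deconvolve(B, c, seed=params.pop("seed", seed), **params)
        return result
    if method == "linseed":
        _, result, _ = linseed_deconvolve(B, c, **params)
        return result
    raise MixDeconError(f"unknown method {method!r}")  # pragma: no cover


def _label_components(
    result: DeconvolutionResult,
    P_true: ProportionMatrix | None,
    marker_truth: dict | None,
    B: ExpressionMatrix,
) -> DeconvolutionResult:
    """Rename unsupervised component rows with matched cell-type labels."""
    assignment = assign_components(
        result.P_est,
        reference_P=P_true,
        marker_truth=None if P_true is not None else marker_truth,
        bulk=B,
    )
    relabeled = result.P_est.data.rename(index=assignment.mapping)
    result.P_est = ProportionMatrix(relabeled, mode="strict",
                                    flagged_samples=result.P_est.flagged_samples)
    result.extras["component_assignment"] = assignment
    return result


def run_comparison(config: RunConfig) -> ComparisonSummary:
    """Run every requested method on the same inputs and compare them.

    Supervised methods see the gene-matched bulk and signature; unsupervised
    methods see the bulk alone and their components are labeled against the
    known truth. Per-method evaluation reports and a summary table are
    returned and, when ``config.output_dir`` is set, written as TSV.
    """
    B, S, P_true, marker_truth = load_or_simulate(config)
    if S is not None:
        _, B_matched, S_matched = match_genes(B, S)
    else:
        B_matched, S_matched = B, None
    c = config.n_cell_types or (S.shape[1] if S is not None else None)
    if c is None and any(m in UNSUPERVISED for m in config.methods):
        raise MixDeconError("cannot infer the number of cell types")

    results: dict[str, DeconvolutionResult] = {}
    reports: dict[str, EvaluationReport] = {}
    failures: dict[str, str] = {}
    runtimes: dict[str, float] = {}
    for method in config.methods:
        t0 = time.perf_counter()
        try:
            res = _run_method(
                method, B_matched if method in SUPERVISED else B,
                S_matched, P_true, c, config.seed,
                config.method_params.get(method, {}),
            )
            if method in UNSUPERVISED and (P_true is not None or marker_truth is not None):
                res = _label_components(res, P_true, marker_truth, B)
            results[method] = res
            if P_true is not None:
                reports[method] = build_report(P_true, res.P_est,
                                               exclude=config.exclude_types)
        except Exception as exc:  # failure isolation: other methods still run
            logger.error("method %s failed: %s", method, exc)
            failures[method] = str(exc)
        finally:
            runtimes[method] = time.perf_counter() - t0
        logger.info(
            "method %s: %d genes x %d samples, %.2fs",
            method, B.shape[0], B.shape[1], runtimes[method],
        )

    rows = []
    for method in config.methods:
        row = {"method": method, "status": "failed" if method in failures else "ok"}
        if method in reports:
            rep = reports[method]
            row["mean_diagonal_corr"] = rep.mean_diagonal_corr
            row["mean_rmse"] = float(rep.rmse_per_type.mean())
            for ct in rep.rmse_per_type.index:
                row[f"rmse_{ct}"] = float(rep.rmse_per_type[ct])
        rows.append(row)
    table = pd.DataFrame(rows)
    if "mean_diagonal_corr" in table.columns:
        best_corr = table["mean_diagonal_corr"].max()
        best_rmse = table["mean_rmse"].min()
        table["best_correlation"] = table["mean_diagonal_corr"] == best_corr
        table["best_rmse"] = table["mean_rmse"] == best_rmse

    summary = ComparisonSummary(
        table=table, reports=reports, results=results,
        failures=failures, runtimes=runtimes,
    )
    if config.output_dir is not None:
        _write_artifacts(config, summary)
    return summary


def _write_artifacts(config: RunConfig, summary: ComparisonSummary) -> None:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    mio.write_table(summary.table, outdir / "summary.tsv")
    for method, res in summary.results.items():
        mdir = outdir / method
        mio.write_proportions(res.P_est, mdir / "P_est.tsv")
        if method in summary.reports:
            rep = summary.reports[method]
            rep.corr_matrix.to_csv(mdir / "corr_matrix.tsv", sep="\t", lineterminator="\n")
            rep.rmse_per_type.to_csv(mdir / "rmse.tsv", sep="\t", lineterminator="\n")
            mio.write_table(rep.bar_mixture, mdir / "bar_mixture.tsv")
            for ct, tab in rep.cell_signature.items():
                safe = str(ct).replace("/", "_").replace(" ", "_")
                mio.write_table(tab, mdir / f"cell_signature_{safe}.tsv")
    if summary.failures:
        fail = pd.DataFrame(
            [{"method": m, "error": e} for m, e in sorted(summary.failures.items())]
        )
        mio.write_table(fail, outdir / "failures.tsv")
    logger.info("artifacts written to %s (runtimes: %s)", outdir,
                {m: f"{t:.2f}s" for m, t in summary.runtimes.items()})
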