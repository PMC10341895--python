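"""Comparative evaluation of deconvolution output against known proportions.

Provides the three analytical views used to compare methods — correlation
matrices between real and estimated proportions (corrplot data), per-cell-
type RMSE with paired real/estimated series (cell-signature plot data), and
long-format stacked-mixture tables (bar-mixture plot data) — plus signature
refinement: distilling a broad reference signature down to the compact
per-cell-type marker sets discovered by simplex-corner deconvolution.

Tables are the tested contract; the optional figures in
:func:`mixdecon.plots.render_report` are conveniences built from them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .core import (
    ExpressionMatrix,
    MixDeconError,
    ProportionMatrix,
    SignatureMatrix,
    match_genes,
)
from .unsupervised import _pearson_rows, linseed_deconvolve

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationReport",
    "RefinedSignature",
    "correlation_matrix",
    "rmse_per_cell_type",
    "mean_diagonal_correlation",
    "bar_mixture_table",
    "cell_signature_table",
    "build_report",
    "collapse_signature",
    "refine_signature",
]


def _as_df(P) -> pd.DataFrame:
    return P.data if isinstance(P, ProportionMatrix) else P


def _align(P_true, P_est) -> tuple[pd.DataFrame, pd.DataFrame]:
    t, e = _as_df(P_true), _as_df(P_est)
    if set(t.index) != set(e.index) or set(t.columns) != set(e.columns):
        raise MixDeconError("true and estimated proportions must share cell types and samples")
    return t, e.loc[t.index, t.columns]


@dataclass
class EvaluationReport:
    """Everything the comparison figures are built from, for one method."""

    corr_matrix: pd.DataFrame                 # real types x estimated types
    rmse_per_type: pd.Series
    mean_diagonal_corr: float
    matched_pairs: dict                       # estimated row -> real row label
    bar_mixture: pd.DataFrame                 # long format
    cell_signature: dict[str, pd.DataFrame]   # per type: sample, real, estimated
    constant_rows: tuple = ()


@dataclass
class RefinedSignature:
    """Compact per-cell-type marker lists distilled from a base signature."""

    markers: dict[str, list]
    base_signature_name: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = {ct: len(genes) for ct, genes in self.markers.items()}

    @property
    def n_genes(self) -> int:
        return len({g for genes in self.markers.values() for g in genes})


def correlation_matrix(P_true, P_est) -> pd.DataFrame:
    """Pearson correlation of every real row against every estimated row.

    Entry (k, l) correlates, across samples, true cell type k with estimated
    type l; the diagonal of a well-matched estimate is what corrplots show.
    Constant rows (a type absent everywhere) yield 0 and a log note rather
    than an error.
    """
    t, e = _align(P_true, P_est)
    if t.shape[1] < 3:
        raise MixDeconError("correlation needs at least 3 samples")
    tv, ev = t.to_numpy(dtype=float), e.to_numpy(dtype=float)
    const = [ct for ct, row in zip(t.index, tv) if np.ptp(row) == 0]
    const += [ct for ct, row in zip(e.index, ev) if np.ptp(row) == 0 and ct not in const]
    if const:
        logger.info("correlation_matrix: constant rows treated as r=0: %s", const)
    R = _pearson_rows(tv, ev)
    return pd.DataFrame(R, index=t.index, columns=e.index)


def rmse_per_cell_type(P_true, P_est) -> pd.Series:
    """Root mean square error between real and estimated proportions, per type.

    Computed on the proportion scale [0, 1], averaged over samples.
    """
    t, e = _align(P_true, P_est)
    diff = t.to_numpy(dtype=float) - e.to_numpy(dtype=float)
    return pd.Series(np.sqrt(np.mean(diff**2, axis=1)), index=t.index, name="rmse")


def mean_diagonal_correlation(corr_matrix: pd.DataFrame, exclude: Sequence = ()) -> float:
    """Average of the diagonal (matched-type) correlations.

    ``exclude`` drops listed cell types first — the usual way to report an
    average that is not dragged down by a few hard, very specific subtypes.
    """
    if list(corr_matrix.index) != list(corr_matrix.columns):
        raise MixDeconError("mean diagonal requires a square, matched correlation matrix")
    keep = [ct for ct in corr_matrix.index if ct not in set(exclude)]
    if not keep:
        raise MixDeconError("all cell types excluded")
    return float(np.mean([corr_matrix.at[ct, ct] for ct in keep]))


def bar_mixture_table(P_true, P_est) -> pd.DataFrame:
    """Long-format table backing stacked-bar mixture plots.

    One row per (sample, cell type, source), source in {real, estimated};
    proportions per (sample, source) sum to 1.
    """
    t, e = _align(P_true, P_est)
    frames = []
    for source, df in (("real", t), ("estimated", e)):
        long = df.reset_index(names="cell_type").melt(
            id_vars="cell_type", var_name="sample", value_name="proportion"
        )
        long.insert(2, "source", source)
        frames.append(long)
    out = pd.concat(frames, ignore_index=True)
    return out[["sample", "cell_type", "source", "proportion"]]


def cell_signature_table(P_true, P_est, cell_type: str) -> tuple[pd.DataFrame, float]:
    """Paired real/estimated series for one cell type, plus its RMSE.

    Backs the dot-series (cell-signature) plots: one row per sample with the
    real and estimated proportion of ``cell_type``.
    """
    t, e = _align(P_true, P_est)
    if cell_type not in t.index:
        raise MixDeconError(f"unknown cell type {cell_type!r}")
    df = pd.DataFrame(
        {
            "sample": t.columns,
            "real": t.loc[cell_type].to_numpy(dtype=float),
            "estimated": e.loc[cell_type].to_numpy(dtype=float),
        }
    )
    rmse = float(np.sqrt(np.mean((df["real"] - df["estimated"]) ** 2)))
    return df, rmse


def build_report(P_true, P_est, exclude: Sequence = ()) -> EvaluationReport:
    """Assemble the full evaluation for one method's matched estimate."""
    t, e = _align(P_true, P_est)
    corr = correlation_matrix(t, e)
    rmse = rmse_per_cell_type(t, e)
    const = tuple(ct for ct in t.index if np.ptp(t.loc[ct].to_numpy()) == 0)
    sig = {}
    for ct in t.index:
        sig[ct], _ = cell_signature_table(t, e, ct)
    return EvaluationReport(
        corr_matrix=corr,
        rmse_per_type=rmse,
        mean_diagonal_corr=mean_diagonal_correlation(corr, exclude=exclude),
        matched_pairs={ct: ct for ct in t.index},
        bar_mixture=bar_mixture_table(t, e),
        cell_signature=sig,
        constant_rows=const,
    )


def collapse_signature(
    S: SignatureMatrix, lineage_map: Mapping[str, str]
) -> SignatureMatrix:
    """Collapse signature subtypes to major lineages by column means.

    ``lineage_map`` sends each subtype column to a major type (e.g. the 22
    immune subtypes of an LM22-style matrix onto B/T/NK/Monocyte/Neutrophil).
    Unmapped columns are dropped with a log note.
    """
    groups: dict[str, list] = {}
    dropped = []
    for ct in S.cell_type_ids:
        major = lineage_map.get(ct)
        if major is None:
            dropped.append(ct)
        else:
            groups.setdefault(major, []).append(ct)
    if dropped:
        logger.info("collapse_signature: dropping unmapped subtypes %s", dropped)
    if not groups:
        raise MixDeconError("lineage map matches no signature column")
    data = {major: S.data[cols].mean(axis=1) for major, cols in sorted(groups.items())}
    return SignatureMatrix(pd.DataFrame(data))


def refine_signature(
    B: ExpressionMatrix,
    base_signature: SignatureMatrix,
    lineage_map: Mapping[str, str],
    c: int | None = None,
    top_genes_per_type: int = 50,
    **linseed_kwargs,
) -> RefinedSignature:
    """Distill a broad signature into compact per-cell-type marker sets.

    The bulk is restricted to genes shared with the base signature, the
    signature's subtypes are collapsed to major lineages, and simplex-corner
    deconvolution is run on the shared genes. Each discovered corner is
    assigned to the major type whose top signature genes (ranked by
    specificity, i.e. the fraction of the collapsed row signal in that type)
    overlap its marker set the most (exact bipartite matching). The refined
    marker lists are by construction subsets of the base signature's genes.
    A corner overlapping no type at all is an error listing its genes.
    """
    match, B2, _ = match_genes(B, base_signature)
    collapsed = collapse_signature(base_signature, lineage_map)
    collapsed = SignatureMatrix(collapsed.data.loc[[g for g in match.shared_gene_ids]])
    majors = collapsed.cell_type_ids
    if c is None:
        c = len(majors)
    if len(match.shared_gene_ids) < c:
        raise MixDeconError("fewer shared genes than cell types")

    _, _, marker_sets = linseed_deconvolve(B2, c, **linseed_kwargs)
    corner_ids = sorted(marker_sets)

    # top signature genes per major type, ranked by specificity
    vals = collapsed.data.to_numpy(dtype=float)
    specificity = vals / np.maximum(vals.sum(axis=1, keepdims=True), 1e-300)
    top: dict[str, set] = {}
    for k, major in enumerate(majors):
        order = np.argsort(-specificity[:, k], kind="stable")
        top[major] = set(np.array(collapsed.gene_ids)[order[:top_genes_per_type]])

    overlap = np.zeros((len(corner_ids), len(majors)))
    for i, cid in enumerate(corner_ids):
        genes = set(marker_sets[cid])
        for k, major in enumerate(majors):
            overlap[i, k] = len(genes & top[major])
    zero = [corner_ids[i] for i in range(len(corner_ids)) if overlap[i].sum() == 0]
    if zero:
        details = {cid: marker_sets[cid] for cid in zero}
        raise MixDeconError(f"corners with no overlap to any cell type: {details}")
    rows, cols = linear_sum_assignment(-overlap)
    markers = {majors[k]: sorted(marker_sets[corner_ids[i]]) for i, k in zip(rows, cols)}

    base_genes = set(base_signature.gene_ids)
    assert all(g in base_genes for genes in markers.values() for g in genes), (
        "refined markers must be contained in the base signature"
    )
    return RefinedSignature(markers=markers, base_signature_name="base")
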