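"""Shared data model for the linear mixing formulation of cell-mixture deconvolution.

Bulk expression is modelled as ``B = S @ P``: an ``n x m`` bulk matrix ``B``
(genes x samples) is the product of an ``n x c`` signature matrix ``S``
(expected expression of each gene in each pure cell type) and a ``c x m``
proportion matrix ``P`` whose columns live on the probability simplex
(entries in [0, 1], each sample column summing to one).

All matrices are held as pandas DataFrames in linear (anti-log) scale; the
mixing model is only additive in linear scale, so readers that ingest
log2 data must unlog first (see :mod:`mixdecon.io`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SignatureMatrix",
    "ProportionMatrix",
    "GeneMatchResult",
    "DeconvolutionResult",
    "ValidationResult",
    "validate_proportions",
    "renormalize_to_simplex",
    "match_genes",
]


class MixDeconError(Exception):
    """Base error for structural problems in deconvolution inputs."""


def _check_unique(ids: Sequence, what: str) -> list:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if list(ids).count(x) > 1})
        raise MixDeconError(f"duplicate {what}: {dupes[:5]}")
    return ids


@dataclass
class ExpressionMatrix:
    """Bulk expression matrix B (genes x samples), linear scale, non-negative."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.size == 0:
            raise MixDeconError("empty expression matrix")
        _check_unique(self.data.index, "gene ids")
        _check_unique(self.data.columns, "sample ids")
        vals = self.data.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise MixDeconError("expression matrix contains missing values")
        if (vals < 0).any():
            raise MixDeconError("expression matrix contains negative values; "
                                "expected linear-scale (non-negative) signal")
        self.data = pd.DataFrame(vals, index=self.data.index, columns=self.data.columns)

    @property
    def gene_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class SignatureMatrix:
    """Signature matrix S (genes x cell types): expected expression per pure type."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.size == 0:
            raise MixDeconError("empty signature matrix")
        _check_unique(self.data.index, "gene ids")
        _check_unique(self.data.columns, "cell type ids")
        vals = self.data.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise MixDeconError("signature matrix contains missing values")
        if (vals < 0).any():
            raise MixDeconError("signature matrix contains negative values")
        if (vals.sum(axis=0) <= 0).any():
            bad = [c for c, s in zip(self.data.columns, vals.sum(axis=0)) if s <= 0]
            raise MixDeconError(f"signature columns with no positive signal: {bad}")
        self.data = pd.DataFrame(vals, index=self.data.index, columns=self.data.columns)

    @property
    def gene_ids(self) -> list:
        return list(self.data.index)

    @property
    def cell_type_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class ProportionMatrix:
    """Proportion matrix P (cell types x samples).

    In ``strict`` mode every column must lie on the probability simplex; in
    ``raw`` mode entries only need to be in [0, 1] (e.g. intermediate,
    not-yet-normalized estimates).
    """

    data: pd.DataFrame
    mode: str = "strict"  # "strict" | "raw"
    flagged_samples: tuple = ()

    def __post_init__(self) -> None:
        if self.data.size == 0:
            raise MixDeconError("empty proportion matrix")
        if self.mode not in ("strict", "raw"):
            raise ValueError(f"unknown mode {self.mode!r}")
        _check_unique(self.data.index, "cell type ids")
        _check_unique(self.data.columns, "sample ids")
        vals = self.data.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise MixDeconError("proportion matrix contains missing values")
        self.data = pd.DataFrame(vals, index=self.data.index, columns=self.data.columns)
        if self.mode == "strict":
            verdict = validate_proportions(self, tol=1e-9)
            if not verdict.ok:
                raise MixDeconError(
                    "proportion matrix violates simplex constraints: "
                    + "; ".join(verdict.violations[:5])
                )

    @property
    def cell_type_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class GeneMatchResult:
    """Outcome of intersecting bulk and signature gene identifiers."""

    shared_gene_ids: list
    bulk_only_count: int
    signature_only_count: int


@dataclass
class DeconvolutionResult:
    """Estimated proportions plus method metadata and fit diagnostics.

    ``P_est`` is always simplex-valid (strict mode); ``per_sample_fit`` maps
    sample id to the residual norm ||S p - b|| of the finalized fit (or a
    reconstruction-error analogue for unsupervised methods); ``extras``
    carries method-specific output (chosen nu per sample, mRNA-scaling
    factors, outlier flags, component assignment, ...).
    """

    P_est: ProportionMatrix
    method: str
    per_sample_fit: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)


@dataclass
class ValidationResult:
    ok: bool
    violations: list = field(default_factory=list)

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.ok


def validate_proportions(P: ProportionMatrix | pd.DataFrame, tol: float = 1e-9) -> ValidationResult:
    """Check the simplex constraints on a proportion matrix.

    Every entry must be in [0, 1] and each sample column must sum to one
    within ``tol``. Returns an ``ok`` verdict or the list of offending
    entries / columns.
    """
    df = P.data if isinstance(P, ProportionMatrix) else P
    if df.size == 0 or df.shape[1] < 1:
        raise MixDeconError("proportion matrix has no columns")
    vals = df.to_numpy(dtype=float)
    violations: list[str] = []
    bad = np.argwhere((vals < 0 - tol) | (vals > 1 + tol))
    for r, c in bad[:20]:
        violations.append(
            f"entry ({df.index[r]}, {df.columns[c]}) = {vals[r, c]:.6g} outside [0, 1]"
        )
    sums = vals.sum(axis=0)
    for j, s in enumerate(sums):
        if not (1 - tol <= s <= 1 + tol):
            violations.append(f"column {df.columns[j]} sums to {s:.6g}")
    return ValidationResult(ok=not violations, violations=violations)


def renormalize_to_simplex(
    values: pd.DataFrame | np.ndarray,
    cell_type_ids: Sequence | None = None,
    sample_ids: Sequence | None = None,
) -> ProportionMatrix:
    """Project non-negative raw estimates onto the probability simplex.

    Each column is divided by its sum. An all-zero column (no signal
    attributable to any cell type) is replaced by the uniform distribution
    1/c and recorded in ``flagged_samples`` rather than raising, so that
    pipelines on noisy data do not abort.
    """
    if isinstance(values, pd.DataFrame):
        df = values
    else:
        arr = np.asarray(values, dtype=float)
        c, m = arr.shape
        idx = list(cell_type_ids) if cell_type_ids is not None else [f"type_{k}" for k in range(c)]
        cols = list(sample_ids) if sample_ids is not None else [f"sample_{j}" for j in range(m)]
        df = pd.DataFrame(arr, index=idx, columns=cols)
    vals = df.to_numpy(dtype=float)
    if (vals < 0).any():
        raise MixDeconError("renormalize_to_simplex requires non-negative entries; "
                            "truncate negatives first")
    sums = vals.sum(axis=0)
    flagged = tuple(df.columns[j] for j in np.nonzero(sums == 0)[0])
    out = vals.copy()
    c = vals.shape[0]
    for j, s in enumerate(sums):
        if s == 0:
            out[:, j] = 1.0 / c
        elif abs(s - 1.0) > 1e-12:  # treat near-1 sums as normalized: idempotence
            out[:, j] = vals[:, j] / s
    if flagged:
        logger.warning("renormalize_to_simplex: all-zero columns set to uniform: %s", flagged)
    return ProportionMatrix(
        pd.DataFrame(out, index=df.index, columns=df.columns),
        mode="strict",
        flagged_samples=flagged,
    )


def match_genes(
    B: ExpressionMatrix, S: SignatureMatrix
) -> tuple[GeneMatchResult, ExpressionMatrix, SignatureMatrix]:
    """Intersect bulk and signature genes and subset both to the shared set.

    The shared genes keep the bulk row order (deterministic). A warning is
    emitted when fewer than half of the signature's genes are found in the
    bulk; zero shared genes is a hard error.
    """
    bulk_genes = B.gene_ids
    sig_genes = set(S.gene_ids)
    shared = [g for g in bulk_genes if g in sig_genes]
    if not shared:
        raise MixDeconError("no shared genes between bulk and signature")
    result = GeneMatchResult(
        shared_gene_ids=shared,
        bulk_only_count=len(bulk_genes) - len(shared),
        signature_only_count=len(sig_genes) - len(shared),
    )
    if len(shared) < 0.5 * len(sig_genes):
        logger.warning(
            "only %d of %d signature genes found in bulk (<50%%)", len(shared), len(sig_genes)
        )
    B_sub = ExpressionMatrix(B.data.loc[shared])
    S_sub = SignatureMatrix(S.data.loc[shared])
    return result, B_sub, S_sub
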