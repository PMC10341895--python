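"""Unsupervised (complete) deconvolution: estimate proportions from B alone.

Two routes:

* ``ica_deconvolve`` - independent component analysis of the gene-wise data
  (fixed-point ICA, logcosh contrast). Cell-type signals over genes are
  sparse and strongly skewed, hence far from Gaussian; the mixing weights
  over samples recovered by ICA track the cell proportions up to scale.
* ``linseed_deconvolve`` - linear-subspace / simplex-corner deconvolution.
  Marker genes of one cell type are mutually linear across samples, so
  row-normalized gene points live in the convex hull of the (row-normalized)
  proportion rows; the hull's corners are the pure cell types and the genes
  nearest each corner are its markers.

Unsupervised output rows are unlabeled components; ``assign_components``
matches them one-to-one to reference cell types by maximal Pearson
correlation (exact bipartite matching).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment, nnls as _nnls
from scipy.stats import skew
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .core import (
    DeconvolutionResult,
    ExpressionMatrix,
    MixDeconError,
    ProportionMatrix,
    renormalize_to_simplex,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ComponentDecomposition",
    "SimplexModel",
    "MutualLinearityGraph",
    "ComponentAssignment",
    "ica_deconvolve",
    "assign_components",
    "mutual_linearity",
    "linseed_deconvolve",
]


@dataclass
class ComponentDecomposition:
    """ICA decomposition B ~ S_est @ A_est with per-component skewness."""

    S_est: pd.DataFrame  # genes x components (loadings)
    A_est: pd.DataFrame  # components x samples (mixing weights)
    component_ids: list
    skewness_per_component: np.ndarray
    seed: int
    converged: bool = True


@dataclass
class MutualLinearityGraph:
    """Pairwise squared-Pearson linearity of genes across samples.

    ``scores`` is the symmetric gene x gene matrix of r^2 values (diagonal
    zeroed); ``collinearity`` holds each gene's summed weight over its
    ``top_k_edges`` strongest edges — high for genes that share a cell type
    with many others.
    """

    gene_ids: list
    scores: pd.DataFrame
    collinearity: pd.Series
    top_k_edges: int
    excluded_constant_genes: list = field(default_factory=list)


@dataclass
class SimplexModel:
    """Geometry of the simplex-corner fit."""

    X_norm: pd.DataFrame           # kept genes, row-normalized
    projection_basis: np.ndarray   # m x c orthonormal directions
    corner_coords: np.ndarray      # c x c coordinates of corners in the subspace
    corner_gene_ids: list
    marker_sets: dict              # corner id -> list[(gene, distance)]
    H_norm_est: pd.DataFrame       # c x m row-normalized proportion estimate
    loadings: pd.DataFrame         # kept genes x corners, simplex rows (alpha)


@dataclass
class ComponentAssignment:
    """One-to-one map of unlabeled components to reference cell types."""

    mapping: dict                   # component id -> cell type
    correlations: dict              # component id -> matched Pearson r
    low_confidence: tuple = ()      # components with matched r < 0.5


def ica_deconvolve(
    B: ExpressionMatrix, c: int, seed: int = 0, max_iter: int = 1000, tol: float = 1e-6
) -> tuple[ComponentDecomposition, DeconvolutionResult]:
    """Fixed-point ICA of the bulk matrix into c independent components.

    Genes are treated as observations and samples as variables; the data is
    centered and whitened, then unmixed with the logcosh contrast. Each
    component is oriented so its gene-loading skewness is positive (cell
    type signals are sparse positive spikes). Proportions are derived from
    the mixing rows by truncating negatives and renormalizing each sample
    column onto the simplex.
    """
    n, m = B.shape
    if c < 2:
        raise MixDeconError("need at least 2 components")
    if c >= m:
        raise MixDeconError(f"number of components ({c}) must be below sample count ({m})")
    ica = FastICA(
        n_components=c,
        algorithm="parallel",
        fun="logcosh",
        max_iter=max_iter,
        tol=tol,
        whiten="unit-variance",
        random_state=seed,
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        sources = ica.fit_transform(B.values)  # n x c
    if any(issubclass(w.category, ConvergenceWarning) for w in caught):
        converged = False
        logger.warning("ica did not converge in %d iterations; last iterate returned", max_iter)
    A = ica.mixing_.T  # c x m
    sk = skew(sources, axis=0)
    flip = sk < 0
    sources[:, flip] *= -1
    A[flip, :] *= -1
    sk = np.abs(sk)
    comp_ids = [f"IC{k + 1}" for k in range(c)]
    decomp = ComponentDecomposition(
        S_est=pd.DataFrame(sources, index=B.gene_ids, columns=comp_ids),
        A_est=pd.DataFrame(A, index=comp_ids, columns=B.sample_ids),
        component_ids=comp_ids,
        skewness_per_component=sk,
        seed=seed,
        converged=converged,
    )
    P = renormalize_to_simplex(np.where(A < 0, 0.0, A), comp_ids, B.sample_ids)
    recon = sources @ ica.mixing_.T + ica.mean_
    resid = B.values - recon
    fits = {s: float(np.linalg.norm(resid[:, j])) for j, s in enumerate(B.sample_ids)}
    result = DeconvolutionResult(
        P_est=P, method="ica", per_sample_fit=fits,
        extras={"converged": converged, "skewness": sk, "seed": seed},
    )
    return decomp, result


def _pearson_rows(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Row-by-row Pearson correlation matrix; constant rows give 0."""
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(Xc, axis=1)
    yn = np.linalg.norm(Yc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (Xc @ Yc.T) / np.outer(xn, yn)
    R[~np.isfinite(R)] = 0.0
    return R


def assign_components(
    P_est: ProportionMatrix | pd.DataFrame,
    reference_P: ProportionMatrix | pd.DataFrame | None = None,
    marker_truth: Mapping[str, Sequence] | None = None,
    bulk: ExpressionMatrix | None = None,
) -> ComponentAssignment:
    """Match unlabeled component rows to reference cell types.

    The assignment maximizes the total Pearson correlation between component
    rows and reference rows, solved exactly as a bipartite matching.
    The reference is either a known proportion matrix or, lacking one, a
    marker map plus the bulk matrix: the mean expression of each type's
    markers across samples is proportional to its proportions and serves as
    a surrogate reference row. Constant rows correlate as 0; a component
    whose matched correlation is below 0.5 is flagged low-confidence.
    Reference types are processed in lexical order so ties break
    deterministically.
    """
    est = P_est.data if isinstance(P_est, ProportionMatrix) else P_est
    if reference_P is not None:
        ref = reference_P.data if isinstance(reference_P, ProportionMatrix) else reference_P
    elif marker_truth is not None:
        if bulk is None:
            raise MixDeconError("marker-based assignment requires the bulk matrix")
        rows = {}
        for ct, genes in marker_truth.items():
            present = [g for g in genes if g in bulk.data.index]
            if not present:
                raise MixDeconError(f"no marker genes of {ct!r} present in bulk")
            rows[ct] = bulk.data.loc[present].mean(axis=0)
        ref = pd.DataFrame(rows).T
        ref = ref[est.columns]
    else:
        raise MixDeconError("need reference_P or marker_truth")
    if est.shape[0] != ref.shape[0]:
        raise MixDeconError(
            f"component count {est.shape[0]} != reference type count {ref.shape[0]}"
        )
    ref = ref.sort_index()
    R = _pearson_rows(est.to_numpy(dtype=float), ref.to_numpy(dtype=float))
    rows, cols = linear_sum_assignment(-R)
    mapping = {est.index[i]: ref.index[j] for i, j in zip(rows, cols)}
    corrs = {est.index[i]: float(R[i, j]) for i, j in zip(rows, cols)}
    low = tuple(comp for comp, r in corrs.items() if r < 0.5)
    return ComponentAssignment(mapping=mapping, correlations=corrs, low_confidence=low)


def mutual_linearity(
    B: ExpressionMatrix, top_n_genes: int = 2000, top_k_edges: int = 10
) -> MutualLinearityGraph:
    """Score pairwise gene-gene linearity (squared Pearson r) across samples.

    Restricted to the ``top_n_genes`` by mean expression; constant genes are
    excluded (their correlation is undefined). Each gene's collinearity
    score sums its ``top_k_edges`` strongest edge weights; marker genes of
    a well-represented cell type score near ``top_k_edges``.
    """
    if B.shape[1] < 3:
        raise MixDeconError("mutual linearity needs at least 3 samples")
    if top_n_genes > B.shape[0]:
        top_n_genes = B.shape[0]
    df = B.data
    sds = df.std(axis=1, ddof=0)
    # relative cut: rows constant up to float rounding carry no signal but
    # would correlate spuriously through shared rounding patterns
    scale = df.abs().mean(axis=1) + 1e-300
    informative = sds > 1e-9 * scale
    constant = list(df.index[~informative])
    if constant:
        logger.info("mutual_linearity: excluding %d constant genes", len(constant))
    kept = df.loc[informative]
    kept = kept.loc[kept.mean(axis=1).sort_values(ascending=False, kind="stable").index[:top_n_genes]]
    # restore bulk order for determinism
    kept = kept.loc[[g for g in df.index if g in set(kept.index)]]
    vals = kept.to_numpy(dtype=float)
    R = _pearson_rows(vals, vals) ** 2
    np.fill_diagonal(R, 0.0)
    R = np.clip(R, 0.0, 1.0)
    k = min(top_k_edges, R.shape[0] - 1)
    if k < 1:
        raise MixDeconError("not enough genes for mutual linearity")
    part = np.partition(R, -k, axis=1)[:, -k:]
    coll = part.sum(axis=1)
    scores = pd.DataFrame(R, index=kept.index, columns=kept.index)
    return MutualLinearityGraph(
        gene_ids=list(kept.index),
        scores=scores,
        collinearity=pd.Series(coll, index=kept.index),
        top_k_edges=top_k_edges,
        excluded_constant_genes=constant,
    )


def _successive_projection(Y: np.ndarray, c: int) -> list[int]:
    """Pick c extreme points by successive projection (deterministic).

    Repeatedly take the point of largest norm and deflate the data onto the
    orthogonal complement of its direction; ties go to the lowest index.
    """
    R = Y.astype(float).copy()
    corners: list[int] = []
    for _ in range(c):
        norms = np.linalg.norm(R, axis=1)
        idx = int(np.argmax(norms))
        if norms[idx] <= 1e-12:
            raise MixDeconError(
                "degenerate geometry: fewer extreme directions than requested "
                "components; the data may contain fewer cell types - try a smaller c"
            )
        corners.append(idx)
        u = R[idx] / norms[idx]
        R = R - np.outer(R @ u, u)
    return corners


def _simplex_lsq(Hmat: np.ndarray, x: np.ndarray, weight: float = 1e4) -> np.ndarray:
    """Least-squares x ~ alpha @ Hmat with alpha >= 0 summing to 1.

    Solved as NNLS on the system augmented with a heavily weighted
    sum-to-one row, then exactly renormalized.
    """
    c = Hmat.shape[0]
    A = np.vstack([Hmat.T, np.full((1, c), weight)])
    b = np.concatenate([x, [weight]])
    alpha, _ = _nnls(A, b)
    s = alpha.sum()
    return alpha / s if s > 0 else np.full(c, 1.0 / c)


def linseed_deconvolve(
    B: ExpressionMatrix,
    c: int,
    top_n_genes: int = 2000,
    top_k_edges: int = 10,
    collinearity_quantile: float = 0.9,
    marker_distance_quantile: float = 0.05,
    min_markers: int = 3,
    subtract_baseline: bool = True,
) -> tuple[SimplexModel, DeconvolutionResult, dict]:
    """Simplex-corner deconvolution with marker-gene discovery.

    Pipeline: (1) keep the most mutually linear genes (collinearity score at
    or above the given quantile); (2) subtract each gene's per-sample
    minimum (baseline ubiquitous expression would otherwise pull every gene
    point toward the simplex centre) and row-normalize, so each gene point
    is a convex combination of the row-normalized proportion rows;
    (3) project the points onto the top-c singular subspace; (4) find the c
    corners by successive projection; (5) call genes within the given
    distance quantile of a corner its markers (at least ``min_markers``,
    nearest first); (6) estimate the row-normalized proportion matrix H as
    the marker-centroid of each corner and express every kept gene as a
    simplex combination of the corners; (7) undo the row normalization by
    scaling each corner's row with its total marker signal and renormalize
    sample columns.

    Fully deterministic given the inputs. Returns the geometric model, the
    proportion estimate (components labeled corner_1..c) and the marker map.
    """
    if c < 2:
        raise MixDeconError("need at least 2 cell types")
    if B.shape[1] < c:
        raise MixDeconError(f"need at least c={c} samples, got {B.shape[1]}")
    graph = mutual_linearity(B, top_n_genes=top_n_genes, top_k_edges=top_k_edges)
    thr = float(np.quantile(graph.collinearity.to_numpy(), collinearity_quantile))
    kept_genes = [g for g in graph.gene_ids if graph.collinearity[g] >= thr]
    # the quantile cut assumes plenty of uninformative genes below it; keep a
    # floor of highly collinear genes so clean data (few, all-marker genes)
    # retains every cell type's markers
    min_kept = min(len(graph.gene_ids), max(10 * c, 30))
    if len(kept_genes) < min_kept:
        order = graph.collinearity.sort_values(ascending=False, kind="stable").index
        chosen = set(order[:min_kept])
        kept_genes = [g for g in graph.gene_ids if g in chosen]
    if len(kept_genes) < c:
        raise MixDeconError(
            f"only {len(kept_genes)} candidate genes after collinearity filtering; need >= {c}"
        )
    X = B.data.loc[kept_genes].to_numpy(dtype=float)
    orig_scale = X.sum(axis=1)
    if subtract_baseline:
        X = X - X.min(axis=1, keepdims=True)
    rowsums = X.sum(axis=1)
    nz = rowsums > 1e-9 * orig_scale
    if (~nz).any():
        logger.info("linseed: dropping %d zero-sum gene rows", int((~nz).sum()))
    kept_genes = [g for g, ok in zip(kept_genes, nz) if ok]
    X = X[nz]
    if len(kept_genes) < c:
        raise MixDeconError("too few informative genes after baseline removal")
    Xn = X / X.sum(axis=1, keepdims=True)

    _, _, Vt = np.linalg.svd(Xn, full_matrices=False)
    basis = Vt[:c].T  # m x c
    Y = Xn @ basis    # gene points in the c-dim subspace

    corner_idx = _successive_projection(Y, c)
    corner_pts = Y[corner_idx]
    for a in range(c):
        for b2 in range(a + 1, c):
            if np.linalg.norm(corner_pts[a] - corner_pts[b2]) < 1e-9:
                raise MixDeconError(
                    "duplicate simplex corners found; the data may contain fewer "
                    f"than c={c} cell types"
                )

    corner_ids = [f"corner_{k + 1}" for k in range(c)]
    marker_sets: dict[str, list] = {}
    marker_detail: dict[str, list] = {}
    for k, cid in enumerate(corner_ids):
        d = np.linalg.norm(Y - corner_pts[k], axis=1)
        # absolute floor so exactly coincident corner genes are never split
        # by floating-point noise in the quantile
        cut = max(float(np.quantile(d, marker_distance_quantile)), 1e-9)
        order = np.argsort(d, kind="stable")
        chosen = [i for i in order if d[i] <= cut]
        if len(chosen) < min_markers:
            chosen = list(order[:min_markers])
        marker_sets[cid] = [kept_genes[i] for i in chosen]
        marker_detail[cid] = [(kept_genes[i], float(d[i])) for i in chosen]

    # H rows: marker centroids in row-normalized space (rows already sum to 1)
    H = np.vstack([
        Xn[[kept_genes.index(g) for g in marker_sets[cid]]].mean(axis=0)
        for cid in corner_ids
    ])
    loadings = np.vstack([_simplex_lsq(H, Xn[i]) for i in range(Xn.shape[0])])

    # undo row normalization: per-corner total signal = summed (baseline-
    # subtracted) expression of its marker genes; markers are the only genes
    # attributable to a single type
    scales = np.array([
        X[[kept_genes.index(g) for g in marker_sets[cid]]].sum()
        for cid in corner_ids
    ])
    raw = H * scales[:, None]
    P = renormalize_to_simplex(raw, corner_ids, B.sample_ids)

    model = SimplexModel(
        X_norm=pd.DataFrame(Xn, index=kept_genes, columns=B.sample_ids),
        projection_basis=basis,
        corner_coords=corner_pts,
        corner_gene_ids=[kept_genes[i] for i in corner_idx],
        marker_sets=marker_detail,
        H_norm_est=pd.DataFrame(H, index=corner_ids, columns=B.sample_ids),
        loadings=pd.DataFrame(loadings, index=kept_genes, columns=corner_ids),
    )
    recon = loadings @ H
    fits = {
        s: float(np.linalg.norm(Xn[:, j] - recon[:, j]))
        for j, s in enumerate(B.sample_ids)
    }
    result = DeconvolutionResult(
        P_est=P, method="linseed", per_sample_fit=fits,
        extras={"marker_sets": marker_sets, "n_kept_genes": len(kept_genes)},
    )
    return model, result, marker_sets
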