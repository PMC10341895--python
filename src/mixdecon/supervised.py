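"""Supervised (partial) deconvolution: estimate P given bulk B and signature S.

Four regression cores solve, per sample j, the linear system
``b_j = S p_j`` under simplex constraints on ``p_j``:

* ``nnls_deconvolve``  - non-negative least squares baseline,
* ``svr_deconvolve``   - linear nu-support-vector regression on standardized
  data (CIBERSORT-style), choosing nu by reconstruction RMSD,
* ``rlm_deconvolve``   - robust linear model via Huber IRLS, with optional
  per-cell-type mRNA-abundance scaling of the signature (ABIS-style),
* ``alts_deconvolve``  - adaptive least trimmed squares: iteratively discard
  high-residual (outlier) genes and refit (FARDEEP-style).

All methods share the same finalization: negative coefficients are truncated
to zero and each sample column is renormalized onto the probability simplex,
so methods differ only in their regression core.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls as _nnls
from sklearn.svm import NuSVR

from .core import (
    DeconvolutionResult,
    ExpressionMatrix,
    MixDeconError,
    ProportionMatrix,
    SignatureMatrix,
    match_genes,
    renormalize_to_simplex,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SvrConfig",
    "MrnaScalingFactors",
    "OutlierFlags",
    "nnls_deconvolve",
    "svr_deconvolve",
    "fit_mrna_scaling",
    "rlm_deconvolve",
    "alts_deconvolve",
    "ols_deconvolve",
]


@dataclass(frozen=True)
class SvrConfig:
    """nu-SVR hyperparameters: candidate nu values, error cost C, z-scoring."""

    nu_grid: tuple[float, ...] = (0.25, 0.5, 0.75)
    C: float = 1.0
    standardize: bool = True

    def __post_init__(self) -> None:
        if not self.nu_grid:
            raise MixDeconError("nu_grid must be non-empty")
        if any(not (0 < nu <= 1) for nu in self.nu_grid):
            raise MixDeconError("nu values must lie in (0, 1]")
        if self.C <= 0:
            raise MixDeconError("C must be positive")


@dataclass
class MrnaScalingFactors:
    """Per-cell-type mRNA-abundance coefficients alpha, bounded to [l, u]."""

    alpha: dict[str, float]
    bounds: tuple[float, float] = (0.1, 10.0)
    flagged_types: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        l, u = self.bounds
        for ct, a in self.alpha.items():
            if not (l <= a <= u):
                raise MixDeconError(f"alpha[{ct}]={a} outside bounds [{l}, {u}]")


@dataclass
class OutlierFlags:
    """Genes discarded as outliers, per sample."""

    flagged_gene_ids: dict[str, list] = field(default_factory=dict)
    threshold_multiplier: float = 10.0


def _prepare(B: ExpressionMatrix, S: SignatureMatrix):
    match, B2, S2 = match_genes(B, S)
    n, c = S2.shape
    if c > n:
        raise MixDeconError(f"more cell types ({c}) than shared genes ({n})")
    return match, B2, S2


def _finalize(
    raw: np.ndarray,
    S2: SignatureMatrix,
    B2: ExpressionMatrix,
    method: str,
    extras: dict,
) -> DeconvolutionResult:
    """Truncate negatives, renormalize columns to the simplex, record residuals."""
    raw = np.where(raw < 0, 0.0, raw)
    P = renormalize_to_simplex(raw, S2.cell_type_ids, B2.sample_ids)
    resid = B2.values - S2.values @ raw
    fits = {s: float(np.linalg.norm(resid[:, j])) for j, s in enumerate(B2.sample_ids)}
    return DeconvolutionResult(P_est=P, method=method, per_sample_fit=fits, extras=extras)


def nnls_deconvolve(B: ExpressionMatrix, S: SignatureMatrix) -> DeconvolutionResult:
    """Per-sample non-negative least squares, then simplex renormalization."""
    _, B2, S2 = _prepare(B, S)
    Sv, Bv = S2.values, B2.values
    if np.linalg.matrix_rank(Sv) < Sv.shape[1]:
        logger.warning("rank-deficient signature; NNLS solution may not be unique")
    raw = np.empty((Sv.shape[1], Bv.shape[1]))
    for j in range(Bv.shape[1]):
        raw[:, j], _ = _nnls(Sv, Bv[:, j])
    return _finalize(raw, S2, B2, "nnls", {})


def ols_deconvolve(B: ExpressionMatrix, S: SignatureMatrix) -> DeconvolutionResult:
    """Unconstrained ordinary least squares (reference for robustness checks)."""
    _, B2, S2 = _prepare(B, S)
    raw, *_ = np.linalg.lstsq(S2.values, B2.values, rcond=None)
    return _finalize(raw, S2, B2, "ols", {})


def svr_deconvolve(
    B: ExpressionMatrix, S: SignatureMatrix, cfg: SvrConfig = SvrConfig()
) -> DeconvolutionResult:
    """Linear nu-SVR regression of each mixture on the signature columns.

    The marker genes act as support vectors. Per sample, the mixture and the
    signature are optionally z-scored (each by its own global mean/sd), a
    linear NuSVR is fit for every nu in the grid, and the nu minimizing the
    root-mean-square deviation between the reconstruction S w and the
    (standardized) mixture is kept. Negative coefficients are truncated and
    the column renormalized. A sample whose truncated coefficients are all
    zero (no signal along any signature column) is flagged degenerate and
    set to the uniform column.
    """
    _, B2, S2 = _prepare(B, S)
    Sv, Bv = S2.values, B2.values
    if cfg.standardize:
        Ss = (Sv - Sv.mean()) / Sv.std()
    else:
        Ss = Sv
    c, m = Sv.shape[1], Bv.shape[1]
    raw = np.zeros((c, m))
    chosen_nu: dict[str, float] = {}
    degenerate: list[str] = []
    for j, sample in enumerate(B2.sample_ids):
        b = Bv[:, j]
        if cfg.standardize:
            sd = b.std()
            if sd < 1e-12:
                degenerate.append(sample)
                chosen_nu[sample] = float("nan")
                continue
            bs = (b - b.mean()) / sd
        else:
            bs = b
        best = None
        for nu in cfg.nu_grid:
            model = NuSVR(kernel="linear", nu=nu, C=cfg.C)
            model.fit(Ss, bs)
            w = model.coef_.ravel()
            rmsd = float(np.sqrt(np.mean((Ss @ w + model.intercept_ - bs) ** 2)))
            if best is None or rmsd < best[0]:
                best = (rmsd, nu, w)
        _, nu, w = best
        chosen_nu[sample] = nu
        w = np.where(w < 0, 0.0, w)
        if w.sum() <= 0:
            degenerate.append(sample)
        else:
            raw[:, j] = w
    if degenerate:
        logger.warning("svr: degenerate samples set to uniform: %s", degenerate)
    extras = {"chosen_nu": chosen_nu, "degenerate_samples": tuple(degenerate)}
    return _finalize(raw, S2, B2, "svr", extras)


def fit_mrna_scaling(
    P_est_raw: ProportionMatrix | pd.DataFrame,
    P_true: ProportionMatrix | pd.DataFrame,
    bounds: tuple[float, float] = (0.1, 10.0),
) -> MrnaScalingFactors:
    """Calibrate per-cell-type mRNA-abundance coefficients against known truth.

    For each type k the least-squares scaling of the estimates onto the true
    proportions has the closed form ``alpha_k = <p_hat, p> / <p_hat, p_hat>``,
    clipped to ``bounds``. Types with all-zero estimates get alpha = 1 and
    are flagged. This is a calibration utility: it requires experimentally
    known proportions and is never applied silently.
    """
    est = P_est_raw.data if isinstance(P_est_raw, ProportionMatrix) else P_est_raw
    true = P_true.data if isinstance(P_true, ProportionMatrix) else P_true
    if list(est.index) != list(true.index) or list(est.columns) != list(true.columns):
        true = true.loc[est.index, est.columns]
    l, u = bounds
    alpha: dict[str, float] = {}
    flagged: list[str] = []
    for ct in est.index:
        e = est.loc[ct].to_numpy(dtype=float)
        t = true.loc[ct].to_numpy(dtype=float)
        denom = float(e @ e)
        if denom == 0:
            alpha[ct] = 1.0
            flagged.append(ct)
            continue
        alpha[ct] = float(np.clip((e @ t) / denom, l, u))
    if flagged:
        logger.warning("fit_mrna_scaling: zero estimates, alpha=1 for %s", flagged)
    return MrnaScalingFactors(alpha=alpha, bounds=bounds, flagged_types=tuple(flagged))


def _huber_irls(
    X: np.ndarray,
    y: np.ndarray,
    tuning: float = 1.345,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> tuple[np.ndarray, bool]:
    """Iteratively reweighted least squares with Huber weights.

    Scale is re-estimated each iteration by the normalized median absolute
    deviation of the residuals; a vanishing scale (perfect fit) terminates
    immediately, which makes the noiseless case coincide with OLS.
    """
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    yscale = max(1.0, float(np.median(np.abs(y))))
    for _ in range(max_iter):
        r = y - X @ beta
        if np.max(np.abs(r)) <= 1e-10 * yscale:  # perfect fit
            return beta, True
        # MAD scale with a floor: many tied residuals (e.g. flat background
        # genes) give MAD 0 even when gross outliers remain, and a vanishing
        # scale must downweight those outliers, not disable reweighting
        scale = max(np.median(np.abs(r - np.median(r))) / 0.6745, 1e-8 * yscale)
        u = np.abs(r / scale)
        w = np.where(u <= tuning, 1.0, tuning / np.maximum(u, 1e-300))
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        if np.max(np.abs(beta_new - beta)) < tol:
            return beta_new, True
        beta = beta_new
    return beta, False


def rlm_deconvolve(
    B: ExpressionMatrix,
    S: SignatureMatrix,
    alphas: MrnaScalingFactors | None = None,
) -> DeconvolutionResult:
    """Robust linear model fit of each mixture, Huber M-estimation.

    When mRNA-scaling factors are supplied, each signature column k is first
    multiplied by alpha_k so that the fitted coefficients estimate the cell
    proportions corrected for per-type mRNA content; alpha = 1 leaves the
    fit unchanged. Huber tuning constant 1.345 (95% Gaussian efficiency),
    convergence when coefficients move < 1e-8, at most 50 iterations.
    """
    _, B2, S2 = _prepare(B, S)
    Sv = S2.values.copy()
    used_alpha = None
    if alphas is not None:
        used_alpha = {ct: alphas.alpha.get(ct, 1.0) for ct in S2.cell_type_ids}
        Sv = Sv * np.array([used_alpha[ct] for ct in S2.cell_type_ids])[None, :]
    Bv = B2.values
    raw = np.empty((Sv.shape[1], Bv.shape[1]))
    nonconv: list[str] = []
    for j, sample in enumerate(B2.sample_ids):
        raw[:, j], converged = _huber_irls(Sv, Bv[:, j])
        if not converged:
            nonconv.append(sample)
    if nonconv:
        logger.warning("rlm: IRLS not converged for samples %s; last iterate used", nonconv)
    S_scaled = SignatureMatrix(pd.DataFrame(Sv, index=S2.gene_ids, columns=S2.cell_type_ids))
    extras = {"alpha": used_alpha, "nonconverged_samples": tuple(nonconv)}
    return _finalize(raw, S_scaled, B2, "rlm", extras)


def alts_deconvolve(
    B: ExpressionMatrix,
    S: SignatureMatrix,
    threshold_multiplier: float = 10.0,
    max_iter: int = 20,
) -> tuple[DeconvolutionResult, OutlierFlags]:
    """Adaptive least trimmed squares: NNLS with iterative outlier trimming.

    Per sample: fit NNLS on the currently kept genes, flag every gene whose
    squared residual exceeds ``threshold_multiplier`` times the median
    squared residual (an adaptive, contamination-driven cut), refit, and
    stop when the flag set is stable. A zero median (noiseless data) falls
    back to an absolute squared-residual tolerance of 1e-10 so that nothing
    is flagged on clean data; flagging more than half of the genes aborts as
    degenerate contamination.

    Trimming is gradual: each sweep flags at most 5% of genes beyond the
    previous flag count, worst residuals first. The initial fit is biased by
    the outliers themselves, so flagging everything above threshold in one
    sweep can discard informative marker genes and lock in a wrong solution;
    under gradual trimming the gross outliers (whose residuals dominate) are
    removed first and previously flagged genes may re-enter once the fit
    improves.
    """
    if threshold_multiplier <= 0:
        raise MixDeconError("threshold_multiplier must be positive")
    _, B2, S2 = _prepare(B, S)
    Sv, Bv = S2.values, B2.values
    n, c = Sv.shape
    genes = np.array(S2.gene_ids)
    raw = np.empty((c, Bv.shape[1]))
    flags: dict[str, list] = {}
    for j, sample in enumerate(B2.sample_ids):
        b = Bv[:, j]
        keep = np.ones(n, dtype=bool)
        step = max(1, n // 20)
        for _ in range(max_iter):
            p, _ = _nnls(Sv[keep], b[keep])
            r2 = (b - Sv @ p) ** 2
            # scale from the kept (inlier) genes, as for any trimmed estimator
            med = float(np.median(r2[keep]))
            # near-zero median (noiseless fit): absolute tolerance, flag nothing
            thr = threshold_multiplier * med if med > 1e-10 else 1e-10
            candidates = np.nonzero(r2 > thr)[0]
            budget = int((~keep).sum()) + step
            if len(candidates) > budget:
                candidates = candidates[np.argsort(r2[candidates])[::-1][:budget]]
            new_keep = np.ones(n, dtype=bool)
            new_keep[candidates] = False
            if (~new_keep).sum() > 0.5 * n:
                raise MixDeconError(
                    f"alts: >50% of genes flagged as outliers in sample {sample}; "
                    "contamination too high"
                )
            if np.array_equal(new_keep, keep):
                break
            keep = new_keep
        raw[:, j] = p
        flags[sample] = list(genes[~keep])
    result = _finalize(raw, S2, B2, "alts", {"outlier_flags": flags})
    return result, OutlierFlags(flagged_gene_ids=flags, threshold_multiplier=threshold_multiplier)
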