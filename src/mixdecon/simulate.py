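"""Ground-truthed synthetic cell mixtures.

The generator emulates the statistical structure deconvolution assumes:
a marker-block signature matrix (each cell type over-expresses a private
set of marker genes ``marker_fold`` times above a shared background, with
optional spillover of marker signal into one other cell type), proportion
matrices drawn on the simplex (symmetric Dirichlet, explicit designs, or a
12-sample cancer/immune mixture design with two pure-tumour samples), and
bulk expression ``B = S @ P`` under multiplicative log-normal noise of a
given coefficient of variation.

The 12-sample design (``gse64385_like`` mode) mirrors a classic benchmark
layout: 6 cell types (cancer cells plus neutrophils, monocytes, B, NK and
T cells), the first two samples 100% cancer cells, and the remaining ten
samples with a cancer fraction of 30/40/50% and the rest split over the
five immune types.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    ExpressionMatrix,
    MixDeconError,
    ProportionMatrix,
    SignatureMatrix,
    validate_proportions,
)

__all__ = [
    "GSE64385_CELL_TYPES",
    "SignatureDesign",
    "MixtureDesign",
    "SyntheticDataset",
    "generate_signature",
    "generate_proportions",
    "mix",
    "make_dataset",
]

GSE64385_CELL_TYPES = ("CC", "Neutrophils", "Monocytes", "B", "NK", "T")


@dataclass(frozen=True)
class SignatureDesign:
    """Parameters of the marker-block signature generator.

    marker_fold is the expression of a marker gene in its own cell type
    relative to the shared background; spillover is the fraction of that
    excess leaked into one other (randomly chosen, seed-deterministic)
    cell type, emulating overlapping gene signatures between populations.
    """

    n_genes: int = 500
    cell_types: tuple[str, ...] = GSE64385_CELL_TYPES
    markers_per_type: int = 10
    marker_fold: float = 10.0
    spillover: float = 0.0
    background_level: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        c = len(self.cell_types)
        if c * self.markers_per_type > self.n_genes:
            raise MixDeconError(
                f"{c} cell types x {self.markers_per_type} markers exceed {self.n_genes} genes"
            )
        if not self.marker_fold > 1:
            raise MixDeconError("marker_fold must exceed 1")
        if not (0 <= self.spillover < 1):
            raise MixDeconError("spillover must be in [0, 1)")
        if not self.background_level > 0:
            raise MixDeconError("background_level must be positive")


@dataclass(frozen=True)
class MixtureDesign:
    """Parameters of the proportion/mixing generator.

    proportion_mode is one of ``dirichlet`` (symmetric Dirichlet(alpha)
    columns), ``explicit`` (a user matrix, validated), or ``gse64385_like``
    (the 12-sample cancer/immune design). noise_cv is the coefficient of
    variation of the unit-mean multiplicative log-normal noise on B.
    """

    n_samples: int = 12
    proportion_mode: str = "gse64385_like"
    dirichlet_alpha: float = 1.0
    explicit: pd.DataFrame | None = None
    pure_samples: tuple[tuple[int, str], ...] = ()
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.proportion_mode not in ("dirichlet", "explicit", "gse64385_like"):
            raise MixDeconError(f"unknown proportion_mode {self.proportion_mode!r}")
        if self.noise_cv < 0:
            raise MixDeconError("noise_cv must be >= 0")
        if self.proportion_mode == "explicit":
            if self.explicit is None:
                raise MixDeconError("explicit mode requires a proportion matrix")
            verdict = validate_proportions(self.explicit, tol=1e-9)
            if not verdict.ok:
                raise MixDeconError(
                    "explicit proportions invalid: " + "; ".join(verdict.violations[:3])
                )


@dataclass
class SyntheticDataset:
    """Bundle of bulk data with its generating truth."""

    B: ExpressionMatrix
    S_true: SignatureMatrix
    P_true: ProportionMatrix
    marker_truth: Mapping[str, list]
    sig_design: SignatureDesign | None = None
    mix_design: MixtureDesign | None = None


def generate_signature(design: SignatureDesign) -> tuple[SignatureMatrix, dict[str, list]]:
    """Build a marker-block signature matrix and the true marker map.

    Marker gene i of cell type k takes value background * marker_fold in
    column k and background elsewhere; with spillover > 0 the excess
    ``spillover * (marker - background)`` is added to one other randomly
    chosen column. Non-marker genes sit at background in every type.
    """
    rng = np.random.default_rng(design.seed)
    c = len(design.cell_types)
    bg = design.background_level
    vals = np.full((design.n_genes, c), bg, dtype=float)
    gene_ids = [f"g{i + 1:04d}" for i in range(design.n_genes)]
    marker_truth: dict[str, list] = {ct: [] for ct in design.cell_types}
    for k, ct in enumerate(design.cell_types):
        start = k * design.markers_per_type
        for i in range(start, start + design.markers_per_type):
            vals[i, k] = bg * design.marker_fold
            marker_truth[ct].append(gene_ids[i])
            if design.spillover > 0 and c > 1:
                target = rng.choice([t for t in range(c) if t != k])
                vals[i, target] += design.spillover * (vals[i, k] - bg)
    S = SignatureMatrix(pd.DataFrame(vals, index=gene_ids, columns=list(design.cell_types)))
    return S, marker_truth


def generate_proportions(
    design: MixtureDesign, cell_types: Sequence[str] = GSE64385_CELL_TYPES
) -> ProportionMatrix:
    """Draw a ground-truth proportion matrix on the simplex.

    ``gse64385_like`` requires the 6-type cancer/immune panel and always
    yields 12 samples: S01/S02 one-hot on CC, S03..S12 with a CC fraction
    drawn uniformly from {0.3, 0.4, 0.5} and the remainder split over the
    immune types by a flat Dirichlet.
    """
    rng = np.random.default_rng(design.seed)
    cell_types = list(cell_types)
    c = len(cell_types)
    for _, ct in design.pure_samples:
        if ct not in cell_types:
            raise MixDeconError(f"pure_samples references unknown cell type {ct!r}")

    if design.proportion_mode == "explicit":
        P = design.explicit.copy()
        cols = list(P.columns)
    elif design.proportion_mode == "gse64385_like":
        if "CC" not in cell_types:
            raise MixDeconError("gse64385_like mode requires a 'CC' cell type")
        m = 12
        cc = cell_types.index("CC")
        others = [k for k in range(c) if k != cc]
        vals = np.zeros((c, m))
        vals[cc, 0] = vals[cc, 1] = 1.0
        for j in range(2, m):
            frac = rng.choice([0.3, 0.4, 0.5])
            vals[cc, j] = frac
            immune = rng.dirichlet(np.ones(len(others)))
            for t, k in enumerate(others):
                vals[k, j] = (1 - frac) * immune[t]
        cols = [f"S{j + 1:02d}" for j in range(m)]
        P = pd.DataFrame(vals, index=cell_types, columns=cols)
    else:  # dirichlet
        m = design.n_samples
        vals = rng.dirichlet(np.full(c, design.dirichlet_alpha), size=m).T
        cols = [f"S{j + 1:02d}" for j in range(m)]
        P = pd.DataFrame(vals, index=cell_types, columns=cols)

    for j, ct in design.pure_samples:
        P.iloc[:, j] = 0.0
        P.loc[ct, P.columns[j]] = 1.0
    return ProportionMatrix(P, mode="strict")


def mix(
    S: SignatureMatrix,
    P: ProportionMatrix,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Form bulk expression B = S @ P with multiplicative log-normal noise.

    The noise factors have unit mean and coefficient of variation
    ``noise_cv`` (sigma^2 = log(1 + cv^2), mu = -sigma^2/2), so expected
    signal is unchanged and noise scales with expression. noise_cv = 0
    returns the exact product.
    """
    if S.shape[1] != P.shape[0] or S.cell_type_ids != P.cell_type_ids:
        raise MixDeconError(
            f"signature cell types {S.cell_type_ids} do not align with proportion rows "
            f"{P.cell_type_ids}"
        )
    clean = S.values @ P.values
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma2 = np.log1p(noise_cv**2)
        factors = rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=clean.shape)
        clean = clean * factors
    return ExpressionMatrix(pd.DataFrame(clean, index=S.gene_ids, columns=P.sample_ids))


def make_dataset(
    sig_design: SignatureDesign = SignatureDesign(),
    mix_design: MixtureDesign = MixtureDesign(),
) -> SyntheticDataset:
    """Compose signature, proportions and noisy bulk into one bundle.

    Deterministic under the designs' seeds; with noise_cv = 0 the bulk
    equals S_true @ P_true exactly.
    """
    S, markers = generate_signature(sig_design)
    P = generate_proportions(mix_design, cell_types=sig_design.cell_types)
    # decorrelate mixing noise from the proportion draw deterministically
    B = mix(S, P, noise_cv=mix_design.noise_cv, seed=mix_design.seed + 1_000_003)
    return SyntheticDataset(B=B, S_true=S, P_true=P, marker_truth=markers,
                            sig_design=sig_design, mix_design=mix_design)
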