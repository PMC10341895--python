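"""Static figures rendered from the evaluation tables.

Three views: a correlation heatmap (corrplot), per-type dot series of real
vs estimated proportions (cell-signature plot), and stacked bars of the
mixture composition per sample (bar-mixture plot). The figures are
conveniences; the long-format tables in :mod:`mixdecon.evaluate` are the
tested contract.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .evaluate import EvaluationReport  # noqa: E402

__all__ = ["plot_corr_matrix", "plot_cell_signature", "plot_bar_mixture", "render_report"]


def plot_corr_matrix(corr: pd.DataFrame, path: str | Path, title: str = "") -> Path:
    fig, ax = plt.subplots(figsize=(1.0 + 0.6 * corr.shape[1], 1.0 + 0.6 * corr.shape[0]))
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(corr.shape[1]), corr.columns, rotation=90)
    ax.set_yticks(range(corr.shape[0]), corr.index)
    ax.set_xlabel("estimated")
    ax.set_ylabel("real")
    for i in range(corr.shape[0]):
        for j in range(corr.shape[1]):
            ax.text(j, i, f"{corr.iat[i, j]:.2f}", ha="center", va="center", fontsize=7)
    fig.colorbar(im, ax=ax, shrink=0.8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_cell_signature(table: pd.DataFrame, rmse: float, path: str | Path,
                        cell_type: str = "") -> Path:
    fig, ax = plt.subplots(figsize=(6, 3))
    x = np.arange(len(table))
    ax.plot(x, table["real"], "s-", color="tab:blue", label="Real")
    ax.plot(x, table["estimated"], "o-", color="tab:red", label="Estimated")
    ax.set_xticks(x, table["sample"], rotation=90)
    ax.set_ylabel("proportion")
    ax.set_title(f"{cell_type}  RMSE = {rmse:.3g}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_bar_mixture(table: pd.DataFrame, path: str | Path, title: str = "") -> Path:
    samples = list(dict.fromkeys(table["sample"]))
    types = list(dict.fromkeys(table["cell_type"]))
    cmap = plt.get_cmap("tab10")
    fig, ax = plt.subplots(figsize=(1.5 + 0.7 * len(samples), 4))
    width = 0.38
    for off, (source, alpha) in enumerate((("estimated", 1.0), ("real", 0.45))):
        sub = table[table["source"] == source].pivot(
            index="sample", columns="cell_type", values="proportion"
        ).loc[samples, types]
        bottom = np.zeros(len(samples))
        for k, ct in enumerate(types):
            vals = sub[ct].to_numpy()
            ax.bar(np.arange(len(samples)) + (off - 0.5) * width, vals, width,
                   bottom=bottom, color=cmap(k % 10), alpha=alpha,
                   label=ct if off == 0 else None)
            bottom += vals
    ax.set_xticks(range(len(samples)), samples, rotation=90)
    ax.set_ylabel("proportion")
    ax.legend(fontsize=7, ncols=min(len(types), 4))
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def render_report(report: EvaluationReport, outdir: str | Path, method: str = "") -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = [plot_corr_matrix(report.corr_matrix, outdir / "corr_matrix.png", title=method)]
    paths.append(plot_bar_mixture(report.bar_mixture, outdir / "bar_mixture.png", title=method))
    for ct, table in report.cell_signature.items():
        safe = str(ct).replace("/", "_").replace(" ", "_")
        paths.append(
            plot_cell_signature(table, float(report.rmse_per_type[ct]),
                                outdir / f"cell_signature_{safe}.png", cell_type=str(ct))
        )
    return paths
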