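"""Ensemble comparison statistics.

Distributions of a per-geometry metric (typically interchromosomal DSB
clustering) are compared between two groups with a two-sided two-sample
Kolmogorov-Smirnov test at every (LET, cluster radius) grid cell, and
p-values are Benjamini-Hochberg adjusted across the whole grid of one
comparison pair.  Cells are classed with the conventional significance
colours: red p > 0.05, purple 0.01 < p <= 0.05, yellow
0.001 < p <= 0.01, green p <= 0.001.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ks_two_sided",
    "bh_adjust",
    "significance_grid",
    "SignificanceGrid",
    "classify_p",
]


def ks_two_sided(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided two-sample KS test (asymptotic p-value).

    D = sup |ECDF_a - ECDF_b|; the null hypothesis is that both samples
    are drawn from the same continuous distribution.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("samples must be non-empty")
    res = sstats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    Standard p * m / rank with cumulative-minimum monotonicity
    enforcement, capped at 1; adjusted values are never below raw ones.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)


def classify_p(p: float) -> str:
    if p > 0.05:
        return "red"
    if p > 0.01:
        return "purple"
    if p > 0.001:
        return "yellow"
    return "green"


@dataclass
class SignificanceGrid:
    """LET x cluster-radius grid of group comparisons.

    ``mean_diff[i, j]`` is mean(group_a) - mean(group_b) at
    (lets[i], radii_nm[j]); ``p_adj`` the BH-adjusted KS p-value and
    ``classes`` its significance colour."""

    lets: np.ndarray
    radii_nm: np.ndarray
    mean_diff: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    classes: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, let in enumerate(self.lets):
            for j, radius in enumerate(self.radii_nm):
                rows.append(
                    (
                        float(let),
                        float(radius),
                        float(self.mean_diff[i, j]),
                        float(self.p_raw[i, j]),
                        float(self.p_adj[i, j]),
                        str(self.classes[i, j]),
                    )
                )
        return pd.DataFrame(
            rows,
            columns=["let_kev_um", "radius_nm", "mean_diff", "p_raw", "p_adj", "class"],
        )

    def plot(self, path) -> None:
        """Heat map of mean differences coloured by significance class."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.colors import ListedColormap

        order = ["red", "purple", "yellow", "green"]
        codes = np.vectorize(order.index)(self.classes)
        fig, ax = plt.subplots(figsize=(1.2 * len(self.radii_nm) + 2, 0.6 * len(self.lets) + 2))
        ax.imshow(codes, cmap=ListedColormap(order), vmin=0, vmax=3, aspect="auto")
        for i in range(len(self.lets)):
            for j in range(len(self.radii_nm)):
                ax.text(j, i, f"{self.mean_diff[i, j]:.3g}", ha="center", va="center", fontsize=7)
        ax.set_xticks(range(len(self.radii_nm)), [f"{r:g}" for r in self.radii_nm])
        ax.set_yticks(range(len(self.lets)), [f"{l:g}" for l in self.lets])
        ax.set_xlabel("cluster radius (nm)")
        ax.set_ylabel("LET (keV/um)")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def significance_grid(
    group_a: np.ndarray,
    group_b: np.ndarray,
    lets: Sequence[float],
    radii_nm: Sequence[float],
) -> SignificanceGrid:
    """Compare two groups of per-geometry metrics over a LET x radius grid.

    ``group_a``/``group_b`` are arrays of shape (n_lets, n_radii,
    n_geometries): one metric value per geometry per grid cell.  BH
    adjustment spans all cells of this comparison pair.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    lets = np.asarray(lets, dtype=float)
    radii_nm = np.asarray(radii_nm, dtype=float)
    shape = (len(lets), len(radii_nm))
    if a.shape[:2] != shape or b.shape[:2] != shape:
        raise ValueError(
            f"group arrays must have shape (n_lets={shape[0]}, n_radii={shape[1]}, n_geom)"
        )
    p_raw = np.empty(shape)
    diff = np.empty(shape)
    for i in range(shape[0]):
        for j in range(shape[1]):
            _, p = ks_two_sided(a[i, j], b[i, j])
            p_raw[i, j] = p
            diff[i, j] = float(np.mean(a[i, j]) - np.mean(b[i, j]))
    p_adj = bh_adjust(p_raw)
    classes = np.vectorize(classify_p)(p_adj)
    return SignificanceGrid(lets, radii_nm, diff, p_raw, p_adj, classes)
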