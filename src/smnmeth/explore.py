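"""Unsupervised structure: PCA and hierarchical clustering of samples.

Samples are observations, CpG sites are variables. PCA follows the
FactoMineR convention of standardized variables by default; clustering
uses Ward linkage on Euclidean distances (the ward.D2 convention:
distances are not pre-squared), which scipy's ``linkage(method="ward")``
implements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .types import MethylationMatrix


def _complete_data(
    matrix: MethylationMatrix, missing: str, standardize: bool
) -> tuple[pd.DataFrame, list[str]]:
    """Samples x sites table with no missing cells.

    ``missing="drop"`` removes sites with any missing value (reported);
    ``missing="mean"`` imputes the site mean. Zero-variance sites are
    dropped when standardizing (they carry no direction and would divide
    by zero)."""
    X = matrix.percent.T  # samples x sites
    dropped: list[str] = []
    if missing == "drop":
        incomplete = X.columns[X.isna().any()]
        dropped = list(incomplete)
        X = X.drop(columns=incomplete)
    elif missing == "mean":
        X = X.fillna(X.mean())
    else:
        raise ValueError(f"unknown missing policy {missing!r}")
    if standardize:
        sd = X.std(ddof=1)
        flat = X.columns[(sd == 0) | sd.isna()]
        dropped += list(flat)
        X = X.drop(columns=flat)
    return X, dropped


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # sites x components
    variance_explained: np.ndarray  # percent, sums to 100
    dropped_sites: list[str]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca(
    matrix: MethylationMatrix, standardize: bool = True, missing: str = "drop"
) -> PcaResult:
    """Centered (and by default unit-scaled) SVD of samples x sites.

    Components are ordered by decreasing variance; each component's sign
    is fixed so that its largest-magnitude loading is positive, making
    score tables reproducible. ``scores @ loadings.T`` reconstructs the
    centered/scaled data.
    """
    if matrix.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    X, dropped = _complete_data(matrix, missing, standardize)
    vals = X.to_numpy(dtype=float)
    vals = vals - vals.mean(axis=0)
    if standardize:
        vals = vals / X.std(ddof=1).to_numpy()
    U, s, Vt = np.linalg.svd(vals, full_matrices=False)
    keep = s > s[0] * 1e-12 if s.size and s[0] > 0 else np.zeros(s.size, bool)
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    # sign convention: largest-|loading| positive per component
    for k in range(s.size):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    comp_names = [f"PC{k + 1}" for k in range(s.size)]
    scores = pd.DataFrame(U * s, index=X.index, columns=comp_names)
    loadings = pd.DataFrame(Vt.T, index=X.columns, columns=comp_names)
    var = s**2
    var_explained = 100.0 * var / var.sum() if var.sum() > 0 else var
    return PcaResult(scores, loadings, var_explained, dropped)


@dataclass
class ClusterResult:
    """Sample dendrogram from Ward (ward.D2) agglomeration."""

    linkage_matrix: np.ndarray  # scipy linkage format
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in leaves_list(self.linkage_matrix)]

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with merge heights as branch depths."""
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        text = {i: self.labels[i] for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.linkage_matrix):
            a, b = int(a), int(b)
            la = text[a] + f":{h - height[a]:.6g}"
            lb = text[b] + f":{h - height[b]:.6g}"
            text[n + k] = f"({la},{lb})"
            height[n + k] = h
        return text[n + len(self.linkage_matrix) - 1] + ";"


def hclust_ward(
    matrix: MethylationMatrix, standardize: bool = False, missing: str = "drop"
) -> ClusterResult:
    """Agglomerative Ward clustering of samples on Euclidean distances.

    Uses the ward.D2 convention (squared-distance updates on unsquared
    input distances). Ties are broken deterministically by scipy's
    nearest-neighbor chain order.
    """
    if matrix.n_samples < 2:
        raise ValueError("clustering needs at least 2 samples")
    X, _ = _complete_data(matrix, missing, standardize)
    Z = linkage(X.to_numpy(dtype=float), method="ward")
    return ClusterResult(Z, list(X.index))


def export_heatmap_data(
    matrix: MethylationMatrix,
    cluster: ClusterResult,
    sample_annotations: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Samples x sites table in dendrogram leaf order with annotation
    columns (tissue, sex, type, ...) prepended, ready for heatmap
    rendering. Annotation rows naming samples absent from the matrix are
    an error."""
    order = cluster.leaf_order
    out = matrix.percent.T.loc[order]
    if sample_annotations is not None:
        unknown = set(sample_annotations.index) - set(matrix.samples)
        if unknown:
            raise ValueError(f"annotations for unknown samples: {sorted(unknown)}")
        out = pd.concat([sample_annotations.reindex(order), out], axis=1)
    return out
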