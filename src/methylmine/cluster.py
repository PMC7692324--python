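"""Semi-unsupervised hierarchical clustering of filtered probes.

"Semi-unsupervised" means rows (probes) are clustered by similarity while
columns (samples) stay grouped by their known (cancer, tissue) labels, so
the heatmap exposes which probe clusters track which cohorts.  Clustering
is agglomerative with Euclidean distance and average linkage by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


@dataclass
class ClusterResult:
    probe_order: list[str]
    merge_tree: np.ndarray  # scipy linkage matrix (n-1, 4)
    metric_name: str
    linkage_name: str
    item_ids: list[str]

    def to_newick(self) -> str:
        """Merge tree as a Newick string (leaf names = item ids)."""
        root = hierarchy.to_tree(self.merge_tree)

        def walk(node) -> str:
            if node.is_leaf():
                return self.item_ids[node.id]
            left, right = walk(node.left), walk(node.right)
            return f"({left}:{node.dist:.6g},{right}:{node.dist:.6g})"

        return walk(root) + ";"


def hierarchical_order(
    matrix: pd.DataFrame,
    axis: str = "rows",
    metric: str = "euclidean",
    linkage: str = "average",
) -> ClusterResult:
    """Cluster one axis of the matrix and return the leaf order.

    Missing values are mean-imputed per probe (row) before distances.
    Leaf order is scipy's deterministic dendrogram order; merge heights of
    average linkage are non-decreasing.
    """
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    data = matrix if axis == "rows" else matrix.T
    if data.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    values = data.to_numpy(dtype=float)
    # per-probe mean imputation keeps distances defined with missing cells
    row_means = np.nanmean(np.where(np.isnan(values), np.nan, values), axis=1)
    row_means = np.where(np.isnan(row_means), 0.0, row_means)
    idx = np.where(np.isnan(values))
    values[idx] = row_means[idx[0]]
    dist = pdist(values, metric=metric)
    tree = hierarchy.linkage(dist, method=linkage)
    order = hierarchy.leaves_list(tree)
    ids = [str(i) for i in data.index]
    return ClusterResult(
        probe_order=[ids[i] for i in order],
        merge_tree=tree,
        metric_name=metric,
        linkage_name=linkage,
        item_ids=ids,
    )


def grouped_column_order(manifest: pd.DataFrame, samples) -> list[str]:
    """Samples ordered in (cancer, tissue) blocks, stable within each group."""
    keys = {s: (manifest.at[s, "cancer_code"], manifest.at[s, "tissue_type"])
            for s in samples}
    block_order = list(dict.fromkeys(keys.values()))
    return [s for block in block_order for s in samples if keys[s] == block]


def heatmap_export(
    matrix: pd.DataFrame,
    row_order: list[str],
    column_order: list[str],
    path: str | Path,
    tsv_path: str | Path | None = None,
) -> pd.DataFrame:
    """Render a heatmap with fixed column blocks and write the reordered TSV.

    ``row_order`` and ``column_order`` must be permutations of the matrix
    axes; the returned (and TSV-written) frame is the bit-exact reordered
    input.
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError("cannot render an empty matrix")
    if sorted(row_order) != sorted(matrix.index) or sorted(column_order) != sorted(matrix.columns):
        raise ValueError("orders must be permutations of the matrix axes")
    ordered = matrix.loc[row_order, column_order]
    if tsv_path is not None:
        out = ordered.copy()
        out.index.name = matrix.index.name or "probe_id"
        out.to_csv(tsv_path, sep="\t", na_rep="NA")

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    fig, ax = plt.subplots(figsize=(6, max(3, 0.08 * len(row_order))))
    sns.heatmap(ordered, cmap="RdYlBu_r", vmin=0, vmax=1,
                xticklabels=False, yticklabels=False, ax=ax,
                cbar_kws={"label": "beta value"})
    ax.set_xlabel("samples (grouped by cancer / tissue)")
    ax.set_ylabel("CpG probes (clustered)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return ordered
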