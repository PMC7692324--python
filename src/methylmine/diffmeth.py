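"""Per-CpG tumor-vs-normal differential methylation.

For each probe and cancer: a two-sided Mann–Whitney U test between the
tumor and normal beta values, Benjamini–Hochberg FDR adjustment across the
probes of the analysed subset, a log2 fold change of group mean betas, and
a volcano classification (hyper / hypo / not significant).  Typically run
on a pathway- and region-restricted matrix (e.g. CpG-island probes of a
gene set's promoters).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSet, subset_probes

VOLCANO_CLASSES = ("hyper", "hypo", "not_significant")


@dataclass(frozen=True)
class DiffMethOptions:
    """Cutoffs and modes for the comparative analysis.

    ``adjust='bh'`` gates the volcano call on BH FDR q < alpha (the default);
    ``adjust='none'`` gates on the raw p.  ``fc_mode`` selects mean- or
    median-ratio fold change.
    """

    alpha: float = 0.05
    fc_cut: float = 1.0
    adjust: str = "bh"  # "bh" | "none"
    fc_mode: str = "mean"  # "mean" | "median"
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.fc_cut <= 0:
            raise ValueError("fc_cut must be > 0")
        if self.adjust not in ("bh", "none"):
            raise ValueError("adjust must be 'bh' or 'none'")
        if self.fc_mode not in ("mean", "median"):
            raise ValueError("fc_mode must be 'mean' or 'median'")


def mann_whitney_u(tumor_values, normal_values) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    U counts (tumor, normal) pairs with tumor > normal, ties ½.  The p-value
    is exact (permutation distribution of U) whenever the pooled values are
    untied and the smaller group has at most 25 samples — beta values are
    continuous, so this is the common case and keeps the test's true size
    close to nominal; otherwise a normal approximation with tie and
    continuity correction is used.  Missing values are dropped first.
    """
    x = np.asarray(tumor_values, dtype=float)
    y = np.asarray(normal_values, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("Mann-Whitney test needs non-empty groups")
    # complete tie across both groups: U is its null mean, no evidence
    if np.ptp(np.concatenate([x, y])) == 0:
        return len(x) * len(y) / 2.0, 1.0
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if min(len(x), len(y)) <= 25 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log2_fold_change(tumor_values, normal_values, epsilon: float = 1e-6,
                     mode: str = "mean") -> float:
    """log2((m_T + eps) / (m_N + eps)) of group mean (or median) betas."""
    x = np.asarray(tumor_values, dtype=float)
    y = np.asarray(normal_values, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("fold change needs non-empty groups")
    agg = np.median if mode == "median" else np.mean
    return float(np.log2((agg(x) + epsilon) / (agg(y) + epsilon)))


def volcano_classify(q_or_p: float, log2_fc: float, alpha: float = 0.05,
                     fc_cut: float = 1.0) -> str:
    """hyper / hypo / not_significant from a significance value and log2 FC.

    Both cutoffs are strict: significance requires q_or_p < alpha, effect
    requires |log2_fc| > fc_cut.
    """
    if q_or_p < alpha:
        if log2_fc > fc_cut:
            return "hyper"
        if log2_fc < -fc_cut:
            return "hypo"
    return "not_significant"


def run_pathway_diffmeth(
    matrix: pd.DataFrame,
    manifest: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
    gene_set: GeneSet | None = None,
    options: DiffMethOptions = DiffMethOptions(),
    region_filter=(),
    promoter_only: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tumor-vs-normal test per probe per cancer on a pathway subset.

    When ``annotation``/``gene_set`` are given the matrix is first restricted
    with :func:`methylmine.io.subset_probes`.  BH adjustment is applied
    within each cancer across the retained probes of the subset.  Returns
    (records, summary): one record per probe per cancer with columns
    probe_id, cancer_code, u_statistic, p_value, q_value, log2_fc,
    neg_log10_p, volcano_class; and a per-cancer summary with n_hyper,
    n_hypo and n_genes (distinct gene symbols the significant probes
    annotate to).
    """
    if annotation is not None and (gene_set is not None or region_filter or promoter_only):
        matrix = subset_probes(matrix, annotation, gene_set, region_filter, promoter_only)
    if matrix.shape[0] == 0:
        warnings.warn("no probes retained after subsetting", stacklevel=2)
        empty = pd.DataFrame(columns=[
            "probe_id", "cancer_code", "u_statistic", "p_value", "q_value",
            "log2_fc", "neg_log10_p", "volcano_class"])
        return empty, pd.DataFrame(columns=["cancer_code", "n_hyper", "n_hypo", "n_genes"])

    codes = list(dict.fromkeys(manifest["cancer_code"]))
    rows = []
    for code in codes:
        t_cols = manifest.index[(manifest["cancer_code"] == code)
                                & (manifest["tissue_type"] == "primary_tumor")]
        n_cols = manifest.index[(manifest["cancer_code"] == code)
                                & (manifest["tissue_type"] == "normal_tissue")]
        t_cols = [c for c in t_cols if c in matrix.columns]
        n_cols = [c for c in n_cols if c in matrix.columns]
        if not t_cols or not n_cols:
            raise ValueError(f"cancer {code!r} lacks paired tumor/normal samples")
        tum = matrix[t_cols].to_numpy(dtype=float)
        nor = matrix[n_cols].to_numpy(dtype=float)
        p_vals, u_stats, lfcs = [], [], []
        for i in range(matrix.shape[0]):
            u, p = mann_whitney_u(tum[i], nor[i])
            u_stats.append(u)
            p_vals.append(p)
            lfcs.append(log2_fold_change(tum[i], nor[i], options.epsilon, options.fc_mode))
        q_vals = bh_adjust(p_vals)
        gate = q_vals if options.adjust == "bh" else np.asarray(p_vals)
        for probe, u, p, q, g, lfc in zip(matrix.index, u_stats, p_vals, q_vals, gate, lfcs):
            rows.append({
                "probe_id": probe, "cancer_code": code, "u_statistic": u,
                "p_value": p, "q_value": q, "log2_fc": lfc,
                "neg_log10_p": -np.log10(max(p, 1e-300)),
                "volcano_class": volcano_classify(g, lfc, options.alpha, options.fc_cut),
            })
    records = pd.DataFrame(rows)

    def _genes_of(probes) -> int:
        if annotation is None:
            return 0
        syms: set[str] = set()
        for p in probes:
            if p in annotation.index:
                gs = annotation.at[p, "gene_symbols"]
                if isinstance(gs, tuple):
                    syms.update(g.upper() for g in gs)
        return len(syms)

    summary_rows = []
    for code in codes:
        sub = records[records["cancer_code"] == code]
        sig = sub[sub["volcano_class"] != "not_significant"]
        summary_rows.append({
            "cancer_code": code,
            "n_hyper": int((sub["volcano_class"] == "hyper").sum()),
            "n_hypo": int((sub["volcano_class"] == "hypo").sum()),
            "n_genes": _genes_of(sig["probe_id"]),
        })
    return records, pd.DataFrame(summary_rows)


def write_records(records: pd.DataFrame, path: str | Path,
                  options: DiffMethOptions = DiffMethOptions()) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# adjust={options.adjust}\talpha={options.alpha}\t"
                 f"fc_cut={options.fc_cut}\tfc_mode={options.fc_mode}\n")
        records.to_csv(fh, sep="\t", index=False)


def volcano_plot(records: pd.DataFrame, path: str | Path,
                 options: DiffMethOptions = DiffMethOptions()) -> None:
    """Volcano scatter (log2 FC vs -log10 p) with dashed cutoff lines.

    Hypermethylated probes green, hypomethylated red, the rest grey.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"hyper": "green", "hypo": "red", "not_significant": "0.6"}
    fig, ax = plt.subplots(figsize=(5, 4))
    for cls, col in colors.items():
        sub = records[records["volcano_class"] == cls]
        ax.scatter(sub["log2_fc"], sub["neg_log10_p"], s=8, c=col, label=cls)
    ax.axvline(options.fc_cut, ls="--", c="k", lw=0.8)
    ax.axvline(-options.fc_cut, ls="--", c="k", lw=0.8)
    ax.axhline(-np.log10(options.alpha), ls="--", c="k", lw=0.8)
    ax.set_xlabel("log2 fold change (beta)")
    ax.set_ylabel("-log10 p")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
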