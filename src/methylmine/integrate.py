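"""Pair filtered CpG probes with expression features and correlate.

Each probe is matched, via its annotated gene symbols, to every expression
feature of those genes; Pearson correlation is computed per pair over the
shared samples.  Promoter methylation typically represses transcription, so
strong pairs are expected to be negatively correlated.  Expression is
log2(FPKM + 1)-transformed before correlation by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProbeTranscriptPair:
    probe_id: str
    feature_id: str
    gene_symbol: str
    r: float = float("nan")
    n: int = 0

    @property
    def direction(self) -> str:
        return "negative" if self.r < 0 else "positive"


def match_probe_transcript(
    annotation: pd.DataFrame,
    beta: pd.DataFrame,
    expression: pd.DataFrame,
    feature_gene_map: dict[str, str] | None = None,
) -> list[ProbeTranscriptPair]:
    """Candidate (probe, expression feature) pairs sharing an annotated gene.

    ``feature_gene_map`` maps expression feature ids to gene symbols; when
    omitted, feature ids are taken to be gene symbols (gene-level matrix).
    Pairs need >=3 shared samples between the two matrices.
    """
    shared = [s for s in beta.columns if s in set(expression.columns)]
    if not shared:
        raise ValueError("beta and expression matrices share no samples")
    if feature_gene_map is None:
        feature_gene_map = {f: f for f in expression.index}
    by_gene: dict[str, list[str]] = {}
    for feat, gene in feature_gene_map.items():
        if feat in expression.index:
            by_gene.setdefault(gene.upper(), []).append(feat)

    pairs: list[ProbeTranscriptPair] = []
    for probe in beta.index:
        if probe not in annotation.index:
            continue
        genes = annotation.at[probe, "gene_symbols"]
        if not isinstance(genes, tuple):
            continue
        for gene in genes:
            for feat in by_gene.get(gene.upper(), []):
                n = int(
                    (~beta.loc[probe, shared].isna()
                     & ~expression.loc[feat, shared].isna()).sum()
                )
                if n >= 3:
                    pairs.append(ProbeTranscriptPair(str(probe), str(feat), gene, n=n))
    return pairs


def correlate_pairs(
    pairs: list[ProbeTranscriptPair],
    beta: pd.DataFrame,
    expression: pd.DataFrame,
    cutoff: float = 0.6,
    log_transform: bool = True,
) -> list[ProbeTranscriptPair]:
    """Pearson r per pair on shared non-missing samples; keep |r| >= cutoff.

    A pair with zero variance in either vector is dropped (r undefined) with
    a logged reason.  Expression is log2(FPKM+1)-transformed unless
    ``log_transform`` is False.
    """
    if not 0 <= cutoff <= 1:
        raise ValueError("cutoff must be in [0, 1]")
    shared = [s for s in beta.columns if s in set(expression.columns)]
    kept: list[ProbeTranscriptPair] = []
    for pair in pairs:
        b = beta.loc[pair.probe_id, shared].to_numpy(dtype=float)
        e = expression.loc[pair.feature_id, shared].to_numpy(dtype=float)
        if log_transform:
            e = np.log2(e + 1.0)
        ok = ~np.isnan(b) & ~np.isnan(e)
        b, e = b[ok], e[ok]
        if len(b) < 3:
            log.info("pair (%s, %s) dropped: <3 shared samples", pair.probe_id, pair.feature_id)
            continue
        if np.ptp(b) == 0 or np.ptp(e) == 0:
            log.info("pair (%s, %s) dropped: zero variance", pair.probe_id, pair.feature_id)
            continue
        r = float(stats.pearsonr(b, e).statistic)
        if abs(r) >= cutoff:
            kept.append(ProbeTranscriptPair(pair.probe_id, pair.feature_id,
                                            pair.gene_symbol, r=r, n=len(b)))
    return kept


def write_pairs(pairs: list[ProbeTranscriptPair], path: str | Path) -> None:
    """Pairs TSV (probe, feature, gene, r, n, direction).

    Header notes that r is a plain per-pair Pearson correlation on matched
    samples, not a latent-component correlation.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# method=pearson_per_pair\ttransform=log2(FPKM+1)\n")
        fh.write("probe_id\tfeature_id\tgene_symbol\tr\tn\tdirection\n")
        for p in pairs:
            fh.write(f"{p.probe_id}\t{p.feature_id}\t{p.gene_symbol}\t"
                     f"{p.r:.6g}\t{p.n}\t{p.direction}\n")
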