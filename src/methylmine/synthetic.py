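"""Synthetic multi-cancer methylation cohorts with planted class patterns.

Generates paired tumor/normal beta matrices for 2-12 cancer types in which
some probes carry a planted cancer- or tissue-specific hyper/hypomethylation
pattern and the rest are unstructured background.  Group beta values are
drawn from Beta distributions, honoring the [0, 1] support:

* ``high_state`` (default Beta(50, 5), mean ~0.909) for methylated groups,
* ``low_state`` (default Beta(2, 30), mean 0.0625) for unmethylated groups,
* ``mid_state`` (default Beta(10, 10), mean 0.5) for background probes.

The defaults give strong separation: the expected high-state mean clears
the 0.6 hyper threshold and the low-state mean sits below the 0.3 hypo
threshold, so the quartile filter should recover the truth table exactly.
Optionally, a matched expression matrix is generated with a planted
negative methylation-expression correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CALL_CLASSES
from .io import TISSUE_TYPES, GeneSet


@dataclass(frozen=True)
class SimulationConfig:
    cancer_codes: tuple[str, ...] = ("BRCA", "COAD", "LUSC", "PRAD")
    n_tumor: int = 20
    n_normal: int = 10
    n_background_probes: int = 500
    #: list of (call_class, target_cancer, count)
    planted: tuple[tuple[str, str, int], ...] = ()
    high_state: tuple[float, float] = (50.0, 5.0)
    low_state: tuple[float, float] = (2.0, 30.0)
    mid_state: tuple[float, float] = (10.0, 10.0)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= len(self.cancer_codes) <= 12:
            raise ValueError("need 2-12 cancer codes")
        if len(set(self.cancer_codes)) != len(self.cancer_codes):
            raise ValueError("duplicate cancer codes")
        if min(self.n_tumor, self.n_normal) < 1 or self.n_background_probes < 0:
            raise ValueError("counts must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        for shapes in (self.high_state, self.low_state, self.mid_state):
            if min(shapes) <= 0:
                raise ValueError("Beta shape parameters must be > 0")
        for cls, target, count in self.planted:
            if cls not in CALL_CLASSES:
                raise ValueError(f"unknown call class {cls!r}")
            if target not in self.cancer_codes:
                raise ValueError(f"planted target {target!r} not a cancer code")
            if count < 0:
                raise ValueError("planted counts must be >= 0")


@dataclass
class SimulatedCohort:
    beta: pd.DataFrame
    manifest: pd.DataFrame
    truth: pd.DataFrame  # probe_id, call_class, target_cancer (planted only)
    config: SimulationConfig
    annotation: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    expression: pd.DataFrame | None = None


def _default_pattern(cls: str, target: str, codes: tuple[str, ...]) -> dict[tuple[str, str], str]:
    """Which Beta state each (cancer, tissue) group draws from for a class."""
    t, n = TISSUE_TYPES
    state = {(c, tt): "low" for c in codes for tt in (t, n)}
    if cls == "cancer_hyper":
        state[(target, t)] = "high"
    elif cls == "cancer_hypo":
        state = {k: "high" for k in state}
        state[(target, t)] = "low"
    elif cls == "tissue_hyper":
        state[(target, t)] = "high"
        state[(target, n)] = "high"
    elif cls == "tissue_hypo":
        state = {k: "high" for k in state}
        state[(target, t)] = "low"
        state[(target, n)] = "low"
    return state


def _make_manifest(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for code in config.cancer_codes:
        for i in range(config.n_tumor):
            rows.append((f"{code}_T{i:03d}", code, "primary_tumor"))
        for i in range(config.n_normal):
            rows.append((f"{code}_N{i:03d}", code, "normal_tissue"))
    mf = pd.DataFrame(rows, columns=["sample_id", "cancer_code", "tissue_type"])
    return mf.set_index("sample_id")


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate beta matrix, manifest, truth table and probe annotation.

    One random stream drives the beta matrix, drawn probe-by-probe in a
    fixed order (planted probes first, then background), so increasing
    ``n_background_probes`` never perturbs the planted draws.  A second
    stream drives the missingness mask.  Bit-identical output for a fixed
    config.
    """
    manifest = _make_manifest(config)
    shapes = {"high": config.high_state, "low": config.low_state, "mid": config.mid_state}
    rng_beta = np.random.default_rng(config.seed)
    rng_miss = np.random.default_rng((config.seed, 1))

    group_cols = {
        (code, tissue): [s for s in manifest.index
                         if manifest.at[s, "cancer_code"] == code
                         and manifest.at[s, "tissue_type"] == tissue]
        for code in config.cancer_codes for tissue in TISSUE_TYPES
    }
    samples = list(manifest.index)
    col_of = {s: j for j, s in enumerate(samples)}

    rows, probe_ids, truth_rows = [], [], []
    k = 0
    for cls, target, count in config.planted:
        pattern = _default_pattern(cls, target, config.cancer_codes)
        for _ in range(count):
            probe = f"cgP{k:05d}"
            k += 1
            row = np.empty(len(samples))
            for key, cols in group_cols.items():
                a, b = shapes[pattern[key]]
                draws = rng_beta.beta(a, b, size=len(cols))
                for s, v in zip(cols, draws):
                    row[col_of[s]] = v
            rows.append(row)
            probe_ids.append(probe)
            truth_rows.append((probe, cls, target))
    for i in range(config.n_background_probes):
        probe = f"cgB{i:05d}"
        a, b = shapes["mid"]
        rows.append(rng_beta.beta(a, b, size=len(samples)))
        probe_ids.append(probe)

    beta = pd.DataFrame(np.vstack(rows) if rows else np.empty((0, len(samples))),
                        index=pd.Index(probe_ids, name="probe_id"), columns=samples)
    if config.missing_rate > 0:
        mask = rng_miss.random(beta.shape) < config.missing_rate
        beta = beta.mask(mask)

    truth = pd.DataFrame(truth_rows, columns=["probe_id", "call_class", "target_cancer"])
    annotation = _annotate(probe_ids, truth)
    return SimulatedCohort(beta=beta, manifest=manifest, truth=truth,
                           config=config, annotation=annotation)


def _annotate(probe_ids: list[str], truth: pd.DataFrame) -> pd.DataFrame:
    """Planted probes get one synthetic gene each (island, promoter);
    background probes are open-sea with no gene."""
    planted = set(truth["probe_id"])
    recs = []
    gene_i = 0
    for probe in probe_ids:
        if probe in planted:
            recs.append((probe, (f"GENE{gene_i:04d}",), "island", True))
            gene_i += 1
        else:
            recs.append((probe, (), "open_sea", False))
    ann = pd.DataFrame(recs, columns=["probe_id", "gene_symbols", "region_class",
                                      "promoter_associated"])
    return ann.set_index("probe_id")


def planted_gene_set(cohort: SimulatedCohort, name: str = "planted_pathway") -> GeneSet:
    """Gene set covering every planted probe's synthetic gene."""
    genes: list[str] = []
    for probe in cohort.truth["probe_id"]:
        genes.extend(cohort.annotation.at[probe, "gene_symbols"])
    return GeneSet(name, "synthetic planted genes", tuple(dict.fromkeys(genes)))


def simulate_expression(cohort: SimulatedCohort, rho: float = -0.9,
                        noise: float | None = None,
                        seed_offset: int = 2) -> pd.DataFrame:
    """Matched expression with planted methylation-expression correlation.

    For each planted probe's gene, a latent log2-expression is a decreasing
    (for negative rho) affine function of the standardized beta values plus
    Gaussian noise scaled so the expected Pearson correlation is ~rho; the
    latent value is mapped to non-negative FPKM as 2**latent - 1, so the
    log2(FPKM+1) transform used downstream recovers the latent exactly.
    ``noise`` overrides the derived noise standard deviation (0 => exact).
    """
    if not -1 <= rho <= 1 or abs(rho) > 1:
        raise ValueError("rho must lie in [-1, 1]")
    if abs(rho) == 1 and noise not in (None, 0):
        raise ValueError("|rho| = 1 requires zero noise")
    rng = np.random.default_rng((cohort.config.seed, seed_offset))
    noise_sd = float(np.sqrt(1 - rho ** 2)) if noise is None else float(noise)
    samples = list(cohort.beta.columns)
    feats, rows = [], []
    for probe in cohort.truth["probe_id"]:
        genes = cohort.annotation.at[probe, "gene_symbols"]
        if not genes:
            continue
        b = cohort.beta.loc[probe, samples].to_numpy(dtype=float)
        filled = np.where(np.isnan(b), np.nanmean(b), b)
        sd = filled.std()
        z = (filled - filled.mean()) / sd if sd > 0 else np.zeros_like(filled)
        latent = rho * z + noise_sd * rng.standard_normal(len(samples))
        log2_expr = np.clip(5.0 + latent, 0.0, None)  # mean log2 FPKM ~ 5
        feats.append(genes[0])
        rows.append(np.power(2.0, log2_expr) - 1.0)
    expr = pd.DataFrame(np.vstack(rows) if rows else np.empty((0, len(samples))),
                        index=pd.Index(feats, name="feature_id"), columns=samples)
    cohort.expression = expr
    return expr


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    """Write beta/manifest/annotation/truth (and expression) in the TSV/CSV
    dialects the readers accept, plus a GMT of the planted genes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": outdir / "beta.tsv",
        "manifest": outdir / "manifest.tsv",
        "annotation": outdir / "annotation.csv",
        "truth": outdir / "truth.tsv",
        "gene_sets": outdir / "planted.gmt",
    }
    cohort.beta.to_csv(paths["beta"], sep="\t", na_rep="NA")
    cohort.manifest.reset_index().to_csv(paths["manifest"], sep="\t", index=False)
    ann = cohort.annotation
    relation = {"island": "Island", "shore": "N_Shore", "shelf": "N_Shelf", "open_sea": ""}
    pd.DataFrame({
        "IlmnID": ann.index,
        "UCSC_RefGene_Name": [";".join(g) for g in ann["gene_symbols"]],
        "UCSC_RefGene_Group": ["TSS200" if p else "" for p in ann["promoter_associated"]],
        "Relation_to_UCSC_CpG_Island": [relation[r] for r in ann["region_class"]],
    }).to_csv(paths["annotation"], index=False)
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["gene_sets"], "w", encoding="utf-8") as fh:
        if len(cohort.truth):
            gs = planted_gene_set(cohort)
            fh.write(f"{gs.name}\t{gs.description}\t" + "\t".join(gs.gene_symbols) + "\n")
    if cohort.expression is not None:
        paths["expression"] = outdir / "expression.tsv"
        cohort.expression.to_csv(paths["expression"], sep="\t", na_rep="NA")
    return paths
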