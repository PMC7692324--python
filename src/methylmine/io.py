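"""Readers, writers and probe-annotation utilities.

Matrices are plain :class:`pandas.DataFrame` objects with probes (or
expression features) in rows and samples in columns.  Beta values live in
[0, 1] with ``NaN`` marking missing cells; FPKM values are non-negative.
The sample manifest maps every sample to a cancer code and a tissue type
(``primary_tumor`` or ``normal_tissue``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TISSUE_TYPES = ("primary_tumor", "normal_tissue")
REGION_CLASSES = ("island", "shore", "shelf", "open_sea")

#: 450K manifest Relation_to_UCSC_CpG_Island values -> region class
_ISLAND_RELATION = {
    "island": "island",
    "n_shore": "shore",
    "s_shore": "shore",
    "n_shelf": "shelf",
    "s_shelf": "shelf",
    "": "open_sea",
    "opensea": "open_sea",
    "open_sea": "open_sea",
}

#: UCSC_RefGene_Group values counted as promoter-associated
_PROMOTER_GROUPS = {"tss200", "tss1500", "5'utr"}


@dataclass(frozen=True)
class GeneSet:
    """A named pathway gene list (GMT line)."""

    name: str
    description: str
    gene_symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.gene_symbols:
            raise ValueError(f"gene set {self.name!r} has no genes")

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in {g.upper() for g in self.gene_symbols}


def _check_unique(values: Iterable[str], kind: str, path: str | Path) -> None:
    seen: set[str] = set()
    dupes = set()
    for v in values:
        if v in seen:
            dupes.add(v)
        seen.add(v)
    if dupes:
        raise ValueError(f"{path}: duplicate {kind} id(s): {sorted(dupes)[:5]}")


def _check_header_unique(path: str | Path) -> None:
    # pandas mangles duplicate header names, so inspect the raw line
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    _check_unique(header[1:], "sample", path)


def read_beta_matrix(path: str | Path, missing_token: str = "NA") -> pd.DataFrame:
    """Read a probes x samples beta-value TSV.

    First column holds probe ids, the header row sample ids.  Cells equal to
    ``missing_token`` become NaN.  Any value outside [0, 1] is a hard error
    naming the offending probe, sample and value.
    """
    _check_header_unique(path)
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=[missing_token], keep_default_na=False
    )
    df.index = df.index.astype(str)
    df.index.name = "probe_id"
    df.columns = df.columns.astype(str)
    _check_unique(df.index, "probe", path)
    _check_unique(df.columns, "sample", path)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric beta value: {exc}") from exc
    bad = (df < 0) | (df > 1)
    if bad.any().any():
        probe = df.index[bad.any(axis=1)][0]
        sample = df.columns[bad.loc[probe].fillna(False)][0]
        raise ValueError(
            f"{path}: beta value out of [0,1] at probe {probe!r}, "
            f"sample {sample!r}: {df.loc[probe, sample]}"
        )
    return df


def write_beta_matrix(matrix: pd.DataFrame, path: str | Path, missing_token: str = "NA") -> None:
    """TSV writer; round-trips bit-identically with :func:`read_beta_matrix`."""
    out = matrix.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", na_rep=missing_token)


def read_expression_matrix(path: str | Path, missing_token: str = "NA") -> pd.DataFrame:
    """Read a features x samples FPKM TSV; values must be non-negative."""
    _check_header_unique(path)
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=[missing_token], keep_default_na=False
    )
    df.index = df.index.astype(str)
    df.index.name = "feature_id"
    df.columns = df.columns.astype(str)
    _check_unique(df.index, "feature", path)
    _check_unique(df.columns, "sample", path)
    df = df.astype(float)
    if (df < 0).any().any():
        feat = df.index[(df < 0).any(axis=1)][0]
        raise ValueError(f"{path}: negative FPKM value at feature {feat!r}")
    return df


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read the sample manifest TSV (sample_id, cancer_code, tissue_type)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "cancer_code", "tissue_type"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: manifest needs columns {sorted(required)}")
    _check_unique(df["sample_id"], "sample", path)
    bad_tissue = set(df["tissue_type"]) - set(TISSUE_TYPES)
    if bad_tissue:
        raise ValueError(f"{path}: unknown tissue_type(s) {sorted(bad_tissue)}")
    return df.set_index("sample_id")[["cancer_code", "tissue_type"]]


def validate_manifest_groups(manifest: pd.DataFrame) -> list[str]:
    """Return cancer codes in manifest order; error if any lacks a tissue type."""
    codes = list(dict.fromkeys(manifest["cancer_code"]))
    for code in codes:
        tissues = set(manifest.loc[manifest["cancer_code"] == code, "tissue_type"])
        missing = set(TISSUE_TYPES) - tissues
        if missing:
            raise ValueError(
                f"cancer {code!r} has no {'/'.join(sorted(missing))} samples"
            )
    return codes


def merge_matrices(
    per_sample_files: Sequence[str | Path],
    manifest: pd.DataFrame,
    missing_token: str = "NA",
    how: str = "intersection",
) -> pd.DataFrame:
    """Merge per-sample beta TSVs into one matrix.

    Keeps the intersection of probes by default (450K files share a platform
    manifest, so loss is normally nil); ``how='union'`` keeps the union with
    missing cells.  Column order follows manifest order; a sample absent from
    the manifest is an error.
    """
    if how not in ("intersection", "union"):
        raise ValueError(f"unknown merge mode {how!r}")
    frames = [read_beta_matrix(f, missing_token) for f in per_sample_files]
    all_samples = [s for f in frames for s in f.columns]
    _check_unique(all_samples, "sample", "merge")
    unknown = set(all_samples) - set(manifest.index)
    if unknown:
        raise ValueError(f"sample(s) not in manifest: {sorted(unknown)[:5]}")
    if how == "intersection":
        probes = frames[0].index
        for f in frames[1:]:
            probes = probes.intersection(f.index)
        if len(probes) == 0:
            raise ValueError("empty probe intersection across input files")
        frames = [f.loc[probes] for f in frames]
        merged = pd.concat(frames, axis=1)
    else:
        merged = pd.concat(frames, axis=1, join="outer")
    order = [s for s in manifest.index if s in set(all_samples)]
    merged = merged[order]
    merged.index.name = "probe_id"
    return merged


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a 450K-style probe annotation CSV.

    Expects columns ``IlmnID``, ``UCSC_RefGene_Name``, ``UCSC_RefGene_Group``,
    ``Relation_to_UCSC_CpG_Island``.  Returns a frame indexed by probe_id with
    columns ``gene_symbols`` (tuple), ``region_class`` (island/shore/shelf/
    open_sea) and ``promoter_associated`` (bool: any TSS200/TSS1500/5'UTR
    mapping).
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {
        "IlmnID",
        "UCSC_RefGene_Name",
        "UCSC_RefGene_Group",
        "Relation_to_UCSC_CpG_Island",
    }
    if not required.issubset(raw.columns):
        raise ValueError(f"{path}: annotation needs columns {sorted(required)}")
    _check_unique(raw["IlmnID"], "probe", path)

    def _genes(cell: str) -> tuple[str, ...]:
        return tuple(dict.fromkeys(g for g in cell.split(";") if g))

    def _region(cell: str) -> str:
        key = cell.strip().lower()
        if key not in _ISLAND_RELATION:
            raise ValueError(f"{path}: unknown island relation {cell!r}")
        return _ISLAND_RELATION[key]

    def _promoter(cell: str) -> bool:
        return any(g.strip().lower() in _PROMOTER_GROUPS for g in cell.split(";") if g)

    ann = pd.DataFrame(
        {
            "gene_symbols": [_genes(c) for c in raw["UCSC_RefGene_Name"]],
            "region_class": [_region(c) for c in raw["Relation_to_UCSC_CpG_Island"]],
            "promoter_associated": [_promoter(c) for c in raw["UCSC_RefGene_Group"]],
        },
        index=pd.Index(raw["IlmnID"].astype(str), name="probe_id"),
    )
    return ann


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: name <tab> description <tab> gene [<tab> gene ...]."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has <3 fields")
            genes: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                if g and g.upper() not in seen:
                    seen.add(g.upper())
                    genes.append(g)
            sets.append(GeneSet(fields[0], fields[1], tuple(genes)))
    return sets


def subset_probes(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    gene_set: GeneSet | Sequence[str] | None,
    region_filter: Iterable[str] = (),
    promoter_only: bool = False,
) -> pd.DataFrame:
    """Restrict a beta matrix to probes matching a gene set and region filter.

    Gene matching is case-insensitive exact match on any annotated symbol.
    ``region_filter`` is a subset of island/shore/shelf/open_sea (empty means
    no region restriction); ``promoter_only`` additionally requires a
    promoter-associated gene-region mapping.  Probe order is preserved.
    """
    regions = set(region_filter)
    bad = regions - set(REGION_CLASSES)
    if bad:
        raise ValueError(f"unknown region class(es) {sorted(bad)}")
    if gene_set is None:
        wanted = None
    elif isinstance(gene_set, GeneSet):
        wanted = {g.upper() for g in gene_set.gene_symbols}
    else:
        wanted = {g.upper() for g in gene_set}

    keep: list[str] = []
    ann = annotation.reindex(matrix.index)
    for probe, row in ann.iterrows():
        if not isinstance(row["gene_symbols"], tuple):  # probe not annotated
            continue
        if wanted is not None and not any(
            g.upper() in wanted for g in row["gene_symbols"]
        ):
            continue
        if regions and row["region_class"] not in regions:
            continue
        if promoter_only and not row["promoter_associated"]:
            continue
        keep.append(probe)
    if not keep:
        warnings.warn("probe subset is empty", stacklevel=2)
    return matrix.loc[keep]
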