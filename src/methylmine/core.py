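"""Quartile-based classification of CpG probes across multiple cancers.

For each probe, per-group first and third quartiles (Q1/Q3) of the beta
values are computed for every (cancer, tissue) group.  A probe is then
classified, per target cancer, into one of four classes by comparing those
quartiles against a hyper threshold (default 0.6) and a hypo threshold
(default 0.3):

``cancer_hyper``
    >75% of the target cancer's tumor samples above the hyper threshold
    (Q1 > hyper) while the target's normal tissue and every other cancer's
    tumor and normal groups sit below the hypo threshold (Q3 < hypo).
``cancer_hypo``
    the mirror image: target tumor Q3 < hypo, everything else Q1 > hyper.
``tissue_hyper``
    both tumor and normal of the target cancer high (Q1 > hyper) while
    every other cancer's groups are low (Q3 < hypo).
``tissue_hypo``
    both target groups low (Q3 < hypo), all other cancers high (Q1 > hyper).

All inequalities are strict; boundary-equal quartiles never fire a rule.
The quartile rules mean at least 75% of a group's samples lie on the stated
side of the threshold, which is what makes the selection robust to outliers
without any distributional assumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .io import TISSUE_TYPES, validate_manifest_groups

CALL_CLASSES = ("cancer_hyper", "cancer_hypo", "tissue_hyper", "tissue_hypo")

#: Table-style export labels for the four classes
CLASS_LABELS = {
    "cancer_hyper": "Cancer-specific hypermethylation",
    "cancer_hypo": "Cancer-specific hypomethylation",
    "tissue_hyper": "Tissue-specific hypermethylation",
    "tissue_hypo": "Tissue-specific hypomethylation",
}

_QUANTILE_METHODS = {"linear": "linear", "nearest": "closest_observation"}


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds and options for the quartile filter."""

    hyper_threshold: float = 0.6
    hypo_threshold: float = 0.3
    min_group_size: int = 2
    quantile_method: str = "linear"
    max_cancers: int = 12

    def __post_init__(self) -> None:
        if not (0 <= self.hypo_threshold < self.hyper_threshold <= 1):
            raise ValueError(
                "need 0 <= hypo_threshold < hyper_threshold <= 1, got "
                f"({self.hypo_threshold}, {self.hyper_threshold})"
            )
        if self.min_group_size < 1:
            raise ValueError("min_group_size must be >= 1")
        if self.quantile_method not in _QUANTILE_METHODS:
            raise ValueError(
                f"quantile_method must be one of {sorted(_QUANTILE_METHODS)}"
            )


@dataclass(frozen=True)
class ProbeCall:
    probe_id: str
    call_class: str  # one of CALL_CLASSES or "none"
    target_cancer: str  # empty iff call_class == "none"

    def __post_init__(self) -> None:
        if (self.call_class == "none") != (self.target_cancer == ""):
            raise ValueError("target_cancer must be non-empty iff a class is called")


@dataclass
class CallTable:
    """Winning call per probe plus all satisfied (probe, class, target) triples."""

    calls: list[ProbeCall]
    all_calls: list[ProbeCall]
    cancer_codes: list[str]
    config: FilterConfig
    quartiles: pd.DataFrame  # per-probe Q1/Q3/n per group, long format

    @property
    def tally(self) -> pd.DataFrame:
        return tally_calls(self.calls, self.cancer_codes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.probe_id, c.call_class, c.target_cancer) for c in self.calls],
            columns=["probe_id", "call_class", "target_cancer"],
        )

    def called(self) -> set[tuple[str, str, str]]:
        """All satisfied (probe, class, target) triples, long format."""
        return {
            (c.probe_id, c.call_class, c.target_cancer)
            for c in self.all_calls
            if c.call_class != "none"
        }


def _group_columns(manifest: pd.DataFrame, samples: pd.Index) -> dict[tuple[str, str], list[str]]:
    groups: dict[tuple[str, str], list[str]] = {}
    sub = manifest.loc[manifest.index.intersection(samples)]
    for sample in samples:
        if sample not in sub.index:
            raise ValueError(f"sample {sample!r} missing from manifest")
        key = (sub.at[sample, "cancer_code"], sub.at[sample, "tissue_type"])
        groups.setdefault(key, []).append(sample)
    return groups


def group_quartiles(
    matrix: pd.DataFrame, manifest: pd.DataFrame, config: FilterConfig = FilterConfig()
) -> pd.DataFrame:
    """Per-probe Q1/Q3 and non-missing count for every (cancer, tissue) group.

    Missing values are dropped per group before the quantiles; a group with
    fewer than ``min_group_size`` non-missing values gets NaN quartiles for
    that probe (the probe becomes uncallable for targets that need the group).
    Returns a long-format frame with columns probe_id, cancer_code,
    tissue_type, q1, q3, n.
    """
    codes = validate_manifest_groups(manifest)
    groups = _group_columns(manifest, matrix.columns)
    method = _QUANTILE_METHODS[config.quantile_method]
    records = []
    for code in codes:
        for tissue in TISSUE_TYPES:
            cols = groups.get((code, tissue), [])
            block = matrix[cols].to_numpy(dtype=float)
            n = np.sum(~np.isnan(block), axis=1)
            with np.errstate(all="ignore"):
                q1 = np.nanquantile(block, 0.25, axis=1, method=method)
                q3 = np.nanquantile(block, 0.75, axis=1, method=method)
            small = n < config.min_group_size
            q1[small] = np.nan
            q3[small] = np.nan
            records.append(
                pd.DataFrame(
                    {
                        "probe_id": matrix.index,
                        "cancer_code": code,
                        "tissue_type": tissue,
                        "q1": q1,
                        "q3": q3,
                        "n": n,
                    }
                )
            )
    return pd.concat(records, ignore_index=True)


def classify_probe(
    profile: dict[tuple[str, str], tuple[float, float]],
    target_cancer: str,
    cancer_codes: list[str],
    config: FilterConfig = FilterConfig(),
) -> str:
    """Classify one probe for one target cancer from its quartile profile.

    ``profile`` maps (cancer_code, tissue_type) to (q1, q3).  Classes are
    checked in the fixed precedence cancer_hyper > cancer_hypo >
    tissue_hyper > tissue_hypo; the first whose full rule set holds wins,
    otherwise "none".  A missing or NaN group makes the probe uncallable.
    """
    hyper, hypo = config.hyper_threshold, config.hypo_threshold
    others = [c for c in cancer_codes if c != target_cancer]
    needed = [(c, t) for c in cancer_codes for t in TISSUE_TYPES]
    for key in needed:
        q = profile.get(key)
        if q is None or np.isnan(q[0]) or np.isnan(q[1]):
            return "none"

    def q1(c: str, t: str) -> float:
        return profile[(c, t)][0]

    def q3(c: str, t: str) -> float:
        return profile[(c, t)][1]

    t, n = "primary_tumor", "normal_tissue"
    others_low = all(q3(o, t) < hypo and q3(o, n) < hypo for o in others)
    others_high = all(q1(o, t) > hyper and q1(o, n) > hyper for o in others)

    if q1(target_cancer, t) > hyper and q3(target_cancer, n) < hypo and others_low:
        return "cancer_hyper"
    if q3(target_cancer, t) < hypo and q1(target_cancer, n) > hyper and others_high:
        return "cancer_hypo"
    if q1(target_cancer, t) > hyper and q1(target_cancer, n) > hyper and others_low:
        return "tissue_hyper"
    if q3(target_cancer, t) < hypo and q3(target_cancer, n) < hypo and others_high:
        return "tissue_hypo"
    return "none"


def run_filter(
    matrix: pd.DataFrame, manifest: pd.DataFrame, config: FilterConfig = FilterConfig()
) -> CallTable:
    """Classify every probe against every target cancer.

    Vectorized over probes: per-group Q1/Q3 arrays are compared against the
    thresholds, and the four rule sets are evaluated as boolean masks.  The
    winning call per probe is the first satisfied (target, class) pair in
    manifest cancer order with class precedence cancer_hyper > cancer_hypo >
    tissue_hyper > tissue_hypo; all satisfied pairs are retained in
    ``all_calls`` (long format).  Deterministic for fixed input.
    """
    codes = validate_manifest_groups(manifest)
    if len(codes) < 2:
        raise ValueError("quartile rules quantify over other cancers; need >=2 cancer codes")
    if len(codes) > config.max_cancers:
        raise ValueError(f"{len(codes)} cancer codes exceed max_cancers={config.max_cancers}")

    quart = group_quartiles(matrix, manifest, config)
    hyper, hypo = config.hyper_threshold, config.hypo_threshold

    # pivot to probe x group arrays, aligned to matrix.index
    q1_grid: dict[tuple[str, str], np.ndarray] = {}
    q3_grid: dict[tuple[str, str], np.ndarray] = {}
    for (code, tissue), sub in quart.groupby(["cancer_code", "tissue_type"], sort=False):
        sub = sub.set_index("probe_id").reindex(matrix.index)
        q1_grid[(code, tissue)] = sub["q1"].to_numpy()
        q3_grid[(code, tissue)] = sub["q3"].to_numpy()

    t, n = "primary_tumor", "normal_tissue"
    # per-group threshold masks (NaN compares False, i.e. uncallable)
    with np.errstate(invalid="ignore"):
        high_q1 = {k: v > hyper for k, v in q1_grid.items()}
        low_q3 = {k: v < hypo for k, v in q3_grid.items()}

    n_probes = len(matrix.index)
    all_calls: list[ProbeCall] = []
    winner_call: list[tuple[str, str] | None] = [None] * n_probes

    for code in codes:
        others = [c for c in codes if c != code]
        others_low = np.logical_and.reduce(
            [low_q3[(o, tt)] for o in others for tt in (t, n)]
        )
        others_high = np.logical_and.reduce(
            [high_q1[(o, tt)] for o in others for tt in (t, n)]
        )
        masks = {
            "cancer_hyper": high_q1[(code, t)] & low_q3[(code, n)] & others_low,
            "cancer_hypo": low_q3[(code, t)] & high_q1[(code, n)] & others_high,
            "tissue_hyper": high_q1[(code, t)] & high_q1[(code, n)] & others_low,
            "tissue_hypo": low_q3[(code, t)] & low_q3[(code, n)] & others_high,
        }
        # within one target, precedence picks the first satisfied class
        claimed = np.zeros(n_probes, dtype=bool)
        for cls in CALL_CLASSES:
            mask = masks[cls] & ~claimed
            claimed |= mask
            for i in np.flatnonzero(mask):
                all_calls.append(ProbeCall(str(matrix.index[i]), cls, code))
                if winner_call[i] is None:
                    winner_call[i] = (cls, code)

    calls = [
        ProbeCall(str(p), *(wc if wc is not None else ("none", "")))
        for p, wc in zip(matrix.index, winner_call)
    ]
    return CallTable(calls=calls, all_calls=all_calls, cancer_codes=codes,
                     config=config, quartiles=quart)


def tally_calls(calls: list[ProbeCall], cancer_codes: list[str]) -> pd.DataFrame:
    """Class x cancer count grid of non-none calls, zeros included."""
    grid = pd.DataFrame(0, index=list(CALL_CLASSES), columns=list(cancer_codes))
    for c in calls:
        if c.call_class != "none":
            grid.loc[c.call_class, c.target_cancer] += 1
    grid.index = [CLASS_LABELS[c] for c in grid.index]
    grid.index.name = "Feature"
    return grid


def write_calls(table: CallTable, path: str | Path) -> None:
    """Export calls with per-group quartiles as TSV."""
    wide = table.quartiles.pivot_table(
        index="probe_id",
        columns=["cancer_code", "tissue_type"],
        values=["q1", "q3"],
        sort=False,
    )
    wide.columns = [f"{q}_{c}_{t}" for q, c, t in wide.columns]
    out = table.to_frame().set_index("probe_id").join(wide)
    meta = f"# quantile_method={table.config.quantile_method}\t" \
           f"hyper={table.config.hyper_threshold}\thypo={table.config.hypo_threshold}\n"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(meta)
        out.to_csv(fh, sep="\t")


def write_tally(table: CallTable, path: str | Path) -> None:
    table.tally.to_csv(path, sep="\t")
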