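"""Tabular I/O, probe-level quality filtering and chip harmonization.

Beta matrices, detection-p matrices, probe manifests and sample sheets are
plain TSV files; in memory they are pandas DataFrames. A beta/detection-p
matrix is probes x samples with the probe id as first column and a header
row of sample ids. Coordinates are 0-based half-open; sequence names are
normalized to carry a ``chr`` prefix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "read_beta_matrix",
    "write_beta_matrix",
    "read_manifest",
    "write_manifest",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_cpg_track",
    "write_cpg_track",
    "FilterPolicy",
    "FilterReport",
    "filter_probes",
    "harmonize_chips",
    "normalize_chrom",
]

SEX_CHROMS = {"chrX", "chrY"}
ISLAND_CATEGORIES = ("Island", "Shore", "Shelf", "OpenSea")

_FLOAT_FMT = "%.10g"


def normalize_chrom(name: str) -> str:
    """Normalize a sequence name to the ``chr``-prefixed convention."""
    name = str(name)
    return name if name.startswith("chr") else f"chr{name}"


def _check_beta_values(df: pd.DataFrame, tol: float = 1e-9) -> None:
    vals = df.to_numpy(dtype=float)
    bad = (vals < -tol) | (vals > 1 + tol)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"beta value {vals[i, j]!r} outside [0, 1] at probe "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        )


def read_beta_matrix(path) -> pd.DataFrame:
    """Read a probes x samples beta (or detection-p) matrix from TSV.

    Missing cells (``NA``/empty) become NaN, never 0. Values outside [0, 1]
    are rejected with the offending probe and sample named.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index = df.index.astype(str)
    df.index.name = "probe_id"
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate probe id {dup!r}")
    _check_beta_values(df)
    return df.astype(float)


def write_beta_matrix(beta: pd.DataFrame, path) -> None:
    _check_beta_values(beta)
    beta.to_csv(path, sep="\t", na_rep="NA", float_format=_FLOAT_FMT, index_label="probe_id")


def read_manifest(path) -> pd.DataFrame:
    """Read a probe manifest TSV; chromosome names are normalized."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "probe_id"
    df["chrom"] = df["chrom"].map(normalize_chrom)
    bad = ~df["island_relation"].isin(ISLAND_CATEGORIES)
    if bad.any():
        raise ValueError(
            f"unknown island relation {df.loc[bad, 'island_relation'].iloc[0]!r}"
        )
    for col in ("cross_reactive", "snp_overlap", "lad", "on_450k", "on_epic"):
        df[col] = df[col].astype(bool)
    return df


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, sep="\t", index_label="probe_id")


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    if df.index.has_duplicates:
        raise ValueError("duplicate sample ids in sample sheet")
    return df


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index_label="sample_id")


def read_cpg_track(path) -> pd.DataFrame:
    """Read a bedGraph-like CpG track: chrom, pos (0-based), ratio, coverage."""
    df = pd.read_csv(path, sep="\t")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def write_cpg_track(track: pd.DataFrame, path) -> None:
    track.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


@dataclass(frozen=True)
class FilterPolicy:
    """Probe-removal policy.

    ``detection_p_max``: a probe fails detection in a sample if its
    detection p exceeds this. ``max_failing_fraction``: the probe is removed
    if the fraction of failing samples exceeds this; 0 (the default) is the
    strict reading where a single failing sample removes the probe.
    ``require_both_chips`` removes probes absent from either chip, for
    450K/EPIC comparability.
    """

    detection_p_max: float = 0.01
    max_failing_fraction: float = 0.0
    drop_sex_chromosomes: bool = True
    drop_cross_reactive: bool = True
    drop_snp_overlap: bool = True
    require_both_chips: bool = False


# Reporting precedence: a probe hit by several rules is attributed to the
# first matching category; the retained set is identical regardless.
_CATEGORY_ORDER = ("detection", "sex_chromosome", "cross_reactive", "snp_overlap", "chip")


@dataclass
class FilterReport:
    """Disjoint accounting of removed probes, one category per probe."""

    n_input: int
    n_retained: int
    removed: dict = field(default_factory=dict)  # category -> sorted probe id list

    @property
    def counts(self) -> dict:
        return {cat: len(self.removed.get(cat, [])) for cat in _CATEGORY_ORDER}

    def to_json_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "counts": self.counts,
            "removed": {k: list(v) for k, v in self.removed.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")


def filter_probes(
    beta: pd.DataFrame,
    detp: pd.DataFrame | None,
    manifest: pd.DataFrame,
    policy: FilterPolicy = FilterPolicy(),
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply probe-level quality filtering to a beta matrix.

    Removes probes failing detection (p > ``detection_p_max``), probes on
    the sex chromosomes, cross-reactive probes, SNP-overlapping probes and
    (optionally) probes absent from either chip. Probe order is preserved;
    the report attributes each removed probe to exactly one category in a
    fixed precedence order.
    """
    missing = beta.index.difference(manifest.index)
    if len(missing):
        raise KeyError(f"{len(missing)} beta probes absent from manifest, e.g. {missing[0]!r}")
    if detp is not None:
        if not (detp.index.equals(beta.index) and detp.columns.equals(beta.columns)):
            raise ValueError("detection-p matrix is not aligned to the beta matrix")

    man = manifest.loc[beta.index]
    masks: dict[str, pd.Series] = {}
    if detp is not None:
        failing_frac = (detp.to_numpy() > policy.detection_p_max).mean(axis=1)
        masks["detection"] = pd.Series(failing_frac > policy.max_failing_fraction, index=beta.index)
    if policy.drop_sex_chromosomes:
        masks["sex_chromosome"] = man["chrom"].map(normalize_chrom).isin(SEX_CHROMS)
    if policy.drop_cross_reactive:
        masks["cross_reactive"] = man["cross_reactive"]
    if policy.drop_snp_overlap:
        masks["snp_overlap"] = man["snp_overlap"]
    if policy.require_both_chips:
        masks["chip"] = ~(man["on_450k"] & man["on_epic"])

    removed: dict[str, list] = {}
    claimed = pd.Series(False, index=beta.index)
    for cat in _CATEGORY_ORDER:
        if cat not in masks:
            continue
        hit = masks[cat] & ~claimed
        if hit.any():
            removed[cat] = sorted(beta.index[hit])
        claimed |= masks[cat]

    retained = beta.loc[~claimed]
    report = FilterReport(n_input=len(beta), n_retained=len(retained), removed=removed)
    return retained, report


def harmonize_chips(
    a: pd.DataFrame, b: pd.DataFrame, manifest: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict two beta matrices to the probes present on both chips.

    The output matrices share an identical, canonically sorted probe set:
    the intersection of the two inputs' probes, limited to probes the
    manifest flags as present on both the 450K and EPIC chips.
    """
    common = a.index.intersection(b.index)
    known = common.intersection(manifest.index)
    dual = manifest.loc[known]
    keep = sorted(dual.index[dual["on_450k"] & dual["on_epic"]])
    if not keep:
        raise ValueError("no probes shared by both matrices and present on both chips")
    return a.loc[keep], b.loc[keep]
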