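"""DNA-methylation canyon calling and canyon-centred array summaries.

Canyons are long (>= 3.5 kb) genomic stretches almost devoid of DNA
methylation, larger than CpG islands and typically spanning developmental
regulator genes. This module calls them from a per-CpG methylation-ratio
track (WGBS-style), maps array probes into the called intervals, and
computes size-normalized meta-profiles: every canyon is mapped to a common
[0, 1) axis, probes are binned along it, and per-group mean betas per bin
show whether a methylation change is flat along the canyon or concentrated
at its borders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dmp import welch_test

__all__ = [
    "CanyonParams",
    "CanyonSet",
    "call_canyons",
    "map_probes",
    "canyon_group_means",
    "size_normalized_profile",
]


@dataclass(frozen=True)
class CanyonParams:
    """Canyon-calling parameters.

    A canyon is a maximal run of >= ``min_cpgs`` consecutive sufficiently
    covered CpGs with methylation ratio <= ``low_thresh``; runs separated
    by <= ``merge_gap_bp`` are chained together, and merged intervals
    shorter than ``min_length_bp`` (the 3.5 kb canyon floor) are dropped.
    Only the length floor is canonical; the remaining defaults follow the
    canyon literature and are configurable.
    """

    low_thresh: float = 0.1
    min_cpgs: int = 5
    merge_gap_bp: int = 1000
    min_length_bp: int = 3500
    min_coverage: int = 5

    def __post_init__(self):
        if self.low_thresh <= 0 or self.min_cpgs <= 0 or self.min_length_bp <= 0:
            raise ValueError("canyon parameters must be positive")
        if self.merge_gap_bp < 0 or self.min_coverage < 0:
            raise ValueError("merge_gap_bp and min_coverage must be non-negative")


@dataclass
class CanyonSet:
    """Called canyons: sorted, non-overlapping half-open intervals."""

    intervals: pd.DataFrame  # chrom, start, end, mean_ratio, n_cpgs, length
    params: CanyonParams = field(default_factory=CanyonParams)

    def __len__(self) -> int:
        return len(self.intervals)

    def to_bed(self, path) -> None:
        """Write BED3+ (chrom, start, end, mean_ratio, n_cpgs)."""
        cols = ["chrom", "start", "end", "mean_ratio", "n_cpgs"]
        self.intervals[cols].to_csv(path, sep="\t", header=False, index=False,
                                    float_format="%.6g")


def _empty_canyons(params: CanyonParams) -> pd.DataFrame:
    return pd.DataFrame(
        {c: pd.Series(dtype=t) for c, t in
         [("chrom", str), ("start", int), ("end", int),
          ("mean_ratio", float), ("n_cpgs", int), ("length", int)]}
    )


def call_canyons(track: pd.DataFrame, params: CanyonParams = CanyonParams()) -> CanyonSet:
    """Call hypomethylated canyons from a sorted per-CpG track.

    Steps: drop CpGs under ``min_coverage``; find maximal runs of
    consecutive retained CpGs with ratio <= ``low_thresh`` containing at
    least ``min_cpgs`` CpGs; chain-merge runs separated by at most
    ``merge_gap_bp``; keep merged intervals at least ``min_length_bp``
    long. An interval spans [first CpG, last CpG + 1) — no assumption is
    made about unobserved sequence beyond the last CpG.
    """
    if track.empty:
        return CanyonSet(_empty_canyons(params), params)
    pos_sorted = track.sort_values(["chrom", "pos"], kind="stable")
    if not pos_sorted["pos"].to_numpy().shape == track["pos"].to_numpy().shape or not (
        (pos_sorted[["chrom", "pos"]].to_numpy() == track[["chrom", "pos"]].to_numpy()).all()
    ):
        raise ValueError("track must be sorted by (chrom, pos)")

    rows = []
    for chrom, sub in track.groupby("chrom", sort=False):
        sub = sub[sub["coverage"] >= params.min_coverage]
        if sub.empty:
            continue
        pos = sub["pos"].to_numpy()
        ratio = sub["ratio"].to_numpy(dtype=float)
        low = ratio <= params.low_thresh

        # maximal runs of consecutive low CpGs
        runs = []
        i = 0
        n = len(pos)
        while i < n:
            if low[i]:
                j = i
                while j + 1 < n and low[j + 1]:
                    j += 1
                if j - i + 1 >= params.min_cpgs:
                    runs.append((i, j))
                i = j + 1
            else:
                i += 1

        # transitive merge of nearby runs: gap measured between the end of
        # one interval (last CpG + 1) and the first CpG of the next
        merged = []
        for i0, j0 in runs:
            if merged and pos[i0] - (pos[merged[-1][1]] + 1) <= params.merge_gap_bp:
                merged[-1] = (merged[-1][0], j0)
            else:
                merged.append((i0, j0))

        for i0, j0 in merged:
            start, end = int(pos[i0]), int(pos[j0]) + 1
            if end - start >= params.min_length_bp:
                inside = ratio[i0:j0 + 1]
                rows.append(
                    {"chrom": chrom, "start": start, "end": end,
                     "mean_ratio": float(inside.mean()), "n_cpgs": int(j0 - i0 + 1),
                     "length": end - start}
                )

    out = pd.DataFrame(rows) if rows else _empty_canyons(params)
    out = out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return CanyonSet(out, params)


def map_probes(canyons: CanyonSet, manifest: pd.DataFrame) -> pd.Series:
    """Assign each probe to the canyon containing it, or -1 if none.

    Containment is half-open: a probe at ``start`` is inside, at ``end``
    outside. Probes with missing coordinates are never assigned. Returns a
    Series indexed by probe id with the row number of the containing
    canyon in ``canyons.intervals``.
    """
    assignment = pd.Series(-1, index=manifest.index, name="canyon", dtype=int)
    assignment.attrs["pos"] = manifest["pos"]
    if len(canyons) == 0:
        return assignment
    iv = canyons.intervals
    for chrom, sub in iv.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        idx = sub.index.to_numpy()
        probes = manifest[(manifest["chrom"] == chrom) & manifest["pos"].notna()]
        if probes.empty:
            continue
        pos = probes["pos"].to_numpy(dtype=float)
        k = np.searchsorted(starts, pos, side="right") - 1
        ok = (k >= 0) & (pos < ends[np.clip(k, 0, len(ends) - 1)])
        assignment.loc[probes.index[ok]] = idx[k[ok]]
    return assignment


def canyon_group_means(
    assignment: pd.Series, beta: pd.DataFrame, labels
) -> dict:
    """Group mean methylation over canyon-associated probes, with Welch p.

    The overall group mean pools every (canyon probe, sample-in-group)
    beta; the Welch test compares the per-sample means of canyon probes
    between the two groups.
    """
    labels = pd.Series(labels)
    labels = labels.loc[labels.index.intersection(beta.columns)]
    groups = sorted(labels.dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    if "WT" in groups:
        ga, gb = "WT", next(g for g in groups if g != "WT")
    else:
        ga, gb = groups

    probes = assignment.index[(assignment >= 0)].intersection(beta.index)
    if len(probes) == 0:
        raise ValueError("no canyon-assigned probes present in the beta matrix")
    per_sample = beta.loc[probes].mean(axis=0)
    va = per_sample[labels.index[labels == ga]].to_numpy()
    vb = per_sample[labels.index[labels == gb]].to_numpy()
    t, df, p = welch_test(va, vb)
    return {
        "group_a": ga, "group_b": gb,
        "mean_a": float(va.mean()), "mean_b": float(vb.mean()),
        "delta_beta": float(vb.mean() - va.mean()),
        "n_probes": int(len(probes)),
        "welch_t": t, "welch_df": df, "welch_p": p,
    }


def size_normalized_profile(
    canyons: CanyonSet,
    assignment: pd.Series,
    beta: pd.DataFrame,
    labels,
    n_bins: int = 50,
) -> pd.DataFrame:
    """Size-normalized canyon meta-profile of per-group mean methylation.

    Each canyon's [start, end) is mapped affinely to [0, 1); an assigned
    probe falls in bin ``floor(n_bins * relative_position)``. Per bin and
    group the mean is taken over all probes of all canyons and all samples
    of the group. Returns a tidy frame (bin, group, mean, n_probes); bins
    with no probes carry NaN means and n_probes = 0.
    """
    if n_bins < 2:
        raise ValueError("need at least two bins")
    labels = pd.Series(labels)
    labels = labels.loc[labels.index.intersection(beta.columns)]
    groups = sorted(labels.dropna().unique())

    probes = assignment.index[(assignment >= 0)].intersection(beta.index)
    iv = canyons.intervals
    rows = []
    pos = assignment.attrs.get("pos")
    if pos is None:
        raise ValueError(
            "assignment lacks probe positions; build it with map_probes (which "
            "records them) or set assignment.attrs['pos']"
        )
    rel = {}
    for pid in probes:
        row = iv.loc[assignment.loc[pid]]
        r = (pos.loc[pid] - row["start"]) / (row["end"] - row["start"])
        rel[pid] = min(int(np.floor(n_bins * r)), n_bins - 1)
    rel = pd.Series(rel, dtype=int)

    for g in groups:
        cols = labels.index[labels == g]
        sub = beta.loc[probes, cols]
        probe_mean = sub.mean(axis=1)
        for b in range(n_bins):
            ids = rel.index[rel == b]
            rows.append(
                {"bin": b, "group": g,
                 "mean": float(probe_mean.loc[ids].mean()) if len(ids) else np.nan,
                 "n_probes": int(len(ids))}
            )
    return pd.DataFrame(rows)
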