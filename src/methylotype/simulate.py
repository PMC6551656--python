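"""Synthetic methylation data with known ground truth.

Generators for the four kinds of input the analysis consumes:

* two-group patient cohorts (beta matrix + detection-p matrix + sample
  sheet) with hypermethylation planted at a known probe subset, emulating
  a mutant-vs-wildtype AML contrast;
* reference methylomes of four sorted myeloid differentiation stages
  (CMP -> GMP -> PMC -> PMN) with a strictly decreasing global-methylation
  gradient, emulating sorted-blood-cell array profiles;
* per-CpG whole-genome bisulfite-style methylation tracks with planted
  hypomethylated canyons;
* probe manifests with CpG-island relation, mask flags and chip membership.

Every generator takes an integer seed and is fully deterministic. Each
returns, alongside the data, a small truth record so downstream stages can
be scored against what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortTruth",
    "ReferenceTruth",
    "TrackTruth",
    "simulate_cohort",
    "simulate_reference",
    "simulate_cpg_track",
    "simulate_manifest",
    "simulate_canyon_cohort",
    "STAGE_ORDER",
]

STAGE_ORDER = ("CMP", "GMP", "PMC", "PMN")

# Mean-clamp bounds: keep beta-distribution shape parameters non-degenerate.
_CLAMP_LO = 0.001
_CLAMP_HI = 0.999


@dataclass(frozen=True)
class CohortTruth:
    """What was planted into a simulated two-group cohort."""

    dmp_indices: frozenset
    planted_delta: dict  # probe index -> signed methylation shift actually applied
    group_labels: dict  # sample id -> "WT" | "MUT"
    seed: int

    def to_json_dict(self) -> dict:
        return {
            "dmp_indices": sorted(self.dmp_indices),
            "planted_delta": {str(k): v for k, v in sorted(self.planted_delta.items())},
            "group_labels": dict(self.group_labels),
            "seed": self.seed,
        }


@dataclass(frozen=True)
class ReferenceTruth:
    """Generating parameters of a simulated differentiation reference."""

    stage_order: tuple
    stage_global_mean: tuple
    samples_per_stage: int
    seed: int

    def to_json_dict(self) -> dict:
        return {
            "stage_order": list(self.stage_order),
            "stage_global_mean": list(self.stage_global_mean),
            "samples_per_stage": self.samples_per_stage,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class TrackTruth:
    """Planted canyon intervals of a simulated CpG track.

    Intervals are half-open 0-based (chrom, start, end), non-overlapping
    and sorted. ``canyon_level`` must sit below any sensible calling
    threshold and ``background_level`` above it.
    """

    canyon_intervals: tuple  # of (chrom, start, end)
    background_level: float = 0.85
    canyon_level: float = 0.02

    def __post_init__(self):
        ivs = sorted(self.canyon_intervals)
        for (c1, s1, e1), (c2, s2, e2) in zip(ivs, ivs[1:]):
            if c1 == c2 and e1 > s2:
                raise ValueError(f"overlapping canyon intervals: {(c1, s1, e1)} and {(c2, s2, e2)}")
        object.__setattr__(self, "canyon_intervals", tuple(ivs))
        if not self.canyon_level < self.background_level:
            raise ValueError("canyon_level must be below background_level")

    def to_json_dict(self) -> dict:
        return {
            "canyon_intervals": [list(iv) for iv in self.canyon_intervals],
            "background_level": self.background_level,
            "canyon_level": self.canyon_level,
        }


def _beta_noise(rng: np.random.Generator, means: np.ndarray, dispersion: float) -> np.ndarray:
    """Draw from Beta(m*nu, (1-m)*nu) with nu = 1/dispersion.

    dispersion -> 0 is the noise-free limit and returns the means exactly.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    if dispersion == 0:
        return means.copy()
    nu = 1.0 / dispersion
    return rng.beta(means * nu, (1.0 - means) * nu)


def _baseline_means(
    rng: np.random.Generator,
    n_probes: int,
    low_weight: float,
) -> np.ndarray:
    """Bimodal per-probe baselines mimicking array beta distributions.

    A mixture of a low (~0.1) and a high (~0.85) component; array betas are
    famously bimodal because most CpG islands are unmethylated and most open
    sea is methylated.
    """
    low = rng.random(n_probes) < low_weight
    means = np.where(
        low,
        rng.beta(5.0, 45.0, size=n_probes),  # mean 0.10
        rng.beta(42.5, 7.5, size=n_probes),  # mean 0.85
    )
    return np.clip(means, _CLAMP_LO, _CLAMP_HI)


def simulate_cohort(
    n_wt: int,
    n_mut: int,
    n_probes: int,
    frac_dmp: float = 0.1,
    delta: float = 0.2,
    dispersion: float = 0.02,
    seed: int = 0,
    *,
    low_weight: float = 0.5,
    detp_fail_fraction: float = 0.0,
    clamp: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, CohortTruth]:
    """Simulate a two-group methylation cohort with planted differential probes.

    Parameters
    ----------
    n_wt, n_mut
        Sample counts of the wildtype and mutant groups.
    n_probes
        Number of array probes.
    frac_dmp
        Fraction of probes planted as differential; exactly
        ``round(frac_dmp * n_probes)`` probes are shifted.
    delta
        Signed methylation shift added to the mutant-group generating mean
        at planted probes. Planted-probe baselines are drawn from an
        intermediate methylation band (0.25-0.6), reflecting that
        differential probes sit at intermediate levels in the wildtype
        group and gain on the order of 20% methylation in mutants; the
        remaining probes keep the bimodal baseline.
    dispersion
        Spread of the beta-distribution noise; 0 gives the noise-free limit
        where sample betas equal the generating means.
    detp_fail_fraction
        Fraction of (probe, sample) cells whose detection p is set to 0.5
        (failing) instead of 0, to exercise quality filtering.
    clamp
        Clamp shifted means into [0.001, 0.999]; if False, a shift leaving
        [0, 1] raises.

    Returns
    -------
    (beta, detp, sample_sheet, truth)
        ``beta`` and ``detp`` are probes x samples DataFrames with aligned
        index/columns; ``sample_sheet`` is indexed by sample id with
        ``idh_status``/``tet2_status``/``dnmt3a_status``/``fab_class``/
        ``cohort`` columns; ``truth`` records the planted probes and shifts.
    """
    if n_wt <= 0 or n_mut <= 0:
        raise ValueError("sample counts must be positive")
    if not 0.0 <= frac_dmp <= 1.0:
        raise ValueError("frac_dmp must be in [0, 1]")
    rng = np.random.default_rng(seed)

    n_dmp = int(round(frac_dmp * n_probes))
    dmp_idx = rng.choice(n_probes, size=n_dmp, replace=False) if n_dmp else np.array([], dtype=int)

    base = _baseline_means(rng, n_probes, low_weight)
    # Differential probes start from intermediate methylation (see docstring).
    base[dmp_idx] = 0.25 + 0.35 * rng.random(n_dmp)

    mut_mean = base.copy()
    shifted = base[dmp_idx] + delta
    if clamp:
        shifted = np.clip(shifted, _CLAMP_LO, _CLAMP_HI)
    elif ((shifted < 0) | (shifted > 1)).any():
        raise ValueError("delta pushes generating means outside [0, 1] and clamping is disabled")
    mut_mean[dmp_idx] = shifted

    wt = _beta_noise(rng, np.repeat(base[:, None], n_wt, axis=1), dispersion)
    mut = _beta_noise(rng, np.repeat(mut_mean[:, None], n_mut, axis=1), dispersion)

    probe_ids = [f"cg{i:08d}" for i in range(n_probes)]
    wt_ids = [f"WT_{i:03d}" for i in range(n_wt)]
    mut_ids = [f"MUT_{i:03d}" for i in range(n_mut)]
    beta = pd.DataFrame(np.hstack([wt, mut]), index=probe_ids, columns=wt_ids + mut_ids)
    beta.index.name = "probe_id"

    detp = pd.DataFrame(0.0, index=beta.index, columns=beta.columns)
    if detp_fail_fraction > 0:
        fail = rng.random(beta.shape) < detp_fail_fraction
        detp = detp.mask(pd.DataFrame(fail, index=beta.index, columns=beta.columns), 0.5)

    labels = {s: "WT" for s in wt_ids} | {s: "MUT" for s in mut_ids}
    sheet = pd.DataFrame(
        {
            "idh_status": [labels[s] for s in beta.columns],
            "tet2_status": "NA",
            "dnmt3a_status": "NA",
            "fab_class": "NA",
            "cohort": "simulated",
        },
        index=pd.Index(beta.columns, name="sample_id"),
    )

    planted = {int(i): float(mut_mean[i] - base[i]) for i in dmp_idx}
    truth = CohortTruth(
        dmp_indices=frozenset(int(i) for i in dmp_idx),
        planted_delta=planted,
        group_labels=labels,
        seed=seed,
    )
    return beta, detp, sheet, truth


def simulate_reference(
    samples_per_stage: int = 3,
    n_probes: int = 2000,
    gradient: Sequence[float] = (0.8, 0.7, 0.5, 0.4),
    within_stage_sd: float = 0.02,
    seed: int = 0,
    *,
    probe_offset_sd: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame, ReferenceTruth]:
    """Simulate reference methylomes of four myeloid differentiation stages.

    Models the global loss of methylation during myeloid differentiation: a
    strictly decreasing per-stage global mean along CMP -> GMP -> PMC -> PMN.
    Per-probe offsets (centered to exact zero mean) are shared across stages,
    so each stage's generating global mean equals the gradient value; sample
    noise is Gaussian with ``within_stage_sd``, clipped to [0, 1].
    """
    gradient = tuple(float(g) for g in gradient)
    if len(gradient) != len(STAGE_ORDER):
        raise ValueError(f"gradient must have {len(STAGE_ORDER)} entries")
    if any(b >= a for a, b in zip(gradient, gradient[1:])):
        raise ValueError("gradient must be strictly decreasing")
    if any(not 0.0 <= g <= 1.0 for g in gradient):
        raise ValueError("gradient values must lie in [0, 1]")
    if samples_per_stage <= 0:
        raise ValueError("samples_per_stage must be positive")
    rng = np.random.default_rng(seed)

    offsets = rng.normal(0.0, probe_offset_sd, size=n_probes)
    offsets -= offsets.mean()  # exact zero mean: stage global means hit the gradient
    # rescale so gradient + offset stays in [0, 1] at every stage (scaling
    # preserves the exact zero mean, unlike clipping)
    room = min(min(gradient), 1.0 - max(gradient))
    peak = np.abs(offsets).max()
    if peak > 0 and peak > room:
        offsets *= room / peak

    probe_ids = [f"cg{i:08d}" for i in range(n_probes)]
    cols, data = [], []
    for stage, g in zip(STAGE_ORDER, gradient):
        means = g + offsets
        for r in range(samples_per_stage):
            cols.append(f"{stage}_{r}")
            noise = rng.normal(0.0, within_stage_sd, size=n_probes) if within_stage_sd > 0 else 0.0
            data.append(np.clip(means + noise, 0.0, 1.0))
    beta = pd.DataFrame(np.column_stack(data), index=probe_ids, columns=cols)
    beta.index.name = "probe_id"

    sheet = pd.DataFrame(
        {
            "idh_status": "NA",
            "tet2_status": "NA",
            "dnmt3a_status": "NA",
            "fab_class": "NA",
            "cohort": "reference",
            "stage": [c.rsplit("_", 1)[0] for c in cols],
        },
        index=pd.Index(cols, name="sample_id"),
    )
    truth = ReferenceTruth(STAGE_ORDER, gradient, samples_per_stage, seed)
    return beta, sheet, truth


def simulate_cpg_track(
    chrom_length: int,
    cpg_spacing: int,
    truth: TrackTruth,
    noise_sd: float = 0.0,
    coverage_mean: int = 30,
    seed: int = 0,
    chrom: str = "chr1",
) -> pd.DataFrame:
    """Simulate a per-CpG methylation-ratio track with planted canyons.

    CpGs sit on a regular grid every ``cpg_spacing`` bp. Ratios are
    ``truth.canyon_level`` inside planted intervals and
    ``truth.background_level`` outside, plus optional Gaussian noise,
    clipped to [0, 1]. Coverage is Poisson around ``coverage_mean``
    (shifted by +1 so no CpG is unobserved).
    """
    for c, s, e in truth.canyon_intervals:
        if c == chrom and not (0 <= s < e <= chrom_length):
            raise ValueError(f"canyon interval {(c, s, e)} outside [0, {chrom_length})")
    rng = np.random.default_rng(seed)

    pos = np.arange(0, chrom_length, cpg_spacing)
    ratio = np.full(pos.shape, truth.background_level)
    for c, s, e in truth.canyon_intervals:
        if c == chrom:
            ratio[(pos >= s) & (pos < e)] = truth.canyon_level
    if noise_sd > 0:
        ratio = np.clip(ratio + rng.normal(0.0, noise_sd, size=pos.shape), 0.0, 1.0)
    coverage = 1 + rng.poisson(max(coverage_mean - 1, 0), size=pos.shape)

    return pd.DataFrame({"chrom": chrom, "pos": pos, "ratio": ratio, "coverage": coverage})


def simulate_manifest(
    n_probes: int,
    island_fractions: Sequence[float] = (0.3, 0.25, 0.1, 0.35),
    lad_fraction: float = 0.1,
    mask_fractions: dict | None = None,
    seed: int = 0,
    *,
    chrom: str = "chr1",
    probe_spacing: int = 500,
    sex_fraction: float = 0.0,
) -> pd.DataFrame:
    """Simulate a probe manifest with island relation, flags and coordinates.

    Probes are placed on a regular genomic grid (``probe_spacing`` bp apart)
    on ``chrom``; a ``sex_fraction`` of probes is relocated to chrX to
    exercise sex-chromosome filtering. Island relation is a single draw per
    probe from {Island, Shore, Shelf, OpenSea} with the given fractions;
    mask flags (``cross_reactive``, ``snp_overlap``) and the LAD flag are
    independent Bernoulli draws. All probes are marked present on both
    chips unless a ``mask_fractions['only_450k'|'only_epic']`` entry moves
    a fraction to a single chip.
    """
    fracs = np.asarray(island_fractions, dtype=float)
    if fracs.shape != (4,) or (fracs < 0).any() or (fracs > 1).any():
        raise ValueError("island_fractions must be 4 values in [0, 1]")
    if not np.isclose(fracs.sum(), 1.0):
        raise ValueError("island_fractions must sum to 1")
    if not 0.0 <= lad_fraction <= 1.0:
        raise ValueError("lad_fraction must be in [0, 1]")
    mask_fractions = dict(mask_fractions or {})
    for k, v in mask_fractions.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"mask fraction {k!r} must be in [0, 1]")
    rng = np.random.default_rng(seed)

    cats = np.array(["Island", "Shore", "Shelf", "OpenSea"])
    relation = cats[rng.choice(4, size=n_probes, p=fracs)]
    cross = rng.random(n_probes) < mask_fractions.get("cross_reactive", 0.0)
    snp = rng.random(n_probes) < mask_fractions.get("snp_overlap", 0.0)
    lad = rng.random(n_probes) < lad_fraction
    chroms = np.where(rng.random(n_probes) < sex_fraction, "chrX", chrom)

    on_450k = np.ones(n_probes, dtype=bool)
    on_epic = np.ones(n_probes, dtype=bool)
    only_450k = rng.random(n_probes) < mask_fractions.get("only_450k", 0.0)
    only_epic = (rng.random(n_probes) < mask_fractions.get("only_epic", 0.0)) & ~only_450k
    on_epic[only_450k] = False
    on_450k[only_epic] = False

    manifest = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.arange(n_probes) * probe_spacing,
            "island_relation": relation,
            "cross_reactive": cross,
            "snp_overlap": snp,
            "lad": lad,
            "on_450k": on_450k,
            "on_epic": on_epic,
        },
        index=pd.Index([f"cg{i:08d}" for i in range(n_probes)], name="probe_id"),
    )
    return manifest


def _random_canyon_truth(
    rng: np.random.Generator,
    chrom_length: int,
    n_canyons: int,
    length_range: tuple[int, int],
    min_separation: int,
    chrom: str,
) -> TrackTruth:
    """Place non-overlapping canyon intervals separated by > min_separation."""
    lengths = rng.integers(length_range[0], length_range[1] + 1, size=n_canyons)
    total = int(lengths.sum()) + (n_canyons + 1) * min_separation
    if total > chrom_length:
        raise ValueError("chromosome too short for requested canyons")
    slack = chrom_length - total
    gaps = rng.multinomial(slack, np.ones(n_canyons + 1) / (n_canyons + 1))
    intervals, cursor = [], 0
    for i in range(n_canyons):
        cursor += min_separation + int(gaps[i])
        intervals.append((chrom, cursor, cursor + int(lengths[i])))
        cursor += int(lengths[i])
    return TrackTruth(tuple(intervals))


def simulate_canyon_cohort(
    n_wt: int = 28,
    n_mut: int = 112,
    n_probes: int = 4000,
    chrom_length: int = 200_000,
    cpg_spacing: int = 100,
    n_canyons: int = 5,
    canyon_shift: float = 0.014,
    dispersion: float = 0.02,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> dict:
    """Simulate a coupled CpG track + manifest + cohort for canyon analysis.

    Canyons are planted into a WGBS-style track on one chromosome; the probe
    manifest tiles the same chromosome, so a subset of probes falls inside
    canyons. Probes inside canyons start near the canyon methylation level
    and the mutant group's generating mean is raised by ``canyon_shift``
    uniformly along each canyon (default 0.014, the minimal canyon
    hypermethylation the mutant contrast is expected to show), so the
    planted group difference is flat along the size-normalized canyon axis.

    Returns a dict with keys ``track``, ``manifest``, ``beta``, ``sheet``,
    ``track_truth`` and ``canyon_probe_indices``.
    """
    rng = np.random.default_rng(seed)
    truth = _random_canyon_truth(
        rng, chrom_length, n_canyons, length_range=(4000, 8000), min_separation=3000, chrom="chr1"
    )
    track = simulate_cpg_track(
        chrom_length, cpg_spacing, truth, noise_sd=noise_sd, seed=int(rng.integers(2**31))
    )
    spacing = max(chrom_length // n_probes, 1)
    manifest = simulate_manifest(
        n_probes, seed=int(rng.integers(2**31)), probe_spacing=spacing
    )

    pos = manifest["pos"].to_numpy()
    in_canyon = np.zeros(n_probes, dtype=bool)
    for _, s, e in truth.canyon_intervals:
        in_canyon |= (pos >= s) & (pos < e)

    base = _baseline_means(rng, n_probes, low_weight=0.5)
    base[in_canyon] = np.clip(
        truth.canyon_level + 0.05 * rng.random(in_canyon.sum()), _CLAMP_LO, _CLAMP_HI
    )
    mut_mean = base.copy()
    mut_mean[in_canyon] = np.clip(base[in_canyon] + canyon_shift, _CLAMP_LO, _CLAMP_HI)

    wt = _beta_noise(rng, np.repeat(base[:, None], n_wt, axis=1), dispersion)
    mut = _beta_noise(rng, np.repeat(mut_mean[:, None], n_mut, axis=1), dispersion)
    wt_ids = [f"WT_{i:03d}" for i in range(n_wt)]
    mut_ids = [f"MUT_{i:03d}" for i in range(n_mut)]
    beta = pd.DataFrame(np.hstack([wt, mut]), index=manifest.index, columns=wt_ids + mut_ids)

    sheet = pd.DataFrame(
        {
            "idh_status": ["WT"] * n_wt + ["MUT"] * n_mut,
            "tet2_status": "NA",
            "dnmt3a_status": "NA",
            "fab_class": "NA",
            "cohort": "simulated",
        },
        index=pd.Index(beta.columns, name="sample_id"),
    )
    return {
        "track": track,
        "manifest": manifest,
        "beta": beta,
        "sheet": sheet,
        "track_truth": truth,
        "canyon_probe_indices": np.flatnonzero(in_canyon),
    }
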