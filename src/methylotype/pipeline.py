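"""End-to-end orchestration: config, staged execution, results bundle.

A run takes a :class:`RunConfig` (from YAML or built in code), executes
filter -> differential methylation -> stratification -> top-K selection ->
PCA -> clustering -> overlap, plus the canyon analysis when a CpG track is
available, and writes a flat results bundle: TSV tables, JSON reports and
a bundle manifest. Bundles contain no timestamps, so a re-run with the
same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import canyons as _canyons
from . import dmp as _dmp
from . import io as _io
from . import projection as _proj
from . import simulate as _sim

__all__ = ["RunConfig", "StageError", "run_cohort_contrast", "run_canyon_analysis", "run_all"]

log = logging.getLogger("methylotype.pipeline")

_FLOAT_FMT = "%.10g"

STAGE_EXIT_CODES = {
    "inputs": 2,
    "filter": 3,
    "dmp": 4,
    "stratify": 5,
    "select": 6,
    "pca": 7,
    "cluster": 8,
    "overlap": 9,
    "canyons": 10,
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for exit codes."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything a run needs; fully serialized into the bundle.

    Either ``paths`` points at beta/detp/manifest/sheet (and optionally
    track) TSVs, or ``simulate=True`` and the ``cohort``/``canyon``
    sections parameterize the generators.
    """

    seed: int = 0
    simulate: bool = True
    paths: dict = field(default_factory=dict)
    cohort: dict = field(
        default_factory=lambda: {
            "n_wt": 28, "n_mut": 112, "n_probes": 10000,
            "frac_dmp": 0.1, "delta": 0.2, "dispersion": 0.02,
            "detp_fail_fraction": 0.002,
        }
    )
    manifest: dict = field(
        default_factory=lambda: {
            "sex_fraction": 0.03,
            "mask_fractions": {"cross_reactive": 0.02, "snp_overlap": 0.02},
            "lad_fraction": 0.1,
        }
    )
    canyon: dict = field(
        default_factory=lambda: {
            "enabled": True, "n_wt": 28, "n_mut": 112, "n_probes": 4000,
            "chrom_length": 200000, "cpg_spacing": 100, "n_canyons": 5,
            "canyon_shift": 0.014, "dispersion": 0.02, "n_bins": 50,
        }
    )
    alpha: float = 0.05
    top_k: tuple = (5000, 10000)
    contrast: str = "idh_status"
    scale_unit: bool = False
    canyon_params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.top_k = tuple(cfg.top_k)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["top_k"] = list(self.top_k)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")


def _write_table(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", na_rep="NA", float_format=_FLOAT_FMT, index=index)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - surfaced with stage context
                raise StageError(name, exc) from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapper

    return deco


@_stage("inputs")
def _load_inputs(config: RunConfig):
    if config.simulate:
        c = dict(config.cohort)
        beta, detp, sheet, truth = _sim.simulate_cohort(
            n_wt=c["n_wt"], n_mut=c["n_mut"], n_probes=c["n_probes"],
            frac_dmp=c["frac_dmp"], delta=c["delta"], dispersion=c["dispersion"],
            seed=config.seed, detp_fail_fraction=c.get("detp_fail_fraction", 0.0),
        )
        m = dict(config.manifest)
        manifest = _sim.simulate_manifest(
            c["n_probes"], seed=config.seed + 1,
            lad_fraction=m.get("lad_fraction", 0.1),
            mask_fractions=m.get("mask_fractions"),
            sex_fraction=m.get("sex_fraction", 0.0),
        )
        log.info("simulated cohort: %d probes x %d samples", *beta.shape)
        return beta, detp, manifest, sheet, truth
    p = config.paths
    beta = _io.read_beta_matrix(p["beta"])
    detp = _io.read_beta_matrix(p["detp"]) if "detp" in p else None
    manifest = _io.read_manifest(p["manifest"])
    sheet = _io.read_sample_sheet(p["sheet"])
    log.info("loaded cohort: %d probes x %d samples", *beta.shape)
    return beta, detp, manifest, sheet, None


def run_cohort_contrast(config: RunConfig, outdir) -> dict:
    """Run the cohort contrast end to end; returns the bundle manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    summary: dict = {"contrast": config.contrast}

    beta, detp, manifest, sheet, truth = _load_inputs(config)
    if truth is not None:
        _write_json(truth.to_json_dict(), outdir / "cohort_truth.json")
        files.append("cohort_truth.json")

    @_stage("filter")
    def do_filter():
        filtered, report = _io.filter_probes(beta, detp, manifest, _io.FilterPolicy())
        report.to_json(outdir / "filter_report.json")
        log.info("filter: %d -> %d probes (%s)", report.n_input, report.n_retained,
                 ", ".join(f"{k}={v}" for k, v in report.counts.items() if v))
        return filtered, report

    filtered, report = do_filter()
    files.append("filter_report.json")
    summary["n_probes_retained"] = report.n_retained

    labels = sheet[config.contrast]
    labels = labels[labels.isin(["WT", "MUT"])]

    @_stage("dmp")
    def do_dmp():
        fit = _dmp.fit_groups(filtered[labels.index], labels)
        prior = _dmp.estimate_prior(fit.s2, fit.df)
        table = _dmp.moderated_test(fit, prior, alpha=config.alpha)
        _write_table(table, outdir / f"dmp_{config.contrast}.tsv")
        n_sig = int((table["adj_p"] < config.alpha).sum())
        n_hyper = int((table["direction"] == "hyper").sum())
        log.info("dmp: %d significant probes (%d hyper, %d hypo); prior d0=%.3g s0^2=%.3g",
                 n_sig, n_hyper, n_sig - n_hyper, prior.d0, prior.s0_sq)
        return table, prior, n_sig, n_hyper

    table, prior, n_sig, n_hyper = do_dmp()
    files.append(f"dmp_{config.contrast}.tsv")
    summary.update(
        n_significant=n_sig, n_hyper=n_hyper, n_hypo=n_sig - n_hyper,
        prior_d0=float(prior.d0) if np.isfinite(prior.d0) else "inf",
        prior_s0_sq=float(prior.s0_sq),
    )

    @_stage("stratify")
    def do_stratify():
        strat = _dmp.stratify_by_feature(table, manifest, filtered, labels, alpha=config.alpha)
        _write_table(strat, outdir / f"stratification_{config.contrast}.tsv")
        return strat

    do_stratify()
    files.append(f"stratification_{config.contrast}.tsv")

    @_stage("select")
    def do_select():
        import warnings

        sel = {}
        for k in config.top_k:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ids = _dmp.select_top_k(table, k, significant_only=True, alpha=config.alpha)
            name = f"top{k}_{config.contrast}.txt"
            (outdir / name).write_text("\n".join(map(str, ids)) + "\n")
            files.append(name)
            sel[k] = ids
        return sel

    selections = do_select()
    summary["top_k_sizes"] = {str(k): len(v) for k, v in selections.items()}

    @_stage("pca")
    def do_pca():
        model, scores = _proj.pca_fit(filtered[labels.index].T, scale_unit=config.scale_unit)
        scores = scores.iloc[:, : min(10, scores.shape[1])]
        _write_table(scores.assign(group=labels.loc[scores.index]), outdir / "pca_scores.tsv")
        ev = pd.DataFrame({"component": [f"PC{i+1}" for i in range(len(model.explained))],
                           "explained_fraction": model.explained})
        _write_table(ev, outdir / "pca_explained.tsv", index=False)
        log.info("pca: PC1 %.1f%%, PC2 %.1f%%", 100 * model.explained[0],
                 100 * model.explained[1] if len(model.explained) > 1 else float("nan"))
        return model, scores

    do_pca()
    files += ["pca_scores.tsv", "pca_explained.tsv"]

    @_stage("cluster")
    def do_cluster():
        k0 = config.top_k[0]
        ids = pd.Index(selections[k0]).intersection(filtered.index)
        if len(ids) < 2:
            log.info("cluster: skipped, fewer than 2 selected probes")
            return None
        dend = _proj.hclust_complete(filtered.loc[ids, labels.index].T)
        _write_json(dend.to_json_dict(), outdir / "dendrogram.json")
        clusters = _proj.cut_tree(dend, 2)
        _write_table(clusters.to_frame().assign(group=labels.loc[clusters.index]),
                     outdir / "clusters.tsv")
        return dend

    if do_cluster() is not None:
        files += ["dendrogram.json", "clusters.tsv"]

    @_stage("overlap")
    def do_overlap():
        if truth is None:
            return None
        sig = set(table.index[table["adj_p"] < config.alpha])
        planted = {f"cg{i:08d}" for i in truth.dmp_indices} & set(table.index)
        k = len(sig & planted)
        p = _dmp.hypergeom_overlap(k, len(sig), len(planted), len(table))
        out = {"overlap": k, "n_significant": len(sig), "n_planted_tested": len(planted),
               "universe": len(table), "hypergeom_p": p}
        _write_json(out, outdir / "overlap.json")
        log.info("overlap: %d/%d planted among %d significant (p=%.3g)",
                 k, len(planted), len(sig), p)
        return out

    if do_overlap() is not None:
        files.append("overlap.json")

    fab = _proj.fab_distribution(sheet.loc[labels.index], config.contrast)
    _write_table(fab, outdir / "fab_distribution.tsv")
    files.append("fab_distribution.tsv")

    return {"files": files, "summary": summary}


def run_canyon_analysis(config: RunConfig, outdir) -> dict:
    """Run canyon calling + probe mapping + group means + meta-profile."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    @_stage("canyons")
    def run():
        if config.simulate:
            if not config.canyon.get("enabled", True):
                log.info("canyon stage skipped: disabled in config")
                return {"files": [], "summary": {"skipped": True}}
            c = {k: v for k, v in config.canyon.items() if k not in ("enabled", "n_bins")}
            sim = _sim.simulate_canyon_cohort(seed=config.seed + 2, **c)
            track, manifest = sim["track"], sim["manifest"]
            beta, labels = sim["beta"], sim["sheet"]["idh_status"]
            _write_json(sim["track_truth"].to_json_dict(), outdir / "track_truth.json")
            files.append("track_truth.json")
        else:
            if "track" not in config.paths:
                log.info("canyon stage skipped: no CpG track provided")
                return {"files": [], "summary": {"skipped": True}}
            track = _io.read_cpg_track(config.paths["track"])
            manifest = _io.read_manifest(config.paths["manifest"])
            beta = _io.read_beta_matrix(config.paths["beta"])
            sheet = _io.read_sample_sheet(config.paths["sheet"])
            labels = sheet[config.contrast]

        params = _canyons.CanyonParams(**config.canyon_params)
        cset = _canyons.call_canyons(track, params)
        cset.to_bed(outdir / "canyons.bed")
        files.append("canyons.bed")
        log.info("canyons: %d called", len(cset))
        summary: dict = {"n_canyons": len(cset), "params": dataclasses.asdict(params)}
        if len(cset) == 0:
            summary["empty"] = True
            _write_json(summary, outdir / "canyon_summary.json")
            files.append("canyon_summary.json")
            return {"files": files, "summary": summary}

        assignment = _canyons.map_probes(cset, manifest)
        summary["n_canyon_probes"] = int((assignment >= 0).sum())
        gm = _canyons.canyon_group_means(assignment, beta, labels)
        summary["group_means"] = gm
        log.info("canyon probes: %d; delta_beta=%.4f (p=%.3g)",
                 summary["n_canyon_probes"], gm["delta_beta"], gm["welch_p"])
        profile = _canyons.size_normalized_profile(
            cset, assignment, beta, labels, n_bins=config.canyon.get("n_bins", 50)
        )
        _write_table(profile, outdir / "canyon_metaprofile.tsv", index=False)
        files.append("canyon_metaprofile.tsv")
        _write_json(summary, outdir / "canyon_summary.json")
        files.append("canyon_summary.json")
        return {"files": files, "summary": summary}

    return run()


def run_all(config: RunConfig, outdir) -> dict:
    """Full pipeline; writes the bundle manifest and echoed config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    cohort = run_cohort_contrast(config, outdir)
    canyon = run_canyon_analysis(config, outdir)

    from importlib.metadata import PackageNotFoundError, version

    try:
        pkg_version = version("methylotype")
    except PackageNotFoundError:
        pkg_version = "unknown"

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "version": pkg_version,
        "files": ["config.yaml"] + cohort["files"] + canyon["files"],
        "summary": {"cohort": cohort["summary"], "canyon": canyon["summary"]},
    }
    _write_json(manifest, outdir / "bundle_manifest.json")
    missing = [f for f in manifest["files"] if not (outdir / f).exists()]
    if missing:
        raise StageError("inputs", FileNotFoundError(f"bundle files missing: {missing}"))
    return manifest
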