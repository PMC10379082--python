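"""Stage orchestration with a YAML config and reproducible run manifests.

A run executes the requested stages in the fixed analysis order
(simulate -> filter -> stats -> scan -> ld -> ne -> pca -> admixture),
writing each stage's tables next to the manifest.  The manifest records
parameters, input hashes and a content hash for every output file, so a
rerun with the same config and seed yields an identical manifest for
every deterministic stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity, filtering, linkage, simulate, structure, sweep, vcf_io

log = logging.getLogger(__name__)

STAGE_ORDER = ["simulate", "filter", "stats", "scan", "ld", "ne", "pca", "admixture"]

_KNOWN_KEYS = {
    "stages", "seed", "out_dir", "vcf", "pops", "gff",
    "simulate", "filter", "scan", "ld", "ne", "pca", "admixture", "stats",
}


@dataclass
class RunConfig:
    stages: list
    out_dir: str
    seed: int = 0
    vcf: str | None = None
    pops: str | None = None
    gff: str | None = None
    stage_params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict):
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        stages = raw.get("stages") or []
        bad = [s for s in stages if s not in STAGE_ORDER]
        if bad:
            raise ValueError(f"unknown stages: {bad}")
        stage_params = {k: raw.get(k) or {} for k in STAGE_ORDER}
        return cls(
            stages=sorted(stages, key=STAGE_ORDER.index),
            out_dir=raw.get("out_dir", "radsweep_out"),
            seed=int(raw.get("seed", 0)),
            vcf=raw.get("vcf"),
            pops=raw.get("pops"),
            gff=raw.get("gff"),
            stage_params=stage_params,
        )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_config(cfg: RunConfig):
    """Fail fast on inconsistent stage requests before any work runs."""
    if not cfg.stages:
        raise ValueError("no stages requested")
    if "scan" in cfg.stages:
        pair = (cfg.stage_params.get("scan") or {}).get("pair")
        if not pair or len(pair) != 2:
            raise ValueError("scan stage needs pair: [ref_pop, focal_pop]")
        known = None
        if "simulate" in cfg.stages:
            sim = cfg.stage_params.get("simulate") or {}
            known = sim.get("pop_labels") or [
                f"pop{i + 1}" for i in range(sim.get("n_pops", 2))
            ]
        elif cfg.pops:
            known = list(
                vcf_io.read_population_map(cfg.pops).assignments.values()
            )
        if known is not None:
            missing = [p for p in pair if p not in known]
            if missing:
                raise ValueError(f"scan pair references unknown population(s) {missing}")
    needs_input = [s for s in cfg.stages if s != "simulate"]
    if needs_input and "simulate" not in cfg.stages and not cfg.vcf:
        raise ValueError("stages other than 'simulate' need an input VCF")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    validate_config(cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": cfg.seed, "stages": {}}
    vt = gm = pmap = genes = None
    scan_windows = None

    def _load_inputs():
        nonlocal vt, gm, pmap, genes
        if vt is None:
            if cfg.vcf is None:
                raise ValueError("stage needs a VCF: provide one or run 'simulate'")
            vt, gm = vcf_io.read_vcf(cfg.vcf)
            if cfg.pops:
                pmap = vcf_io.read_population_map(cfg.pops, gm.samples)
        if genes is None and cfg.gff:
            genes = vcf_io.read_gff_genes(cfg.gff)

    def _record(stage, params, files):
        manifest["stages"][stage] = {
            "params": params,
            "outputs": {str(Path(f).name): _sha256(f) for f in files},
        }

    for stage in cfg.stages:
        params = dict(cfg.stage_params.get(stage) or {})
        log.info("pipeline: stage %s", stage)
        try:
            if stage == "simulate":
                sweeps = [simulate.SweepSpec(**s) for s in params.pop("sweep_regions", [])]
                sim_cfg = simulate.SimulationConfig(
                    seed=params.pop("seed", cfg.seed), sweep_regions=sweeps, **params
                )
                vt, gm, pmap, truth = simulate.simulate_balding_nichols(sim_cfg)
                genes = simulate.toy_gff_genes(sim_cfg.n_chrom, sim_cfg.chrom_length_bp)
                paths = simulate.write_simulation(out, vt, gm, pmap, truth, genes)
                cfg.vcf = str(paths["vcf"])
                cfg.pops = str(paths["pops"])
                _record(stage, params | {"seed": sim_cfg.seed}, paths.values())

            elif stage == "filter":
                _load_inputs()
                fp = filtering.FilterParams(**params)
                vt, gm, reports = filtering.apply_filter_pipeline(vt, gm, fp, pmap)
                vcf_path = out / "filtered.vcf"
                rep_path = out / "filter_report.tsv"
                vcf_io.write_vcf(vcf_path, vt, gm)
                filtering.reports_to_tsv(reports, rep_path)
                _record(stage, params, [vcf_path, rep_path])

            elif stage == "stats":
                _load_inputs()
                if pmap is None:
                    raise ValueError("stats stage needs a population map")
                tbl = diversity.diversity_table(gm, pmap)
                path = out / "diversity.tsv"
                tbl.to_csv(path, sep="\t", index=False, float_format="%.6f")
                dens = vcf_io.snp_density(vt, params.get("density_window_bp", 100_000))
                dpath = out / "snp_density.tsv"
                dens.to_csv(dpath, sep="\t", index=False)
                _record(stage, params, [path, dpath])

            elif stage == "scan":
                _load_inputs()
                if pmap is None:
                    raise ValueError("scan stage needs a population map")
                pair = params.get("pair")
                if not pair:
                    raise ValueError("scan stage needs pair: [ref_pop, focal_pop]")
                for p in pair:
                    if p not in pmap.populations:
                        raise ValueError(f"unknown population {p!r} in scan pair")
                wf, regions, (t_z, t_r) = sweep.sweep_scan(
                    vt, gm, pmap, pair[0], pair[1],
                    window_bp=params.get("window_bp", 100_000),
                    step_bp=params.get("step_bp", 10_000),
                    quantile=params.get("quantile", 0.95),
                    genes=genes,
                )
                wpath = out / "scan_windows.tsv"
                rpath = out / "sweep_regions.tsv"
                wf.to_csv(wpath, sep="\t", index=False, float_format="%.6g")
                sweep.regions_to_tsv(regions, rpath)
                scan_windows = wf
                _record(stage, params | {"t_z": round(t_z, 6), "t_ratio": round(t_r, 6)},
                        [wpath, rpath])

            elif stage == "ld":
                _load_inputs()
                rng = np.random.default_rng(params.get("seed", cfg.seed))
                d, r2 = linkage.ld_pairs(
                    gm, vt,
                    max_dist=params.get("max_dist", 100_000),
                    maf_min=params.get("maf_min", 0.05),
                    max_missing=params.get("max_missing", 0.1),
                    max_snps_per_chrom=params.get("max_snps_per_chrom", 10_000),
                    rng=rng,
                )
                bins = linkage.ld_decay_bins(d, r2)
                path = out / "ld_decay.tsv"
                linkage.bins_to_tsv(bins, path)
                manifest.setdefault("_ld_bins", bins)
                _record(stage, params, [path])

            elif stage == "ne":
                _load_inputs()
                bins = manifest.pop("_ld_bins", None)
                if bins is None:
                    raise ValueError("ne stage requires the ld stage in the same run")
                est = linkage.ne_from_ld(
                    bins, n=gm.n_samples,
                    bp_per_cM=params.get("bp_per_cM", 1e6),
                    alpha=params.get("alpha", 1.0),
                )
                path = out / "ne_trajectory.tsv"
                linkage.ne_to_tsv(est, path)
                _record(stage, params, [path])

            elif stage == "pca":
                _load_inputs()
                res = structure.pca(gm, n_components=params.get("n_components", 10))
                df = pd.DataFrame(
                    res.coords, columns=[f"PC{i + 1}" for i in range(res.coords.shape[1])]
                )
                df.insert(0, "sample", gm.samples)
                path = out / "pca.tsv"
                df.to_csv(path, sep="\t", index=False, float_format="%.6f")
                _record(stage, params, [path])

            elif stage == "admixture":
                _load_inputs()
                ks = params.get("k_range", [2, 3, 4])
                tbl = structure.choose_k(
                    gm, k_range=ks,
                    n_runs=params.get("n_runs", 20),
                    cv_folds=params.get("cv_folds", 5),
                    seed=params.get("seed", cfg.seed),
                    max_iter=params.get("max_iter", 300),
                )
                cv_path = out / "admixture_cv.tsv"
                tbl.to_csv(cv_path, sep="\t", index=False, float_format="%.6f")
                best_k = int(tbl.loc[tbl["cv_error"].idxmin(), "K"])
                fit = structure.best_of_runs(
                    gm, best_k, n_runs=params.get("n_runs", 20),
                    seed=params.get("seed", cfg.seed),
                    max_iter=params.get("max_iter", 300),
                )
                q = pd.DataFrame(fit.Q, columns=[f"q{k + 1}" for k in range(best_k)])
                q.insert(0, "sample", gm.samples)
                q_path = out / "admixture_Q.tsv"
                q.to_csv(q_path, sep="\t", index=False, float_format="%.6f")
                _record(stage, params | {"best_k": best_k}, [cv_path, q_path])

        except Exception as exc:
            # keep partial outputs recognizable
            part = out / f"{stage}.partial"
            part.write_text(f"stage failed: {exc}\n")
            log.error("pipeline: stage %s failed: %s", stage, exc)
            raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest.pop("_ld_bins", None)
    mpath = out / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
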