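"""End-to-end orchestration: qc -> normalize -> trends -> breakpoints -> annotate."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate, breakpoints, normalize, qc, trajectory
from ._utils import child_seed
from .breakpoints import ScanConfig

log = logging.getLogger(__name__)

STAGES = ("qc", "normalize", "trends", "breakpoints", "annotate")


@dataclass
class RunConfig:
    counts: str
    samples: str
    outdir: str
    assay: str = "atac"                 # atac | rna
    fdr_threshold: float | None = None  # default 0.05 atac / 0.10 rna
    gene_sets: str | None = None        # GMT path for enrichment / choose_k
    k: int = 3
    nstart: int = 100
    max_iter: int = 100
    max_p: int = 5
    max_q: int = 5
    # peak-filter thresholds; max_cpm=500 presumes a genome-scale peak set
    # (CPM scales inversely with the number of features)
    min_reads: int = 20
    max_cpm: float = 500.0
    seed: int = 0
    scan: ScanConfig = field(default_factory=ScanConfig)

    def __post_init__(self):
        if self.assay not in ("atac", "rna"):
            raise ValueError("assay must be 'atac' or 'rna'")
        if self.fdr_threshold is None:
            self.fdr_threshold = 0.05 if self.assay == "atac" else 0.10

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        scan = doc.pop("scan", None)
        cfg = cls(**doc)
        if scan:
            scan.setdefault("windows", list(ScanConfig().windows))
            scan["windows"] = tuple(scan["windows"])
            if "bandwidths" in scan:
                scan["bandwidths"] = tuple(scan["bandwidths"])
            cfg.scan = ScanConfig(**scan)
        return cfg

    def param_hash(self) -> str:
        doc = dataclasses.asdict(self)
        blob = json.dumps(doc, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage_seed(config: RunConfig, stage: str) -> int:
    return child_seed(config.seed, STAGES.index(stage))


def run_pipeline(config: RunConfig, counts: pd.DataFrame | None = None,
                 samples: pd.DataFrame | None = None) -> dict:
    """Execute every stage; returns the run manifest.

    Stage outputs are written under ``config.outdir``; a failing stage
    aborts with its name and cause while earlier outputs are retained.
    """
    from . import io as eio

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if counts is None:
        counts = eio.read_counts_tsv(config.counts)
    if samples is None:
        samples = eio.read_sample_table(config.samples)
    gene_sets = eio.read_gmt(config.gene_sets) if config.gene_sets else None

    manifest = {"seed": config.seed, "assay": config.assay,
                "param_hash": config.param_hash(), "stages": {}}
    stage = None
    try:
        # ------------------------------------------------------------- qc
        stage = "qc"
        kept = qc.filter_peaks(counts, min_reads=config.min_reads,
                               max_cpm=config.max_cpm)
        counts = counts.loc[kept]
        calls = qc.derive_calls(counts)
        old = samples["age"] >= samples["age"].median()
        bench = qc.discover_benchmark_peaks(counts, calls, old)
        if len(bench):
            flags = qc.flag_samples(calls, bench)
        else:
            log.warning("no benchmark peaks found; sample QC flagging skipped")
            flags = pd.DataFrame({"benchmark_call_rate": np.nan,
                                  "qc_pass": True}, index=counts.columns)
        flags.to_csv(out / "sample_qc.tsv", sep="\t")
        good = flags.index[flags["qc_pass"]]
        counts = counts[good]
        samples = samples.loc[good]
        manifest["stages"]["qc"] = {
            "kept_features": int(len(kept)), "benchmark_peaks": int(len(bench)),
            "passed_samples": int(len(good)),
        }

        # ------------------------------------------------------ normalize
        stage = "normalize"
        factors = normalize.tmm_factors(counts)
        eff = normalize.effective_lib_size(counts, factors)
        null_design = pd.DataFrame({
            "log2_eff_libsize": np.log2(eff),
        }, index=counts.columns)
        if "batch" in samples.columns and samples["batch"].nunique() > 1:
            null_design = pd.concat(
                [null_design,
                 pd.get_dummies(samples["batch"], prefix="batch", drop_first=True,
                                dtype=float)], axis=1)
        adjusted = normalize.model_adjusted_values(
            counts, null_design, factors, protect=("age_group", "sex"))
        adjusted.to_csv(out / "adjusted_values.tsv", sep="\t")
        design = null_design.copy()
        design["age_group"] = old.loc[counts.columns].astype(float)
        diff = normalize.differential_test(counts, design, "age_group",
                                           fdr_threshold=config.fdr_threshold)
        diff.table.to_csv(out / "differential.tsv", sep="\t")
        manifest["stages"]["normalize"] = {
            "n_significant": int(diff.table["significant"].sum()),
            "fdr_threshold": config.fdr_threshold,
        }

        # --------------------------------------------------------- trends
        stage = "trends"
        seed = _stage_seed(config, "trends")
        models, clusters, zs = {}, {}, {}
        for sex in ("F", "M"):
            ages, series = trajectory.build_age_series(adjusted, samples, sex)
            models[sex] = trajectory.fit_all(series, max_p=config.max_p,
                                             max_q=config.max_q)
            ids = trajectory.select_trending(models[sex])
            z = trajectory.fitted_zscores(models[sex], ids)
            zs[sex] = z
            if len(z) >= config.k:
                clusters[sex] = trajectory.cluster_trends(
                    z, config.k, nstart=config.nstart,
                    max_iter=config.max_iter, seed=seed)
                clusters[sex].labels.to_csv(out / f"clusters_{sex}.tsv", sep="\t")
        shared = sorted(set(zs["F"].index) & set(zs["M"].index))
        if len(shared) >= config.k:
            shared_clusters, _ = trajectory.concat_shared(
                models["F"], models["M"], shared, config.k,
                nstart=config.nstart, max_iter=config.max_iter, seed=seed)
            shared_clusters.labels.to_csv(out / "clusters_shared.tsv", sep="\t")
        manifest["stages"]["trends"] = {
            sex: {"n_trending": int(len(zs[sex]))} for sex in ("F", "M")
        }
        manifest["stages"]["trends"]["n_shared"] = len(shared)

        # ---------------------------------------------------- breakpoints
        stage = "breakpoints"
        if config.assay == "rna":
            log.info("assay=rna: breakpoint stage skipped "
                     "(age sampling too sparse for windowed tests)")
            manifest["stages"]["breakpoints"] = {"skipped": "rna assay"}
        else:
            cfg = dataclasses.replace(config.scan,
                                      seed=_stage_seed(config, "breakpoints"))
            intervals = []
            curve_rows = []
            for sex in ("F", "M"):
                if sex not in clusters:
                    continue
                cols = samples.index[samples["sex"] == sex]
                ages = samples.loc[cols, "age"].to_numpy()
                for c in range(clusters[sex].k):
                    members = clusters[sex].members(c)
                    if len(members) < cfg.n_pcs:
                        continue
                    det = breakpoints.BreakpointDetector(cfg).fit(
                        adjusted.loc[members, cols].T, ages)
                    for w, curve in det.curves_.items():
                        if len(curve.table):
                            curve_rows.append(curve.table.assign(
                                w=w, cluster=c, sex=sex))
                    intervals += [{
                        "cluster": int(c), "sex": sex,
                        "median_age": iv.median_age,
                        "range": [iv.age_min, iv.age_max],
                        "combined_p": iv.combined_p,
                    } for iv in det.intervals_]
            if curve_rows:
                pd.concat(curve_rows, ignore_index=True).to_csv(
                    out / "breakpoint_curves.tsv", sep="\t", index=False)
            (out / "breakpoints.json").write_text(json.dumps(intervals, indent=2))
            manifest["stages"]["breakpoints"] = {"n_intervals": len(intervals)}

        # -------------------------------------------------------- annotate
        stage = "annotate"
        if gene_sets:
            sig = diff.significant
            enr = annotate.enrichment_test(sig, gene_sets, counts.index)
            enr.to_csv(out / "enrichment.tsv", sep="\t")
            manifest["stages"]["annotate"] = {
                "n_enriched": int((enr["fdr"] <= 0.05).sum())}
        else:
            manifest["stages"]["annotate"] = {"skipped": "no gene sets supplied"}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()).hexdigest()[:16]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
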