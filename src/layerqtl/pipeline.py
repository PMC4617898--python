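"""End-to-end orchestration: simulate/load -> QC -> adjust -> kinship ->
scan -> QTL calling -> interaction tests -> report.

Every stage writes its artifacts as TSV under the configured output
directory and appends to a plain-text log; a manifest of SHA-256 hashes
makes byte-for-byte reproducibility checkable. Re-running with the same
configuration and seed reproduces every artifact exactly.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as lio
from .adjust import adjust_phenotypes
from .data import CONDITION_ALL, GenotypeMatrix, Pedigree, PipelineError
from .gwas import MixedModelScan, compute_thresholds
from .gxe import within_condition_scan_and_augment
from .kinship import build_A
from .qc import apply_snp_filters
from .qtl import call_qtls, merge_across_traits
from .simulate import SimConfig, simulate_dataset

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "analyze_dataset"]


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    Either ``sim`` (synthetic data) or the three input paths
    (``genotypes_path`` + ``pedigree_path`` + ``phenotypes_path``) must
    be set. ``trait_kinds`` maps trait name to ``production``/``quality``
    and is inferred from the data when omitted (records without an age
    label are production traits).
    """

    out_dir: str = "layerqtl_out"
    sim: SimConfig | None = None
    genotypes_path: str | None = None
    genotypes_format: str = "pedmap"      # or "vcf"
    pedigree_path: str | None = None
    phenotypes_path: str | None = None
    trait_kinds: dict[str, str] | None = None
    # QC
    run_qc: bool = True
    snp_call_rate_min: float = 0.95
    ind_call_rate_min: float = 0.95
    maf_min: float = 0.05
    hwe_alpha: float = 0.05
    w_call_rate_min: float = 0.05
    # adjustment
    p_keep: float = 0.2
    sd_trim: float = 4.0
    # scan and thresholds
    chrom_level: float = 0.01
    genome_alpha: float = 0.05
    n_chromosomes: int | None = None
    unknown_chrom: str | None = None
    n_draws: int = 5_000
    threshold_method: str = "montecarlo"
    seed: int = 0
    # QTL and interaction options
    gap_tolerance: int = 0
    z_variant: str = "literal"
    class_alpha: float = 0.1
    run_gxe: bool = True

    def to_yaml(self, path: str) -> str:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)
        return path

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        sim = payload.pop("sim", None)
        cfg = cls(**payload)
        if sim is not None:
            from .simulate import QTLSpec, TraitSpec
            sim["traits"] = [TraitSpec(**t) for t in sim.get("traits", [])]
            sim["qtl_spec"] = [QTLSpec(**q) for q in sim.get("qtl_spec", [])]
            sim["maf_bounds"] = tuple(sim["maf_bounds"])
            cfg.sim = SimConfig(**sim)
        return cfg


@dataclass
class PipelineResult:
    config: PipelineConfig
    genotypes: GenotypeMatrix
    pedigree: Pedigree
    filter_report: pd.DataFrame | None
    sire_means: pd.DataFrame
    variance_components: pd.DataFrame
    scan_results: pd.DataFrame
    thresholds: pd.DataFrame
    qtl_catalogue: pd.DataFrame
    additional_qtls: pd.DataFrame
    interactions: pd.DataFrame
    manifest: dict[str, str] = field(default_factory=dict)


def _log(path: str, msg: str) -> None:
    stamp = datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds")
    with open(path, "a") as fh:
        fh.write(f"{stamp}\t{msg}\n")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def infer_trait_kinds(records: pd.DataFrame) -> dict[str, str]:
    kinds = {}
    for trait, grp in records.groupby("trait", sort=True):
        kinds[trait] = "production" if grp["age"].isna().all() else "quality"
    return kinds


def analyze_dataset(genotypes: GenotypeMatrix, pedigree: Pedigree,
                    records: pd.DataFrame, cfg: PipelineConfig
                    ) -> PipelineResult:
    """Run the analysis stages on in-memory data (no artifact writing)."""
    filter_frame = None
    if cfg.run_qc:
        genotypes, report = apply_snp_filters(
            genotypes, snp_call_rate_min=cfg.snp_call_rate_min,
            ind_call_rate_min=cfg.ind_call_rate_min, maf_min=cfg.maf_min,
            hwe_alpha=cfg.hwe_alpha, w_call_rate_min=cfg.w_call_rate_min)
        filter_frame = report.to_frame()

    trait_kinds = cfg.trait_kinds or infer_trait_kinds(records)
    records = records[records["sire"].isin(genotypes.sire_ids)]
    adjusted, exclusions, means = adjust_phenotypes(
        records, trait_kinds, p_keep=cfg.p_keep, sd_trim=cfg.sd_trim)

    A = build_A(pedigree, ids=genotypes.sire_ids)
    scanner = MixedModelScan(A)

    vc_rows, scan_frames, thr_rows = [], [], []
    all_qtls = []
    qtls_by_trait: dict[str, list] = {}
    add_frames, inter_rows = [], []
    for t_i, (trait, kind) in enumerate(sorted(trait_kinds.items())):
        sub = means[(means["trait"] == trait)
                    & (means["condition"] == CONDITION_ALL)]
        sub = sub.set_index("sire").reindex(scanner.ids)
        if sub["mean"].isna().any():
            raise PipelineError(f"trait {trait}: sires without adjusted means")
        y = sub["mean"].to_numpy(float)
        vc = scanner.fit_null_reml(y, trait, CONDITION_ALL)
        vc_rows.append({"trait": trait, "condition": CONDITION_ALL,
                        "sigma2_g": vc.sigma2_g, "sigma2_e": vc.sigma2_e,
                        "loglik": vc.loglik})
        res = scanner.scan(y, genotypes.dosages, genotypes.markers, vc)
        res.insert(0, "trait", trait)
        res.insert(1, "condition", CONDITION_ALL)
        scan_frames.append(res)
        ts = compute_thresholds(
            scanner, genotypes, vc, chrom_level=cfg.chrom_level,
            genome_alpha=cfg.genome_alpha, n_chromosomes=cfg.n_chromosomes,
            unknown_chrom=cfg.unknown_chrom, n_draws=cfg.n_draws,
            seed=cfg.seed + 10_000 * t_i, method=cfg.threshold_method)
        tf = ts.to_frame()
        tf.insert(0, "trait", trait)
        thr_rows.append(tf)
        var_sire = float(np.var(y, ddof=1))
        qtls = call_qtls(res, ts, trait=trait, condition=CONDITION_ALL,
                         var_sire=var_sire, gap_tolerance=cfg.gap_tolerance)
        all_qtls.extend(qtls)
        qtls_by_trait[trait] = qtls

    # merge before the interaction stage so whole-data QTL carry their
    # catalogue ids into the interaction table
    catalogue = merge_across_traits(all_qtls)

    if cfg.run_gxe:
        for t_i, (trait, kind) in enumerate(sorted(trait_kinds.items())):
            additional, inters = within_condition_scan_and_augment(
                means, genotypes, A, trait=trait,
                whole_qtls=qtls_by_trait[trait],
                chrom_level=cfg.chrom_level, genome_alpha=cfg.genome_alpha,
                n_chromosomes=cfg.n_chromosomes,
                unknown_chrom=cfg.unknown_chrom, n_draws=cfg.n_draws,
                seed=cfg.seed + 10_000 * t_i + 5_000,
                threshold_method=cfg.threshold_method,
                variant=cfg.z_variant, class_alpha=cfg.class_alpha,
                scanner=scanner)
            if additional:
                add_frames.append(pd.DataFrame(
                    [dataclasses.asdict(q) for q in additional]))
            inter_rows.extend(dataclasses.asdict(r) for r in inters)
    return PipelineResult(
        config=cfg, genotypes=genotypes, pedigree=pedigree,
        filter_report=filter_frame,
        sire_means=means,
        variance_components=pd.DataFrame(
            vc_rows, columns=["trait", "condition", "sigma2_g", "sigma2_e",
                              "loglik"]),
        scan_results=pd.concat(scan_frames, ignore_index=True),
        thresholds=pd.concat(thr_rows, ignore_index=True),
        qtl_catalogue=catalogue,
        additional_qtls=(pd.concat(add_frames, ignore_index=True)
                         if add_frames else pd.DataFrame()),
        interactions=pd.DataFrame(inter_rows),
    )


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run all stages, writing TSV artifacts, a log and a hash manifest.

    Data come either from ``cfg.sim`` (the synthetic generator) or from
    the configured genotype/pedigree/phenotype paths. Raises
    :class:`PipelineError` on stage failure; artifacts written up to the
    failure point are retained alongside the manifest.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    log = os.path.join(cfg.out_dir, "pipeline.log")
    cfg.to_yaml(os.path.join(cfg.out_dir, "config.yaml"))
    _log(log, f"start seed={cfg.seed}")

    if cfg.sim is not None:
        pedigree, genotypes, records = simulate_dataset(cfg.sim)
        _log(log, f"simulated {genotypes.n_sires} sires x "
                  f"{genotypes.n_markers} markers, {len(records)} records "
                  f"(sim seed={cfg.sim.seed})")
    else:
        if not (cfg.genotypes_path and cfg.pedigree_path and cfg.phenotypes_path):
            raise PipelineError("either sim or all three input paths required")
        genotypes = (lio.read_vcf(cfg.genotypes_path)
                     if cfg.genotypes_format == "vcf"
                     else lio.read_ped_map(cfg.genotypes_path))
        pedigree = lio.read_pedigree(cfg.pedigree_path)
        records = lio.read_phenotypes(cfg.phenotypes_path)
        _log(log, f"loaded {genotypes.n_sires} sires x "
                  f"{genotypes.n_markers} markers, {len(records)} records")

    result = analyze_dataset(genotypes, pedigree, records, cfg)

    artifacts = {
        "filter_report.tsv": result.filter_report,
        "sire_means.tsv": result.sire_means,
        "variance_components.tsv": result.variance_components,
        "scan_results.tsv": result.scan_results,
        "thresholds.tsv": result.thresholds,
        "qtl_catalogue.tsv": result.qtl_catalogue,
        "additional_qtls.tsv": result.additional_qtls,
        "interactions.tsv": result.interactions,
    }
    for name, frame in artifacts.items():
        if frame is None:
            continue
        path = lio.write_table(frame, os.path.join(cfg.out_dir, name))
        result.manifest[name] = _sha256(path)
        _log(log, f"wrote {name} ({0 if frame is None else len(frame)} rows)")
    if result.filter_report is not None:
        counts = result.filter_report[["n_markers_excluded",
                                       "n_individuals_excluded"]].sum()
        _log(log, f"QC excluded markers={counts.iloc[0]} "
                  f"individuals={counts.iloc[1]}")
    manifest_path = os.path.join(cfg.out_dir, "manifest.tsv")
    pd.DataFrame(sorted(result.manifest.items()),
                 columns=["artifact", "sha256"]).to_csv(
        manifest_path, sep="\t", index=False)
    _log(log, "done")
    return result
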