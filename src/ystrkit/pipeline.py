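"""End-to-end pipeline: discover -> genotype -> site filters -> analytics.

A single YAML config drives every stage (unknown keys are rejected) and
each run writes a manifest accounting for every record: scanned loci =
kept + excluded per reason, genotyped loci = retained + dropped per
reason, so nothing silently disappears between stages.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import yaml

from . import io as yio
from .catalog import RegionMask, ScanParams, assign_names, filter_catalog, scan_tandem_repeats
from .genotyper import FilterConfig, StutterModel, female_read_counts, genotype_sample, site_filters
from .popgen import bruvo_matrix, gene_diversity, upgma


@dataclass
class PipelineConfig:
    reference: str = ""
    chrom: str | None = None
    mask: str | None = None
    sample_sheet: str = ""
    out_dir: str = "ystrkit_out"
    prefix: str = "YSTR"
    seed: int = 0
    lowcov: bool = False
    scan: dict = field(default_factory=dict)  # ScanParams overrides
    genotype: dict = field(default_factory=dict)  # FilterConfig overrides
    stutter: dict = field(default_factory=dict)  # StutterModel overrides
    popgen: dict = field(default_factory=dict)  # {tree: bool, diversity: bool}

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run discovery + genotyping + QC + basic analytics; returns the manifest."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    manifest: dict = {"config": asdict(cfg), "stages": {}}

    # --- discover -----------------------------------------------------
    try:
        ref = yio.read_fasta(cfg.reference, cfg.chrom)
        params = ScanParams(**cfg.scan)
        mask = yio.read_bed_mask(cfg.mask) if cfg.mask else RegionMask()
        scanned = scan_tandem_repeats(ref, params)
        kept, excluded = filter_catalog(scanned, mask, params)
        catalog = assign_names(kept, cfg.prefix)
    except Exception as exc:  # noqa: BLE001
        raise StageError("discover", str(exc)) from exc
    reasons: dict[str, int] = {}
    for L in excluded:
        reasons[L.exclusion_reason] = reasons.get(L.exclusion_reason, 0) + 1
    manifest["stages"]["discover"] = {
        "scanned": len(scanned),
        "kept": len(catalog),
        "excluded_by_reason": reasons,
    }
    yio.write_catalog_bed(catalog, os.path.join(cfg.out_dir, "catalog.bed"))
    yio.write_catalog_tsv(catalog, os.path.join(cfg.out_dir, "catalog.tsv"), excluded)
    if not catalog:
        raise StageError("genotype", "catalog is empty after filtering; nothing to genotype")

    # --- genotype -----------------------------------------------------
    try:
        sheet = yio.read_sample_sheet(cfg.sample_sheet)
        fcfg = FilterConfig.lowcov(**cfg.genotype) if cfg.lowcov else FilterConfig(**cfg.genotype)
        model = StutterModel(**cfg.stutter)
        males = [r for r in sheet if r.sex == "M"]
        females = [r for r in sheet if r.sex == "F"]
        calls: dict[str, dict] = {L.name: {} for L in catalog}
        for row in males:
            reads = yio.read_alignments(row.path)
            for call in genotype_sample(reads, catalog, model, fcfg, sample=row.sample):
                calls[call.locus][row.sample] = call
        fem_reads = {r.sample: yio.read_alignments(r.path) for r in females}
        fem_counts = female_read_counts(fem_reads, catalog, fcfg)
        site_kept, site_dropped, stats = site_filters(calls, fem_counts, fcfg)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("genotype", str(exc)) from exc
    drop_reasons: dict[str, int] = {}
    for name in site_dropped:
        r = stats[name].drop_reason
        drop_reasons[r] = drop_reasons.get(r, 0) + 1
    manifest["stages"]["genotype"] = {
        "samples_male": len(males),
        "samples_female": len(females),
        "loci_in": len(catalog),
        "loci_retained": len(site_kept),
        "dropped_by_reason": drop_reasons,
    }
    kept_catalog = [L for L in catalog if L.name in set(site_kept)]
    kept_calls = {name: calls[name] for name in site_kept}
    yio.write_vcf(
        os.path.join(cfg.out_dir, "calls.vcf"),
        ref, kept_catalog, kept_calls, [r.sample for r in males], stats,
    )
    with open(os.path.join(cfg.out_dir, "dropped_sites.tsv"), "w") as fh:
        fh.write("locus\treason\tmissing_frac\tmax_female_reads\n")
        for name in site_dropped:
            st = stats[name]
            fh.write(f"{name}\t{st.drop_reason}\t{st.missing_frac:.4f}\t{st.max_female_reads}\n")

    # --- popgen -------------------------------------------------------
    if site_kept and len(males) >= 2:
        matrix, _ = yio.read_vcf(os.path.join(cfg.out_dir, "calls.vcf"))
        dist = bruvo_matrix(matrix)
        yio.write_distance_tsv(dist, os.path.join(cfg.out_dir, "bruvo.tsv"))
        popstats: dict = {}
        if not dist.isna().any().any():
            tree = upgma(dist)
            yio.write_newick(tree, os.path.join(cfg.out_dir, "upgma.nwk"))
            popstats["tree"] = "upgma.nwk"
        _, means = gene_diversity(matrix)
        popstats["mean_gene_diversity"] = {k: round(v, 6) for k, v in means.items()}
        manifest["stages"]["popgen"] = popstats

    manifest["checksum"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True, default=str).encode()
    ).hexdigest()
    with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
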