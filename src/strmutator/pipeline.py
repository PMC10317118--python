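"""End-to-end orchestration: simulate or ingest a panel, infer founder
haplotypes, call and filter mutations, compute mutator phenotypes, scan
for QTLs and summarise mutation patterns -- with per-stage checkpoints
keyed by a config+seed hash so a rerun resumes after the last completed
stage.

A single config mapping (YAML on disk or a dict) drives everything; see
``DEFAULT_CONFIG`` for the full set of keys.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calling, founders as finf, io as fio, patterns, phenotypes as phen, qtl
from .sim import (
    BreedingPlan,
    MutationModelParams,
    generate_founders,
    render_panel,
    simulate_panel,
)
from .types import (
    ConfigurationError,
    FounderPanel,
    GenotypeTables,
    LabelTracks,
    MarkerMap,
    ScanResult,
)

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {
        "n_chromosomes": 5,
        "n_markers_per_chrom": 200,
        "n_strs_per_chrom": 1000,
        "frac_snp_informative": 0.95,
        "frac_str_polymorphic": 0.3,
        "frac_founder_missing": 0.05,
        "missing_call_rate": 0.0,
        "het_error_rate": 0.0,
        "epochs": [
            {"id": "1", "n_strains": 30, "n_generations": 20},
            {"id": "2", "n_strains": 30, "n_generations": 40},
            {"id": "3", "n_strains": 30, "n_generations": 60},
            {"id": "4", "n_strains": 30, "n_generations": 80},
            {"id": "5", "n_strains": 30, "n_generations": 100},
        ],
        "model": {
            "base_rate_per_transmission": 1e-3,
            "length_slope": 0.02,
            "rate_cap": 0.05,
            "step_geometric_p": 0.9,
            "expansion_prob_B": 0.5,
            "expansion_prob_D": 0.5,
            "mutator_locus": None,
        },
    },
    "inputs": None,  # real-data mode: paths for str_vcf, snp_table, metadata, marker_map, founder_snps, founder_strs
    "founder_inference": {"error_rate": 0.002, "min_prob": 0.5},
    "calling": {"max_strains": 10, "min_mutations": 10, "outlier_fold": 2.0},
    "scan": {
        "phenotypes": ["mutation_count", "expansion_propensity"],
        "n_perm": 100,
        "alphas": [0.05],
        "lod_drop": 1.5,
        "per_motif_length": False,
    },
    "patterns": {"bin_width_bp": 4.0, "focal_marker": None, "group_by": ["motif_len"]},
    "pca": True,
    "sweep": None,  # e.g. {"max_strains": [5, 10, 20]}
    "epoch_subset": None,
}


def load_config(source: str | Path | dict | None) -> dict:
    """Merge a user config (YAML path or dict) over the defaults."""

    def merge(base: dict, over: dict) -> dict:
        out = copy.deepcopy(base)
        for k, v in over.items():
            if isinstance(v, dict) and isinstance(out.get(k), dict):
                out[k] = merge(out[k], v)
            else:
                out[k] = copy.deepcopy(v)
        return out

    if source is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    if isinstance(source, dict):
        return merge(DEFAULT_CONFIG, source)
    with open(source) as fh:
        user = yaml.safe_load(fh) or {}
    return merge(DEFAULT_CONFIG, user)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: dict
    founders: FounderPanel
    marker_map: MarkerMap
    tables: GenotypeTables
    truth: pd.DataFrame | None
    tracks: LabelTracks
    blocks: pd.DataFrame
    resolved_reference: pd.DataFrame
    dropped_loci: list[str]
    locus_labels: np.ndarray
    calls_raw: pd.DataFrame
    calls: pd.DataFrame
    outlier_strains: list[str]
    excluded_strains: list[str]
    analyzed_strains: list[str]
    phenotypes: pd.DataFrame
    pca_scores: pd.DataFrame | None
    scans: dict[str, ScanResult]
    pattern_tables: dict[str, pd.DataFrame]
    manifest: fio.RunManifest
    sweep_results: dict[str, dict] = field(default_factory=dict)


class _Checkpointer:
    def __init__(self, out_dir: Path | None, chash: str):
        self.out_dir = out_dir
        self.chash = chash

    def done_path(self, stage: str) -> Path | None:
        return None if self.out_dir is None else self.out_dir / f"stage_{stage}.done.json"

    def is_done(self, stage: str) -> bool:
        p = self.done_path(stage)
        if p is None or not p.exists():
            return False
        try:
            return json.loads(p.read_text()).get("config_hash") == self.chash
        except json.JSONDecodeError:
            return False

    def mark(self, stage: str) -> None:
        p = self.done_path(stage)
        if p is not None:
            p.write_text(json.dumps({"config_hash": self.chash, "stage": stage}))


def _simulate(cfg: dict, seed: int):
    sc = cfg["simulate"]
    panel, marker_map = generate_founders(
        sc["n_chromosomes"],
        sc["n_markers_per_chrom"],
        sc["n_strs_per_chrom"],
        sc["frac_snp_informative"],
        sc["frac_str_polymorphic"],
        sc["frac_founder_missing"],
        seed=seed,
    )
    model = MutationModelParams(**sc["model"])
    plan = BreedingPlan(
        [
            (e["id"], e["n_strains"], e["n_generations"], e.get("n_stock_generations", 0))
            for e in sc["epochs"]
        ],
        seed=seed + 1,
    )
    genomes, metadata = simulate_panel(panel, marker_map, plan, model)
    tables, truth = render_panel(
        genomes,
        panel,
        marker_map,
        metadata,
        missing_call_rate=sc["missing_call_rate"],
        het_error_rate=sc["het_error_rate"],
        seed=seed + 2,
    )
    return panel, marker_map, tables, truth


def _ingest(cfg: dict):
    paths = cfg["inputs"]
    marker_map = fio.read_marker_map(paths["marker_map"])
    snp_alleles = pd.read_csv(paths["founder_snps"], sep="\t", index_col="marker")
    str_ref = pd.read_csv(paths["founder_strs"], sep="\t", index_col="locus_id")
    panel = FounderPanel(snp_alleles, str_ref)
    geno, vcf_ref = fio.read_str_vcf(paths["str_vcf"])
    # founder reference is authoritative for motifs; VCF for genotypes
    snp_calls = fio.read_snp_table(paths["snp_table"])
    metadata = fio.read_metadata(paths["metadata"])
    fio.check_strain_consistency(geno, metadata, snp_calls)
    tables = GenotypeTables(snp_calls, geno, metadata)
    return panel, marker_map, tables, None


def _filter_and_phenotype(
    calls_raw: pd.DataFrame,
    tables: GenotypeTables,
    cfg_call: dict,
    manifest: fio.RunManifest,
    epoch_subset: list | None,
    stage_prefix: str = "",
):
    """Recurrence filter -> outlier exclusion -> per-strain minimum ->
    phenotype table.  Returns (calls, outliers, excluded, analyzed,
    phenotype table)."""
    calls_rec = calling.filter_recurrent(calls_raw, cfg_call["max_strains"])
    n_rec = len(calls_rec)
    outliers = calling.flag_outlier_strains(
        calls_rec, tables.metadata, cfg_call["outlier_fold"]
    )
    n_outlier_calls = int(calls_rec["strain_id"].isin(outliers).sum())
    calls_rec = calls_rec[~calls_rec["strain_id"].isin(outliers)].reset_index(drop=True)
    calls_flt, low_strains = calling.filter_strains(calls_rec, cfg_call["min_mutations"])

    meta = tables.metadata
    strains = list(meta["strain_id"])
    if epoch_subset is not None:
        keep_epochs = {str(e) for e in epoch_subset}
        strains = [s for s, e in zip(meta["strain_id"], meta["epoch"]) if str(e) in keep_epochs]
    analyzed = [s for s in strains if s not in set(outliers) | set(low_strains)]
    calls_used = calls_flt[
        (~calls_flt["strain_excluded"]) & calls_flt["strain_id"].isin(analyzed)
    ].drop(columns="strain_excluded")

    manifest.record(
        stage_prefix + "calls",
        input=len(calls_raw),
        dropped_recurrent=len(calls_raw) - n_rec,
        dropped_outlier_strain=n_outlier_calls,
        dropped_low_count_strain=int(calls_flt["strain_excluded"].sum()),
        dropped_subset=len(calls_flt[~calls_flt["strain_excluded"]]) - len(calls_used),
        retained=len(calls_used),
    )
    in_subset = set(strains)
    manifest.record(
        stage_prefix + "strains",
        input=len(meta),
        dropped_subset=len(meta) - len(strains),
        dropped_outlier=len(set(outliers) & in_subset),
        dropped_low_count=len((set(low_strains) - set(outliers)) & in_subset),
        retained=len(analyzed),
    )
    pheno = phen.build_phenotype_table(calls_used, tables.str_genotypes, meta, analyzed)
    return calls_used, outliers, sorted(low_strains), analyzed, pheno


def _scan_phenotypes(
    pheno: pd.DataFrame,
    tracks: LabelTracks,
    marker_map: MarkerMap,
    cfg_scan: dict,
    seed: int,
) -> dict[str, ScanResult]:
    strains = list(pheno.index)
    idx = [tracks.strains.index(s) for s in strains]
    genoprobs = finf.genotype_probabilities(tracks)[idx]
    kinship = qtl.calc_kinship_loco(genoprobs, marker_map)
    covar = np.column_stack(
        [np.ones(len(strains)), pheno["n_generations"].to_numpy(dtype=float)]
    )
    scans: dict[str, ScanResult] = {}
    for name in cfg_scan["phenotypes"]:
        y = pheno[name].to_numpy(dtype=float)
        scan = qtl.scan1(genoprobs, y, kinship, covar, marker_map)
        thresholds, _ = qtl.permutation_threshold(
            genoprobs,
            y,
            kinship,
            covar,
            marker_map,
            n_perm=cfg_scan["n_perm"],
            alphas=tuple(cfg_scan["alphas"]),
            seed=seed + int(hashlib.sha256(name.encode()).hexdigest(), 16) % 10_000,
        )
        scan.thresholds = thresholds
        alpha = min(cfg_scan["alphas"])
        thr = thresholds[float(alpha)]
        for chrom in scan.lod["chrom"].unique():
            if scan.lod.loc[scan.lod["chrom"] == chrom, "lod"].max() >= thr:
                scan.intervals[chrom] = qtl.lod_support_interval(
                    scan, chrom, cfg_scan["lod_drop"]
                )
        scans[name] = scan
    return scans


def run_all(config: dict | str | Path | None, out_dir: str | Path | None = None) -> PipelineResult:
    """Run every stage; deterministic given config+seed.

    When ``out_dir`` is given, all artifacts (tables, VCF, BED blocks,
    scan TSVs and JSON sidecars, the run manifest and the resolved
    config) are written there and completed stages are checkpointed so a
    rerun with the same config resumes from the serialized intermediates.
    """
    cfg = load_config(config)
    seed = int(cfg["seed"])
    chash = config_hash(cfg)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        (out / "resolved_config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=False))
    ckpt = _Checkpointer(out, chash)
    manifest = fio.RunManifest(config=cfg, seed=seed)
    logger.info("run_all: seed=%d config_hash=%s", seed, chash)

    # --- stage: panel (simulate or ingest) ---
    if cfg["inputs"] is not None:
        panel, marker_map, tables, truth = _ingest(cfg)
    elif out is not None and ckpt.is_done("simulate"):
        logger.info("resuming: simulate stage checkpoint found")
        marker_map = fio.read_marker_map(out / "marker_map.tsv")
        snp_alleles = pd.read_csv(out / "founders.snp_alleles.tsv", sep="\t", index_col="marker")
        str_ref = pd.read_csv(out / "founders.full_str_reference.tsv", sep="\t", index_col="locus_id")
        panel = FounderPanel(snp_alleles, str_ref)
        geno, _ = fio.read_str_vcf(out / "str_genotypes.vcf")
        tables = GenotypeTables(
            fio.read_snp_table(out / "snp_calls.tsv"), geno, fio.read_metadata(out / "metadata.tsv")
        )
        truth = pd.read_csv(out / "truth_mutations.tsv", sep="\t")
    else:
        panel, marker_map, tables, truth = _simulate(cfg, seed)
        if out is not None:
            fio.write_marker_map(out / "marker_map.tsv", marker_map)
            fio.write_founder_panel(out / "founders", panel)
            # full (unmasked) reference so a resumed run keeps the truth
            panel.str_reference.to_csv(
                out / "founders.full_str_reference.tsv", sep="\t", index_label="locus_id"
            )
            fio.write_snp_table(out / "snp_calls.tsv", tables.snp_calls)
            fio.write_str_vcf(out / "str_genotypes.vcf", tables.str_genotypes, panel.str_reference)
            fio.write_metadata(out / "metadata.tsv", tables.metadata)
            truth.to_csv(out / "truth_mutations.tsv", sep="\t", index=False)
            ckpt.mark("simulate")
    manifest.record(
        "panel",
        n_strains=len(tables.metadata),
        n_markers=marker_map.n_markers,
        n_loci=len(tables.str_genotypes.loci),
    )
    if out is not None:
        for f in ("snp_calls.tsv", "metadata.tsv", "str_genotypes.vcf"):
            p = out / f
            if p.exists():
                manifest.input_checksums[f] = fio.sha256_file(p)

    # --- stage: founder inference ---
    fi = cfg["founder_inference"]
    track0 = finf.assign_founder_labels(tables.snp_calls, panel, marker_map)
    tracks = finf.impute_missing_labels(track0, fi["error_rate"], fi["min_prob"])
    blocks = finf.build_blocks(tracks)
    locus_labels = finf.assign_locus_labels(
        blocks, panel.str_reference, tables.str_genotypes.strains
    )
    reported = panel.reported_str_reference()
    resolved_ref, dropped_loci = finf.infer_missing_founder_strs(
        reported, tables.str_genotypes, locus_labels
    )
    manifest.record(
        "founder_loci",
        input=len(reported),
        dropped_unresolved=len(dropped_loci),
        retained=len(reported) - len(dropped_loci),
    )
    if out is not None:
        fio.write_bed_blocks(out / "haplotype_blocks.bed", blocks)
        resolved_ref.to_csv(out / "resolved_str_reference.tsv", sep="\t", index_label="locus_id")

    # --- stage: calling + filters + phenotypes (optionally swept) ---
    calls_raw = calling.call_new_mutations(
        tables.str_genotypes, resolved_ref, locus_labels, dropped_loci
    )
    if out is not None:
        calls_raw.to_csv(out / "calls_raw.tsv", sep="\t", index=False)

    calls, outliers, low, analyzed, pheno = _filter_and_phenotype(
        calls_raw, tables, cfg["calling"], manifest, cfg["epoch_subset"]
    )
    pca_scores = None
    if cfg["pca"] and len(analyzed) >= 2 and not calls.empty:
        mat_ok = calls[["locus_id", "observed_ru"]].drop_duplicates().shape[0] >= 2
        if mat_ok:
            pca_scores, _ = phen.mutation_pca(calls, analyzed)
    if out is not None:
        calls.to_csv(out / "calls_filtered.tsv", sep="\t", index=False)
        pheno.to_csv(out / "phenotypes.tsv", sep="\t")
        if pca_scores is not None:
            pca_scores.to_csv(out / "pca_scores.tsv", sep="\t")

    # --- stage: QTL scans ---
    scans = _scan_phenotypes(pheno, tracks, marker_map, cfg["scan"], seed)
    if cfg["scan"].get("per_motif_length"):
        for ml in sorted(calls["motif_len"].unique()):
            sub = calls[calls["motif_len"] == ml]
            pheno_ml = phen.build_phenotype_table(
                sub, tables.str_genotypes, tables.metadata, analyzed
            )
            for name, scan in _scan_phenotypes(
                pheno_ml, tracks, marker_map, cfg["scan"], seed
            ).items():
                scans[f"{name}_motif{ml}"] = scan
    if out is not None:
        for name, scan in scans.items():
            scan.lod.to_csv(out / f"scan_{name}.tsv", sep="\t", index=False)
            sidecar = {
                "h2_by_chrom": scan.h2_by_chrom,
                "thresholds": {str(a): t for a, t in scan.thresholds.items()},
                "intervals": {c: list(iv) for c, iv in scan.intervals.items()},
            }
            (out / f"scan_{name}.json").write_text(json.dumps(sidecar, indent=2))

    # --- stage: pattern summaries (set patterns: null to skip) ---
    pat_cfg = cfg["patterns"]
    pattern_tables: dict[str, pd.DataFrame] = {}
    for grp in [None] + list(pat_cfg["group_by"]) if pat_cfg else []:
        key = grp or "overall"
        pattern_tables[key] = patterns.binned_mutation_rate(
            calls,
            tables.str_genotypes,
            resolved_ref,
            locus_labels,
            bin_width_bp=pat_cfg["bin_width_bp"],
            group_by=grp,
            tracks=tracks,
            focal_marker=pat_cfg["focal_marker"],
        )
    if pat_cfg and pat_cfg["focal_marker"] is not None:
        pattern_tables["haplotype_contrast"] = patterns.haplotype_contrast(
            calls,
            tables.str_genotypes,
            resolved_ref,
            locus_labels,
            tracks,
            pat_cfg["focal_marker"],
        )
    if out is not None:
        for key, tab in pattern_tables.items():
            tab.to_csv(out / f"patterns_{key}.tsv", sep="\t", index=False)

    result = PipelineResult(
        config=cfg,
        founders=panel,
        marker_map=marker_map,
        tables=tables,
        truth=truth,
        tracks=tracks,
        blocks=blocks,
        resolved_reference=resolved_ref,
        dropped_loci=dropped_loci,
        locus_labels=locus_labels,
        calls_raw=calls_raw,
        calls=calls,
        outlier_strains=outliers,
        excluded_strains=low,
        analyzed_strains=analyzed,
        phenotypes=pheno,
        pca_scores=pca_scores,
        scans=scans,
        pattern_tables=pattern_tables,
        manifest=manifest,
    )

    # --- optional filter sweep ---
    if cfg["sweep"]:
        for ms in cfg["sweep"].get("max_strains", [cfg["calling"]["max_strains"]]):
            for mm in cfg["sweep"].get("min_mutations", [cfg["calling"]["min_mutations"]]):
                sub_cfg = dict(cfg["calling"], max_strains=ms, min_mutations=mm)
                key = f"max_strains={ms},min_mutations={mm}"
                c2, o2, l2, a2, p2 = _filter_and_phenotype(
                    calls_raw, tables, sub_cfg, manifest, cfg["epoch_subset"],
                    stage_prefix=f"sweep[{key}].",
                )
                s2 = _scan_phenotypes(p2, tracks, marker_map, cfg["scan"], seed)
                result.sweep_results[key] = {
                    "calls": c2,
                    "phenotypes": p2,
                    "scans": s2,
                }
                if out is not None:
                    sweep_dir = out / f"sweep_ms{ms}_mm{mm}"
                    sweep_dir.mkdir(exist_ok=True)
                    c2.to_csv(sweep_dir / "calls_filtered.tsv", sep="\t", index=False)
                    p2.to_csv(sweep_dir / "phenotypes.tsv", sep="\t")
                    for name, scan in s2.items():
                        scan.lod.to_csv(sweep_dir / f"scan_{name}.tsv", sep="\t", index=False)

    if out is not None:
        manifest.to_json(out / "manifest.json")
    else:
        manifest.reconcile()
    return result
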