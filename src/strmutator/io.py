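"""Readers and writers for the pipeline's external formats.

Internal coordinates are 0-based half-open everywhere; conversion to
1-based happens only when writing/reading VCF, and BED stays 0-based.
STR genotypes travel as VCF 4.2 with an ``RU`` INFO field (motif) and a
per-sample ``REPCN`` FORMAT field carrying the diploid repeat-copy
numbers, mirroring common STR genotyper output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .types import FounderPanel, MarkerMap, SchemaError, STRGenotypes

logger = logging.getLogger(__name__)

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=RU,Number=1,Type=String,Description="Repeat unit (motif)">
##INFO=<ID=REF_RU,Number=1,Type=Integer,Description="Repeat-unit count of the REF allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=REPCN,Number=2,Type=Integer,Description="Diploid repeat-unit copy numbers">
"""


def write_str_vcf(
    path: str | Path,
    str_genotypes: STRGenotypes,
    str_reference: pd.DataFrame,
) -> None:
    """Write STR genotypes as VCF 4.2 (uncompressed text).

    One record per locus; REF spans the reference repeat (founder B
    allele where known, else D, else the smallest observed).  Missing
    calls are written as ``./.`` with missing REPCN.
    """
    path = Path(path)
    ref = str_reference.reindex(str_genotypes.loci)
    a1, a2 = str_genotypes.a1, str_genotypes.a2
    lines = [_VCF_HEADER]
    for chrom in dict.fromkeys(ref["chrom"]):
        lines.append(f"##contig=<ID={chrom}>\n")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(str_genotypes.strains)
        + "\n"
    )
    for j, (lid, row) in enumerate(ref.iterrows()):
        motif = row["motif"]
        ru_candidates = [row.get("ru_B"), row.get("ru_D")]
        ru_ref = next(
            (int(r) for r in ru_candidates if r is not None and not pd.isna(r)), None
        )
        obs = np.unique(np.concatenate([a1[:, j], a2[:, j]]))
        obs = obs[obs >= 0]
        if ru_ref is None:
            ru_ref = int(obs[0]) if obs.size else 1
        alts = [int(o) for o in obs if int(o) != ru_ref]
        allele_idx = {ru_ref: 0, **{a: i + 1 for i, a in enumerate(alts)}}
        alt_field = ",".join(motif * a for a in alts) if alts else "."
        fields = [
            row["chrom"],
            str(int(row["pos_bp"]) + 1),  # 0-based internal -> 1-based VCF
            str(lid),
            motif * ru_ref,
            alt_field,
            ".",
            ".",
            f"RU={motif};REF_RU={ru_ref}",
            "GT:REPCN",
        ]
        samples = []
        for i in range(len(str_genotypes.strains)):
            if a1[i, j] < 0 or a2[i, j] < 0:
                samples.append("./.:.,.")
            else:
                g1, g2 = allele_idx[int(a1[i, j])], allele_idx[int(a2[i, j])]
                samples.append(f"{g1}/{g2}:{a1[i, j]},{a2[i, j]}")
        lines.append("\t".join(fields + samples) + "\n")
    path.write_text("".join(lines))


def read_str_vcf(path: str | Path) -> tuple[STRGenotypes, pd.DataFrame]:
    """Read a REPCN-style STR VCF into genotype arrays plus a locus
    table (chrom, pos_bp, motif, motif_len).  ``./.`` and absent REPCN
    become missing calls; positions convert to 0-based."""
    path = Path(path)
    vcf = VCF(str(path))
    strains = list(vcf.samples)
    loci, rows, g1, g2 = [], [], [], []
    for rec in vcf:
        motif = rec.INFO.get("RU")
        if motif is None:
            raise SchemaError(
                f"record {rec.CHROM}:{rec.POS} ({rec.ID}) lacks the RU INFO tag"
            )
        loci.append(rec.ID)
        rows.append((rec.CHROM, rec.POS - 1, motif, len(motif)))
        repcn = rec.format("REPCN")
        if repcn is None:
            a = np.full((len(strains), 2), -1, dtype=np.int32)
        else:
            a = np.asarray(repcn, dtype=np.int64)
            a = np.where((a < 0) | (a > np.iinfo(np.int32).max // 2), -1, a)
        # any missing half -> whole call missing
        miss = (a < 0).any(axis=1)
        a[miss] = -1
        g1.append(a[:, 0])
        g2.append(a[:, 1])
    ref = pd.DataFrame(
        rows,
        columns=["chrom", "pos_bp", "motif", "motif_len"],
        index=pd.Index(loci, name="locus_id"),
    )
    geno = STRGenotypes(
        strains,
        ref.index,
        np.stack(g1, axis=1) if g1 else np.empty((len(strains), 0), dtype=np.int32),
        np.stack(g2, axis=1) if g2 else np.empty((len(strains), 0), dtype=np.int32),
    )
    return geno, ref


def write_snp_table(path: str | Path, snp_calls: pd.DataFrame) -> None:
    snp_calls.to_csv(path, sep="\t", index_label="strain_id")


def read_snp_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="strain_id", dtype=str)
    bad = set(np.unique(df.fillna("NA").to_numpy())) - {"B", "H", "D", "NA"}
    if bad:
        raise SchemaError(f"SNP table contains invalid values: {sorted(bad)}")
    return df.fillna("NA")


def write_metadata(path: str | Path, metadata: pd.DataFrame) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"strain_id": str, "epoch": str})
    required = {"strain_id", "epoch", "n_generations"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"metadata missing columns: {sorted(missing)}")
    return df


def check_strain_consistency(
    str_genotypes: STRGenotypes, metadata: pd.DataFrame, snp_calls: pd.DataFrame
) -> None:
    """Every strain in the genotype files must appear in the metadata."""
    meta = set(metadata["strain_id"])
    for name, strains in (
        ("STR VCF", set(str_genotypes.strains)),
        ("SNP table", set(snp_calls.index)),
    ):
        orphan = strains - meta
        if orphan:
            raise SchemaError(
                f"strains in {name} absent from metadata: {sorted(orphan)[:5]}"
            )


def write_bed_blocks(path: str | Path, blocks: pd.DataFrame) -> None:
    """Haplotype blocks as a multi-strain BED-like TSV (0-based
    half-open): chrom, start, end, label, strain_id."""
    blocks[["chrom", "start_bp", "end_bp", "label", "strain_id"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_bed_blocks(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        names=["chrom", "start_bp", "end_bp", "label", "strain_id"],
        dtype={"chrom": str, "label": str, "strain_id": str},
    )
    return df[["strain_id", "chrom", "start_bp", "end_bp", "label"]]


def write_marker_map(path: str | Path, marker_map: MarkerMap) -> None:
    marker_map.df.to_csv(path, sep="\t", index=False)


def read_marker_map(path: str | Path) -> MarkerMap:
    return MarkerMap(pd.read_csv(path, sep="\t"))


def write_founder_panel(path_prefix: str | Path, panel: FounderPanel) -> None:
    prefix = Path(path_prefix)
    panel.snp_alleles.to_csv(f"{prefix}.snp_alleles.tsv", sep="\t", index_label="marker")
    panel.reported_str_reference().to_csv(
        f"{prefix}.str_reference.tsv", sep="\t", index_label="locus_id"
    )


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Provenance record for one pipeline run.

    ``counts`` holds per-stage record counts; drop reasons must
    reconcile: for each stage recording an ``input``/``retained`` pair,
    input = retained + sum of ``dropped_*`` entries.
    """

    config: dict = dataclasses.field(default_factory=dict)
    seed: int = 0
    input_checksums: dict = dataclasses.field(default_factory=dict)
    counts: dict = dataclasses.field(default_factory=dict)

    def record(self, stage: str, **kwargs: int) -> None:
        self.counts.setdefault(stage, {}).update({k: int(v) for k, v in kwargs.items()})

    def reconcile(self) -> None:
        """Raise if any stage's drop-reason counts do not add up."""
        for stage, c in self.counts.items():
            if "input" in c and "retained" in c:
                dropped = sum(v for k, v in c.items() if k.startswith("dropped_"))
                if c["input"] != c["retained"] + dropped:
                    raise ValueError(
                        f"manifest stage {stage!r} does not reconcile: "
                        f"{c['input']} != {c['retained']} + {dropped}"
                    )

    def to_json(self, path: str | Path) -> None:
        self.reconcile()
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        return cls(**d)
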