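"""Core containers shared across the pipeline.

Conventions
-----------
* Founder labels are encoded as small ints: ``0`` = B, ``1`` = D, ``-1`` =
  missing/unassigned.  String forms ("B"/"D") appear only at file boundaries.
* All internal genomic coordinates are 0-based, half-open.  Conversion to
  1-based (VCF) or BED happens exclusively in :mod:`strmutator.io`.
* STR genotypes are diploid repeat-unit (RU) copy numbers; ``-1`` marks a
  missing call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LABEL_B: int = 0
LABEL_D: int = 1
LABEL_MISSING: int = -1

LABEL_CHARS = {LABEL_B: "B", LABEL_D: "D", LABEL_MISSING: "NA"}
CHAR_LABELS = {"B": LABEL_B, "D": LABEL_D}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class ConfigurationError(ValueError):
    """Raised for invalid run parameters."""


class SchemaError(ValueError):
    """Raised when an input table/file violates the expected schema."""


def canonical_motif(motif: str) -> str:
    """Canonical form of a repeat unit: the lexicographically smallest
    string among all cyclic rotations of the motif and of its reverse
    complement (so e.g. TCTA, AGAT and ATAG all canonicalise to AGAT)."""
    motif = motif.upper()
    rc = motif.translate(_COMPLEMENT)[::-1]
    candidates = [
        s[i:] + s[:i] for s in (motif, rc) for i in range(len(s))
    ]
    return min(candidates)


@dataclass
class MarkerMap:
    """Genetic/physical map of SNP markers.

    ``df`` columns: ``marker`` (str, unique), ``chrom`` (str),
    ``pos_bp`` (int), ``pos_cm`` (float).  Markers are sorted by
    (chrom, pos_bp) and cM positions are non-decreasing within a
    chromosome.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"marker", "chrom", "pos_bp", "pos_cm"}
        missing = required - set(self.df.columns)
        if missing:
            raise SchemaError(f"marker map missing columns: {sorted(missing)}")
        self.df = self.df.reset_index(drop=True)
        for chrom, sub in self.df.groupby("chrom", sort=False):
            if not sub["pos_bp"].is_monotonic_increasing:
                raise SchemaError(f"markers on {chrom} not sorted by pos_bp")
            if not sub["pos_cm"].is_monotonic_increasing:
                raise SchemaError(f"cM positions on {chrom} not monotone")
        if self.df["marker"].duplicated().any():
            raise SchemaError("duplicate marker identifiers")

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    @property
    def n_markers(self) -> int:
        return len(self.df)

    def chrom_slice(self, chrom: str) -> slice:
        idx = np.flatnonzero((self.df["chrom"] == chrom).to_numpy())
        if idx.size == 0:
            return slice(0, 0)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def marker_index(self, marker: str) -> int:
        hits = np.flatnonzero((self.df["marker"] == marker).to_numpy())
        if hits.size == 0:
            raise SchemaError(f"marker {marker!r} not in map")
        return int(hits[0])

    def interp_cm(self, chrom: str, pos_bp: np.ndarray) -> np.ndarray:
        """Interpolate cM positions for arbitrary bp positions on a
        chromosome (clamped at the terminal markers)."""
        sl = self.chrom_slice(chrom)
        sub = self.df.iloc[sl]
        if len(sub) == 0:
            raise SchemaError(f"chromosome {chrom!r} not in map")
        return np.interp(
            np.asarray(pos_bp, dtype=float),
            sub["pos_bp"].to_numpy(dtype=float),
            sub["pos_cm"].to_numpy(dtype=float),
        )


@dataclass
class FounderPanel:
    """Founder SNP alleles and STR reference on a shared map.

    ``snp_alleles``: DataFrame indexed like the marker map rows with
    columns ``allele_B``, ``allele_D`` (single-base strings).

    ``str_reference``: DataFrame indexed by ``locus_id`` with columns
    ``chrom``, ``pos_bp``, ``motif``, ``motif_len``, ``ru_B``, ``ru_D``
    (float, may be NaN when unknown) and, for simulated panels,
    boolean masks ``missing_B``/``missing_D`` hiding the true value
    from the reported view.
    """

    snp_alleles: pd.DataFrame
    str_reference: pd.DataFrame

    def __post_init__(self) -> None:
        bad = self.str_reference["motif"].str.len()
        if ((bad < 2) | (bad > 6)).any():
            raise SchemaError("STR motif length outside [2, 6]")

    @property
    def informative(self) -> np.ndarray:
        """Boolean mask over markers where the founders carry different
        alleles (only these can yield founder labels)."""
        return (
            self.snp_alleles["allele_B"] != self.snp_alleles["allele_D"]
        ).to_numpy()

    def reported_str_reference(self) -> pd.DataFrame:
        """The STR reference as an analyst would see it: founder repeat
        lengths masked to NaN where flagged missing."""
        out = self.str_reference.copy()
        for founder in ("B", "D"):
            col = f"missing_{founder}"
            if col in out.columns:
                out.loc[out[col].astype(bool), f"ru_{founder}"] = np.nan
                out = out.drop(columns=col)
        return out


@dataclass
class StrainGenome:
    """Phased genome of one (possibly not fully inbred) individual.

    ``snp``: int8 array (2, n_markers) of founder labels per haplotype.
    ``strs``: int32 array (2, n_loci) of repeat-unit counts per haplotype.
    """

    strain_id: str
    snp: np.ndarray
    strs: np.ndarray
    #: transmitted founder label per STR haplotype (simulation truth)
    str_labels: np.ndarray | None = None


@dataclass
class GenotypeTables:
    """Rendered panel observations (what the real pipeline would see)."""

    snp_calls: pd.DataFrame  # strains x markers, values in {B, H, D, NA}
    str_genotypes: "STRGenotypes"
    metadata: pd.DataFrame  # columns strain_id, epoch, n_generations


class STRGenotypes:
    """Diploid STR repeat-copy-number calls for a panel.

    Two ``(n_strains, n_loci)`` int arrays, ``a1``/``a2``; ``-1`` marks a
    missing call. Heterozygous means ``a1 != a2`` at a non-missing call.
    """

    def __init__(self, strains: list[str], loci: pd.Index, a1: np.ndarray, a2: np.ndarray):
        a1 = np.asarray(a1, dtype=np.int32)
        a2 = np.asarray(a2, dtype=np.int32)
        if a1.shape != (len(strains), len(loci)) or a2.shape != a1.shape:
            raise SchemaError("STR genotype arrays do not match strains x loci")
        self.strains = list(strains)
        self.loci = pd.Index(loci)
        self.a1 = a1
        self.a2 = a2

    @property
    def missing(self) -> np.ndarray:
        return (self.a1 < 0) | (self.a2 < 0)

    @property
    def heterozygous(self) -> np.ndarray:
        return (~self.missing) & (self.a1 != self.a2)

    @property
    def homozygous(self) -> np.ndarray:
        return (~self.missing) & (self.a1 == self.a2)

    def n_genotyped(self) -> pd.Series:
        """Non-missing call count per strain."""
        return pd.Series((~self.missing).sum(axis=1), index=self.strains)

    def strain_index(self, strain: str) -> int:
        try:
            return self.strains.index(strain)
        except ValueError:
            raise SchemaError(f"strain {strain!r} not in STR genotypes") from None

    def copy(self) -> "STRGenotypes":
        return STRGenotypes(self.strains, self.loci, self.a1.copy(), self.a2.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, STRGenotypes):
            return NotImplemented
        return (
            self.strains == other.strains
            and self.loci.equals(other.loci)
            and np.array_equal(self.a1, other.a1)
            and np.array_equal(self.a2, other.a2)
        )


@dataclass
class LabelTracks:
    """Per-strain founder labels at map markers.

    ``labels``: int8 array (n_strains, n_markers) in {0=B, 1=D, -1=missing}.
    ``posterior_b``: optional float array of HMM marginal P(B).
    """

    strains: list[str]
    marker_map: MarkerMap
    labels: np.ndarray
    posterior_b: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.labels.shape != (len(self.strains), self.marker_map.n_markers):
            raise SchemaError("label matrix does not match strains x markers")

    def copy(self) -> "LabelTracks":
        post = None if self.posterior_b is None else self.posterior_b.copy()
        return LabelTracks(list(self.strains), self.marker_map, self.labels.copy(), post)


@dataclass
class ScanResult:
    """Single-phenotype genome scan output."""

    lod: pd.DataFrame  # columns marker, chrom, pos_bp, lod
    h2_by_chrom: dict[str, float]
    thresholds: dict[float, float] = field(default_factory=dict)
    intervals: dict[str, tuple[int, int]] = field(default_factory=dict)

    def max_lod(self) -> float:
        return float(self.lod["lod"].max())

    def peak(self) -> pd.Series:
        return self.lod.loc[self.lod["lod"].idxmax()]
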