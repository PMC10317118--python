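"""New-mutation discovery and the recurrence / per-strain / outlier filters.

A candidate new mutation is a homozygous strain genotype whose repeat
length matches neither founder allele at the locus.  The local founder
haplotype (from the SNP blocks) then determines which founder allele the
mutation arose from, and hence its signed size.  Heterozygous strain
calls, het-flagged founder loci, and loci whose founder alleles could not
be resolved are skipped.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import LABEL_B, LABEL_MISSING, STRGenotypes, canonical_motif

logger = logging.getLogger(__name__)

CALL_COLUMNS = [
    "strain_id",
    "locus_id",
    "chrom",
    "pos_bp",
    "motif",
    "motif_len",
    "canonical_motif",
    "founder_label",
    "founder_ru",
    "observed_ru",
    "delta_ru",
    "direction",
]


def call_new_mutations(
    str_genotypes: STRGenotypes,
    resolved_reference: pd.DataFrame,
    locus_labels: np.ndarray,
    dropped_loci: list[str] | None = None,
    het_founder_loci: set[str] | None = None,
) -> pd.DataFrame:
    """Identify new STR mutations against the resolved founder alleles.

    ``resolved_reference`` is the STR reference after missing-founder
    inference; loci still carrying a NaN founder allele, listed in
    ``dropped_loci``, or flagged as heterozygous in a founder are
    excluded.  ``locus_labels`` is the strain x locus local-haplotype
    label matrix from :func:`strmutator.founders.assign_locus_labels`;
    unassigned entries (gap midpoint ties, uncovered chromosomes) yield
    no call.
    """
    ref = resolved_reference
    drop = set(dropped_loci or [])
    if het_founder_loci:
        drop |= set(het_founder_loci)
    ref_aligned = ref.reindex(str_genotypes.loci)
    ru_b = ref_aligned["ru_B"].to_numpy(dtype=float)
    ru_d = ref_aligned["ru_D"].to_numpy(dtype=float)
    usable = ~np.isnan(ru_b) & ~np.isnan(ru_d)
    if drop:
        usable &= ~str_genotypes.loci.isin(drop)

    hom = str_genotypes.homozygous
    obs = str_genotypes.a1
    founder_ru = np.stack([ru_b, ru_d])  # indexed by label

    locus_ids = np.asarray(str_genotypes.loci)
    chrom_arr = ref_aligned["chrom"].to_numpy()
    pos_arr = ref_aligned["pos_bp"].to_numpy()
    motif_arr = ref_aligned["motif"].to_numpy()
    mlen_arr = ref_aligned["motif_len"].to_numpy()
    canon_arr = np.array([canonical_motif(m) for m in motif_arr])

    frames = []
    for i, strain in enumerate(str_genotypes.strains):
        lab = locus_labels[i]
        ok = hom[i] & usable & (lab != LABEL_MISSING)
        # candidate: matches neither founder allele
        cand = np.flatnonzero(ok & (obs[i] != ru_b) & (obs[i] != ru_d))
        if cand.size == 0:
            continue
        f_ru = founder_ru[lab[cand], cand].astype(int)
        delta = obs[i, cand] - f_ru
        frames.append(
            pd.DataFrame(
                {
                    "strain_id": strain,
                    "locus_id": locus_ids[cand],
                    "chrom": chrom_arr[cand],
                    "pos_bp": pos_arr[cand].astype(int),
                    "motif": motif_arr[cand],
                    "motif_len": mlen_arr[cand].astype(int),
                    "canonical_motif": canon_arr[cand],
                    "founder_label": np.where(lab[cand] == LABEL_B, "B", "D"),
                    "founder_ru": f_ru,
                    "observed_ru": obs[i, cand].astype(int),
                    "delta_ru": delta.astype(int),
                    "direction": np.where(delta > 0, "expansion", "contraction"),
                }
            )
        )
    if frames:
        calls = pd.concat(frames, ignore_index=True)[CALL_COLUMNS]
    else:
        calls = pd.DataFrame(columns=CALL_COLUMNS)
    logger.info("called %d candidate new mutations", len(calls))
    return calls


def filter_recurrent(calls: pd.DataFrame, max_strains: int = 10) -> pd.DataFrame:
    """Drop calls where the identical new allele at a locus is carried by
    more than ``max_strains`` strains (recurrent or founder-mistyped
    alleles have likely been segregating on many backgrounds)."""
    if calls.empty:
        return calls.copy()
    counts = calls.groupby(["locus_id", "observed_ru"])["strain_id"].transform("nunique")
    return calls[counts <= max_strains].reset_index(drop=True)


def filter_strains(
    calls: pd.DataFrame, min_mutations: int = 10
) -> tuple[pd.DataFrame, list[str]]:
    """Flag strains with fewer than ``min_mutations`` retained calls.

    Their calls are kept in the output but marked ``strain_excluded`` so
    phenotype computation can skip them; returns the excluded strains.
    """
    calls = calls.copy()
    if calls.empty:
        calls["strain_excluded"] = pd.Series(dtype=bool)
        return calls, []
    n = calls.groupby("strain_id")["locus_id"].transform("count")
    calls["strain_excluded"] = n < min_mutations
    excluded = sorted(calls.loc[calls["strain_excluded"], "strain_id"].unique())
    return calls, excluded


def flag_outlier_strains(
    calls: pd.DataFrame, metadata: pd.DataFrame, fold: float = 2.0
) -> list[str]:
    """Strains with an outlier mutation load: call count more than
    ``fold`` times the median of the other strains in the same epoch.
    Epochs with a single strain never flag it."""
    counts = calls.groupby("strain_id")["locus_id"].count() if not calls.empty else pd.Series(dtype=int)
    flagged = []
    for _, epoch_meta in metadata.groupby("epoch"):
        strains = epoch_meta["strain_id"].tolist()
        if len(strains) < 2:
            continue
        c = np.array([int(counts.get(s, 0)) for s in strains], dtype=float)
        for k, s in enumerate(strains):
            others = np.delete(c, k)
            if c[k] > fold * float(np.median(others)):
                flagged.append(s)
    return sorted(flagged)
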