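"""Mutation-spectrum summaries: rates and expansion fractions binned by
parent repeat length, stratified by motif, by haplotype at a focal
marker, or by chromosome class, with the pooled two-proportion z-test
used for group contrasts.

The "parent" repeat length of a strain x locus observation is the
founder allele of the strain's local haplotype at that locus, in bp
(repeat units x motif length): the template length the mutation process
acted on, not the possibly-mutated observed length.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .types import ConfigurationError, LABEL_MISSING, LabelTracks, STRGenotypes

logger = logging.getLogger(__name__)


def classify_chromosome(chrom: str) -> str:
    name = chrom.removeprefix("chr")
    if name in ("X", "Y"):
        return name
    return "autosome"


def z_proportion_test(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Two-sided two-proportion z-test with pooled variance.

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with p the pooled
    proportion; degenerate pooled proportions (0 or 1) give z=0, p=1.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("both sample sizes must be >= 1")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return 0.0, 1.0
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (x1 / n1 - x2 / n2) / se
    p = 2.0 * stats.norm.sf(abs(z))
    expected = min(n1 * pooled, n1 * (1 - pooled), n2 * pooled, n2 * (1 - pooled))
    if expected < 5:
        logger.warning("z-proportion test with expected cell count %.1f < 5", expected)
    return float(z), float(p)


def _observation_arrays(
    str_genotypes: STRGenotypes,
    resolved_reference: pd.DataFrame,
    locus_labels: np.ndarray,
):
    """Flatten usable strain x locus observations.

    Returns index arrays (strain_idx, locus_idx) plus per-observation
    parent length in bp, and boolean mutation / expansion marks are
    added later from the call table.
    """
    ref = resolved_reference.reindex(str_genotypes.loci)
    ru = np.stack(
        [ref["ru_B"].to_numpy(dtype=float), ref["ru_D"].to_numpy(dtype=float)]
    )
    resolved = ~np.isnan(ru).any(axis=0)
    valid = (~str_genotypes.missing) & (locus_labels != LABEL_MISSING) & resolved[None, :]
    sidx, lidx = np.nonzero(valid)
    parent_ru = ru[locus_labels[sidx, lidx], lidx]
    parent_bp = parent_ru * ref["motif_len"].to_numpy(dtype=float)[lidx]
    return ref, sidx, lidx, parent_bp


def _mutation_marks(
    calls: pd.DataFrame, str_genotypes: STRGenotypes, sidx: np.ndarray, lidx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    n_loci = len(str_genotypes.loci)
    mut = np.zeros((len(str_genotypes.strains), n_loci), dtype=bool)
    exp = np.zeros_like(mut)
    if not calls.empty:
        smap = {s: i for i, s in enumerate(str_genotypes.strains)}
        lmap = {l: j for j, l in enumerate(str_genotypes.loci)}
        ci = calls["strain_id"].map(smap).to_numpy()
        cj = calls["locus_id"].map(lmap).to_numpy()
        mut[ci, cj] = True
        exp[ci[calls["delta_ru"].to_numpy() > 0], cj[calls["delta_ru"].to_numpy() > 0]] = True
    return mut[sidx, lidx], exp[sidx, lidx]


def binned_mutation_rate(
    calls: pd.DataFrame,
    str_genotypes: STRGenotypes,
    resolved_reference: pd.DataFrame,
    locus_labels: np.ndarray,
    bin_width_bp: float = 4.0,
    group_by: str | None = None,
    tracks: LabelTracks | None = None,
    focal_marker: str | None = None,
) -> pd.DataFrame:
    """Relative mutation rate and expansion fraction binned by parent
    repeat length (bp, half-open bins of ``bin_width_bp``).

    ``group_by`` may be None, "motif_len", "canonical_motif",
    "chrom_class" (autosome/X/Y) or "focal_haplotype" (B vs D at
    ``focal_marker`` from the imputed ``tracks``).  Every non-missing
    genotype observation with a resolvable parent haplotype contributes
    to exactly one (group, bin) cell.
    """
    if bin_width_bp <= 0:
        raise ConfigurationError("bin_width_bp must be positive")
    ref, sidx, lidx, parent_bp = _observation_arrays(
        str_genotypes, resolved_reference, locus_labels
    )
    is_mut, is_exp = _mutation_marks(calls, str_genotypes, sidx, lidx)

    if group_by is None:
        groups = np.full(len(sidx), "all", dtype=object)
    elif group_by == "motif_len":
        groups = ref["motif_len"].to_numpy()[lidx]
    elif group_by == "canonical_motif":
        from .types import canonical_motif

        canon = np.array([canonical_motif(m) for m in ref["motif"]])
        groups = canon[lidx]
    elif group_by == "chrom_class":
        cls = np.array([classify_chromosome(c) for c in ref["chrom"]])
        groups = cls[lidx]
    elif group_by == "focal_haplotype":
        if tracks is None or focal_marker is None:
            raise ConfigurationError("focal_haplotype grouping needs tracks and focal_marker")
        lab = strain_labels_at_marker(tracks, focal_marker)
        lab_arr = np.array(
            [lab.get(s, "NA") for s in str_genotypes.strains], dtype=object
        )
        groups = lab_arr[sidx]
        keep = groups != "NA"
        sidx, lidx, parent_bp = sidx[keep], lidx[keep], parent_bp[keep]
        is_mut, is_exp, groups = is_mut[keep], is_exp[keep], groups[keep]
    else:
        raise ConfigurationError(f"unknown group_by {group_by!r}")

    bins = np.floor(parent_bp / bin_width_bp).astype(int)
    df = pd.DataFrame(
        {"group": groups, "bin": bins, "mut": is_mut, "exp": is_exp, "one": 1}
    )
    agg = (
        df.groupby(["group", "bin"])
        .agg(
            n_genotyped_calls=("one", "sum"),
            n_mutations=("mut", "sum"),
            n_expansions=("exp", "sum"),
        )
        .reset_index()
    )
    agg["bin_lo_bp"] = agg["bin"] * bin_width_bp
    agg["bin_hi_bp"] = (agg["bin"] + 1) * bin_width_bp
    agg["relative_rate"] = agg["n_mutations"] / agg["n_genotyped_calls"]
    agg["expansion_fraction"] = np.where(
        agg["n_mutations"] > 0, agg["n_expansions"] / agg["n_mutations"].clip(lower=1), np.nan
    )
    return agg.drop(columns="bin")[
        [
            "group",
            "bin_lo_bp",
            "bin_hi_bp",
            "n_genotyped_calls",
            "n_mutations",
            "relative_rate",
            "n_expansions",
            "expansion_fraction",
        ]
    ]


def length_trend_correlation(
    table: pd.DataFrame, value: str = "relative_rate"
) -> tuple[float, float]:
    """Pearson correlation (and two-sided t-test p) of bin midpoint
    against ``value`` across non-empty bins; (nan, nan) with fewer than
    3 usable bins or zero variance."""
    mid = (table["bin_lo_bp"] + table["bin_hi_bp"]) / 2.0
    vals = table[value]
    ok = vals.notna() & mid.notna()
    if ok.sum() < 3:
        return float("nan"), float("nan")
    x = mid[ok].to_numpy(dtype=float)
    y = vals[ok].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def strain_labels_at_marker(tracks: LabelTracks, marker: str) -> dict[str, str]:
    """Founder label per strain at one marker ("B"/"D"; strains with a
    missing label there are omitted)."""
    j = tracks.marker_map.marker_index(marker)
    out = {}
    for i, s in enumerate(tracks.strains):
        lab = int(tracks.labels[i, j])
        if lab != LABEL_MISSING:
            out[s] = "B" if lab == 0 else "D"
    return out


def haplotype_contrast(
    calls: pd.DataFrame,
    str_genotypes: STRGenotypes,
    resolved_reference: pd.DataFrame,
    locus_labels: np.ndarray,
    tracks: LabelTracks,
    focal_marker: str,
    strata: tuple[str, ...] = ("all", "motif_len"),
) -> pd.DataFrame:
    """Compare strains carrying the B vs D haplotype at a focal marker.

    Within each stratum (all observations, per motif length, per
    canonical motif, per chromosome class) the two groups' pooled
    expansion counts (expansions / mutations) and pooled mutation counts
    (mutations / genotyped calls) are compared with the two-sided
    z-proportion test.  Strains with a missing label at the focal marker
    are excluded (and counted in the log).
    """
    lab = strain_labels_at_marker(tracks, focal_marker)
    excluded = [s for s in str_genotypes.strains if s not in lab]
    if excluded:
        logger.info(
            "haplotype_contrast: excluding %d strains with missing label at %s",
            len(excluded),
            focal_marker,
        )
    ref, sidx, lidx, parent_bp = _observation_arrays(
        str_genotypes, resolved_reference, locus_labels
    )
    is_mut, is_exp = _mutation_marks(calls, str_genotypes, sidx, lidx)
    strain_arr = np.array(str_genotypes.strains, dtype=object)
    glab = np.array([lab.get(s, "NA") for s in strain_arr], dtype=object)[sidx]
    keep = glab != "NA"
    sidx, lidx, is_mut, is_exp, glab = (
        a[keep] for a in (sidx, lidx, is_mut, is_exp, glab)
    )

    from .types import canonical_motif

    stratum_values: dict[str, np.ndarray] = {}
    for st in strata:
        if st == "all":
            stratum_values[st] = np.full(len(lidx), "all", dtype=object)
        elif st == "motif_len":
            stratum_values[st] = ref["motif_len"].to_numpy()[lidx]
        elif st == "canonical_motif":
            canon = np.array([canonical_motif(m) for m in ref["motif"]])
            stratum_values[st] = canon[lidx]
        elif st == "chrom_class":
            cls = np.array([classify_chromosome(c) for c in ref["chrom"]])
            stratum_values[st] = cls[lidx]
        else:
            raise ConfigurationError(f"unknown stratum {st!r}")

    rows = []
    for st, values in stratum_values.items():
        for level in pd.unique(values):
            m = values == level
            for measure, num, den in (
                ("expansion_propensity", is_exp[m], is_mut[m]),
                ("mutation_rate", is_mut[m], np.ones(int(m.sum()), dtype=bool)),
            ):
                gb = glab[m] == "B"
                x1, n1 = int(num[gb].sum()), int(den[gb].sum())
                x2, n2 = int(num[~gb].sum()), int(den[~gb].sum())
                if n1 == 0 or n2 == 0:
                    rows.append(
                        (st, level, measure, x1, n1, x2, n2, np.nan, np.nan, False)
                    )
                    continue
                z, p = z_proportion_test(x1, n1, x2, n2)
                rows.append((st, level, measure, x1, n1, x2, n2, z, p, True))
    return pd.DataFrame(
        rows,
        columns=[
            "stratum_type",
            "stratum",
            "measure",
            "x_B",
            "n_B",
            "x_D",
            "n_D",
            "z",
            "p",
            "comparable",
        ],
    )
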