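"""Founder haplotype inference for a two-founder RI panel.

Stages: (1) assign B/D labels at founder-informative SNP markers;
(2) impute missing labels with a two-state hidden Markov model whose
transition probabilities come from the genetic map (Haldane recombination
fractions expanded for an RI-by-sibling panel, R = 4r / (1 + 6r)); (3)
collapse label runs into haplotype blocks; (4) infer missing founder STR
alleles from the strains carrying the corresponding haplotype (modal
allele rule).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import (
    CHAR_LABELS,
    FounderPanel,
    LABEL_B,
    LABEL_D,
    LABEL_MISSING,
    LabelTracks,
    MarkerMap,
    SchemaError,
)

logger = logging.getLogger(__name__)

#: posterior must exceed min_prob by this margin before a missing label is
#: imputed, so that exactly-tied marginals (p = 0.5) stay missing
_TIE_EPS = 1e-12


def assign_founder_labels(
    snp_calls: pd.DataFrame, founders: FounderPanel, marker_map: MarkerMap
) -> LabelTracks:
    """Per-strain founder labels from SNP calls.

    ``snp_calls`` is strains x markers with values in {B, H, D, NA}.
    At founder-informative markers a homozygous B (D) call maps to label
    B (D); heterozygous and missing calls map to missing.  Markers where
    the founders share an allele are uninformative and always missing.
    """
    markers = marker_map.df["marker"].to_numpy()
    absent = [m for m in snp_calls.columns if m not in set(founders.snp_alleles.index)]
    if absent:
        raise SchemaError(f"markers absent from founder panel: {absent[:5]}")
    calls = snp_calls.reindex(columns=markers).to_numpy(dtype="U2")
    labels = np.full(calls.shape, LABEL_MISSING, dtype=np.int8)
    labels[calls == "B"] = LABEL_B
    labels[calls == "D"] = LABEL_D
    labels[:, ~founders.informative] = LABEL_MISSING
    return LabelTracks(list(snp_calls.index), marker_map, labels)


def _haldane_r(d_cm: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))


def ri_transition_prob(d_cm: np.ndarray) -> np.ndarray:
    """Probability that founder labels differ at two markers d cM apart
    in an RI-by-sibling strain: R = 4r / (1 + 6r) with Haldane r."""
    r = _haldane_r(np.asarray(d_cm, dtype=float))
    return 4.0 * r / (1.0 + 6.0 * r)


def _forward_backward(
    obs: np.ndarray, switch: np.ndarray, error_rate: float
) -> np.ndarray:
    """Marginal posteriors of a two-state chain for all strains at once.

    ``obs``: (n_strains, n_markers) labels with -1 missing; ``switch``:
    (n_markers - 1,) per-interval label-switch probabilities.  Emission:
    the observed label matches the state with probability 1 - error_rate.
    Returns (n_strains, n_markers, 2) posteriors.
    """
    n, m = obs.shape
    if m == 0:
        return np.zeros((n, 0, 2))
    # emission likelihoods
    e = np.ones((n, m, 2))
    for state in (LABEL_B, LABEL_D):
        match = obs == state
        e[match, state] = 1.0 - error_rate
        e[match, 1 - state] = error_rate
    alpha = np.empty((n, m, 2))
    c = np.empty((n, m))
    alpha[:, 0] = 0.5 * e[:, 0]
    c[:, 0] = alpha[:, 0].sum(axis=1)
    alpha[:, 0] /= c[:, 0, None]
    for t in range(1, m):
        s = switch[t - 1]
        prev = alpha[:, t - 1]
        pred = np.empty_like(prev)
        pred[:, 0] = prev[:, 0] * (1 - s) + prev[:, 1] * s
        pred[:, 1] = prev[:, 0] * s + prev[:, 1] * (1 - s)
        a = pred * e[:, t]
        c[:, t] = a.sum(axis=1)
        alpha[:, t] = a / c[:, t, None]
    beta = np.ones((n, 2))
    post = np.empty((n, m, 2))
    post[:, m - 1] = alpha[:, m - 1]
    for t in range(m - 2, -1, -1):
        s = switch[t]
        b = beta * e[:, t + 1]
        nb = np.empty_like(b)
        nb[:, 0] = b[:, 0] * (1 - s) + b[:, 1] * s
        nb[:, 1] = b[:, 0] * s + b[:, 1] * (1 - s)
        beta = nb / c[:, t + 1, None]
        p = alpha[:, t] * beta
        post[:, t] = p / p.sum(axis=1, keepdims=True)
    return post


def impute_missing_labels(
    track: LabelTracks,
    error_rate: float = 0.002,
    min_prob: float = 0.5,
) -> LabelTracks:
    """Fill missing founder labels by HMM marginal posteriors.

    A missing label becomes B (D) when the marginal posterior of that
    state exceeds ``min_prob``; ties and low-confidence markers stay
    missing.  Observed labels are never overwritten.  The full posterior
    P(B) is retained on the returned track (it later provides genotype
    probabilities for QTL mapping).
    """
    mm = track.marker_map
    labels = track.labels
    out = labels.copy()
    post_b = np.full(labels.shape, 0.5)
    cm = mm.df["pos_cm"].to_numpy()
    for chrom in mm.chromosomes:
        sl = mm.chrom_slice(chrom)
        obs = labels[:, sl]
        if obs.shape[1] == 0:
            continue
        switch = ri_transition_prob(np.diff(cm[sl]))
        post = _forward_backward(obs, switch, error_rate)
        post_b[:, sl] = post[:, :, 0]
        fill = obs == LABEL_MISSING
        imp = np.where(
            post[:, :, 0] > min_prob + _TIE_EPS,
            LABEL_B,
            np.where(post[:, :, 1] > min_prob + _TIE_EPS, LABEL_D, LABEL_MISSING),
        ).astype(np.int8)
        out[:, sl] = np.where(fill, imp, obs)
    return LabelTracks(list(track.strains), mm, out, post_b)


def genotype_probabilities(track: LabelTracks) -> np.ndarray:
    """(n_strains, n_markers, 2) founder genotype probabilities [P(B),
    P(D)] from the imputation posteriors (run ``impute_missing_labels``
    first)."""
    if track.posterior_b is None:
        raise SchemaError("track has no posteriors; run impute_missing_labels first")
    pb = track.posterior_b
    return np.stack([pb, 1.0 - pb], axis=-1)


def build_blocks(track: LabelTracks) -> pd.DataFrame:
    """Collapse maximal runs of identical non-missing labels into
    haplotype blocks (connected components along each chromosome).

    Returns a DataFrame with columns strain_id, chrom, start_bp, end_bp,
    label; coordinates are 0-based half-open, spanning from the first to
    the last marker of the run.  Residual-missing markers interrupt runs:
    the flanking blocks stay separate and the gap persists.
    """
    mm = track.marker_map
    pos = mm.df["pos_bp"].to_numpy()
    rows = []
    for chrom in mm.chromosomes:
        sl = mm.chrom_slice(chrom)
        cpos = pos[sl]
        for i, strain in enumerate(track.strains):
            lab = track.labels[i, sl]
            ok = np.flatnonzero(lab != LABEL_MISSING)
            if ok.size == 0:
                continue
            # run boundaries: label change or an intervening missing marker
            brk = np.flatnonzero(
                (lab[ok[1:]] != lab[ok[:-1]]) | (np.diff(ok) > 1)
            )
            starts = np.concatenate([[0], brk + 1])
            ends = np.concatenate([brk, [ok.size - 1]])
            for s, t in zip(starts, ends):
                rows.append(
                    (
                        strain,
                        chrom,
                        int(cpos[ok[s]]),
                        int(cpos[ok[t]]) + 1,
                        "B" if lab[ok[s]] == LABEL_B else "D",
                    )
                )
    return pd.DataFrame(rows, columns=["strain_id", "chrom", "start_bp", "end_bp", "label"])


def assign_locus_labels(
    blocks: pd.DataFrame,
    str_reference: pd.DataFrame,
    strains: list[str],
) -> np.ndarray:
    """Founder label of the local haplotype for every strain x STR locus.

    A locus inside a block takes that block's label; a locus in a gap
    between two blocks is assigned to the nearest block by bp distance to
    the block edge, with exact midpoint ties left unassigned (-1), as is
    anything outside all blocks' chromosomes.
    """
    n_loci = len(str_reference)
    out = np.full((len(strains), n_loci), LABEL_MISSING, dtype=np.int8)
    strain_pos = {s: i for i, s in enumerate(strains)}
    loci_by_chrom = {
        chrom: (np.flatnonzero((str_reference["chrom"] == chrom).to_numpy()),)
        for chrom in str_reference["chrom"].unique()
    }
    for (strain, chrom), sub in blocks.groupby(["strain_id", "chrom"], sort=False):
        if strain not in strain_pos or chrom not in loci_by_chrom:
            continue
        i = strain_pos[strain]
        (lidx,) = loci_by_chrom[chrom]
        pos = str_reference["pos_bp"].to_numpy()[lidx]
        sub = sub.sort_values("start_bp")
        starts = sub["start_bp"].to_numpy()
        ends = sub["end_bp"].to_numpy()
        labs = np.where(sub["label"].to_numpy() == "B", LABEL_B, LABEL_D).astype(np.int8)
        # index of the block starting at or before each locus
        k = np.searchsorted(starts, pos, side="right") - 1
        inside = (k >= 0) & (pos < ends[np.clip(k, 0, len(ends) - 1)])
        lab = np.full(pos.shape, LABEL_MISSING, dtype=np.int8)
        lab[inside] = labs[k[inside]]
        gap = ~inside
        if gap.any():
            gp = pos[gap]
            kk = k[gap]
            # distance to the nearest edge of the flanking blocks
            left_d = np.where(kk >= 0, gp - (ends[np.clip(kk, 0, None)] - 1), np.iinfo(np.int64).max)
            has_right = kk + 1 < len(starts)
            right_d = np.where(
                has_right, starts[np.clip(kk + 1, 0, len(starts) - 1)] - gp, np.iinfo(np.int64).max
            )
            choice = np.full(gp.shape, LABEL_MISSING, dtype=np.int8)
            nearer_left = left_d < right_d
            nearer_right = right_d < left_d
            choice[nearer_left] = labs[np.clip(kk, 0, None)[nearer_left]]
            choice[nearer_right] = labs[np.clip(kk + 1, 0, len(labs) - 1)[nearer_right]]
            # exact midpoint ties stay unassigned
            lab[gap] = choice
        out[i, lidx] = lab
    return out


def infer_missing_founder_strs(
    str_reference: pd.DataFrame,
    str_genotypes,
    locus_labels: np.ndarray,
) -> tuple[pd.DataFrame, list[str]]:
    """Fill missing founder STR alleles by the modal-allele rule.

    For a locus with a missing founder allele, consider strains whose
    local haplotype carries that founder's label and that have a
    homozygous non-missing call there.  If at most one non-modal
    ("de novo") allele value is present and the modal allele is carried
    by a strict majority of those strains, the founder gets the modal
    allele; otherwise the locus is dropped from downstream analysis.

    Returns the resolved reference (NaN founder alleles filled where the
    rule succeeded) and the list of dropped locus ids.
    """
    ref = str_reference.copy()
    dropped: list[str] = []
    hom = str_genotypes.homozygous
    alleles = str_genotypes.a1
    locus_pos = {lid: j for j, lid in enumerate(str_genotypes.loci)}
    for founder, label in (("B", LABEL_B), ("D", LABEL_D)):
        col = f"ru_{founder}"
        for lid in ref.index[ref[col].isna()]:
            j = locus_pos.get(lid)
            if j is None:
                dropped.append(lid)
                continue
            grp = (locus_labels[:, j] == label) & hom[:, j]
            vals = alleles[grp, j]
            if vals.size == 0:
                dropped.append(lid)
                continue
            uniq, counts = np.unique(vals, return_counts=True)
            modal = uniq[np.argmax(counts)]
            n_modal = counts.max()
            n_nonmodal_values = len(uniq) - 1
            if n_nonmodal_values <= 1 and n_modal * 2 > vals.size:
                ref.loc[lid, col] = float(modal)
            else:
                dropped.append(lid)
    dropped = sorted(set(dropped))
    if dropped:
        logger.info("modal-rule founder inference dropped %d loci", len(dropped))
    return ref, dropped
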