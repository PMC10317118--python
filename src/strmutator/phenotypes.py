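"""Per-strain mutator phenotypes and the mutation-sharing PCA.

Three phenotypes summarise each strain's accumulated STR mutations:

* mutation count - fraction of genotyped STRs carrying a new mutation;
* mutation size - mean signed repeat-unit change, separately for
  expansions and contractions;
* expansion propensity - fraction of new mutations longer than the
  founder allele (contraction propensity is its complement).

The PCA operates on a binary strain x (locus, new allele) indicator
matrix, column-centred but not scaled, and is used to visualise
epoch-specific sharing of mutations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import STRGenotypes


def mutation_count(calls: pd.DataFrame, str_genotypes: STRGenotypes, strain: str) -> float:
    """Fraction of the strain's genotyped (non-missing) loci with a
    retained new-mutation call; NaN when nothing was genotyped."""
    i = str_genotypes.strain_index(strain)
    n_geno = int((~str_genotypes.missing[i]).sum())
    if n_geno == 0:
        return float("nan")
    n_mut = int((calls["strain_id"] == strain).sum())
    return n_mut / n_geno


def mutation_size(calls: pd.DataFrame, strain: str, direction: str) -> float:
    """Mean signed repeat-unit change of the strain's calls in one
    direction ("expansion" or "contraction"); NaN when empty."""
    if direction not in ("expansion", "contraction"):
        raise ValueError("direction must be 'expansion' or 'contraction'")
    d = calls.loc[
        (calls["strain_id"] == strain) & (calls["direction"] == direction), "delta_ru"
    ]
    return float(d.mean()) if len(d) else float("nan")


def expansion_propensity(calls: pd.DataFrame, strain: str) -> float:
    """Fraction of the strain's calls that are expansions; NaN when the
    strain has no calls."""
    d = calls.loc[calls["strain_id"] == strain, "delta_ru"]
    if len(d) == 0:
        return float("nan")
    return float((d > 0).sum() / len(d))


def build_phenotype_table(
    calls: pd.DataFrame,
    str_genotypes: STRGenotypes,
    metadata: pd.DataFrame,
    strains: list[str] | None = None,
) -> pd.DataFrame:
    """Mutator phenotype table for the given strains (default: all
    strains in the metadata).  ``calls`` should already be filtered
    (recurrence + per-strain rules); pass only retained strains."""
    meta = metadata.set_index("strain_id")
    if strains is None:
        strains = list(meta.index)
    n_geno = str_genotypes.n_genotyped()
    grp = calls.groupby("strain_id") if not calls.empty else None
    rows = []
    for s in strains:
        sub = grp.get_group(s) if grp is not None and s in grp.groups else calls.iloc[0:0]
        n_mut = len(sub)
        ng = int(n_geno.get(s, 0))
        delta = sub["delta_ru"]
        exp = delta[delta > 0]
        con = delta[delta < 0]
        rows.append(
            {
                "strain_id": s,
                "n_genotyped": ng,
                "n_mutations": n_mut,
                "mutation_count": n_mut / ng if ng else float("nan"),
                "expansion_propensity": float(len(exp)) / n_mut if n_mut else float("nan"),
                "mean_expansion_size": float(exp.mean()) if len(exp) else float("nan"),
                "mean_contraction_size": float(con.mean()) if len(con) else float("nan"),
                "epoch": meta.loc[s, "epoch"],
                "n_generations": int(meta.loc[s, "n_generations"]),
            }
        )
    return pd.DataFrame(rows).set_index("strain_id")


def mutation_indicator_matrix(calls: pd.DataFrame, strains: list[str]) -> pd.DataFrame:
    """Binary strain x (locus, new allele) matrix: 1 where the strain
    carries that new allele."""
    index = pd.Index(strains, name="strain_id")
    if calls.empty:
        cols = pd.MultiIndex.from_arrays([[], []], names=["locus_id", "new_allele"])
        return pd.DataFrame(0, index=index, columns=cols, dtype=np.int8)
    mat = (
        calls.assign(one=1)
        .pivot_table(
            index="strain_id",
            columns=["locus_id", "observed_ru"],
            values="one",
            aggfunc="max",
            fill_value=0,
        )
        .reindex(index=index, fill_value=0)
        .astype(np.int8)
    )
    mat.columns = mat.columns.set_names(["locus_id", "new_allele"])
    return mat


def mutation_pca(
    calls: pd.DataFrame, strains: list[str], n_components: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """PCA of mutation sharing: centre the indicator matrix by column
    (no scaling) and take the singular value decomposition.

    Returns (scores, loadings).  Each component's sign is fixed so its
    largest-magnitude loading is positive; a constant matrix yields
    all-zero scores.
    """
    if len(strains) < 2:
        raise ValueError("PCA needs at least 2 strains")
    mat = mutation_indicator_matrix(calls, strains)
    X = mat.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 (locus, allele) columns")
    Xc = X - X.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components, len(s))
    scores = u[:, :k] * s[:k]
    loadings = vt[:k].T
    for c in range(k):
        j = np.argmax(np.abs(loadings[:, c]))
        if loadings[j, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    # fully constant matrix: zero out numerically-null components
    scores[:, s[:k] < 1e-10] = 0.0
    names = [f"PC{c + 1}" for c in range(k)]
    return (
        pd.DataFrame(scores, index=mat.index, columns=names),
        pd.DataFrame(loadings, index=mat.columns, columns=names),
    )
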