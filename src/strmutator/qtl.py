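"""Single-locus genome scan with a linear mixed model and LOCO kinship.

Model: y = X beta + u + e with var(u) = sigma_g^2 * 2K and var(e) =
sigma_e^2 * I.  The null heritability h2 = sigma_g^2 / (sigma_g^2 +
sigma_e^2) is profiled once per chromosome on that chromosome's
leave-one-chromosome-out kinship; each marker is then tested by
generalised least squares in the eigenrotated space, and

    LOD = (n / 2) * log10(RSS0 / RSS1)

compares the covariates-only fit with the fit adding the founder
genotype probability P(B) at the marker.  Genome-wide significance comes
from permutations of the (phenotype, covariate) rows against the
genotypes, and peaks are summarised by LOD-drop support intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .types import ConfigurationError, MarkerMap, ScanResult

logger = logging.getLogger(__name__)

_VAR_FLOOR = 1e-12
_H2_MAX = 0.99


def calc_kinship_loco(
    genoprobs: np.ndarray, marker_map: MarkerMap
) -> dict[str, np.ndarray]:
    """Leave-one-chromosome-out kinship matrices.

    ``K[i, j] = mean_m sum_g P_i(g) P_j(g)`` over the included markers;
    for chromosome ``c`` the mean excludes that chromosome's markers.
    With a single-chromosome map LOCO is impossible and the all-marker
    kinship is returned for that chromosome (with a warning).
    """
    n, n_markers, _ = genoprobs.shape
    if n < 2:
        raise ConfigurationError("kinship needs at least 2 strains")
    G = genoprobs.reshape(n, -1)
    total = G @ G.T
    out: dict[str, np.ndarray] = {}
    chroms = marker_map.chromosomes
    for chrom in chroms:
        sl = marker_map.chrom_slice(chrom)
        m_c = sl.stop - sl.start
        if len(chroms) == 1:
            logger.warning("single-chromosome map: LOCO impossible, using all markers")
            out[chrom] = total / n_markers
            continue
        Gc = genoprobs[:, sl].reshape(n, -1)
        out[chrom] = (total - Gc @ Gc.T) / (n_markers - m_c)
    return out


@dataclass
class NullFit:
    """Profiled null model for one kinship matrix."""

    h2: float
    eigenvalues: np.ndarray  # of 2K
    rotation: np.ndarray  # eigenvectors U; rotated space is U.T @ .
    loglik: float

    @property
    def weights(self) -> np.ndarray:
        """1 / (h2 * lambda_i + 1 - h2): inverse variances in the
        rotated space (up to sigma^2)."""
        return 1.0 / (self.h2 * self.eigenvalues + 1.0 - self.h2)


def _profile_loglik(h2: float, lam: np.ndarray, yr: np.ndarray, Xr: np.ndarray) -> float:
    v = h2 * lam + (1.0 - h2)
    w = 1.0 / np.sqrt(v)
    yw = yr * w
    Xw = Xr * w[:, None]
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    n = len(yr)
    sigma2 = max(float(resid @ resid) / n, _VAR_FLOOR)
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + float(np.sum(np.log(v))) + n)


def fit_null(
    y: np.ndarray,
    covariates: np.ndarray,
    K: np.ndarray,
    eigen: tuple[np.ndarray, np.ndarray] | None = None,
) -> NullFit:
    """Maximise the profiled log-likelihood over h2 in [0, 0.99].

    ``eigen`` may supply a precomputed eigendecomposition of 2K.  The
    scalar search uses Brent to 1e-6; a likelihood flat in h2 (e.g.
    identity kinship) resolves to h2 = 0 by the tie rule.
    """
    if eigen is None:
        lam, U = np.linalg.eigh(2.0 * np.asarray(K))
        lam = np.clip(lam, 0.0, None)
    else:
        lam, U = eigen
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    yr = U.T @ y
    Xr = U.T @ X
    res = minimize_scalar(
        lambda h2: -_profile_loglik(h2, lam, yr, Xr),
        bounds=(0.0, _H2_MAX),
        method="bounded",
        options={"xatol": 1e-6},
    )
    ll_opt = -res.fun
    ll_zero = _profile_loglik(0.0, lam, yr, Xr)
    if ll_zero >= ll_opt - 1e-9:
        return NullFit(0.0, lam, U, ll_zero)
    return NullFit(float(res.x), lam, U, ll_opt)


class _PreparedScan:
    """Shared machinery for a scan and its permutations: per chromosome
    the eigendecomposition of 2K^(-c) and the rotated marker genotypes."""

    def __init__(
        self,
        genoprobs: np.ndarray,
        y: np.ndarray,
        covariates: np.ndarray,
        kinship_set: dict[str, np.ndarray],
        marker_map: MarkerMap,
        drop_monomorphic: bool = True,
    ):
        y = np.asarray(y, dtype=float)
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        if X.shape[0] != len(y):
            X = X.T
        keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
        if not keep.all():
            logger.info("dropping %d strains with non-finite phenotype/covariates", int((~keep).sum()))
        self.y = y[keep]
        self.X = X[keep]
        self.n = len(self.y)
        genoprobs = genoprobs[keep]

        self.chroms = []
        self.marker_rows = []
        pb_all = genoprobs[:, :, 0]
        for chrom in marker_map.chromosomes:
            sl = marker_map.chrom_slice(chrom)
            midx = np.arange(sl.start, sl.stop)
            if drop_monomorphic:
                hard_b = pb_all[:, midx] > 0.5
                poly = hard_b.any(axis=0) & (~hard_b).any(axis=0)
                midx = midx[poly]
            if midx.size == 0:
                continue
            G = pb_all[:, midx]
            lam, U = np.linalg.eigh(2.0 * kinship_set[chrom][np.ix_(keep, keep)])
            lam = np.clip(lam, 0.0, None)
            self.chroms.append(
                {"chrom": chrom, "midx": midx, "lam": lam, "U": U, "UtG": U.T @ G}
            )
            self.marker_rows.append(
                marker_map.df.iloc[midx][["marker", "chrom", "pos_bp"]]
            )
        self.marker_df = (
            pd.concat(self.marker_rows, ignore_index=True)
            if self.marker_rows
            else pd.DataFrame(columns=["marker", "chrom", "pos_bp"])
        )

    def scan(self, y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, dict[str, float]]:
        lods = []
        h2_by_chrom: dict[str, float] = {}
        n = self.n
        for ch in self.chroms:
            lam, U, UtG = ch["lam"], ch["U"], ch["UtG"]
            yr = U.T @ y
            Xr = U.T @ X
            res = minimize_scalar(
                lambda h2: -_profile_loglik(h2, lam, yr, Xr),
                bounds=(0.0, _H2_MAX),
                method="bounded",
                options={"xatol": 1e-6},
            )
            h2 = float(res.x)
            if _profile_loglik(0.0, lam, yr, Xr) >= -res.fun - 1e-9:
                h2 = 0.0
            h2_by_chrom[ch["chrom"]] = h2
            w = 1.0 / np.sqrt(h2 * lam + (1.0 - h2))
            yw = yr * w
            Xw = Xr * w[:, None]
            Gw = UtG * w[:, None]
            Q, _ = np.linalg.qr(Xw)
            ey = yw - Q @ (Q.T @ yw)
            Eg = Gw - Q @ (Q.T @ Gw)
            rss0 = float(ey @ ey)
            num = Eg.T @ ey
            den = np.einsum("ij,ij->j", Eg, Eg)
            # collinear/constant markers add nothing: LOD 0
            ok = den > 1e-10 * max(rss0, 1.0)
            rss1 = np.where(ok, rss0 - num**2 / np.where(ok, den, 1.0), rss0)
            rss0_f = max(rss0, _VAR_FLOOR)
            rss1_f = np.maximum(rss1, _VAR_FLOOR)
            lod = (n / 2.0) * np.log10(rss0_f / rss1_f)
            lods.append(np.clip(lod, 0.0, None))
        return (
            np.concatenate(lods) if lods else np.array([]),
            h2_by_chrom,
        )


def scan1(
    genoprobs: np.ndarray,
    y: np.ndarray,
    kinship_set: dict[str, np.ndarray],
    covariates: np.ndarray,
    marker_map: MarkerMap,
    drop_monomorphic: bool = True,
) -> ScanResult:
    """Genome scan of one phenotype.

    ``genoprobs`` is (n_strains, n_markers, 2) founder genotype
    probabilities aligned to the marker map; ``covariates`` should
    include the intercept (and, for mutator phenotypes, the number of
    inbreeding generations).  Markers monomorphic in the analysed strain
    subset are dropped before scanning.
    """
    prep = _PreparedScan(genoprobs, y, covariates, kinship_set, marker_map, drop_monomorphic)
    lod, h2 = prep.scan(prep.y, prep.X)
    df = prep.marker_df.copy()
    df["lod"] = lod
    return ScanResult(df, h2)


def permutation_threshold(
    genoprobs: np.ndarray,
    y: np.ndarray,
    kinship_set: dict[str, np.ndarray],
    covariates: np.ndarray,
    marker_map: MarkerMap,
    n_perm: int = 100,
    alphas: tuple[float, ...] = (0.05,),
    seed: int = 0,
    drop_monomorphic: bool = True,
) -> tuple[dict[float, float], np.ndarray]:
    """Permutation-based genome-wide LOD thresholds.

    The rows of (phenotype, covariates) are shuffled jointly against the
    genotypes; the threshold at level alpha is the empirical (1 - alpha)
    quantile (linear/type-7 interpolation) of the per-permutation
    genome-wide maximum LODs.  Returns (thresholds, maxima).
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    if n_perm < 20 and any(a <= 0.05 for a in alphas):
        logger.warning("n_perm=%d poorly resolves the alpha<=0.05 quantile", n_perm)
    prep = _PreparedScan(genoprobs, y, covariates, kinship_set, marker_map, drop_monomorphic)
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(prep.n)
        lod, _ = prep.scan(prep.y[perm], prep.X[perm])
        maxima[p] = lod.max() if lod.size else 0.0
    thresholds = {
        float(a): float(np.quantile(maxima, 1.0 - a, method="linear")) for a in alphas
    }
    return thresholds, maxima


def lod_support_interval(
    scan: ScanResult, chromosome: str, drop: float = 1.5
) -> tuple[int, int]:
    """LOD-drop support interval around a chromosome's peak.

    Spans the contiguous marker run containing the peak with
    ``LOD >= peak - drop``, extended outward by one flanking marker on
    each side where present.  Returned as a 0-based half-open bp
    interval.
    """
    sub = scan.lod[scan.lod["chrom"] == chromosome].reset_index(drop=True)
    if sub.empty:
        raise ConfigurationError(f"no markers scanned on {chromosome!r}")
    lod = sub["lod"].to_numpy()
    peak = int(np.argmax(lod))
    thr = lod[peak] - drop
    lo = peak
    while lo > 0 and lod[lo - 1] >= thr:
        lo -= 1
    hi = peak
    while hi < len(lod) - 1 and lod[hi + 1] >= thr:
        hi += 1
    lo = max(lo - 1, 0)
    hi = min(hi + 1, len(lod) - 1)
    return int(sub["pos_bp"].iloc[lo]), int(sub["pos_bp"].iloc[hi]) + 1
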