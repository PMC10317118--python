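"""Synthetic two-founder recombinant-inbred (RI) panel generator.

Emulates a BXD-style panel: two fully inbred founders (B and D), an F1
cross followed by repeated sib-mating with recombination, and a stepwise
STR mutation process acting on every parent-to-gamete transmission.  The
mutation process is length-dependent (longer repeats mutate more often)
and its expansion/contraction bias is controlled by the transmitting
parent's genotype at one designated "mutator" marker, which is what the
downstream QTL machinery is meant to rediscover.

Breeding is simulated explicitly as a two-line sib pedigree per strain
rather than by instant fixation, so that new mutations experience real
drift: most are lost, roughly a quarter fix and become the homozygous
calls the discovery pipeline observes.  Meiosis places crossovers as a
Poisson process on the cM scale (Haldane map, no interference).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    ConfigurationError,
    FounderPanel,
    GenotypeTables,
    LABEL_B,
    LABEL_D,
    MarkerMap,
    StrainGenome,
    STRGenotypes,
)

_BASES = np.array(list("ACGT"))

_MAX_RU_LUT = 512  # repeat lengths are clipped here when looking up rates


@dataclass
class MutationModelParams:
    """Stepwise STR mutation model.

    Per transmission a locus mutates with probability
    ``min(rate_cap, base_rate * exp(length_slope * parent_len_bp))``
    where ``parent_len_bp = parent_ru * motif_len``.  Conditional on
    mutating, the step size is ``|delta| ~ Geometric(step_geometric_p)``
    (support 1, 2, ...; most mass on single-unit steps for large p) and
    the sign is an expansion with probability ``expansion_prob_B`` or
    ``expansion_prob_D`` according to the transmitting parent's genotype
    at ``mutator_locus`` (heterozygous parents use the mean).
    """

    base_rate_per_transmission: float = 1e-3
    length_slope: float = 0.02  # per bp of parent repeat length
    rate_cap: float = 0.05
    step_geometric_p: float = 0.9
    expansion_prob_B: float = 0.5
    expansion_prob_D: float = 0.5
    mutator_locus: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_rate_per_transmission < 1.0:
            raise ConfigurationError("base_rate_per_transmission must be in [0, 1)")
        if not 0.0 < self.rate_cap <= 1.0:
            raise ConfigurationError("rate_cap must be in (0, 1]")
        if not 0.0 < self.step_geometric_p <= 1.0:
            raise ConfigurationError("step_geometric_p must be in (0, 1]")
        for p in (self.expansion_prob_B, self.expansion_prob_D):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("expansion probabilities must be in [0, 1]")

    def expansion_prob(self, genotype: str) -> float:
        """Expansion probability for a parent genotype at the mutator
        locus, given as a two-character label string ("BB", "DD", "BD"...)."""
        probs = {"B": self.expansion_prob_B, "D": self.expansion_prob_D}
        return float(np.mean([probs[g] for g in genotype.upper()]))


@dataclass
class BreedingPlan:
    """Panel composition: epochs of strains sharing a breeding depth.

    Each epoch is ``(epoch_id, n_strains, n_generations)`` or
    ``(epoch_id, n_strains, n_generations, n_stock_generations)``.
    ``n_generations`` counts generations since the founder cross (or
    since the epoch's ancestral stock): generation 1 produces the F1
    sibling pair, later generations are rounds of sib-mating.  A
    positive ``n_stock_generations`` first breeds a shared ancestral
    sibling pair for that many generations; every strain of the epoch
    then continues independently from that pair, so mutations fixed in
    the stock are shared across the epoch (the mechanism behind
    epoch-specific mutation sharing in real RI families).
    """

    epochs: list[tuple]  # (epoch_id, n_strains, n_generations[, n_stock_generations])
    seed: int = 0

    def __post_init__(self) -> None:
        self.epochs = [
            (e[0], int(e[1]), int(e[2]), int(e[3]) if len(e) > 3 else 0)
            for e in self.epochs
        ]
        ids = [e[0] for e in self.epochs]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("epoch ids must be unique")
        for eid, n_strains, n_gen, n_stock in self.epochs:
            if n_strains < 1 or n_gen < 1 or n_stock < 0:
                raise ConfigurationError(
                    f"epoch {eid!r}: n_strains, n_generations must be >= 1"
                )

    @property
    def n_strains(self) -> int:
        return sum(e[1] for e in self.epochs)


def generate_founders(
    n_chromosomes: int,
    n_markers_per_chrom: int,
    n_strs_per_chrom: int,
    frac_snp_informative: float = 0.95,
    frac_str_polymorphic: float = 0.3,
    frac_founder_missing: float = 0.05,
    seed: int = 0,
    chrom_length_bp: int = 100_000_000,
    cm_per_mb: float = 0.5,
) -> tuple[FounderPanel, MarkerMap]:
    """Draw a founder pair and marker map for a synthetic panel.

    Exactly ``round(frac * n)`` loci get each property (informative SNP
    alleles, polymorphic STR founder lengths, one hidden founder STR
    length).  Polymorphic founder alleles differ by 3-6 repeat units so
    that founder origin stays identifiable after typical 1-2 unit
    mutations.  Deterministic given ``seed``.
    """
    if n_chromosomes < 1 or n_markers_per_chrom < 2 or n_strs_per_chrom < 1:
        raise ConfigurationError("counts must be positive (>= 2 markers per chromosome)")
    for name, frac in (
        ("frac_snp_informative", frac_snp_informative),
        ("frac_str_polymorphic", frac_str_polymorphic),
        ("frac_founder_missing", frac_founder_missing),
    ):
        if not 0.0 <= frac <= 1.0:
            raise ConfigurationError(f"{name} must be in [0, 1]")

    rng = np.random.default_rng(seed)
    marker_rows = []
    str_rows = []
    for c in range(n_chromosomes):
        chrom = f"chr{c + 1}"
        lo, hi = 1_000_000, chrom_length_bp - 1_000_000
        pos = np.sort(rng.choice(np.arange(lo, hi, 1000), n_markers_per_chrom, replace=False))
        for j, p in enumerate(pos):
            marker_rows.append(
                (f"m_{chrom}_{j:04d}", chrom, int(p), p * cm_per_mb / 1e6)
            )
        # STRs strictly inside the marker span so every locus sits between
        # two mappable markers
        spos = np.sort(
            rng.integers(pos[0] + 1, pos[-1], size=n_strs_per_chrom)
        )
        for p in spos:
            str_rows.append((chrom, int(p)))

    map_df = pd.DataFrame(marker_rows, columns=["marker", "chrom", "pos_bp", "pos_cm"])
    marker_map = MarkerMap(map_df)

    n_markers = len(map_df)
    n_inf = int(round(frac_snp_informative * n_markers))
    informative = np.zeros(n_markers, dtype=bool)
    informative[rng.permutation(n_markers)[:n_inf]] = True
    allele_b = rng.choice(_BASES, n_markers)
    shift = rng.integers(1, 4, n_markers)  # a different base for D where informative
    allele_d = np.where(
        informative,
        _BASES[(np.searchsorted(_BASES, allele_b) + shift) % 4],
        allele_b,
    )
    snp_alleles = pd.DataFrame(
        {"allele_B": allele_b, "allele_D": allele_d}, index=map_df["marker"]
    )

    n_loci = len(str_rows)
    motif_len = rng.choice([2, 3, 4], n_loci)
    motifs = []
    for ml in motif_len:
        while True:
            m = "".join(rng.choice(_BASES, ml))
            if len(set(m)) > 1:  # avoid homopolymer-like motifs
                break
        motifs.append(m)
    ru_b = rng.integers(5, 21, n_loci)
    poly = np.zeros(n_loci, dtype=bool)
    poly[rng.permutation(n_loci)[: int(round(frac_str_polymorphic * n_loci))]] = True
    delta = rng.integers(3, 7, n_loci) * rng.choice([-1, 1], n_loci)
    ru_d = np.where(poly, np.maximum(1, ru_b + delta), ru_b)

    miss = np.zeros(n_loci, dtype=bool)
    miss[rng.permutation(n_loci)[: int(round(frac_founder_missing * n_loci))]] = True
    miss_side = rng.integers(0, 2, n_loci)  # 0 -> hide B, 1 -> hide D

    str_reference = pd.DataFrame(
        {
            "chrom": [r[0] for r in str_rows],
            "pos_bp": [r[1] for r in str_rows],
            "motif": motifs,
            "motif_len": motif_len.astype(int),
            "ru_B": ru_b.astype(float),
            "ru_D": ru_d.astype(float),
            "missing_B": miss & (miss_side == 0),
            "missing_D": miss & (miss_side == 1),
        },
        index=pd.Index([f"STR{i:06d}" for i in range(n_loci)], name="locus_id"),
    )
    return FounderPanel(snp_alleles, str_reference), marker_map


def mutate_str(
    parent_ru_len: int,
    motif_len: int,
    mutator_genotype: str,
    model: MutationModelParams,
    rng: np.random.Generator,
) -> int:
    """Apply one transmission of the stepwise mutation model to a single
    repeat allele; returns the (possibly unchanged) offspring RU count."""
    if parent_ru_len < 1:
        raise ValueError("parent_ru_len must be >= 1")
    rate = min(
        model.rate_cap,
        model.base_rate_per_transmission
        * float(np.exp(model.length_slope * parent_ru_len * motif_len)),
    )
    if rng.random() >= rate:
        return int(parent_ru_len)
    step = int(rng.geometric(model.step_geometric_p))
    pi = model.expansion_prob(mutator_genotype)
    sign = 1 if rng.random() < pi else -1
    return max(1, int(parent_ru_len) + sign * step)


class _SimContext:
    """Precomputed per-panel arrays used by the inner breeding loop."""

    def __init__(self, founders: FounderPanel, marker_map: MarkerMap, model: MutationModelParams):
        self.map = marker_map
        self.model = model
        ref = founders.str_reference
        self.n_markers = marker_map.n_markers
        self.n_loci = len(ref)
        self.motif_len = ref["motif_len"].to_numpy(dtype=np.int64)
        self.true_ru_b = ref["ru_B"].to_numpy(dtype=np.int32)
        self.true_ru_d = ref["ru_D"].to_numpy(dtype=np.int32)

        # global cM coordinates: per-chromosome cM shifted by a large
        # offset so one sorted crossover list serves the whole genome
        g_mcm = np.empty(self.n_markers)
        g_scm = np.empty(self.n_loci)
        lo, hi = [], []
        offset = 0.0
        for chrom in marker_map.chromosomes:
            msl = marker_map.chrom_slice(chrom)
            sidx = np.flatnonzero((ref["chrom"] == chrom).to_numpy())
            ssl = slice(int(sidx[0]), int(sidx[-1]) + 1) if sidx.size else slice(0, 0)
            mcm = marker_map.df["pos_cm"].to_numpy()[msl]
            scm = marker_map.interp_cm(chrom, ref["pos_bp"].to_numpy()[ssl])
            g_mcm[msl] = mcm - mcm[0] + offset
            g_scm[ssl] = scm - mcm[0] + offset
            lo.append(offset)
            hi.append(offset + float(mcm[-1] - mcm[0]))
            offset = hi[-1] + 1e6  # gap >> any map length isolates chromosomes
        self.g_mcm = g_mcm
        self.g_scm = g_scm
        self.chrom_lo = np.asarray(lo)
        self.chrom_hi = np.asarray(hi)
        self.xo_lambda = (self.chrom_hi - self.chrom_lo) / 100.0
        # phantom flip just before each chromosome start toggles the
        # starting haplotype of that chromosome
        self.phantom = self.chrom_lo - 1.0

        if model.mutator_locus is not None:
            self.mutator_idx = marker_map.marker_index(model.mutator_locus)
        else:
            self.mutator_idx = None

        # rate lookup by (motif_len, ru): cheaper than exp() per gamete
        ru = np.arange(_MAX_RU_LUT, dtype=float)
        ml = np.arange(7, dtype=float)[:, None]
        self.rate_lut = np.minimum(
            model.rate_cap,
            model.base_rate_per_transmission * np.exp(model.length_slope * ml * ru),
        )

    def expansion_prob_for(self, snp_haps: np.ndarray) -> float:
        if self.mutator_idx is None:
            return self.model.expansion_prob_B
        l0, l1 = int(snp_haps[0, self.mutator_idx]), int(snp_haps[1, self.mutator_idx])
        p = {LABEL_B: self.model.expansion_prob_B, LABEL_D: self.model.expansion_prob_D}
        return 0.5 * (p[l0] + p[l1])


def _mutate_inplace(strs: np.ndarray, pi: float, ctx: _SimContext, rng: np.random.Generator) -> None:
    model = ctx.model
    if model.base_rate_per_transmission == 0.0:
        return
    rate = ctx.rate_lut[ctx.motif_len, np.clip(strs, 0, _MAX_RU_LUT - 1)]
    hit = np.flatnonzero(rng.random(strs.shape[0], dtype=np.float32) < rate)
    if hit.size == 0:
        return
    steps = rng.geometric(model.step_geometric_p, size=hit.size)
    signs = np.where(rng.random(hit.size) < pi, 1, -1)
    strs[hit] = np.maximum(1, strs[hit] + signs * steps)


def _gamete(
    snp: np.ndarray,
    strs: np.ndarray,
    str_lab: np.ndarray,
    ctx: _SimContext,
    rng: np.random.Generator,
    homozygous_parent: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One meiosis: recombine the parent's two haplotypes, then mutate
    every STR on the resulting gamete."""
    if homozygous_parent:
        g_snp = snp[0].copy()
        g_str = strs[0].copy()
        g_lab = str_lab[0].copy()
    else:
        n_xo = rng.poisson(ctx.xo_lambda)
        total = int(n_xo.sum())
        spans = ctx.chrom_hi - ctx.chrom_lo
        xo = np.repeat(ctx.chrom_lo, n_xo) + rng.random(total) * np.repeat(spans, n_xo)
        flip_start = rng.integers(0, 2, len(ctx.chrom_lo)).astype(bool)
        pts = np.sort(np.concatenate([xo, ctx.phantom[flip_start]]))
        par_m = np.searchsorted(pts, ctx.g_mcm) & 1
        par_s = np.searchsorted(pts, ctx.g_scm) & 1
        g_snp = np.where(par_m == 0, snp[0], snp[1])
        g_str = np.where(par_s == 0, strs[0], strs[1])
        g_lab = np.where(par_s == 0, str_lab[0], str_lab[1])
    pi = ctx.expansion_prob_for(snp)
    _mutate_inplace(g_str, pi, ctx, rng)
    return g_snp, g_str, g_lab


class _Individual:
    __slots__ = ("snp", "strs", "str_lab")

    def __init__(self, snp, strs, str_lab):
        self.snp = snp
        self.strs = strs
        self.str_lab = str_lab


def _child(p0: _Individual, p1: _Individual, ctx: _SimContext,
           rng: np.random.Generator, founders: bool = False) -> _Individual:
    s0, r0, l0 = _gamete(p0.snp, p0.strs, p0.str_lab, ctx, rng, homozygous_parent=founders)
    s1, r1, l1 = _gamete(p1.snp, p1.strs, p1.str_lab, ctx, rng, homozygous_parent=founders)
    return _Individual(np.stack([s0, s1]), np.stack([r0, r1]), np.stack([l0, l1]))


def _f1_pair(ctx: _SimContext, rng: np.random.Generator) -> tuple[_Individual, _Individual]:
    fb = _Individual(
        np.full((2, ctx.n_markers), LABEL_B, dtype=np.int8),
        np.broadcast_to(ctx.true_ru_b, (2, ctx.n_loci)).copy(),
        np.full((2, ctx.n_loci), LABEL_B, dtype=np.int8),
    )
    fd = _Individual(
        np.full((2, ctx.n_markers), LABEL_D, dtype=np.int8),
        np.broadcast_to(ctx.true_ru_d, (2, ctx.n_loci)).copy(),
        np.full((2, ctx.n_loci), LABEL_D, dtype=np.int8),
    )
    return (_child(fb, fd, ctx, rng, founders=True), _child(fb, fd, ctx, rng, founders=True))


def _breed(ctx: _SimContext, pair, n_rounds: int, rng: np.random.Generator):
    for _ in range(n_rounds):
        pair = (_child(pair[0], pair[1], ctx, rng), _child(pair[0], pair[1], ctx, rng))
    return pair


def _simulate_lineage(
    ctx: _SimContext,
    n_generations: int,
    rng: np.random.Generator,
    start_pair=None,
) -> _Individual:
    if start_pair is None:
        pair = _f1_pair(ctx, rng)
        rounds = n_generations - 1
    else:
        pair = start_pair
        rounds = n_generations
    return _breed(ctx, pair, rounds, rng)[0]


def simulate_strain(
    founders: FounderPanel,
    marker_map: MarkerMap,
    n_generations: int,
    model: MutationModelParams,
    seed: int | np.random.Generator = 0,
    strain_id: str = "RI0000",
) -> StrainGenome:
    """Breed one RI strain: F1 (B x D) then ``n_generations - 1`` rounds
    of sib-mating, mutating STRs at every transmission.  Returns the
    phased genome of one individual of the final sibling pair."""
    if n_generations < 1:
        raise ConfigurationError("n_generations must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ctx = _SimContext(founders, marker_map, model)
    ind = _simulate_lineage(ctx, n_generations, rng)
    return StrainGenome(strain_id, ind.snp, ind.strs, ind.str_lab)


def simulate_panel(
    founders: FounderPanel,
    marker_map: MarkerMap,
    plan: BreedingPlan,
    model: MutationModelParams,
) -> tuple[list[StrainGenome], pd.DataFrame]:
    """Simulate every strain in the breeding plan.  Deterministic given
    ``plan.seed``; strains are independent lineages."""
    ctx = _SimContext(founders, marker_map, model)
    epoch_seeds = np.random.SeedSequence(plan.seed).spawn(len(plan.epochs))
    genomes: list[StrainGenome] = []
    meta_rows = []
    k = 0
    for (epoch_id, n_strains, n_gen, n_stock), eseed in zip(plan.epochs, epoch_seeds):
        seeds = eseed.spawn(n_strains + 1)
        stock_pair = None
        if n_stock > 0:
            stock_rng = np.random.default_rng(seeds[0])
            stock_pair = _f1_pair(ctx, stock_rng)
            stock_pair = _breed(ctx, stock_pair, n_stock - 1, stock_rng)
        for s in range(n_strains):
            rng = np.random.default_rng(seeds[s + 1])
            sid = f"RI{k:04d}"
            ind = _simulate_lineage(ctx, n_gen, rng, start_pair=stock_pair)
            genomes.append(StrainGenome(sid, ind.snp, ind.strs, ind.str_lab))
            meta_rows.append((sid, epoch_id, n_gen + n_stock))
            k += 1
    metadata = pd.DataFrame(meta_rows, columns=["strain_id", "epoch", "n_generations"])
    return genomes, metadata


def true_mutation_table(genomes: list[StrainGenome], founders: FounderPanel) -> pd.DataFrame:
    """Ground-truth fixed mutations: (strain, locus) pairs where the
    final genotype is homozygous, both haplotypes descend from the same
    founder, and the allele differs from that founder's true allele.
    (Unfixed mutations are still segregating as heterozygous calls and
    are outside the discovery pipeline's target set.)"""
    ref = founders.str_reference
    true_ru = np.stack(
        [ref["ru_B"].to_numpy(dtype=np.int32), ref["ru_D"].to_numpy(dtype=np.int32)]
    )
    rows = []
    for g in genomes:
        lab = g.str_labels
        hom = (g.strs[0] == g.strs[1]) & (lab[0] == lab[1])
        founder_ru = true_ru[lab[0], np.arange(lab.shape[1])]
        mut = hom & (g.strs[0] != founder_ru)
        for j in np.flatnonzero(mut):
            rows.append(
                (
                    g.strain_id,
                    ref.index[j],
                    "B" if lab[0, j] == LABEL_B else "D",
                    int(founder_ru[j]),
                    int(g.strs[0, j]),
                )
            )
    return pd.DataFrame(
        rows, columns=["strain_id", "locus_id", "founder_label", "founder_ru", "final_ru"]
    )


def render_panel(
    genomes: list[StrainGenome],
    founders: FounderPanel,
    marker_map: MarkerMap,
    metadata: pd.DataFrame,
    missing_call_rate: float = 0.0,
    het_error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[GenotypeTables, pd.DataFrame]:
    """Turn simulated genomes into observed tables: a strain x marker SNP
    call table ({B, H, D, NA}), diploid STR genotypes, and metadata --
    plus the ground-truth mutation table for benchmarking.

    ``missing_call_rate`` drops SNP and STR calls at random;
    ``het_error_rate`` converts random homozygous STR calls into spurious
    one-unit heterozygotes (a genotyping-error channel; downstream calling
    excludes heterozygous calls).
    """
    for name, rate in (("missing_call_rate", missing_call_rate), ("het_error_rate", het_error_rate)):
        if not 0.0 <= rate < 1.0:
            raise ConfigurationError(f"{name} must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = len(genomes)
    n_markers = marker_map.n_markers
    n_loci = len(founders.str_reference)
    strains = [g.strain_id for g in genomes]

    truth = true_mutation_table(genomes, founders)

    snp = np.empty((n, n_markers), dtype="U2")
    a1 = np.empty((n, n_loci), dtype=np.int32)
    a2 = np.empty((n, n_loci), dtype=np.int32)
    for i, g in enumerate(genomes):
        hom = g.snp[0] == g.snp[1]
        snp[i] = np.where(hom, np.where(g.snp[0] == LABEL_B, "B", "D"), "H")
        a1[i] = g.strs[0]
        a2[i] = g.strs[1]

    if het_error_rate > 0:
        hom = a1 == a2
        err = hom & (rng.random((n, n_loci)) < het_error_rate)
        a2[err] = np.maximum(1, a1[err] + np.where(rng.random(int(err.sum())) < 0.5, 1, -1))
    if missing_call_rate > 0:
        snp[rng.random((n, n_markers)) < missing_call_rate] = "NA"
        drop = rng.random((n, n_loci)) < missing_call_rate
        a1[drop] = -1
        a2[drop] = -1

    snp_calls = pd.DataFrame(snp, index=strains, columns=marker_map.df["marker"].to_numpy())
    str_genotypes = STRGenotypes(strains, founders.str_reference.index, a1, a2)
    tables = GenotypeTables(snp_calls, str_genotypes, metadata.reset_index(drop=True))
    return tables, truth


def sib_mating_heterozygosity(n_rounds: int) -> float:
    """Expected fraction of initially heterozygous loci still segregating
    after ``n_rounds`` of brother-sister mating, from the classical
    recursion H_{t+1} = H_t/2 + H_{t-1}/4 with H_0 = 1 (F1), H_1 = 1/2.

    Used as the independent fixation oracle for the breeding simulator.
    """
    if n_rounds < 0:
        raise ValueError("n_rounds must be >= 0")
    h_prev, h = 1.0, 0.5
    if n_rounds == 0:
        return h_prev
    for _ in range(n_rounds - 1):
        h_prev, h = h, h / 2 + h_prev / 4
    return h
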