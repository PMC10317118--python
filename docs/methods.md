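# Methods

This note documents the models implemented in `strmutator`, the defaults
and why they were chosen, what the synthetic panel does and does not
emulate, and the numerical conventions.

## Synthetic RI panel

**Founders and maps.** `generate_founders` draws per-chromosome marker
positions uniformly (default 100 Mb chromosomes, 0.5 cM/Mb, so a
200-marker chromosome spans ~49 cM) and places STR loci strictly inside
the marker span so genetic positions can always be interpolated. Exact
counts of loci receive each property: `frac_snp_informative` of SNPs have
distinct founder alleles, `frac_str_polymorphic` of STRs have distinct
founder repeat lengths, `frac_founder_missing` have one founder length
hidden from the reported reference (the truth is retained internally for
benchmarking). Polymorphic founder allele pairs differ by 3–6 repeat
units. This is deliberate: mutations are mostly ±1–2 units, so a
well-separated founder pair keeps founder origin identifiable — a
mutated allele essentially never coincides with the other founder's
allele, and a near-breakpoint haplotype mislabel produces a genotype that
matches *a* founder (hence is not called) rather than a spurious call.
Motifs are random non-homopolymeric 2–4-mers; founder lengths are uniform
on 5–20 units.

**Breeding.** Each strain is an explicit two-line sib pedigree: an F1
cross (generation 1) followed by `n_generations − 1` rounds of
brother–sister mating; the strain is one individual of the final pair.
Meiosis drops crossovers as a Poisson process on the cM scale (Haldane
map, no interference, no sex-specific maps), implemented as one global
sorted breakpoint list with a random phase flip at each chromosome start
(chromosomes therefore segregate independently). Explicit breeding, as
opposed to instant fixation, matters because mutations arise on
transmissions and then drift: roughly a quarter fix and become the
homozygous calls the pipeline targets, the rest are lost or linger as
heterozygous calls that the pipeline deliberately ignores. The expected
residual heterozygosity follows the classical recursion
`H_{t+1} = H_t/2 + H_{t-1}/4` (`sib_mating_heterozygosity`), which the
test suite uses as the fixation oracle; after 30 generations ≈ 99.8% of
initially heterozygous markers are fixed.

An epoch may specify `n_stock_generations`: a shared ancestral sibling
pair is bred first and every strain of the epoch continues from it.
Mutations fixed in the stock are then shared by the whole epoch, which is
the mechanism that makes the mutation-sharing PCA separate epochs, as
observed in real RI families where later epochs descend from
partially-inbred ancestral stock. The default (0) gives fully independent
strains.

**Mutation model.** At every parent→gamete transmission each STR mutates
with probability `min(rate_cap, base_rate · exp(length_slope · L))`,
where `L` is the *current* parent allele length in bp (so alleles can
drift over many generations through repeated expansion/contraction
steps). Conditional on mutating, `|Δ| ~ Geometric(step_geometric_p)`
(support 1, 2, …; p = 0.9 puts ~90% of mutations at a single repeat
unit), the sign is an expansion with probability `expansion_prob_B` or
`expansion_prob_D` according to the transmitting parent's genotype at
`mutator_locus` (heterozygous parents use the mean — the neutral choice),
and the result is floored at one repeat unit.

Defaults: `base_rate = 1e-3` per transmission, `length_slope = 0.02`/bp,
`rate_cap = 0.05`, `step_geometric_p = 0.9`. No published per-locus rate
scale exists for this setting, so the defaults are calibrated for test
power rather than realism: a 150-strain, 5,000-locus panel yields on the
order of a few hundred fixed mutations per strain, enough that per-strain
expansion propensity is estimated precisely and all filters have
non-trivial effect. Real panels have rates orders of magnitude lower;
nothing in the pipeline depends on the absolute scale.

**Rendering.** `render_panel` emits what an analyst would see: a
strain × marker SNP label table ({B, H, D, NA}), diploid STR repeat-copy
genotypes, and metadata — plus the ground-truth mutation table. Noise
channels: `missing_call_rate` blanks calls at random;
`het_error_rate` converts random homozygous STR calls into spurious
±1-unit heterozygotes (an error channel, since downstream calling
excludes heterozygous calls anyway). The truth table records *fixed*
mutations only (homozygous, both haplotypes from the same founder,
allele ≠ that founder's allele): still-segregating mutations are
heterozygous and outside the discovery pipeline's target set, so they do
not belong in the benchmark denominator.

**Not emulated:** read-level noise (stutter beyond the het channel),
genotyping bias toward the reference founder, selection/transmission
distortion, sex chromosomes' distinct transmission, and shared laboratory
environments. Passing tests therefore demonstrate the *procedure* is
correct and calibrated under the stated generative model, not that real
BXD data would yield any particular locus.

## Founder inference

Labels: at founder-informative markers, homozygous calls map to B/D;
heterozygous, mismatching or uninformative markers are missing. Missing
labels are imputed by a per-chromosome 2-state HMM: transition
probability between adjacent markers `d` cM apart is the RI-by-sibling
expansion `R = 4r/(1+6r)` of the Haldane fraction
`r = (1 − e^{−2d/100})/2`; emission matches the observed label with
probability `1 − error_rate` (default 0.002 — a free parameter, logged,
standing in for the genotyping-error rate that marginal-probability
imputation tools embed). A missing label is replaced by a state whose
marginal posterior exceeds `min_prob` (0.5) plus a 1e-12 tie guard, so an
exactly symmetric configuration stays missing; observed labels are never
overwritten. The forward–backward pass is hand-rolled because the
transition matrix differs per marker interval, which off-the-shelf HMM
packages do not support; it is validated against brute-force path
enumeration on small instances.

Blocks are maximal runs of identical non-missing labels; residual-missing
markers split runs and the gaps persist (gap attachment is deferred to
calling). STR loci inside a block take its label; loci in gaps attach to
the nearest block edge by bp distance, with exact midpoint ties left
unassigned — an ambiguous origin would corrupt phase-dependent
phenotypes.

Missing founder STR alleles: strains carrying the missing founder's
haplotype at the locus vote with their homozygous alleles; if at most one
non-modal allele value is present **and** the modal allele is carried by
a strict majority (> 50%, ties drop), the founder receives the modal
allele; otherwise the locus is dropped from downstream analysis. With
both founders missing, each side is inferred from its own group and the
locus is dropped if either fails.

## Mutation calling and filters

A candidate mutation is a homozygous, non-missing strain genotype that
matches **neither** founder allele; its origin (founder label and signed
`Δ` in repeat units) comes from the local haplotype block. Requiring a
mismatch against both founders (rather than only the local founder) is
what makes the caller robust to rare haplotype mislabels near
recombination breakpoints. Heterozygous strain calls and het-flagged
founder loci are excluded; unresolved-founder loci are skipped.

Filters, in order: (1) recurrence — drop every call at a locus where the
identical new allele occurs in more than `max_strains` (10) strains;
counting is per (locus, allele), since sharing of the *same* new allele
is what indicates descent or founder mistyping; (2) per-epoch outlier
strains — call count more than 2× the median of the other strains in the
same epoch (singleton epochs never flag); (3) per-strain minimum — strains
with fewer than 10 retained calls are excluded from phenotypes (their
calls stay in the raw output, flagged). The motif of each call is also
reported in canonical form: the lexicographically smallest rotation of
the motif or its reverse complement.

## Phenotypes and PCA

Per strain: mutation count = retained calls / non-missing genotyped loci;
mean expansion and contraction sizes (signed repeat units); expansion
propensity = expansions / calls (missing when a strain has no calls;
contraction propensity is 1 minus it). The sharing PCA builds the binary
strain × (locus, new allele) matrix, centres columns without scaling, and
takes the SVD; each component's sign is fixed so its largest-magnitude
loading is positive, and numerically null components give zero scores.

## QTL scan

Model: `y = Xβ + u + ε`, `var(u) = σ²_g·2K`, `var(ε) = σ²_e·I`, with
`K[i,j] = mean_m Σ_g P_i(g)P_j(g)` over founder genotype probabilities
(the HMM posteriors) and LOCO kinship per scanned chromosome (2K is the
conventional additive multiplier; single-chromosome maps fall back to
all-marker kinship with a warning). The null heritability
`h² = σ²_g/(σ²_g+σ²_e)` is profiled once per chromosome by bounded scalar
search on [0, 0.99] to 1e-6 after eigendecomposing 2K; a likelihood flat
in h² (identity kinship) resolves to 0 by an explicit tie rule, and
residual variances are floored at 1e-12. Each marker is then tested by
weighted GLS in the rotated space (weights `1/(h²λᵢ + 1 − h²)`), with
`LOD = (n/2)·log10(RSS₀/RSS₁)`; collinear or constant markers score 0,
and markers monomorphic in the analysed strain subset are dropped before
scanning. h² is re-estimated under the null only, keeping the scan
O(markers).

Permutation thresholds shuffle the rows of (phenotype, covariates)
jointly against the genotypes — the generations covariate is a property
of the strain's mutation history and cannot be separated from the
phenotype — refit the null per chromosome per permutation, and take the
empirical (1 − α) quantile (linear/type-7 interpolation, fixed for
reproducibility) of the genome-wide maxima; α defaults to 0.05. Support
intervals span the contiguous run around a peak with LOD ≥ peak − 1.5,
extended one flanking marker outward on each side.

## Pattern analyses

The "parent" length of an observation is the founder allele of the local
haplotype × motif length, in bp (default 4-bp half-open bins): the
template the mutation process acted on, not the observed (possibly
mutated) allele. Group contrasts pool counts across strains (the tests
operate on mutation sets, not strain means) and use the two-sided pooled
z-proportion test, `z = (p̂₁ − p̂₂)/√(p̂(1−p̂)(1/n₁+1/n₂))`, with
degenerate pooled proportions returning (z = 0, p = 1) and a logged
warning when any expected cell is below 5 — the normal approximation is
retained at small counts for fidelity to the stated method. Length trends
use Pearson correlation of bin midpoint against rate with the
t-distribution p-value; fewer than 3 usable bins, or zero variance,
yields a missing result.

## Orchestration and I/O

One config mapping drives everything (`pipeline.DEFAULT_CONFIG` lists
every key); each output directory contains the resolved config, all
tables, JSON sidecars with thresholds/intervals/h², and a manifest whose
per-stage input/drop/retained counts must reconcile exactly. Stages are
checkpointed by a config+seed hash so a rerun resumes from serialized
intermediates; filter sweeps (`max_strains` × `min_mutations` grids),
per-motif-length scans, and epoch subsets are config matrices over the
calling/scan stages. Internal coordinates are 0-based half-open
everywhere; conversion happens only at the VCF (1-based) and BED
boundaries. STR genotypes travel as VCF 4.2 with an `RU` INFO tag and a
diploid `REPCN` FORMAT field; `./.` and absent `REPCN` are missing.

## Statistical test design

Study-scale checks use 150 strains, 5 chromosomes × 200 markers, 5,000
loci, and epochs of 20–100 generations, with 100-permutation thresholds —
sizes chosen so the full statistical suite (10 power seeds plus 40 null
replicates) runs on a single CPU in minutes. Two design points worth
recording: (1) the homozygosity-recursion check spreads its 500 markers
over 50 chromosomes and takes the strain × chromosome as the sampling
unit, because linked markers share residual heterozygous segments and a
marker-level error bar would be badly anti-conservative; (2) the null
calibration check compares the α = 0.05 genome-wide detection count over
40 replicates against the exact central binomial acceptance region for
p = 0.05.

## Known limitations

Two founders only; no X-specific transition model (chromosome-class
pattern summaries accept X/Y-named chromosomes, but the simulator default
is autosomal); no read-level or stutter simulation; the recurrence filter
reading (per locus-allele, not per locus) follows the sharing analysis
but the alternative is one config switch away; permutation thresholds
assume exchangeability of strains under the null, which explicit
relatedness (the LMM) only partially restores in small panels.
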