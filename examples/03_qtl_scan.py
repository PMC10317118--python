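"""Map a mutator QTL for expansion propensity.

Runs the whole pipeline on a panel carrying a planted expansion-bias
locus (B haplotype expands 60% of the time, D 40%), then prints the LOD
peak, the 100-permutation genome-wide threshold and the 1.5-LOD support
interval.
"""

from strmutator import run_all

cfg = {
    "seed": 11,
    "simulate": {
        "n_chromosomes": 3,
        "n_markers_per_chrom": 100,
        "n_strs_per_chrom": 600,
        "epochs": [
            {"id": "1", "n_strains": 25, "n_generations": 40},
            {"id": "2", "n_strains": 25, "n_generations": 80},
        ],
        "model": {
            "expansion_prob_B": 0.6,
            "expansion_prob_D": 0.4,
            "mutator_locus": "m_chr2_0050",
        },
    },
    "scan": {"phenotypes": ["expansion_propensity"], "n_perm": 100, "alphas": [0.05]},
    "patterns": None,
    "pca": False,
}
res = run_all(cfg)
scan = res.scans["expansion_propensity"]
peak = scan.peak()
print(f"planted mutator locus: m_chr2_0050 (chr2)")
print(f"peak: {peak['marker']} on {peak['chrom']} at {peak['pos_bp']:,} bp, "
      f"LOD = {peak['lod']:.1f}")
print(f"genome-wide 5% threshold (100 permutations): {scan.thresholds[0.05]:.2f}")
if "chr2" in scan.intervals:
    lo, hi = scan.intervals["chr2"]
    print(f"1.5-LOD support interval on chr2: {lo:,}-{hi:,} bp")
print("\nA LOD far above the permutation threshold on the planted "
      "chromosome means the scan recovered the expansion-bias locus; the "
      "support interval approximates its location.")
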