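"""Population differentiation and multiple-testing thresholds.

Pairwise F_ST between three populations at increasing divergence from a
common ancestor, plus the two genome-wide significance thresholds: plain
Bonferroni over SNP count, and the coarser correction that counts one
effective test per linkage-disequilibrium bin.
"""

import sweepkit as sk

cfg = sk.SimConfig(
    n_chromosomes=1, sites_per_chromosome=4000,
    chrom_length_bp=4_000_000, chrom_length_cM=40.0,
    populations=(sk.PopulationSpec("wild", 30, 0.02),
                 sk.PopulationSpec("landrace", 60, 0.20),
                 sk.PopulationSpec("elite", 60, 0.40)),
    n_founders=None,  # linkage equilibrium: F_ST reflects drift alone
    seed=2)
gm, _, _ = sk.simulate(cfg)

print("pairwise Hudson F_ST:")
print(sk.fst_matrix(gm).round(3).to_string())
print("\neach population diverged from the shared ancestor with its own F; "
      "pairs combine additively, so wild-elite exceeds wild-landrace")

n_snps = 265_487
print(f"\nBonferroni threshold for {n_snps} SNPs at alpha 0.05: "
      f"{sk.bonferroni(0.05, n_snps):.3g}")

genome_bp, ld_bp = 730e6, 150e3
t = sk.ld_adjusted_threshold(0.05, genome_bp, ld_bp)
print(f"LD-bin-adjusted threshold (730 Mb genome, 150 kb LD extent): "
      f"{t:.3g} -> order of magnitude {sk.nearest_power_of_ten(t):.0e}")
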