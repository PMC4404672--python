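# Demonstration pipeline: a small synthetic panel with one shared planted
# sweep, run end to end.  All randomness derives from `seed`.
seed: 42
stages: [simulate, filter, hetscan, fst, hapshare, overlap, thresholds, color]
params:
  simulate:
    n_chromosomes: 2
    sites_per_chromosome: 1200
    chrom_length_bp: 12000000
    chrom_length_cM: 100.0
    block_length_bp: 150000
    n_founders: 8
    missing_rate: 0.02
    populations:
      - {label: wild, n_samples: 20, f_divergence: 0.02, selfing_rate: 0.95}
      - {label: raceA, n_samples: 40, f_divergence: 0.20, selfing_rate: 0.95}
      - {label: raceB, n_samples: 40, f_divergence: 0.30, selfing_rate: 0.95}
    sweeps:
      - populations: [raceA, raceB]
        chrom: Chr01
        start_bp: 0
        end_bp: 5500000
        diversity_retention: 0.05
        haplotype_id: 0
  filter: {max_missing_rate: 0.5, min_maf: 0.02}
  hetscan: {wild_pop: wild, window_sites: 500, top_fraction: 0.25}
  fst: {estimator: hudson}
  hapshare: {n_snps: 60}
  overlap: {bin_cm: 30, n_qtl: 8, fraction_overlapping_sweeps: 0.5, qtl_width_cm: 30}
  # LD extent set to the generator's configured founder-block length
  thresholds: {alpha: 0.05, genome_size_bp: 24000000, ld_extent_bp: 150000}
  color: {n_genotypes: 30, noise_sd: 5.0}
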