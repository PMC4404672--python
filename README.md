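# sweepkit

Statistics for finding and characterizing domestication-era selective
sweeps in diversity panels of inbred crops.

When a crop is domesticated, the genomic regions that were selected lose
diversity in the cultivated gene pool but keep it in the wild relative.
sweepkit implements the core toolchain for that comparison:

- **Selection scan** — windowed wild/cultivated expected-heterozygosity
  ratio (`H_w/H_c`) over consecutive-SNP windows, with top-percentile
  region calling and an explicit flag for fully swept (zero-diversity)
  windows.
- **Differentiation** — pairwise Hudson F_ST (Weir–Cockerham as an
  alternative) across all labelled populations.
- **Linkage disequilibrium** — composite `r²` without phasing, binned decay
  curves, and the distance at which LD reaches background.
- **Haplotype sharing** — a phasing-free two-locus statistic that asks
  whether two cultivated groups inherited the *same* swept haplotype or
  swept independently.
- **Interval statistics** — genetic-map binning, physical/genetic
  coordinate conversion, and a hypergeometric test for whether selection
  regions co-locate with trait (QTL) intervals.
- **Significance thresholds** — Bonferroni and LD-bin-adjusted genome-wide
  thresholds.
- **Seed-color phenotyping** — per-genotype RGB averaging and conversion to
  CIE-L\*a\*b\*.
- **Synthetic data** — a seeded Balding–Nichols generator with founder-block
  LD, selfing, and planted sweeps of known location and strength, so every
  statistic can be validated against ground truth.

A pipeline module ties the stages together behind one config file and one
seed; reruns are byte-identical. See [docs/methods.md](docs/methods.md) for
the exact definitions and modeling assumptions.

## Worked example

Simulate a wild panel plus a cultivated one that lost 90 % of its diversity
over the start of chromosome 1, then scan for the sweep
([examples/01_selection_scan.py](examples/01_selection_scan.py)):

```python
import sweepkit as sk

cfg = sk.SimConfig(
    n_chromosomes=2, sites_per_chromosome=2500,
    chrom_length_bp=26_000_000, chrom_length_cM=100.0,
    populations=(sk.PopulationSpec("wild", 15, 0.02),
                 sk.PopulationSpec("cult", 30, 0.2)),
    sweeps=(sk.SweepSpec(("cult",), "Chr01", 0, 5_600_000,
                         diversity_retention=0.1),),
    seed=1)
gm, gmap, truth = sk.simulate(cfg)

ws = sk.het_ratio_scan(gm, wild_pop="wild", cultivated_pops=["cult"],
                       window_sites=500)
cutoff, regions = sk.top_percentile_regions(ws, top_fraction=0.1)
```

Output:

```
chrom  start_bp   end_bp  Hw_mean  Hc_mean    ratio
Chr01     10394  5197500 0.294116 0.116408 2.526597
Chr01   5207894 10395000 0.281529 0.224749 1.252638
Chr01  10405394 15592500 0.280853 0.236052 1.189793
...
top-10% cutoff on the ratio: 2.527
signature region: Chr01:10394-5197500 (ratio 2.527)
planted sweep:    Chr01:0-5600000
```

The swept window stands out at 2.5× the genome-wide baseline and the called
region coincides with the planted sweep. Asking whether two populations
share the same sweep ([examples/04_haplotype_sharing.py](examples/04_haplotype_sharing.py)):

```
pair   shared  total  ratio
A-B       113    181  0.624
A-C        89    207  0.430
B-C        91    199  0.457
```

A and B were swept onto the same founder haplotype and share 62 % of their
two-locus haplotype types; pairs involving the independently swept C sit
near the background level. The other scripts in [examples/](examples/)
cover F_ST and thresholds, LD decay, the QTL overlap test, seed-color
phenotyping, and the full pipeline.

## Command line

Every stage is also a CLI subcommand operating on VCF/TSV/BED files:

```sh
sweepkit run --out demo_run --seed 42       # packaged demo config
sweepkit run --config my_run.yaml --out out_dir
sweepkit hetscan --genotypes panel.vcf --pops labels.tsv --wild wild \
    --out scan.tsv --bed regions.bed
```

`demo_run/manifest.json` records the package version, full configuration,
seed, and SHA-256 checksums of every output; rerunning with the same seed
reproduces the files byte for byte.

## Repository layout

- `src/sweepkit/` — library modules (`io`, `scan`, `haplotypes`,
  `intervals`, `thresholds`, `color`, `simulate`, `pipeline`, `cli`)
- `examples/` — short narrative scripts, each runnable as-is
- `tests/` — oracle-based unit, property, and acceptance suites
- `docs/methods.md` — methods note: definitions, assumptions, limitations
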