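"""End-to-end orchestration: simulate -> filter -> scan -> F_ST -> haplotype
sharing -> overlap test -> thresholds -> color, with one top-level seed.

A run is described by a :class:`RunConfig` (usually loaded from YAML): stage
toggles plus a parameter block per stage.  Each enabled stage writes its
outputs under the run directory and registers them in a manifest
(``manifest.json``) holding the package version, the full configuration, the
seed, and a SHA-256 checksum per file.  Outputs contain no timestamps, so a
rerun with the same configuration and seed is byte-identical.

Per-stage random seeds are derived deterministically from the top-level seed,
so toggling one stochastic stage does not perturb the others.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__, io, scan, haplotypes, intervals, thresholds, color
from .simulate import (SimConfig, simulate as run_simulation,
                       simulate_intervals, simulate_seed_colors)
from .exceptions import SweepkitError

log = logging.getLogger("sweepkit")

STAGES = ("simulate", "filter", "hetscan", "fst", "hapshare",
          "overlap", "thresholds", "color")


@dataclass
class RunConfig:
    """Pipeline configuration: enabled stages, a parameter dict per stage,
    input paths (used when simulation is disabled) and the top-level seed."""

    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    params: dict[str, dict[str, Any]] = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise SweepkitError(f"unknown stage(s): {sorted(unknown)}")
        if "simulate" not in self.stages:
            for key in ("genotypes", "pop_labels", "map"):
                if key in self.inputs and not Path(self.inputs[key]).exists():
                    raise SweepkitError(f"input file missing: {self.inputs[key]}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(seed=int(raw.get("seed", 0)),
                   stages=list(raw.get("stages", STAGES)),
                   params={k: dict(v) for k, v in raw.get("params", {}).items()},
                   inputs=dict(raw.get("inputs", {})))

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed below 2**31."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run(config: RunConfig, output_dir: str | Path) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = config.params
    outputs: dict[str, str] = {}
    results: dict[str, Any] = {}

    def register(name: str, path: Path) -> None:
        outputs[name] = str(path.relative_to(out))

    gm = gmap = truth = None
    selection_intervals: list[io.Interval] = []
    qtl_intervals: list[io.Interval] = []

    # ----- simulate / load -------------------------------------------------
    if "simulate" in config.stages:
        sim_params = dict(p.get("simulate", {}))
        sim_params.setdefault("seed", config.stage_seed("simulate"))
        cfg = SimConfig.from_dict(sim_params)
        log.info("simulate: %d chromosomes x %d sites, %d populations",
                 cfg.n_chromosomes, cfg.sites_per_chromosome, len(cfg.populations))
        gm, gmap, truth = run_simulation(cfg)
        io.write_vcf(gm, out / "genotypes.vcf")
        io.write_pop_labels(gm, out / "pop_labels.tsv")
        io.write_map(gmap, out / "map.tsv")
        register("genotypes", out / "genotypes.vcf")
        register("pop_labels", out / "pop_labels.tsv")
        register("map", out / "map.tsv")
        if truth.sweep_regions:
            sweeps_bed = [io.Interval(r["chrom"], r["start_bp"], r["end_bp"],
                                      unit="bp", trait="planted-sweep")
                          for r in truth.sweep_regions]
            io.write_bed(sweeps_bed, out / "planted_sweeps.bed")
            register("planted_sweeps", out / "planted_sweeps.bed")
    elif config.inputs.get("genotypes"):
        gm = io.read_genotypes(config.inputs["genotypes"],
                               format=config.inputs.get("format"),
                               pop_labels=config.inputs.get("pop_labels"))
        if config.inputs.get("map"):
            gmap = io.read_map(config.inputs["map"])

    # ----- filter ----------------------------------------------------------
    if "filter" in config.stages:
        if gm is None:
            raise SweepkitError("filter stage requires genotypes")
        fp = p.get("filter", {})
        n_before = gm.n_sites
        gm = io.filter_sites(gm,
                             max_missing_rate=fp.get("max_missing_rate", 0.5),
                             min_maf=fp.get("min_maf", 0.02))
        log.info("filter: %d -> %d sites", n_before, gm.n_sites)
        io.write_dosage_tsv(gm, out / "genotypes.filtered.tsv")
        register("genotypes_filtered", out / "genotypes.filtered.tsv")
        results["filter"] = {"sites_before": n_before, "sites_after": gm.n_sites}

    # ----- heterozygosity-ratio scan --------------------------------------
    if "hetscan" in config.stages:
        if gm is None:
            raise SweepkitError("hetscan stage requires genotypes")
        hp = p.get("hetscan", {})
        wild = hp.get("wild_pop", "wild")
        cult = hp.get("cultivated_pops") or [l for l in gm.population_labels
                                             if l != wild]
        ws = scan.het_ratio_scan(gm, wild, cult,
                                 window_sites=hp.get("window_sites", 500))
        cutoff, selection_intervals = scan.top_percentile_regions(
            ws, top_fraction=hp.get("top_fraction", 0.05))
        ws.to_tsv(out / "hetscan.tsv")
        io.write_bed(selection_intervals, out / "selection_regions.bed")
        register("hetscan", out / "hetscan.tsv")
        register("selection_regions", out / "selection_regions.bed")
        log.info("hetscan: %d windows, cutoff %.4g, %d signature regions",
                 ws.n_windows, cutoff, len(selection_intervals))
        results["hetscan"] = {"n_windows": ws.n_windows, "cutoff": cutoff,
                              "n_regions": len(selection_intervals)}

    # ----- F_ST ------------------------------------------------------------
    if "fst" in config.stages:
        if gm is None:
            raise SweepkitError("fst stage requires genotypes")
        fp = p.get("fst", {})
        mat = scan.fst_matrix(gm, estimator=fp.get("estimator", "hudson"))
        mat.to_csv(out / "fst_matrix.tsv", sep="\t", float_format="%.6g")
        register("fst_matrix", out / "fst_matrix.tsv")
        results["fst"] = {"populations": list(mat.index)}

    # ----- haplotype sharing ----------------------------------------------
    if "hapshare" in config.stages:
        if gm is None:
            raise SweepkitError("hapshare stage requires genotypes")
        hp = p.get("hapshare", {})
        region = hp.get("region")
        if region is None and truth is not None and truth.sweep_regions:
            r = truth.sweep_regions[0]
            region = f"{r['chrom']}:{r['start_bp']}-{r['end_bp']}"
        if region is None:
            raise SweepkitError("hapshare stage needs a region (chrom:start-end)")
        chrom, span = region.split(":")
        start, end = (float(x) for x in span.split("-"))
        iv = io.Interval(chrom, start, end, unit="bp")
        if hp.get("peak") is not None:
            sites = haplotypes.select_linked_snps(
                gm, int(hp["peak"]), iv, r2_min=hp.get("r2_min", 0.6))
        else:
            sites = haplotypes.select_region_snps(gm, iv,
                                                  n_snps=hp.get("n_snps", 100))
        pops = hp.get("populations") or gm.population_labels
        shares = haplotypes.sharing_matrix(gm, sites, pops)
        df = pd.DataFrame([(s.pop_pair[0], s.pop_pair[1], s.shared_count,
                            s.union_count, s.ratio) for s in shares],
                          columns=["pop_a", "pop_b", "shared", "total", "ratio"])
        df.to_csv(out / "hapshare.tsv", sep="\t", index=False, float_format="%.6g")
        register("hapshare", out / "hapshare.tsv")
        results["hapshare"] = {"region": region, "n_sites": len(sites)}

    # ----- overlap test ----------------------------------------------------
    if "overlap" in config.stages:
        if gmap is None:
            raise SweepkitError("overlap stage requires a genetic map")
        op = p.get("overlap", {})
        if op.get("top_fraction") and gm is not None and "hetscan" in config.stages:
            # re-call signatures at the (stricter) overlap-test tail
            hp = p.get("hetscan", {})
            wild = hp.get("wild_pop", "wild")
            cult = hp.get("cultivated_pops") or [l for l in gm.population_labels
                                                 if l != wild]
            ws = scan.het_ratio_scan(gm, wild, cult,
                                     window_sites=hp.get("window_sites", 500))
            _, sel = scan.top_percentile_regions(ws, top_fraction=op["top_fraction"])
        else:
            sel = selection_intervals
        if config.inputs.get("qtl_bed"):
            qtl_intervals = io.read_intervals(config.inputs["qtl_bed"], unit="bp")
        elif truth is not None:
            qtl_intervals = simulate_intervals(
                truth,
                n_qtl=op.get("n_qtl", 12),
                fraction_overlapping_sweeps=op.get("fraction_overlapping_sweeps", 0.0),
                seed=config.stage_seed("overlap"),
                width_cM=op.get("qtl_width_cm", 30.0))
        io.write_bed(qtl_intervals, out / "qtl_intervals.bed")
        register("qtl_intervals", out / "qtl_intervals.bed")
        bins = intervals.make_bins(gmap, width_cM=op.get("bin_cm", 30.0))
        counts = intervals.count_overlap(bins, sel, qtl_intervals, gmap)
        pval = intervals.hypergeom_overlap_p(counts)
        pd.DataFrame([{"n": counts.n, "l": counts.l, "s": counts.s,
                       "m": counts.m, "p": pval}]).to_csv(
            out / "overlap_test.tsv", sep="\t", index=False, float_format="%.6g")
        register("overlap_test", out / "overlap_test.tsv")
        log.info("overlap: n=%d l=%d s=%d m=%d p=%.3g",
                 counts.n, counts.l, counts.s, counts.m, pval)
        results["overlap"] = {"n": counts.n, "l": counts.l, "s": counts.s,
                              "m": counts.m, "p": pval}

    # ----- significance thresholds ----------------------------------------
    if "thresholds" in config.stages:
        tp = p.get("thresholds", {})
        alpha = tp.get("alpha", 0.05)
        rows = []
        if gm is not None:
            rows.append(("bonferroni", alpha, gm.n_sites,
                         thresholds.bonferroni(alpha, gm.n_sites)))
        if tp.get("n_tests"):
            rows.append(("bonferroni", alpha, tp["n_tests"],
                         thresholds.bonferroni(alpha, tp["n_tests"])))
        genome_bp = tp.get("genome_size_bp")
        ld_bp = tp.get("ld_extent_bp")
        if genome_bp and not ld_bp and gm is not None:
            decay = scan.ld_decay_extent(gm,
                                         bin_bp=tp.get("ld_bin_bp", 10_000),
                                         max_distance_bp=tp.get("ld_horizon_bp", 1_000_000))
            ld_bp = decay.extent_bp if decay.reached_background else None
            results.setdefault("thresholds", {})["ld_extent_bp"] = decay.extent_bp
        if genome_bp and ld_bp:
            n_eff = thresholds.effective_tests(genome_bp, ld_bp)
            rows.append(("ld_adjusted", alpha, n_eff,
                         thresholds.ld_adjusted_threshold(alpha, genome_bp, ld_bp)))
        pd.DataFrame(rows, columns=["method", "alpha", "n_tests", "threshold"]
                     ).to_csv(out / "thresholds.tsv", sep="\t", index=False,
                              float_format="%.6g")
        register("thresholds", out / "thresholds.tsv")

    # ----- seed-color phenotyping -----------------------------------------
    if "color" in config.stages:
        cp = p.get("color", {})
        if config.inputs.get("seed_colors"):
            seed_df = pd.read_csv(config.inputs["seed_colors"], sep="\t")
        else:
            palette = [tuple(c) for c in cp.get(
                "palette", [(150, 40, 27), (222, 184, 135), (255, 255, 240)])]
            seed_df, _ = simulate_seed_colors(
                n_genotypes=cp.get("n_genotypes", 50),
                palette_spec=palette,
                noise_sd=cp.get("noise_sd", 5.0),
                seed=config.stage_seed("color"))
            seed_df.to_csv(out / "seed_colors.tsv", sep="\t", index=False)
            register("seed_colors", out / "seed_colors.tsv")
        pheno = color.phenotype_table(seed_df)
        pheno.to_csv(out / "color_phenotypes.tsv", sep="\t", index=False,
                     float_format="%.6g")
        register("color_phenotypes", out / "color_phenotypes.tsv")

    manifest = {
        "sweepkit_version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "params": config.params,
        "inputs": {k: str(v) for k, v in config.inputs.items()},
        "input_checksums": {k: _sha256(Path(v)) for k, v in config.inputs.items()
                            if Path(str(v)).is_file()},
        "outputs": outputs,
        "output_checksums": {k: _sha256(out / v) for k, v in outputs.items()},
        "results": results,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
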