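"""Synthetic genotype, map, interval and seed-color generation with truth.

The generator emulates the structure of a crop diversity panel: a small,
relatively diverse wild progenitor population plus several cultivated races
with configurable pairwise differentiation, high inbreeding (mostly homozygous
genotypes), haplotype-block LD with a tunable length scale, and planted
low-diversity sweep regions in chosen cultivated populations.  Every planted
signal is recorded in a :class:`SimTruth` so downstream statistics can be
checked against ground truth.

Model
-----
* Ancestral allele frequencies p ~ Beta(0.8, 0.8) truncated to [0.05, 0.95].
* Population frequencies follow the Balding-Nichols model,
  q ~ Beta(p(1-F)/F, (1-p)(1-F)/F), giving each population an expected
  divergence F from the ancestor and expected pairwise Hudson F_ST of
  (F_a + F_b)/2 between populations.
* LD: per population and chromosome, ``n_founders`` founder haplotypes are
  drawn from q; each individual haplotype copies one founder per LD block of
  ``block_length_bp``, independently across blocks, so correlation decays to
  zero at the block scale.  ``n_founders=None`` disables the founder pool
  (haplotypes drawn i.i.d. from q, linkage equilibrium) — founder sampling is
  extra drift and would bias F_ST recovery experiments upward.
* Inbreeding: with probability ``selfing_rate`` an individual's two genome
  copies are identical (fully homozygous), else independent.
* Sweeps: inside the swept interval, each haplotype copy of a designated
  population is replaced by the swept haplotype with probability
  1 - diversity_retention.  Sweep specs sharing a ``haplotype_id`` (and
  chromosome) share the swept haplotype — the machinery for shared versus
  convergent (independent) domestication events.

Defaults mirror the sorghum panel the package targets: wild n = 31 plus five
cultivated races of 94 samples each, selfing 0.95, ten chromosomes of 73 Mb /
77 cM, 150 kb LD blocks, no missing data (an imputed SNP set).  SNP density is
scaled to desk size (2,000 sites per chromosome).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .io import MISSING, GeneticMap, GenotypeMatrix, Interval


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationSpec:
    """One simulated population: label, size, Balding-Nichols divergence F
    from the common ancestor, and selfing (inbreeding) probability."""

    label: str
    n_samples: int
    f_divergence: float
    selfing_rate: float = 0.95

    def __post_init__(self) -> None:
        if not (0.0 < self.f_divergence < 1.0):
            raise ValueError("f_divergence must be in (0, 1)")
        if not (0.0 <= self.selfing_rate <= 1.0):
            raise ValueError("selfing_rate must be in [0, 1]")


@dataclass(frozen=True)
class SweepSpec:
    """A planted sweep: populations carrying it, the bp interval, the
    diversity retained (0 = complete fixation), and the swept haplotype
    identity (same id + chrom = same haplotype across specs)."""

    populations: tuple[str, ...]
    chrom: str
    start_bp: int
    end_bp: int
    diversity_retention: float
    haplotype_id: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.diversity_retention <= 1.0):
            raise ValueError("diversity_retention must be in [0, 1]")
        if self.start_bp >= self.end_bp:
            raise ValueError("sweep interval empty")


def _default_populations() -> tuple[PopulationSpec, ...]:
    # Race divergences chosen so expected wild-race pairwise F_ST matches the
    # panel's observed ladder (0.04 .. 0.33) under F_pair = (F_a + F_b) / 2.
    return (
        PopulationSpec("wild", 31, 0.02),
        PopulationSpec("bicolor", 94, 0.06),
        PopulationSpec("guinea", 94, 0.20),
        PopulationSpec("caudatum", 94, 0.26),
        PopulationSpec("durra", 94, 0.38),
        PopulationSpec("kafir", 94, 0.64),
    )


@dataclass(frozen=True)
class SimConfig:
    """Full generator configuration; all randomness derives from ``seed``."""

    n_chromosomes: int = 10
    sites_per_chromosome: int = 2_000
    chrom_length_bp: int = 73_000_000
    chrom_length_cM: float = 77.0
    populations: tuple[PopulationSpec, ...] = field(default_factory=_default_populations)
    block_length_bp: int = 150_000
    n_founders: int | None = 8
    sweeps: tuple[SweepSpec, ...] = ()
    missing_rate: float = 0.0
    map_markers_per_chromosome: int = 11
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        labels = {p.label for p in self.populations}
        for sw in self.sweeps:
            unknown = set(sw.populations) - labels
            if unknown:
                raise ValueError(f"sweep names unknown population(s) {unknown}")
            if sw.end_bp > self.chrom_length_bp:
                raise ValueError("sweep interval beyond chromosome end")
        if self.sites_per_chromosome > self.chrom_length_bp:
            raise ValueError("more sites than base pairs")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "populations" in d:
            d["populations"] = tuple(PopulationSpec(**p) for p in d["populations"])
        if "sweeps" in d:
            d["sweeps"] = tuple(
                SweepSpec(**{**s, "populations": tuple(s["populations"])})
                for s in d["sweeps"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["populations"] = [asdict(p) for p in self.populations]
        d["sweeps"] = [asdict(s) for s in self.sweeps]
        return d


@dataclass
class SimTruth:
    """Everything needed to recompute each planted signal."""

    seed: int
    chrom_names: list[str]
    chrom_length_bp: int
    chrom_length_cM: float
    positions: dict[str, np.ndarray]          # per-chromosome 1-based bp
    ancestral_freq: np.ndarray                # per site, concatenated
    pop_freqs: dict[str, np.ndarray]          # label -> per-site frequency
    sweep_regions: list[dict]                 # chrom, bp range, site range, ...
    founders: dict[str, np.ndarray] | None    # label -> (K, n_sites) alleles
    swept_haplotypes: dict[tuple[str, int], np.ndarray]


# ---------------------------------------------------------------------------
# genotype simulation
# ---------------------------------------------------------------------------

def _truncated_beta(rng: np.random.Generator, a: float, b: float, n: int,
                    lo: float, hi: float) -> np.ndarray:
    out = rng.beta(a, b, size=n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.beta(a, b, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def simulate(config: SimConfig) -> tuple[GenotypeMatrix, GeneticMap, SimTruth]:
    """Generate a genotype matrix, a uniform genetic map and the truth record."""
    rng = np.random.default_rng(config.seed)
    chrom_names = [f"Chr{i + 1:02d}" for i in range(config.n_chromosomes)]
    spacing = config.chrom_length_bp // (config.sites_per_chromosome + 1)
    pos_one = (np.arange(1, config.sites_per_chromosome + 1) * spacing).astype(np.int64)
    positions = {c: pos_one.copy() for c in chrom_names}
    n_sites = config.n_chromosomes * config.sites_per_chromosome
    site_chrom = np.repeat(np.array(chrom_names, dtype=object),
                           config.sites_per_chromosome)
    site_pos = np.tile(pos_one, config.n_chromosomes)

    p_anc = _truncated_beta(rng, 0.8, 0.8, n_sites, 0.05, 0.95)

    # swept haplotypes, one per distinct (chrom, haplotype_id), drawn from the
    # ancestral frequencies over that chromosome's sites
    swept: dict[tuple[str, int], np.ndarray] = {}
    for key in sorted({(sw.chrom, sw.haplotype_id) for sw in config.sweeps}):
        chrom, _hid = key
        sel = site_chrom == chrom
        swept[key] = rng.binomial(1, p_anc[sel]).astype(np.int8)

    # Balding-Nichols population frequencies
    pop_freqs: dict[str, np.ndarray] = {}
    for spec in config.populations:
        f = spec.f_divergence
        a = p_anc * (1.0 - f) / f
        b = (1.0 - p_anc) * (1.0 - f) / f
        q = rng.beta(a, b)
        pop_freqs[spec.label] = np.clip(q, 0.0, 1.0)

    # per-site LD block index within chromosome
    block_of_site = ((pos_one - 1) // config.block_length_bp).astype(np.intp)
    n_blocks = int(block_of_site.max()) + 1

    sample_ids: list[str] = []
    populations: dict[str, str] = {}
    dosage_rows: list[np.ndarray] = []
    founders_out: dict[str, np.ndarray] | None = {} if config.n_founders else None

    sweep_regions: list[dict] = []
    for k, sw in enumerate(config.sweeps):
        ci = chrom_names.index(sw.chrom)
        local = np.flatnonzero((pos_one - 1 >= sw.start_bp) & (pos_one - 1 < sw.end_bp))
        sweep_regions.append({
            "index": k, "chrom": sw.chrom,
            "start_bp": sw.start_bp, "end_bp": sw.end_bp,
            "site_start": int(ci * config.sites_per_chromosome + local[0]) if len(local) else -1,
            "site_stop": int(ci * config.sites_per_chromosome + local[-1] + 1) if len(local) else -1,
            "local_sites": local,
            "populations": sw.populations,
            "haplotype_id": sw.haplotype_id,
            "diversity_retention": sw.diversity_retention,
        })

    for spec in config.populations:
        q = pop_freqs[spec.label]
        n = spec.n_samples
        hap = np.empty((2, n, n_sites), dtype=np.int8)
        if config.n_founders:
            k_f = config.n_founders
            pop_founders = np.empty((k_f, n_sites), dtype=np.int8)
            for ci, chrom in enumerate(chrom_names):
                s0 = ci * config.sites_per_chromosome
                s1 = s0 + config.sites_per_chromosome
                pop_founders[:, s0:s1] = rng.binomial(
                    1, q[s0:s1], size=(k_f, config.sites_per_chromosome))
                for copy in range(2):
                    f_idx = rng.integers(0, k_f, size=(n, n_blocks))
                    expand = f_idx[:, block_of_site]
                    hap[copy, :, s0:s1] = pop_founders[
                        expand, np.arange(config.sites_per_chromosome)[None, :]]
            if founders_out is not None:
                founders_out[spec.label] = pop_founders
        else:
            for copy in range(2):
                hap[copy] = rng.binomial(1, q, size=(n, n_sites)).astype(np.int8)

        # planted sweeps: replace each haplotype copy's swept segment
        for reg in sweep_regions:
            if spec.label not in reg["populations"] or reg["site_start"] < 0:
                continue
            ci = chrom_names.index(reg["chrom"])
            s0 = ci * config.sites_per_chromosome
            local = reg["local_sites"]
            seg = swept[(reg["chrom"], reg["haplotype_id"])][local]
            cols = s0 + local
            for copy in range(2):
                carry = rng.random(n) < (1.0 - reg["diversity_retention"])
                hap[copy][np.ix_(carry, cols)] = seg[None, :]

        inbred = rng.random(n) < spec.selfing_rate
        hap[1, inbred] = hap[0, inbred]
        dosage = (hap[0].astype(np.int8) + hap[1].astype(np.int8))
        dosage_rows.append(dosage)
        for i in range(n):
            sid = f"{spec.label}_{i:03d}"
            sample_ids.append(sid)
            populations[sid] = spec.label

    dosage = np.concatenate(dosage_rows, axis=0)
    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = MISSING

    gm = GenotypeMatrix(
        sample_ids=sample_ids,
        populations=populations,
        chrom=site_chrom,
        pos_bp=site_pos,
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["C"] * n_sites, dtype=object),
        dosage=dosage,
    )
    gmap = _uniform_map(config, chrom_names)
    for reg in sweep_regions:
        reg.pop("local_sites")
    truth = SimTruth(
        seed=config.seed,
        chrom_names=chrom_names,
        chrom_length_bp=config.chrom_length_bp,
        chrom_length_cM=config.chrom_length_cM,
        positions=positions,
        ancestral_freq=p_anc,
        pop_freqs=pop_freqs,
        sweep_regions=sweep_regions,
        founders=founders_out,
        swept_haplotypes=swept,
    )
    return gm, gmap, truth


def _uniform_map(config: SimConfig, chrom_names: list[str]) -> GeneticMap:
    """Evenly spaced markers with a constant cM/bp rate per chromosome."""
    m = max(2, config.map_markers_per_chromosome)
    rows = []
    for chrom in chrom_names:
        bp = np.linspace(1, config.chrom_length_bp, m).astype(np.int64)
        cm = (bp - 1) / (config.chrom_length_bp - 1) * config.chrom_length_cM
        for k in range(m):
            rows.append((f"{chrom}_m{k:02d}", chrom, float(cm[k]), int(bp[k])))
    return GeneticMap(pd.DataFrame(rows, columns=["name", "chrom", "cM", "bp"]))


# ---------------------------------------------------------------------------
# QTL-like intervals
# ---------------------------------------------------------------------------

def simulate_intervals(truth: SimTruth,
                       n_qtl: int,
                       fraction_overlapping_sweeps: float,
                       seed: int,
                       width_cM: float = 30.0) -> list[Interval]:
    """QTL-like bp intervals; a fraction is placed over planted sweeps.

    Interval width defaults to 30 cM (the approximate size of a QTL likelihood
    interval), converted to bp via the uniform map rate.  Overlapping
    intervals are centred at a uniform point inside a randomly chosen sweep
    region; the remainder are uniform on the genome.  ``source`` records
    ``"sweep-overlap"`` or ``"random"``.
    """
    if not (0.0 <= fraction_overlapping_sweeps <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    width_bp = width_cM / truth.chrom_length_cM * truth.chrom_length_bp
    width_bp = min(width_bp, truth.chrom_length_bp)
    n_over = int(round(fraction_overlapping_sweeps * n_qtl))
    if n_over > 0 and not truth.sweep_regions:
        raise ValueError("no sweep regions in truth to overlap")
    out: list[Interval] = []
    for i in range(n_qtl):
        if i < n_over:
            reg = truth.sweep_regions[rng.integers(0, len(truth.sweep_regions))]
            center = rng.uniform(reg["start_bp"], reg["end_bp"])
            start = np.clip(center - width_bp / 2, 0, truth.chrom_length_bp - width_bp)
            out.append(Interval(reg["chrom"], float(start), float(start + width_bp),
                                unit="bp", trait="qtl", source="sweep-overlap"))
        else:
            chrom = truth.chrom_names[rng.integers(0, len(truth.chrom_names))]
            start = rng.uniform(0, truth.chrom_length_bp - width_bp)
            out.append(Interval(chrom, float(start), float(start + width_bp),
                                unit="bp", trait="qtl", source="random"))
    return out


# ---------------------------------------------------------------------------
# seed colors
# ---------------------------------------------------------------------------

def simulate_seed_colors(n_genotypes: int,
                         palette_spec: Sequence[tuple[int, int, int]],
                         noise_sd: float,
                         seed: int,
                         seeds_per_genotype: int = 5
                         ) -> tuple[pd.DataFrame, list[int]]:
    """Per-seed RGB table with Gaussian channel noise, clipped to [0, 255].

    Each genotype is assigned a palette color uniformly at random; the
    returned list of palette indices is the truth.  Output columns:
    genotype_id, seed_index, R, G, B.
    """
    if not palette_spec:
        raise ValueError("palette must be non-empty")
    rng = np.random.default_rng(seed)
    assignment = rng.integers(0, len(palette_spec), size=n_genotypes).tolist()
    rows = []
    for g in range(n_genotypes):
        base = np.asarray(palette_spec[assignment[g]], dtype=float)
        for s in range(seeds_per_genotype):
            noisy = base + rng.normal(0.0, noise_sd, size=3)
            rgb = np.clip(np.floor(noisy + 0.5), 0, 255).astype(int)
            rows.append((f"geno_{g:04d}", s, *rgb))
    df = pd.DataFrame(rows, columns=["genotype_id", "seed_index", "R", "G", "B"])
    return df, assignment
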