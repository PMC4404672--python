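"""Genotype, map and interval I/O.

Containers
----------
:class:`GenotypeMatrix`
    A samples x sites alt-allele dosage matrix (values 0/1/2, missing = -1)
    with per-site coordinates and a population label per sample.  This is the
    substrate of every statistic in the package.
:class:`GeneticMap`
    Markers with paired genetic (cM) and physical (bp) positions; drives
    genetic binning, interval anchoring and coordinate unification.
:class:`Interval`
    A trait-labelled genomic interval in either bp or cM units.

Conventions
-----------
Internal coordinates are 0-based half-open.  VCF I/O is 1-based (converted at
the boundary only), BED I/O is 0-based half-open.  Heterozygous calls are
valid dosage 1 everywhere; only the haplotype-sharing module restricts itself
to homozygotes.  Minor-allele frequency is computed from non-missing calls
(complete case per site).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, LabelingError

#: Sentinel for a missing genotype call in dosage matrices.
MISSING: int = -1


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Alt-allele dosage matrix with sample population labels.

    Attributes
    ----------
    sample_ids:
        Ordered sample identifiers (rows of ``dosage``).
    populations:
        Mapping sample_id -> population label; every sample has exactly one.
    chrom, pos_bp, ref, alt:
        Per-site arrays (columns of ``dosage``).  ``pos_bp`` is 1-based as in
        VCF and non-decreasing within each chromosome.
    dosage:
        ``(n_samples, n_sites)`` int8 array with values in {0, 1, 2, MISSING}.
    """

    sample_ids: list[str]
    populations: dict[str, str]
    chrom: np.ndarray
    pos_bp: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n_samples, n_sites = self.dosage.shape
        if n_samples != len(self.sample_ids):
            raise FormatError("dosage rows != number of samples")
        for arr, name in ((self.chrom, "chrom"), (self.pos_bp, "pos_bp"),
                          (self.ref, "ref"), (self.alt, "alt")):
            if len(arr) != n_sites:
                raise FormatError(f"{name} length != number of sites")
        missing_labels = [s for s in self.sample_ids if s not in self.populations]
        if missing_labels:
            raise LabelingError(f"samples without population label: {missing_labels[:5]}")
        valid = np.isin(self.dosage, (0, 1, 2, MISSING))
        if not valid.all():
            raise FormatError("dosage values outside {0, 1, 2, MISSING}")
        # positions non-decreasing within chromosome; ties allowed only for
        # split multiallelic records (same position, different alt)
        for c in self.chromosomes:
            idx = np.flatnonzero(self.chrom == c)
            pos = self.pos_bp[idx]
            if np.any(np.diff(pos) < 0):
                bad = idx[1:][np.diff(pos) < 0][0]
                raise FormatError(
                    f"unsorted positions on {c} near {self.pos_bp[bad]}")
            keys = list(zip(pos.tolist(), self.alt[idx].tolist()))
            if len(set(keys)) != len(keys):
                raise FormatError(f"duplicate (pos, alt) site on {c}")

    # -- views --------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosage.shape[1]

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    @property
    def population_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.populations[s], None)
        return list(seen)

    def sample_indices(self, population: str | Iterable[str]) -> np.ndarray:
        """Row indices of the samples belonging to one or more populations."""
        pops = {population} if isinstance(population, str) else set(population)
        unknown = pops - set(self.populations.values())
        if unknown:
            raise LabelingError(f"unknown population(s): {sorted(unknown)}")
        return np.array([i for i, s in enumerate(self.sample_ids)
                         if self.populations[s] in pops], dtype=np.intp)

    def take_sites(self, site_idx: np.ndarray | Sequence[int]) -> "GenotypeMatrix":
        """New matrix restricted to the given site indices (order preserved)."""
        site_idx = np.asarray(site_idx, dtype=np.intp)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            populations=dict(self.populations),
            chrom=self.chrom[site_idx],
            pos_bp=self.pos_bp[site_idx],
            ref=self.ref[site_idx],
            alt=self.alt[site_idx],
            dosage=self.dosage[:, site_idx],
        )

    def sites_in(self, chrom: str, start_bp: float, end_bp: float) -> np.ndarray:
        """Site indices with ``chrom`` and ``start_bp <= pos-1 < end_bp``
        (0-based half-open query against 1-based positions)."""
        zero_based = self.pos_bp - 1
        mask = (self.chrom == chrom) & (zero_based >= start_bp) & (zero_based < end_bp)
        return np.flatnonzero(mask)


@dataclass
class GeneticMap:
    """Markers with paired genetic (cM) and physical (bp) positions.

    ``bp`` may be NaN for markers that lack a physical alignment; such markers
    participate in genetic binning but are skipped when anchoring.  Within a
    chromosome cM must be non-decreasing and the mapped (non-NaN) bp strictly
    increasing, with >= 2 markers per chromosome.
    """

    markers: pd.DataFrame  # columns: name, chrom, cM, bp

    def __post_init__(self) -> None:
        required = ["name", "chrom", "cM", "bp"]
        if list(self.markers.columns[:4]) != required:
            self.markers = self.markers.rename(
                columns=dict(zip(self.markers.columns[:4], required)))
        self.markers = self.markers.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        for c, grp in self.markers.groupby("chrom", sort=False):
            if len(grp) < 2:
                raise FormatError(f"chromosome {c} has < 2 map markers")
            if np.any(np.diff(grp["cM"].to_numpy(float)) < 0):
                bad = grp["name"].iloc[int(np.argmax(np.diff(grp["cM"].to_numpy(float)) < 0)) + 1]
                raise FormatError(f"cM not non-decreasing on {c} at marker {bad}")
            bp = grp["bp"].to_numpy(float)
            mapped = bp[~np.isnan(bp)]
            if np.any(np.diff(mapped) <= 0):
                bad = grp.loc[~np.isnan(bp), "name"].iloc[
                    int(np.argmax(np.diff(mapped) <= 0)) + 1]
                raise FormatError(f"bp not strictly increasing on {c} at marker {bad}")

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.markers["chrom"]:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_markers(self, chrom: str, mapped_only: bool = False) -> pd.DataFrame:
        grp = self.markers[self.markers["chrom"] == chrom]
        if grp.empty:
            raise FormatError(f"chromosome {chrom} not in map")
        if mapped_only:
            grp = grp[~grp["bp"].isna()]
        return grp

    def cm_range(self, chrom: str) -> tuple[float, float]:
        cm = self.chrom_markers(chrom)["cM"]
        return float(cm.min()), float(cm.max())


@dataclass(frozen=True)
class Interval:
    """A genomic interval, 0-based half-open, in bp or cM units."""

    chrom: str
    start: float
    end: float
    unit: str = "bp"
    trait: str = ""
    source: str = ""
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(f"interval start > end: {self}")
        if self.unit not in ("bp", "cM"):
            raise FormatError(f"unknown interval unit {self.unit!r}")

    @property
    def length(self) -> float:
        return self.end - self.start


# ---------------------------------------------------------------------------
# genotype readers / writers
# ---------------------------------------------------------------------------

def read_pop_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (sample_id, population) into a dict."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[1] < 2:
        raise FormatError("population labels file needs >= 2 columns")
    first = df.columns[:2]
    return dict(zip(df[first[0]], df[first[1]]))


def _check_labels(sample_ids: Sequence[str], labels: Mapping[str, str]) -> dict[str, str]:
    unknown = set(labels) - set(sample_ids)
    if unknown:
        raise LabelingError(f"labels for unknown sample(s): {sorted(unknown)[:5]}")
    missing = [s for s in sample_ids if s not in labels]
    if missing:
        raise LabelingError(f"no population label for sample(s): {missing[:5]}")
    return {s: labels[s] for s in sample_ids}


def read_genotypes(path: str | Path,
                   format: str | None = None,
                   pop_labels: str | Path | Mapping[str, str] | None = None,
                   multiallelic: str = "reject") -> GenotypeMatrix:
    """Read a genotype matrix from VCF or dosage TSV.

    Parameters
    ----------
    format:
        ``"vcf"`` or ``"dosage_tsv"``; inferred from the file extension when
        omitted.
    pop_labels:
        Path to a (sample_id, population) TSV, or a mapping.  Must cover every
        sample in the genotype file.
    multiallelic:
        ``"reject"`` (default) raises on multiallelic VCF records; ``"split"``
        expands each alternate allele into its own biallelic site (calls
        carrying a different alternate become missing at that site).
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix in (".vcf", ".gz", ".bcf") else "dosage_tsv"
    if format == "vcf":
        gm = _read_vcf(path, multiallelic=multiallelic)
    elif format == "dosage_tsv":
        gm = _read_dosage_tsv(path)
    else:
        raise FormatError(f"unknown genotype format {format!r}")
    if pop_labels is not None:
        labels = (pop_labels if isinstance(pop_labels, Mapping)
                  else read_pop_labels(pop_labels))
        gm.populations = _check_labels(gm.sample_ids, labels)
    return gm


def _read_vcf(path: Path, multiallelic: str = "reject") -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    sample_ids = list(vcf.samples)
    chrom: list[str] = []
    pos: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    dosage_cols: list[np.ndarray] = []
    for v in vcf:
        alts = [a for a in v.ALT if a != "<NON_REF>"]
        if len(alts) == 0:
            continue
        if len(alts) > 1 and multiallelic == "reject":
            raise FormatError(
                f"multiallelic record at {v.CHROM}:{v.POS} (use multiallelic='split')")
        gt = np.array([g[:2] for g in v.genotypes], dtype=np.int16)
        for k, a in enumerate(alts, start=1):
            col = np.full(len(sample_ids), MISSING, dtype=np.int8)
            called = np.all(gt >= 0, axis=1)  # half-calls -> MISSING
            # alleles other than ref/this alt make the call missing for this split
            usable = called & np.all((gt == 0) | (gt == k), axis=1)
            col[usable] = (gt[usable] == k).sum(axis=1).astype(np.int8)
            chrom.append(v.CHROM)
            pos.append(v.POS)
            ref.append(v.REF)
            alt.append(a)
            dosage_cols.append(col)
    vcf.close()
    dosage = (np.stack(dosage_cols, axis=1) if dosage_cols
              else np.zeros((len(sample_ids), 0), dtype=np.int8))
    return GenotypeMatrix(
        sample_ids=sample_ids,
        populations={s: "unassigned" for s in sample_ids},
        chrom=np.array(chrom, dtype=object),
        pos_bp=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        dosage=dosage,
    )


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix as a minimal VCF 4.2 with GT-only genotype fields."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in gm.chromosomes:
            length = int(gm.pos_bp[gm.chrom == c].max()) + 1
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j in range(gm.n_sites):
            calls = "\t".join(gt_code[int(d)] for d in gm.dosage[:, j])
            fh.write(f"{gm.chrom[j]}\t{gm.pos_bp[j]}\t.\t{gm.ref[j]}\t{gm.alt[j]}"
                     f"\t.\t.\t.\tGT\t{calls}\n")


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    fixed = ["chrom", "pos", "ref", "alt"]
    if list(df.columns[:4]) != fixed:
        raise FormatError(f"dosage TSV must start with columns {fixed}")
    sample_ids = list(df.columns[4:])
    dos = df[sample_ids].to_numpy(dtype=float).T
    dos = np.where(np.isnan(dos), MISSING, dos).astype(np.int8)
    return GenotypeMatrix(
        sample_ids=sample_ids,
        populations={s: "unassigned" for s in sample_ids},
        chrom=df["chrom"].to_numpy(dtype=object),
        pos_bp=df["pos"].to_numpy(dtype=np.int64),
        ref=df["ref"].to_numpy(dtype=object),
        alt=df["alt"].to_numpy(dtype=object),
        dosage=dos,
    )


def write_dosage_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix as the package's dosage TSV dialect (NA = missing)."""
    cols = {"chrom": gm.chrom, "pos": gm.pos_bp, "ref": gm.ref, "alt": gm.alt}
    dos = gm.dosage.astype(float)
    dos[dos == MISSING] = np.nan
    df = pd.concat([pd.DataFrame(cols),
                    pd.DataFrame(dos.T, columns=gm.sample_ids)], axis=1)
    df.to_csv(path, sep="\t", index=False, float_format="%g", na_rep="NA")


def write_pop_labels(gm: GenotypeMatrix, path: str | Path) -> None:
    pd.DataFrame({"sample_id": gm.sample_ids,
                  "population": [gm.populations[s] for s in gm.sample_ids]}
                 ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# site filtering
# ---------------------------------------------------------------------------

def filter_sites(gm: GenotypeMatrix,
                 max_missing_rate: float = 0.5,
                 min_maf: float = 0.02) -> GenotypeMatrix:
    """Keep informative sites: missing fraction <= ``max_missing_rate`` and
    minor-allele frequency (over non-missing calls) >= ``min_maf``.

    Idempotent; sample set and site order are unchanged.  An empty result is
    permitted (a warning is emitted).
    """
    if not (0 <= max_missing_rate <= 1):
        raise ValueError("max_missing_rate must be in [0, 1]")
    if not (0 <= min_maf <= 0.5):
        raise ValueError("min_maf must be in [0, 0.5]")
    called = gm.dosage != MISSING
    n_called = called.sum(axis=0)
    miss_rate = 1.0 - n_called / gm.n_samples
    with np.errstate(invalid="ignore"):
        p = np.where(called, gm.dosage, 0).sum(axis=0) / np.maximum(2 * n_called, 1)
    maf = np.minimum(p, 1.0 - p)
    keep = (miss_rate <= max_missing_rate) & (maf >= min_maf) & (n_called > 0)
    if not keep.any():
        warnings.warn("filter_sites removed every site", stacklevel=2)
    return gm.take_sites(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# maps and intervals
# ---------------------------------------------------------------------------

def read_map(path: str | Path) -> GeneticMap:
    """Read a genetic map TSV with columns (name, chrom, cM, bp)."""
    df = pd.read_csv(path, sep="\t", dtype={"name": str, "chrom": str})
    if not {"name", "chrom", "cM", "bp"}.issubset(df.columns):
        raise FormatError("map file needs columns name, chrom, cM, bp")
    return GeneticMap(df[["name", "chrom", "cM", "bp"]].copy())


def write_map(gmap: GeneticMap, path: str | Path) -> None:
    gmap.markers.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_intervals(path: str | Path, unit: str = "bp") -> list[Interval]:
    """Read intervals from BED3+ (bp, 0-based half-open) or a cM TSV
    (chrom, start, end[, trait[, source]])."""
    rows: list[Interval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if parts[0] == "chrom":  # header row in the cM TSV dialect
                continue
            if len(parts) < 3:
                raise FormatError(f"interval line with < 3 columns: {line!r}")
            trait = parts[3] if len(parts) > 3 else ""
            source = parts[4] if len(parts) > 4 else ""
            rows.append(Interval(chrom=parts[0], start=float(parts[1]),
                                 end=float(parts[2]), unit=unit,
                                 trait=trait, source=source))
    return rows


def write_bed(intervals: Sequence[Interval], path: str | Path) -> None:
    """Write bp intervals as BED (0-based half-open); the trait goes in the
    name column and, when present, the score in column 5."""
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.unit != "bp":
                raise FormatError("write_bed requires bp intervals")
            fields = [iv.chrom, str(int(iv.start)), str(int(iv.end))]
            if iv.trait or iv.score is not None:
                fields.append(iv.trait or ".")
            if iv.score is not None:
                fields.append(f"{iv.score:.6g}")
            fh.write("\t".join(fields) + "\n")


def write_intervals_cm(intervals: Sequence[Interval], path: str | Path) -> None:
    """Write cM intervals as the package's 3+ column TSV dialect."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\ttrait\tsource\n")
        for iv in intervals:
            if iv.unit != "cM":
                raise FormatError("write_intervals_cm requires cM intervals")
            fh.write(f"{iv.chrom}\t{iv.start:.6g}\t{iv.end:.6g}\t{iv.trait}\t{iv.source}\n")
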