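"""Diversity scans, F_ST and linkage disequilibrium.

The selection-signature statistic is the ratio of wild to cultivated expected
heterozygosity, H_w/H_c, averaged in non-overlapping windows of a fixed number
of consecutive SNPs (500 by default).  Domestication strips diversity from the
cultivated gene pool around selected loci, so windows with elevated H_w/H_c
mark candidate sweeps; the top tail (5% genome-wide for display, 1% for
overlap testing) is called as the signature set.

Window ratios are computed as the ratio of window means (Hw_mean / Hc_mean),
not the mean of per-site ratios, which would be undefined wherever a site is
fixed in the cultivated pool.  Windows whose cultivated mean is exactly zero
are flagged infinite and rank above every finite ratio — total diversity loss
is the strongest possible sweep signal.

F_ST uses Hudson's estimator (ratio of sums of per-site numerator and
denominator), robust to unequal sample sizes; Weir & Cockerham's theta is
available as a secondary estimator.  LD is composite r²: squared Pearson
correlation of unphased dosage vectors over pairwise-complete samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (EstimationError, UndefinedPairError,
                         UndefinedSiteError)
from .io import MISSING, GenotypeMatrix, Interval


# ---------------------------------------------------------------------------
# per-site frequencies and expected heterozygosity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteFrequency:
    """Alternate-allele frequency at one site; undefined when n_called = 0."""

    p_alt: float
    n_called: int


def site_frequencies(gm: GenotypeMatrix,
                     sample_idx: np.ndarray | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per-site alt-allele frequency and called-sample count.

    Frequencies are complete-case: computed from non-missing calls only.
    Sites with no called sample get frequency NaN.
    """
    dos = gm.dosage if sample_idx is None else gm.dosage[sample_idx]
    called = dos != MISSING
    n_called = called.sum(axis=0)
    alt_sum = np.where(called, dos, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, alt_sum / (2.0 * np.maximum(n_called, 1)), np.nan)
    return p, n_called


def expected_het(freq: SiteFrequency | float | np.ndarray) -> float | np.ndarray:
    """Expected heterozygosity 2p(1-p) of a biallelic site.

    Accepts a :class:`SiteFrequency`, a frequency, or an array of frequencies.
    """
    if isinstance(freq, SiteFrequency):
        if freq.n_called == 0:
            raise UndefinedSiteError("expected_het undefined with n_called = 0")
        p = freq.p_alt
    else:
        p = freq
    return 2.0 * np.asarray(p) * (1.0 - np.asarray(p)) if isinstance(p, np.ndarray) \
        else 2.0 * p * (1.0 - p)


# ---------------------------------------------------------------------------
# windowed H_w / H_c scan
# ---------------------------------------------------------------------------

@dataclass
class WindowScan:
    """Windowed wild/cultivated heterozygosity scan.

    ``windows`` columns: chrom, start_bp, end_bp (0-based half-open),
    first_site_index, n_sites, Hw_mean, Hc_mean, ratio (np.inf when
    Hc_mean = 0).  ``cutoff_value`` is set by :func:`top_percentile_regions`.
    """

    windows: pd.DataFrame
    window_sites: int
    cutoff_value: float | None = None

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def to_tsv(self, path) -> None:
        out = self.windows.copy()
        out["flag"] = np.where(np.isinf(out["ratio"]), "inf", ".")
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def het_ratio_scan(gm: GenotypeMatrix,
                   wild_pop: str,
                   cultivated_pops: str | Iterable[str],
                   window_sites: int = 500) -> WindowScan:
    """Windowed H_w/H_c ratio over consecutive non-overlapping SNP windows.

    Per chromosome, sites are tiled into windows of exactly ``window_sites``
    consecutive SNPs; the trailing remainder is dropped.  Window means are
    taken over the sites called in the respective group (wild / pooled
    cultivated).
    """
    wild_idx = gm.sample_indices(wild_pop)
    cult_idx = gm.sample_indices(cultivated_pops)
    if len(wild_idx) == 0 or len(cult_idx) == 0:
        raise EstimationError("both population groups must be non-empty")
    p_w, n_w = site_frequencies(gm, wild_idx)
    p_c, n_c = site_frequencies(gm, cult_idx)
    hw = np.where(n_w > 0, 2.0 * p_w * (1.0 - p_w), np.nan)
    hc = np.where(n_c > 0, 2.0 * p_c * (1.0 - p_c), np.nan)

    rows = []
    for chrom in gm.chromosomes:
        idx = np.flatnonzero(gm.chrom == chrom)
        for k in range(len(idx) // window_sites):
            win = idx[k * window_sites:(k + 1) * window_sites]
            hw_mean = float(np.nanmean(hw[win])) if np.any(~np.isnan(hw[win])) else np.nan
            hc_mean = float(np.nanmean(hc[win])) if np.any(~np.isnan(hc[win])) else np.nan
            if np.isnan(hw_mean) or np.isnan(hc_mean):
                ratio = np.nan
            elif hc_mean == 0.0:
                ratio = np.inf
            else:
                ratio = hw_mean / hc_mean
            rows.append((chrom, int(gm.pos_bp[win[0]]) - 1, int(gm.pos_bp[win[-1]]),
                         int(win[0]), window_sites, hw_mean, hc_mean, ratio))
    if not rows:
        raise EstimationError(
            f"no chromosome has >= {window_sites} sites; scan is empty")
    windows = pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp",
                                          "first_site_index", "n_sites",
                                          "Hw_mean", "Hc_mean", "ratio"])
    return WindowScan(windows=windows, window_sites=window_sites)


def top_percentile_regions(scan: WindowScan,
                           top_fraction: float = 0.05
                           ) -> tuple[float, list[Interval]]:
    """Empirical top-tail cutoff and the qualifying windows as bp intervals.

    The cutoff is the k-th largest window ratio with k = max(1,
    ceil(top_fraction * n_windows)); windows with ratio >= cutoff qualify
    (ties kept).  Infinite-ratio windows count as largest.  Adjacent
    qualifying windows on a chromosome are merged into one interval whose
    score is the maximum member ratio.
    """
    ratios = scan.windows["ratio"].to_numpy(float)
    valid = ~np.isnan(ratios)
    if not valid.any():
        raise EstimationError("scan has no windows with defined ratio")
    n = int(valid.sum())
    k = max(1, int(np.ceil(top_fraction * n)))
    cutoff = float(np.sort(ratios[valid])[::-1][k - 1])
    scan.cutoff_value = cutoff
    qualify = valid & (ratios >= cutoff)

    intervals: list[Interval] = []
    win = scan.windows
    current: dict | None = None
    for i in range(len(win)):
        if not qualify[i]:
            if current is not None:
                intervals.append(Interval(**current, unit="bp", trait="selection"))
                current = None
            continue
        row = win.iloc[i]
        contiguous = (current is not None
                      and row["chrom"] == current["chrom"]
                      and i > 0 and qualify[i - 1]
                      and win.iloc[i - 1]["chrom"] == row["chrom"])
        if contiguous:
            current["end"] = float(row["end_bp"])
            current["score"] = max(current["score"], float(row["ratio"]))
        else:
            if current is not None:
                intervals.append(Interval(**current, unit="bp", trait="selection"))
            current = {"chrom": row["chrom"], "start": float(row["start_bp"]),
                       "end": float(row["end_bp"]), "score": float(row["ratio"])}
    if current is not None:
        intervals.append(Interval(**current, unit="bp", trait="selection"))
    return cutoff, intervals


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

def _hudson_components(p1, p2, n1, n2):
    """Hudson per-site numerator/denominator on allele frequencies with
    allele sample sizes n1, n2 (numbers of called allele copies)."""
    num = ((p1 - p2) ** 2
           - p1 * (1 - p1) / (n1 - 1)
           - p2 * (1 - p2) / (n2 - 1))
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def fst(gm: GenotypeMatrix,
        pop_a: str | Iterable[str],
        pop_b: str | Iterable[str],
        estimator: str = "hudson") -> float:
    """Pairwise F_ST between two populations (ratio of sums across sites).

    Sites where either population has fewer than 2 called allele copies are
    excluded.  Negative estimates are reported as computed, not truncated.
    ``estimator`` is ``"hudson"`` (default) or ``"wc"`` (Weir & Cockerham).
    """
    ia = gm.sample_indices(pop_a)
    ib = gm.sample_indices(pop_b)
    if estimator == "hudson":
        p1, nc1 = site_frequencies(gm, ia)
        p2, nc2 = site_frequencies(gm, ib)
        n1 = 2.0 * nc1
        n2 = 2.0 * nc2
        use = (n1 >= 2) & (n2 >= 2)
        if not use.any():
            raise EstimationError("no usable sites for F_ST")
        num, den = _hudson_components(p1[use], p2[use], n1[use], n2[use])
        total_den = float(np.sum(den))
        if total_den == 0.0:
            raise EstimationError("all usable sites monomorphic in both populations")
        return float(np.sum(num)) / total_den
    elif estimator == "wc":
        return _fst_weir_cockerham(gm, ia, ib)
    raise ValueError(f"unknown estimator {estimator!r}")


def _fst_weir_cockerham(gm: GenotypeMatrix, ia: np.ndarray, ib: np.ndarray) -> float:
    """Weir & Cockerham (1984) theta for two populations, ratio of sums."""
    r = 2
    num_sum = 0.0
    den_sum = 0.0
    dos_a, dos_b = gm.dosage[ia], gm.dosage[ib]
    for j in range(gm.n_sites):
        da = dos_a[:, j][dos_a[:, j] != MISSING]
        db = dos_b[:, j][dos_b[:, j] != MISSING]
        n_i = np.array([len(da), len(db)], dtype=float)
        if np.any(n_i < 2):
            continue
        p_i = np.array([da.mean() / 2.0, db.mean() / 2.0])
        h_i = np.array([(da == 1).mean(), (db == 1).mean()])
        n_bar = n_i.mean()
        nc = (r * n_bar - (n_i ** 2).sum() / (r * n_bar)) / (r - 1)
        p_bar = (n_i * p_i).sum() / (r * n_bar)
        s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum() / (r * n_bar)
        a = (n_bar / nc) * (s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2
                                  - h_bar / 4) / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar)
                                     - (r - 1) / r * s2
                                     - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
        c = h_bar / 2
        num_sum += a
        den_sum += a + b + c
    if den_sum == 0.0:
        raise EstimationError("no usable sites for F_ST")
    return num_sum / den_sum


def fst_matrix(gm: GenotypeMatrix,
               populations: Sequence[str] | None = None,
               estimator: str = "hudson") -> pd.DataFrame:
    """Symmetric F_ST matrix over population pairs (diagonal 0)."""
    pops = list(populations) if populations else gm.population_labels
    out = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            v = fst(gm, a, b, estimator=estimator)
            out.loc[a, b] = out.loc[b, a] = v
    return out


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

@dataclass
class LdResult:
    """Pairwise composite-LD table: site_i, site_j, distance_bp, r2.

    ``distance_bp`` is NaN for cross-chromosome pairs; ``r2`` is NaN when one
    of the sites is monomorphic over the pairwise-complete samples.
    """

    pairs: pd.DataFrame


def ld_r2(gm: GenotypeMatrix, site_i: int, site_j: int) -> float:
    """Composite LD: squared Pearson correlation of the two dosage vectors
    over samples called at both sites.  NaN when either vector is constant."""
    di = gm.dosage[:, site_i].astype(float)
    dj = gm.dosage[:, site_j].astype(float)
    ok = (di != MISSING) & (dj != MISSING)
    if ok.sum() < 2:
        raise UndefinedPairError(
            f"< 2 complete genotype pairs for sites {site_i}, {site_j}")
    x, y = di[ok], dj[ok]
    vx = x.var()
    vy = y.var()
    if vx == 0.0 or vy == 0.0:
        return float("nan")
    c = ((x - x.mean()) * (y - y.mean())).mean()
    return float(c * c / (vx * vy))


def ld_matrix(gm: GenotypeMatrix, sites: Sequence[int]) -> LdResult:
    """All-pairs composite r² over the given site indices."""
    sites = list(sites)
    rows = []
    for a in range(len(sites)):
        for b in range(a + 1, len(sites)):
            i, j = sites[a], sites[b]
            same = gm.chrom[i] == gm.chrom[j]
            dist = float(abs(int(gm.pos_bp[j]) - int(gm.pos_bp[i]))) if same else np.nan
            rows.append((i, j, dist, ld_r2(gm, i, j)))
    return LdResult(pairs=pd.DataFrame(
        rows, columns=["site_i", "site_j", "distance_bp", "r2"]))


@dataclass
class LdDecayResult:
    """Binned LD decay profile and the estimated decay extent."""

    extent_bp: float
    reached_background: bool
    bin_edges: np.ndarray
    bin_mean_r2: np.ndarray
    background_r2: float


def _pairwise_r2_binned(gm: GenotypeMatrix, max_distance_bp: int,
                        bin_bp: int) -> tuple[np.ndarray, np.ndarray]:
    """Sum of r² and pair count per distance bin, pooled over chromosomes."""
    n_bins = int(np.ceil(max_distance_bp / bin_bp))
    r2_sum = np.zeros(n_bins)
    n_pair = np.zeros(n_bins, dtype=np.int64)
    dos = gm.dosage.astype(np.float64)
    called = gm.dosage != MISSING
    for chrom in gm.chromosomes:
        idx = np.flatnonzero(gm.chrom == chrom)
        pos = gm.pos_bp[idx]
        D = dos[:, idx]
        C = called[:, idx]
        for a in range(len(idx)):
            hi = np.searchsorted(pos, pos[a] + max_distance_bp, side="right")
            js = np.arange(a + 1, hi)
            if len(js) == 0:
                continue
            ok = C[:, a][:, None] & C[:, js]
            cnt = ok.sum(axis=0).astype(float)
            usable = cnt >= 2
            if not usable.any():
                continue
            x = np.where(ok, D[:, a][:, None], 0.0)
            y = np.where(ok, D[:, js], 0.0)
            sx = x.sum(axis=0)
            sy = y.sum(axis=0)
            sxx = (x * x).sum(axis=0)
            syy = (y * y).sum(axis=0)
            sxy = (x * y).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                cov = sxy - sx * sy / cnt
                vx = sxx - sx * sx / cnt
                vy = syy - sy * sy / cnt
                r2 = cov * cov / (vx * vy)
            good = usable & (vx > 0) & (vy > 0)
            if not good.any():
                continue
            bins = ((pos[js[good]] - pos[a]) // bin_bp).astype(int)
            bins = np.minimum(bins, n_bins - 1)
            np.add.at(r2_sum, bins, r2[good])
            np.add.at(n_pair, bins, 1)
    return r2_sum, n_pair


def ld_decay_extent(gm: GenotypeMatrix,
                    background_r2: float = 0.1,
                    bin_bp: int = 10_000,
                    max_distance_bp: int = 1_000_000) -> LdDecayResult:
    """Distance at which mean pairwise r² decays to background.

    Pairwise r² within ``max_distance_bp`` is averaged in distance bins of
    ``bin_bp``; the extent is the left edge of the first non-empty bin whose
    mean drops below ``background_r2``.  If no bin does, the horizon is
    returned with ``reached_background=False``.
    """
    r2_sum, n_pair = _pairwise_r2_binned(gm, max_distance_bp, bin_bp)
    with np.errstate(invalid="ignore"):
        means = np.where(n_pair > 0, r2_sum / np.maximum(n_pair, 1), np.nan)
    edges = np.arange(len(means) + 1) * bin_bp
    for b in range(len(means)):
        if n_pair[b] > 0 and means[b] < background_r2:
            return LdDecayResult(float(edges[b]), True, edges, means, background_r2)
    return LdDecayResult(float(max_distance_bp), False, edges, means, background_r2)
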