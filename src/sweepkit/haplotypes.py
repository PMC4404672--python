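"""Two-locus haplotype sharing between populations.

Around a selected locus, each domesticated population carries one (or few)
swept haplotypes.  If two populations inherited the same sweep, the haplotype
types they carry at consecutive locus pairs largely coincide; if they swept
independently, they do not.  The statistic here is the pooled ratio of common
(shared) two-locus haplotype types to total (union) types over all consecutive
site pairs of a chosen SNP set — the SNP set being either the association peak
plus its r²-linked neighbours, or the first N sites of a region.

Because the populations are highly inbreeding, haplotypes are read directly
from individuals homozygous at both sites of a pair (no phasing); individuals
heterozygous or missing at either site are skipped for that pair only.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .exceptions import EstimationError
from .io import GenotypeMatrix, Interval
from .scan import ld_r2, site_frequencies

#: Two-locus haplotype alphabet: 0 = ref allele, 1 = alt allele.
Haplotype = tuple[int, int]


@dataclass
class HaplotypeProfile:
    """Per-population two-locus haplotype counts for consecutive site pairs.

    ``pair_haplotypes[k]`` counts the haplotype types observed between
    ``site_list[k]`` and ``site_list[k+1]``; only individuals homozygous and
    called at both sites contribute.  An empty counter is recorded (with a
    warning upstream) when no individual qualifies at a pair.
    """

    population: str
    site_list: list[int]
    pair_haplotypes: list[Counter]

    def __post_init__(self) -> None:
        if len(self.pair_haplotypes) != len(self.site_list) - 1:
            raise ValueError("pair count must equal len(site_list) - 1")


@dataclass(frozen=True)
class SharingResult:
    """Pooled common/total two-locus haplotype ratio for one population pair."""

    pop_pair: tuple[str, str]
    shared_count: int
    union_count: int

    @property
    def ratio(self) -> float:
        return self.shared_count / self.union_count


def select_linked_snps(gm: GenotypeMatrix,
                       peak_site: int,
                       region: Interval,
                       r2_min: float = 0.6) -> list[int]:
    """The association peak plus all region sites with r²(peak, site) >= r2_min.

    Returns site indices ordered by position; the peak is always included.
    """
    if region.unit != "bp":
        raise ValueError("select_linked_snps requires a bp region")
    p, n = site_frequencies(gm, None)
    if n[peak_site] == 0 or p[peak_site] in (0.0, 1.0):
        raise EstimationError("peak site is monomorphic; r² undefined")
    candidates = gm.sites_in(region.chrom, region.start, region.end)
    if peak_site not in candidates:
        raise ValueError("peak site not inside region")
    chosen = {peak_site}
    for j in candidates:
        if j == peak_site:
            continue
        r2 = ld_r2(gm, peak_site, int(j))
        if not np.isnan(r2) and r2 >= r2_min:
            chosen.add(int(j))
    return sorted(chosen, key=lambda j: int(gm.pos_bp[j]))


def select_region_snps(gm: GenotypeMatrix,
                       region: Interval,
                       n_snps: int = 100) -> list[int]:
    """The first ``n_snps`` sites of a bp region, in position order.

    This reproduces the fixed-count mode used for the shattering-locus
    neighbourhood (100 SNPs in a 200 kb region) where no single peak exists.
    """
    if region.unit != "bp":
        raise ValueError("select_region_snps requires a bp region")
    sites = gm.sites_in(region.chrom, region.start, region.end)
    return [int(j) for j in sites[:n_snps]]


def build_profile(gm: GenotypeMatrix,
                  sites: Sequence[int],
                  population: str | Iterable[str]) -> HaplotypeProfile:
    """Count two-locus haplotypes at each consecutive site pair.

    An individual homozygous and called at both sites of a pair contributes
    one haplotype: its homozygous allele at each site (0 = ref, 1 = alt).
    Heterozygous or missing individuals are skipped for that pair only.
    """
    sites = [int(s) for s in sites]
    if len(sites) < 2:
        raise ValueError("need >= 2 sites for two-locus haplotypes")
    rows = gm.sample_indices(population)
    if len(rows) == 0:
        raise EstimationError("population has no samples")
    label = population if isinstance(population, str) else "+".join(population)
    dos = gm.dosage[rows][:, sites]
    counters: list[Counter] = []
    for k in range(len(sites) - 1):
        d1 = dos[:, k]
        d2 = dos[:, k + 1]
        ok = np.isin(d1, (0, 2)) & np.isin(d2, (0, 2))
        c: Counter = Counter(zip((d1[ok] // 2).tolist(), (d2[ok] // 2).tolist()))
        if not c:
            import warnings
            warnings.warn(
                f"no homozygous-called individual at pair {k} of {label}",
                stacklevel=2)
        counters.append(c)
    return HaplotypeProfile(population=label, site_list=sites,
                            pair_haplotypes=counters)


def common_haplotype_ratio(a: HaplotypeProfile,
                           b: HaplotypeProfile) -> SharingResult:
    """Pooled shared/total haplotype-type ratio between two profiles.

    shared = sum over pairs of |types(a) ∩ types(b)|; total = sum of
    |types(a) ∪ types(b)|.  A pair empty in both populations contributes
    nothing to either sum.  The statistic is type-based (presence/absence),
    so it is symmetric and equals 1 iff the per-pair type sets coincide.
    """
    if a.site_list != b.site_list:
        raise ValueError("profiles must be built on the same site list")
    shared = 0
    union = 0
    for ca, cb in zip(a.pair_haplotypes, b.pair_haplotypes):
        ta, tb = set(ca), set(cb)
        shared += len(ta & tb)
        union += len(ta | tb)
    if union == 0:
        raise EstimationError("no haplotypes observed in either population")
    return SharingResult(pop_pair=(a.population, b.population),
                         shared_count=shared, union_count=union)


def sharing_matrix(gm: GenotypeMatrix,
                   sites: Sequence[int],
                   populations: Sequence[str]) -> list[SharingResult]:
    """Sharing ratio for every unordered pair of the given populations."""
    if len(populations) < 2:
        raise ValueError("need >= 2 populations")
    profiles = {p: build_profile(gm, sites, p) for p in populations}
    out: list[SharingResult] = []
    for i, pa in enumerate(populations):
        for pb in populations[i + 1:]:
            out.append(common_haplotype_ratio(profiles[pa], profiles[pb]))
    return out
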