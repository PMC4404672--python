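"""Genome-wide significance thresholds for association scans.

Two corrections for an experiment-wide type-I error rate alpha:

* Bonferroni over the literal SNP count: alpha / n_tests.
* An LD-bin correction for strongly autocorrelated (inbreeding) genomes:
  the effective number of independent tests is the number of LD bins,
  genome_size_bp / ld_extent_bp, and the threshold is alpha divided by that.
  With a 730 Mb genome and LD decaying to background within ~150 kb this
  lands within an order of magnitude of 1e-5 — far more permissive than the
  SNP-count Bonferroni cutoff.

The effective test count is kept real-valued (not floored): the bin count is
an approximation, and flooring would only perturb the third significant
figure.
"""

from __future__ import annotations

import math


def bonferroni(alpha: float, n_tests: float) -> float:
    """Per-test threshold alpha / n_tests."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if n_tests <= 0:
        raise ValueError("n_tests must be positive")
    return alpha / n_tests


def effective_tests(genome_size_bp: float, ld_extent_bp: float) -> float:
    """Number of LD bins: genome size / average LD extent (real-valued)."""
    if ld_extent_bp <= 0:
        raise ValueError("ld_extent_bp must be positive")
    if genome_size_bp < ld_extent_bp:
        raise ValueError("genome size must be >= LD extent")
    return genome_size_bp / ld_extent_bp


def ld_adjusted_threshold(alpha: float,
                          genome_size_bp: float,
                          ld_extent_bp: float) -> float:
    """LD-bin corrected threshold: alpha / (genome_size_bp / ld_extent_bp).

    Equal to ``bonferroni(alpha, effective_tests(...))`` exactly; monotone
    increasing in the LD extent and decreasing in genome size.
    """
    return bonferroni(alpha, effective_tests(genome_size_bp, ld_extent_bp))


def nearest_power_of_ten(x: float) -> float:
    """The power of ten nearest to x on a log scale (e.g. 1.03e-5 -> 1e-5)."""
    if x <= 0:
        raise ValueError("x must be positive")
    return 10.0 ** round(math.log10(x))
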