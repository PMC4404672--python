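import numpy as np
import pytest

from sweepkit.io import MISSING, GenotypeMatrix


def make_gm(dosage, populations=None, chrom=None, pos=None, sample_ids=None):
    """Build a GenotypeMatrix from a plain dosage array with minimal metadata.

    ``populations`` maps label -> number of samples (in row order) or is a
    full sample->label dict.
    """
    dosage = np.asarray(dosage, dtype=np.int8)
    n_samples, n_sites = dosage.shape
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n_samples)]
    if populations is None:
        pops = {s: "pop" for s in sample_ids}
    elif isinstance(populations, dict) and all(
            isinstance(v, int) for v in populations.values()):
        pops = {}
        i = 0
        for label, count in populations.items():
            for _ in range(count):
                pops[sample_ids[i]] = label
                i += 1
        assert i == n_samples
    else:
        pops = dict(populations)
    if chrom is None:
        chrom = ["1"] * n_sites
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 1000
    return GenotypeMatrix(
        sample_ids=sample_ids,
        populations=pops,
        chrom=np.asarray(chrom, dtype=object),
        pos_bp=np.asarray(pos, dtype=np.int64),
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["C"] * n_sites, dtype=object),
        dosage=dosage,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_gm(rng, n_samples=20, n_sites=50, missing_rate=0.1, pops=None):
    """Random dosage fixture with some missing calls."""
    dosage = rng.integers(0, 3, size=(n_samples, n_sites)).astype(np.int8)
    mask = rng.random(dosage.shape) < missing_rate
    dosage[mask] = MISSING
    return make_gm(dosage, populations=pops)
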