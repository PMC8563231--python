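import numpy as np
import pytest

from rohscan.io import HET, HOM, MISSING, ChromosomeSites, GenotypeMatrix

CODE = {"o": HOM, "h": HET, ".": MISSING}


def make_matrix(rows: list[str], positions=None, qual=None,
                chrom: str = "1", samples=None) -> GenotypeMatrix:
    """Build a one-chromosome matrix from strings of o/h/. call codes."""
    n = len(rows[0])
    assert all(len(r) == n for r in rows)
    if positions is None:
        positions = np.arange(1, n + 1) * 1000
    positions = np.asarray(positions, dtype=np.int64)
    if qual is None:
        qual = np.full(n, 30.0)
    calls = np.array([[CODE[c] for c in r] for r in rows], dtype=np.int8)
    if samples is None:
        samples = [f"S{i + 1:03d}" for i in range(len(rows))]
    return GenotypeMatrix(samples, {chrom: ChromosomeSites(positions, qual, calls)})


def random_matrix(rng, n_samples=2, n_snps=100, p_het=0.08, p_miss=0.04,
                  max_step=3000, chrom="1"):
    positions = np.cumsum(rng.integers(50, max_step, size=n_snps)).astype(np.int64)
    calls = rng.choice(
        [HOM, HET, MISSING], p=[1 - p_het - p_miss, p_het, p_miss],
        size=(n_samples, n_snps)).astype(np.int8)
    qual = np.full(n_snps, 30.0)
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    return GenotypeMatrix(samples, {chrom: ChromosomeSites(positions, qual, calls)})


@pytest.fixture
def toy_matrix():
    """3 samples x 12 sites with a clean homozygous block in sample 1."""
    return make_matrix([
        "oooooooooooo",
        "ohohohohohoh",
        "oooo....oooo",
    ])
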