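"""Sliding-window ROH calling.

Implements the PLINK-style homozygosity scan: a fixed-SNP-count window
slides along each chromosome of each sample; a window is flagged homozygous
when its heterozygous and missing call counts stay within the allowances
(one het and five missing per window by default). Each SNP is scored by the
fraction of flagged windows covering it, and SNPs whose fraction reaches the
hit threshold are "eligible". Maximal runs of eligible SNPs — split where
adjacent eligible SNPs are further apart than the gap limit — become ROH
segments if they pass the segment-level filters: minimum SNP count (100),
minimum physical length (1 Mb by default, configurable down for short-ROH
summaries), and maximum bp-per-SNP density (50 kb/SNP).

``brute_force_roh`` re-derives the identical contract by naive enumeration
and exists purely as a verification oracle for small inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import HET, MISSING, GenotypeMatrix


@dataclass
class ROHParameters:
    """Thresholds governing the window scan and segment filtering."""

    window_snps: int = 50
    window_max_het: int = 1
    window_max_missing: int = 5
    snp_hit_threshold: float = 0.05
    min_snps: int = 100
    min_length_bp: int = 1_000_000
    min_density_bp_per_snp: float = 50_000.0
    max_gap_bp: int = 1_000_000

    def __post_init__(self) -> None:
        for name in ("window_snps", "window_max_het", "window_max_missing",
                     "min_snps", "max_gap_bp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.window_snps < 1:
            raise ValueError("window_snps must be >= 1")
        if not 0.0 <= self.snp_hit_threshold <= 1.0:
            raise ValueError("snp_hit_threshold must be in [0, 1]")
        if self.min_length_bp <= 0:
            raise ValueError("min_length_bp must be > 0")
        if self.min_density_bp_per_snp <= 0:
            raise ValueError("min_density_bp_per_snp must be > 0")


@dataclass(frozen=True)
class ROHSegment:
    """One homozygous run in one sample (1-based inclusive coordinates)."""

    sample: str
    chrom: str
    start: int
    end: int
    n_snps: int
    n_het: int
    n_missing: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start > end")
        if self.n_snps < 1:
            raise ValueError("segment must contain at least one SNP")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


def window_homozygosity(calls: np.ndarray, params: ROHParameters) -> np.ndarray:
    """Flag each window of ``window_snps`` consecutive calls as homozygous.

    Window j covers calls [j, j + window_snps); only windows fully inside
    the sequence are evaluated, so a length-n input yields
    ``n - window_snps + 1`` flags. A sequence shorter than one window is
    evaluated as a single window covering all its SNPs.
    """
    calls = np.asarray(calls)
    n = calls.size
    if n == 0:
        return np.zeros(0, dtype=bool)
    w = min(params.window_snps, n)
    het = (calls == HET).astype(np.int64)
    mis = (calls == MISSING).astype(np.int64)
    het_c = np.concatenate(([0], np.cumsum(het)))
    mis_c = np.concatenate(([0], np.cumsum(mis)))
    n_win = n - w + 1
    het_in = het_c[w:] - het_c[:n_win]
    mis_in = mis_c[w:] - mis_c[:n_win]
    return (het_in <= params.window_max_het) & (mis_in <= params.window_max_missing)


def snp_hit_fractions(flags: np.ndarray, n_snps: int,
                      params: ROHParameters) -> np.ndarray:
    """Per-SNP fraction of flagged-true windows among windows covering it."""
    flags = np.asarray(flags, dtype=bool)
    if n_snps == 0:
        return np.zeros(0, dtype=float)
    n_win = flags.size
    w = n_snps - n_win + 1  # effective window size actually used
    cum = np.concatenate(([0], np.cumsum(flags.astype(np.int64))))
    idx = np.arange(n_snps)
    lo = np.maximum(0, idx - w + 1)
    hi = np.minimum(idx, n_win - 1)
    hits = cum[hi + 1] - cum[lo]
    denom = hi - lo + 1
    return hits / denom


def _candidate_runs(eligible: np.ndarray, positions: np.ndarray,
                    max_gap_bp: int) -> list[tuple[int, int]]:
    """Index ranges [i, j] of maximal eligible runs, split at large gaps."""
    runs: list[tuple[int, int]] = []
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        return runs
    start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i != prev + 1 or positions[i] - positions[prev] > max_gap_bp:
            runs.append((int(start), int(prev)))
            start = i
        prev = i
    runs.append((int(start), int(prev)))
    return runs


def _emit(sample: str, chrom: str, positions: np.ndarray, calls: np.ndarray,
          runs: list[tuple[int, int]], params: ROHParameters) -> list[ROHSegment]:
    out: list[ROHSegment] = []
    for i, j in runs:
        n_snps = j - i + 1
        length = int(positions[j] - positions[i] + 1)
        if n_snps < params.min_snps or length < params.min_length_bp:
            continue
        if length / n_snps > params.min_density_bp_per_snp:
            continue
        window = calls[i:j + 1]
        out.append(ROHSegment(
            sample=sample, chrom=chrom,
            start=int(positions[i]), end=int(positions[j]),
            n_snps=n_snps,
            n_het=int(np.count_nonzero(window == HET)),
            n_missing=int(np.count_nonzero(window == MISSING)),
        ))
    return out


def call_segments(matrix: GenotypeMatrix,
                  params: ROHParameters | None = None) -> list[ROHSegment]:
    """Call ROH segments for every sample and chromosome of the matrix.

    Returns segments sorted by (sample, chromosome, start); segments of one
    sample-chromosome are pairwise disjoint by construction since each SNP
    belongs to at most one eligible run.
    """
    params = params or ROHParameters()
    segments: list[ROHSegment] = []
    for si, sample in enumerate(matrix.samples):
        for chrom, sites in matrix.chromosomes.items():
            calls = sites.calls[si]
            flags = window_homozygosity(calls, params)
            fracs = snp_hit_fractions(flags, sites.n_sites, params)
            eligible = fracs >= params.snp_hit_threshold
            runs = _candidate_runs(eligible, sites.positions, params.max_gap_bp)
            segments.extend(
                _emit(sample, chrom, sites.positions, calls, runs, params))
    segments.sort(key=lambda s: (s.sample, s.chrom, s.start))
    return segments


def brute_force_roh(matrix: GenotypeMatrix,
                    params: ROHParameters | None = None) -> list[ROHSegment]:
    """Oracle: same contract as :func:`call_segments` by naive enumeration.

    Every window is recounted with explicit python loops and every SNP's
    hit fraction is rebuilt by scanning all windows; intended for small
    inputs (<= ~1000 SNPs per chromosome) in tests.
    """
    params = params or ROHParameters()
    segments: list[ROHSegment] = []
    for si, sample in enumerate(matrix.samples):
        for chrom, sites in matrix.chromosomes.items():
            calls = [int(c) for c in sites.calls[si]]
            positions = [int(p) for p in sites.positions]
            n = len(calls)
            if n == 0:
                continue
            w = min(params.window_snps, n)
            windows = []
            for j in range(n - w + 1):
                chunk = calls[j:j + w]
                n_het = sum(1 for c in chunk if c == HET)
                n_mis = sum(1 for c in chunk if c == MISSING)
                windows.append(n_het <= params.window_max_het
                               and n_mis <= params.window_max_missing)
            eligible = []
            for i in range(n):
                covering = [f for j, f in enumerate(windows) if j <= i <= j + w - 1]
                frac = sum(covering) / len(covering)
                eligible.append(frac >= params.snp_hit_threshold)
            # exhaustive run construction
            runs: list[list[int]] = []
            current: list[int] = []
            for i in range(n):
                if not eligible[i]:
                    if current:
                        runs.append(current)
                        current = []
                    continue
                if current and positions[i] - positions[current[-1]] > params.max_gap_bp:
                    runs.append(current)
                    current = []
                current.append(i)
            if current:
                runs.append(current)
            for run in runs:
                n_snps = len(run)
                length = positions[run[-1]] - positions[run[0]] + 1
                if n_snps < params.min_snps:
                    continue
                if length < params.min_length_bp:
                    continue
                if length / n_snps > params.min_density_bp_per_snp:
                    continue
                chunk = calls[run[0]:run[-1] + 1]
                segments.append(ROHSegment(
                    sample=sample, chrom=chrom,
                    start=positions[run[0]], end=positions[run[-1]],
                    n_snps=n_snps,
                    n_het=sum(1 for c in chunk if c == HET),
                    n_missing=sum(1 for c in chunk if c == MISSING),
                ))
    segments.sort(key=lambda s: (s.sample, s.chrom, s.start))
    return segments
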