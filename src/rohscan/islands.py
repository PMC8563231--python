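"""ROH islands: per-SNP incidence, thresholding, and island merging.

The incidence of a SNP is the proportion of sampled individuals whose ROH
covers that position. Regions where incidence is unusually high across the
population ("ROH islands") are candidate signatures of selection or drift.
Two threshold modes are supported: a fixed proportion (e.g. 0.30), and the
empirical top-q quantile of all per-SNP incidences (nearest-rank, no
interpolation). Runs of consecutive above-threshold SNPs are merged into
islands, optionally tolerating short below-threshold gaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .detect import ROHSegment
from .io import GenotypeMatrix


@dataclass
class SnpIncidenceTrack:
    """Per-chromosome SNP positions and ROH incidence across individuals."""

    n_samples: int
    positions: dict[str, np.ndarray] = field(default_factory=dict)
    incidence: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, pos in self.positions.items():
            inc = self.incidence[chrom]
            if pos.shape != inc.shape:
                raise ValueError(f"{chrom}: positions/incidence length mismatch")
            if inc.size and (inc.min() < 0 or inc.max() > 1):
                raise ValueError("incidence must lie in [0, 1]")

    @property
    def n_snps(self) -> int:
        return sum(p.size for p in self.positions.values())

    def all_incidences(self) -> np.ndarray:
        if not self.incidence:
            return np.zeros(0)
        return np.concatenate([self.incidence[c] for c in self.incidence])


@dataclass(frozen=True)
class ROHIsland:
    """A run of high-incidence SNPs (1-based inclusive bounds)."""

    chrom: str
    start: int
    end: int
    n_snps: int
    max_incidence: float
    mean_incidence: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("island start > end")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


def snp_incidence(segments: list[ROHSegment],
                  matrix: GenotypeMatrix) -> SnpIncidenceTrack:
    """Fraction of samples whose ROH covers each SNP of the matrix."""
    known = set(matrix.chromosomes)
    for seg in segments:
        if seg.chrom not in known:
            raise ValueError(
                f"segment chromosome {seg.chrom!r} absent from genotype matrix")
    n = matrix.n_samples
    positions: dict[str, np.ndarray] = {}
    incidence: dict[str, np.ndarray] = {}
    by_chrom: dict[str, list[ROHSegment]] = {c: [] for c in matrix.chromosomes}
    for seg in segments:
        by_chrom[seg.chrom].append(seg)
    for chrom, sites in matrix.chromosomes.items():
        pos = sites.positions
        covered = np.zeros((n, pos.size), dtype=bool)
        for seg in by_chrom[chrom]:
            si = matrix.sample_index(seg.sample)
            lo = np.searchsorted(pos, seg.start, side="left")
            hi = np.searchsorted(pos, seg.end, side="right")
            covered[si, lo:hi] = True
        positions[chrom] = pos.copy()
        incidence[chrom] = covered.sum(axis=0) / n
    return SnpIncidenceTrack(n_samples=n, positions=positions,
                             incidence=incidence)


def incidence_threshold(track: SnpIncidenceTrack, mode: str = "fixed",
                        value: float = 0.30) -> float:
    """Resolve the island threshold.

    mode='fixed': return ``value`` unchanged (e.g. 0.30 for a 30% line).
    mode='quantile': the (1 - value) empirical quantile of all per-SNP
    incidences by the nearest-rank rule (the ceil(p*n)-th order statistic),
    so value=0.01 marks the top 1% of SNPs.
    """
    if mode == "fixed":
        if not 0.0 <= value <= 1.0:
            raise ValueError("fixed threshold must be in [0, 1]")
        return float(value)
    if mode == "quantile":
        if not 0.0 < value < 1.0:
            raise ValueError("quantile value must be in (0, 1)")
        incidences = track.all_incidences()
        if incidences.size == 0:
            raise ValueError("cannot take a quantile of an empty track")
        p = 1.0 - value
        rank = max(1, math.ceil(p * incidences.size))  # 1-based order statistic
        return float(np.sort(incidences)[rank - 1])
    raise ValueError(f"unknown threshold mode: {mode!r}")


def merge_islands(track: SnpIncidenceTrack, threshold: float,
                  max_gap_snps: int = 0, min_snps: int = 2) -> list[ROHIsland]:
    """Merge consecutive above-threshold SNPs into islands.

    Up to ``max_gap_snps`` consecutive below-threshold SNPs are tolerated
    inside a run (gap SNPs count toward the island's span but not its SNP
    statistics); runs with fewer than ``min_snps`` above-threshold SNPs are
    dropped. Islands are sorted and disjoint per chromosome.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    islands: list[ROHIsland] = []
    for chrom in track.positions:
        pos = track.positions[chrom]
        inc = track.incidence[chrom]
        above = inc >= threshold
        i = 0
        n = pos.size
        while i < n:
            if not above[i]:
                i += 1
                continue
            members = [i]
            j = i + 1
            gap = 0
            while j < n:
                if above[j]:
                    members.append(j)
                    gap = 0
                    j += 1
                else:
                    gap += 1
                    if gap > max_gap_snps:
                        break
                    j += 1
            if len(members) >= min_snps:
                vals = inc[members]
                islands.append(ROHIsland(
                    chrom=chrom,
                    start=int(pos[members[0]]), end=int(pos[members[-1]]),
                    n_snps=len(members),
                    max_incidence=float(vals.max()),
                    mean_incidence=float(vals.mean()),
                ))
            i = members[-1] + 1
    islands.sort(key=lambda isl: (isl.chrom, isl.start))
    return islands


def manhattan_export(track: SnpIncidenceTrack, threshold: float,
                     path: str | Path, plot: bool = False) -> None:
    """Write the incidence track as TSV (chrom, pos, incidence).

    The threshold is stored in a ``#threshold=`` header line so the file is
    self-describing; with ``plot=True`` a Manhattan-style PNG is rendered
    next to the TSV.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#threshold={threshold:.6g}\n")
        fh.write("chrom\tpos\tincidence\n")
        for chrom in track.positions:
            pos = track.positions[chrom]
            inc = track.incidence[chrom]
            for p, v in zip(pos, inc):
                fh.write(f"{chrom}\t{int(p)}\t{v:.6g}\n")
    if plot:
        _render_manhattan(track, threshold, path.with_suffix(".png"))


def read_manhattan(path: str | Path) -> tuple[SnpIncidenceTrack, float]:
    """Reload a TSV written by :func:`manhattan_export`."""
    path = Path(path)
    threshold = math.nan
    positions: dict[str, list[int]] = {}
    incidence: dict[str, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#threshold="):
                threshold = float(line.split("=", 1)[1])
                continue
            if not line or line.startswith("chrom\t"):
                continue
            chrom, p, v = line.split("\t")
            positions.setdefault(chrom, []).append(int(p))
            incidence.setdefault(chrom, []).append(float(v))
    track = SnpIncidenceTrack(
        n_samples=0,
        positions={c: np.array(v, dtype=np.int64) for c, v in positions.items()},
        incidence={c: np.array(v, dtype=float) for c, v in incidence.items()},
    )
    return track, threshold


def write_islands_bed(islands: list[ROHIsland], path: str | Path) -> None:
    """Islands as BED (0-based half-open); score column = mean incidence."""
    with open(path, "w") as fh:
        for k, isl in enumerate(islands, 1):
            fh.write(f"{isl.chrom}\t{isl.start - 1}\t{isl.end}\t"
                     f"island_{k}\t{isl.mean_incidence:.4f}\n")


def _render_manhattan(track: SnpIncidenceTrack, threshold: float,
                      png_path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    offset = 0
    for k, chrom in enumerate(track.positions):
        pos = track.positions[chrom]
        inc = track.incidence[chrom]
        ax.scatter(pos + offset, inc, s=2,
                   color="tab:blue" if k % 2 == 0 else "tab:orange")
        offset += int(pos[-1]) if pos.size else 0
    ax.axhline(threshold, color="red", lw=1)
    ax.set_xlabel("genome position (bp, concatenated)")
    ax.set_ylabel("ROH incidence")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
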