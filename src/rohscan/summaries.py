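"""Descriptive ROH statistics: length classes, per-chromosome load, F_ROH.

F_ROH is the genomic inbreeding coefficient

    F_ROH = L_ROH / L_genome

where L_ROH is the total length of an individual's autosomal ROH and
L_genome is the length of the autosomal genome covered by SNPs (per
chromosome: last SNP position - first SNP position + 1, summed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .detect import ROHSegment
from .io import GenotypeMatrix

#: default length-class edges in kb: [100, 500), [500, 1000), [1000, inf)
DEFAULT_CLASS_BOUNDS_KB: tuple[float, ...] = (100.0, 500.0, 1000.0)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (matches conventional table formatting)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def compute_froh(l_roh: float, l_genome: float) -> float:
    """F_ROH = L_ROH / L_genome; errors on inconsistent inputs, no clamping."""
    if l_genome <= 0:
        raise ValueError("L_genome must be > 0")
    if l_roh < 0:
        raise ValueError("L_ROH must be >= 0")
    if l_roh > l_genome:
        raise ValueError(
            f"L_ROH ({l_roh}) exceeds L_genome ({l_genome}): inconsistent inputs")
    return l_roh / l_genome


def genome_span(matrix: GenotypeMatrix) -> int:
    """Total SNP-covered span: sum over chromosomes of last - first + 1."""
    if not matrix.chromosomes or matrix.n_sites == 0:
        raise ValueError("empty genotype matrix has no genome span")
    return sum(
        int(sites.positions[-1] - sites.positions[0] + 1)
        for sites in matrix.chromosomes.values()
        if sites.n_sites > 0
    )


def chromosome_spans(matrix: GenotypeMatrix) -> dict[str, int]:
    return {
        chrom: int(sites.positions[-1] - sites.positions[0] + 1)
        for chrom, sites in matrix.chromosomes.items()
        if sites.n_sites > 0
    }


@dataclass
class FrohResult:
    """Per-sample L_ROH and F_ROH plus the population mean."""

    per_sample: pd.DataFrame  # columns: sample, l_roh_bp, f_roh
    l_genome: int
    mean_froh: float

    def to_tsv(self, path) -> None:
        self.per_sample.to_csv(path, sep="\t", index=False)


def froh_per_sample(segments: list[ROHSegment], samples: list[str],
                    l_genome: int) -> FrohResult:
    """Compute each sample's F_ROH from its called segments."""
    totals = {s: 0 for s in samples}
    for seg in segments:
        if seg.sample not in totals:
            raise ValueError(f"segment sample {seg.sample!r} not in sample list")
        totals[seg.sample] += seg.length_bp
    rows = [
        {"sample": s, "l_roh_bp": totals[s],
         "f_roh": compute_froh(totals[s], l_genome)}
        for s in samples
    ]
    df = pd.DataFrame(rows, columns=["sample", "l_roh_bp", "f_roh"])
    return FrohResult(per_sample=df, l_genome=l_genome,
                      mean_froh=float(df["f_roh"].mean()))


def length_class_table(
    segments: list[ROHSegment],
    bounds_kb: tuple[float, ...] = DEFAULT_CLASS_BOUNDS_KB,
    l_genome: int | None = None,
) -> pd.DataFrame:
    """Length-class summary: count, % of total, mean±SD length (Mb), coverage %.

    Classes are half-open [low, high) in kb with the last class unbounded,
    so a segment of exactly 500 kb falls in the 500-1000 kb class. Segments
    shorter than the first edge are excluded (they would not have been
    called under the matching minimum-length setting). Returns one row per
    class plus a totals row.
    """
    if any(b2 <= b1 for b1, b2 in zip(bounds_kb, bounds_kb[1:])):
        raise ValueError("class bounds must be strictly increasing")
    edges_bp = [b * 1000.0 for b in bounds_kb] + [math.inf]
    labels = [
        f"{int(bounds_kb[i])}-{int(bounds_kb[i + 1])}" if i + 1 < len(bounds_kb)
        else f">{int(bounds_kb[i])}"
        for i in range(len(bounds_kb))
    ]
    lengths = [
        [] for _ in labels
    ]
    for seg in segments:
        for ci in range(len(labels)):
            if edges_bp[ci] <= seg.length_bp < edges_bp[ci + 1]:
                lengths[ci].append(seg.length_bp)
                break
    total = sum(len(v) for v in lengths)
    rows = []
    for label, vals in zip(labels, lengths):
        arr = np.array(vals, dtype=float)
        count = arr.size
        rows.append({
            "class_kb": label,
            "count": count,
            "pct_of_total": round_half_up(100.0 * count / total, 2) if total else 0.0,
            "mean_mb": float(arr.mean() / 1e6) if count else 0.0,
            "sd_mb": float(arr.std(ddof=1) / 1e6) if count > 1 else 0.0,
            "coverage_pct": (100.0 * arr.sum() / l_genome) if l_genome else float("nan"),
        })
    all_lengths = np.array([x for vals in lengths for x in vals], dtype=float)
    rows.append({
        "class_kb": "total",
        "count": total,
        "pct_of_total": 100.0 if total else 0.0,
        "mean_mb": float(all_lengths.mean() / 1e6) if total else 0.0,
        "sd_mb": float(all_lengths.std(ddof=1) / 1e6) if total > 1 else 0.0,
        "coverage_pct": (100.0 * all_lengths.sum() / l_genome) if l_genome else float("nan"),
    })
    return pd.DataFrame(rows)


def per_chromosome_summary(segments: list[ROHSegment],
                           matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per chromosome: pooled ROH count and mean per-sample ROH coverage (%).

    Coverage of a sample on a chromosome is that sample's total segment
    length divided by the chromosome's SNP-covered span; the table reports
    the mean over samples, as a percentage.
    """
    spans = chromosome_spans(matrix)
    counts = {c: 0 for c in matrix.chromosomes}
    per_sample_len: dict[str, dict[str, int]] = {
        c: {s: 0 for s in matrix.samples} for c in matrix.chromosomes}
    for seg in segments:
        if seg.chrom not in counts:
            raise ValueError(f"segment chromosome {seg.chrom!r} not in matrix")
        counts[seg.chrom] += 1
        per_sample_len[seg.chrom][seg.sample] += seg.length_bp
    rows = []
    for chrom in matrix.chromosomes:
        span = spans.get(chrom, 0)
        if span:
            mean_cov = float(np.mean(
                [per_sample_len[chrom][s] / span for s in matrix.samples]))
        else:
            mean_cov = 0.0
        rows.append({
            "chrom": chrom,
            "n_roh": counts[chrom],
            "mean_coverage_pct": 100.0 * mean_cov,
            "span_bp": span,
        })
    return pd.DataFrame(rows)
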