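"""Gene content of ROH islands.

Intersects island intervals with gene models (closed intervals, 1-based)
and reports every pair overlapping by at least one base pair, together
with the exact overlap length. Strand is ignored — runs of homozygosity
are strand-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

from .io import GeneRecord
from .islands import ROHIsland


@dataclass(frozen=True)
class IslandGeneHit:
    island: ROHIsland
    gene: GeneRecord
    overlap_bp: int

    def __post_init__(self) -> None:
        if self.overlap_bp < 1:
            raise ValueError("a hit requires >= 1 bp of overlap")
        if self.overlap_bp > min(self.island.length_bp, self.gene.length_bp):
            raise ValueError("overlap exceeds interval length")


def overlap_islands_genes(
    islands: list[ROHIsland],
    genes: list[GeneRecord],
    require_containment: bool = False,
) -> tuple[list[IslandGeneHit], list[ROHIsland]]:
    """All (island, gene) pairs sharing >= 1 bp on the same chromosome.

    With ``require_containment`` a gene must lie entirely inside the island.
    Returns the hits (sorted by chrom, island start, gene start, gene id)
    and the islands without any gene.
    """
    trees: dict[str, IntervalTree] = {}
    for gene in genes:
        # half-open tree coordinates: [start, end + 1) covers the closed interval
        trees.setdefault(gene.chrom, IntervalTree()).addi(
            gene.start, gene.end + 1, gene)
    hits: list[IslandGeneHit] = []
    empty: list[ROHIsland] = []
    for isl in islands:
        tree = trees.get(isl.chrom)
        found = sorted(tree.overlap(isl.start, isl.end + 1)) if tree else []
        n_before = len(hits)
        for iv in found:
            gene: GeneRecord = iv.data
            if require_containment and not (isl.start <= gene.start
                                            and gene.end <= isl.end):
                continue
            overlap = min(isl.end, gene.end) - max(isl.start, gene.start) + 1
            hits.append(IslandGeneHit(island=isl, gene=gene, overlap_bp=overlap))
        if len(hits) == n_before:
            empty.append(isl)
    hits.sort(key=lambda h: (h.island.chrom, h.island.start,
                             h.gene.start, h.gene.gene_id))
    return hits, empty


def gene_report(hits: list[IslandGeneHit], path: str | Path) -> pd.DataFrame:
    """Candidate-gene table: chromosome, gene location and inclusive size,
    gene name, overlap, and host island; written as TSV."""
    rows = []
    for h in sorted(hits, key=lambda h: (h.island.chrom, h.gene.start,
                                         h.gene.gene_id)):
        rows.append({
            "chrom": h.island.chrom,
            "gene_start": h.gene.start,
            "gene_end": h.gene.end,
            "gene_size_bp": h.gene.length_bp,
            "gene_id": h.gene.gene_id,
            "gene_name": h.gene.gene_name,
            "overlap_bp": h.overlap_bp,
            "island_start": h.island.start,
            "island_end": h.island.end,
        })
    df = pd.DataFrame(rows, columns=[
        "chrom", "gene_start", "gene_end", "gene_size_bp", "gene_id",
        "gene_name", "overlap_bp", "island_start", "island_end"])
    df.to_csv(path, sep="\t", index=False)
    return df
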