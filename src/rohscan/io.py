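"""Genotype and interval I/O.

Reads multi-sample VCF genotypes into a zygosity matrix, reads gene models
from GFF3/BED, and round-trips ROH segment tables as TSV/BED.

Coordinate conventions: internal coordinates are 1-based inclusive (the VCF
convention); BED input/output converts to/from 0-based half-open at the
boundary. Zygosity is all the downstream scan needs, so genotype calls are
reduced to three codes: HOM (two identical alleles), HET (two distinct
alleles), MISSING (any missing allele).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

# zygosity codes used throughout the package
HOM: int = 0
HET: int = 1
MISSING: int = 2

#: pig autosomes; sex chromosomes and unplaced scaffolds are excluded when
#: reading with autosomes_only=True
DEFAULT_AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 19))

SEGMENT_COLUMNS = [
    "IID", "CHR", "POS1", "POS2", "KB", "NSNP", "DENS_KB", "NHET", "NMISS",
]


def normalize_chrom(name: str) -> str:
    """Strip an optional 'chr'/'Chr' prefix so naming schemes interoperate."""
    low = name.lower()
    return name[3:] if low.startswith("chr") else name


@dataclass
class ChromosomeSites:
    """SNP sites of one chromosome: positions, site quality and calls.

    ``calls`` is an (n_samples, n_sites) int8 array of zygosity codes.
    Positions are 1-based and strictly increasing.
    """

    positions: np.ndarray
    site_quality: np.ndarray
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.site_quality = np.asarray(self.site_quality, dtype=np.float64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.positions.ndim != 1:
            raise ValueError("positions must be 1-D")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.site_quality.shape != self.positions.shape:
            raise ValueError("site_quality length must match positions")
        if self.calls.ndim != 2 or self.calls.shape[1] != self.positions.size:
            raise ValueError("calls must be (n_samples, n_sites)")
        if np.any((self.site_quality < 0) & ~np.isnan(self.site_quality)):
            raise ValueError("site quality must be >= 0")

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ChromosomeSites):
            return NotImplemented
        return (
            np.array_equal(self.positions, other.positions)
            and np.allclose(self.site_quality, other.site_quality, equal_nan=True)
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class GenotypeMatrix:
    """Per-sample, per-site diploid zygosity calls across chromosomes."""

    samples: list[str]
    chromosomes: dict[str, ChromosomeSites] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, chrom in self.chromosomes.items():
            if chrom.calls.shape[0] != len(self.samples):
                raise ValueError(
                    f"chromosome {name}: calls rows ({chrom.calls.shape[0]}) "
                    f"!= n_samples ({len(self.samples)})"
                )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return sum(c.n_sites for c in self.chromosomes.values())

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and list(self.chromosomes) == list(other.chromosomes)
            and all(
                self.chromosomes[k] == other.chromosomes[k]
                for k in self.chromosomes
            )
        )


@dataclass(frozen=True)
class GeneRecord:
    """A gene model interval, 1-based inclusive."""

    gene_id: str
    gene_name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


def read_vcf(
    path: str | Path,
    min_site_quality: float = 10.0,
    autosomes_only: bool = True,
    allowed_chroms: tuple[str, ...] = DEFAULT_AUTOSOMES,
) -> GenotypeMatrix:
    """Read a diploid multi-sample VCF into a :class:`GenotypeMatrix`.

    Sites with QUAL below ``min_site_quality`` (or missing QUAL, when the
    threshold is positive), non-biallelic sites and non-SNP records are
    excluded. With ``autosomes_only`` only chromosomes on ``allowed_chroms``
    (after stripping a 'chr' prefix) are kept.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"VCF not found: {path}")
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare Exceptions on bad input
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"VCF {path} contains no samples")

    allowed = {normalize_chrom(c) for c in allowed_chroms}
    per_chrom: dict[str, list[tuple[int, float, np.ndarray]]] = {}
    for variant in vcf:
        chrom = normalize_chrom(variant.CHROM)
        if autosomes_only and chrom not in allowed:
            continue
        if len(variant.ALT) != 1:
            continue
        if len(variant.REF) != 1 or len(variant.ALT[0]) != 1:
            continue
        qual = variant.QUAL
        if qual is None:
            if min_site_quality > 0:
                continue
            qual = 0.0
        elif qual < min_site_quality:
            continue
        # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
        gt = variant.gt_types
        calls = np.full(len(samples), MISSING, dtype=np.int8)
        calls[(gt == 0) | (gt == 3)] = HOM
        calls[gt == 1] = HET
        per_chrom.setdefault(chrom, []).append((variant.POS, float(qual), calls))
    vcf.close()

    chromosomes: dict[str, ChromosomeSites] = {}
    for chrom, rows in per_chrom.items():
        positions = np.array([r[0] for r in rows], dtype=np.int64)
        quals = np.array([r[1] for r in rows], dtype=np.float64)
        calls = np.stack([r[2] for r in rows], axis=1)
        chromosomes[chrom] = ChromosomeSites(positions, quals, calls)
    return GenotypeMatrix(samples=samples, chromosomes=chromosomes)


def _read_genes_bed(path: Path) -> list[GeneRecord]:
    records: list[GeneRecord] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{i + 1}: BED line has <3 fields")
            chrom = normalize_chrom(parts[0])
            start0, end0 = int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"gene_{i + 1}"
            records.append(
                GeneRecord(gene_id=name, gene_name=name, chrom=chrom,
                           start=start0 + 1, end=end0)
            )
    return records


def _read_genes_gff3(path: Path, feature_type: str) -> list[GeneRecord]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    records: list[GeneRecord] = []
    for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        name = feat.attributes.get("Name", [gene_id])[0]
        records.append(
            GeneRecord(gene_id=gene_id, gene_name=name,
                       chrom=normalize_chrom(feat.seqid),
                       start=feat.start, end=feat.end)
        )
    return records


def read_gene_models(
    path: str | Path,
    fmt: str | None = None,
    feature_type: str = "gene",
) -> list[GeneRecord]:
    """Read gene models from GFF3 (1-based inclusive) or BED (0-based half-open).

    ``fmt`` is 'gff3' or 'bed'; when None it is inferred from the suffix.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        if suffix in {".gff", ".gff3"}:
            fmt = "gff3"
        elif suffix == ".bed":
            fmt = "bed"
        else:
            raise ValueError(f"cannot infer gene-model format from {path.name}")
    fmt = fmt.lower()
    if fmt == "bed":
        return _read_genes_bed(path)
    if fmt == "gff3":
        return _read_genes_gff3(path, feature_type)
    raise ValueError(f"unknown gene-model format: {fmt!r}")


def write_segments(segments, path: str | Path) -> None:
    """Write ROH segments as a PLINK .hom-style TSV.

    Columns: IID (sample), CHR, POS1/POS2 (1-based inclusive bp), KB
    (length in kb), NSNP, DENS_KB (kb per SNP), NHET, NMISS.
    """
    rows = []
    for seg in segments:
        rows.append({
            "IID": seg.sample,
            "CHR": seg.chrom,
            "POS1": seg.start,
            "POS2": seg.end,
            "KB": seg.length_bp / 1000.0,
            "NSNP": seg.n_snps,
            "DENS_KB": seg.length_bp / seg.n_snps / 1000.0,
            "NHET": seg.n_het,
            "NMISS": seg.n_missing,
        })
    df = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.3f")


def read_segments(path: str | Path):
    """Read a segment TSV written by :func:`write_segments`."""
    from .detect import ROHSegment

    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    segments = []
    for row in df.itertuples(index=False):
        segments.append(ROHSegment(
            sample=str(row.IID), chrom=str(row.CHR),
            start=int(row.POS1), end=int(row.POS2),
            n_snps=int(row.NSNP), n_het=int(row.NHET),
            n_missing=int(row.NMISS),
        ))
    return segments


def write_segments_bed(segments, path: str | Path) -> None:
    """Export segments as BED (0-based half-open), name = sample id."""
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(f"{seg.chrom}\t{seg.start - 1}\t{seg.end}\t{seg.sample}\n")
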