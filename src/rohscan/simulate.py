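"""Synthetic diploid genotypes with implanted autozygous tracts.

The generator emulates dense resequencing-derived SNP genotypes for a small
population: shared SNP positions with roughly geometric inter-SNP spacing,
per-sample autozygous tracts whose total length realises a requested genome
fraction exactly, heterozygous-call errors inside tracts, background
heterozygosity outside them, and missing calls anywhere. Ground-truth tract
coordinates are returned so caller sensitivity and inbreeding-coefficient
recovery can be measured against a known answer.

Tract lengths are exponential with a configurable mean, floored at a
minimum; the last tract is trimmed so per-chromosome tract length sums to
``round(target * chrom_length)``. Tracts (plus any fixed implanted regions)
are separated by Dirichlet-distributed gaps over the remaining free space —
placement is non-overlapping by construction and remains well-defined at
autozygosity up to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import HET, HOM, MISSING, ChromosomeSites, GenotypeMatrix


@dataclass(frozen=True)
class TruthTract:
    """A simulated autozygous interval (1-based inclusive), ground truth."""

    sample: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("tract start > end")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ImplantRegion:
    """A fixed region made autozygous in a given fraction of samples.

    Used to build ROH-island scenarios: the same interval is implanted in
    ``round(carrier_fraction * n_samples)`` samples on top of each sample's
    random background tracts.
    """

    chrom: str
    start: int
    end: int
    carrier_fraction: float = 1.0


@dataclass
class SimulationConfig:
    """Parameters of the synthetic genotype generator.

    Defaults describe a desk-scale analogue of a small conserved pig
    population genotyped by ~10x resequencing: 20 diploid samples, dense
    SNPs (mean spacing 500 bp), strongly inbred genomes (half the genome
    autozygous), tracts of mean 2 Mb, a low heterozygous-error rate inside
    tracts and realistic background heterozygosity outside them.
    """

    n_samples: int = 20
    chromosomes: list[tuple[str, int]] = field(
        default_factory=lambda: [("1", 20_000_000), ("2", 15_000_000)]
    )
    snp_spacing_bp: float = 500.0
    target_autozygosity: float | list[float] = 0.5
    tract_mean_bp: float = 2_000_000.0
    tract_min_bp: int = 100_000
    het_error_rate: float = 0.001
    missing_rate: float = 0.002
    background_het_rate: float = 0.25
    low_quality_rate: float = 0.0
    implant_regions: list[ImplantRegion] = field(default_factory=list)
    seed: int = 0

    def per_sample_targets(self) -> list[float]:
        if isinstance(self.target_autozygosity, (int, float)):
            return [float(self.target_autozygosity)] * self.n_samples
        targets = [float(t) for t in self.target_autozygosity]
        if len(targets) != self.n_samples:
            raise ValueError("per-sample target list length != n_samples")
        return targets

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be >= 1")
        if not self.chromosomes:
            raise ValueError("at least one chromosome is required")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name}: length must be > 0")
        for t in self.per_sample_targets():
            if not 0.0 <= t <= 1.0:
                raise ValueError("target_autozygosity must be in [0, 1]")
        for rate in (self.het_error_rate, self.missing_rate,
                     self.background_het_rate, self.low_quality_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.snp_spacing_bp < 1:
            raise ValueError("snp_spacing_bp must be >= 1")
        if self.tract_min_bp < 1 or self.tract_mean_bp < self.tract_min_bp:
            raise ValueError("need tract_mean_bp >= tract_min_bp >= 1")
        chrom_len = dict(self.chromosomes)
        for region in self.implant_regions:
            if region.chrom not in chrom_len:
                raise ValueError(f"implant region on unknown chromosome {region.chrom}")
            if not (1 <= region.start <= region.end <= chrom_len[region.chrom]):
                raise ValueError("implant region outside chromosome bounds")
            if not 0.0 <= region.carrier_fraction <= 1.0:
                raise ValueError("carrier_fraction must be in [0, 1]")


def _draw_tract_lengths(total: int, mean: float, minimum: int,
                        rng: np.random.Generator) -> list[int]:
    """Exponential(mean) lengths floored at `minimum`, trimmed to sum to `total`."""
    if total <= 0:
        return []
    lengths: list[int] = []
    acc = 0
    while acc < total:
        length = max(int(round(rng.exponential(mean))), minimum)
        lengths.append(length)
        acc += length
    excess = acc - total
    # take the excess out of the last tract; if that would erase it, fold the
    # remainder into the previous tract instead
    if lengths[-1] - excess >= minimum or len(lengths) == 1:
        lengths[-1] = max(lengths[-1] - excess, 1)
    else:
        lengths.pop()
        lengths[-1] += total - sum(lengths)
    return lengths


def _place_in_interval(lo: int, hi: int, lengths: list[int],
                       rng: np.random.Generator) -> list[tuple[int, int]]:
    """Place non-overlapping tracts of given lengths inside [lo, hi]."""
    if not lengths:
        return []
    span = hi - lo + 1
    free = span - sum(lengths)
    if free < 0:
        raise ValueError("tracts exceed interval capacity")
    k = len(lengths)
    if free == 0:
        gaps = np.zeros(k + 1, dtype=np.int64)
    else:
        weights = rng.dirichlet(np.ones(k + 1))
        gaps = np.floor(weights * free).astype(np.int64)
        gaps[-1] += free - gaps.sum()
    order = rng.permutation(k)
    placed = []
    cursor = lo
    for j, idx in enumerate(order):
        cursor += int(gaps[j])
        placed.append((cursor, cursor + lengths[idx] - 1))
        cursor += lengths[idx]
    return placed


def _sample_tracts(chrom: str, chrom_len: int, target: float,
                   fixed: list[tuple[int, int]], cfg: SimulationConfig,
                   rng: np.random.Generator) -> list[tuple[int, int]]:
    """Background tracts realising `target` of the chromosome, avoiding `fixed`."""
    total = int(round(target * chrom_len))
    if target >= 1.0:
        # saturation: a single tract covers the chromosome
        return [(1, chrom_len)]
    lengths = _draw_tract_lengths(total, cfg.tract_mean_bp, cfg.tract_min_bp, rng)
    fixed = sorted(fixed)
    # free intervals: complement of the fixed regions
    free_ivs: list[tuple[int, int]] = []
    cursor = 1
    for s, e in fixed:
        if s > cursor:
            free_ivs.append((cursor, s - 1))
        cursor = e + 1
    if cursor <= chrom_len:
        free_ivs.append((cursor, chrom_len))
    # assign each tract to a free interval with probability proportional to
    # remaining capacity; trim tracts that no interval can hold
    capacity = [e - s + 1 for s, e in free_ivs]
    assigned: list[list[int]] = [[] for _ in free_ivs]
    for length in sorted(lengths, reverse=True):
        options = [i for i, cap in enumerate(capacity) if cap >= length]
        if not options:
            big = int(np.argmax(capacity))
            if capacity[big] <= 0:
                continue
            length = capacity[big]
            options = [big]
        probs = np.array([capacity[i] for i in options], dtype=float)
        choice = options[rng.choice(len(options), p=probs / probs.sum())]
        assigned[choice].append(length)
        capacity[choice] -= length
    tracts = list(fixed)
    for (lo, hi), lens in zip(free_ivs, assigned):
        tracts.extend(_place_in_interval(lo, hi, lens, rng))
    return sorted(tracts)


def _snp_positions(chrom_len: int, spacing: float,
                   rng: np.random.Generator) -> np.ndarray:
    p = min(1.0, 1.0 / spacing)
    n_guess = int(chrom_len / spacing * 1.3) + 16
    positions: list[int] = []
    pos = 0
    while pos < chrom_len:
        steps = rng.geometric(p, size=n_guess)
        for step in steps:
            pos += int(step)
            if pos > chrom_len:
                break
            positions.append(pos)
        else:
            continue
        break
    return np.array(positions, dtype=np.int64)


def simulate_genotypes(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, list[TruthTract]]:
    """Generate a genotype matrix plus the ground-truth autozygous tracts.

    Within a truth tract a site is homozygous except with probability
    ``het_error_rate`` (called het) and ``missing_rate`` (missing); outside
    tracts sites are het with ``background_het_rate``. The realised
    autozygous fraction per sample equals the target up to integer rounding.
    Identical configs (same seed) produce identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    samples = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    targets = config.per_sample_targets()

    # which samples carry each implanted region (deterministic given seed)
    implant_carriers: list[np.ndarray] = []
    for region in config.implant_regions:
        k = int(round(region.carrier_fraction * config.n_samples))
        implant_carriers.append(rng.choice(config.n_samples, size=k, replace=False))

    truth: list[TruthTract] = []
    chromosomes: dict[str, ChromosomeSites] = {}
    for chrom, chrom_len in config.chromosomes:
        positions = _snp_positions(chrom_len, config.snp_spacing_bp, rng)
        n_sites = positions.size
        # 2-dp qualities so the VCF fixture round-trips exactly
        qual = np.round(rng.uniform(20.0, 60.0, size=n_sites), 2)
        if config.low_quality_rate > 0:
            low = rng.random(n_sites) < config.low_quality_rate
            qual[low] = np.round(rng.uniform(0.0, 9.99, size=int(low.sum())), 2)
        calls = np.empty((config.n_samples, n_sites), dtype=np.int8)
        for si, sample in enumerate(samples):
            fixed = [
                (r.start, r.end)
                for r, carriers in zip(config.implant_regions, implant_carriers)
                if r.chrom == chrom and si in carriers
            ]
            tracts = _sample_tracts(chrom, chrom_len, targets[si], fixed,
                                    config, rng)
            in_tract = np.zeros(n_sites, dtype=bool)
            for s, e in tracts:
                lo = np.searchsorted(positions, s, side="left")
                hi = np.searchsorted(positions, e, side="right")
                in_tract[lo:hi] = True
                truth.append(TruthTract(sample=sample, chrom=chrom, start=s, end=e))
            u = rng.random(n_sites)
            row = np.where(
                in_tract,
                np.where(u < config.het_error_rate, HET, HOM),
                np.where(u < config.background_het_rate, HET, HOM),
            ).astype(np.int8)
            miss = rng.random(n_sites) < config.missing_rate
            row[miss] = MISSING
            calls[si] = row
        chromosomes[chrom] = ChromosomeSites(positions, qual, calls)

    truth.sort(key=lambda t: (t.sample, t.chrom, t.start))
    return GenotypeMatrix(samples=samples, chromosomes=chromosomes), truth


def realized_autozygosity(truth: list[TruthTract],
                          chromosomes: list[tuple[str, int]]) -> dict[str, float]:
    """Per-sample fraction of the genome inside truth tracts."""
    genome = sum(length for _, length in chromosomes)
    totals: dict[str, int] = {}
    for t in truth:
        totals[t.sample] = totals.get(t.sample, 0) + t.length_bp
    return {s: total / genome for s, total in totals.items()}


def write_fixture_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix as a minimal but valid VCF v4.2 fixture.

    Zygosity is all downstream stages use, so alleles are fixed as A (ref)
    and G (alt): HOM -> 0/0, HET -> 0/1, MISSING -> ./. ; QUAL carries the
    per-site quality. Round-trips through :func:`rohscan.io.read_vcf`.
    """
    if matrix.n_samples == 0 or matrix.n_sites == 0:
        raise ValueError("refusing to write an empty fixture VCF")
    gt_map = {HOM: "0/0", HET: "0/1", MISSING: "./."}
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rohscan-simulate\n")
        for chrom, sites in matrix.chromosomes.items():
            max_pos = int(sites.positions[-1]) if sites.n_sites else 0
            fh.write(f"##contig=<ID={chrom},length={max_pos + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.samples) + "\n")
        for chrom, sites in matrix.chromosomes.items():
            for j in range(sites.n_sites):
                gts = "\t".join(gt_map[int(sites.calls[i, j])]
                                for i in range(matrix.n_samples))
                fh.write(
                    f"{chrom}\t{int(sites.positions[j])}\t.\tA\tG\t"
                    f"{sites.site_quality[j]:.2f}\t.\t.\tGT\t{gts}\n"
                )


def write_truth_bed(truth: list[TruthTract], path: str | Path) -> None:
    """Write truth tracts as BED (0-based half-open), name = sample id."""
    with open(path, "w") as fh:
        for t in truth:
            fh.write(f"{t.chrom}\t{t.start - 1}\t{t.end}\t{t.sample}\n")
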