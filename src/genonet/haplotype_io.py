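"""Phased variant input/output and binary haplotype encoding.

Phased diploid samples contribute two independent haplotype rows each.  Every
retained site is a biallelic SNV; alleles are encoded 0 (reference) / 1
(alternative), so a window of k sites maps each haplotype to a binary string
of length k — the coordinates of a vertex in the k-dimensional genotype space.

Two minor-allele-frequency filter modes are supported, because real-data and
simulation protocols differ:

``global``
    minor-allele frequency computed over all haplotypes pooled must reach the
    threshold (the 1000 Genomes-style filter);
``any_population``
    the frequency must reach the threshold in at least one population (the
    simulation filter: a site is dropped only when it is rare everywhere).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SiteRecord",
    "HaplotypeMatrix",
    "FilterStats",
    "load_phased_vcf",
    "load_ms_matrix",
    "genotype_strings",
    "maf_filter",
    "write_vcf",
    "write_ms",
]

logger = logging.getLogger(__name__)

ANNOTATION_CLASSES = ("coding", "noncoding", "none")


@dataclass(frozen=True)
class SiteRecord:
    """One biallelic SNV site."""

    chromosome: str
    position: int  # 1-based, as in VCF
    ref_allele: str = "A"
    alt_allele: str = "G"
    annotation_class: str = "none"

    def __post_init__(self):
        if self.annotation_class not in ANNOTATION_CLASSES:
            raise ValueError(
                f"annotation_class must be one of {ANNOTATION_CLASSES}, "
                f"got {self.annotation_class!r}"
            )


@dataclass
class FilterStats:
    """Counts of sites dropped at each filtering step."""

    non_snv: int = 0
    multiallelic: int = 0
    unphased: int = 0
    missing: int = 0
    low_maf: int = 0
    low_coverage: int = 0

    def total(self) -> int:
        return (
            self.non_snv + self.multiallelic + self.unphased
            + self.missing + self.low_maf + self.low_coverage
        )

    def as_dict(self) -> dict:
        return {
            "non_snv": self.non_snv,
            "multiallelic": self.multiallelic,
            "unphased": self.unphased,
            "missing": self.missing,
            "low_maf": self.low_maf,
            "low_coverage": self.low_coverage,
        }


@dataclass
class HaplotypeMatrix:
    """Phased binary haplotypes over an ordered list of SNV sites.

    ``alleles`` has one row per haplotype and one column per site, entries in
    {0, 1}.  Haplotypes from a diploid VCF appear sample-by-sample, left
    haplotype then right.  ``population_labels`` assigns one label per row.
    """

    sites: list[SiteRecord]
    alleles: np.ndarray
    population_labels: np.ndarray
    filter_stats: FilterStats = field(default_factory=FilterStats)

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        self.population_labels = np.asarray(self.population_labels, dtype=object)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix (haplotypes x sites)")
        if self.alleles.shape[1] != len(self.sites):
            raise ValueError(
                f"alleles has {self.alleles.shape[1]} columns but {len(self.sites)} sites given"
            )
        if self.alleles.shape[0] != len(self.population_labels):
            raise ValueError("one population label per haplotype row is required")
        if self.alleles.size and self.alleles.max() > 1:
            raise ValueError("allele matrix entries must be 0 or 1")
        # positions strictly increasing within each chromosome
        last: dict[str, int] = {}
        for s in self.sites:
            if s.chromosome in last and s.position <= last[s.chromosome]:
                raise ValueError(
                    f"site positions must strictly increase within a chromosome "
                    f"({s.chromosome}:{s.position} after {last[s.chromosome]})"
                )
            last[s.chromosome] = s.position

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.sites], dtype=np.int64)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.array([s.chromosome for s in self.sites], dtype=object)

    def populations(self) -> list[str]:
        """Distinct population labels in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.population_labels:
            seen.setdefault(p)
        return list(seen)

    def rows_for_population(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.population_labels == label)

    def subset_rows(self, rows: Sequence[int]) -> "HaplotypeMatrix":
        rows = np.asarray(rows, dtype=np.intp)
        return HaplotypeMatrix(
            sites=self.sites,
            alleles=self.alleles[rows],
            population_labels=self.population_labels[rows],
        )

    def subset_sites(self, cols: Sequence[int]) -> "HaplotypeMatrix":
        cols = np.asarray(cols, dtype=np.intp)
        return HaplotypeMatrix(
            sites=[self.sites[int(c)] for c in cols],
            alleles=self.alleles[:, cols],
            population_labels=self.population_labels,
        )

    def with_annotations(self, table: Mapping[tuple[str, int], str]) -> "HaplotypeMatrix":
        """Return a copy whose sites carry annotation classes from a
        (chromosome, position) -> class mapping; absent sites keep 'none'."""
        sites = [
            replace(s, annotation_class=table.get((s.chromosome, s.position), s.annotation_class))
            for s in self.sites
        ]
        return HaplotypeMatrix(sites, self.alleles, self.population_labels, self.filter_stats)


def genotype_strings(matrix: HaplotypeMatrix, start: int, stop: int) -> list[str]:
    """Binary genotype strings of the site range [start, stop), one per
    haplotype row, duplicates preserved.  Ranges are forward only."""
    if not (0 <= start < stop <= matrix.n_sites):
        raise ValueError(
            f"invalid site range [{start}, {stop}) for {matrix.n_sites} sites "
            "(ranges are forward, non-empty, within bounds)"
        )
    block = matrix.alleles[:, start:stop]
    digits = np.array(["0", "1"])
    return ["".join(row) for row in digits[block]]


def _minor_freq(counts: np.ndarray, n: int) -> np.ndarray:
    freq = counts / n
    return np.minimum(freq, 1.0 - freq)


def maf_filter(
    matrix: HaplotypeMatrix, threshold: float, mode: str
) -> tuple[HaplotypeMatrix, int]:
    """Drop sites below the minor-allele-frequency threshold.

    Returns the filtered matrix and the number of sites dropped.  The filter
    is idempotent.  ``mode`` is required: 'global' or 'any_population'.
    """
    if mode not in ("global", "any_population"):
        raise ValueError(f"maf_mode must be 'global' or 'any_population', got {mode!r}")
    if matrix.n_sites == 0:
        return matrix, 0
    if mode == "global":
        maf = _minor_freq(matrix.alleles.sum(axis=0), matrix.n_haplotypes)
        keep = maf >= threshold
    else:
        keep = np.zeros(matrix.n_sites, dtype=bool)
        for pop in matrix.populations():
            rows = matrix.rows_for_population(pop)
            maf = _minor_freq(matrix.alleles[rows].sum(axis=0), len(rows))
            keep |= maf >= threshold
    dropped = int((~keep).sum())
    if dropped == 0:
        return matrix, 0
    return matrix.subset_sites(np.flatnonzero(keep)), dropped


def load_phased_vcf(
    path: str,
    maf_threshold: float,
    maf_mode: str,
    populations: Mapping[str, str] | None = None,
    annotations: Mapping[tuple[str, int], str] | None = None,
    min_info_coverage: float | None = None,
    coverage_info_field: str = "DP",
) -> HaplotypeMatrix:
    """Load phased biallelic SNVs from a VCF into a HaplotypeMatrix.

    Sites that are not biallelic SNVs, or that carry any unphased or missing
    genotype among retained samples, are dropped and counted in the returned
    matrix's ``filter_stats``.  The MAF filter then runs in the requested
    mode.  ``populations`` maps sample name -> population label; when given,
    only mapped samples are retained.  ``min_info_coverage`` optionally drops
    sites whose INFO ``coverage_info_field`` is below the given value (off by
    default; most VCFs do not carry a standardized per-site coverage).

    Zero surviving sites is not an error: an empty matrix is returned.
    """
    from cyvcf2 import VCF

    if maf_mode not in ("global", "any_population"):
        raise ValueError(f"maf_mode must be 'global' or 'any_population', got {maf_mode!r}")

    vcf = VCF(path)
    samples = list(vcf.samples)
    if populations is not None:
        missing_samples = set(populations) - set(samples)
        if missing_samples:
            raise ValueError(f"samples not in VCF header: {sorted(missing_samples)}")
        keep_idx = [i for i, s in enumerate(samples) if s in populations]
        labels_per_sample = [populations[samples[i]] for i in keep_idx]
    else:
        keep_idx = list(range(len(samples)))
        labels_per_sample = ["ALL"] * len(samples)
    if not keep_idx:
        raise ValueError("no samples retained")

    stats = FilterStats()
    sites: list[SiteRecord] = []
    columns: list[np.ndarray] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            stats.multiallelic += 1
            continue
        if len(variant.REF) != 1 or len(variant.ALT[0]) != 1:
            stats.non_snv += 1
            continue
        if min_info_coverage is not None:
            cov = variant.INFO.get(coverage_info_field)
            if cov is None or float(cov) < min_info_coverage:
                stats.low_coverage += 1
                continue
        gts = variant.genotypes  # per sample: [allele_a, allele_b, phased]
        col = np.empty(2 * len(keep_idx), dtype=np.int16)
        unphased = False
        missing = False
        for j, i in enumerate(keep_idx):
            g = gts[i]
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                missing = True
                break
            if len(g) >= 3 and not g[2]:
                unphased = True
                break
            col[2 * j] = a
            col[2 * j + 1] = b
        if missing:
            stats.missing += 1
            continue
        if unphased:
            stats.unphased += 1
            continue
        if col.max() > 1:
            stats.multiallelic += 1
            continue
        sites.append(
            SiteRecord(
                chromosome=str(variant.CHROM),
                position=int(variant.POS),
                ref_allele=variant.REF,
                alt_allele=variant.ALT[0],
            )
        )
        columns.append(col.astype(np.uint8))

    n_haps = 2 * len(keep_idx)
    labels = np.array(
        [lab for lab in labels_per_sample for _ in range(2)], dtype=object
    )
    alleles = (
        np.column_stack(columns) if columns else np.empty((n_haps, 0), dtype=np.uint8)
    )
    matrix = HaplotypeMatrix(sites=sites, alleles=alleles, population_labels=labels)
    matrix, dropped = maf_filter(matrix, maf_threshold, maf_mode)
    stats.low_maf = dropped
    if annotations:
        matrix = matrix.with_annotations(annotations)
    matrix.filter_stats = stats
    if matrix.n_sites == 0:
        logger.warning("no sites survived filtering of %s", path)
    logger.info(
        "loaded %s: %d haplotypes x %d sites (dropped: %s)",
        path, matrix.n_haplotypes, matrix.n_sites, stats.as_dict(),
    )
    return matrix


def load_ms_matrix(
    path: str,
    population_sizes: Sequence[int],
    region_length_bp: int = 1_000_000,
    chromosome: str = "sim1",
) -> HaplotypeMatrix:
    """Read an ms-style haplotype block (``segsites:``/``positions:`` header
    followed by 0/1 rows).

    Fractional positions are scaled onto ``region_length_bp``; population
    labels P0, P1, ... are assigned to contiguous row blocks of the given
    sizes.  Only the first replicate block in the file is read.
    """
    positions: list[float] | None = None
    rows: list[str] = []
    n_expected: int | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("segsites:"):
                if n_expected is not None:  # second replicate block: stop
                    break
                n_expected = int(line.split(":")[1])
            elif line.startswith("positions:"):
                positions = [float(x) for x in line.split(":")[1].split()]
            elif line and set(line) <= {"0", "1"} and positions is not None:
                rows.append(line)
    if positions is None or n_expected is None:
        raise ValueError(f"{path}: not an ms-format block (no segsites/positions header)")
    if any(len(r) != n_expected for r in rows):
        raise ValueError(f"{path}: inconsistent haplotype row lengths")
    if sum(population_sizes) != len(rows):
        raise ValueError(
            f"population_sizes sum to {sum(population_sizes)} but block has {len(rows)} haplotypes"
        )
    # scale to integer bp, strictly increasing
    pos_bp = []
    prev = 0
    for p in positions:
        bp = max(prev + 1, int(round(p * region_length_bp)))
        pos_bp.append(bp)
        prev = bp
    sites = [SiteRecord(chromosome=chromosome, position=p) for p in pos_bp]
    alleles = np.array([[int(c) for c in r] for r in rows], dtype=np.uint8)
    labels = np.concatenate(
        [np.full(n, f"P{i}", dtype=object) for i, n in enumerate(population_sizes)]
    )
    return HaplotypeMatrix(sites=sites, alleles=alleles, population_labels=labels)


def write_vcf(matrix: HaplotypeMatrix, path: str, sample_prefix: str = "S") -> None:
    """Write the matrix as a phased VCF v4.2 text file.

    Consecutive haplotype row pairs become one diploid sample, so the row
    count must be even.  Reloading with filters disabled round-trips the
    allele matrix exactly.
    """
    if matrix.n_haplotypes % 2:
        raise ValueError("VCF export needs an even number of haplotype rows (diploid samples)")
    n_samples = matrix.n_haplotypes // 2
    names = [f"{sample_prefix}{i:05d}" for i in range(n_samples)]
    contigs: dict[str, int] = {}
    for s in matrix.sites:
        contigs[s.chromosome] = max(contigs.get(s.chromosome, 0), s.position)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=genonet\n")
        for chrom, length in contigs.items():
            fh.write(f"##contig=<ID={chrom},length={length + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(names) + "\n")
        for j, site in enumerate(matrix.sites):
            col = matrix.alleles[:, j]
            gts = "\t".join(f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(n_samples))
            fh.write(
                f"{site.chromosome}\t{site.position}\t.\t{site.ref_allele}\t"
                f"{site.alt_allele}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_ms(matrix: HaplotypeMatrix, path: str, region_length_bp: int | None = None) -> None:
    """Write the matrix as a single ms-style replicate block."""
    if region_length_bp is None:
        region_length_bp = int(matrix.positions.max()) + 1 if matrix.n_sites else 1
    with open(path, "w") as fh:
        fh.write("genonet ms export\n\n//\n")
        fh.write(f"segsites: {matrix.n_sites}\n")
        pos = " ".join(f"{p / region_length_bp:.6f}" for p in matrix.positions)
        fh.write(f"positions: {pos}\n")
        for row in matrix.alleles:
            fh.write("".join(str(int(x)) for x in row) + "\n")
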