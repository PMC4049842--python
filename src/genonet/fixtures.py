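"""Small deterministic fixture files for tests and demonstrations.

Everything is plain text and byte-identical for a given seed: phased VCFs
(including a five-SNV toy whose haplotypes form a three-node path network,
and a filter-exercise VCF with known triallelic/unphased/missing/rare
sites), an annotation table, a genetic map, a BED mask, and an ms-format
block.
"""

from __future__ import annotations

import os

import numpy as np

__all__ = ["make_fixtures", "TOY_HAPLOTYPES", "FILTER_VCF_EXPECTED"]

# Two diploid samples; four haplotypes carrying three distinct genotypes
# that form the path 00000 - 00001 - 01001 (average path length 4/3).
TOY_HAPLOTYPES = ("00000", "00001", "01001", "00000")

# The filter VCF has 10 sites over 100 diploid samples (200 haplotypes):
# one triallelic, one unphased, one with a missing call, and one singleton
# (MAF 0.005 < 0.01); six sites survive a global MAF 0.01 filter.
FILTER_VCF_EXPECTED = {
    "n_sites_in": 10,
    "multiallelic": 1,
    "unphased": 1,
    "missing": 1,
    "low_maf": 1,
    "n_sites_out": 6,
}


def _write(path: str, text: str) -> None:
    with open(path, "w") as fh:
        fh.write(text)


def _toy_vcf() -> str:
    haps = TOY_HAPLOTYPES
    lines = [
        "##fileformat=VCFv4.2",
        "##source=genonet-fixtures",
        "##contig=<ID=chr1,length=2000>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tIND1\tIND2",
    ]
    positions = [100, 350, 600, 850, 1100]
    for j, pos in enumerate(positions):
        g1 = f"{haps[0][j]}|{haps[1][j]}"
        g2 = f"{haps[2][j]}|{haps[3][j]}"
        lines.append(f"chr1\t{pos}\t.\tA\tG\t.\tPASS\t.\tGT\t{g1}\t{g2}")
    return "\n".join(lines) + "\n"


def _filter_vcf(seed: int) -> str:
    rng = np.random.default_rng(seed)
    n_samples = 100
    n_haps = 2 * n_samples
    positions = [1000 + 500 * j for j in range(10)]
    # common biallelic columns (MAF ~ 0.3)
    cols = (rng.random((n_haps, 10)) < 0.3).astype(int)
    # site index 2: singleton alternative allele -> MAF 0.005
    cols[:, 2] = 0
    cols[0, 2] = 1
    header = [
        "##fileformat=VCFv4.2",
        "##source=genonet-fixtures",
        "##contig=<ID=chr2,length=10000>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(f"S{i:03d}" for i in range(n_samples)),
    ]
    lines = []
    for j, pos in enumerate(positions):
        alt = "G"
        gts = []
        for i in range(n_samples):
            a, b = cols[2 * i, j], cols[2 * i + 1, j]
            sep = "|"
            if j == 5 and i == 0:
                sep = "/"  # unphased genotype -> site dropped
            if j == 7 and i == 3:
                a = "."  # missing call -> site dropped
            gts.append(f"{a}{sep}{b}")
        if j == 4:
            alt = "G,T"  # triallelic -> site dropped
        lines.append(f"chr2\t{pos}\t.\tA\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts))
    return "\n".join(header + lines) + "\n"


def _annotations() -> str:
    rows = ["# chromosome\tposition\tclass"]
    classes = ["coding", "none", "noncoding", "coding", "none"]
    for pos, cls in zip([100, 350, 600, 850, 1100], classes):
        rows.append(f"chr1\t{pos}\t{cls}")
    return "\n".join(rows) + "\n"


def _genetic_map() -> str:
    rows = ["# chromosome\tposition\tcM"]
    for pos, cm in [(0, 0.0), (500, 0.02), (1000, 0.05), (2000, 0.2)]:
        rows.append(f"chr1\t{pos}\t{cm}")
    return "\n".join(rows) + "\n"


def _mask_bed() -> str:
    return "chr1\t340\t360\n"


def _ms_block() -> str:
    return (
        "ms 4 1\n\n//\n"
        "segsites: 3\n"
        "positions: 0.1 0.5 0.9\n"
        "010\n011\n000\n110\n"
    )


def make_fixtures(out_dir: str, seed: int = 0) -> dict[str, str]:
    """Write all fixture files into ``out_dir``; returns name -> path.

    Regeneration with the same seed is byte-identical.
    """
    os.makedirs(out_dir, exist_ok=True)
    files = {
        "toy.vcf": _toy_vcf(),
        "filters.vcf": _filter_vcf(seed),
        "annotations.tsv": _annotations(),
        "genetic_map.tsv": _genetic_map(),
        "mask.bed": _mask_bed(),
        "example.ms": _ms_block(),
    }
    paths = {}
    for name, text in files.items():
        path = os.path.join(out_dir, name)
        _write(path, text)
        paths[name] = path
    return paths


def load_annotation_table(path: str) -> dict[tuple[str, int], str]:
    """Read a chromosome/position/class table into the mapping accepted by
    the VCF loader."""
    table: dict[tuple[str, int], str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, pos, cls = line.split("\t")
            table[(chrom, int(pos))] = cls
    return table
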