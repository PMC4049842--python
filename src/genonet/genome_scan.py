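"""Sliding-window genome scan of genotype-network properties.

Windows contain a fixed number of SNVs (default 11), slide by a fixed number
of SNVs (default 1, maximal overlap), and never span chromosomes.  For each
window one network is built per population plus one over all haplotypes
pooled (the GLOBAL population).  Window spans are reported as 1-based closed
intervals [first SNV position, last SNV position]; emitted browser tracks
use the 0-based half-open BED/bedGraph conventions.

A window's annotation class summarises its sites: ``coding`` (at least one
coding SNV, no non-coding), ``noncoding`` (the reverse), ``both``, or
``no_annotation`` (no annotated SNV at all; excluded from downstream class
comparisons).

The recombination covariable is the genetic-map distance (cM) between the
first and last SNV of the window, linearly interpolated from a user-supplied
map; positions outside the map are extrapolated to the nearest endpoint and
counted.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .haplotype_io import HaplotypeMatrix, SiteRecord
from .network_core import PROPERTY_NAMES, properties_packed

__all__ = [
    "WindowSpec",
    "GeneticMap",
    "iter_windows",
    "scan",
    "classify_window",
    "load_bed",
    "apply_masks",
    "top_regions",
    "write_tracks",
    "write_scan_tsv",
    "window_size_sweep",
    "GLOBAL",
]

logger = logging.getLogger(__name__)

GLOBAL = "GLOBAL"

ANNOTATION_WINDOW_CLASSES = ("coding", "both", "noncoding", "no_annotation")


@dataclass(frozen=True)
class WindowSpec:
    """A window of k consecutive SNVs on one chromosome."""

    chromosome: str
    first_site_index: int  # index into the matrix's site list
    k: int
    step: int
    start: int  # 1-based position of first SNV
    end: int  # 1-based position of last SNV (closed interval)
    recomb_cM: float = np.nan

    @property
    def span_bp(self) -> int:
        return self.end - self.start


class GeneticMap:
    """Piecewise-linear position -> cumulative cM map per chromosome."""

    def __init__(self, table: pd.DataFrame):
        # columns: chromosome, position, cM
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, grp in table.groupby("chromosome", sort=False):
            grp = grp.sort_values("position")
            self._by_chrom[str(chrom)] = (
                grp["position"].to_numpy(dtype=float),
                grp["cM"].to_numpy(dtype=float),
            )
        self.n_extrapolated = 0

    @classmethod
    def from_file(cls, path: str) -> "GeneticMap":
        """Three-column whitespace/tab file: chromosome, position, cumulative cM."""
        table = pd.read_csv(
            path,
            sep=r"\s+",
            comment="#",
            names=["chromosome", "position", "cM"],
            dtype={"chromosome": str},
        )
        return cls(table)

    def interpolate(self, chromosome: str, positions: np.ndarray) -> np.ndarray:
        """Cumulative cM at each position; nearest-endpoint extrapolation
        outside the mapped range (occurrences counted)."""
        if chromosome not in self._by_chrom:
            raise KeyError(f"chromosome {chromosome!r} not in genetic map")
        xs, ys = self._by_chrom[chromosome]
        positions = np.asarray(positions, dtype=float)
        outside = int(((positions < xs[0]) | (positions > xs[-1])).sum())
        if outside:
            self.n_extrapolated += outside
            logger.warning(
                "%d position(s) outside genetic map on %s; nearest-endpoint extrapolation",
                outside, chromosome,
            )
        return np.interp(positions, xs, ys)


def classify_window(sites: Sequence[SiteRecord]) -> str:
    """Annotation class of a window from its sites' per-SNV classes."""
    has_coding = any(s.annotation_class == "coding" for s in sites)
    has_noncoding = any(s.annotation_class == "noncoding" for s in sites)
    if has_coding and has_noncoding:
        return "both"
    if has_coding:
        return "coding"
    if has_noncoding:
        return "noncoding"
    return "no_annotation"


def iter_windows(
    matrix: HaplotypeMatrix,
    k: int,
    step: int = 1,
    genetic_map: GeneticMap | None = None,
) -> Iterator[WindowSpec]:
    """Windows of k SNVs at site-index offsets 0, step, 2·step, ... per
    chromosome; a trailing partial window is discarded.  If k exceeds a
    chromosome's site count that chromosome yields no windows (warning)."""
    if k < 2:
        raise ValueError("window size k must be at least 2")
    if step < 1:
        raise ValueError("step must be at least 1")
    chroms = matrix.chromosomes
    positions = matrix.positions
    for chrom in dict.fromkeys(chroms):  # unique, order-preserving
        idx = np.flatnonzero(chroms == chrom)
        if len(idx) < k:
            logger.warning(
                "chromosome %s has %d sites (< k=%d); no windows", chrom, len(idx), k
            )
            continue
        cm = None
        if genetic_map is not None:
            cm = genetic_map.interpolate(str(chrom), positions[idx])
        for off in range(0, len(idx) - k + 1, step):
            first = int(idx[off])
            last = int(idx[off + k - 1])
            yield WindowSpec(
                chromosome=str(chrom),
                first_site_index=first,
                k=k,
                step=step,
                start=int(positions[first]),
                end=int(positions[last]),
                recomb_cM=(
                    float(cm[off + k - 1] - cm[off]) if cm is not None else np.nan
                ),
            )


def _pack_weights(k: int) -> np.ndarray:
    if k > 63:
        raise ValueError(f"window size {k} exceeds the supported maximum of 63")
    return (np.uint64(1) << np.arange(k, dtype=np.uint64)).astype(np.uint64)


def scan(
    matrix: HaplotypeMatrix,
    k: int = 11,
    step: int = 1,
    genetic_map: GeneticMap | None = None,
    include_global: bool = True,
) -> pd.DataFrame:
    """Per-window, per-population genotype-network properties.

    Returns the long-form ScanResult table: one row per window x population,
    with the GLOBAL row computed over all haplotypes pooled.  Columns:
    chromosome, first_site_index, k, step, start, end, span_bp, recomb_cM,
    annotation_class, population, and the five property columns (undefined
    average path length is NaN).
    """
    pops = matrix.populations()
    groups: list[tuple[str, np.ndarray | slice]] = [
        (p, matrix.rows_for_population(p)) for p in pops
    ]
    if include_global and (len(pops) > 1 or GLOBAL not in pops):
        groups.append((GLOBAL, slice(None)))
    rows = []
    for win in iter_windows(matrix, k=k, step=step, genetic_map=genetic_map):
        cols = matrix.alleles[:, win.first_site_index : win.first_site_index + k]
        packed = cols.astype(np.uint64) @ _pack_weights(k)
        ann = classify_window(
            matrix.sites[win.first_site_index : win.first_site_index + k]
        )
        base = {
            "chromosome": win.chromosome,
            "first_site_index": win.first_site_index,
            "k": k,
            "step": step,
            "start": win.start,
            "end": win.end,
            "span_bp": win.span_bp,
            "recomb_cM": win.recomb_cM,
            "annotation_class": ann,
        }
        for label, sel in groups:
            props = properties_packed(packed[sel], k)
            rows.append({**base, "population": label, **props.as_dict()})
    result = pd.DataFrame(rows)
    if result.empty:
        result = pd.DataFrame(
            columns=[
                "chromosome", "first_site_index", "k", "step", "start", "end",
                "span_bp", "recomb_cM", "annotation_class", "population",
                *PROPERTY_NAMES,
            ]
        )
    return result


def load_bed(path: str) -> list[tuple[str, int, int]]:
    """Read BED intervals (0-based half-open); malformed lines raise with
    their line number."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line needs >=3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if start < 0 or end < start:
                raise ValueError(f"{path}:{lineno}: invalid BED interval [{start}, {end})")
            intervals.append((parts[0], start, end))
    return intervals


def apply_masks(
    result: pd.DataFrame,
    masks: Sequence[tuple[str, int, int]],
    matrix: HaplotypeMatrix,
) -> pd.DataFrame:
    """Remove every window with at least one SNV inside any mask interval.

    Masks are BED-convention (0-based half-open); a 1-based SNV position p
    is inside [start, end) when start < p <= end.  The matrix supplies the
    per-window SNV positions.
    """
    if result.empty or not masks:
        return result.copy()
    positions = matrix.positions
    chroms = matrix.chromosomes
    site_masked = np.zeros(len(positions), dtype=bool)
    for chrom, start, end in masks:
        on_chrom = chroms == chrom
        site_masked |= on_chrom & (positions > start) & (positions <= end)
    masked_idx = np.flatnonzero(site_masked)

    def window_hit(row) -> bool:
        lo = row["first_site_index"]
        hi = lo + row["k"]
        j = np.searchsorted(masked_idx, lo)
        return j < len(masked_idx) and masked_idx[j] < hi

    windows = result[["first_site_index", "k"]].drop_duplicates()
    bad = {
        int(r["first_site_index"])
        for _, r in windows.iterrows()
        if window_hit(r)
    }
    kept = result[~result["first_site_index"].isin(bad)].copy()
    logger.info(
        "masking removed %d of %d windows",
        len(bad), windows.shape[0],
    )
    return kept


def top_regions(
    result: pd.DataFrame,
    property_name: str,
    quantile: float = 0.999,
    population: str | None = None,
) -> pd.DataFrame:
    """Windows above the upper quantile of a property, overlap-merged into
    regions and ranked by value (ties at the threshold included).

    Supports the vertices_per_component composite (few components but many
    vertices).  ``population`` defaults to GLOBAL when present.
    """
    if property_name not in PROPERTY_NAMES:
        raise ValueError(
            f"unknown property {property_name!r}; choose from {PROPERTY_NAMES}"
        )
    if population is None:
        pops = result["population"].unique()
        population = GLOBAL if GLOBAL in pops else pops[0]
    sub = result[result["population"] == population].dropna(subset=[property_name])
    if sub.empty:
        raise ValueError("no windows available for top-region extraction")
    threshold = sub[property_name].quantile(quantile)
    hits = sub[sub[property_name] >= threshold].sort_values(
        ["chromosome", "start"]
    )
    regions = []
    current = None
    for _, row in hits.iterrows():
        if (
            current is not None
            and row["chromosome"] == current["chromosome"]
            and row["start"] <= current["end"]  # closed intervals overlap
        ):
            current["end"] = max(current["end"], row["end"])
            current["value"] = max(current["value"], row[property_name])
            current["n_windows"] += 1
        else:
            if current is not None:
                regions.append(current)
            current = {
                "chromosome": row["chromosome"],
                "start": int(row["start"]),
                "end": int(row["end"]),
                "value": float(row[property_name]),
                "n_windows": 1,
            }
    if current is not None:
        regions.append(current)
    out = pd.DataFrame(regions)
    out.insert(0, "property", property_name)
    out.insert(1, "population", population)
    return out.sort_values("value", ascending=False).reset_index(drop=True)


def write_tracks(
    result: pd.DataFrame,
    out_dir: str,
    top: pd.DataFrame | None = None,
) -> list[str]:
    """One bedGraph per property x population (0-based half-open spans);
    windows with an undefined property value are omitted from that track.
    An optional top-regions table is written as BED."""
    if result.empty:
        raise ValueError("cannot write tracks for an empty scan result")
    os.makedirs(out_dir, exist_ok=True)
    written = []
    for population, grp in result.groupby("population"):
        for prop in PROPERTY_NAMES:
            path = os.path.join(out_dir, f"{prop}.{population}.bedGraph")
            with open(path, "w") as fh:
                fh.write(
                    f'track type=bedGraph name="{prop} {population}"\n'
                )
                for _, row in grp.iterrows():
                    value = row[prop]
                    if pd.isna(value):
                        continue
                    # repr round-trips the float exactly
                    fh.write(
                        f"{row['chromosome']}\t{row['start'] - 1}\t{row['end']}\t{float(value)!r}\n"
                    )
            written.append(path)
    if top is not None and not top.empty:
        path = os.path.join(out_dir, "top_regions.bed")
        with open(path, "w") as fh:
            for _, row in top.iterrows():
                name = f"{row['property']}={row['value']:g}"
                fh.write(
                    f"{row['chromosome']}\t{row['start'] - 1}\t{row['end']}\t{name}\n"
                )
        written.append(path)
    return written


def write_scan_tsv(result: pd.DataFrame, path: str) -> None:
    result.to_csv(path, sep="\t", index=False, na_rep="NA")


def window_size_sweep(
    matrix: HaplotypeMatrix,
    k_values: Sequence[int] = tuple(range(5, 30, 2)),
    n_resamples: int = 5,
    resample_size: int = 370,
    seed: int | None = None,
    step: int = 1,
    include_global: bool = True,
) -> pd.DataFrame:
    """Mean network properties per window size and population, averaged over
    seeded random haplotype subsamples of fixed size.

    Emulates the window-size calibration: each (k, population) cell is the
    mean over ``n_resamples`` subsamples of ``resample_size`` haplotypes of
    the per-window property means.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    pops = matrix.populations()
    groups: list[tuple[str, np.ndarray]] = [
        (p, matrix.rows_for_population(p)) for p in pops
    ]
    if include_global and len(pops) > 1:
        groups.append((GLOBAL, np.arange(matrix.n_haplotypes)))
    for label, rows in groups:
        if resample_size > len(rows):
            raise ValueError(
                f"resample_size {resample_size} exceeds the {len(rows)} haplotypes of {label}"
            )
    records = []
    for label, rows in groups:
        draws = [
            rows
            if resample_size == len(rows)
            else rng.choice(rows, size=resample_size, replace=False)
            for _ in range(n_resamples)
        ]
        for k in k_values:
            per_resample = []
            for draw in draws:
                sub = matrix.subset_rows(np.sort(draw))
                if label == GLOBAL:  # pooled: one network over all rows
                    sub.population_labels = np.full(
                        sub.n_haplotypes, GLOBAL, dtype=object
                    )
                res = scan(sub, k=k, step=step, include_global=False)
                per_resample.append(
                    res[list(PROPERTY_NAMES)].mean(numeric_only=True)
                )
            means = pd.concat(per_resample, axis=1).T
            for prop in PROPERTY_NAMES:
                records.append(
                    {
                        "k": k,
                        "population": label,
                        "property": prop,
                        "mean": means[prop].mean(),
                        "sem": means[prop].sem() if n_resamples > 1 else np.nan,
                        "n_resamples": n_resamples,
                        "resample_size": resample_size,
                    }
                )
    return pd.DataFrame(records)
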