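"""Sliding-window scan, masks, annotation classes, tracks, window sizing."""

import numpy as np
import pandas as pd
import pytest

import genonet as gn
from genonet.genome_scan import GLOBAL, GeneticMap
from genonet.haplotype_io import HaplotypeMatrix, SiteRecord


def matrix_with_sites(n_haps, n_sites, labels=None, chrom="chr1", seed=0,
                      annotations=None):
    rng = np.random.default_rng(seed)
    alleles = (rng.random((n_haps, n_sites)) < 0.4).astype(np.uint8)
    sites = [
        SiteRecord(
            chrom, 100 * (j + 1),
            annotation_class=(annotations[j] if annotations else "none"),
        )
        for j in range(n_sites)
    ]
    labels = labels if labels is not None else ["ALL"] * n_haps
    return HaplotypeMatrix(sites=sites, alleles=alleles, population_labels=labels)


class TestWindows:
    @pytest.mark.parametrize(
        "n_sites,k,step,expected",
        [(25, 11, 1, 15), (25, 11, 11, 2), (10, 11, 1, 0)],
    )
    def test_window_counts(self, n_sites, k, step, expected):
        m = matrix_with_sites(4, n_sites)
        wins = list(gn.iter_windows(m, k=k, step=step))
        assert len(wins) == expected

    def test_windows_never_span_chromosomes(self):
        sites = [SiteRecord("chr1", p) for p in (10, 20, 30)] + [
            SiteRecord("chr2", p) for p in (10, 20, 30)
        ]
        m = HaplotypeMatrix(
            sites=sites,
            alleles=np.zeros((2, 6), dtype=np.uint8),
            population_labels=["A", "A"],
        )
        wins = list(gn.iter_windows(m, k=3))
        assert len(wins) == 2
        assert {w.chromosome for w in wins} == {"chr1", "chr2"}

    def test_invalid_k_or_step(self):
        m = matrix_with_sites(4, 10)
        with pytest.raises(ValueError):
            list(gn.iter_windows(m, k=1))
        with pytest.raises(ValueError):
            list(gn.iter_windows(m, k=3, step=0))


class TestScan:
    def test_row_arithmetic_two_pops_plus_global(self):
        m = matrix_with_sites(8, 13, labels=["P0"] * 4 + ["P1"] * 4)
        res = gn.scan(m, k=11, step=1)
        # 3 windows x (2 populations + GLOBAL)
        assert len(res) == 9
        assert set(res["population"]) == {"P0", "P1", GLOBAL}

    def test_monomorphic_sample(self):
        m = matrix_with_sites(6, 12)
        m.alleles[:] = 0
        res = gn.scan(m, k=11)
        assert (res["n_vertices"] == 1).all()
        assert (res["avg_degree"] == 0).all()
        assert res["avg_path_length"].isna().all()

    def test_global_vertices_dominate_populations(self, neutral_scan):
        piv = neutral_scan.pivot_table(
            index="first_site_index", columns="population", values="n_vertices"
        )
        pops = [c for c in piv.columns if c != GLOBAL]
        assert (piv[GLOBAL] >= piv[pops].max(axis=1)).all()

    def test_recomb_covariable_from_map(self, tmp_path):
        m = matrix_with_sites(4, 12)
        path = tmp_path / "map.tsv"
        path.write_text("chr1\t0\t0.0\nchr1\t1000\t1.0\nchr1\t2000\t1.5\n")
        gmap = GeneticMap.from_file(str(path))
        res = gn.scan(m, k=11, genetic_map=gmap)
        # window spans positions 100..1100 and 200..1200: 1 cM/kb then 0.5
    # piecewise interpolation
        first = res.iloc[0]
        assert first["recomb_cM"] == pytest.approx(1.0 * (1000 - 100) / 1000 + 0.05)

    def test_map_extrapolation_is_counted(self):
        gmap = GeneticMap(
            pd.DataFrame(
                {"chromosome": ["chr1", "chr1"], "position": [100, 200], "cM": [0.0, 0.1]}
            )
        )
        vals = gmap.interpolate("chr1", np.array([50, 150, 250]))
        assert gmap.n_extrapolated == 2
        assert vals[0] == 0.0 and vals[2] == pytest.approx(0.1)


class TestAnnotationClasses:
    @pytest.mark.parametrize(
        "classes,expected",
        [
            (["coding", "none", "coding"], "coding"),
            (["coding", "noncoding"], "both"),
            (["noncoding", "none"], "noncoding"),
            (["none"] * 11, "no_annotation"),
        ],
    )
    def test_rules(self, classes, expected):
        sites = [
            SiteRecord("chr1", 10 * (j + 1), annotation_class=c)
            for j, c in enumerate(classes)
        ]
        assert gn.classify_window(sites) == expected


class TestMasks:
    def test_mask_hit_and_miss(self):
        m = matrix_with_sites(4, 12)  # positions 100..1200
        res = gn.scan(m, k=11)  # 2 windows: sites 0..10, 1..11
        hit = gn.apply_masks(res, [("chr1", 149, 160)], m)  # covers pos 150? no: 100*j
        # mask [149,160) contains no site (positions are multiples of 100)
        assert hit["first_site_index"].nunique() == 2
        removed = gn.apply_masks(res, [("chr1", 99, 100)], m)  # contains pos 100
        assert removed["first_site_index"].nunique() == 1  # only window 1 survives
        assert gn.apply_masks(res, [], m).equals(res)

    def test_mask_bed_convention_half_open(self):
        m = matrix_with_sites(4, 12)
        res = gn.scan(m, k=11)
        # [100, 200) excludes position 100 (1-based) start boundary but not 200?
        # BED start<p<=end: interval (100, 200]
        out = gn.apply_masks(res, [("chr1", 100, 199)], m)
        assert out["first_site_index"].nunique() == 2  # no site in (100,199]
        out = gn.apply_masks(res, [("chr1", 100, 200)], m)
        # position 200 is masked and lies in both windows
        assert out["first_site_index"].nunique() == 0

    def test_masking_monotone(self, neutral_matrix, neutral_scan):
        small = [("sim1", 0, 5_000)]
        big = [("sim1", 0, 20_000)]
        kept_small = gn.apply_masks(neutral_scan, small, neutral_matrix)
        kept_big = gn.apply_masks(neutral_scan, big, neutral_matrix)
        assert len(kept_big) <= len(kept_small) <= len(neutral_scan)
        assert set(kept_big["first_site_index"]) <= set(kept_small["first_site_index"])

    def test_malformed_bed_reports_line(self, tmp_path):
        bad = tmp_path / "bad.bed"
        bad.write_text("chr1\t10\t20\nchr1\toops\t30\n")
        with pytest.raises(ValueError, match="bad.bed:2"):
            gn.load_bed(str(bad))


class TestTopRegions:
    def test_quantile_with_ties(self, neutral_scan):
        sub = neutral_scan[neutral_scan["population"] == GLOBAL]
        top = gn.top_regions(neutral_scan, "n_vertices", quantile=0.95)
        threshold = sub["n_vertices"].quantile(0.95)
        n_qualifying = (sub["n_vertices"] >= threshold).sum()
        assert top["n_windows"].sum() == n_qualifying
        assert n_qualifying >= np.ceil(0.05 * len(sub)) - 1

    def test_overlapping_windows_merge(self):
        m = matrix_with_sites(20, 14, seed=3)
        res = gn.scan(m, k=11)  # 4 heavily overlapping windows
        top = gn.top_regions(res, "n_vertices", quantile=0.0)
        assert len(top) == 1  # one merged region covering everything
        assert top.loc[0, "n_windows"] == 4

    def test_unknown_property(self, neutral_scan):
        with pytest.raises(ValueError, match="unknown property"):
            gn.top_regions(neutral_scan, "modularity")

    def test_supports_vertices_per_component(self, neutral_scan):
        top = gn.top_regions(neutral_scan, "vertices_per_component", quantile=0.9)
        assert (top["value"] > 0).all()


class TestTracks:
    def test_bedgraph_layout_and_round_trip(self, tmp_path):
        m = matrix_with_sites(6, 13, labels=["P0"] * 6)
        res = gn.scan(m, k=11, include_global=False)
        files = gn.write_tracks(res, str(tmp_path))
        assert len(files) == 5  # five properties x one population
        track = tmp_path / "n_vertices.P0.bedGraph"
        lines = [l for l in track.read_text().splitlines() if not l.startswith("track")]
        assert len(lines) == 3
        # 0-based half-open conversion of the closed 1-based span
        chrom, start, end, value = lines[0].split("\t")
        row = res.iloc[0]
        assert int(start) == row["start"] - 1 and int(end) == row["end"]
        parsed = [float(l.split("\t")[3]) for l in lines]
        assert parsed == res[res.population == "P0"]["n_vertices"].tolist()
        # fractional values round-trip exactly too
        apl_track = tmp_path / "avg_path_length.P0.bedGraph"
        apl_lines = [
            l for l in apl_track.read_text().splitlines()
            if not l.startswith("track")
        ]
        parsed_apl = [float(l.split("\t")[3]) for l in apl_lines]
        want = res[res.population == "P0"]["avg_path_length"].dropna().tolist()
        assert parsed_apl == want

    def test_undefined_apl_lines_omitted(self, tmp_path):
        m = matrix_with_sites(4, 12)
        m.alleles[:] = 0  # monomorphic: APL undefined everywhere
        res = gn.scan(m, k=11, include_global=False)
        gn.write_tracks(res, str(tmp_path))
        track = tmp_path / "avg_path_length.ALL.bedGraph"
        lines = [l for l in track.read_text().splitlines() if not l.startswith("track")]
        assert lines == []


class TestWindowSizeSweep:
    def test_degenerate_resampling_equals_direct_scan(self):
        m = matrix_with_sites(10, 9, labels=["P0"] * 10)
        table = gn.window_size_sweep(
            m, k_values=[5], n_resamples=1, resample_size=10, seed=0
        )
        direct = gn.scan(m, k=5, include_global=False)
        for prop in gn.network_core.PROPERTY_NAMES:
            got = table[(table["property"] == prop)]["mean"].iloc[0]
            want = direct[prop].mean()
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want)

    def test_deterministic_for_fixed_seed(self, neutral_matrix):
        kwargs = dict(k_values=[5, 9], n_resamples=2, resample_size=50, seed=99)
        t1 = gn.window_size_sweep(neutral_matrix, **kwargs)
        t2 = gn.window_size_sweep(neutral_matrix, **kwargs)
        pd.testing.assert_frame_equal(t1, t2)

    def test_resample_size_validated(self, neutral_matrix):
        with pytest.raises(ValueError, match="resample_size"):
            gn.window_size_sweep(neutral_matrix, k_values=[5], resample_size=10**6)

    def test_vertices_nondecreasing_in_window_size(self, neutral_matrix):
        """Widening a window from a fixed start cannot lose distinct types."""
        sub = neutral_matrix.subset_rows(np.arange(100))
        strings = {
            k: gn.genotype_strings(sub, 0, k) for k in (5, 9, 13)
        }
        counts = {k: len(set(s)) for k, s in strings.items()}
        assert counts[5] <= counts[9] <= counts[13]
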