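"""Subsampling curves, correlations, ANCOVA, scenario comparison."""

import numpy as np
import pandas as pd
import pytest

import genonet as gn
from genonet.genome_scan import GLOBAL
from genonet.network_core import PROPERTY_NAMES


def synthetic_scan(n_windows, seed=0, classes=("coding", "both", "noncoding"),
                   class_effects=None, recomb_slope=0.0, noise=0.3,
                   population=GLOBAL):
    """Construct a scan-shaped table with known class/covariable structure."""
    rng = np.random.default_rng(seed)
    cls = rng.choice(classes, size=n_windows)
    recomb = rng.gamma(2.0, 0.2, size=n_windows)
    effects = class_effects or {c: 0.0 for c in classes}
    base = np.array([effects[c] for c in cls])
    y = base + recomb_slope * recomb + rng.normal(0, noise, n_windows)
    frame = {
        "chromosome": "chrS",
        "first_site_index": np.arange(n_windows),
        "k": 11,
        "step": 1,
        "start": 100 * np.arange(n_windows) + 1,
        "end": 100 * np.arange(n_windows) + 1000,
        "span_bp": 999,
        "recomb_cM": recomb,
        "annotation_class": cls,
        "population": population,
    }
    for prop in PROPERTY_NAMES:
        frame[prop] = y + 5.0
    return pd.DataFrame(frame)


class TestSubsamplingExperiment:
    def test_full_size_single_replicate_equals_direct_scan(self, neutral_matrix):
        curve = gn.subsampling_experiment(
            neutral_matrix, k=11, sizes=(200,), replicates=1, seed=0,
            include_global=False,
        )
        direct = gn.scan(neutral_matrix, k=11)
        for pop in neutral_matrix.populations():
            for prop in PROPERTY_NAMES:
                got = curve[
                    (curve.population == pop) & (curve["property"] == prop)
                ]["mean"].iloc[0]
                want = direct[direct.population == pop][prop].mean()
                assert got == pytest.approx(want, nan_ok=True)

    def test_vertex_means_monotone_in_sample_size(self, neutral_matrix):
        curve = gn.subsampling_experiment(
            neutral_matrix, k=11, sizes=(200, 100, 50), replicates=3, seed=7
        )
        v = curve[curve["property"] == "n_vertices"].pivot(
            index="sample_size", columns="population", values="mean"
        )
        for pop in v.columns:
            assert v[pop].is_monotonic_increasing

    def test_global_dominates_populations(self, neutral_matrix):
        curve = gn.subsampling_experiment(
            neutral_matrix, k=11, sizes=(100, 50), replicates=3, seed=7
        )
        v = curve[curve["property"] == "n_vertices"].pivot(
            index="sample_size", columns="population", values="mean"
        )
        pops = [c for c in v.columns if c != GLOBAL]
        assert (v[GLOBAL] >= v[pops].max(axis=1)).all()

    def test_oversized_request_rejected(self, neutral_matrix):
        with pytest.raises(ValueError, match="sample size"):
            gn.subsampling_experiment(neutral_matrix, sizes=(10**6,), seed=0)


class TestCorrelations:
    def test_self_and_linear_pairs(self):
        df = synthetic_scan(100, seed=1)
        df["n_vertices"] = np.arange(100.0)
        df["avg_degree"] = 2.0 * np.arange(100.0)
        coef, pval = gn.correlate_properties(df)
        assert coef.loc["n_vertices", "n_vertices"] == 1.0
        assert coef.loc["n_vertices", "avg_degree"] == pytest.approx(1.0)
        assert pval.loc["n_vertices", "avg_degree"] < 1e-10

    def test_constant_column_gives_nan(self):
        df = synthetic_scan(50, seed=2)
        df["n_components"] = 3.0
        coef, _ = gn.correlate_properties(df)
        assert np.isnan(coef.loc["n_components", "n_vertices"])

    def test_too_few_rows(self):
        with pytest.raises(ValueError, match="at least 3"):
            gn.correlate_properties(synthetic_scan(2))

    def test_log_vertices_strengthens_degree_relation(self, neutral_scan):
        lin, _ = gn.correlate_properties(neutral_scan)
        log, _ = gn.correlate_properties(neutral_scan, log_vertices=True)
        assert abs(log.loc["n_vertices", "avg_degree"]) > 0
        # both are strong positive correlations on scan data
        assert lin.loc["n_vertices", "avg_degree"] > 0.3

    def test_recomb_sign_pattern_on_simulated_scan(self, neutral_matrix, tmp_path):
        """Recombination distance correlates positively with degree on
        neutral scans (more shuffling, more one-step neighbours)."""
        gmap = gn.GeneticMap(
            pd.DataFrame(
                {
                    "chromosome": ["sim1", "sim1"],
                    "position": [0, 40_000],
                    "cM": [0.0, 0.4],
                }
            )
        )
        res = gn.scan(neutral_matrix, k=11, genetic_map=gmap)
        coef, _ = gn.correlate_properties(res)
        # constant-rate map: recomb_cM is proportional to span_bp
        assert coef.loc["recomb_cM", "span_bp"] == pytest.approx(1.0)


class TestAncova:
    def test_recovers_injected_class_effect(self):
        effects = {"coding": 0.5, "both": 0.25, "noncoding": 0.0}
        df = synthetic_scan(
            400, seed=3, class_effects=effects, recomb_slope=1.5, noise=0.3
        )
        tables = gn.ancova_annotation(df, recomb_cutoff_cM=2.0)
        c = tables["contrasts"]
        row = c[
            (c["property"] == "n_vertices")
            & (c.class_a == "coding")
            & (c.class_b == "noncoding")
        ].iloc[0]
        assert row["effect"] == pytest.approx(-0.5, abs=0.25)
        assert row["p_bonferroni"] < 0.01
        means = tables["adjusted_means"].query("property == 'n_vertices'")
        order = means.set_index("annotation_class")["adjusted_mean"]
        assert order["coding"] > order["both"] > order["noncoding"]

    def test_identical_classes_give_null_result(self):
        df = synthetic_scan(300, seed=4, recomb_slope=1.0)
        tables = gn.ancova_annotation(df, recomb_cutoff_cM=2.0)
        g = tables["group_tests"]
        assert (g["p_value"] > 0.01).all()
        assert tables["contrasts"]["effect"].abs().max() < 0.2

    def test_bonferroni_never_below_raw(self):
        df = synthetic_scan(200, seed=5, recomb_slope=0.5)
        c = gn.ancova_annotation(df, recomb_cutoff_cM=2.0)["contrasts"]
        assert (c["p_bonferroni"] >= c["p_raw"] - 1e-12).all()
        assert (c["p_bonferroni"] <= 1.0).all()

    def test_cutoff_removing_everything_raises(self):
        df = synthetic_scan(100, seed=6)
        with pytest.raises(ValueError, match="no windows left"):
            gn.ancova_annotation(df, recomb_cutoff_cM=0.0)

    def test_high_recomb_windows_excluded(self):
        df = synthetic_scan(200, seed=7, recomb_slope=0.0)
        df.loc[df.index[:50], "recomb_cM"] = 5.0  # beyond the cutoff
        tables = gn.ancova_annotation(df, recomb_cutoff_cM=1.0)
        assert tables["group_tests"]["n_windows"].max() <= 150


class TestCompareScenarios:
    def test_identical_inputs_null(self):
        df = synthetic_scan(150, seed=8)
        comp = gn.compare_scenarios(df, df.copy())
        assert (comp.table["p_value"] > 0.9).all()
        assert (comp.table["direction"] == 0).all()

    def test_detects_known_location_shift(self):
        a = synthetic_scan(200, seed=9)
        b = synthetic_scan(200, seed=10)
        for prop in PROPERTY_NAMES:
            b[prop] = b[prop] + 0.25
        comp = gn.compare_scenarios(a, b)
        assert (comp.table["p_value"] < 0.05).all()
        assert (comp.table["direction"] == 1).all()

    def test_window_order_invariance(self):
        a = synthetic_scan(120, seed=11)
        b = synthetic_scan(120, seed=12)
        shuffled = b.sample(frac=1.0, random_state=0).reset_index(drop=True)
        c1 = gn.compare_scenarios(a, b)
        c2 = gn.compare_scenarios(a, shuffled)
        pd.testing.assert_frame_equal(c1.table, c2.table)

    def test_qq_pairs_monotone(self):
        a = synthetic_scan(100, seed=13)
        b = synthetic_scan(100, seed=14)
        comp = gn.compare_scenarios(a, b)
        for pairs in comp.qq_pairs.values():
            assert pairs["neutral"].is_monotonic_increasing
            assert pairs["sweep"].is_monotonic_increasing

    def test_empty_scan_rejected(self):
        df = synthetic_scan(50, seed=15)
        with pytest.raises(ValueError):
            gn.compare_scenarios(df.iloc[:0], df)
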