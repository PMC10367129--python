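"""Cascade behaviour on small labelled synthetic populations."""

import numpy as np
import pandas as pd
import pytest

from lipogate.features import build_feature_table
from lipogate.phenotypes import (
    classify_expression,
    classify_filaments,
    classify_morphology,
    classify_ps,
    classify_relocalization,
    classify_replication,
    expression_stats,
    identify_liposomes,
    population_summary,
)
from lipogate.synthetic import (
    DEFAULT_OPTICS,
    PopulationComposition,
    sample_population,
)


def features_for(weights, n, seed):
    comp = PopulationComposition(class_weights=weights, n_events=n, seed=seed)
    events, truth = sample_population(comp, DEFAULT_OPTICS)
    return build_feature_table(events), truth


@pytest.fixture(scope="module")
def sphere_pop():
    return features_for({"sphere": 1.0}, 60, 201)


class TestIdentify:
    def test_debris_rejected_before_focus_stages(self):
        table, _ = features_for({"debris": 1.0}, 40, 202)
        labels, result = identify_liposomes(table)
        assert (labels["identification"] == "debris").mean() >= 0.9
        # nothing survives to be called out_of_focus
        assert (labels["identification"] == "out_of_focus").sum() == 0

    def test_defocused_spheres_fail_gradient_rms_stage(self):
        table, _ = features_for({"out_of_focus": 1.0}, 40, 203)
        labels, result = identify_liposomes(table)
        assert (labels["identification"] == "out_of_focus").mean() >= 0.9
        assert result.stage_counts.loc["in_focus", "fraction"] < 0.1

    def test_clean_spheres_mostly_good(self, sphere_pop):
        table, _ = sphere_pop
        labels, result = identify_liposomes(table)
        assert (labels["identification"] == "good_liposome").mean() >= 0.95
        # accounting conserves events at each stage
        sc = result.stage_counts
        assert (sc["passing"] <= sc["entering"]).all()

    def test_rerun_is_bit_identical(self, sphere_pop):
        table, _ = sphere_pop
        l1, _ = identify_liposomes(table)
        l2, _ = identify_liposomes(table)
        pd.testing.assert_frame_equal(l1, l2)


class TestMorphology:
    def test_multilamellar_called(self):
        table, _ = features_for({"multilamellar": 1.0}, 50, 204)
        labels, _ = identify_liposomes(table)
        labels = classify_morphology(table, labels)
        good = labels["identification"] == "good_liposome"
        assert (labels.loc[good, "morphology"]
                == "spherical_multilamellar").mean() >= 0.85

    def test_doublet_called(self):
        table, _ = features_for({"doublet": 1.0}, 50, 205)
        labels, _ = identify_liposomes(table)
        labels = classify_morphology(table, labels)
        good = labels["identification"] == "good_liposome"
        assert (labels.loc[good, "morphology"] == "doublet").mean() >= 0.9

    def test_every_good_liposome_gets_morphology_label(self, sphere_pop):
        table, _ = sphere_pop
        labels, _ = identify_liposomes(table)
        labels = classify_morphology(table, labels)
        good = labels["identification"] == "good_liposome"
        assert labels.loc[good, "morphology"].notna().all()
        assert (labels.loc[~good, "morphology"] == "unclassified").all()


class TestExpression:
    def test_bright_lumen_expressing_dark_not(self):
        table, truth = features_for(
            {"expressing": 0.5, "nonexpressing": 0.5}, 80, 206)
        labels, _ = identify_liposomes(table)
        labels = classify_expression(table, labels)
        joined = labels.join(truth)
        expr = joined[joined["class_label"] == "expressing"]
        nonex = joined[joined["class_label"] == "nonexpressing"]
        assert (expr["expression"] == "expressing").mean() >= 0.9
        assert (nonex["expression"] == "nonexpressing").mean() >= 0.9
        stats = expression_stats(table, labels)
        assert stats["expressing"]["n"] > 0

    def test_monotonicity_in_threshold(self):
        table, _ = features_for({"expressing": 0.5, "nonexpressing": 0.5},
                                60, 207)
        labels, _ = identify_liposomes(table)
        counts = []
        for thr in (100.0, 1000.0, 10000.0):
            lab = classify_expression(table, labels, threshold=thr)
            counts.append(int((lab["expression"] == "expressing").sum()))
        assert counts[0] >= counts[1] >= counts[2]


class TestReplication:
    def test_three_way_call(self):
        table, truth = features_for(
            {"repl_negative": 1, "repl_homogeneous": 1, "repl_blob": 1},
            90, 208)
        labels, _ = identify_liposomes(table)
        labels = classify_replication(table, labels)
        joined = labels.join(truth)
        for cls, expect in (("repl_negative", "negative"),
                            ("repl_homogeneous", "homogeneous"),
                            ("repl_blob", "blob")):
            sub = joined[joined["class_label"] == cls]
            assert (sub["replication"] == expect).mean() >= 0.85, cls

    def test_blob_population_smaller_when_generated_smaller(self):
        # draw blob events from a smaller size distribution and check the
        # recovered per-class area ordering
        big = PopulationComposition(
            class_weights={"repl_homogeneous": 1.0}, n_events=50, seed=209,
            size_mean=8.2, size_sd=1.2)
        small = PopulationComposition(
            class_weights={"repl_blob": 1.0}, n_events=50, seed=210,
            size_mean=5.8, size_sd=1.2)
        tables = []
        for comp in (big, small):
            events, _ = sample_population(comp, DEFAULT_OPTICS)
            tables.append(build_feature_table(events))
        table = pd.concat(tables)
        table.index = [f"r{i}" for i in range(len(table))]
        labels, _ = identify_liposomes(table)
        labels = classify_replication(table, labels)
        area = table["area"]
        blob_mean = area[labels["replication"] == "blob"].mean()
        hom_mean = area[labels["replication"] == "homogeneous"].mean()
        assert blob_mean < hom_mean


class TestFilaments:
    def test_filament_vs_uniform_lumen(self):
        table, truth = features_for(
            {"filament": 0.5, "no_filament": 0.5}, 80, 211)
        labels, _ = identify_liposomes(table)
        labels = classify_filaments(table, labels)
        joined = labels.join(truth)
        fil = joined[joined["class_label"] == "filament"]
        nof = joined[joined["class_label"] == "no_filament"]
        assert (fil["filament"] == "filament").mean() >= 0.85
        assert (nof["filament"] == "no_filament").mean() >= 0.85

    def test_dim_reporter_excluded_by_intensity_cut(self):
        table, _ = features_for({"filament_negative": 1.0}, 40, 212)
        labels, _ = identify_liposomes(table)
        labels = classify_filaments(table, labels)
        good = labels["identification"] == "good_liposome"
        assert (labels.loc[good, "filament"] == "below_intensity").mean() >= 0.9


class TestRelocalization:
    def test_membrane_vs_lumen_reporter(self):
        table, truth = features_for(
            {"min_active": 0.5, "min_inactive": 0.5}, 80, 213)
        labels, _ = identify_liposomes(table)
        labels = classify_relocalization(table, labels)
        joined = labels.join(truth)
        act = joined[joined["class_label"] == "min_active"]
        inact = joined[joined["class_label"] == "min_inactive"]
        assert (act["relocalization"] == "active").mean() >= 0.85
        assert (inact["relocalization"] == "inactive").mean() >= 0.85


class TestPs:
    def test_negative_against_itself_bounded_fpr(self):
        table, _ = features_for({"ps_negative": 1.0}, 100, 214)
        labels, _ = identify_liposomes(table)
        labels, info = classify_ps(table, table, labels, max_fpr=0.05)
        frac_pos = (labels["ps"] == "ps_positive").mean()
        assert frac_pos <= 0.05
        assert info["negative_fpr"] <= 0.05

    def test_bright_probe_recovered(self):
        pos_table, _ = features_for({"ps_positive": 1.0}, 60, 215)
        neg_table, _ = features_for({"ps_negative": 1.0}, 60, 216)
        labels, _ = identify_liposomes(pos_table)
        labels, info = classify_ps(pos_table, neg_table, labels, max_fpr=0.05)
        good = labels["identification"] == "good_liposome"
        assert (labels.loc[good, "ps"] == "ps_positive").mean() >= 0.9

    def test_empty_negative_rejected(self):
        pos_table, _ = features_for({"ps_positive": 1.0}, 10, 217)
        labels, _ = identify_liposomes(pos_table)
        with pytest.raises(ValueError):
            classify_ps(pos_table, pos_table.iloc[:0], labels)


class TestPopulationSummary:
    def test_all_sphere_population(self, sphere_pop):
        table, _ = sphere_pop
        labels, _ = identify_liposomes(table)
        labels = classify_morphology(table, labels)
        summary = population_summary(labels, table)
        fr = summary["morphology"]["fractions"]
        assert fr.get("spherical_unilamellar", 0.0) >= 0.9
        for level in ("identification", "morphology"):
            assert sum(summary[level]["fractions"].values()) == pytest.approx(1.0)

    def test_diameter_estimator_consistency(self):
        table, truth = features_for({"sphere": 1.0}, 150, 218)
        labels, _ = identify_liposomes(table)
        summary = population_summary(labels, table)
        est = summary["diameter_good"]["mean"]
        true_mean = truth["true_diameter"].mean()
        # size-calibrated estimate: bias well below the sampling noise
        assert abs(est - true_mean) < 3.5 * 1.7 / np.sqrt(150) + 0.1
        assert summary["diameter_good"]["fraction_below_cut"] >= 0.5
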