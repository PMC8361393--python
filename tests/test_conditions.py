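"""Sampling-bias corrections (UL, AR), condition pipeline and cohort report."""

import numpy as np
import pandas as pd
import pytest

import ieegnet as ig
from ieegnet.conditions import (
    AmbiguousHemisphereError,
    conditions_frame,
    n_resected_rois,
    resection_hemisphere,
)
from ieegnet.types import ConditionSet, DrsResult, InvalidSpecError, Rat11Fit

from conftest import make_sensors, random_symmetric


def bilateral_net(rng, n_per_side=10, resected_right=3, resected_left=0):
    rows = []
    for i in range(n_per_side):
        rows.append((f"r{i}", 40.0 + i, 5.0 * i - 20, 0.0, "depth", "GM",
                     "right_mid_sup_cortical", "right", i < resected_right))
    for i in range(n_per_side):
        rows.append((f"l{i}", -40.0 - i, 5.0 * i - 20, 0.0, "depth", "GM",
                     "left_mid_sup_cortical", "left", i < resected_left))
    sensors = make_sensors(rows)
    a = random_symmetric(2 * n_per_side, rng)
    return ig.build_patient_network(sensors, a, "SEEG", patient_id="p")


class TestUnilateralFilter:
    def test_all_ipsilateral_is_identity(self, rng):
        net = bilateral_net(rng, resected_right=3)
        right = ig.unilateral_filter(net)
        ipsi_only = bilateral_net(rng, resected_right=3)
        assert right.n_nodes == 10
        assert all(h == "right" for h in right.nodes["hemisphere"])
        assert right.resected_mask.sum() == 3

    def test_mixed_implant_keeps_resection_side(self, rng):
        net = bilateral_net(rng, resected_right=4, resected_left=1)
        out = ig.unilateral_filter(net)
        assert out.n_nodes == 10
        assert resection_hemisphere(net) == "right"
        # the minority-side resected node is dropped and logged
        assert out.resected_mask.sum() == 4
        assert any("UL" in e for e in out.exclusions)

    def test_even_split_is_ambiguous(self, rng):
        net = bilateral_net(rng, resected_right=2, resected_left=2)
        with pytest.raises(AmbiguousHemisphereError):
            ig.unilateral_filter(net)

    def test_no_resected_nodes_rejected(self, rng):
        net = bilateral_net(rng, resected_right=0)
        with pytest.raises(InvalidSpecError):
            ig.unilateral_filter(net)


class TestAtlasReduce:
    def make_two_roi_net(self):
        sensors = make_sensors([
            ("a1", 40.0, 20.0, 0.0, "surface", "GM", "right_ant_sup_cortical", "right", False),
            ("a2", 45.0, 22.0, 0.0, "surface", "GM", "right_ant_sup_cortical", "right", False),
            ("b1", 40.0, -20.0, 0.0, "surface", "GM", "right_post_sup_cortical", "right", True),
        ])
        a = np.array([
            [0.0, 0.9, 0.2],
            [0.9, 0.0, 0.4],
            [0.2, 0.4, 0.0],
        ])
        return ig.build_patient_network(sensors, a, "ECoG")

    def test_inter_roi_edge_is_mean_of_contact_edges(self):
        ar = ig.atlas_reduce(self.make_two_roi_net())
        assert ar.n_nodes == 2
        assert ar.adjacency[0, 1] == pytest.approx((0.2 + 0.4) / 2)

    def test_roi_resected_iff_any_contact_resected(self):
        ar = ig.atlas_reduce(self.make_two_roi_net())
        flags = dict(zip(ar.nodes["contact_id"], ar.nodes["resected"]))
        assert bool(flags["right_post_sup_cortical"]) is True
        assert bool(flags["right_ant_sup_cortical"]) is False

    def test_idempotent(self, rng):
        sensors = ig.generate_layout("SEEG", seed=0)
        truth = ig.plant_ground_truth(sensors, ig.EffectConfig(), seed=0)
        net = ig.build_patient_network(sensors, truth.weights, "SEEG")
        once = ig.atlas_reduce(net)
        twice = ig.atlas_reduce(once)
        np.testing.assert_allclose(once.adjacency, twice.adjacency)
        assert once.nodes["contact_id"].tolist() == twice.nodes["contact_id"].tolist()
        assert once.nodes["resected"].tolist() == twice.nodes["resected"].tolist()

    def test_uniform_edges_stay_uniform(self):
        net = self.make_two_roi_net()
        net.adjacency = np.array([
            [0.0, 0.3, 0.3],
            [0.3, 0.0, 0.3],
            [0.3, 0.3, 0.0],
        ])
        ar = ig.atlas_reduce(net)
        assert ar.adjacency[0, 1] == pytest.approx(0.3)

    def test_single_roi_rejected(self):
        net = self.make_two_roi_net()
        net.nodes["roi_label"] = "right_ant_sup_cortical"
        with pytest.raises(InvalidSpecError):
            ig.atlas_reduce(net)


def synthetic_net(seed, modality="SEEG", n_rois=2, resection_effect=-0.04):
    layout = (ig.SEEGLayout(n_resection_rois=n_rois) if modality == "SEEG"
              else ig.ECoGLayout(n_resection_rois=n_rois))
    sensors = ig.generate_layout(modality, layout, seed=seed)
    cfg = ig.EffectConfig(resection_effect=resection_effect)
    truth = ig.plant_ground_truth(sensors, cfg, seed=seed)
    return ig.build_patient_network(sensors, truth.weights, modality,
                                    patient_id=f"{modality}_{seed}")


class TestRunConditions:
    def test_gm_condition_matches_direct_drs(self):
        net = synthetic_net(0)
        fits = ig.fit_class_models([net], seed=0)
        cs = ig.run_conditions(net, fits)
        direct = ig.distinguishability(ig.node_strength(net.adjacency),
                                       net.resected_mask)
        assert cs.drs["GM"].value == pytest.approx(direct.value)
        assert cs.n_resected_rois == n_resected_rois(net)

    def test_fully_ipsilateral_patient_has_ul_equal_dc(self):
        net = synthetic_net(1)  # default SEEG layout has contralateral shafts
        keep = (net.nodes["hemisphere"] == resection_hemisphere(net)).to_numpy()
        from ieegnet.network import subset_network
        ipsi = subset_network(net, keep, condition="GM")
        fits = ig.fit_class_models([ipsi], seed=0)
        cs = ig.run_conditions(ipsi, fits)
        assert cs.drs["UL"].value == pytest.approx(cs.drs["DC"].value)
        assert cs.node_counts["UL"] == cs.node_counts["DC"]

    def test_all_four_conditions_present(self):
        net = synthetic_net(2)
        fits = ig.fit_class_models([net], seed=0)
        cs = ig.run_conditions(net, fits)
        assert set(cs.drs) == {"GM", "DC", "UL", "AR"}
        assert not cs.skip_reasons
        for res in cs.drs.values():
            assert 0.0 <= res.value <= 1.0

    def test_stage_error_recorded_as_skip_reason(self):
        net = synthetic_net(3)
        # remove the D-D fit so residualization fails but GM still computes
        cs = ig.run_conditions(net, {})
        assert "GM" in cs.drs
        assert "DC" in cs.skip_reasons
        # later conditions fall back to the last good stage
        assert "UL" in cs.drs and "AR" in cs.drs


def fake_condition_sets(drs_by_modality, n_rois=None):
    sets = []
    k = 0
    for modality, values in drs_by_modality.items():
        for v in values:
            cs = ConditionSet(patient_id=f"{modality}{k}", modality=modality,
                              measure="beta_coherence",
                              n_resected_rois=(n_rois[k] if n_rois else 2))
            for cond in ("GM", "DC", "UL", "AR"):
                cs.drs[cond] = DrsResult(value=v, n_resected=3, n_spared=10,
                                         condition=cond)
                cs.node_counts[cond] = 13
            sets.append(cs)
            k += 1
    return sets


class TestCohortReport:
    def test_identical_groups_are_not_significant(self):
        values = list(np.linspace(0.2, 0.8, 7))
        sets = fake_condition_sets({"ECoG": values, "SEEG": values})
        report = ig.cohort_report(sets)
        for cond, cmp in report["modality_comparisons"].items():
            assert cmp.p_value > 0.9

    def test_planted_negative_focality_relation_detected(self):
        rng = np.random.default_rng(0)
        n_rois = list(rng.integers(1, 6, 20))
        values = [0.9 - 0.12 * r + rng.normal(0, 0.02) for r in n_rois]
        sets = fake_condition_sets({"ECoG": values[:10], "SEEG": values[10:]},
                                   n_rois=n_rois)
        report = ig.cohort_report(sets)
        assert report["focality"]["rho"] < 0

    def test_condition_vs_gm_signrank_present(self):
        rng = np.random.default_rng(1)
        sets = fake_condition_sets({"ECoG": rng.uniform(0.2, 0.4, 6).tolist(),
                                    "SEEG": rng.uniform(0.5, 0.9, 6).tolist()})
        # shift the DC values so paired differences are nonzero
        for cs in sets:
            cs.drs["DC"] = DrsResult(value=min(cs.drs["GM"].value + 0.1, 1.0),
                                     n_resected=3, n_spared=10, condition="DC")
        report = ig.cohort_report(sets)
        assert ("ECoG", "DC") in report["condition_vs_gm"]
        assert report["condition_vs_gm"][("ECoG", "DC")].p_value < 0.1

    def test_table1_summary_counts(self):
        nets = [synthetic_net(s, "ECoG") for s in (0, 1)] + \
               [synthetic_net(s, "SEEG") for s in (2, 3)]
        fits = ig.fit_class_models(nets, seed=0)
        sets = [ig.run_conditions(n, fits) for n in nets]
        tables = {f"ECoG_{s}": ig.generate_layout("ECoG", ig.ECoGLayout(n_resection_rois=2), seed=s)
                  for s in (0, 1)}
        tables.update({f"SEEG_{s}": ig.generate_layout("SEEG", ig.SEEGLayout(n_resection_rois=2), seed=s)
                       for s in (2, 3)})
        report = ig.cohort_report(sets, patient_tables=tables)
        t1 = report["table1"]
        assert t1["n_subjects"] == {"ECoG": 2, "SEEG": 2}
        assert t1["gm"]["ECoG"]["mean"] > 0
        assert t1["depth_gm"]["SEEG"]["mean"] == t1["gm"]["SEEG"]["mean"]
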