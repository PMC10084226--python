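"""Trial ingestion, label canonicalization, network and diagnostics."""

import io
import itertools

import networkx as nx
import numpy as np
import pytest

import myelorank as mr
from myelorank import FormatError, ValidationError
from myelorank.effect_measures import EffectEstimate
from myelorank.trial_data import TreatmentNetwork

HEADER = "study_id,year,treatment,n,endpoint,stat_type,value1,value2\n"


class TestReadTrials:
    def test_packaged_fixture_structure(self):
        trials = mr.read_trials(mr.fixture_csv_path())
        assert len(trials) == 27
        assert sum(t.total_n for t in trials) == 12_935

    def test_header_only_file_is_empty(self):
        assert mr.read_trials(io.StringIO(HEADER)) == []

    def test_minimal_two_arm_trial(self):
        csv = HEADER + "S1,2020,A,10,,,,\nS1,2020,B,10,,,,\n"
        trials = mr.read_trials(io.StringIO(csv))
        assert len(trials) == 1
        assert trials[0].treatments == ("A", "B")
        assert trials[0].total_n == 20

    def test_missing_column_names_the_column(self):
        csv = "study_id,year,treatment,endpoint,stat_type,value1,value2\nS1,2020,A,,,,\n"
        with pytest.raises(FormatError, match="n"):
            mr.read_trials(io.StringIO(csv))

    def test_multiple_endpoints_per_arm_allowed(self):
        csv = HEADER + "S1,2020,A,10,ORR,events_total,5,10\nS1,2020,B,10,,,,\n"
        csv += "S1,2020,A,10,CR,events_total,1,10\n"
        trials = mr.read_trials(io.StringIO(csv))
        assert len(trials[0].arms) == 2
        assert set(trials[0].arms[0].endpoint_summaries) == {"ORR", "CR"}

    def test_duplicate_arm_rejected(self):
        dup = HEADER + (
            "S1,2020,A,10,ORR,events_total,5,10\n"
            "S1,2020,B,10,ORR,events_total,4,10\n"
            "S1,2020,A,10,ORR,events_total,6,10\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            mr.read_trials(io.StringIO(dup))

    def test_nonpositive_n_rejected(self):
        bad = HEADER + "S2,2020,A,0,,,,\nS2,2020,B,5,,,,\n"
        with pytest.raises(ValidationError):
            mr.read_trials(io.StringIO(bad))

    def test_round_trip(self, table1_trials, tmp_path):
        path = tmp_path / "trials.csv"
        mr.write_trials(table1_trials, path)
        back = mr.read_trials(path)
        assert [t.study_id for t in back] == [t.study_id for t in table1_trials]
        assert sum(t.total_n for t in back) == sum(t.total_n for t in table1_trials)


class TestCanonicalize:
    def test_default_merge_yields_23_regimens(self, canon_trials):
        labels = {a.treatment for t in canon_trials for a in t.arms}
        assert len(labels) == 23
        assert "VTP" not in labels and "VTD" in labels
        # maintenance variants remain distinct
        assert {"MPT", "MPT-T", "MPR", "MPR-R", "Rd", "Rd18", "Rd9"} <= labels

    def test_empty_map_keeps_vtp_distinct(self, table1_trials):
        out = mr.canonicalize_treatments(table1_trials, merge_map={})
        labels = {a.treatment for t in out for a in t.arms}
        assert len(labels) == 24 and "VTP" in labels
        assert len(out) == len(table1_trials)

    def test_case_and_punctuation_insensitive(self, table1_trials):
        out = mr.canonicalize_treatments(table1_trials)
        labels = {a.treatment for t in out for a in t.arms}
        assert "Rd" in labels and "RD" not in labels
        assert "DrVMP" in labels and "VMPDr" not in labels

    def test_degenerate_merge_rejects_every_multiarm_trial(self, table1_trials):
        labels = {a.treatment for t in table1_trials for a in t.arms}
        to_x = {lab: "X" for lab in labels}
        with pytest.raises(ValidationError):
            mr.canonicalize_treatments(table1_trials, merge_map=to_x)
        out = mr.canonicalize_treatments(
            table1_trials, merge_map=to_x, drop_invalid=True
        )
        assert out == []  # every trial has >= 2 arms, all collapse


class TestNetwork:
    def test_fixture_network(self, fixture_network):
        assert len(fixture_network.nodes) == 23
        assert fixture_network.connected
        assert sum(fixture_network.node_weights.values()) == 12_935

    def test_single_three_arm_trial(self):
        csv = HEADER + "".join(
            f"S1,2020,{t},10,,,,\n" for t in ("A", "B", "C")
        )
        net = mr.build_network(mr.read_trials(io.StringIO(csv)))
        assert len(net.nodes) == 3
        assert net.edges == {("A", "B"): 1, ("A", "C"): 1, ("B", "C"): 1}

    def test_edge_multiplicity_matches_pair_enumeration(self):
        """Edge counts equal brute-force counting of co-occurring pairs."""
        rng = np.random.default_rng(42)
        labels = [f"T{i}" for i in range(8)]
        for _ in range(50):
            arms_per_trial = [
                sorted(rng.choice(labels, size=rng.integers(2, 4), replace=False))
                for _ in range(rng.integers(3, 12))
            ]
            trials = [
                mr.TrialRecord(
                    f"S{j}", 2020, tuple(mr.ArmRecord(t, 10) for t in arms)
                )
                for j, arms in enumerate(arms_per_trial)
            ]
            net = mr.build_network(trials)
            expected = {}
            for arms in arms_per_trial:
                for pair in itertools.combinations(sorted(arms), 2):
                    expected[pair] = expected.get(pair, 0) + 1
            assert net.edges == expected

    def test_fixture_triangles(self, fixture_network):
        tris = mr.enumerate_triangles(fixture_network)
        assert len(tris) == 9
        assert ("MPT", "Rd", "Rd18") in tris
        assert ("VD", "VMP", "VTD") in tris

    def test_star_graph_has_no_triangles(self):
        g = nx.star_graph(4)
        net = TreatmentNetwork(graph=nx.relabel_nodes(g, str), connected=True)
        assert mr.enumerate_triangles(net) == []

    def test_triangles_match_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(3, 16))
            g = nx.gnp_random_graph(n, float(rng.uniform(0.1, 0.7)),
                                    seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, str)
            net = TreatmentNetwork(graph=g, connected=True)
            brute = sorted(
                tuple(sorted(tri))
                for tri in itertools.combinations(sorted(g.nodes), 3)
                if g.has_edge(tri[0], tri[1])
                and g.has_edge(tri[0], tri[2])
                and g.has_edge(tri[1], tri[2])
            )
            assert mr.enumerate_triangles(net) == brute


class TestQualityAndFunnel:
    @pytest.mark.parametrize(
        "items", list(itertools.product([False, True], repeat=5))
    )
    def test_score_counts_true_items(self, items):
        trial = mr.TrialRecord(
            "S", 2020,
            (mr.ArmRecord("A", 10), mr.ArmRecord("B", 10)),
            items,
        )
        assert mr.quality_score(trial).score == sum(items)

    def test_single_estimate_centers_at_zero(self):
        est = EffectEstimate("logOR", 0.7, 0.04)
        assert mr.funnel_points([est]) == [(0.0, est.se)]

    def test_equal_variance_pair_is_symmetric(self):
        a = EffectEstimate("logOR", 0.2, 0.05)
        b = EffectEstimate("logOR", 0.8, 0.05)
        pts = mr.funnel_points([a, b])
        assert pts[0][0] == pytest.approx(-0.3)
        assert pts[1][0] == pytest.approx(0.3)

    def test_unbiased_simulation_has_flat_funnel(self):
        """Centered effects show no SE trend when there is no publication bias."""
        rng = np.random.default_rng(0)
        ses = rng.uniform(0.05, 0.5, 200)
        ests = [
            EffectEstimate("logOR", rng.normal(0.3, se), se**2) for se in ses
        ]
        pts = np.array(mr.funnel_points(ests))
        x = np.column_stack([np.ones(200), pts[:, 1]])
        beta, res, *_ = np.linalg.lstsq(x, pts[:, 0], rcond=None)
        resid = pts[:, 0] - x @ beta
        s2 = resid @ resid / (200 - 2)
        se_slope = np.sqrt(s2 * np.linalg.inv(x.T @ x)[1, 1])
        assert abs(beta[1]) < 2 * se_slope

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            EffectEstimate("logOR", 0.1, 0.0)
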