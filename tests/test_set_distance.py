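import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from combonet.propagation import AttenuationParams
from combonet.regnet_model import DrugActionProfile, RegEdge, build_network
from combonet.set_distance import (
    ANTAGONISM,
    INDETERMINATE,
    SYNERGISM,
    CombinationAssessment,
    SetDistances,
    assess_pair,
    classify,
    relative_distances,
    set_distance,
    synergy_score,
    write_assessments,
)
from combonet.synthetic import SyntheticSpec, generate_combination

from _oracles import brute_force_set_distance, random_network_and_profile


class TestSetDistance:
    def test_identical_singletons(self):
        net = build_network([], extra_nodes=["a"])
        assert set_distance(net, {"a"}, {"a"}) == 0

    def test_two_source_example(self):
        net = build_network(
            [
                RegEdge("a", "c", "activation"),
                RegEdge("b", "x", "activation"),
                RegEdge("x", "c", "activation"),
            ]
        )
        # forward: (1 + 2)/2 = 1.5; no reverse reachability
        assert math.isclose(set_distance(net, {"a", "b"}, {"c"}), 1.5)

    def test_empty_set_undefined(self, chain_network, caplog):
        with caplog.at_level("WARNING"):
            assert set_distance(chain_network, set(), {"A"}) is None

    def test_stray_node_rejected(self, chain_network):
        with pytest.raises(ValueError, match="absent"):
            set_distance(chain_network, {"A"}, {"ZZZ"})

    def test_no_reachability_undefined(self):
        net = build_network([], extra_nodes=["a", "b"])
        assert set_distance(net, {"a"}, {"b"}) is None

    def test_symmetry_random(self):
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(250):
            network, _ = random_network_and_profile(rng)
            nodes = sorted(network.nodes)
            size_i = int(rng.integers(1, len(nodes) + 1))
            size_j = int(rng.integers(1, len(nodes) + 1))
            set_i = set(rng.choice(nodes, size=size_i, replace=False))
            set_j = set(rng.choice(nodes, size=size_j, replace=False))
            d_ij = set_distance(network, set_i, set_j)
            d_ji = set_distance(network, set_j, set_i)
            if d_ij is None:
                assert d_ji is None
            else:
                assert math.isclose(d_ij, d_ji, rel_tol=0, abs_tol=1e-12)
                checked += 1
        assert checked >= 100

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(250):
            network, _ = random_network_and_profile(rng)
            nodes = sorted(network.nodes)
            set_i = set(rng.choice(nodes, size=int(rng.integers(1, len(nodes) + 1)), replace=False))
            set_j = set(rng.choice(nodes, size=int(rng.integers(1, len(nodes) + 1)), replace=False))
            got = set_distance(network, set_i, set_j)
            expected = brute_force_set_distance(network, set_i, set_j)
            if expected is None:
                assert got is None
            else:
                assert math.isclose(got, expected, rel_tol=0, abs_tol=1e-12)

    def test_disconnected_component_does_not_change_distance(self, chain_network):
        base = set_distance(chain_network, {"A"}, {"C"})
        bigger = build_network(
            list(chain_network.edges) + [RegEdge("u", "v", "inhibition")],
            extra_nodes=chain_network.nodes,
        )
        assert set_distance(bigger, {"A"}, {"C"}) == base


class TestRelativeDistances:
    def test_reference_sample_2(self):
        d_plus, d_minus = relative_distances(SetDistances(2.80, 3.91, 4.38, 4.51))
        assert math.isclose(d_plus, -1.58, abs_tol=1e-9)
        assert math.isclose(d_minus, -0.47, abs_tol=1e-9)

    def test_reference_sample_9(self):
        d_plus, d_minus = relative_distances(SetDistances(5.31, 3.41, 5.07, 5.15))
        assert math.isclose(d_plus, 0.24, abs_tol=1e-9)
        assert math.isclose(d_minus, -1.66, abs_tol=1e-9)

    def test_all_equal_cancels(self):
        assert relative_distances(SetDistances(2.0, 2.0, 2.0, 2.0)) == (0.0, 0.0)

    def test_undefined_cross_min(self):
        assert relative_distances(SetDistances(1.0, 1.0, None, None)) == (None, None)

    def test_one_sided_cross_min(self):
        d_plus, d_minus = relative_distances(SetDistances(1.0, 3.0, None, 2.0))
        assert (d_plus, d_minus) == (-1.0, 1.0)

    def test_undefined_forward(self):
        d_plus, d_minus = relative_distances(SetDistances(None, 3.0, 2.0, 2.5))
        assert d_plus is None
        assert d_minus == 1.0


class TestClassify:
    @pytest.mark.parametrize(
        "d_plus,d_minus,expected",
        [
            (-1.58, -0.47, SYNERGISM),
            (0.24, -1.66, ANTAGONISM),
            (-0.24, 0.12, ANTAGONISM),
            (0.0, 0.0, INDETERMINATE),
            (None, -1.0, INDETERMINATE),
            (-0.5, None, INDETERMINATE),
            (-0.5, 0.0, INDETERMINATE),  # catch-all: no rule fires
        ],
    )
    def test_cases(self, d_plus, d_minus, expected):
        assert classify(d_plus, d_minus) == expected


class TestSynergyScore:
    def test_values(self):
        assert math.isclose(synergy_score(-1.58, -0.47), 0.47)
        assert math.isclose(synergy_score(0.24, -1.66), -0.24)

    def test_undefined(self):
        assert synergy_score(None, 1.0) is None

    @given(
        st.floats(-10, 10, allow_nan=False),
        st.floats(-10, 10, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_sign_consistent_with_classify(self, d_plus, d_minus):
        score = synergy_score(d_plus, d_minus)
        call = classify(d_plus, d_minus)
        if score > 0:
            assert call == SYNERGISM
        elif score < 0:
            assert call == ANTAGONISM


class TestAssessPair:
    def test_planted_synergy(self):
        net, pa, pb, _ = generate_combination(SyntheticSpec(planted="synergism", seed=5))
        assessment = assess_pair(net, pa, pb, AttenuationParams(1.5, 1.1, 2))
        assert assessment.call == SYNERGISM
        assert assessment.d_plus < 0 and assessment.d_minus < 0
        assert assessment.score > 0

    def test_planted_antagonism(self):
        net, pa, pb, _ = generate_combination(SyntheticSpec(planted="antagonism", seed=5))
        assessment = assess_pair(net, pa, pb, AttenuationParams(1.5, 1.1, 2))
        assert assessment.call == ANTAGONISM

    def test_disconnected_drugs_indeterminate(self):
        net = build_network(
            [RegEdge("a1", "a2", "activation"), RegEdge("b1", "b2", "activation")]
        )
        pa = DrugActionProfile("A", {"a1": "activation", "a2": "inhibition"})
        pb = DrugActionProfile("B", {"b1": "activation", "b2": "inhibition"})
        assessment = assess_pair(net, pa, pb)
        assert assessment.call == INDETERMINATE
        assert assessment.score is None

    def test_all_zero_effect_indeterminate(self, caplog):
        # drug B's only target is missing from the network -> no nonzero IA
        net = build_network([RegEdge("a1", "a2", "activation")])
        pa = DrugActionProfile("A", {"a1": "activation"})
        pb = DrugActionProfile("B", {"zz": "activation"})
        with caplog.at_level("WARNING"):
            assessment = assess_pair(net, pa, pb)
        assert assessment.call == INDETERMINATE

    def test_drug_order_symmetry(self):
        rng = np.random.default_rng(23)
        for _ in range(40):
            network, pa = random_network_and_profile(rng)
            _, pb = random_network_and_profile(rng)
            pb = DrugActionProfile(
                "other",
                {t: a for t, a in pb.actions.items() if t in network.nodes},
            )
            if not pb.actions:
                continue
            ab = assess_pair(network, pa, pb)
            ba = assess_pair(network, pb, pa)
            assert ab.call == ba.call
            for x, y in ((ab.d_plus, ba.d_plus), (ab.d_minus, ba.d_minus)):
                if x is None:
                    assert y is None
                else:
                    assert math.isclose(x, y, rel_tol=0, abs_tol=1e-12)


def test_assessment_dump(tmp_path):
    assessment = CombinationAssessment(
        drug_a="D1",
        drug_b="D2",
        distances=SetDistances(1.0, None, 2.0, 2.5),
        d_plus=-1.0,
        d_minus=None,
        call=INDETERMINATE,
        score=None,
    )
    out = tmp_path / "assess.tsv"
    write_assessments([assessment], out)
    lines = out.read_text().splitlines()
    assert lines[0].split("\t") == [
        "drug_a", "drug_b", "d_pp", "d_mm", "d_pm", "d_mp", "d_plus", "d_minus", "call", "score",
    ]
    fields = lines[1].split("\t")
    assert fields[3] == "NA" and fields[7] == "NA" and fields[9] == "NA"
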