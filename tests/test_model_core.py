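import numpy as np
import pytest

from crosstalksim.model_core import (
    BACKBONE_EDGES,
    DrugDose,
    DrugRegimen,
    MODULE_IDS,
    ModuleTopology,
    Species,
    build_module,
    default_parameters,
    stimulus_library,
    validate_topology,
)

A, B, C, D, O = Species.A, Species.B, Species.C, Species.D, Species.O

# crosstalk edge -> expected V at scale 1, per module
EXPECTED_CROSSTALK = {
    0: {},
    1: {(A, D): +0.4},
    2: {(A, D): -1.0},
    3: {(B, C): +0.4},
    4: {(B, C): -1.0},
    5: {(B, C): +0.4, (D, A): +0.4},
    6: {(B, C): -0.5, (D, A): -1.0},
    7: {(B, C): -1.0, (D, A): +0.4},
    8: {(B, C): +0.4, (D, A): -1.0},
}


class TestBuildModule:
    @pytest.mark.parametrize("module_id", MODULE_IDS)
    def test_backbone_present_in_every_module(self, module_id):
        topo = build_module(module_id)
        for src, dst in BACKBONE_EDGES:
            assert topo.edge(src, dst) == pytest.approx(0.4)
            assert topo.K[src.idx, dst.idx] == pytest.approx(0.8)

    @pytest.mark.parametrize("module_id", MODULE_IDS)
    def test_crosstalk_edges_match_registry(self, module_id):
        topo = build_module(module_id)
        expected = EXPECTED_CROSSTALK[module_id]
        assert topo.crosstalk_edges == set(expected)
        for (src, dst), v in expected.items():
            assert topo.edge(src, dst) == pytest.approx(v)
        # no stray edges beyond backbone + crosstalk
        n_edges = np.count_nonzero(topo.V)
        assert n_edges == len(BACKBONE_EDGES) + len(expected)

    def test_module0_has_no_crosstalk(self):
        assert build_module(0, 1).crosstalk_edges == frozenset()

    @pytest.mark.parametrize("module_id", MODULE_IDS[1:])
    def test_scale_acts_only_on_crosstalk_edges(self, module_id):
        base = build_module(module_id, 1.0)
        scaled = build_module(module_id, 3.0)
        for src, dst in BACKBONE_EDGES:
            assert scaled.edge(src, dst) == base.edge(src, dst)
        for src, dst in base.crosstalk_edges:
            assert scaled.edge(src, dst) == pytest.approx(
                3.0 * base.edge(src, dst)
            )

    @pytest.mark.parametrize("module_id", MODULE_IDS[1:])
    def test_small_scale_degenerates_to_module0(self, module_id):
        tiny = build_module(module_id, 1e-9)
        base0 = build_module(0)
        assert np.allclose(tiny.V, base0.V, atol=1e-8)

    def test_module6_asymmetric_mutual_inhibition(self):
        topo = build_module(6)
        assert abs(topo.edge(D, A)) > abs(topo.edge(B, C))

    @pytest.mark.parametrize("bad", [-1, 9, 42])
    def test_unknown_module_id_rejected(self, bad):
        with pytest.raises(ValueError, match="0-8"):
            build_module(bad)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError, match="crosstalk_scale"):
            build_module(1, 0.0)


def test_default_parameters_standard_values():
    p = default_parameters()
    assert (p.d, p.K_D) == (0.2, 0.1)
    assert (p.V_A, p.K_A, p.V_C, p.K_C) == (0.2, 0.5, 0.2, 0.5)
    assert (p.V_act, p.V_inh, p.K_default) == (0.4, -1.0, 0.8)


class TestStimulusLibrary:
    def test_contains_basic_and_variants(self):
        lib = stimulus_library()
        assert set(lib) == {"S0", "S1", "S2", "S3", "S4", "S5", "S6"}
        for g1, g2 in lib.values():
            assert g1.channel == "G1" and g2.channel == "G2"

    def test_s0_is_unit_pulse(self):
        g1, _ = stimulus_library()["S0"]
        assert g1(0.0) == 1.0
        assert g1(15.0) == 1.0
        assert g1(30.0) == 0.0
        assert g1(99.0) == 0.0

    def test_amplitudes_bounded_by_one(self):
        for g1, g2 in stimulus_library().values():
            for profile in (g1, g2):
                assert all(amp <= 1.0 for _, _, amp in profile.segments)

    def test_overlapping_segments_rejected(self):
        from crosstalksim.model_core import StimulusProfile

        with pytest.raises(ValueError, match="overlap"):
            StimulusProfile("bad", "G1", ((0, 10, 1.0), (5, 15, 1.0)))

    def test_negative_amplitude_rejected(self):
        from crosstalksim.model_core import StimulusProfile

        with pytest.raises(ValueError, match="amplitude"):
            StimulusProfile("bad", "G1", ((0, 10, -0.5),))


class TestValidateTopology:
    @pytest.mark.parametrize("module_id", MODULE_IDS)
    def test_registry_modules_are_valid(self, module_id):
        assert validate_topology(build_module(module_id)) == []

    def test_zero_k_on_active_edge_flagged(self):
        topo = build_module(3)
        K = topo.K.copy()
        K[B.idx, C.idx] = 0.0
        bad = ModuleTopology(topo.module_id, topo.V, K,
                             topo.crosstalk_edges, topo.crosstalk_scale)
        violations = validate_topology(bad)
        assert len(violations) == 1 and "K[B,C]" in violations[0]

    def test_missing_backbone_edge_flagged(self):
        topo = build_module(0)
        V = topo.V.copy()
        V[B.idx, O.idx] = 0.0
        bad = ModuleTopology(0, V, topo.K)
        violations = validate_topology(bad)
        assert any("B->O" in v for v in violations)

    def test_module0_with_crosstalk_flagged(self):
        topo = build_module(1)
        bad = ModuleTopology(0, topo.V, topo.K, topo.crosstalk_edges)
        assert any("module 0" in v for v in validate_topology(bad))

    def test_wrong_crosstalk_sign_flagged(self):
        topo = build_module(1)  # A -> D activation
        V = topo.V.copy()
        V[A.idx, D.idx] = -0.4
        bad = ModuleTopology(1, V, topo.K, topo.crosstalk_edges)
        assert any("sign" in v for v in validate_topology(bad))


class TestSpeciesAndRegimens:
    @pytest.mark.parametrize("raw,expected", [
        ("b", B), ("O", O), (1, A), (5, O), (D, D),
    ])
    def test_species_parse(self, raw, expected):
        assert Species.parse(raw) is expected

    @pytest.mark.parametrize("raw", ["X", 0, 6])
    def test_species_parse_rejects(self, raw):
        with pytest.raises(ValueError):
            Species.parse(raw)

    def test_output_is_index_five(self):
        assert Species.O == 5 and len(Species) == 5

    def test_regimen_labels(self):
        assert DrugRegimen.untreated().label == "untreated"
        assert DrugRegimen.single("B").label == "B(1)"
        assert DrugRegimen.combo(["B", "D"], 0.5).label == "B(0.5)+D(0.5)"

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError, match="dose"):
            DrugDose(B, -0.1)

    def test_regimen_round_trip(self):
        reg = DrugRegimen.combo(["B", "B"], 1.0)
        assert DrugRegimen.from_dict(reg.to_dict()) == reg
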