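"""Editing-state chemistry: mass deltas, CE ensembles, species enumeration."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pseudomap.chemistry import (
    ChemistryError,
    apply_editing,
    cyanoethylate,
    enumerate_species,
    seq_to_fragment,
)
from pseudomap.digestion import neutral_mass
from pseudomap.maldi import mz
from pseudomap.sequence import parse_modified_sequence


def seq_mass(seq):
    return neutral_mass(seq_to_fragment(seq))


class TestApplyEditing:
    def test_c_to_u_mass_shift(self, trna_seq):
        edited = apply_editing(trna_seq, 32, "U")
        assert edited.code_at(32) == "U"
        assert seq_mass(edited) - seq_mass(trna_seq) == pytest.approx(0.98402, abs=1e-4)

    def test_c_to_psi_is_isobaric_with_u(self, trna_seq):
        as_u = apply_editing(trna_seq, 32, "U")
        as_psi = apply_editing(trna_seq, 32, "Y")
        assert seq_mass(as_psi) == pytest.approx(seq_mass(as_u), abs=1e-12)

    def test_o18_label_adds_two_daltons(self, trna_seq):
        light = apply_editing(trna_seq, 32, "U")
        heavy = apply_editing(trna_seq, 32, "U", o18_labeled=True)
        assert 32 in heavy.o18_positions
        assert seq_mass(heavy) - seq_mass(light) == pytest.approx(2.00425, abs=1e-4)

    def test_reverting_to_c_drops_the_label(self, trna_seq):
        heavy = apply_editing(trna_seq, 32, "Y", o18_labeled=True)
        back = apply_editing(heavy, 32, "C")
        assert back.o18_positions == frozenset()

    def test_non_editable_site_rejected(self, trna_seq):
        with pytest.raises(ChemistryError):
            apply_editing(trna_seq, 13, "U")  # G13


class TestCyanoethylate:
    def test_full_efficiency_single_species(self):
        frag = seq_to_fragment(parse_modified_sequence("AGAU", [(4, "Y")]))
        (species,) = cyanoethylate(frag, efficiency=1.0)
        assert species.fragment.ce_count == 1
        assert neutral_mass(species.fragment) - neutral_mass(frag) == pytest.approx(
            53.0266, abs=1e-4
        )

    def test_no_reactive_sites_identity(self):
        frag = seq_to_fragment(parse_modified_sequence("AGAC"))
        (species,) = cyanoethylate(frag, efficiency=1.0)
        assert species.fragment == frag and species.weight == 1.0

    def test_half_efficiency_binomial_split(self):
        frag = seq_to_fragment(parse_modified_sequence("AGAU", [(4, "Y")]))
        ensemble = cyanoethylate(frag, efficiency=0.5)
        weights = sorted((s.fragment.ce_count, s.weight) for s in ensemble)
        assert weights == [(0, 0.5), (1, 0.5)]

    def test_two_sites_binomial(self):
        frag = seq_to_fragment(parse_modified_sequence("AUAU", [(2, "Y"), (4, "Y")]))
        ensemble = cyanoethylate(frag, efficiency=0.5)
        weights = {s.fragment.ce_count: s.weight for s in ensemble}
        assert weights == pytest.approx({0: 0.25, 1: 0.5, 2: 0.25})


class TestEnumerateSpecies:
    def test_unedited_condition_collapses(self, agac_fragment):
        ensemble = enumerate_species(agac_fragment, 32, edit_fraction=0.0)
        (species,) = ensemble
        assert species.label.state == "C" and species.weight == 1.0

    def test_fully_edited_ce_collapses_to_psi_ce(self, agac_fragment):
        ensemble = enumerate_species(
            agac_fragment, 32, edit_fraction=1.0, ce_efficiency=1.0, o18_fraction=0.0
        )
        (species,) = ensemble
        assert species.label.state == "Y" and species.label.ce == 1

    def test_three_way_split_at_half_labeling(self, agac_fragment):
        ensemble = enumerate_species(
            agac_fragment, 32, edit_fraction=0.5, ce_efficiency=1.0, o18_fraction=0.5
        )
        weights = {s.label.text(): s.weight for s in ensemble}
        assert weights == pytest.approx({"C": 0.5, "Ψ+CE": 0.25, "Ψ+CE+18O": 0.25})

    def test_u_state_is_ce_silent(self, agac_fragment):
        ensemble = enumerate_species(
            agac_fragment, 32, edit_fraction=1.0, o18_fraction=0.5, edit_state="U"
        )
        assert all(s.label.ce == 0 for s in ensemble)
        assert {s.label.o18 for s in ensemble} == {True, False}

    def test_composed_edit_plus_ce_mass(self, agac_fragment):
        # editing then CE must equal the enumerated Ψ+CE species mass
        ensemble = enumerate_species(
            agac_fragment, 32, edit_fraction=1.0, ce_efficiency=1.0, o18_fraction=0.0
        )
        (species,) = ensemble
        expected = mz(agac_fragment) + 0.98402 + 53.0266
        assert mz(species.fragment) == pytest.approx(expected, abs=1e-4)

    def test_position_outside_fragment_rejected(self, gagd_fragment):
        with pytest.raises(ChemistryError):
            enumerate_species(gagd_fragment, 32, edit_fraction=0.5)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        st.floats(0, 1, allow_nan=False),
        st.floats(0, 1, allow_nan=False),
        st.floats(0, 1, allow_nan=False),
    )
    def test_weights_always_sum_to_one(self, f, c, w):
        from pseudomap.simulate import SimConfig, make_trna_like
        from pseudomap.digestion import digest, protect_window, RNASE_A

        seq = make_trna_like(SimConfig(seed=1))
        (frag,) = [x for x in digest(protect_window(seq), RNASE_A) if x.covers(32)]
        ensemble = enumerate_species(frag, 32, f, c, w)
        assert sum(s.weight for s in ensemble) == pytest.approx(1.0, abs=1e-9)
        assert all(s.weight > 0 for s in ensemble)
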