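"""m/z computation against an independent NMP oracle, matching, inference."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pseudomap.chemistry import Species, SpeciesLabel, candidate_species
from pseudomap.digestion import Fragment
from pseudomap.maldi import (
    MatchingError,
    estimate_edit_fraction,
    infer_editing_state,
    load_peaklist,
    match_peaks,
    mz,
)

# Independent oracle: published monoisotopic masses of the 5'-NMPs and water.
NMP = {"A": 347.063084, "G": 363.057999, "C": 323.051851, "U": 324.035867}
WATER = 18.010565
PROTON = 1.007276


def oracle_mz(bases: str) -> float:
    """[M-H]- of a 5'-OH/3'-p oligo = Σ NMP − (n−1)·H2O − H+."""
    neutral = sum(NMP[b] for b in bases) - (len(bases) - 1) * WATER
    return neutral - PROTON


def peaks_frame(rows):
    return pd.DataFrame(rows, columns=["mz", "intensity"])


class TestMz:
    def test_agac_matches_nmp_oracle(self, agac_fragment):
        assert mz(agac_fragment) == pytest.approx(oracle_mz("AGAC"), abs=1e-4)

    def test_positive_mode_offset(self, agac_fragment):
        assert mz(agac_fragment, ion="[M+H]+") - mz(agac_fragment) == pytest.approx(
            2 * 1.0072765, abs=1e-5
        )

    def test_unknown_ion_rejected(self, agac_fragment):
        with pytest.raises(MatchingError):
            mz(agac_fragment, ion="[M+Na]+")

    def test_gagd_equals_u_tetramer_plus_h2(self, gagd_fragment):
        assert mz(gagd_fragment) == pytest.approx(oracle_mz("GAGU") + 2.01565, abs=1e-3)


class TestMatchPeaks:
    def test_exact_peaks_all_matched(self, theoretical_species):
        peaks = peaks_frame(
            [(mz(s.fragment), 100.0) for s in theoretical_species]
        )
        assignments = match_peaks(theoretical_species, peaks)
        assert len(assignments) == len(theoretical_species)
        assert all(a.error == pytest.approx(0.0, abs=1e-9) for a in assignments)

    def test_offset_beyond_tolerance_unmatched(self, agac_fragment):
        species = [Species(agac_fragment, 1.0)]
        peaks = peaks_frame([(mz(agac_fragment) + 0.6, 50.0)])
        assert match_peaks(species, peaks, tolerance_da=0.3) == []

    def test_close_species_resolved_to_nearer_mass(self, agac_fragment):
        # C and U species sit 0.984 Da apart; a peak 0.3 Da above the C
        # species is within tolerance of both but nearer to C
        species = candidate_species(agac_fragment, 32, include_o18=False)
        by_label = {s.label.text(): s for s in species}
        peaks = peaks_frame([(mz(by_label["C"].fragment) + 0.3, 10.0)])
        assignments = match_peaks(species, peaks, tolerance_da=0.8)
        assert len(assignments) == 1
        assert assignments[0].label.text() == "C"

    def test_each_peak_and_species_used_once(self, agac_fragment):
        species = [Species(agac_fragment, 1.0)]
        m = mz(agac_fragment)
        peaks = peaks_frame([(m - 0.05, 10.0), (m + 0.01, 90.0)])
        assignments = match_peaks(species, peaks)
        assert len(assignments) == 1
        assert assignments[0].mz_observed == pytest.approx(m + 0.01)

    def test_assignments_recompute_from_formula(self, theoretical_species):
        peaks = peaks_frame([(mz(s.fragment) + 0.05, 10.0) for s in theoretical_species])
        for a in match_peaks(theoretical_species, peaks):
            assert a.mz_theoretical == pytest.approx(mz(a.fragment), abs=1e-6)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(tol_a=st.floats(0.01, 0.5), tol_b=st.floats(0.01, 0.5))
    def test_shrinking_tolerance_never_adds_assignments(self, tol_a, tol_b):
        from pseudomap.digestion import RNASE_A, digest, protect_window
        from pseudomap.simulate import SimConfig, make_trna_like

        seq = make_trna_like(SimConfig(seed=1))
        species = [
            Species(f, 1.0) for f in digest(protect_window(seq), RNASE_A)
        ]
        rng = np.random.default_rng(7)
        peaks = peaks_frame(
            [(mz(s.fragment) + rng.normal(0, 0.15), 10.0) for s in species]
        )
        lo, hi = sorted((tol_a, tol_b))
        n_lo = len(match_peaks(species, peaks, tolerance_da=lo))
        n_hi = len(match_peaks(species, peaks, tolerance_da=hi))
        assert n_lo <= n_hi


def _diag_assignments(fragment, intensities):
    """Build assignments for labeled diagnostic species with set intensities."""
    species = candidate_species(fragment, 32)
    by_label = {s.label.text(): s for s in species}
    peaks = peaks_frame(
        [(mz(by_label[t].fragment), i) for t, i in intensities.items()]
    )
    return match_peaks(list(by_label.values()), peaks)


class TestInference:
    def test_only_unedited_species_calls_c(self, agac_fragment):
        call = infer_editing_state(_diag_assignments(agac_fragment, {"C": 100.0}), 32)
        assert call.state == "C" and call.edited_fraction == 0.0

    def test_ce_shifted_species_calls_psi(self, agac_fragment):
        call = infer_editing_state(_diag_assignments(agac_fragment, {"Ψ+CE": 80.0}), 32)
        assert call.state == "Y" and call.edited_fraction == 1.0

    def test_plus_one_without_ce_calls_u(self, agac_fragment):
        call = infer_editing_state(_diag_assignments(agac_fragment, {"U": 60.0}), 32)
        assert call.state == "U" and call.edited_fraction == 1.0

    def test_mixture_reports_fraction(self, agac_fragment):
        call = infer_editing_state(
            _diag_assignments(agac_fragment, {"C": 50.0, "Ψ+CE": 150.0}), 32
        )
        assert call.state == "Y"
        assert call.edited_fraction == pytest.approx(0.75)

    def test_no_diagnostic_fragment_errors(self, gagd_fragment):
        peaks = peaks_frame([(mz(gagd_fragment), 10.0)])
        assignments = match_peaks([Species(gagd_fragment, 1.0)], peaks)
        with pytest.raises(MatchingError):
            infer_editing_state(assignments, 32)


class TestFractionEstimator:
    def test_even_split_gives_half(self, agac_fragment):
        assignments = _diag_assignments(agac_fragment, {"C": 70.0, "Ψ+CE": 70.0})
        assert estimate_edit_fraction(assignments) == pytest.approx(0.5)

    def test_scale_invariance(self, agac_fragment):
        base = {"C": 30.0, "Ψ+CE": 60.0, "Ψ+CE+18O": 10.0}
        f1 = estimate_edit_fraction(_diag_assignments(agac_fragment, base))
        scaled = {k: 37.5 * v for k, v in base.items()}
        f2 = estimate_edit_fraction(_diag_assignments(agac_fragment, scaled))
        assert f1 == pytest.approx(f2, abs=1e-12)

    def test_zero_intensity_errors(self, agac_fragment):
        assignments = _diag_assignments(agac_fragment, {"C": 0.0})
        with pytest.raises(MatchingError):
            estimate_edit_fraction(assignments)

    def test_no_labeled_species_errors(self, gagd_fragment):
        peaks = peaks_frame([(mz(gagd_fragment), 10.0)])
        assignments = match_peaks([Species(gagd_fragment, 1.0)], peaks)
        with pytest.raises(MatchingError):
            estimate_edit_fraction(assignments)


class TestPeakListIO:
    def test_load_tsv_with_header(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("mz\tintensity\n1325.20\t80\n1000.0\t5\n")
        peaks = load_peaklist(path)
        assert list(peaks["mz"]) == [1000.0, 1325.2]  # sorted ascending

    def test_load_csv_headerless(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text("1325.2,80\n1379.2,20\n")
        assert len(load_peaklist(path)) == 2

    def test_missing_file_names_path(self, tmp_path):
        with pytest.raises(MatchingError, match="nope.tsv"):
            load_peaklist(tmp_path / "nope.tsv")

    def test_negative_values_rejected(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("mz\tintensity\n-5.0\t10\n")
        with pytest.raises(MatchingError):
            load_peaklist(path)
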