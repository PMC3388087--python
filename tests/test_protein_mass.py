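"""Intact masses, m/z conversion, and contiguous fragment-mass search."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hemequant import (
    MassPeak, ProteinConstruct, average_mass, construct_from_fasta,
    fragment_search, mz_to_neutral, neutral_to_mz, sequence_mass,
)
from hemequant.protein_mass import (
    AVERAGE_RESIDUE_MASS, MassError, WATER_AVERAGE, read_peak_csv,
)
from hemequant import synthetic as syn


def simple_construct(seq):
    return ProteinConstruct(sequence=seq, ref_numbers=range(1, len(seq) + 1))


class TestAverageMass:
    def test_single_glycine(self):
        assert sequence_mass("G") == pytest.approx(75.07, abs=0.005)

    def test_two_glycines_one_water(self):
        assert sequence_mass("GG") == pytest.approx(132.12, abs=0.005)

    def test_subrange_by_reference_numbers(self):
        c = simple_construct("GAVLI")
        assert average_mass(c, 2, 3) == pytest.approx(
            AVERAGE_RESIDUE_MASS["A"] + AVERAGE_RESIDUE_MASS["V"] + WATER_AVERAGE)

    def test_range_outside_construct(self):
        c = simple_construct("GAVLI")
        with pytest.raises(MassError, match="not in construct"):
            average_mass(c, 2, 9)

    @settings(deadline=None, derandomize=True)
    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=2, max_size=40),
           st.integers(0, 100))
    def test_split_additivity(self, seq, cut_seed):
        c = simple_construct(seq)
        k = 1 + cut_seed % (len(seq) - 1) if len(seq) > 1 else 1
        whole = average_mass(c, 1, len(seq))
        left = average_mass(c, 1, k)
        right = average_mass(c, k + 1, len(seq))
        assert whole == pytest.approx(left + right - WATER_AVERAGE, abs=1e-9)

    def test_against_pyteomics_average_masses(self):
        """Independent oracle: pyteomics' isotope-abundance-weighted masses."""
        pyteomics_mass = pytest.importorskip("pyteomics.mass")
        seq = "ACDEFGHIKLMNPQRSTVWY" * 3
        ours = sequence_mass(seq)
        theirs = pyteomics_mass.calculate_mass(sequence=seq, average=True)
        assert ours == pytest.approx(theirs, rel=2e-5)

    def test_monoisotopic_flag_against_pyteomics(self):
        pyteomics_mass = pytest.importorskip("pyteomics.mass")
        seq = "PEPTIDEWKR"
        ours = sequence_mass(seq, monoisotopic=True)
        theirs = pyteomics_mass.calculate_mass(sequence=seq)
        assert ours == pytest.approx(theirs, abs=0.001)


class TestMzConversion:
    def test_singly_protonated(self):
        assert round(mz_to_neutral(MassPeak(mz=6820.0))) == 6819
        assert round(mz_to_neutral(MassPeak(mz=4445.0))) == 4444

    def test_bare_proton(self):
        assert mz_to_neutral(MassPeak(mz=1.008)) == pytest.approx(0.0, abs=1e-9)

    @settings(deadline=None, derandomize=True)
    @given(mass=st.floats(100, 30000), charge=st.integers(1, 5))
    def test_round_trip_identity(self, mass, charge):
        mz = neutral_to_mz(mass, charge)
        assert mz_to_neutral(MassPeak(mz=mz, charge=charge)) == pytest.approx(mass, rel=1e-12)

    def test_invalid_peaks_rejected(self):
        with pytest.raises(MassError):
            MassPeak(mz=-5.0)
        with pytest.raises(MassError):
            MassPeak(mz=100.0, charge=0)


class TestFragmentSearch:
    def test_whole_chain_identity(self):
        c = simple_construct("ACDEFGHIKLMNPQRSTVWY")
        target = average_mass(c)
        matches = fragment_search(c, [target], tolerance_da=0.5)[0]
        assert matches[0].start_ref == 1 and matches[0].end_ref == 20
        assert matches[0].delta == pytest.approx(0.0, abs=1e-9)

    def test_all_ggg_windows_found(self):
        c = simple_construct("GGGG")
        matches = fragment_search(c, [3 * 57.0519 + WATER_AVERAGE], tolerance_da=0.1)[0]
        spans = {(m.start_ref, m.end_ref) for m in matches}
        assert spans == {(1, 3), (2, 4)}

    def test_brute_force_oracle_exact(self):
        """Prefix-sum masses equal naive per-window summation, and the search
        returns exactly the windows the oracle says are in tolerance."""
        for seed in (1, 2, 3):
            c = syn.random_construct(120, seed=seed)
            rng = np.random.default_rng(seed + 100)
            naive = {}
            for i, j in itertools.combinations_with_replacement(range(len(c)), 2):
                naive[(i + 1, j + 1)] = sequence_mass(c.sequence[i:j + 1])
            for _ in range(5):
                i, j = sorted(rng.integers(0, len(c), 2))
                target = naive[(i + 1, j + 1)]
                tol = 0.5
                expected = {k for k, m in naive.items() if abs(m - target) <= tol}
                got = fragment_search(c, [target], tolerance_da=tol)[0]
                assert {(m.start_ref, m.end_ref) for m in got} == expected
                for m in got:
                    assert m.neutral_mass == pytest.approx(
                        naive[(m.start_ref, m.end_ref)], abs=1e-6)

    def test_sort_order_and_tie_breaks(self):
        # GGGG: target between the G3 windows and nothing else nearby
        c = simple_construct("GGGG")
        target = 3 * 57.0519 + WATER_AVERAGE + 0.01
        matches = fragment_search(c, [target], tolerance_da=0.1)[0]
        # equal |delta| -> equal length -> smaller start_ref first
        assert [(m.start_ref, m.end_ref) for m in matches] == [(1, 3), (2, 4)]

    def test_planted_fragment_recovered(self):
        c = syn.random_construct(150, seed=5)
        truths, peaks = syn.simulate_degradation(c, 4, calib_error_frac=5e-4, seed=9)
        targets = [mz_to_neutral(p) for p in peaks]
        per_target = fragment_search(c, targets, tolerance_frac=3 * 5e-4)
        for (i, j, mass), matches in zip(truths, per_target):
            assert (i, j) in {(m.start_ref, m.end_ref) for m in matches}

    def test_planted_fragment_is_top_match_without_calibration_error(self):
        c = syn.random_construct(150, seed=5)
        truths, peaks = syn.simulate_degradation(c, 4, calib_error_frac=0.0, seed=9)
        targets = [mz_to_neutral(p) for p in peaks]
        per_target = fragment_search(c, targets, tolerance_frac=1e-5)
        for (i, j, mass), matches in zip(truths, per_target):
            assert (matches[0].start_ref, matches[0].end_ref) == (i, j)

    def test_empty_target_list_rejected(self):
        with pytest.raises(MassError, match="empty"):
            fragment_search(simple_construct("GGGG"), [])


class TestConstructFromFasta:
    def test_met_span_tag_lengths(self, fasta_record):
        path, seq = fasta_record
        c = construct_from_fasta(path, native_range=(278, 497),
                                 c_term_tag="LEHHHHHH", n_term_met=True)
        assert len(c) == 1 + 220 + 8
        assert c.sequence[0] == "M"
        assert c.sequence[1:221] == seq[277:497]
        assert c.sequence[-8:] == "LEHHHHHH"
        assert c.ref_numbers[0] == 0
        assert c.ref_numbers[1] == 278 and c.ref_numbers[220] == 497
        assert all(r < 0 for r in c.ref_numbers[-8:])

    def test_no_met_no_tag(self, fasta_record):
        path, seq = fasta_record
        c = construct_from_fasta(path, native_range=(10, 20),
                                 n_term_met=False, c_term_tag="")
        assert c.sequence == seq[9:20]
        assert c.ref_numbers == tuple(range(10, 21))

    def test_met_variant_mass_difference(self, fasta_record):
        """Retained initiator Met adds exactly one Met residue mass."""
        path, _ = fasta_record
        with_met = construct_from_fasta(path, native_range=(10, 60), n_term_met=True)
        without = construct_from_fasta(path, native_range=(10, 60), n_term_met=False)
        assert average_mass(with_met) - average_mass(without) == pytest.approx(
            AVERAGE_RESIDUE_MASS["M"], abs=1e-9)

    def test_range_outside_record(self, fasta_record):
        path, _ = fasta_record
        with pytest.raises(MassError, match="outside"):
            construct_from_fasta(path, native_range=(400, 600))

    def test_numbering_offset(self, fasta_record):
        path, seq = fasta_record
        c = construct_from_fasta(path, native_range=(180, 392),
                                 numbering_start=101, n_term_met=True,
                                 c_term_tag="LEHHHHHH")
        # 1 Met + 213 native + 8 tag residues
        assert len(c) == 222
        assert c.sequence[1:214] == seq[79:292]


class TestPeakCsv:
    def test_round_trip(self, tmp_path):
        p = tmp_path / "peaks.csv"
        p.write_text("mz,intensity\n# comment\n4445.0,1200\n6820.0,800\n")
        peaks = read_peak_csv(p)
        assert [pk.mz for pk in peaks] == [4445.0, 6820.0]
        assert peaks[0].charge == 1
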