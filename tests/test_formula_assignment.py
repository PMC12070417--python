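"""Constrained formula enumeration, assignment and blank subtraction."""

import datetime

import numpy as np
import pytest

from fticrdom.chem_core import MolecularFormula, ion_mz
from fticrdom.formula_assignment import (
    AssignmentConfig,
    BlankPolicy,
    Candidate,
    _tie_break_key,
    assign_peaklist,
    blank_subtract,
    enumerate_candidates,
)
from fticrdom.peak_processing import estimate_noise_threshold, filter_peaks
from fticrdom.spectra_io import AssignedPeak, AssignedSample, SampleMetadata
from fticrdom.synthetic_data import SimulationConfig, simulate_sample

CONFIG = AssignmentConfig()


def formula_tuple(f: MolecularFormula) -> tuple:
    return (f.c, f.h, f.n, f.o, f.s)


class TestEnumerateCandidates:
    def test_glucose_ion_found(self):
        cands = enumerate_candidates(ion_mz(MolecularFormula.from_hill("C6H12O6")), CONFIG)
        assert MolecularFormula.from_hill("C6H12O6") in {c.formula for c in cands}

    def test_tiny_tolerance_off_mass_is_empty(self):
        config = AssignmentConfig(tol_ppm=1e-6)
        assert enumerate_candidates(179.123456, config) == []

    def test_soundness(self):
        rng = np.random.default_rng(2)
        for mz in rng.uniform(100, 700, 50):
            for cand in enumerate_candidates(float(mz), CONFIG):
                f = cand.formula
                assert 1 <= f.c <= 90 and 4 <= f.h <= 200 and 1 <= f.o <= 26
                assert 0 <= f.n <= 2 and 0 <= f.s <= 1
                theo = ion_mz(f)
                assert abs((mz - theo) / theo * 1e6) <= CONFIG.tol_ppm

    def test_oracle_equivalence_random_masses(self, brute_force_box):
        rng = np.random.default_rng(8)
        for mz in rng.uniform(100, 700, 250):
            mz = float(mz)
            got = {formula_tuple(c.formula) for c in enumerate_candidates(mz, CONFIG)}
            assert got == brute_force_box.candidates(mz, CONFIG.tol_ppm)

    def test_oracle_equivalence_near_true_ions(self, brute_force_box, small_library):
        rng = np.random.default_rng(9)
        for f in small_library[::3]:
            mz = ion_mz(f) * (1 + float(rng.uniform(-0.45, 0.45)) * 1e-6)
            got = {formula_tuple(c.formula) for c in enumerate_candidates(mz, CONFIG)}
            assert got == brute_force_box.candidates(mz, CONFIG.tol_ppm)
            assert formula_tuple(f) in got

    def test_dbe_filter_excludes_nonchemical(self, brute_force_box):
        config = AssignmentConfig(require_integer_dbe_ge_zero=False)
        rng = np.random.default_rng(10)
        for mz in rng.uniform(100, 700, 100):
            mz = float(mz)
            got = {formula_tuple(c.formula) for c in enumerate_candidates(mz, config)}
            assert got == brute_force_box.candidates(mz, config.tol_ppm, False)

    def test_nonpositive_mz_rejected(self):
        with pytest.raises(ValueError):
            enumerate_candidates(-5.0, CONFIG)


class TestTieBreaking:
    def test_smaller_error_wins(self):
        a = Candidate(MolecularFormula(c=10, h=12, o=4), 0.10)
        b = Candidate(MolecularFormula(c=9, h=8, n=2, o=4), 0.30)
        assert _tie_break_key(a, CONFIG.tie_break_order) < _tie_break_key(b, CONFIG.tie_break_order)

    def test_fewer_heteroatoms_break_error_ties(self):
        cho = Candidate(MolecularFormula(c=10, h=12, o=4), 0.20)
        chno = Candidate(MolecularFormula(c=9, h=10, n=1, o=4), -0.20)
        assert _tie_break_key(cho, CONFIG.tie_break_order) < _tie_break_key(chno, CONFIG.tie_break_order)

    def test_lower_dbe_breaks_remaining_ties(self):
        low = Candidate(MolecularFormula(c=10, h=16, o=4), 0.20)   # DBE 3
        high = Candidate(MolecularFormula(c=10, h=10, o=4), -0.20)  # DBE 6
        assert _tie_break_key(low, CONFIG.tie_break_order) < _tie_break_key(high, CONFIG.tie_break_order)

    def test_best_candidate_minimizes_abs_error(self):
        # a widened tolerance forces multiple candidates on one peak
        wide = AssignmentConfig(tol_ppm=20.0)
        mz = ion_mz(MolecularFormula.from_hill("C20H24O9"))
        cands = enumerate_candidates(mz, wide)
        assert len(cands) > 1
        assert abs(cands[0].ppm_error) == min(abs(c.ppm_error) for c in cands)


class TestAssignPeaklist:
    def test_zero_drift_assignment_recovers_library(self, small_library):
        cfg = SimulationConfig(seed=11, n_formulas=150, drift_coeffs=(0, 0, 0),
                               noise_peaks=1000)
        peaks, truth = simulate_sample(small_library, cfg)
        noise = estimate_noise_threshold(peaks)
        filtered = filter_peaks(peaks, 100, 700, 0.01, noise)
        assigned = assign_peaklist(filtered, CONFIG)
        correct = assigned.formulas() & set(small_library)
        assert len(correct) / len(small_library) >= 0.99

    def test_unassigned_peaks_retained(self, small_library):
        cfg = SimulationConfig(seed=11, n_formulas=150, drift_coeffs=(0, 0, 0),
                               noise_peaks=500)
        peaks, _ = simulate_sample(small_library, cfg)
        assigned = assign_peaklist(peaks, CONFIG)
        assert len(assigned.peaks) == len(peaks)
        assert any(not p.assigned for p in assigned.peaks)


def make_assigned(sample_id, entries, acquisition_date, sample_type="sample"):
    meta = SampleMetadata(sample_id=sample_id, sample_type=sample_type,
                          acquisition_date=acquisition_date)
    peaks = [AssignedPeak(mz=200.0 + i, intensity=inten, calibrated_mz=200.0 + i,
                          formula=f, ppm_error=0.0 if f else float("nan"),
                          n_candidates=1 if f else 0)
             for i, (f, inten) in enumerate(entries)]
    return AssignedSample(meta=meta, peaks=peaks)


F1 = MolecularFormula.from_hill("C6H12O6")
F2 = MolecularFormula.from_hill("C10H14O5")
F3 = MolecularFormula.from_hill("C8H10O3")
DAY = datetime.date(2019, 4, 1)
OTHER_DAY = datetime.date(2019, 4, 2)


class TestBlankSubtract:
    def test_high_prominence_contaminant_removed(self):
        blank = make_assigned("b", [(F1, 25.0), (F2, 100.0)], DAY, "blank")
        sample = make_assigned("s", [(F1, 50.0), (F3, 10.0)], DAY)
        out, log = blank_subtract([sample], [blank], BlankPolicy())
        assert out[0].formulas() == {F3}
        assert set(log["formula"]) == {"C6H12O6"}

    def test_exactly_threshold_retained(self):
        # 20.0% prominence is NOT "more than 20%"
        blank = make_assigned("b", [(F1, 20.0), (F2, 100.0)], DAY, "blank")
        sample = make_assigned("s", [(F1, 50.0)], DAY)
        out, log = blank_subtract([sample], [blank], BlankPolicy())
        assert out[0].formulas() == {F1}
        assert len(log) == 0

    def test_different_day_blank_ignored(self):
        blank = make_assigned("b", [(F1, 90.0), (F2, 100.0)], OTHER_DAY, "blank")
        sample = make_assigned("s", [(F1, 50.0)], DAY)
        out, _ = blank_subtract([sample], [blank], BlankPolicy())
        assert out[0].formulas() == {F1}

    def test_no_same_day_blank_warns_and_passes_through(self, caplog):
        sample = make_assigned("s", [(F1, 50.0)], DAY)
        with caplog.at_level("WARNING", logger="fticrdom"):
            out, _ = blank_subtract([sample], [], BlankPolicy())
        assert out[0].formulas() == {F1}
        assert "no same-day blank" in caplog.text

    def test_monotone_in_blank_set(self):
        sample = make_assigned("s", [(F1, 50.0), (F2, 30.0), (F3, 20.0)], DAY)
        b1 = make_assigned("b1", [(F1, 90.0), (F2, 100.0)], DAY, "blank")
        b2 = make_assigned("b2", [(F3, 40.0), (F2, 100.0)], DAY, "blank")
        n_with_one = len(blank_subtract([sample], [b1])[0][0].formulas())
        n_with_two = len(blank_subtract([sample], [b1, b2])[0][0].formulas())
        assert n_with_two <= n_with_one

    def test_prominence_relative_to_blank_base_peak(self):
        # F1 at 15 counts is 15% of the blank's 100-count base peak: kept
        blank = make_assigned("b", [(F1, 15.0), (F2, 100.0)], DAY, "blank")
        sample = make_assigned("s", [(F1, 1e6)], DAY)  # huge in the sample
        out, _ = blank_subtract([sample], [blank])
        assert out[0].formulas() == {F1}
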