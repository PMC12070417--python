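"""Bulk metrics, compound classes, diversity and per-sample summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fticrdom.chem_core import MolecularFormula, compute_indices, default_mass_table
from fticrdom.dom_metrics import (
    BulkRecord,
    ClassBoundaryTable,
    EmptySampleError,
    bulk_metrics,
    classify_formula,
    diversity,
    sample_summary,
)
from fticrdom.spectra_io import AssignedPeak, AssignedSample, SampleMetadata


def assigned_sample(entries, sample_id="s"):
    peaks = [AssignedPeak(mz=200.0 + i, intensity=inten, calibrated_mz=200.0 + i,
                          formula=f, ppm_error=0.0, n_candidates=1)
             for i, (f, inten) in enumerate(entries)]
    return AssignedSample(meta=SampleMetadata(sample_id=sample_id), peaks=peaks)


def exact_record(f: MolecularFormula) -> BulkRecord:
    """Weight-% record of a pure compound from standard atomic weights."""
    w = default_mass_table().atomic_weight
    masses = {el: getattr(f, el.lower()) * w[el] for el in ("C", "H", "N", "O", "S")}
    total = sum(masses.values())
    return BulkRecord(
        wt_c=100 * masses["C"] / total, wt_h=100 * masses["H"] / total,
        wt_n=100 * masses["N"] / total, wt_o=100 * masses["O"] / total,
        wt_c_org=100 * masses["C"] / total)


class TestBulkMetrics:
    def test_glucose_composition(self):
        m = bulk_metrics(BulkRecord(wt_c=40.00, wt_h=6.71, wt_n=0, wt_o=53.29,
                                    wt_c_org=40.00))
        assert m.h_c_molar == pytest.approx(2.0, abs=0.01)
        assert m.o_c_molar == pytest.approx(1.0, abs=0.01)
        assert m.c_ox == pytest.approx(0.0, abs=0.02)
        assert m.or_value == pytest.approx(1.0, abs=0.01)
        assert math.isinf(m.c_n_molar)

    def test_all_carbon_organic(self):
        m = bulk_metrics(BulkRecord(wt_c=50, wt_h=5, wt_n=1, wt_o=40, wt_c_org=50))
        assert m.pct_c_org == pytest.approx(100.0)

    def test_reduced_hydrocarbon(self):
        # CH2-like stoichiometry: C_ox = 0 - 2 + 0 = -2
        m = bulk_metrics(BulkRecord(wt_c=85.6, wt_h=14.4, wt_n=0, wt_o=0, wt_c_org=85.6))
        assert m.c_ox == pytest.approx(-2.0, abs=0.01)
        assert m.or_value == pytest.approx(1.5, abs=0.01)

    def test_zero_carbon_rejected(self):
        with pytest.raises(ValueError):
            bulk_metrics(BulkRecord(wt_c=0, wt_h=5, wt_n=0, wt_o=50, wt_c_org=0))

    def test_corg_cannot_exceed_total(self):
        with pytest.raises(ValueError):
            BulkRecord(wt_c=40, wt_h=5, wt_n=0, wt_o=50, wt_c_org=45)

    @settings(max_examples=100, derandomize=True)
    @given(f=st.builds(MolecularFormula, c=st.integers(1, 60), h=st.integers(1, 120),
                       n=st.integers(0, 2), o=st.integers(0, 26)))
    def test_bulk_cox_equals_nosc_for_sulfur_free(self, f):
        # cross-module consistency: bulk C_ox of a pure compound's exact
        # stoichiometry equals the formula's NOSC when S = 0
        m = bulk_metrics(exact_record(f))
        assert m.c_ox == pytest.approx(compute_indices(f).nosc, abs=1e-9)


class TestClassification:
    @pytest.mark.parametrize(
        "hill, label",
        [
            ("C6H12O6", "carbohydrate"),
            ("C18H34O2", "lipid"),
            ("C9H13N3O5", "nucleotide"),     # cytidine-like: N/C 0.33, O/C 0.56, H/C 1.44
            ("C8H15NO6", "amino sugar"),     # N-acetylhexosamine-like
            ("C5H9NO2", "peptide"),          # proline-like residue
            ("C10H8O4", "oxy-aromatic"),     # low H/C phenolic
            ("C10H3", "unclassified"),       # H/C 0.3 matches no box
        ],
    )
    def test_reference_compounds(self, hill, label):
        assert classify_formula(MolecularFormula.from_hill(hill)) == label

    def test_first_matching_rule_wins(self):
        table = ClassBoundaryTable.from_yaml()
        order = [r.label for r in table.rules]
        assert order.index("peptide") < order.index("lipid")

    def test_schema_rejects_unknown_keys(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("rules:\n  - label: x\n    p_c: [0, 1]\n")
        with pytest.raises(ValueError):
            ClassBoundaryTable.from_yaml(p)

    def test_schema_rejects_inverted_bounds(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("rules:\n  - label: x\n    h_c: [2, 1]\n")
        with pytest.raises(ValueError):
            ClassBoundaryTable.from_yaml(p)


class TestDiversity:
    def test_uniform_maximizes_shannon(self):
        for n in (2, 5, 64):
            richness, shannon, _ = diversity(np.full(n, 3.5))
            assert richness == n
            assert shannon == pytest.approx(math.log(n), abs=1e-12)

    def test_single_formula(self):
        assert diversity([7.0]) == (1, 0.0, 0.0)

    def test_two_equal_formulas_gini(self):
        _, _, gini = diversity([0.5, 0.5])
        assert gini == pytest.approx(0.5)

    def test_zeros_ignored(self):
        richness, _, _ = diversity([1.0, 0.0, 2.0])
        assert richness == 2

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            diversity([0.0, 0.0])

    def test_against_skbio(self):
        from skbio.diversity.alpha import shannon, simpson
        rng = np.random.default_rng(4)
        counts = rng.integers(1, 50, size=30)
        richness, sh, gini = diversity(counts)
        assert sh == pytest.approx(float(shannon(counts, base=math.e)), abs=1e-9)
        assert gini == pytest.approx(float(simpson(counts)), abs=1e-9)

    @settings(max_examples=60, derandomize=True)
    @given(p=st.lists(st.floats(0.01, 100), min_size=1, max_size=40))
    def test_shannon_bounded_by_log_richness(self, p):
        richness, shannon, gini = diversity(p)
        assert shannon <= math.log(richness) + 1e-9
        assert 0.0 <= gini < 1.0


GLUCOSE = MolecularFormula.from_hill("C6H12O6")
BENZENE = MolecularFormula.from_hill("C6H6")        # NOSC -1
FUMARATE = MolecularFormula.from_hill("C4H4O4")     # NOSC +1
OLEIC = MolecularFormula.from_hill("C18H34O2")


class TestSampleSummary:
    def test_singleton_sample(self):
        m = sample_summary(assigned_sample([(GLUCOSE, 10.0)]))
        assert m.n_formulas == 1
        assert m.mean_c == 6 and m.mean_o == 6
        assert m.mean_nosc == pytest.approx(0.0)
        assert m.pct_class["carbohydrate"] == pytest.approx(100.0)
        assert m.shannon == 0.0

    def test_symmetric_nosc_cancels(self):
        m = sample_summary(assigned_sample([(BENZENE, 5.0), (FUMARATE, 5.0)]))
        assert m.mean_nosc == pytest.approx(0.0, abs=1e-12)

    def test_intensity_weighted_means_hand_computed(self):
        entries = [(GLUCOSE, 0.5), (BENZENE, 0.3), (OLEIC, 0.2)]
        m = sample_summary(assigned_sample(entries), weighting="intensity")
        assert m.mean_c == pytest.approx(0.5 * 6 + 0.3 * 6 + 0.2 * 18)
        assert m.mean_h == pytest.approx(0.5 * 12 + 0.3 * 6 + 0.2 * 34)
        assert m.mean_nosc == pytest.approx(0.5 * 0.0 + 0.3 * -1.0 + 0.2 * (2 * 2 / 18 - 34 / 18))

    def test_class_percentages_sum_to_100(self):
        entries = [(GLUCOSE, 1.0), (BENZENE, 2.0), (OLEIC, 3.0),
                   (MolecularFormula.from_hill("C10H3"), 4.0)]
        for weighting in ("count", "intensity"):
            m = sample_summary(assigned_sample(entries), weighting=weighting)
            assert sum(m.pct_class.values()) == pytest.approx(100.0, abs=1e-9)

    def test_count_weighting_invariant_to_rescaling(self):
        entries = [(GLUCOSE, 1.0), (BENZENE, 2.0)]
        scaled = [(f, 1000 * i) for f, i in entries]
        m1 = sample_summary(assigned_sample(entries), weighting="count")
        m2 = sample_summary(assigned_sample(scaled), weighting="count")
        assert m1.mean_c == m2.mean_c
        assert m1.pct_class == m2.pct_class
        assert m1.shannon == pytest.approx(m2.shannon, abs=1e-12)

    def test_duplicate_formula_peaks_collapse(self):
        m = sample_summary(assigned_sample([(GLUCOSE, 1.0), (GLUCOSE, 2.0)]))
        assert m.n_formulas == 1

    def test_empty_sample_rejected(self):
        empty = AssignedSample(meta=SampleMetadata(sample_id="e"), peaks=[
            AssignedPeak(mz=200.0, intensity=1.0, calibrated_mz=200.0)])
        with pytest.raises(EmptySampleError):
            sample_summary(empty)
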