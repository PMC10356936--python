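"""CPMM/CPMT abundance: filters, equations, normalization, stratification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diazoscan.abundance import (
    AlignmentRecord,
    MappingSummary,
    abundance_matrix,
    assign_depth_band,
    assign_latitude_band,
    cpmm,
    cpmm_to_percent,
    cpmt,
    filter_alignments,
    length_normalize,
    select_largest_run,
    stratify,
    subsample_run,
)


def _rec(identity, aln_len, read_len, genome="G1", read="r"):
    return AlignmentRecord(read_id=read, genome_id=genome, identity=identity,
                           alignment_length=aln_len, read_length=read_len)


class TestFilterAlignments:
    def test_all_boundaries_inclusive(self):
        counts = filter_alignments([_rec(95.0, 80, 100)], "s")
        assert counts == {("s", "G1"): 1}

    @pytest.mark.parametrize("identity,aln,read", [
        (94.999, 200, 200),   # identity just below
        (95.0, 79, 98),       # alignment length just below
        (95.0, 80, 101),      # aligned fraction just below 0.8
    ])
    def test_any_single_criterion_below_rejects(self, identity, aln, read):
        assert filter_alignments([_rec(identity, aln, read)], "s") == {}

    def test_zero_read_length_rejected_with_warning(self, caplog):
        rec = AlignmentRecord("r", "G1", 95.0, 0, 0)
        assert filter_alignments([rec], "s") == {}

    @given(st.lists(st.tuples(
        st.floats(min_value=0, max_value=100),
        st.integers(min_value=1, max_value=150),
        st.integers(min_value=150, max_value=300)), max_size=40))
    @settings(max_examples=60, deadline=None)
    def test_counts_equal_naive_refilter(self, triples):
        records = [_rec(i, a, r, genome=f"G{n % 3}", read=f"r{n}")
                   for n, (i, a, r) in enumerate(triples)]
        counts = filter_alignments(records, "s")
        naive = {}
        for rec in records:
            if rec.identity >= 95 and rec.alignment_length >= 80 \
                    and rec.alignment_length / rec.read_length >= 0.8:
                key = ("s", rec.genome_id)
                naive[key] = naive.get(key, 0) + 1
        assert counts == naive


class TestSubsampleRun:
    def test_within_cap_unchanged(self):
        assert subsample_run([100] * 10, cap_bp=10_000) == list(range(10))

    def test_over_cap_bounded(self):
        lengths = [100] * 100
        kept = subsample_run(lengths, cap_bp=5_000, seed=1)
        assert sum(lengths[i] for i in kept) <= 5_000
        assert len(set(kept)) == len(kept)  # without replacement

    def test_seed_determinism(self):
        lengths = list(range(50, 150))
        assert subsample_run(lengths, 3_000, seed=9) == subsample_run(lengths, 3_000, seed=9)

    def test_largest_run_selected(self):
        runs = {"runA": [100] * 5, "runB": [100] * 50, "runC": [100] * 20}
        assert select_largest_run(runs) == "runB"


def _summary(counts, lengths, totals):
    return MappingSummary(counts=counts, genome_lengths=lengths, total_reads=totals)


class TestEquations:
    def test_length_normalize_hand_values(self):
        s = _summary({("s", "A"): 10, ("s", "B"): 0},
                     {"A": 1000, "B": 500}, {"s": 100})
        frame = length_normalize(s).set_index("genome")
        assert frame.loc["A", "G"] == 10.0
        assert frame.loc["B", "G"] == 0.0

    def test_cpmt_single_genome(self):
        assert cpmt(np.array([3.0])) == pytest.approx([1e6])

    def test_cpmt_symmetry(self):
        assert cpmt(np.array([5.0, 5.0])) == pytest.approx([5e5, 5e5])

    def test_cpmt_from_counts_and_lengths(self):
        # lengths (1000, 2000), counts (10, 20) -> G = (10, 10) -> equal split
        s = _summary({("s", "A"): 10, ("s", "B"): 20},
                     {"A": 1000, "B": 2000}, {"s": 1000})
        m = abundance_matrix(s).set_index("genome")
        assert m.loc["A", "CPMT"] == pytest.approx(5e5)
        assert m.loc["B", "CPMT"] == pytest.approx(5e5)

    def test_cpmm_hand_value(self):
        assert cpmm(np.array([5e5]), 30, 1000) == pytest.approx([1.5e4])

    def test_cpmm_saturation_and_zero(self):
        assert cpmm(np.array([7e5]), 100, 100) == pytest.approx([7e5])
        assert cpmm(np.array([7e5]), 0, 100) == pytest.approx([0.0])

    def test_mapped_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            cpmm(np.array([1.0]), 10, 5)

    def test_counts_for_unknown_sample_or_genome_rejected(self):
        with pytest.raises(ValueError, match="without a total read count"):
            _summary({("sX", "A"): 1}, {"A": 1000}, {"s": 10}).validate()
        with pytest.raises(ValueError, match="without a length"):
            _summary({("s", "B"): 1}, {"A": 1000}, {"s": 10}).validate()

    @pytest.mark.parametrize("value,percent", [
        (1000, 0.1),
        (12841, 1.28),
        (152821, 15.28),
    ])
    def test_cpmm_percent_worked_values(self, value, percent):
        assert round(cpmm_to_percent(value), 2) == percent

    def test_all_zero_sample_emits_zeros(self):
        s = _summary({}, {"A": 1000}, {"s": 100})
        m = abundance_matrix(s)
        assert (m[["CPMT", "CPMM"]] == 0).all().all()


class TestInvariants:
    @given(st.lists(st.tuples(st.integers(0, 10_000), st.integers(1000, 5_000_000)),
                    min_size=1, max_size=8))
    @settings(max_examples=100, deadline=None)
    def test_cpmt_sums_to_a_million(self, pairs):
        counts = {("s", f"G{i}"): c for i, (c, _) in enumerate(pairs)}
        lengths = {f"G{i}": length for i, (_, length) in enumerate(pairs)}
        total = max(sum(c for c, _ in pairs), 1)
        m = abundance_matrix(_summary(counts, lengths, {"s": total}))
        if m["CPMT"].sum() > 0:
            assert m["CPMT"].sum() == pytest.approx(1e6, rel=1e-6)
        assert (m["CPMM"] <= m["CPMT"] + 1e-9).all()

    def test_scale_invariance_of_cpmt(self):
        counts = {("s", "A"): 10, ("s", "B"): 30}
        lengths = {"A": 1000, "B": 3000}
        base = abundance_matrix(_summary(counts, lengths, {"s": 1000}))
        scaled = abundance_matrix(_summary(
            {k: 5 * v for k, v in counts.items()}, lengths, {"s": 5000}))
        assert base["CPMT"].to_numpy() == pytest.approx(scaled["CPMT"].to_numpy())
        assert base["CPMM"].to_numpy() == pytest.approx(scaled["CPMM"].to_numpy())

    def test_length_invariance_of_g(self):
        a = length_normalize(_summary({("s", "A"): 10}, {"A": 1000}, {"s": 100}))
        b = length_normalize(_summary({("s", "A"): 20}, {"A": 2000}, {"s": 100}))
        assert a.loc[0, "G"] == b.loc[0, "G"]


class TestStratify:
    def test_depth_band_boundaries(self):
        assert assign_depth_band(200) == "shallow"
        assert assign_depth_band(250) == "intermediate"
        assert assign_depth_band(1000) == "deep"

    def test_latitude_band_boundary(self):
        assert assign_latitude_band(66.5) == "arctic"
        assert assign_latitude_band(66.49) == "low_latitude"

    def _matrix_and_meta(self, cpmm_value):
        matrix = pd.DataFrame({"sample": ["s1"], "genome": ["A"], "C": [1],
                               "G": [1.0], "CPMT": [1e6], "CPMM": [cpmm_value]})
        meta = pd.DataFrame({"sample": ["s1"], "latitude": [70.0],
                             "depth": [250.0], "fraction": ["total"]})
        return matrix, meta

    def test_sample_at_250m_in_intermediate_only(self):
        strat = stratify(*self._matrix_and_meta(5.0))
        assert set(strat["depth_band"]) == {"intermediate"}
        assert strat["n_detected"].sum() == 1

    def test_below_detection_threshold_not_detected(self):
        strat = stratify(*self._matrix_and_meta(0.5))
        assert strat["n_detected"].sum() == 0

    def test_unknown_fraction_rejected(self):
        matrix, meta = self._matrix_and_meta(5.0)
        meta["fraction"] = "giant"
        with pytest.raises(ValueError):
            stratify(matrix, meta)
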