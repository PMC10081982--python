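"""Pairwise-identity statistics: column/region PI, profiles, runs, logos."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paralog_evol import conservation as cons
from paralog_evol.errors import CoordinateError, ParameterError
from paralog_evol.seqio import RegionAnnotation, SequenceRecord

from conftest import make_alignment


def brute_force_pi(column):
    """Independent oracle: enumerate all unordered pairs under the gap rules."""
    identical = counted = 0
    for a, b in itertools.combinations(column, 2):
        if a == "-" and b == "-":
            continue
        counted += 1
        if a == b and a not in "-X":
            identical += 1
    return 100.0 * identical / counted if counted else float("nan")


class TestColumnIdentity:
    @pytest.mark.parametrize("column, expected", [
        (["A", "A", "A", "A"], 100.0),
        (["A", "A", "A", "T"], 50.0),          # 3 identical of 6 pairs
        (["A", "-", "A"], 100.0 / 3.0),        # 1 identical of 3 counted
        (["A", "X", "A"], 100.0 / 3.0),        # X never matches
        (["X", "X"], 0.0),                     # even against another X
    ])
    def test_documented_examples(self, column, expected):
        # anchor column keeps gap-only rows legal
        aln = make_alignment(["M" + c for c in column])
        assert cons.column_identity(aln, 2) == pytest.approx(expected)

    def test_all_gap_column_flagged_missing(self):
        aln = make_alignment(["-A", "-A", "-A"])
        assert math.isnan(cons.column_identity(aln, 1))

    def test_out_of_range_column(self, tiny_protein_alignment):
        with pytest.raises(IndexError):
            cons.column_identity(tiny_protein_alignment, 5)

    @given(st.lists(
        st.lists(st.sampled_from("AV-X"), min_size=2, max_size=6),
        min_size=1, max_size=5).filter(lambda cols: len({len(c) for c in cols}) == 1
                                       and any(set(c) != {"-"} for c in cols)))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_pair_enumeration(self, columns):
        """PI equals exhaustive pair enumeration on alignments <= 5x6."""
        n_rows = len(columns[0])
        rows = ["".join(col[r] for col in columns) for r in range(n_rows)]
        if any(set(r) == {"-"} for r in rows):
            return
        aln = make_alignment(rows)
        for c, col in enumerate(columns, start=1):
            got = cons.column_identity(aln, c)
            want = brute_force_pi(col)
            assert (math.isnan(got) and math.isnan(want)) or \
                got == pytest.approx(want)

    def test_one_extra_mismatch_never_raises_pi(self):
        """Monotonicity under mutation, exhaustive on 4-row binary columns."""
        for col in itertools.product("AV", repeat=4):
            base = brute_force_pi(list(col))
            for i in range(4):
                if col[i] == "A":
                    mutated = list(col)
                    mutated[i] = "W"  # a fresh residue = one more mismatch
                    assert brute_force_pi(mutated) <= base + 1e-12


class TestRegionIdentity:
    def test_identical_rows_any_region(self, identical_alignment):
        region = RegionAnnotation("r", "s1", 2, 5)
        row = cons.region_identity(identical_alignment, region)
        assert row.pi_percent == 100.0 and row.n_residues == 4

    def test_length_from_coordinates(self):
        assert RegionAnnotation("Hinge", "x", 428, 432).n_residues == 5

    def test_pooled_pair_counts(self):
        # 2 rows, 4 columns, 2 identical / 2 mismatched -> 50%
        aln = make_alignment(["MKVA", "MKTT"])
        region = RegionAnnotation("r", "s1", 1, 4)
        assert cons.region_identity(aln, region).pi_percent == pytest.approx(50.0)

    def test_subdivision_recovers_parent_exactly(self):
        rng = np.random.default_rng(11)
        rows = ["".join(rng.choice(list("ACDEF-"), 12)) for _ in range(6)]
        rows = [r if set(r) != {"-"} else "A" * 12 for r in rows]
        aln = make_alignment(rows)
        ref = aln.rows[0].id
        n = len(aln.rows[0].ungapped())
        whole = cons.region_identity(aln, RegionAnnotation("w", ref, 1, n))
        mid = n // 2
        left = cons.region_identity(aln, RegionAnnotation("l", ref, 1, mid))
        right = cons.region_identity(aln, RegionAnnotation("r", ref, mid + 1, n))
        # pool pair counts, not percentages
        def counts(region_row, start, end):
            cols = cons.map_reference_to_columns(aln, ref, start, end)
            ident = tot = 0
            for c in cols:
                i, t = cons._pair_counts(aln.column(c))
                ident += i
                tot += t
            return ident, tot
        i1, t1 = counts(left, 1, mid)
        i2, t2 = counts(right, mid + 1, n)
        assert whole.pi_percent == pytest.approx(100.0 * (i1 + i2) / (t1 + t2))


class TestReferenceMapping:
    def test_gapless_reference_is_identity(self, identical_alignment):
        assert cons.map_reference_to_columns(
            identical_alignment, "s1", 2, 4) == [2, 3, 4]

    def test_gapped_reference_counts_residues(self):
        aln = make_alignment(["M-KV", "MAKV"])
        assert cons.map_reference_to_columns(aln, "s1", 2, 3) == [3, 4]

    def test_beyond_ungapped_length(self):
        aln = make_alignment(["M-KV", "MAKV"])
        with pytest.raises(CoordinateError):
            cons.map_reference_to_columns(aln, "s1", 1, 5)


class TestProfile:
    def test_window_one_is_raw(self, tiny_protein_alignment):
        prof = cons.identity_profile(tiny_protein_alignment, window=1)
        raw = [cons.column_identity(tiny_protein_alignment, c)
               for c in range(1, 5)]
        assert np.allclose(prof.per_column_pi, raw, equal_nan=True)

    def test_constant_profile_invariant_under_smoothing(self, identical_alignment):
        prof = cons.identity_profile(identical_alignment, window=3)
        assert np.allclose(prof.per_column_pi, 100.0)

    def test_shrinking_edge_windows(self):
        # per-column PI [0, 100, 100] smoothed with window 3
        aln = make_alignment(["AKV", "TKV"])
        prof = cons.identity_profile(aln, window=3)
        assert np.allclose(prof.per_column_pi, [50.0, 200.0 / 3.0, 100.0])

    def test_even_window_rejected(self, tiny_protein_alignment):
        with pytest.raises(ParameterError):
            cons.identity_profile(tiny_protein_alignment, window=2)


def brute_force_runs(alignment, ref_id, min_length, threshold):
    """Oracle: score every reference residue, then scan linearly."""
    row = alignment.row(ref_id).residues
    residue = 0
    scored = []  # (residue, passes, column)
    for col, ch in enumerate(row, start=1):
        if ch == "-":
            scored.append((None, False, col))
            continue
        residue += 1
        pi = cons.column_identity(alignment, col)
        scored.append((residue, (not math.isnan(pi)) and pi >= threshold, col))
    runs = []
    start = None
    prev = None
    for res, ok, col in scored:
        if res is None or not ok:
            if start is not None and prev - start + 1 >= min_length:
                runs.append((start, prev))
            start = None
            continue
        if start is None:
            start = res
        prev = res
    if start is not None and prev - start + 1 >= min_length:
        runs.append((start, prev))
    return runs


class TestConservedRuns:
    def test_fully_identical_alignment_single_run(self, identical_alignment):
        runs = cons.find_conserved_runs(identical_alignment, "s1",
                                        min_length=6, threshold=100.0)
        assert runs == [(1, 7, "MKVARST")]

    def test_planted_invariant_block_recovered(self):
        rng = np.random.default_rng(3)
        n_rows, n_cols = 24, 60
        base = rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), n_cols)
        rows = []
        for r in range(n_rows):
            row = base.copy()
            mutate = rng.random(n_cols) < 0.25
            row[mutate] = rng.choice(list("ACDEFGHIKLMNPQRSTVWY"),
                                     int(mutate.sum()))
            row[30:36] = list("AKVFRT")
            rows.append("".join(row))
        aln = make_alignment(rows)
        runs = cons.find_conserved_runs(aln, aln.rows[0].id,
                                        min_length=6, threshold=100.0)
        assert (31, 36, "AKVFRT") in runs

    def test_mismatch_inside_block_breaks_run(self):
        rows = ["AKVFRT"] * 5 + ["AKVVRT"]
        aln = make_alignment(rows)
        runs = cons.find_conserved_runs(aln, "s1", min_length=6,
                                        threshold=100.0)
        assert runs == []

    def test_agrees_with_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n_rows = int(rng.integers(3, 8))
            n_cols = int(rng.integers(10, 200))
            rows = []
            base = rng.choice(list("AVLK"), n_cols)
            for r in range(n_rows):
                row = base.copy()
                mutate = rng.random(n_cols) < 0.3
                row[mutate] = rng.choice(list("AVLK"), int(mutate.sum()))
                gaps = rng.random(n_cols) < 0.05
                row[gaps] = "-"
                if (row == "-").all():
                    row[0] = "A"
                rows.append("".join(row))
            aln = make_alignment(rows)
            threshold = float(rng.choice([60.0, 80.0, 100.0]))
            min_len = int(rng.integers(1, 6))
            got = [(a, b) for a, b, _ in cons.find_conserved_runs(
                aln, aln.rows[0].id, min_len, threshold)]
            want = brute_force_runs(aln, aln.rows[0].id, min_len, threshold)
            assert got == want


class TestLogo:
    def test_invariant_column_has_full_information(self):
        aln = make_alignment(["AA", "AA", "AA"])
        logo = cons.logo_matrix(aln, RegionAnnotation("r", "s1", 1, 2))
        assert logo.frequencies.loc["A", 1] == 1.0
        assert logo.information[0] == pytest.approx(math.log2(20))

    def test_half_half_column_entropy(self):
        aln = make_alignment(["A", "A", "V", "V"])
        logo = cons.logo_matrix(aln, RegionAnnotation("r", "s1", 1, 1))
        assert logo.frequencies.loc["A", 1] == pytest.approx(0.5)
        assert logo.information[0] == pytest.approx(math.log2(20) - 1.0)

    def test_gaps_excluded_from_denominator(self):
        aln = make_alignment(["MA", "M-", "MA"])
        logo = cons.logo_matrix(aln, RegionAnnotation("r", "s1", 2, 2))
        assert logo.frequencies.loc["A", 2] == pytest.approx(1.0)

    def test_frequencies_sum_to_one(self, tiny_protein_alignment):
        logo = cons.logo_matrix(tiny_protein_alignment,
                                RegionAnnotation("r", "s1", 1, 4))
        sums = logo.frequencies.sum(axis=0)
        assert np.allclose(sums, 1.0, atol=1e-9)


class TestLengthFilter:
    def test_uniform_lengths_all_kept(self):
        recs = [SequenceRecord(f"s{i}", "A" * 100) for i in range(4)]
        kept, discarded = cons.length_filter(recs)
        assert len(kept) == 4 and not discarded

    def test_short_sequence_discarded_by_single_pass_mean(self):
        lengths = [100, 100, 100, 40]  # mean 85, cutoff 42.5
        recs = [SequenceRecord(f"s{i}", "A" * n) for i, n in enumerate(lengths)]
        kept, discarded = cons.length_filter(recs)
        assert [len(r.residues) for r in discarded] == [40]
        assert len(kept) == 3

    def test_single_record_kept(self):
        kept, discarded = cons.length_filter([SequenceRecord("s", "AAA")])
        assert len(kept) == 1 and not discarded

    def test_empty_input_rejected(self):
        with pytest.raises(ParameterError):
            cons.length_filter([])


class TestMaskColumns:
    def test_gapless_untouched(self, identical_alignment):
        masked, kept = cons.mask_columns(identical_alignment, 0.5)
        assert masked.n_columns == 7 and kept == list(range(1, 8))

    def test_gappy_column_removed(self):
        aln = make_alignment(["A-VA", "A-VA", "A-VA", "AKVA"])
        masked, kept = cons.mask_columns(aln, 0.5)
        assert masked.n_columns == 3 and kept == [1, 3, 4]

    def test_threshold_one_removes_nothing(self):
        aln = make_alignment(["A-VA", "A-VA", "A-VA", "AKVA"])
        masked, kept = cons.mask_columns(aln, 1.0)
        assert masked.n_columns == 4


class TestModelInterface:
    def test_fit_produces_tables_and_summary(self, identical_alignment):
        regions = [RegionAnnotation("head", "s1", 1, 3),
                   RegionAnnotation("tail", "s1", 4, 7)]
        res = cons.ConservationModel(identical_alignment, regions).fit()
        table = res.region_table
        assert list(table["length_aa"]) == [3, 4]
        assert (table["pi_percent"] == 100.0).all()
        assert "100" in res.summary()
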