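"""Conserved-orthogroup identification, loss calling and the F-index."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ortholoss.errors import ParseError, ValidationError
from ortholoss.family_matrix import (
    GeneCountMatrix,
    LossReport,
    call_losses,
    conserved_orthogroups,
    f_index,
    f_summary,
    f_table,
    load_gene_counts,
    partition_losses,
    tukey_summary,
)

from conftest import PANEL6, SPECIES9, make_matrix


class TestLoadGeneCounts:
    def test_round_trip(self, toy_counts_tsv):
        m = load_gene_counts(toy_counts_tsv)
        assert m.orthogroup_ids == ["OG1", "OG2", "OG3"]
        assert m.species_ids == ["spA", "spB"]
        assert m.counts.to_numpy().tolist() == [[1, 2], [0, 3], [4, 0]]

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(ParseError, match="empty"):
            load_gene_counts(path)

    def test_duplicate_orthogroup_names_offender(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("Orthogroup\tspA\nOG1\t1\nOG1\t2\n")
        with pytest.raises(ParseError, match="OG1"):
            load_gene_counts(path)

    @pytest.mark.parametrize(
        "body, message",
        [
            ("OG1\t1\t2\t3\n", "line 2"),  # ragged row
            ("OG1\tx\t2\n", "non-integer"),
            ("OG1\t-1\t2\n", "negative"),
        ],
    )
    def test_malformed_rows_name_the_line(self, tmp_path, body, message):
        path = tmp_path / "bad.tsv"
        path.write_text("Orthogroup\tspA\tspB\n" + body)
        with pytest.raises(ParseError, match=message):
            load_gene_counts(path)

    def test_total_column_ignored(self, tmp_path):
        path = tmp_path / "total.tsv"
        path.write_text("Orthogroup\tspA\tspB\tTotal\nOG1\t1\t2\t3\n")
        m = load_gene_counts(path)
        assert m.species_ids == ["spA", "spB"]


class TestConservedOrthogroups:
    def test_rule_on_nine_species(self):
        # ref present + 5/6 panel → in; ref absent + 6/6 panel → out;
        # targets' counts never matter
        m = make_matrix(
            {
                "OGin": [2, 1, 1, 1, 1, 1, 0, 0, 0],
                "OGout": [0, 1, 1, 1, 1, 1, 1, 9, 9],
                "OGsparse": [1, 1, 1, 0, 0, 0, 0, 5, 5],
            },
            species=SPECIES9,
        )
        cs = conserved_orthogroups(m, "Atha", PANEL6, 5)
        assert set(cs.orthogroup_ids) == {"OGin"}

    def test_matches_planted_labels(self, rng):
        # brute-force the rule per row on a random 10-orthogroup matrix
        counts = rng.integers(0, 3, size=(10, 9))
        m = GeneCountMatrix(
            pd.DataFrame(counts, index=[f"OG{i}" for i in range(10)], columns=SPECIES9)
        )
        expected = {
            f"OG{i}"
            for i in range(10)
            if counts[i, 0] >= 1 and sum(c >= 1 for c in counts[i, 1:7]) >= 5
        }
        cs = conserved_orthogroups(m, "Atha", PANEL6, 5)
        assert set(cs.orthogroup_ids) == expected

    @given(st.integers(min_value=0, max_value=6))
    def test_monotone_in_min_present(self, min_present):
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 2, size=(50, 9))
        counts[:, 0] = 1
        m = GeneCountMatrix(
            pd.DataFrame(counts, index=[f"OG{i}" for i in range(50)], columns=SPECIES9)
        )
        looser = conserved_orthogroups(m, "Atha", PANEL6, min_present)
        if min_present < 6:
            stricter = conserved_orthogroups(m, "Atha", PANEL6, min_present + 1)
            assert set(stricter.orthogroup_ids) <= set(looser.orthogroup_ids)

    def test_unknown_species_rejected(self):
        m = make_matrix({"OG1": [1, 1]})
        with pytest.raises(ValidationError, match="unknown species"):
            conserved_orthogroups(m, "nope", ["sp1"], 1)


class TestCallLosses:
    def test_direct_rule(self):
        m = make_matrix({"A": [1, 0], "B": [1, 1], "C": [1, 0]}, species=["ref", "tgt"])
        cs = conserved_orthogroups(m, "ref", [], 0)
        report = call_losses(m, cs, "tgt")
        assert report.lost_orthogroups == {"A", "C"}
        assert report.loss_fraction == pytest.approx(2 / 3)

    def test_no_losses(self):
        m = make_matrix({"A": [1, 2], "B": [1, 1]}, species=["ref", "tgt"])
        cs = conserved_orthogroups(m, "ref", [], 0)
        report = call_losses(m, cs, "tgt")
        assert report.lost_orthogroups == frozenset()
        assert report.loss_fraction == 0.0

    def test_recovers_planted_zero_rows(self, rng):
        n = 1000
        counts = rng.integers(1, 5, size=(n, 3))
        zero_rows = rng.choice(n, size=117, replace=False)
        counts[zero_rows, 2] = 0
        ids = [f"OG{i:04d}" for i in range(n)]
        m = GeneCountMatrix(pd.DataFrame(counts, index=ids, columns=["ref", "p1", "tgt"]))
        cs = conserved_orthogroups(m, "ref", ["p1"], 1)
        report = call_losses(m, cs, "tgt")
        assert report.lost_orthogroups == {ids[i] for i in zero_rows}


class TestPartitionLosses:
    def _report(self, target, lost, universe):
        return LossReport(target, frozenset(lost), len(universe),
                          len(lost) / len(universe), frozenset(universe))

    def test_set_algebra(self):
        universe = {"A", "B", "C", "D", "E"}
        part = partition_losses(
            self._report("x", {"A", "B", "C"}, universe),
            self._report("y", {"B", "C", "D"}, universe),
        )
        assert part.joint == {"B", "C"}
        assert part.specific_a == {"A"}
        assert part.specific_b == {"D"}

    def test_mismatched_universes_rejected(self):
        with pytest.raises(ValidationError, match="different conserved sets"):
            partition_losses(
                self._report("x", {"A"}, {"A", "B"}),
                self._report("y", {"A"}, {"A", "C"}),
            )

    @given(st.sets(st.integers(0, 40)), st.sets(st.integers(0, 40)))
    def test_counting_identity(self, lost_a, lost_b):
        universe = set(range(41))
        part = partition_losses(
            self._report("x", {str(i) for i in lost_a}, {str(i) for i in universe}),
            self._report("y", {str(i) for i in lost_b}, {str(i) for i in universe}),
        )
        assert part.n_joint + part.n_specific_a + part.n_specific_b == len(lost_a | lost_b)
        assert part.n_specific_a == len(lost_a) - part.n_joint


class TestFIndex:
    def test_equal_counts_give_half(self):
        m = make_matrix({"OG1": [2, 2, 2]})
        assert f_index(m, "OG1", "sp0") == 0.5

    def test_zero_count_gives_zero(self):
        m = make_matrix({"OG1": [0, 2, 2]})
        assert f_index(m, "OG1", "sp0") == 0.0

    def test_nine_species_hand_value(self):
        # counts (4,2,...,2): x̄ = 20/9, F = 4/(4 + 20/9) = 36/56
        m = make_matrix({"OG1": [4, 2, 2, 2, 2, 2, 2, 2, 2]})
        assert f_index(m, "OG1", "sp0") == pytest.approx(36 / 56, abs=1e-12)

    def test_all_zero_family_rejected(self):
        m = make_matrix({"OG1": [0, 0, 0]})
        with pytest.raises(ValidationError, match="all-zero"):
            f_index(m, "OG1", "sp0")

    @given(
        st.lists(st.integers(0, 20), min_size=3, max_size=9),
        st.integers(0, 20),
        st.integers(0, 20),
    )
    def test_strictly_increasing_in_focal_count(self, others, a, b):
        if a == b or (a == 0 and b == 0 and sum(others) == 0):
            return
        lo, hi = sorted((a, b))
        if sum(others) == 0 and lo == 0:
            return  # all-zero family is rejected
        m_lo = make_matrix({"OG1": [lo, *others]})
        m_hi = make_matrix({"OG1": [hi, *others]})
        assert f_index(m_lo, "OG1", "sp0") < f_index(m_hi, "OG1", "sp0")

    def test_range_and_half_iff_mean(self, rng):
        counts = rng.integers(0, 10, size=(10_000, 9))
        counts[counts.sum(axis=1) == 0, 0] = 1
        m = GeneCountMatrix(pd.DataFrame(
            counts, index=[f"OG{i}" for i in range(10_000)], columns=SPECIES9))
        table = f_table(m).values.to_numpy()
        assert ((table >= 0) & (table < 1)).all()
        means = counts.mean(axis=1, keepdims=True)
        assert np.array_equal(table == 0.5, counts == means)


class TestFSummary:
    def test_degenerate_all_half(self):
        m = make_matrix({f"OG{i}": [2, 2, 2] for i in range(5)})
        cs = conserved_orthogroups(m, "sp0", ["sp1", "sp2"], 2)
        box = f_summary(m, cs, "sp0")
        assert box.q1 == box.median == box.q3 == box.mean == 0.5
        assert box.outliers == ()
        assert box.fraction_below_half == 0.0

    def test_tukey_on_known_sample(self):
        box = tukey_summary([0.0, 0.25, 0.5, 0.75, 1.0], fraction_below_half=0.4)
        assert box.median == 0.5
        assert (box.q1, box.q3) == (0.25, 0.75)
        assert (box.whisker_low, box.whisker_high) == (0.0, 1.0)
        assert box.outliers == ()
        assert box.fraction_below_half == 0.4

    def test_whiskers_and_outliers(self):
        values = [0.4] * 10 + [0.41] * 10 + [0.95]
        box = tukey_summary(values)
        assert box.whisker_high == 0.41
        assert box.outliers == (0.95,)
        assert box.whisker_low == 0.4

    def test_fraction_matches_direct_computation(self, rng):
        counts = rng.integers(0, 6, size=(400, 9))
        counts[:, 0] = np.maximum(counts[:, 0], 1)
        counts[:, 1:7] = np.maximum(counts[:, 1:7], 1)
        m = GeneCountMatrix(pd.DataFrame(
            counts, index=[f"OG{i}" for i in range(400)], columns=SPECIES9))
        cs = conserved_orthogroups(m, "Atha", PANEL6, 5)
        box = f_summary(m, cs, "Caus")
        direct = np.mean(counts[:, 7] < counts.mean(axis=1))
        assert box.fraction_below_half == pytest.approx(direct, abs=1e-12)

    def test_empty_conserved_set_rejected(self):
        m = make_matrix({"OG1": [0, 1]})
        cs = conserved_orthogroups(m, "sp0", ["sp1"], 1)
        with pytest.raises(ValidationError, match="empty"):
            f_summary(m, cs, "sp1")
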