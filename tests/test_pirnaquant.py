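"""Quantification rules: trimming, length filter, exact matching and UMI
deduplication, including brute-force oracles and truth recovery."""

import itertools
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from piwiflow.containers import IntegrityError
from piwiflow.pirnaquant import (
    FastqParseError,
    PiRNAReference,
    exact_match,
    length_filter,
    quantify,
    trim_and_extract,
    umi_dedup,
)
from piwiflow.synthcohort import generate_reads, molecule_table

ADAPTER = "AACTGTAGGCACCATCAAT"


class TestTrimAndExtract:
    def test_constructed_layout(self):
        raw = "ACGTACGT" + ADAPTER + "AAACCCGGGTTT"
        read = trim_and_extract("r1", raw, adapter=ADAPTER, umi_len=12)
        assert read.trimmed_ok
        assert read.insert == "ACGTACGT"
        assert read.umi == "AAACCCGGGTTT"

    def test_missing_adapter_flags_failure(self):
        read = trim_and_extract("r1", "ACGT" * 10, adapter=ADAPTER, umi_len=12)
        assert not read.trimmed_ok
        assert read.insert is None

    def test_short_umi_tail_flags_failure(self):
        read = trim_and_extract("r1", "ACGT" + ADAPTER + "AAA", adapter=ADAPTER, umi_len=12)
        assert not read.trimmed_ok

    def test_empty_insert_allowed_then_removed_by_length_filter(self):
        read = trim_and_extract("r1", ADAPTER + "AAACCCGGGTTT", adapter=ADAPTER, umi_len=12)
        assert read.trimmed_ok and read.insert == ""
        assert length_filter(read) is False

    def test_leftmost_adapter_occurrence_wins(self):
        raw = "AC" + ADAPTER + "GG" + ADAPTER + "TTTTTTTTTTTT"
        read = trim_and_extract("r1", raw, adapter=ADAPTER, umi_len=2)
        assert read.insert == "AC"


class TestLengthFilter:
    @pytest.mark.parametrize("length,expected", [(0, False), (23, False), (24, True),
                                                 (28, True), (34, True), (35, False)])
    def test_inclusive_24_34_bounds(self, length, expected):
        from piwiflow.pirnaquant import SmallRNARead

        read = SmallRNARead(read_id="r", raw="", insert="A" * length)
        assert length_filter(read) is expected


class TestExactMatch:
    def reference(self):
        return PiRNAReference({"p1": "ACGTACGTACGTACGTACGTACGTACGT",
                               "p2": "UGGAAUGUAAAGAAGUAUGUAUCUCA"})

    def test_identical_sequence_matches(self):
        ref = self.reference()
        assert exact_match("ACGTACGTACGTACGTACGTACGTACGT", ref) is not None

    def test_u_to_t_normalization_both_sides(self):
        ref = self.reference()
        assert exact_match("TGGAATGTAAAGAAGTATGTATCTCA", ref) is not None
        assert exact_match("UGGAAUGUAAAGAAGUAUGUAUCUCA", ref) is not None

    def test_single_substitution_never_matches(self):
        ref = self.reference()
        assert exact_match("CCGTACGTACGTACGTACGTACGTACGT", ref) is None

    def test_truncation_by_one_base_never_matches(self):
        ref = self.reference()
        assert exact_match("ACGTACGTACGTACGTACGTACGTACG", ref) is None

    def test_n_containing_insert_never_matches(self):
        ref = PiRNAReference({"p1": "ACGTN" * 5 + "ACG"})
        assert exact_match("ACGTN" * 5 + "ACG", ref) is None


class TestUmiDedup:
    def test_directional_collapse_of_dominant_umi(self):
        assert umi_dedup(["AAAA"] * 5 + ["AAAT"]) == 1

    def test_distant_umis_stay_separate(self):
        assert umi_dedup(["AAAA", "AAAA", "TTTT", "TTTT"]) == 2

    def test_identical_umis_are_one_molecule(self):
        assert umi_dedup(["AAAA"] * 10) == 1

    def test_balanced_neighbours_not_collapsed(self):
        # counts 3 vs 3: 3 >= 2*3-1 is false, no edge either way
        assert umi_dedup(["AAAA"] * 3 + ["AAAT"] * 3) == 2

    def test_mixed_umi_lengths_raise(self):
        with pytest.raises(IntegrityError):
            umi_dedup(["AAAA", "AAA"])

    def test_unique_mode_counts_distinct_umis(self):
        assert umi_dedup(["AAAA"] * 5 + ["AAAT"], method="unique") == 2

    @staticmethod
    def _oracle(umis):
        """Independent directional clustering: explicit pairwise adjacency
        then greedy cluster assignment from the highest-count root."""
        counts = Counter(umis)
        nodes = sorted(counts, key=lambda u: (-counts[u], u))
        adj = {u: set() for u in nodes}
        for a, b in itertools.permutations(nodes, 2):
            if sum(x != y for x, y in zip(a, b)) == 1 and counts[a] >= 2 * counts[b] - 1:
                adj[a].add(b)
        unassigned = set(nodes)
        clusters = 0
        for root in nodes:
            if root not in unassigned:
                continue
            clusters += 1
            frontier = {root}
            while frontier:
                u = frontier.pop()
                unassigned.discard(u)
                frontier |= adj[u] & unassigned
        return clusters

    @given(st.lists(st.sampled_from(["AA", "AT", "AC", "TA", "TT", "CC"]),
                    min_size=1, max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_matches_exhaustive_oracle_on_small_groups(self, umis):
        if len(set(umis)) <= 6:
            assert umi_dedup(umis) == self._oracle(umis)


class TestQuantify:
    def _cohort_fixture(self, tiny_cohort, tmp_path, dup_rate, error_rate=0.0):
        col = tiny_cohort.pirna_counts.counts.iloc[:, 0].clip(upper=15)
        fq = tmp_path / "sample.fastq"
        generate_reads(molecule_table(col), tiny_cohort.truth.pirna_sequences, fq,
                       dup_rate=dup_rate, error_rate=error_rate, seed=77)
        ref = PiRNAReference(tiny_cohort.truth.pirna_sequences)
        truth = col.groupby(col.index.map(ref.id_to_seq)).sum()
        return fq, ref, truth[truth > 0]

    def test_dedup_counts_equal_truth_without_duplication(self, tiny_cohort, tmp_path):
        fq, ref, truth = self._cohort_fixture(tiny_cohort, tmp_path, dup_rate=0.0)
        res = quantify(fq, ref)
        dedup = pd.Series({s: e["dedup_count"] for s, e in res.entries.items()})
        pd.testing.assert_series_equal(dedup.sort_index(), truth.sort_index(),
                                       check_names=False, check_dtype=False)

    def test_dedup_recovers_truth_under_pcr_duplication(self, tiny_cohort, tmp_path):
        fq, ref, truth = self._cohort_fixture(tiny_cohort, tmp_path, dup_rate=3.0)
        res = quantify(fq, ref)
        raw = pd.Series({s: e["raw_count"] for s, e in res.entries.items()})
        dedup = pd.Series({s: e["dedup_count"] for s, e in res.entries.items()})
        assert (raw.sum()) > (dedup.sum())
        pd.testing.assert_series_equal(dedup.sort_index(), truth.sort_index(),
                                       check_names=False, check_dtype=False)

    def test_attrition_monotone_and_idempotent(self, tiny_cohort, tmp_path):
        fq, ref, _ = self._cohort_fixture(tiny_cohort, tmp_path, dup_rate=1.0, error_rate=0.05)
        res1 = quantify(fq, ref)
        res2 = quantify(fq, ref)
        a = res1.attrition
        assert a["input"] >= a["trimmed"] >= a["length_pass"] >= a["matched"] >= a["deduplicated"]
        assert res1.entries == res2.entries and res1.attrition == res2.attrition

    def test_shared_sequences_reported_under_one_representative(self, tiny_cohort, tmp_path):
        ref = PiRNAReference(tiny_cohort.truth.pirna_sequences)
        shared = [ids for ids in ref.seq_to_ids.values() if len(ids) > 1]
        assert shared, "fixture must contain duplicated reference sequences"
        fq, ref, _ = self._cohort_fixture(tiny_cohort, tmp_path, dup_rate=0.0)
        res = quantify(fq, ref)
        for entry in res.entries.values():
            assert entry["representative_id"] == sorted(entry["all_ids"])[0]

    def test_empty_fastq_yields_zero_tallies(self, tmp_path):
        fq = tmp_path / "empty.fastq"
        fq.write_text("")
        ref = PiRNAReference({"p": "ACGT" * 7})
        res = quantify(fq, ref)
        assert all(v == 0 for v in res.attrition.values())
        assert res.entries == {}

    def test_malformed_fastq_reports_record_index(self, tmp_path):
        fq = tmp_path / "bad.fastq"
        fq.write_text("@r1\nACGT\n+\nIIII\n@r2\nACGT\nmissing-plus\nIIII\n")
        ref = PiRNAReference({"p": "ACGT" * 7})
        with pytest.raises(FastqParseError, match="index 1"):
            quantify(fq, ref)

    def test_dedup_bounds_per_sequence(self, tiny_cohort, tmp_path):
        fq, ref, _ = self._cohort_fixture(tiny_cohort, tmp_path, dup_rate=2.0)
        res = quantify(fq, ref)
        for e in res.entries.values():
            assert 1 <= e["dedup_count"] <= e["raw_count"]
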