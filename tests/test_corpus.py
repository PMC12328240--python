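"""Curation: annotation parsing, nested-event detection, record building."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dominsert.corpus import (
    AnnotationError,
    DomainAnnotation,
    InsertionEvent,
    InsertionRecord,
    LABEL_POSITIVE,
    ProteinRecord,
    build_parent_only,
    corpus_statistics,
    detect_intradomain_insertions,
    filter_by_length,
    make_label_vector,
    parse_annotations,
    read_records_tsv,
    reduce_redundancy,
    write_records_fasta,
    write_records_tsv,
)

from conftest import make_record, oracle_nested_events, random_annotation_layout


def write_tsv(path, rows):
    lines = ["accession\tsuperfamily_id\tstart\tend"]
    lines += ["\t".join(map(str, r)) for r in rows]
    path.write_text("\n".join(lines) + "\n")


def write_fasta(path, seqs):
    path.write_text(
        "".join(f">{acc}\n{seq}\n" for acc, seq in seqs.items())
    )


class TestParseAnnotations:
    def test_groups_segments_by_superfamily(self, tmp_path):
        write_tsv(
            tmp_path / "ann.tsv",
            [("P1", "A", 0, 50), ("P1", "A", 150, 250), ("P1", "B", 50, 150)],
        )
        write_fasta(tmp_path / "seq.fasta", {"P1": "A" * 250})
        parsed = parse_annotations(tmp_path / "ann.tsv", tmp_path / "seq.fasta")
        _, anns = parsed["P1"]
        by_sf = {a.superfamily_id: a for a in anns}
        assert by_sf["A"].segments == ((0, 50), (150, 250))
        assert by_sf["B"].segments == ((50, 150),)

    def test_empty_annotation_file(self, tmp_path):
        (tmp_path / "ann.tsv").write_text("")
        (tmp_path / "seq.fasta").write_text("")
        assert parse_annotations(tmp_path / "ann.tsv", tmp_path / "seq.fasta") == {}

    @pytest.mark.parametrize(
        "row, message",
        [
            (("P1", "A", 50, 50), "invalid segment"),
            (("P1", "A", "x", 50), "non-integer"),
            (("P1", "A", 5), "4 tab-separated"),
        ],
    )
    def test_malformed_rows_raise_with_line_number(self, tmp_path, row, message):
        write_tsv(tmp_path / "ann.tsv", [row])
        write_fasta(tmp_path / "seq.fasta", {"P1": "A" * 100})
        with pytest.raises(AnnotationError, match="line 2"):
            parse_annotations(tmp_path / "ann.tsv", tmp_path / "seq.fasta")

    def test_rows_beyond_sequence_end_are_rejected_not_fatal(self, tmp_path, caplog):
        write_tsv(
            tmp_path / "ann.tsv", [("P1", "A", 0, 500), ("P1", "B", 0, 10)]
        )
        write_fasta(tmp_path / "seq.fasta", {"P1": "A" * 100})
        parsed = parse_annotations(tmp_path / "ann.tsv", tmp_path / "seq.fasta")
        assert [a.superfamily_id for a in parsed["P1"][1]] == ["B"]

    def test_rows_for_missing_sequences_are_skipped(self, tmp_path):
        write_tsv(tmp_path / "ann.tsv", [("GHOST", "A", 0, 10)])
        write_fasta(tmp_path / "seq.fasta", {"P1": "A" * 20})
        parsed = parse_annotations(tmp_path / "ann.tsv", tmp_path / "seq.fasta")
        assert parsed["P1"][1] == []
        assert "GHOST" not in parsed

    def test_roundtrip_of_synthetic_corpus(self, small_corpus_files):
        """Writing then parsing reproduces the fixture's annotations exactly."""
        corpus, paths = small_corpus_files
        parsed = parse_annotations(paths["annotations"], paths["fasta"])
        expected = {}
        for acc, sf, start, end in corpus.annotation_rows:
            expected.setdefault((acc, sf), []).append((start, end))
        got = {
            (acc, a.superfamily_id): list(a.segments)
            for acc, (_, anns) in parsed.items()
            for a in anns
        }
        assert got == {k: sorted(v) for k, v in expected.items()}


class TestDetectEvents:
    def test_clean_nested_pair(self):
        anns = [
            DomainAnnotation("P1", "A", ((0, 50), (150, 250))),
            DomainAnnotation("P1", "B", ((50, 150),)),
        ]
        events = detect_intradomain_insertions(anns)
        assert len(events) == 1
        ev = events[0]
        assert (ev.parent_superfamily, ev.insert_superfamily) == ("A", "B")
        assert ev.insert_span == (50, 150)
        assert ev.parent_span == (0, 250)

    def test_disjoint_domains_yield_nothing(self):
        anns = [
            DomainAnnotation("P1", "A", ((0, 100),)),
            DomainAnnotation("P1", "B", ((150, 250),)),
        ]
        assert detect_intradomain_insertions(anns) == []

    def test_gap_slack_admits_imprecise_boundaries(self):
        anns = [
            DomainAnnotation("P1", "A", ((0, 50), (150, 250))),
            DomainAnnotation("P1", "B", ((52, 148),)),
        ]
        assert detect_intradomain_insertions(anns) == []
        assert len(detect_intradomain_insertions(anns, gap_slack=2)) == 1

    def test_matches_bruteforce_oracle_on_random_layouts(self):
        """Property: detection equals the exhaustive nested-interval scan."""
        rng = np.random.default_rng(123)
        n_layouts = 0
        n_events = 0
        for trial in range(120):
            anns = random_annotation_layout(rng, f"P{trial}")
            got = [
                (e.parent_superfamily, e.insert_superfamily, e.insert_span)
                for e in detect_intradomain_insertions(anns)
            ]
            assert got == oracle_nested_events(anns)
            n_layouts += 1
            n_events += len(got)
        assert n_layouts >= 100 and n_events > 20  # the sweep saw real events


class TestBuildParentOnly:
    def test_basic_deletion(self):
        prot = ProteinRecord("P1", "M" * 50 + "I" * 100 + "K" * 100)
        ev = InsertionEvent("P1", "A", "B", (50, 150), (0, 250))
        rec = build_parent_only(prot, ev)
        assert len(rec.parent_only_sequence) == 150
        assert rec.junction == 50
        assert rec.parent_only_sequence == "M" * 50 + "K" * 100
        assert rec.insert_length == 100 and rec.full_length == 250

    def test_tiny_flanks_accepted(self):
        prot = ProteinRecord("P1", "M" + "I" * 248 + "K")
        ev = InsertionEvent("P1", "A", "B", (1, 249), (0, 250))
        rec = build_parent_only(prot, ev)
        assert len(rec.parent_only_sequence) == 2 and rec.junction == 1

    def test_terminal_junctions_are_invalid(self):
        with pytest.raises(ValueError, match="terminus"):
            InsertionRecord("P1", "AC", 0, "A", "B", 10, 12)
        with pytest.raises(ValueError, match="terminus"):
            InsertionRecord("P1", "AC", 2, "A", "B", 10, 12)

    def test_concatenation_oracle_on_synthetic_corpus(self, small_corpus_files):
        corpus, paths = small_corpus_files
        parsed = parse_annotations(paths["annotations"], paths["fasta"])
        checked = 0
        for acc, (prot, anns) in parsed.items():
            for ev in detect_intradomain_insertions(anns):
                rec = build_parent_only(prot, ev)
                b0, b1 = ev.insert_span
                assert (
                    rec.parent_only_sequence
                    == prot.sequence[:b0] + prot.sequence[b1:]
                )
                checked += 1
        assert checked > 30


class TestLabelVector:
    def test_junction_centred_triple(self):
        rec = make_record("P1", junction=5, length=10)
        assert make_label_vector(rec).positive_indices == (4, 5, 6)

    def test_clipped_at_n_terminus(self):
        rec = make_record("P1", junction=1, length=10)
        assert make_label_vector(rec).positive_indices == (0, 1, 2)

    @given(
        L=st.integers(min_value=3, max_value=500),
        j_frac=st.floats(min_value=0.0, max_value=1.0, exclude_max=True),
        radius=st.integers(min_value=0, max_value=3),
    )
    @settings(max_examples=200, derandomize=True)
    def test_positive_set_matches_set_intersection_oracle(self, L, j_frac, radius):
        j = min(max(int(j_frac * L), 1), L - 1)
        rec = make_record("P1", junction=j, length=L)
        vec = make_label_vector(rec, window_radius=radius)
        expected = set(range(j - radius, j + radius + 1)) & set(range(L))
        assert set(vec.positive_indices) == expected
        pos = vec.positive_indices
        assert j in pos
        assert list(pos) == list(range(pos[0], pos[-1] + 1))  # contiguous


class TestFilters:
    def test_length_filter_is_strict(self):
        records = [
            make_record("A", length=10, insert_length=2038),  # full 2048
            make_record("B", length=10, insert_length=2037),  # full 2047
        ]
        kept = filter_by_length(records)
        assert [r.accession for r in kept] == ["B"]

    def test_length_filter_matches_bruteforce(self):
        rng = np.random.default_rng(5)
        records = [
            make_record(f"R{i}", length=10, insert_length=int(x))
            for i, x in enumerate(rng.integers(1000, 3000, size=50))
        ]
        kept = filter_by_length(records)
        assert {r.accession for r in kept} == {
            r.accession for r in records if r.full_length < 2048
        }

    def test_redundancy_reduction_intersection_semantics(self, caplog):
        records = [make_record(a) for a in ("A1", "A2", "A3", "A4")]
        cluster_map = {"A1": "C1", "A2": "C1", "A3": "C2"}  # A4 unmapped
        kept = reduce_redundancy(records, cluster_map)
        assert {r.accession for r in kept} == {"A1", "A3"}

    def test_redundancy_reduction_is_idempotent(self, combo_records):
        rng = np.random.default_rng(9)
        cluster_map = {
            r.accession: f"C{rng.integers(40)}" for r in combo_records
        }
        once = reduce_redundancy(combo_records, cluster_map)
        twice = reduce_redundancy(once, cluster_map)
        assert [r.record_id for r in once] == [r.record_id for r in twice]
        clusters = {cluster_map[r.accession] for r in combo_records}
        assert len(once) == len(clusters)

    def test_empty_cluster_map_drops_everything(self):
        assert reduce_redundancy([make_record("A1")], {}) == []


class TestCorpusStatistics:
    def test_single_record_partner_counts(self):
        stats = corpus_statistics([make_record("A", parent="PA", insert="IB")])
        assert stats.parent_partner_counts.iloc[0].tolist() == ["PA", 1]
        assert stats.insert_partner_counts.iloc[0].tolist() == ["IB", 1]

    def test_relative_junction_position(self):
        rec = make_record("A", junction=50, length=150)
        stats = corpus_statistics([rec])
        hist = stats.junction_rel_protein_hist
        # j_rel = 50/150 = 0.3333 lands in exactly one bin
        assert hist["count"].sum() == 1
        row = hist[hist["count"] == 1].iloc[0]
        assert row["j_rel_bin_start"] <= 50 / 150 < row["j_rel_bin_end"]

    def test_histograms_conserve_record_counts(self, combo_records):
        stats = corpus_statistics(combo_records)
        n = len(combo_records)
        assert stats.n_records == n
        for name in (
            "insert_length_hist",
            "protein_length_hist",
            "junction_rel_protein_hist",
        ):
            assert stats.tables[name]["count"].sum() == n
        combos = {(r.parent_superfamily, r.insert_superfamily) for r in combo_records}
        assert stats.parent_partner_counts["n_unique_insert_partners"].sum() == len(combos)

    def test_empty_corpus_does_not_crash(self, tmp_path):
        stats = corpus_statistics([])
        assert stats.n_records == 0
        stats.write(tmp_path / "stats")


class TestRecordIO:
    def test_tsv_fasta_roundtrip(self, tmp_path, small_corpus_files):
        from dominsert.corpus import curate

        corpus, paths = small_corpus_files
        records = curate(paths["annotations"], paths["fasta"])
        write_records_fasta(records, tmp_path / "po.fasta")
        write_records_tsv(records, tmp_path / "rec.tsv")
        back = read_records_tsv(tmp_path / "rec.tsv", tmp_path / "po.fasta")
        assert [r.record_id for r in back] == [r.record_id for r in records]
        assert all(
            a.parent_only_sequence == b.parent_only_sequence
            and a.parent_span == b.parent_span
            for a, b in zip(back, records)
        )
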