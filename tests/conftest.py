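import numpy as np
import pytest

from dominsert.corpus import DomainAnnotation, InsertionRecord
from dominsert.synthetic import FixtureConfig, generate_synthetic_corpus


@pytest.fixture(scope="session")
def small_corpus_files(tmp_path_factory):
    """A 60-protein synthetic corpus (20% decoys) written to disk."""
    corpus = generate_synthetic_corpus(FixtureConfig(n_proteins=60, seed=7))
    outdir = tmp_path_factory.mktemp("small_corpus")
    paths = corpus.write(outdir)
    return corpus, paths


def make_record(
    accession: str,
    junction: int = 5,
    length: int = 12,
    parent: str = "PA",
    insert: str = "IA",
    insert_length: int = 30,
) -> InsertionRecord:
    """A minimal valid record for split/filter tests (sequence content unused)."""
    seq = ("ACDEFGHIKLMNPQRSTVWY" * (length // 20 + 1))[:length]
    return InsertionRecord(
        accession=accession,
        parent_only_sequence=seq,
        junction=junction,
        parent_superfamily=parent,
        insert_superfamily=insert,
        insert_length=insert_length,
        full_length=length + insert_length,
    )


@pytest.fixture(scope="session")
def combo_records():
    """~300 records over 60 combinations with skewed combination sizes."""
    rng = np.random.default_rng(42)
    records = []
    i = 0
    for c in range(60):
        size = 1 + rng.zipf(1.5)
        size = min(int(size), 12)  # largest combination share ~4%
        for _ in range(size):
            records.append(
                make_record(f"Q{i:05d}", parent=f"P{c % 12:02d}", insert=f"I{c:02d}")
            )
            i += 1
    return records


def random_annotation_layout(
    rng: np.random.Generator, accession: str, seq_len: int = 300
) -> list[DomainAnnotation]:
    """A random mix of nested, disjoint, multi-segment and decoy annotations.

    Used to exercise nested-event detection against the brute-force oracle:
    layouts include clean two-segment parents with gap-filling inserts,
    gaps left unfilled, inserts not matching the gap, >2-segment parents,
    and ambiguous double-filled gaps.
    """
    annotations: list[DomainAnnotation] = []
    n_parents = rng.integers(0, 4)
    cursor = 0
    for p in range(n_parents):
        a0 = cursor + int(rng.integers(0, 10))
        seg1 = int(rng.integers(5, 30))
        gap = int(rng.integers(5, 40))
        seg2 = int(rng.integers(5, 30))
        a1, b0, b1 = a0 + seg1, a0 + seg1, a0 + seg1 + gap
        a_end = b1 + seg2
        if a_end > seq_len:
            break
        cursor = a_end
        kind = rng.integers(0, 6)
        sf = f"A{p}"
        if kind == 0:  # clean nested event
            annotations.append(
                DomainAnnotation(accession, sf, ((a0, a1), (b1, a_end)))
            )
            annotations.append(DomainAnnotation(accession, f"B{p}", ((b0, b1),)))
        elif kind == 1:  # gap left empty
            annotations.append(
                DomainAnnotation(accession, sf, ((a0, a1), (b1, a_end)))
            )
        elif kind == 2:  # insert does not fill the gap
            if b1 - b0 > 4:
                annotations.append(
                    DomainAnnotation(accession, sf, ((a0, a1), (b1, a_end)))
                )
                annotations.append(
                    DomainAnnotation(accession, f"B{p}", ((b0 + 2, b1 - 2),))
                )
        elif kind == 3:  # parent with three segments: skipped by contract
            third = (a_end + 2, a_end + 6)
            if third[1] <= seq_len:
                annotations.append(
                    DomainAnnotation(
                        accession, sf, ((a0, a1), (b1, a_end), third)
                    )
                )
                cursor = third[1]
        elif kind == 4:  # ambiguous: two candidates fill the same gap
            annotations.append(
                DomainAnnotation(accession, sf, ((a0, a1), (b1, a_end)))
            )
            annotations.append(DomainAnnotation(accession, f"B{p}", ((b0, b1),)))
            annotations.append(DomainAnnotation(accession, f"C{p}", ((b0, b1),)))
        else:  # plain single-segment domain, nothing nested
            annotations.append(DomainAnnotation(accession, sf, ((a0, a_end),)))
    return annotations


def oracle_nested_events(annotations):
    """Independent exhaustive scan for nested-insertion pairs.

    For every two-segment parent, collect contiguous annotations whose
    overall span equals the inter-segment gap exactly; a unique candidate
    is an event, anything else is not. Returns (parent_sf, insert_sf,
    insert_span) tuples sorted like the implementation's output.
    """
    events = []
    for parent in annotations:
        if len(parent.segments) != 2:
            continue
        gap = (parent.segments[0][1], parent.segments[1][0])
        fillers = [
            b
            for b in annotations
            if b is not parent and b.is_contiguous and b.span == gap
        ]
        if len(fillers) == 1:
            events.append(
                (
                    parent.superfamily_id,
                    fillers[0].superfamily_id,
                    fillers[0].span,
                )
            )
    return sorted(events, key=lambda e: (e[0], e[2][0]))
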