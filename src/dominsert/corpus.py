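"""Curation of natural intradomain-insertion events.

Domain-annotation databases occasionally record one domain as two
discontinuous segments with a second, complete domain annotated in between:
a natural domain-insertion event. This module parses per-protein domain
segment tables, detects such nested configurations, deletes the insert to
obtain the ``parent_only`` sequence, and labels the insertion junction so
the events can serve as positive training signal for a per-residue
insertion-tolerance classifier.

Coordinates are 0-based, half-open throughout. The junction ``j`` of a
record counts the residues N-terminal of the deleted insert, i.e. the
insert sat between ``parent_only`` indices ``j - 1`` and ``j``.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids, alphabetical by one-letter code.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Ambiguity codes tolerated in raw input sequences (records containing them
#: are dropped at curation unless ``keep_noncanonical`` is set).
AMBIGUOUS_AA = "BJOUXZ"

_CANONICAL_SET = frozenset(CANONICAL_AA)
_ALLOWED_SET = frozenset(CANONICAL_AA + AMBIGUOUS_AA)

LABEL_POSITIVE = 1
LABEL_UNKNOWN = 0


class AnnotationError(ValueError):
    """Raised for malformed annotation tables or inconsistent coordinates."""


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence keyed by accession."""

    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - _ALLOWED_SET
        if bad:
            raise ValueError(
                f"{self.accession}: disallowed residue codes {sorted(bad)}"
            )

    @property
    def is_canonical(self) -> bool:
        return set(self.sequence) <= _CANONICAL_SET


@dataclass(frozen=True)
class DomainAnnotation:
    """One domain instance: a superfamily ID plus >= 1 residue segments.

    Segments are sorted, non-overlapping, half-open ``[start, end)``
    intervals. A discontinuous (two-segment) annotation is the signature of
    a potential insertion event.
    """

    accession: str
    superfamily_id: str
    segments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("annotation with no segments")
        prev_end = -1
        for start, end in self.segments:
            if start >= end:
                raise ValueError(
                    f"{self.accession}/{self.superfamily_id}: "
                    f"empty or inverted segment [{start}, {end})"
                )
            if start < prev_end:
                raise ValueError(
                    f"{self.accession}/{self.superfamily_id}: "
                    "segments overlap or are unsorted"
                )
            prev_end = end

    @property
    def span(self) -> tuple[int, int]:
        """Overall interval from first segment start to last segment end."""
        return self.segments[0][0], self.segments[-1][1]

    @property
    def is_contiguous(self) -> bool:
        return all(
            self.segments[i][1] == self.segments[i + 1][0]
            for i in range(len(self.segments) - 1)
        )


@dataclass(frozen=True)
class InsertionEvent:
    """A nested pair: ``insert`` fills the gap of a two-segment ``parent``."""

    accession: str
    parent_superfamily: str
    insert_superfamily: str
    insert_span: tuple[int, int]
    parent_span: tuple[int, int]

    def __post_init__(self) -> None:
        (b0, b1), (p0, p1) = self.insert_span, self.parent_span
        if not (p0 < b0 and b1 < p1):
            raise ValueError(
                f"{self.accession}: insert span {self.insert_span} not "
                f"strictly inside parent span {self.parent_span}"
            )


@dataclass(frozen=True)
class InsertionRecord:
    """A curated event: the parent-only sequence and its junction.

    ``parent_only_sequence`` is the full protein with the insert domain
    deleted; ``junction`` is the number of residues N-terminal of the
    deletion point. ``parent_span`` (optional) is the parent annotation's
    overall interval in full-protein coordinates, retained for
    domain-relative junction statistics.
    """

    accession: str
    parent_only_sequence: str
    junction: int
    parent_superfamily: str
    insert_superfamily: str
    insert_length: int
    full_length: int
    parent_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        L = len(self.parent_only_sequence)
        if L + self.insert_length != self.full_length:
            raise ValueError(
                f"{self.accession}: length bookkeeping violated "
                f"({L} + {self.insert_length} != {self.full_length})"
            )
        if not 0 < self.junction < L:
            raise ValueError(
                f"{self.accession}: junction {self.junction} at a terminus "
                f"of a {L}-residue parent_only sequence"
            )

    @property
    def combination(self) -> tuple[str, str]:
        """The (parent, insert) superfamily combination key."""
        return (self.parent_superfamily, self.insert_superfamily)

    @property
    def record_id(self) -> str:
        return (
            f"{self.accession}|j={self.junction}"
            f"|parent={self.parent_superfamily}"
            f"|insert={self.insert_superfamily}"
        )


@dataclass(frozen=True)
class LabelVector:
    """Per-residue POSITIVE/UNKNOWN labels for one parent_only sequence."""

    length: int
    labels: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != self.length:
            raise ValueError("label count != declared length")

    @property
    def positive_indices(self) -> tuple[int, ...]:
        return tuple(
            i for i, v in enumerate(self.labels) if v == LABEL_POSITIVE
        )

    @property
    def unknown_indices(self) -> tuple[int, ...]:
        return tuple(
            i for i, v in enumerate(self.labels) if v == LABEL_UNKNOWN
        )


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ("accession", "superfamily_id", "start", "end")


def parse_annotations(
    annotation_table_path: str | Path,
    fasta_path: str | Path,
) -> dict[str, tuple[ProteinRecord, list[DomainAnnotation]]]:
    """Read a segment table plus FASTA into grouped per-protein annotations.

    The table is tab-separated with a header line ``accession
    superfamily_id start end`` and one row per segment; ``#`` lines are
    comments. Segments sharing (accession, superfamily_id) are grouped into
    one :class:`DomainAnnotation`. Rows referencing sequences absent from
    the FASTA, and annotations whose segments overlap or run past the
    sequence end, are logged and skipped; structurally malformed rows
    (wrong column count, non-integer or inverted coordinates) raise
    :class:`AnnotationError` with the offending line number.
    """
    proteins: dict[str, ProteinRecord] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        proteins[rec.id] = ProteinRecord(rec.id, str(rec.seq).upper())

    rows: dict[tuple[str, str], list[tuple[int, int]]] = defaultdict(list)
    header_seen = False
    with open(annotation_table_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if tuple(fields) != _TSV_COLUMNS:
                    raise AnnotationError(
                        f"line {lineno}: expected header "
                        f"{list(_TSV_COLUMNS)}, got {fields}"
                    )
                header_seen = True
                continue
            if len(fields) != 4:
                raise AnnotationError(
                    f"line {lineno}: expected 4 tab-separated fields, "
                    f"got {len(fields)}"
                )
            acc, sf, start_s, end_s = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise AnnotationError(
                    f"line {lineno}: non-integer coordinates "
                    f"({start_s!r}, {end_s!r})"
                ) from exc
            if start >= end or start < 0:
                raise AnnotationError(
                    f"line {lineno}: invalid segment [{start}, {end})"
                )
            if acc not in proteins:
                logger.warning(
                    "line %d: accession %s absent from FASTA; row skipped",
                    lineno,
                    acc,
                )
                continue
            rows[(acc, sf)].append((start, end))

    result: dict[str, tuple[ProteinRecord, list[DomainAnnotation]]] = {
        acc: (prot, []) for acc, prot in proteins.items()
    }
    for (acc, sf), segments in rows.items():
        seq_len = len(proteins[acc].sequence)
        segments = sorted(segments)
        if segments[-1][1] > seq_len:
            logger.warning(
                "%s/%s: segment end %d beyond sequence length %d; "
                "annotation rejected",
                acc,
                sf,
                segments[-1][1],
                seq_len,
            )
            continue
        try:
            ann = DomainAnnotation(acc, sf, tuple(segments))
        except ValueError as exc:
            logger.warning("%s/%s rejected: %s", acc, sf, exc)
            continue
        result[acc][1].append(ann)
    for acc in result:
        result[acc][1].sort(key=lambda a: (a.superfamily_id, a.span))
    return result


# ---------------------------------------------------------------------------
# Event detection and record construction
# ---------------------------------------------------------------------------


def detect_intradomain_insertions(
    annotations: Sequence[DomainAnnotation],
    gap_slack: int = 0,
) -> list[InsertionEvent]:
    """Find every nested pair among one protein's annotations.

    A parent candidate is an annotation with exactly two segments; an
    insert candidate is a contiguous annotation whose overall span fills
    the parent's inter-segment gap, exactly by default or within
    ``gap_slack`` residues per edge. Parents with more than two segments,
    and gaps matched by multiple candidate inserts, are skipped and logged
    (ambiguous configurations the curation does not attempt to resolve).
    Events are returned sorted by (parent_superfamily, insert start).
    """
    events: list[InsertionEvent] = []
    for parent in annotations:
        if len(parent.segments) == 1:
            continue
        if len(parent.segments) > 2:
            logger.info(
                "%s/%s: %d segments; parents with >2 segments are skipped",
                parent.accession,
                parent.superfamily_id,
                len(parent.segments),
            )
            continue
        gap_start = parent.segments[0][1]
        gap_end = parent.segments[1][0]
        candidates = []
        for insert in annotations:
            if insert is parent or not insert.is_contiguous:
                continue
            b0, b1 = insert.span
            if b0 < gap_start or b1 > gap_end:
                continue
            if (b0 - gap_start) <= gap_slack and (gap_end - b1) <= gap_slack:
                candidates.append(insert)
        if len(candidates) > 1:
            logger.info(
                "%s/%s: gap [%d, %d) matched by %d candidate inserts; "
                "skipped as ambiguous",
                parent.accession,
                parent.superfamily_id,
                gap_start,
                gap_end,
                len(candidates),
            )
            continue
        if candidates:
            insert = candidates[0]
            events.append(
                InsertionEvent(
                    accession=parent.accession,
                    parent_superfamily=parent.superfamily_id,
                    insert_superfamily=insert.superfamily_id,
                    insert_span=insert.span,
                    parent_span=parent.span,
                )
            )
    events.sort(key=lambda e: (e.parent_superfamily, e.insert_span[0]))
    return events


def build_parent_only(
    protein: ProteinRecord, event: InsertionEvent
) -> InsertionRecord:
    """Delete the insert domain and record the junction position.

    The junction equals the insert's start coordinate: everything N-terminal
    of the insert keeps its index after the deletion.
    """
    if protein.accession != event.accession:
        raise ValueError(
            f"event accession {event.accession} != protein "
            f"{protein.accession}"
        )
    b0, b1 = event.insert_span
    if b1 > len(protein.sequence):
        raise ValueError(
            f"{protein.accession}: insert span {event.insert_span} beyond "
            f"sequence length {len(protein.sequence)}"
        )
    parent_only = protein.sequence[:b0] + protein.sequence[b1:]
    return InsertionRecord(
        accession=protein.accession,
        parent_only_sequence=parent_only,
        junction=b0,
        parent_superfamily=event.parent_superfamily,
        insert_superfamily=event.insert_superfamily,
        insert_length=b1 - b0,
        full_length=len(protein.sequence),
        parent_span=event.parent_span,
    )


def make_label_vector(
    record: InsertionRecord, window_radius: int = 1
) -> LabelVector:
    """Label the junction and its flanking residues POSITIVE.

    Domain boundaries in annotation databases are imprecise and
    experimentally tolerant sites come in short stretches, so the residues
    adjacent to the junction are labelled positive too: positions
    ``{j - r, ..., j + r}`` clipped to the sequence (default radius 1 gives
    the junction-centred triple ``{j-1, j, j+1}``). Everything else is
    UNKNOWN, not negative — absence of a recorded insertion is not evidence
    of intolerance.
    """
    L = len(record.parent_only_sequence)
    j = record.junction
    labels = [LABEL_UNKNOWN] * L
    for i in range(j - window_radius, j + window_radius + 1):
        if 0 <= i < L:
            labels[i] = LABEL_POSITIVE
    return LabelVector(length=L, labels=tuple(labels))


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def filter_by_length(
    records: Iterable[InsertionRecord], max_len: int = 2048
) -> list[InsertionRecord]:
    """Keep records whose full protein is strictly shorter than ``max_len``."""
    records = list(records)
    kept = [r for r in records if r.full_length < max_len]
    removed = len(records) - len(kept)
    if removed:
        logger.info(
            "length filter (< %d aa) removed %d of %d records",
            max_len,
            removed,
            len(records),
        )
    return kept


def filter_canonical(
    records: Iterable[InsertionRecord],
) -> list[InsertionRecord]:
    """Drop records whose parent_only sequence has non-canonical residues."""
    records = list(records)
    kept = [
        r
        for r in records
        if set(r.parent_only_sequence) <= _CANONICAL_SET
    ]
    removed = len(records) - len(kept)
    if removed:
        logger.info("dropped %d records with non-canonical residues", removed)
    return kept


def reduce_redundancy(
    records: Iterable[InsertionRecord],
    cluster_map: Mapping[str, str],
) -> list[InsertionRecord]:
    """Keep at most one record per sequence cluster.

    ``cluster_map`` assigns accessions to precomputed identity clusters (a
    UniRef50-style table); sequence identity itself is never computed here.
    Records whose accession has no cluster assignment are dropped —
    intersection semantics. Within a cluster the first record in canonical
    (accession, junction, insert) order is retained, which makes the
    operation deterministic and idempotent.
    """
    records = sorted(
        records,
        key=lambda r: (r.accession, r.junction, r.insert_superfamily),
    )
    if not cluster_map:
        logger.warning("empty cluster map: all records dropped")
        return []
    seen: set[str] = set()
    kept: list[InsertionRecord] = []
    dropped_unmapped = 0
    for rec in records:
        cluster = cluster_map.get(rec.accession)
        if cluster is None:
            dropped_unmapped += 1
            continue
        if cluster in seen:
            continue
        seen.add(cluster)
        kept.append(rec)
    if dropped_unmapped:
        logger.info(
            "dropped %d records with no cluster assignment", dropped_unmapped
        )
    return kept


def deduplicate_records(
    records: Iterable[InsertionRecord],
) -> list[InsertionRecord]:
    """Collapse records identical in (accession, insert span)."""
    seen: set[tuple[str, int, int]] = set()
    out = []
    for rec in records:
        key = (rec.accession, rec.junction, rec.insert_length)
        if key in seen:
            continue
        seen.add(key)
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# High-level curation
# ---------------------------------------------------------------------------


def curate(
    annotation_table_path: str | Path,
    fasta_path: str | Path,
    cluster_map: Mapping[str, str] | None = None,
    max_len: int = 2048,
    gap_slack: int = 0,
    keep_noncanonical: bool = False,
) -> list[InsertionRecord]:
    """Full curation: parse, detect, build, filter, de-redundify.

    Returns the curated insertion records sorted by record identity.
    ``cluster_map=None`` skips redundancy reduction entirely (distinct from
    an *empty* map, which drops everything by intersection semantics).
    """
    parsed = parse_annotations(annotation_table_path, fasta_path)
    records: list[InsertionRecord] = []
    for accession in sorted(parsed):
        protein, annotations = parsed[accession]
        for event in detect_intradomain_insertions(annotations, gap_slack):
            try:
                records.append(build_parent_only(protein, event))
            except ValueError as exc:
                logger.warning("record rejected: %s", exc)
    records = deduplicate_records(records)
    records = filter_by_length(records, max_len=max_len)
    if not keep_noncanonical:
        records = filter_canonical(records)
    if cluster_map is not None:
        records = reduce_redundancy(records, cluster_map)
    records.sort(key=lambda r: r.record_id)
    return records


# ---------------------------------------------------------------------------
# Corpus statistics
# ---------------------------------------------------------------------------


@dataclass
class CorpusStatistics:
    """Corpus-level summaries: partner counts, lengths, junction positions."""

    parent_partner_counts: pd.DataFrame
    insert_partner_counts: pd.DataFrame
    insert_length_hist: pd.DataFrame
    parent_domain_length_hist: pd.DataFrame
    protein_length_hist: pd.DataFrame
    junction_rel_protein_hist: pd.DataFrame
    junction_rel_domain_hist: pd.DataFrame
    n_records: int = 0
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tables = {
            "parent_partner_counts": self.parent_partner_counts,
            "insert_partner_counts": self.insert_partner_counts,
            "insert_length_hist": self.insert_length_hist,
            "parent_domain_length_hist": self.parent_domain_length_hist,
            "protein_length_hist": self.protein_length_hist,
            "junction_rel_protein_hist": self.junction_rel_protein_hist,
            "junction_rel_domain_hist": self.junction_rel_domain_hist,
        }

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, frame in self.tables.items():
            frame.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)


def _hist_frame(
    values: np.ndarray, bins: np.ndarray, label: str
) -> pd.DataFrame:
    counts, edges = np.histogram(values, bins=bins)
    return pd.DataFrame(
        {
            f"{label}_bin_start": edges[:-1],
            f"{label}_bin_end": edges[1:],
            "count": counts,
        }
    )


def corpus_statistics(
    records: Sequence[InsertionRecord],
    n_position_bins: int = 20,
) -> CorpusStatistics:
    """Summaries of a curated corpus.

    Reports (i) per-superfamily counts of unique partner combinations,
    (ii) length distributions of inserts, parent domains (insert removed)
    and parent proteins, and (iii) the relative junction position within
    the parent_only protein and within the parent-domain span. Histogram
    bin counts each sum to the number of contributing records.
    """
    empty = pd.DataFrame()
    if not records:
        return CorpusStatistics(
            empty, empty, empty, empty, empty, empty, empty, n_records=0
        )

    combos = sorted({r.combination for r in records})
    parent_counts = (
        pd.DataFrame(combos, columns=["parent_superfamily", "insert_superfamily"])
        .groupby("parent_superfamily")
        .size()
        .reset_index(name="n_unique_insert_partners")
    )
    insert_counts = (
        pd.DataFrame(combos, columns=["parent_superfamily", "insert_superfamily"])
        .groupby("insert_superfamily")
        .size()
        .reset_index(name="n_unique_parent_partners")
    )

    insert_lengths = np.array([r.insert_length for r in records])
    protein_lengths = np.array([r.full_length for r in records])

    def length_bins(values: np.ndarray) -> np.ndarray:
        hi = int(values.max()) + 1
        return np.linspace(0, hi, min(30, hi) + 1)

    # Parent-domain length with the insert removed.
    domain_lengths = []
    j_rel_domain = []
    for r in records:
        if r.parent_span is None:
            continue
        p0, p1 = r.parent_span
        dlen = (p1 - p0) - r.insert_length
        domain_lengths.append(dlen)
        j_rel_domain.append((r.junction - p0) / dlen)
    domain_lengths_a = np.array(domain_lengths, dtype=float)

    j_rel_protein = np.array(
        [r.junction / len(r.parent_only_sequence) for r in records]
    )
    pos_bins = np.linspace(0.0, 1.0, n_position_bins + 1)
    pos_bins[-1] = np.nextafter(1.0, 2.0)  # right-closed final bin

    return CorpusStatistics(
        parent_partner_counts=parent_counts,
        insert_partner_counts=insert_counts,
        insert_length_hist=_hist_frame(
            insert_lengths, length_bins(insert_lengths), "insert_length"
        ),
        parent_domain_length_hist=(
            _hist_frame(
                domain_lengths_a,
                length_bins(domain_lengths_a),
                "parent_domain_length",
            )
            if len(domain_lengths_a)
            else pd.DataFrame()
        ),
        protein_length_hist=_hist_frame(
            protein_lengths, length_bins(protein_lengths), "protein_length"
        ),
        junction_rel_protein_hist=_hist_frame(
            j_rel_protein, pos_bins, "j_rel"
        ),
        junction_rel_domain_hist=(
            _hist_frame(np.array(j_rel_domain), pos_bins, "j_rel_domain")
            if j_rel_domain
            else pd.DataFrame()
        ),
        n_records=len(records),
    )


# ---------------------------------------------------------------------------
# Corpus I/O
# ---------------------------------------------------------------------------


def write_records_fasta(
    records: Sequence[InsertionRecord], path: str | Path
) -> None:
    """Write parent_only sequences; headers carry junction and superfamilies."""
    seq_records = [
        SeqRecord(
            Seq(r.parent_only_sequence), id=r.record_id, description=""
        )
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


_RECORD_COLUMNS = [
    "accession",
    "junction",
    "parent_superfamily",
    "insert_superfamily",
    "insert_length",
    "full_length",
    "parent_start",
    "parent_end",
]


def write_records_tsv(
    records: Sequence[InsertionRecord], path: str | Path
) -> None:
    rows = []
    for r in records:
        p0, p1 = r.parent_span if r.parent_span is not None else (-1, -1)
        rows.append(
            (
                r.accession,
                r.junction,
                r.parent_superfamily,
                r.insert_superfamily,
                r.insert_length,
                r.full_length,
                p0,
                p1,
            )
        )
    pd.DataFrame(rows, columns=_RECORD_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_records_tsv(
    tsv_path: str | Path, fasta_path: str | Path
) -> list[InsertionRecord]:
    """Rebuild records from the TSV plus the parent_only FASTA."""
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    frame = pd.read_csv(tsv_path, sep="\t")
    records = []
    for row in frame.itertuples(index=False):
        rid = (
            f"{row.accession}|j={row.junction}"
            f"|parent={row.parent_superfamily}|insert={row.insert_superfamily}"
        )
        if rid not in seqs:
            raise AnnotationError(f"record {rid} missing from FASTA")
        span = (
            (int(row.parent_start), int(row.parent_end))
            if int(row.parent_start) >= 0
            else None
        )
        records.append(
            InsertionRecord(
                accession=row.accession,
                parent_only_sequence=seqs[rid],
                junction=int(row.junction),
                parent_superfamily=str(row.parent_superfamily),
                insert_superfamily=str(row.insert_superfamily),
                insert_length=int(row.insert_length),
                full_length=int(row.full_length),
                parent_span=span,
            )
        )
    return records


def read_cluster_map(path: str | Path) -> dict[str, str]:
    """Read an accession -> cluster TSV (header ``accession\tcluster``)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if list(frame.columns[:2]) != ["accession", "cluster"]:
        raise AnnotationError(
            f"cluster map must start with columns accession, cluster; "
            f"got {list(frame.columns)}"
        )
    return dict(zip(frame["accession"], frame["cluster"]))
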