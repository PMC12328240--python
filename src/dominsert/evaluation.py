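"""Score traces and benchmarking against experimental insertion screens.

A trained head turns any query sequence into a per-residue *score trace* —
the probability that a domain insertion at that position is tolerated.
This module predicts traces (including on artificial head-to-tail
concatemers, which inform the model of oligomeric context), converts
published screen tables into POS/NEG/UNKNOWN label sets under the
conventions used for AraC-, Cas9- and Kir2.1-style datasets, and scores
traces with a Mann-Whitney AUROC, normalized site scores, and
secondary-structure groupings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .encoding import EmbeddingProvider, EncodedSequence, encode_with_provider
from .model import ModelParams, forward

logger = logging.getLogger(__name__)

POS, NEG, UNKNOWN = "POS", "NEG", "UNKNOWN"

CONVENTIONS = ("ge1_of_k", "ge1_of_k_with_unknown", "m_of_n")


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ScoreTrace:
    """Per-residue insertion-tolerance scores for one sequence."""

    accession: str
    scores: np.ndarray
    checkpoint_id: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.scores)
        if s.ndim != 1 or s.size == 0:
            raise EvaluationError("scores must be a non-empty 1-D array")
        if np.any(s <= 0.0) or np.any(s >= 1.0):
            raise EvaluationError("scores must lie strictly inside (0, 1)")

    def __len__(self) -> int:
        return len(self.scores)

    def to_frame(self, sequence: str | None = None) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "position": np.arange(len(self.scores)),
                "score": self.scores,
            }
        )
        if sequence is not None:
            if len(sequence) != len(self.scores):
                raise EvaluationError("sequence length != trace length")
            frame.insert(1, "residue", list(sequence))
        return frame

    def write(self, path: str | Path, sequence: str | None = None) -> None:
        self.to_frame(sequence).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class BenchmarkLabelSet:
    """Per-position POS/NEG/UNKNOWN labels derived from a screen."""

    labels: tuple[str, ...]
    convention_id: str

    def __post_init__(self) -> None:
        bad = set(self.labels) - {POS, NEG, UNKNOWN}
        if bad:
            raise EvaluationError(f"invalid labels {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)

    def counts(self) -> dict[str, int]:
        return {
            k: sum(1 for v in self.labels if v == k)
            for k in (POS, NEG, UNKNOWN)
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": np.arange(len(self.labels)), "label": self.labels}
        )


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


def predict_trace(
    params: ModelParams,
    provider: EmbeddingProvider,
    sequence: str,
    accession: str = "",
    cache_dir: str | Path | None = None,
    checkpoint_id: str = "",
) -> ScoreTrace:
    """Encode a sequence and run the head; no smoothing is applied."""
    if not sequence:
        raise EvaluationError("cannot predict on an empty sequence")
    if params.encoder_id and params.encoder_id != provider.encoder_id:
        raise EvaluationError(
            f"model expects encoder {params.encoder_id!r} but provider is "
            f"{provider.encoder_id!r}"
        )
    encoded = encode_with_provider(
        sequence, provider, accession=accession, cache_dir=cache_dir
    )
    _, scores = forward(params, encoded)
    return ScoreTrace(accession or "query", scores, checkpoint_id)


def predict_from_encoding(
    params: ModelParams,
    encoded: EncodedSequence,
    checkpoint_id: str = "",
) -> ScoreTrace:
    """Run the head on an already-encoded sequence (cache-backed workflows)."""
    _, scores = forward(params, encoded)
    return ScoreTrace(encoded.accession or "query", scores, checkpoint_id)


@dataclass(frozen=True)
class ConcatemerPrediction:
    monomer_length: int
    n_copies: int
    per_copy: tuple[ScoreTrace, ...]
    mean_trace: ScoreTrace


def predict_concatemer(
    params: ModelParams,
    provider: EmbeddingProvider,
    sequence: str,
    n_copies: int,
    accession: str = "",
    cache_dir: str | Path | None = None,
) -> ConcatemerPrediction:
    """Predict on a head-to-tail multimer and fold the trace back per copy.

    Useful for obligate oligomers: the concatemer exposes the model to
    inter-protomer context a monomer sequence cannot convey. The full-trace
    windows are sliced back to monomer length and summarized by their
    positionwise mean.
    """
    if n_copies < 1:
        raise EvaluationError("n_copies must be >= 1")
    L = len(sequence)
    full = predict_trace(
        params,
        provider,
        sequence * n_copies,
        accession=accession or "concatemer",
        cache_dir=cache_dir,
    )
    per_copy = tuple(
        ScoreTrace(
            f"{full.accession}|copy{c}",
            full.scores[c * L : (c + 1) * L],
            full.checkpoint_id,
        )
        for c in range(n_copies)
    )
    mean_scores = np.mean([t.scores for t in per_copy], axis=0)
    mean = ScoreTrace(
        f"{full.accession}|mean", mean_scores, full.checkpoint_id
    )
    return ConcatemerPrediction(L, n_copies, per_copy, mean)


# ---------------------------------------------------------------------------
# Screen label conventions
# ---------------------------------------------------------------------------


def read_screen_table(path: str | Path) -> pd.DataFrame:
    """Read a screen TSV: ``position`` (1-based) plus one column per insert."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    if "position" not in frame.columns:
        raise EvaluationError("screen table must have a 'position' column")
    return frame


def labels_from_screen(
    screen: pd.DataFrame | str | Path,
    convention: str,
    sequence_length: int,
    m: int | None = None,
) -> BenchmarkLabelSet:
    """Convert a per-position screen table into POS/NEG/UNKNOWN labels.

    Positions in the table are 1-based (mutagenesis-literature convention)
    and converted to 0-based internally. Conventions:

    ``ge1_of_k``
        POS where any insert's enrichment is strictly positive, NEG
        everywhere else — including positions absent from the table.
    ``ge1_of_k_with_unknown``
        as above, but positions absent from the table are UNKNOWN.
    ``m_of_n``
        POS where >= m inserts are tolerated (value > 0), NEG where >= m
        are not tolerated (value <= 0), UNKNOWN otherwise (including
        positions absent from the table); requires ``m``.

    Missing cells (NaN) count as "no data for that insert". Duplicate rows
    for one position with conflicting values are an error.
    """
    if convention not in CONVENTIONS:
        raise EvaluationError(
            f"unknown convention {convention!r}; expected one of {CONVENTIONS}"
        )
    if convention == "m_of_n" and m is None:
        raise EvaluationError("convention m_of_n requires the threshold m")
    if isinstance(screen, (str, Path)):
        screen = read_screen_table(screen)
    insert_cols = [c for c in screen.columns if c != "position"]
    if not insert_cols:
        raise EvaluationError("screen table has no insert columns")

    dedup = screen.drop_duplicates()
    if dedup["position"].duplicated().any():
        dups = dedup.loc[
            dedup["position"].duplicated(), "position"
        ].tolist()
        raise EvaluationError(
            f"conflicting duplicate rows for positions {sorted(set(dups))}"
        )
    logger.info(
        "screen positions read as 1-based; converting to 0-based internally"
    )

    default = NEG if convention == "ge1_of_k" else UNKNOWN
    labels = [default] * sequence_length
    for row in dedup.itertuples(index=False):
        pos0 = int(row.position) - 1
        if not 0 <= pos0 < sequence_length:
            raise EvaluationError(
                f"screen position {row.position} (1-based) outside sequence "
                f"of length {sequence_length}"
            )
        values = np.array(
            [getattr(row, c) for c in insert_cols], dtype=float
        )
        present = ~np.isnan(values)
        if convention in ("ge1_of_k", "ge1_of_k_with_unknown"):
            labels[pos0] = POS if np.any(values[present] > 0) else NEG
        else:
            n_tol = int(np.sum(values[present] > 0))
            n_not = int(np.sum(values[present] <= 0))
            if n_tol >= m:
                labels[pos0] = POS
            elif n_not >= m:
                labels[pos0] = NEG
            else:
                labels[pos0] = UNKNOWN
    return BenchmarkLabelSet(tuple(labels), convention)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def _auroc_from_scores(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann-Whitney AUROC: P(pos > neg) with ties counted 0.5."""
    ranks = rankdata(np.concatenate([pos, neg]))
    n_pos, n_neg = pos.size, neg.size
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auroc(trace: ScoreTrace | np.ndarray, labels: BenchmarkLabelSet) -> float:
    """AUROC of POS vs NEG positions; UNKNOWN positions are dropped."""
    scores = np.asarray(
        trace.scores if isinstance(trace, ScoreTrace) else trace, dtype=float
    )
    if scores.shape[0] != len(labels):
        raise EvaluationError(
            f"trace length {scores.shape[0]} != label length {len(labels)}"
        )
    lab = np.asarray(labels.labels)
    pos = scores[lab == POS]
    neg = scores[lab == NEG]
    if pos.size == 0 or neg.size == 0:
        raise EvaluationError(
            f"AUROC needs >= 1 POS and >= 1 NEG position; got "
            f"{pos.size} POS, {neg.size} NEG"
        )
    return _auroc_from_scores(pos, neg)


def normalized_site_score(
    trace: ScoreTrace | np.ndarray, site_position: int
) -> float:
    """Site score divided by the trace mean.

    The convention used to compare engineered-insertion sites across
    protein orthologs whose overall score levels differ.
    """
    scores = np.asarray(
        trace.scores if isinstance(trace, ScoreTrace) else trace, dtype=float
    )
    if not 0 <= site_position < scores.size:
        raise EvaluationError(
            f"site {site_position} outside trace of length {scores.size}"
        )
    return float(scores[site_position] / scores.mean())


SS_CLASSES = ("H", "E", "C")


def group_scores_by_structure(
    trace: ScoreTrace | np.ndarray, ss_string: str
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Partition scores by secondary-structure class (H/E/C).

    ``ss_string`` comes from an external secondary-structure predictor and
    must match the trace length. Returns the per-class score arrays and a
    summary frame (count, median, quartiles by linear interpolation).
    """
    scores = np.asarray(
        trace.scores if isinstance(trace, ScoreTrace) else trace, dtype=float
    )
    if len(ss_string) != scores.size:
        raise EvaluationError(
            f"secondary-structure string length {len(ss_string)} != trace "
            f"length {scores.size}"
        )
    bad = set(ss_string) - set(SS_CLASSES)
    if bad:
        raise EvaluationError(f"invalid secondary-structure codes {sorted(bad)}")
    ss = np.array(list(ss_string))
    groups = {cls: scores[ss == cls] for cls in SS_CLASSES if (ss == cls).any()}
    rows = []
    for cls, vals in groups.items():
        q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
        rows.append((cls, vals.size, q1, med, q3))
    summary = pd.DataFrame(
        rows, columns=["ss_class", "count", "q1", "median", "q3"]
    )
    return groups, summary


def score_distribution_summary(
    traces: Sequence[ScoreTrace],
    label_sets: Sequence[BenchmarkLabelSet],
) -> pd.DataFrame:
    """Pooled score distributions of POS vs NEG/UNKNOWN positions.

    The TSV analogue of box plots comparing predicted scores on true
    insertion sites against all other positions.
    """
    pooled: dict[str, list[float]] = {POS: [], NEG: [], UNKNOWN: []}
    for trace, labels in zip(traces, label_sets):
        lab = np.asarray(labels.labels)
        for cls in pooled:
            pooled[cls].extend(trace.scores[lab == cls].tolist())
    rows = []
    for cls, vals in pooled.items():
        if not vals:
            continue
        arr = np.asarray(vals)
        q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
        rows.append((cls, arr.size, arr.mean(), q1, med, q3))
    return pd.DataFrame(
        rows, columns=["label", "count", "mean", "q1", "median", "q3"]
    )
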