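"""Synthetic proteome with planted, learnable insertion junctions.

The real training corpus is mined from public domain-annotation snapshots
that cannot ship with a test suite. This module fabricates a drop-in
replacement: a proteome whose every non-decoy protein carries one
intradomain-insertion event at a known junction, marked by a short
sequence motif centred on the junction. The motif gives the downstream
classifier a local, learnable ground-truth signal — a stand-in for
whatever sequence features the real model exploits — without claiming any
biological realism (no domain-family composition biases, no phylogeny, no
true identity clustering).

Emitted artifacts use exactly the file dialects the curation pipeline
consumes (FASTA, segment TSV, cluster-map TSV), plus a truth table of
junction positions for oracle checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .corpus import CANONICAL_AA

_AA = np.array(list(CANONICAL_AA))


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureConfig:
    """Stated world of the synthetic corpus.

    Defaults: parent_only lengths 150-400 (matching typical single-domain
    protein scales and keeping desk-scale training fast), insert domains of
    60-140 residues (small globular domains), a 5-residue junction motif,
    Zipf-skewed superfamily usage so combination sizes are realistically
    unequal, and 20% decoy proteins without any insertion event.
    """

    n_proteins: int = 600
    length_range: tuple[int, int] = (150, 400)
    motif: str = "GSGSG"
    insert_length_range: tuple[int, int] = (60, 140)
    n_parent_superfamilies: int = 10
    n_insert_superfamilies: int = 8
    decoy_fraction: float = 0.2
    n_duplicate_clusters: int = 0
    zipf_exponent: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not set(self.motif) <= set(CANONICAL_AA):
            raise FixtureError("motif must use canonical residues")
        if len(self.motif) >= self.length_range[0]:
            raise FixtureError("motif longer than the minimum protein length")
        if not 0.0 <= self.decoy_fraction <= 1.0:
            raise FixtureError("decoy_fraction must be in [0, 1]")


@dataclass
class SyntheticCorpus:
    """In-memory corpus plus writers for the on-disk dialects."""

    sequences: dict[str, str]
    annotation_rows: list[tuple[str, str, int, int]]
    cluster_map: dict[str, str]
    truth: pd.DataFrame
    config: FixtureConfig = field(repr=False, default=None)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "proteome.fasta",
            "annotations": outdir / "annotations.tsv",
            "cluster_map": outdir / "clusters.tsv",
            "truth": outdir / "truth.tsv",
        }
        SeqIO.write(
            (
                SeqRecord(Seq(seq), id=acc, description="")
                for acc, seq in sorted(self.sequences.items())
            ),
            str(paths["fasta"]),
            "fasta",
        )
        pd.DataFrame(
            self.annotation_rows,
            columns=["accession", "superfamily_id", "start", "end"],
        ).to_csv(paths["annotations"], sep="\t", index=False)
        pd.DataFrame(
            sorted(self.cluster_map.items()), columns=["accession", "cluster"]
        ).to_csv(paths["cluster_map"], sep="\t", index=False)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _zipf_probs(n: int, exponent: float) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1) ** exponent
    return w / w.sum()


def generate_synthetic_corpus(config: FixtureConfig) -> SyntheticCorpus:
    """Build the synthetic proteome; fully determined by ``config.seed``.

    Per non-decoy protein: a uniform-background ``parent_only`` sequence of
    the configured length receives the motif at a random interior position;
    the insert domain (random sequence) is spliced in immediately after the
    motif's central residue, so the junction ``j`` sits at motif start + 3
    (for the default 5-mer) and the junction-centred positive window
    {j-1, j, j+1} lies inside the motif. Annotations are emitted as a
    two-segment parent superfamily plus a single-segment insert superfamily
    exactly filling the gap. Decoy proteins carry one ordinary
    single-segment annotation and no insertion. Each protein gets its own
    cluster, except ``n_duplicate_clusters`` pairs sharing a cluster to
    exercise redundancy reduction.
    """
    rng = np.random.default_rng(config.seed)
    motif = config.motif
    k = len(motif)
    n_decoys = int(round(config.n_proteins * config.decoy_fraction))
    parent_probs = _zipf_probs(
        config.n_parent_superfamilies, config.zipf_exponent
    )
    insert_probs = _zipf_probs(
        config.n_insert_superfamilies, config.zipf_exponent
    )

    sequences: dict[str, str] = {}
    rows: list[tuple[str, str, int, int]] = []
    truth_rows = []
    for i in range(config.n_proteins):
        acc = f"SYN{i:05d}"
        L = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        background = "".join(rng.choice(_AA, size=L))
        if i < n_decoys:
            # decoy: one plain single-segment domain, no nesting
            sequences[acc] = background
            sf = f"PAR{rng.choice(config.n_parent_superfamilies, p=parent_probs):03d}"
            d0 = int(rng.integers(0, L // 2))
            d1 = int(rng.integers(d0 + 10, L + 1))
            rows.append((acc, sf, d0, d1))
            continue

        # motif interior placement: junction j = m + k//2 + 1 must satisfy
        # 0 < j < L and leave room for non-empty parent segments
        m = int(rng.integers(2, L - k - 2))
        j = m + k // 2 + 1
        parent_only = background[:m] + motif + background[m + k :]
        ilen = int(
            rng.integers(
                config.insert_length_range[0],
                config.insert_length_range[1] + 1,
            )
        )
        insert_seq = "".join(rng.choice(_AA, size=ilen))
        full = parent_only[:j] + insert_seq + parent_only[j:]

        # parent span around the motif, in parent_only coordinates
        p0 = int(rng.integers(0, m + 1))
        p1 = int(rng.integers(m + k, L + 1))
        parent_sf = f"PAR{rng.choice(config.n_parent_superfamilies, p=parent_probs):03d}"
        insert_sf = f"INS{rng.choice(config.n_insert_superfamilies, p=insert_probs):03d}"

        sequences[acc] = full
        rows.append((acc, parent_sf, p0, j))
        rows.append((acc, parent_sf, j + ilen, p1 + ilen))
        rows.append((acc, insert_sf, j, j + ilen))
        truth_rows.append(
            (
                acc,
                j,
                parent_sf,
                insert_sf,
                ilen,
                len(full),
                m,
            )
        )

    cluster_map = {acc: f"CL{i:05d}" for i, acc in enumerate(sorted(sequences))}
    accs = sorted(sequences)
    for d in range(min(config.n_duplicate_clusters, len(accs) // 2)):
        # merge pairs from the end of the accession list into shared clusters
        a, b = accs[-2 * d - 1], accs[-2 * d - 2]
        cluster_map[a] = cluster_map[b]

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "accession",
            "junction",
            "parent_superfamily",
            "insert_superfamily",
            "insert_length",
            "full_length",
            "motif_start",
        ],
    )
    return SyntheticCorpus(sequences, rows, cluster_map, truth, config)


def generate_screen_table(
    length: int,
    junction: int,
    n_inserts: int = 5,
    noise_rate: float = 0.0,
    seed: int = 0,
    window_radius: int = 1,
) -> pd.DataFrame:
    """Emulate an experimental insertion screen for one protein.

    Every position is assayed with ``n_inserts`` pseudo-insert domains.
    True-tolerant positions (the junction +- ``window_radius``) receive
    positive enrichments for all inserts, everything else negative ones,
    and each position's outcome is flipped with probability ``noise_rate``.
    At zero noise, every downstream label convention recovers the truth
    exactly. Positions are 1-based in the emitted table, matching the
    screen-file dialect.
    """
    if not 0.0 <= noise_rate < 1.0:
        raise FixtureError("noise_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    tolerant = np.zeros(length, dtype=bool)
    for i in range(junction - window_radius, junction + window_radius + 1):
        if 0 <= i < length:
            tolerant[i] = True
    flipped = rng.random(length) < noise_rate
    effective = tolerant ^ flipped
    data = {"position": np.arange(1, length + 1)}
    for ins in range(n_inserts):
        pos_vals = rng.uniform(0.2, 2.0, size=length)
        neg_vals = rng.uniform(-2.0, -0.2, size=length)
        data[f"insert_{ins}"] = np.where(effective, pos_vals, neg_vals)
    return pd.DataFrame(data)
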