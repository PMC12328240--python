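"""Leakage-controlled train/validation/test partitioning.

Three partitioning strategies of increasing stringency are supported, all
targeting a 70:20:10 record-count ratio and all sharing one *common test
set* so models trained under different regimes are compared on identical
held-out data:

``random``
    records shuffled and divided by count — homologous records may land in
    different sets (redundancy is assumed to have been reduced upstream at
    the corpus level via a 50%-identity cluster map);
``combination``
    every (parent, insert) superfamily combination is kept whole within a
    single set, so the model is validated on unseen domain topologies;
``single``
    at most one representative record per combination enters train or
    validation — a maximally diverse, minimally redundant regime.

The common test set is built first by sampling whole combinations, which
guarantees zero combination leakage under every strategy.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .corpus import InsertionRecord

STRATEGIES = ("random", "combination", "single")


class SplitError(ValueError):
    pass


@dataclass(frozen=True)
class SplitAssignment:
    strategy: str
    train: tuple[InsertionRecord, ...]
    validation: tuple[InsertionRecord, ...]
    test: tuple[InsertionRecord, ...]
    seed: int

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise SplitError(f"unknown strategy {self.strategy!r}")
        ids = [r.record_id for part in self.parts.values() for r in part]
        if len(ids) != len(set(ids)):
            raise SplitError("train/validation/test sets are not disjoint")

    @property
    def parts(self) -> dict[str, tuple[InsertionRecord, ...]]:
        return {
            "train": self.train,
            "validation": self.validation,
            "test": self.test,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (r.record_id, part)
            for part, recs in self.parts.items()
            for r in recs
        ]
        return pd.DataFrame(rows, columns=["accession", "set"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _by_combination(
    records: Iterable[InsertionRecord],
) -> dict[tuple[str, str], list[InsertionRecord]]:
    groups: dict[tuple[str, str], list[InsertionRecord]] = defaultdict(list)
    for rec in sorted(records, key=lambda r: r.record_id):
        groups[rec.combination].append(rec)
    return groups


def build_common_test_set(
    records: Sequence[InsertionRecord],
    fraction: float = 0.10,
    seed: int = 0,
) -> list[InsertionRecord]:
    """Sample whole combinations into a shared test set.

    Combinations are drawn in seeded random order until the test set holds
    at least ``fraction`` of all records. Because entire combinations move,
    the realized fraction overshoots by at most the largest combination's
    share. The same test set must be passed to every split strategy.
    """
    groups = _by_combination(records)
    if len(groups) < 3:
        raise SplitError(
            f"need >= 3 (parent, insert) combinations to build three sets; "
            f"got {len(groups)}"
        )
    rng = np.random.default_rng(seed)
    combos = sorted(groups)
    order = rng.permutation(len(combos))
    target = fraction * len(records)
    test: list[InsertionRecord] = []
    for idx in order:
        if len(test) >= target:
            break
        test.extend(groups[combos[idx]])
    test.sort(key=lambda r: r.record_id)
    return test


def _remaining(
    records: Sequence[InsertionRecord],
    test_set: Sequence[InsertionRecord],
) -> list[InsertionRecord]:
    test_ids = {r.record_id for r in test_set}
    missing = test_ids - {r.record_id for r in records}
    if missing:
        raise SplitError(f"test set contains unknown records: {missing}")
    return sorted(
        (r for r in records if r.record_id not in test_ids),
        key=lambda r: r.record_id,
    )


def split_random(
    records: Sequence[InsertionRecord],
    test_set: Sequence[InsertionRecord],
    ratios: tuple[float, float] = (0.70, 0.20),
    seed: int = 0,
) -> SplitAssignment:
    """Shuffle non-test records and divide them by count.

    Train receives ``round(ratios[0] * N)`` records of the original total
    ``N``; validation receives the remainder, so realized sizes track
    70:20:10 up to the test set's combination-granularity overshoot.
    """
    pool = _remaining(records, test_set)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool))
    n_train = min(round(ratios[0] * len(records)), len(pool))
    train_idx = set(order[:n_train].tolist())
    train = [pool[i] for i in sorted(train_idx)]
    validation = [pool[i] for i in range(len(pool)) if i not in train_idx]
    return SplitAssignment(
        "random", tuple(train), tuple(validation), tuple(test_set), seed
    )


def split_by_combination(
    records: Sequence[InsertionRecord],
    test_set: Sequence[InsertionRecord],
    ratios: tuple[float, float] = (0.70, 0.20),
    seed: int = 0,
) -> SplitAssignment:
    """Assign whole combinations to train or validation.

    Greedy largest-first bin packing toward the 70:20 record-count targets:
    combinations are sorted by descending size (ties broken by combination
    key), and each goes to whichever of train/validation has the larger
    remaining deficit. Deterministic — the seed is recorded but unused.
    """
    pool = _remaining(records, test_set)
    groups = _by_combination(pool)
    if len(groups) < 2:
        raise SplitError(
            f"need >= 2 non-test combinations, got {len(groups)}"
        )
    order = sorted(groups, key=lambda c: (-len(groups[c]), c))
    targets = {
        "train": ratios[0] * len(records),
        "validation": ratios[1] * len(records),
    }
    filled = {"train": 0, "validation": 0}
    out: dict[str, list[InsertionRecord]] = {"train": [], "validation": []}
    for combo in order:
        deficit = {k: targets[k] - filled[k] for k in targets}
        dest = max(deficit, key=lambda k: (deficit[k], k == "train"))
        out[dest].extend(groups[combo])
        filled[dest] += len(groups[combo])
    for part in out.values():
        part.sort(key=lambda r: r.record_id)
    return SplitAssignment(
        "combination",
        tuple(out["train"]),
        tuple(out["validation"]),
        tuple(test_set),
        seed,
    )


def split_single_representative(
    records: Sequence[InsertionRecord],
    test_set: Sequence[InsertionRecord],
    train_fraction: float = 0.79,
    seed: int = 0,
) -> SplitAssignment:
    """One seeded-uniform representative per non-test combination.

    The representatives are shuffled and divided between train and
    validation at ``train_fraction`` (default 79:21, the ratio implied by
    reported set sizes of 174 and 46). Each combination contributes at most
    one record across train ∪ validation; the common test set is passed
    through untouched so it stays byte-identical across strategies.
    """
    pool = _remaining(records, test_set)
    groups = _by_combination(pool)
    rng = np.random.default_rng(seed)
    reps = [
        group[rng.integers(len(group))]
        for combo, group in sorted(groups.items())
    ]
    order = rng.permutation(len(reps))
    n_train = round(train_fraction * len(reps))
    train = sorted(
        (reps[i] for i in order[:n_train]), key=lambda r: r.record_id
    )
    validation = sorted(
        (reps[i] for i in order[n_train:]), key=lambda r: r.record_id
    )
    return SplitAssignment(
        "single", tuple(train), tuple(validation), tuple(test_set), seed
    )


def make_all_splits(
    records: Sequence[InsertionRecord],
    seed: int = 0,
    test_fraction: float = 0.10,
) -> dict[str, SplitAssignment]:
    """Build the common test set once and all three strategies on top."""
    test_set = build_common_test_set(records, fraction=test_fraction, seed=seed)
    return {
        "random": split_random(records, test_set, seed=seed),
        "combination": split_by_combination(records, test_set, seed=seed),
        "single": split_single_representative(records, test_set, seed=seed),
    }
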