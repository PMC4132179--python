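"""Replicate-based gold standard and screen precision/recall.

A pair is "called" in a replicate if it scored nonzero there; severity is
ignored.  The gold standard is the set of pairs supported by at least
`min_support` replicates (default 2), and an *independent* screen is then
scored against that standard.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import AbstractSet, Sequence

Pair = tuple[str, str]


@dataclass(frozen=True)
class ScreenReplicateSet:
    replicates: tuple[frozenset[Pair], ...]
    min_support: int = 2

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValueError("empty replicate list")
        if not 1 <= self.min_support <= len(self.replicates):
            raise ValueError(
                f"min_support {self.min_support} outside 1..{len(self.replicates)}"
            )


def build_standard(reps: ScreenReplicateSet) -> frozenset[Pair]:
    """Pairs called in at least `min_support` replicates."""
    if len(reps.replicates) < 2:
        raise ValueError("need at least 2 replicates to build a standard")
    support: Counter[Pair] = Counter()
    for rep in reps.replicates:
        support.update(rep)
    return frozenset(p for p, c in support.items() if c >= reps.min_support)


@dataclass(frozen=True)
class ValidationReport:
    standard: frozenset[Pair]
    called: frozenset[Pair]
    n_called: int
    n_standard: int
    n_overlap: int
    precision: float
    recall: float


def precision_recall(
    called: AbstractSet[Pair], standard: AbstractSet[Pair]
) -> ValidationReport:
    """Score a called set against a gold standard.

    precision = |called & standard| / |called|;
    recall    = |called & standard| / |standard|.
    """
    if not called:
        raise ValueError("precision undefined: empty called set")
    if not standard:
        raise ValueError("recall undefined: empty standard")
    overlap = frozenset(called) & frozenset(standard)
    return ValidationReport(
        standard=frozenset(standard),
        called=frozenset(called),
        n_called=len(called),
        n_standard=len(standard),
        n_overlap=len(overlap),
        precision=len(overlap) / len(called),
        recall=len(overlap) / len(standard),
    )


def read_replicate_edges(path) -> frozenset[Pair]:
    """Read one replicate's called pairs from a tab-delimited edge list."""
    pairs = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: malformed edge line {line!r}")
            pairs.add((fields[0], fields[1]))
    return frozenset(pairs)


def write_replicate_edges(pairs: AbstractSet[Pair], path) -> None:
    with open(path, "w") as fh:
        for allele, gene in sorted(pairs):
            fh.write(f"{allele}\t{gene}\n")


def expected_standard_membership(detection_prob: float, n_replicates: int,
                                 min_support: int = 2) -> float:
    """P(a true pair enters the standard) under independent per-replicate
    detection with probability `detection_prob` — the closed form used to
    bound observed precision in tests."""
    from scipy.stats import binom

    return float(binom.sf(min_support - 1, n_replicates, detection_prob))
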