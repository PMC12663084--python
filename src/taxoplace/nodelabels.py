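"""Propagate tip taxonomy to interior nodes with one-to-many labels.

A node is considered resolvable at a rank when its tip diameter is
within that rank's (multiplier-adjusted) threshold. The node's label
set at the rank is then chosen by a binomial dominance model: assuming
a 5% rate of mis-annotation among reference sequences, a candidate
label with k of n tips is retained when the upper-tail probability
P(X >= k) under Binomial(n, 0.05) is at most 0.20 - i.e. the label is
too frequent to plausibly be annotation error. If several labels pass,
all are retained (a one-to-many label); if none passes, all observed
labels are retained. Once a node's assignment becomes ambiguous at some
rank, finer ranks are labeled hierarchically: the tip labels are
partitioned by each retained coarser label and the dominance model runs
separately within each partition, with results unioned.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field

from scipy.stats import binom

from .taxonomy import EMPTY, N_RANKS, RANKS
from .thresholds import (
    SENSITIVE_MULTIPLIER,
    SPECIFIC_MULTIPLIER,
    ThresholdSet,
)
from .tree import RegionTree

DEFAULT_ERROR_RATE = 0.05
DEFAULT_ERROR_PROB = 0.20


def dominant_labels(
    counts: dict[str, int],
    error_rate: float = DEFAULT_ERROR_RATE,
    error_prob: float = DEFAULT_ERROR_PROB,
    tail_rule: str = "le",
) -> frozenset[str]:
    """Labels whose abundance is too high to be annotation error.

    With n = total tips, a label with count k passes when
    ``P(X >= k | n, error_rate) <= error_prob`` (rule ``"le"``, the
    default reading: the observed count is implausibly large under the
    error model). ``tail_rule="ge"`` selects the opposite reading.
    If no label passes, all labels are returned.
    """
    if not counts:
        raise ValueError("empty count vector")
    n = sum(counts.values())
    if n <= 0:
        raise ValueError("count vector sums to zero")
    if tail_rule not in ("le", "ge"):
        raise ValueError(f"tail_rule must be 'le' or 'ge': {tail_rule!r}")
    passing = set()
    for label, k in counts.items():
        tail = float(binom.sf(k - 1, n, error_rate))  # P(X >= k)
        ok = tail <= error_prob if tail_rule == "le" else tail >= error_prob
        if ok:
            passing.add(label)
    if not passing:
        passing = set(counts)
    return frozenset(passing)


@dataclass
class NodeEntry:
    """Per-rank label sets for one node plus its resolved (finest) rank."""

    labels: tuple[frozenset[str], ...]
    resolved_rank: int | None

    def at(self, r: int) -> frozenset[str]:
        return self.labels[r]


@dataclass
class NodeLabeling:
    entries: dict[str, NodeEntry] = field(default_factory=dict)

    def __getitem__(self, node: str) -> NodeEntry:
        return self.entries[node]

    def __contains__(self, node: str) -> bool:
        return node in self.entries

    def __len__(self):
        return len(self.entries)


def specificity_mode(thresholds: ThresholdSet, mode: str) -> ThresholdSet:
    """Return a ThresholdSet configured for a named mode.

    ``specific`` sets the species multiplier to 0.1 (precision-first,
    the default); ``sensitive`` to 1.0 (uses the optimizer's species
    threshold unchanged). Other ranks are untouched.
    """
    if mode == "specific":
        return thresholds.with_multiplier(SPECIFIC_MULTIPLIER)
    if mode == "sensitive":
        return thresholds.with_multiplier(SENSITIVE_MULTIPLIER)
    raise ValueError(f"unknown mode {mode!r}; expected specific/sensitive")


def _rank_counts(tree: RegionTree, tips, r: int) -> Counter:
    counts: Counter[str] = Counter()
    for tip in tips:
        for label in tree.taxonomy[tip].labels[r]:
            counts[label] += 1
    return counts


def propagate(
    tree: RegionTree,
    thresholds: ThresholdSet,
    error_rate: float = DEFAULT_ERROR_RATE,
    error_prob: float = DEFAULT_ERROR_PROB,
    tail_rule: str = "le",
    hierarchical: str = "partition",
) -> NodeLabeling:
    """Assign per-rank label sets to every node of the tree.

    Ranks are visited coarse to fine; the descent stops at the first
    rank whose effective threshold the node's tip diameter does not
    meet. ``hierarchical="partition"`` (default) applies the dominance
    model within each retained coarser label separately once an
    ambiguous assignment has occurred; ``"pooled"`` always pools tip
    labels at each rank.
    """
    if hierarchical not in ("partition", "pooled"):
        raise ValueError(f"unknown hierarchical mode {hierarchical!r}")
    labeling = NodeLabeling()
    for name, info in tree.nodes.items():
        per_rank: list[frozenset[str]] = [EMPTY] * N_RANKS
        resolved: int | None = None
        prev_labels: frozenset[str] = EMPTY
        prev_rank: int | None = None
        for r in range(N_RANKS):
            if not info.diameter < thresholds.effective(r):
                break
            if (
                hierarchical == "partition"
                and prev_rank is not None
                and len(prev_labels) > 1
            ):
                result: set[str] = set()
                for parent_label in prev_labels:
                    sub = [
                        tip for tip in info.tips
                        if parent_label in tree.taxonomy[tip].labels[prev_rank]
                    ]
                    counts = _rank_counts(tree, sub, r)
                    if counts:
                        result |= dominant_labels(
                            counts, error_rate, error_prob, tail_rule
                        )
                labels = frozenset(result)
            else:
                counts = _rank_counts(tree, info.tips, r)
                labels = (
                    dominant_labels(counts, error_rate, error_prob, tail_rule)
                    if counts else EMPTY
                )
            per_rank[r] = labels
            if labels:
                resolved = r
                prev_labels = labels
                prev_rank = r
        labeling.entries[name] = NodeEntry(
            labels=tuple(per_rank), resolved_rank=resolved
        )
    return labeling


def write_node_table(labeling: NodeLabeling, tree: RegionTree, path) -> None:
    """Node table TSV: node ID, tip diameter, resolved rank, and the
    ';'-joined label set per rank."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["node", "is_tip", "diameter", "resolved_rank", *RANKS])
        for name, entry in labeling.entries.items():
            info = tree.nodes[name]
            w.writerow([
                name,
                int(info.is_tip),
                f"{info.diameter:.6g}",
                RANKS[entry.resolved_rank] if entry.resolved_rank is not None else "",
                *(";".join(sorted(entry.labels[r])) for r in range(N_RANKS)),
            ])
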