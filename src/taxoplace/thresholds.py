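"""Per-rank cophenetic distance thresholds minimizing over-merging plus
over-splitting error across the region tree.

For a candidate threshold *t* the tree is cut into groups: the maximal
clades whose tip diameter (max cophenetic distance among descendant
tips) is strictly less than *t*. Each group is named for its plurality
("majority") taxon at the scored rank. Every additional ground-truth
taxon co-occurring in a group contributes one over-merging error; every
additional group sharing a majority name contributes one over-splitting
error. The summed error, normalized by the number of labeled tips at
the rank, is minimized over a grid of thresholds independently per rank
(ties broken toward the smallest, most conservative threshold).

The species-level threshold is further scaled by a multiplier before
use in node labeling and query assignment: 0.1 in *specific* mode
(precision-oriented) and 1.0 in *sensitive* mode.
"""

from __future__ import annotations

import csv
import json
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np

from .taxonomy import N_RANKS, RANKS, SPECIES, rank_index, render_labels
from .tree import RegionTree

SPECIFIC_MULTIPLIER = 0.1
SENSITIVE_MULTIPLIER = 1.0


@dataclass(frozen=True)
class Group:
    """One threshold-defined group: the tip set of a maximal qualifying node."""

    node: str
    tips: tuple[str, ...]


@dataclass
class GroupPartition:
    threshold: float
    groups: list[Group]

    def __len__(self):
        return len(self.groups)


@dataclass
class ErrorReport:
    threshold: float
    over_merge: int
    over_split: int
    n_labeled_tips: int

    @property
    def total_error(self) -> float:
        """(over-merge + over-split) normalized to [0, 1] by the number
        of labeled tips at the scored rank."""
        if self.n_labeled_tips == 0:
            return 0.0
        return min(1.0, (self.over_merge + self.over_split) / self.n_labeled_tips)


@dataclass
class ThresholdSet:
    """One chosen threshold per rank plus the species multiplier."""

    thresholds: dict[str, float]
    multiplier: float = SPECIFIC_MULTIPLIER
    curves: dict[str, list[ErrorReport]] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.multiplier <= 0:
            raise ValueError("species multiplier must be > 0")

    def threshold(self, rank: int | str) -> float:
        return self.thresholds[RANKS[rank_index(rank)]]

    def effective(self, rank: int | str) -> float:
        """Multiplier-adjusted threshold (adjustment applies to Species only)."""
        r = rank_index(rank)
        t = self.thresholds[RANKS[r]]
        return t * self.multiplier if r == SPECIES else t

    def with_multiplier(self, multiplier: float) -> "ThresholdSet":
        return replace(self, multiplier=multiplier)

    # -- serialization --------------------------------------------------

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"thresholds": self.thresholds, "multiplier": self.multiplier},
                fh, indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "ThresholdSet":
        with open(path) as fh:
            data = json.load(fh)
        return cls(thresholds=data["thresholds"],
                   multiplier=data.get("multiplier", SPECIFIC_MULTIPLIER))


def cophenetic_distance(tree: RegionTree, tip_a: str, tip_b: str) -> float:
    """Sum of branch lengths on the path between two tips."""
    return tree.cophenetic(tip_a, tip_b)


def cut_tree(tree: RegionTree, t: float) -> GroupPartition:
    """Cut the tree into the maximal clades with tip diameter < t.

    A single preorder traversal stops descending as soon as a node
    qualifies. Tips that qualify only as singletons (inequality is
    strict, so t = 0 admits no node) form singleton groups, so the
    partition always covers all tips.
    """
    if t < 0:
        raise ValueError("threshold must be >= 0")
    groups: list[Group] = []
    stack = [tree.root_name]
    while stack:
        name = stack.pop()
        info = tree.nodes[name]
        if info.is_tip or info.diameter < t:
            groups.append(Group(node=name, tips=info.tips))
        else:
            stack.extend(
                c.name for c in reversed(tree._skbio[name].children)
            )
    return GroupPartition(threshold=t, groups=groups)


def _tip_label(tree: RegionTree, tip: str, r: int) -> str | None:
    """Canonical label string of a tip at rank r, or None if unlabeled."""
    labels = tree.taxonomy[tip].labels[r]
    if not labels:
        return None
    return render_labels(labels)


def score_threshold(
    tree: RegionTree, partition: GroupPartition, rank: int | str
) -> ErrorReport:
    """Count over-merging and over-splitting errors of a partition.

    Tips unlabeled at the scored rank are excluded from both error
    terms; groups with no labeled tips contribute nothing.
    """
    r = rank_index(rank)
    over_merge = 0
    majorities: Counter[str] = Counter()
    n_labeled = 0
    for group in partition.groups:
        counts: Counter[str] = Counter()
        for tip in group.tips:
            label = _tip_label(tree, tip, r)
            if label is not None:
                counts[label] += 1
        if not counts:
            continue
        n_labeled += sum(counts.values())
        over_merge += len(counts) - 1
        # plurality majority, lexicographic tie-break for determinism
        top = max(counts.values())
        majority = min(l for l, c in counts.items() if c == top)
        majorities[majority] += 1
    over_split = sum(c - 1 for c in majorities.values())
    return ErrorReport(
        threshold=partition.threshold,
        over_merge=over_merge,
        over_split=over_split,
        n_labeled_tips=n_labeled,
    )


def default_grid(diameter: float, n_points: int = 200) -> np.ndarray:
    """Hybrid geometric + linear threshold grid on (0, diameter], plus one
    point just above the diameter so the single-group partition is reachable
    under the strict inequality."""
    if diameter <= 0:
        return np.array([0.0, 1e-9])
    half = max(2, n_points // 2)
    geo = np.geomspace(diameter * 1e-4, diameter, half)
    lin = np.linspace(diameter / half, diameter, half)
    grid = np.unique(np.concatenate([geo, lin, [diameter * (1 + 1e-9)]]))
    return grid


def find_thresholds(
    tree: RegionTree,
    ranks=None,
    grid=None,
    n_points: int = 200,
    multiplier: float = SPECIFIC_MULTIPLIER,
) -> ThresholdSet:
    """Grid-search the error-minimizing threshold independently per rank.

    Ties go to the smallest threshold. The full error curve per rank is
    retained for diagnostics.
    """
    if ranks is None:
        ranks = list(range(N_RANKS))
    ranks = [rank_index(r) for r in ranks]
    if grid is None:
        grid = default_grid(tree.diameter, n_points)
    grid = np.asarray(sorted(set(float(g) for g in grid)))
    if grid.size == 0:
        raise ValueError("empty threshold grid")

    partitions = [cut_tree(tree, float(t)) for t in grid]
    thresholds: dict[str, float] = {}
    curves: dict[str, list[ErrorReport]] = {}
    for r in ranks:
        reports = [score_threshold(tree, p, r) for p in partitions]
        errors = [rep.total_error for rep in reports]
        best = int(np.argmin(errors))  # argmin returns first = smallest t
        thresholds[RANKS[r]] = float(grid[best])
        curves[RANKS[r]] = reports
    return ThresholdSet(thresholds=thresholds, multiplier=multiplier,
                        curves=curves)


def write_threshold_report(ts: ThresholdSet, path, curves_path=None) -> None:
    """TSV of chosen thresholds (+ errors at the chosen point) and,
    optionally, the full error curve per rank."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["rank", "threshold", "over_merge", "over_split",
                    "total_error"])
        for rank, t in ts.thresholds.items():
            rep = None
            for cand in ts.curves.get(rank, []):
                if cand.threshold == t:
                    rep = cand
                    break
            if rep is None:
                w.writerow([rank, f"{t:.6g}", "", "", ""])
            else:
                w.writerow([rank, f"{t:.6g}", rep.over_merge, rep.over_split,
                            f"{rep.total_error:.6g}"])
    if curves_path is not None:
        with open(curves_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["rank", "threshold", "over_merge", "over_split",
                        "total_error"])
            for rank, reports in ts.curves.items():
                for rep in reports:
                    w.writerow([rank, f"{rep.threshold:.6g}", rep.over_merge,
                                rep.over_split, f"{rep.total_error:.6g}"])
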