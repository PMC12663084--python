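"""Ambiguity-aware benchmarking: outcome judging, metrics, holdout
construction, and the species-multiplier precision-recall sweep.

The accounting treats a one-to-many assignment as correct when at
least one member matches the truth, and a non-assignment as correct
(a true positive) when the truth taxon is absent from the reference
database. The latter convention is deliberate and non-standard; a
switch reverts to the textbook definition in which correct
non-assignments are true negatives excluded from precision/recall.
"""

from __future__ import annotations

import csv
import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .classify import AssignmentRecord
from .nodelabels import propagate
from .taxonomy import N_RANKS, RANKS, SPECIES, TaxonomyTable, rank_index
from .thresholds import ThresholdSet
from .tree import RegionTree

log = logging.getLogger(__name__)

CORRECT_ASSIGNED = "correct-assigned"
INCORRECT_ASSIGNED = "incorrect-assigned"
CORRECT_UNASSIGNED = "correct-unassigned"
INCORRECT_UNASSIGNED = "incorrect-unassigned"

#: Default species threshold multipliers for the precision-recall sweep.
DEFAULT_MULTIPLIERS = tuple(np.round(np.arange(0.0, 2.0, 0.05), 10))


def judge(
    truth: str | frozenset[str] | set[str],
    predicted: frozenset[str] | set[str],
    truth_in_db: bool,
) -> str:
    """Classify one (truth, prediction) pair at a fixed rank.

    A non-empty prediction containing (any member of) the truth is
    correct; an empty prediction is correct exactly when the truth is
    absent from the database.
    """
    truth_set = {truth} if isinstance(truth, str) else set(truth)
    if predicted:
        return (CORRECT_ASSIGNED if truth_set & set(predicted)
                else INCORRECT_ASSIGNED)
    return INCORRECT_UNASSIGNED if truth_in_db else CORRECT_UNASSIGNED


@dataclass
class MetricRow:
    rank: str
    n: int
    accuracy: float | None
    precision: float | None
    recall: float | None
    f1: float | None
    n_ambiguous: int = 0
    mean_labels_per_ambiguous: float | None = None
    counts: dict = field(default_factory=dict)


def compute_metrics(outcomes: list[str], rank: str = "",
                    unassigned_as_tp: bool = True) -> MetricRow:
    """Accuracy / precision / recall / F1 from outcome classes.

    With the default convention, TP = correct-assigned +
    correct-unassigned; with ``unassigned_as_tp=False`` correct
    non-assignments are true negatives excluded from precision and
    recall. Undefined metrics (zero denominators) are reported as None.
    """
    if not outcomes:
        raise ValueError("no outcomes to score")
    c = Counter(outcomes)
    tp = c[CORRECT_ASSIGNED] + (c[CORRECT_UNASSIGNED] if unassigned_as_tp else 0)
    fp = c[INCORRECT_ASSIGNED]
    fn = c[INCORRECT_UNASSIGNED]
    total = sum(c.values())
    accuracy = (c[CORRECT_ASSIGNED] + c[CORRECT_UNASSIGNED]) / total
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    if precision is None or recall is None or (precision + recall) == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricRow(rank=rank, n=total, accuracy=accuracy,
                     precision=precision, recall=recall, f1=f1,
                     counts=dict(c))


def evaluate_assignments(
    records: list[AssignmentRecord],
    truth: TaxonomyTable,
    db_taxonomy: TaxonomyTable,
    ranks=None,
    unassigned_as_tp: bool = True,
    dropped: dict[str, str] | None = None,
) -> list[MetricRow]:
    """Score assignments against a truth table, per rank.

    Queries dropped by the pipeline count as non-assignments. Queries
    whose truth is unlabeled at a rank are skipped at that rank.
    """
    if ranks is None:
        ranks = list(range(N_RANKS))
    ranks = [rank_index(r) for r in ranks]
    db_labels = {r: db_taxonomy.labels_at(r) for r in ranks}
    by_query = {rec.query_id: rec for rec in records}
    all_ids = list(by_query) + list(dropped or {})
    rows = []
    for r in ranks:
        outcomes = []
        n_ambig = 0
        ambig_sizes = []
        for query_id in all_ids:
            if query_id not in truth:
                continue
            truth_set = truth[query_id].labels[r]
            if not truth_set:
                continue
            rec = by_query.get(query_id)
            predicted = rec.labels[r] if rec is not None else frozenset()
            in_db = bool(truth_set & db_labels[r])
            outcomes.append(judge(truth_set, predicted, in_db))
            if len(predicted) > 1:
                n_ambig += 1
                ambig_sizes.append(len(predicted))
        if not outcomes:
            continue
        row = compute_metrics(outcomes, RANKS[r], unassigned_as_tp)
        row.n_ambiguous = n_ambig
        row.mean_labels_per_ambiguous = (
            float(np.mean(ambig_sizes)) if ambig_sizes else None
        )
        rows.append(row)
    return rows


def write_metrics_tsv(rows: list[MetricRow], path) -> None:
    def fmt(x):
        return "" if x is None else f"{x:.4f}"

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["rank", "n", "accuracy", "precision", "recall", "f1",
                    "n_ambiguous", "mean_labels_per_ambiguous"])
        for row in rows:
            w.writerow([row.rank, row.n, fmt(row.accuracy), fmt(row.precision),
                        fmt(row.recall), fmt(row.f1), row.n_ambiguous,
                        fmt(row.mean_labels_per_ambiguous)])


# ----------------------------------------------------------------------
# holdout construction
# ----------------------------------------------------------------------

class HoldoutError(ValueError):
    pass


@dataclass
class HoldoutSplit:
    query_ids: list[str]
    reference_ids: list[str]
    truth: TaxonomyTable


def _genus_groups(taxonomy: TaxonomyTable, ids) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    for seq_id in ids:
        for genus in taxonomy[seq_id].at("Genus"):
            groups.setdefault(genus, []).append(seq_id)
    return groups


def build_holdout(
    ids: list[str],
    taxonomy: TaxonomyTable,
    scheme: str,
    seed: int = 0,
    rate: float = 0.01,
    min_per_genus: int = 5,
    n: int | None = None,
    n_genera: int | None = None,
) -> HoldoutSplit:
    """Split sequence IDs into held-out queries and remaining references.

    Schemes:
      * ``per-genus-rate``: sample each genus at `rate` (default 1%) or
        at least `min_per_genus` sequences (all available if fewer).
      * ``random-n``: `n` sequences uniformly at random.
      * ``single-rep-genus``: one random sequence per genus.
      * ``genus-outside-db``: all sequences of `n_genera` random genera,
        so correct behaviour is non-assignment at genus and species.
    """
    rng = np.random.default_rng(seed)
    ids = list(ids)
    queries: list[str] = []
    if scheme == "per-genus-rate":
        for genus, members in sorted(_genus_groups(taxonomy, ids).items()):
            take = min(len(members),
                       max(math.ceil(rate * len(members)), min_per_genus))
            queries.extend(
                rng.choice(sorted(members), size=take, replace=False)
            )
    elif scheme == "random-n":
        if n is None or n <= 0 or n > len(ids):
            raise HoldoutError(f"random-n needs 0 < n <= {len(ids)}")
        queries = list(rng.choice(sorted(ids), size=n, replace=False))
    elif scheme == "single-rep-genus":
        for genus, members in sorted(_genus_groups(taxonomy, ids).items()):
            queries.append(str(rng.choice(sorted(members))))
    elif scheme == "genus-outside-db":
        groups = sorted(_genus_groups(taxonomy, ids))
        if n_genera is None or n_genera <= 0 or n_genera >= len(groups):
            raise HoldoutError(
                f"genus-outside-db needs 0 < n_genera < {len(groups)}"
            )
        chosen = set(rng.choice(groups, size=n_genera, replace=False))
        genus_map = _genus_groups(taxonomy, ids)
        for genus in sorted(chosen):
            queries.extend(genus_map[genus])
    else:
        raise HoldoutError(f"unknown holdout scheme {scheme!r}")
    queries = sorted(set(str(q) for q in queries))
    if not queries or len(queries) == len(ids):
        raise HoldoutError("holdout scheme produced an infeasible split")
    reference = [i for i in ids if i not in set(queries)]
    return HoldoutSplit(
        query_ids=queries,
        reference_ids=reference,
        truth=taxonomy.subset(queries),
    )


def write_truth_tsv(truth: TaxonomyTable, path, rank=SPECIES) -> None:
    from .taxonomy import render_labels
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for seq_id, lin in truth.items():
            w.writerow([seq_id, render_labels(lin, rank)])


# ----------------------------------------------------------------------
# precision-recall sweep over the species multiplier
# ----------------------------------------------------------------------

@dataclass
class PRPoint:
    multiplier: float
    precision: float | None
    recall: float | None
    f1: float | None
    n_assigned: int


def pr_sweep(
    queries: dict[str, str],
    reference,
    rtree: RegionTree,
    thresholds: ThresholdSet,
    truth: TaxonomyTable,
    db_taxonomy: TaxonomyTable,
    multipliers=DEFAULT_MULTIPLIERS,
    unassigned_as_tp: bool = True,
    **classify_kwargs,
) -> list[PRPoint]:
    """Species-level precision-recall curve over threshold multipliers.

    Placements are computed once (they do not depend on the species
    multiplier); only node labeling and assignment are re-run per
    multiplier. A multiplier of zero forces an empty effective species
    threshold, hence no species assignments.
    """
    from .classify import (
        ReferenceIndex, align_query, filter_placements, place_query,
        qc_coverage, assign_from_placement, combine_placements,
    )

    index = ReferenceIndex(reference)
    cached: dict[str, list] = {}
    for query_id, seq in queries.items():
        qa = align_query(query_id, seq, index)
        if not qc_coverage(qa):
            continue
        pls = filter_placements(place_query(qa, rtree, index))
        if pls:
            cached[query_id] = pls

    points: list[PRPoint] = []
    for m in multipliers:
        m = float(m)
        if m <= 0:
            # degenerate multiplier: the strict inequality makes the
            # species rank unreachable, so every query is unassigned
            outcomes = []
            db_species = db_taxonomy.labels_at(SPECIES)
            for qid in cached:
                if qid not in truth or not truth[qid].labels[SPECIES]:
                    continue
                in_db = bool(truth[qid].labels[SPECIES] & db_species)
                outcomes.append(judge(truth[qid].labels[SPECIES],
                                      frozenset(), in_db))
            if outcomes:
                row = compute_metrics(outcomes, "Species", unassigned_as_tp)
                points.append(PRPoint(m, row.precision, row.recall, row.f1, 0))
            else:
                points.append(PRPoint(m, None, None, None, 0))
            continue
        ts = thresholds.with_multiplier(m)
        labeling = propagate(rtree, ts)
        records = []
        for qid, pls in cached.items():
            per = [assign_from_placement(p, labeling, ts, rtree) for p in pls]
            records.append(combine_placements(qid, per, pls))
        rows = evaluate_assignments(records, truth, db_taxonomy,
                                    ranks=[SPECIES],
                                    unassigned_as_tp=unassigned_as_tp)
        n_assigned = sum(1 for rec in records if rec.labels[SPECIES])
        if rows:
            row = rows[0]
            points.append(PRPoint(m, row.precision, row.recall, row.f1,
                                  n_assigned))
        else:
            points.append(PRPoint(m, None, None, None, n_assigned))
    return points


def write_pr_tsv(points: list[PRPoint], path) -> None:
    def fmt(x):
        return "" if x is None else f"{x:.4f}"

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["multiplier", "precision", "recall", "f1", "n_assigned"])
        for p in points:
            w.writerow([f"{p.multiplier:g}", fmt(p.precision), fmt(p.recall),
                        fmt(p.f1), p.n_assigned])
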