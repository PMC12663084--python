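"""Align queries to the trimmed reference alignment, place them in the
region tree, and emit (possibly multi-label) taxonomic assignments.

Alignment follows the template-based scheme used by mothur's aligner: a
k-mer search selects the best reference template, the query is globally
aligned to the degapped template (Needleman-Wunsch with free end gaps),
and the pairwise alignment is projected into the fixed reference
coordinate frame NAST-style - query insertions relative to the template
are shifted into adjacent template gap columns, or trimmed (and
counted) when no gap column is available, so the alignment width never
changes. Queries covering < 80% of their template are dropped.

Placement accepts standard jplace JSON (the fidelity route, e.g. from
pplacer or EPA-ng) or computes a lightweight internal placement that
attaches the query above each of the top-K most k-mer-similar reference
tips, scoring candidate edges by corrected alignment distance and
normalizing the scores into a likelihood-weight-ratio analogue.

Assignment: the "index node" is the child node of the placement edge.
A query's distance to a tip is pendant length + distal offset + the
tree path from the index node, and the proposed level is the finest
rank at which the query is within the rank's effective threshold of
all tips under the index node (walking toward the root if the index
node itself does not qualify). Placements within 50% of the best
likelihood weight ratio are combined: the modal proposed level wins
(ties to the coarser level) and label sets are unioned per rank.
"""

from __future__ import annotations

import json
import logging
import re
from collections import Counter
from dataclasses import dataclass, field

from Bio import Align, SeqIO
from skbio import TreeNode

from .nodelabels import NodeLabeling
from .refprep import (
    RegionSlice,
    _degap_with_map,
    jukes_cantor,
    normalize_sequence,
    reverse_complement,
)
from .taxonomy import EMPTY, N_RANKS, RANKS, render_labels
from .thresholds import ThresholdSet
from .tree import RegionTree

log = logging.getLogger(__name__)

DEFAULT_KMER = 8
DEFAULT_TOP_K = 5
DEFAULT_MIN_COVERAGE = 0.80
LWR_FRACTION = 0.5


class PlacementError(ValueError):
    pass


# ----------------------------------------------------------------------
# query alignment
# ----------------------------------------------------------------------

def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def _make_aligner(match=2.0, mismatch=-3.0, gap_open=-5.0, gap_extend=-2.0):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    # free end gaps: overlap-style alignment so truncated queries are
    # not penalised into the template interior
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


class ReferenceIndex:
    """k-mer index over the degapped sequences of a region slice."""

    def __init__(self, sl: RegionSlice, k: int = DEFAULT_KMER):
        self.slice = sl
        self.k = k
        self.degapped: dict[str, str] = {}
        self.colmaps: dict[str, list[int]] = {}
        self.kmer_sets: dict[str, set[str]] = {}
        for seq_id, seq in sl.seqs.items():
            text, colmap = _degap_with_map(seq)
            self.degapped[seq_id] = text
            self.colmaps[seq_id] = colmap
            self.kmer_sets[seq_id] = _kmers(text, k)

    def shared_kmers(self, seq: str) -> dict[str, int]:
        q = _kmers(seq, self.k)
        return {i: len(q & s) for i, s in self.kmer_sets.items()}

    def best_templates(self, seq: str, n: int = 1) -> list[str]:
        scores = self.shared_kmers(seq)
        return sorted(scores, key=lambda i: (-scores[i], i))[:n]


@dataclass
class QueryAlignment:
    query_id: str
    template_id: str
    gapped: str        # query in reference alignment coordinates
    coverage: float    # aligned span / template ungapped span
    strand: str = "+"
    trimmed_bases: int = 0


def align_query(
    query_id: str,
    seq: str,
    reference: RegionSlice | ReferenceIndex,
    k: int = DEFAULT_KMER,
    aligner: Align.PairwiseAligner | None = None,
    auto_flip: bool = True,
) -> QueryAlignment:
    """Align one query into the reference alignment coordinate frame."""
    index = (reference if isinstance(reference, ReferenceIndex)
             else ReferenceIndex(reference, k))
    qseq = normalize_sequence(seq).replace("-", "")
    if not qseq:
        raise ValueError(f"empty query sequence {query_id!r}")
    strand = "+"
    if auto_flip:
        fwd = max(index.shared_kmers(qseq).values(), default=0)
        rc = reverse_complement(qseq)
        rev = max(index.shared_kmers(rc).values(), default=0)
        if rev > fwd:
            qseq, strand = rc, "-"
    template_id = index.best_templates(qseq, 1)[0]
    tseq = index.degapped[template_id]
    colmap = index.colmaps[template_id]

    if aligner is None:
        aligner = _make_aligner()
    aln = aligner.align(tseq, qseq)[0]
    t_blocks, q_blocks = aln.aligned

    width = index.slice.width
    out = ["-"] * width
    trimmed = int(q_blocks[0][0]) if len(q_blocks) else len(qseq)
    prev_t_end = prev_q_end = None
    for (t0, t1), (q0, q1) in zip(t_blocks, q_blocks):
        t0, t1, q0, q1 = int(t0), int(t1), int(q0), int(q1)
        if prev_t_end is not None and q0 > prev_q_end:
            # insertion relative to the template: shift into free columns
            # (template gap columns / skipped template columns) between
            # the flanking matched positions, NAST-style. The pairwise
            # aligner reports the leftmost of equivalent indel placements,
            # so when no column is free the insertion is rotated rightward
            # through equal bases until one is.
            while (
                colmap[t0] - colmap[prev_t_end - 1] <= 1
                and t0 < t1 - 1
                and qseq[prev_q_end] == tseq[t0]
            ):
                out[colmap[t0]] = qseq[prev_q_end]
                prev_q_end += 1
                prev_t_end = t0 + 1
                t0 += 1
                q0 += 1
            left_col = colmap[prev_t_end - 1]
            right_col = colmap[t0]
            slots = list(range(left_col + 1, right_col))
            ins = qseq[prev_q_end:q0]
            for c, base in zip(slots, ins):
                out[c] = base
            trimmed += max(0, len(ins) - len(slots))
        for t, q in zip(range(t0, t1), range(q0, q1)):
            out[colmap[t]] = qseq[q]
        prev_t_end, prev_q_end = t1, q1
    if prev_q_end is not None:
        trimmed += len(qseq) - prev_q_end
    if len(t_blocks):
        span = int(t_blocks[-1][1]) - int(t_blocks[0][0])
    else:
        span = 0
    coverage = span / len(tseq) if tseq else 0.0
    return QueryAlignment(
        query_id=query_id,
        template_id=template_id,
        gapped="".join(out),
        coverage=coverage,
        strand=strand,
        trimmed_bases=trimmed,
    )


def qc_coverage(qa: QueryAlignment, min_cov: float = DEFAULT_MIN_COVERAGE) -> bool:
    """Keep a query iff its template coverage is >= min_cov (inclusive)."""
    return qa.coverage >= min_cov


# ----------------------------------------------------------------------
# placements
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class Placement:
    """One placement of a query: the child node of the placement edge,
    its likelihood weight ratio, and pendant/distal branch lengths.
    The distal offset is measured from the child node toward the parent."""

    edge: str
    lwr: float
    pendant: float = 0.0
    distal: float = 0.0
    likelihood: float = 0.0


_EDGE_NUM_RE = re.compile(r"\{(\d+)\}")
# move a jplace edge number "{n}" into the node label so a standard
# newick parser can carry it through: "A:0.1{0}" -> "A@@0:0.1"
_EDGE_REWRITE_RE = re.compile(
    r"([^(),:{}\s]*)((?::[^(),{}]*)?)\{(\d+)\}"
)


@dataclass
class JplaceDocument:
    version: int
    fields: list[str]
    tree: TreeNode                      # parsed reference tree
    edge_nodes: dict[int, TreeNode]     # edge number -> child node
    placements: dict[str, list[dict]]   # query -> raw field dicts

    def map_placements(self, rtree: RegionTree) -> dict[str, list[Placement]]:
        """Resolve edge numbers to node names of `rtree` by matching
        descendant tip sets, and build Placement lists sorted by LWR."""
        by_tipset = {
            frozenset(info.tips): name for name, info in rtree.nodes.items()
        }
        edge_to_name: dict[int, str] = {}
        for num, node in self.edge_nodes.items():
            if node.is_tip():
                tips = frozenset([node.name])
            else:
                tips = frozenset(t.name for t in node.tips())
            name = by_tipset.get(tips)
            if name is None:
                raise PlacementError(
                    f"jplace edge {num} does not correspond to any node of "
                    f"the region tree"
                )
            edge_to_name[num] = name
        out: dict[str, list[Placement]] = {}
        for query, rows in self.placements.items():
            pls = []
            for row in rows:
                num = int(row["edge_num"])
                if num not in edge_to_name:
                    raise PlacementError(f"unknown edge number {num} in jplace")
                pls.append(Placement(
                    edge=edge_to_name[num],
                    lwr=float(row.get("like_weight_ratio", 0.0)),
                    pendant=float(row.get("pendant_length", 0.0)),
                    distal=float(row.get("distal_length", 0.0)),
                    likelihood=float(row.get("likelihood", 0.0)),
                ))
            out[query] = sorted(pls, key=lambda p: -p.lwr)
        return out


def read_jplace(source) -> JplaceDocument:
    """Parse a jplace (version 3 dialect) JSON document."""
    if hasattr(source, "read"):
        data = json.load(source)
    elif isinstance(source, str) and source.lstrip().startswith("{"):
        data = json.loads(source)
    else:
        with open(source) as fh:
            data = json.load(fh)
    for key in ("tree", "placements", "fields"):
        if key not in data:
            raise PlacementError(f"jplace missing required key {key!r}")
    fields = list(data["fields"])
    if "edge_num" not in fields:
        raise PlacementError("jplace fields must include edge_num")

    newick = _EDGE_REWRITE_RE.sub(r"\1@@\3\2", data["tree"])
    if _EDGE_NUM_RE.search(newick):
        raise PlacementError("could not rewrite all jplace edge numbers")
    import io as _io
    tree = TreeNode.read(_io.StringIO(newick), format="newick",
                         convert_underscores=False)
    edge_nodes: dict[int, TreeNode] = {}
    for node in tree.traverse():
        if node.name and "@@" in node.name:
            base, num = node.name.rsplit("@@", 1)
            node.name = base or None
            edge_nodes[int(num)] = node

    placements: dict[str, list[dict]] = {}
    for entry in data["placements"]:
        names = entry.get("n") or [nm[0] for nm in entry.get("nm", [])]
        rows = [dict(zip(fields, p)) for p in entry["p"]]
        for name in names:
            placements[name] = rows
    return JplaceDocument(
        version=int(data.get("version", 3)),
        fields=fields,
        tree=tree,
        edge_nodes=edge_nodes,
        placements=placements,
    )


def _newick_with_edge_numbers(rtree: RegionTree) -> tuple[str, dict[str, int]]:
    numbers: dict[str, int] = {}
    counter = [0]

    def serialize(node) -> str:
        if node.is_tip():
            body = node.name
        else:
            body = "(" + ",".join(serialize(c) for c in node.children) + ")"
            if node.parent is not None:
                body += node.name or ""
        if node.parent is None:
            return body + ";"
        numbers[node.name] = counter[0]
        tag = f"{{{counter[0]}}}"
        counter[0] += 1
        return f"{body}:{node.length or 0.0:g}{tag}"

    return serialize(rtree.tree), numbers


def write_jplace(
    rtree: RegionTree,
    placements: dict[str, list[Placement]],
    path=None,
) -> str:
    """Serialize placements against the region tree as jplace v3 JSON."""
    newick, numbers = _newick_with_edge_numbers(rtree)
    fields = ["edge_num", "likelihood", "like_weight_ratio",
              "distal_length", "pendant_length"]
    entries = []
    for query, pls in placements.items():
        entries.append({
            "p": [
                [numbers[p.edge], p.likelihood, p.lwr, p.distal, p.pendant]
                for p in pls
            ],
            "n": [query],
        })
    doc = {
        "version": 3,
        "tree": newick,
        "fields": fields,
        "placements": entries,
        "metadata": {"invocation": "taxoplace"},
    }
    text = json.dumps(doc, indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def place_query(
    qa: QueryAlignment,
    rtree: RegionTree,
    reference: RegionSlice | ReferenceIndex,
    top_k: int = DEFAULT_TOP_K,
) -> list[Placement]:
    """Internal distance-based placement (pplacer stand-in).

    Candidate edges are the pendant edges of the top-K reference tips
    by k-mer similarity; each is scored by the corrected pairwise
    distance between the query and the tip over shared non-gap columns,
    and scores are converted to normalized weights. An exact match
    collapses to (one or more) zero-pendant placements.
    """
    index = (reference if isinstance(reference, ReferenceIndex)
             else ReferenceIndex(reference))
    qseq = qa.gapped.replace("-", "")
    tip_set = set(rtree.tip_names)
    scores = {
        i: s for i, s in index.shared_kmers(qseq).items() if i in tip_set
    }
    candidates = sorted(scores, key=lambda i: (-scores[i], i))[:top_k]
    if not candidates:
        return []

    import math
    dists: dict[str, tuple[float, int]] = {}
    for tip in candidates:
        ref = index.slice.seqs[tip]
        n = diff = 0
        for qb, rb in zip(qa.gapped, ref):
            if qb != "-" and rb != "-":
                n += 1
                if qb != rb:
                    diff += 1
        d = jukes_cantor(diff / n) if n else float("inf")
        dists[tip] = (d, n)
    d_min = min(d for d, _ in dists.values())
    if d_min == 0.0:
        exact = sorted(t for t, (d, _) in dists.items() if d == 0.0)
        lwr = 1.0 / len(exact)
        return [Placement(edge=t, lwr=lwr, pendant=0.0, distal=0.0)
                for t in exact]
    weights = {
        tip: math.exp(-(d - d_min) * n) for tip, (d, n) in dists.items()
    }
    total = sum(weights.values())
    placements = [
        Placement(edge=tip, lwr=weights[tip] / total,
                  pendant=dists[tip][0], distal=0.0)
        for tip in candidates
    ]
    return sorted(placements, key=lambda p: (-p.lwr, p.edge))


def filter_placements(placements: list[Placement]) -> list[Placement]:
    """Keep placements with LWR within 50% of the greatest value
    (boundary inclusive)."""
    if not placements:
        return []
    best = max(p.lwr for p in placements)
    return [p for p in placements if p.lwr >= LWR_FRACTION * best]


# ----------------------------------------------------------------------
# assignment
# ----------------------------------------------------------------------

def _query_tip_distance(
    rtree: RegionTree,
    placement: Placement,
    tip: str,
    include_distal: bool = True,
) -> float:
    """Distance from the query's attachment point to a tip.

    The attachment sits on the edge above the placement's child node C,
    at `distal` from C; the distance is pendant + distal-adjusted path
    through the tree.
    """
    child = placement.edge
    info = rtree.node(child)
    distal = min(placement.distal, info.length) if include_distal else 0.0
    lca = rtree.lca(child, tip)
    if lca == child:
        path = distal + rtree.node(tip).depth - info.depth
    else:
        path = (info.depth - distal) + rtree.node(tip).depth \
            - 2.0 * rtree.node(lca).depth
    return placement.pendant + path


def assign_from_placement(
    placement: Placement,
    labeling: NodeLabeling,
    thresholds: ThresholdSet,
    rtree: RegionTree,
    include_distal: bool = True,
) -> tuple[tuple[frozenset[str], ...], int | None, str | None]:
    """Assign per-rank labels from one placement.

    Returns (labels per rank, proposed level, index node). Starting at
    the index node (child of the placement edge), the proposed level is
    the finest rank whose effective threshold exceeds the query's
    distance to every tip under the node, clamped to the node's
    resolved rank; if no rank qualifies the walk continues toward the
    root, and an exhausted walk returns an unassigned result.
    """
    node: str | None = placement.edge
    while node is not None:
        info = rtree.node(node)
        maxdist = max(
            _query_tip_distance(rtree, placement, tip, include_distal)
            for tip in info.tips
        )
        level: int | None = None
        for r in range(N_RANKS):
            if maxdist < thresholds.effective(r):
                level = r
            else:
                break
        entry = labeling[node] if node in labeling else None
        if level is not None and entry is not None \
                and entry.resolved_rank is not None:
            level = min(level, entry.resolved_rank)
            labels = tuple(
                entry.labels[r] if r <= level else EMPTY
                for r in range(N_RANKS)
            )
            return labels, level, node
        node = info.parent
    return tuple([EMPTY] * N_RANKS), None, None


@dataclass
class AssignmentRecord:
    query_id: str
    labels: tuple[frozenset[str], ...]
    resolved_rank: int | None
    n_placements: int = 0
    max_lwr: float = 0.0
    provenance: dict = field(default_factory=dict)

    @property
    def assigned(self) -> bool:
        return self.resolved_rank is not None


def combine_placements(
    query_id: str,
    per_placement: list[tuple[tuple[frozenset[str], ...], int | None, str | None]],
    placements: list[Placement] | None = None,
) -> AssignmentRecord:
    """Combine per-placement assignments: the modal proposed level wins
    (ties to the coarser level) and label sets are unioned per rank down
    to that level; finer ranks are emptied."""
    levels = [lvl for _, lvl, _ in per_placement if lvl is not None]
    placements = placements or []
    prov = {
        "index_nodes": [n for _, _, n in per_placement],
        "proposed_levels": [
            RANKS[lvl] if lvl is not None else None
            for _, lvl, _ in per_placement
        ],
        "placements": [
            {"edge": p.edge, "lwr": round(p.lwr, 6),
             "pendant": round(p.pendant, 6), "distal": round(p.distal, 6)}
            for p in placements
        ],
    }
    if not levels:
        return AssignmentRecord(
            query_id=query_id,
            labels=tuple([EMPTY] * N_RANKS),
            resolved_rank=None,
            n_placements=len(placements),
            max_lwr=max((p.lwr for p in placements), default=0.0),
            provenance=prov,
        )
    counts = Counter(levels)
    top = max(counts.values())
    mode_level = min(l for l, c in counts.items() if c == top)  # coarser wins
    union: list[frozenset[str]] = []
    for r in range(N_RANKS):
        if r > mode_level:
            union.append(EMPTY)
            continue
        merged: set[str] = set()
        for labels, lvl, _ in per_placement:
            if lvl is not None:
                merged |= labels[r]
        union.append(frozenset(merged))
    return AssignmentRecord(
        query_id=query_id,
        labels=tuple(union),
        resolved_rank=mode_level,
        n_placements=len(placements),
        max_lwr=max((p.lwr for p in placements), default=0.0),
        provenance=prov,
    )


# ----------------------------------------------------------------------
# pipeline
# ----------------------------------------------------------------------

def read_query_fasta(path) -> dict[str, str]:
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq)
    return out


def classify_queries(
    queries: dict[str, str],
    reference: RegionSlice,
    rtree: RegionTree,
    labeling: NodeLabeling,
    thresholds: ThresholdSet,
    jplace_placements: dict[str, list[Placement]] | None = None,
    min_cov: float = DEFAULT_MIN_COVERAGE,
    k: int = DEFAULT_KMER,
    top_k: int = DEFAULT_TOP_K,
    include_distal: bool = True,
) -> tuple[list[AssignmentRecord], dict[str, str]]:
    """Full classification pipeline for a set of query sequences.

    Returns (assignment records, dropped queries with reasons). When
    `jplace_placements` is given (parsed and mapped from an external
    placement run), the internal placement step is skipped.
    """
    index = ReferenceIndex(reference, k)
    records: list[AssignmentRecord] = []
    dropped: dict[str, str] = {}
    for query_id, seq in queries.items():
        qa = align_query(query_id, seq, index, k=k)
        if not qc_coverage(qa, min_cov):
            dropped[query_id] = (
                f"coverage {qa.coverage:.2f} < {min_cov:.2f} vs template "
                f"{qa.template_id}"
            )
            continue
        if jplace_placements is not None:
            pls = jplace_placements.get(query_id)
            if not pls:
                dropped[query_id] = "absent from jplace placements"
                continue
        else:
            pls = place_query(qa, rtree, index, top_k=top_k)
            if not pls:
                dropped[query_id] = "no placement candidates"
                continue
        pls = filter_placements(pls)
        per_placement = [
            assign_from_placement(p, labeling, thresholds, rtree,
                                  include_distal)
            for p in pls
        ]
        records.append(combine_placements(query_id, per_placement, pls))
    return records, dropped


def write_assignments(records: list[AssignmentRecord], path,
                      dropped: dict[str, str] | None = None) -> None:
    """Assignment TSV: query, one column per rank (';'-joined labels),
    resolved rank, placement count, max LWR."""
    import csv
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["query", *RANKS, "resolved_rank", "n_placements",
                    "max_lwr"])
        for rec in records:
            w.writerow([
                rec.query_id,
                *(render_labels(rec.labels[r]) for r in range(N_RANKS)),
                RANKS[rec.resolved_rank] if rec.resolved_rank is not None else "",
                rec.n_placements,
                f"{rec.max_lwr:.4f}",
            ])
        if dropped:
            for query_id, reason in dropped.items():
                w.writerow([query_id, *["unassigned"] * N_RANKS, "",
                            0, "0.0000"])
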