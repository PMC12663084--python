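"""Synthetic fixture generator: taxonomy, tree, sequences and queries
with controllable taxonomy/phylogeny concordance.

A rank-nested random tree is generated (taxa are clades by
construction), sequences are evolved along it under a Jukes-Cantor
substitution process, and conserved primer motifs are written into
fixed alignment columns so the in-silico PCR step has real binding
sites to find. Noise knobs inject label swaps (mis-annotation) after
the truth table is recorded. All randomness flows from a single seed;
identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from .evaluate import HoldoutSplit, build_holdout
from .refprep import (
    AlignedDatabase,
    PrimerPair,
    RegionSlice,
    find_primer_site,
    normalize_sequence,
    reverse_complement,
    trim_to_region,
)
from .taxonomy import Lineage, RANKS, TaxonomyTable
from .tree import RegionTree

BASES = np.frombuffer(b"ACGT", dtype="S1")

#: Mean branch length of the edge entering a node at each rank depth
#: (Domain..Species) and, last, the pendant edge of each sequence tip.
DEFAULT_BRANCH_SCALES = (0.03, 0.07, 0.04, 0.035, 0.07, 0.09, 0.025, 0.006)

#: V4V5-style primer pair; degenerate codes are kept in the pair (so
#: IUPAC matching is exercised) but a concrete realisation is embedded
#: into the conserved template columns.
DEFAULT_FWD_PRIMER = "GTGYCAGCMGCCGCGGTAA"
DEFAULT_REV_PRIMER = "CCGYCAATTYMTTTRAGTTT"
_IUPAC_REALIZE = str.maketrans({"R": "A", "Y": "C", "S": "G", "W": "A",
                                "K": "G", "M": "C", "B": "C", "D": "A",
                                "H": "A", "V": "A", "N": "A"})


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic fixture.

    ``counts[i]`` is the number of rank-(i) taxa nested under each
    rank-(i-1) taxon (Domain..Species); ``seqs_per_taxon`` is the
    number of sequence tips per species.
    """

    counts: tuple[int, ...] = (1, 2, 1, 1, 2, 2, 2)
    seqs_per_taxon: int = 4
    branch_scales: tuple[float, ...] = DEFAULT_BRANCH_SCALES
    branch_jitter: float = 0.15
    seq_length: int = 600
    fwd_primer: str = DEFAULT_FWD_PRIMER
    rev_primer: str = DEFAULT_REV_PRIMER
    fwd_position: int = 40
    rev_position: int = 540     # column where the reverse site starts
    label_swap_rate: float = 0.0
    gap_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(self.counts) != len(RANKS):
            raise ValueError(f"counts must have {len(RANKS)} entries")
        if any(c < 1 for c in self.counts) or self.seqs_per_taxon < 1:
            raise ValueError("all counts must be >= 1")
        for rate in (self.label_swap_rate, self.gap_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must be in [0, 1]")


@dataclass
class Fixture:
    spec: FixtureSpec
    db: AlignedDatabase          # full-length aligned sequences
    taxonomy: TaxonomyTable      # working taxonomy (after label swaps)
    truth: TaxonomyTable         # pre-swap ground truth
    tree: TreeNode               # true generating tree (sequence tips)
    primers: PrimerPair
    fwd_site: tuple[int, int] = (0, 0)
    rev_site: tuple[int, int] = (0, 0)
    n_swapped: int = 0

    def region_slice(self, keep_primers: bool = False) -> RegionSlice:
        return trim_to_region(self.db, self.fwd_site, self.rev_site,
                              keep_primers=keep_primers)

    def region_tree(self, ids=None) -> RegionTree:
        """RegionTree over the true generating tree, optionally sheared
        to a subset of tips."""
        tree = self.tree.copy()
        if ids is not None:
            tree = tree.shear(list(ids))
            tree.prune()
        return RegionTree(tree=tree, taxonomy=self.taxonomy)


_PREFIXES = ("D", "P", "C", "O", "F", "G")


def _evolve(parent: np.ndarray, bl: float, rng, mutable: np.ndarray) -> np.ndarray:
    """Jukes-Cantor evolution: each mutable site substitutes with
    probability 3/4 (1 - exp(-4/3 bl)) to a uniformly chosen other base."""
    child = parent.copy()
    p_sub = 0.75 * (1.0 - math.exp(-4.0 / 3.0 * bl))
    hit = np.where(mutable & (rng.random(child.size) < p_sub))[0]
    for i in hit:
        others = BASES[BASES != child[i]]
        child[i] = others[rng.integers(3)]
    return child


def simulate_fixture(spec: FixtureSpec) -> Fixture:
    """Generate a rank-nested tree, evolve sequences along it, and
    return the full fixture with truth tables."""
    rng = np.random.default_rng(spec.seed)

    # root sequence with conserved primer motifs
    L = spec.seq_length
    fwd = normalize_sequence(spec.fwd_primer).translate(_IUPAC_REALIZE)
    rev_rc = reverse_complement(
        normalize_sequence(spec.rev_primer).translate(_IUPAC_REALIZE)
    )
    f0, f1 = spec.fwd_position, spec.fwd_position + len(fwd)
    r0, r1 = spec.rev_position, spec.rev_position + len(rev_rc)
    if not (0 <= f0 < f1 < r0 < r1 <= L):
        raise ValueError("primer positions do not fit the sequence length")
    root_seq = BASES[rng.integers(4, size=L)].copy()
    root_seq[f0:f1] = np.frombuffer(fwd.encode(), dtype="S1")
    root_seq[r0:r1] = np.frombuffer(rev_rc.encode(), dtype="S1")
    mutable = np.ones(L, dtype=bool)
    mutable[f0:f1] = False
    mutable[r0:r1] = False

    def branch(depth: int) -> float:
        scale = spec.branch_scales[depth]
        j = spec.branch_jitter
        return scale * float(rng.uniform(1 - j, 1 + j))

    seqs: dict[str, np.ndarray] = {}
    lineages: dict[str, Lineage] = {}
    tip_nodes: dict[str, TreeNode] = {}

    def descend(node_seq, depth, names, parent_node):
        """Recursively create rank-(depth) taxa under the current taxon."""
        if depth == len(RANKS):
            # tips descend from a caterpillar genealogy with real internal
            # branches, not a star: a hard multifurcation would make the
            # within-species resolution of a reconstructed tree arbitrary
            cur_parent, cur_seq = parent_node, node_seq
            for s in range(spec.seqs_per_taxon):
                seq_id = f"{names[-1].replace(' ', '_')}_seq{s + 1}"
                bl = branch(len(RANKS))
                child_seq = _evolve(cur_seq, bl, rng, mutable)
                seqs[seq_id] = child_seq
                lineages[seq_id] = Lineage.from_names(names)
                tip = TreeNode(name=seq_id, length=bl)
                cur_parent.append(tip)
                tip_nodes[seq_id] = tip
                if s < spec.seqs_per_taxon - 2:
                    ibl = branch(len(RANKS))
                    inner = TreeNode(name=None, length=ibl)
                    cur_parent.append(inner)
                    cur_seq = _evolve(cur_seq, ibl, rng, mutable)
                    cur_parent = inner
            return
        for i in range(spec.counts[depth]):
            if depth == len(RANKS) - 1:  # species: binomial under genus
                name = f"{names[-1]} sp{i + 1}"
            else:
                parent_tag = names[-1] if names else ""
                name = (f"{_PREFIXES[depth]}{i + 1}" if not parent_tag
                        else f"{parent_tag}.{_PREFIXES[depth]}{i + 1}")
            bl = branch(depth)
            child_seq = _evolve(node_seq, bl, rng, mutable)
            child_node = TreeNode(name=None, length=bl)
            parent_node.append(child_node)
            descend(child_seq, depth + 1, names + [name], child_node)

    root = TreeNode(name="root", length=None)
    descend(root_seq, 0, [], root)

    truth = TaxonomyTable(dict(lineages))

    # label-swap noise: exchange full lineages between random tip pairs
    working = dict(lineages)
    ids = sorted(working)
    n_swap_pairs = int(round(spec.label_swap_rate * len(ids) / 2))
    swapped = 0
    if n_swap_pairs:
        chosen = rng.choice(ids, size=2 * n_swap_pairs, replace=False)
        for a, b in zip(chosen[::2], chosen[1::2]):
            working[a], working[b] = working[b], working[a]
            swapped += 2

    # gap decoration: random columns blanked in a random subset of rows
    text = {i: s.tobytes().decode() for i, s in seqs.items()}
    if spec.gap_rate > 0:
        candidate_cols = [c for c in range(L) if mutable[c]]
        n_cols = int(round(spec.gap_rate * len(candidate_cols)))
        cols = rng.choice(candidate_cols, size=n_cols, replace=False)
        for c in sorted(int(c) for c in cols):
            rows = [i for i in ids if rng.random() < 0.5]
            for i in rows:
                s = text[i]
                text[i] = s[:c] + "-" + s[c + 1:]

    db = AlignedDatabase(text)
    primers = PrimerPair("synthetic", spec.fwd_primer, spec.rev_primer)
    fwd_site = find_primer_site(db, primers.forward, "forward")
    rev_site = find_primer_site(db, primers.reverse, "reverse")
    return Fixture(
        spec=spec,
        db=db,
        taxonomy=TaxonomyTable(working),
        truth=truth,
        tree=root,
        primers=primers,
        fwd_site=fwd_site,
        rev_site=rev_site,
        n_swapped=swapped,
    )


@dataclass
class QuerySet:
    queries: dict[str, str]       # unaligned region sequences
    truth: TaxonomyTable
    reference_ids: list[str]
    split: HoldoutSplit


def make_queries(
    fixture: Fixture,
    scheme: str = "single-rep-genus",
    mutation_rate: float = 0.0,
    seed: int | None = None,
    **scheme_params,
) -> QuerySet:
    """Hold out sequences as queries: region-trimmed, degapped, with a
    known truth table. With ``mutation_rate=0`` queries are exact
    region substrings of the held-out sequences."""
    seed = fixture.spec.seed if seed is None else seed
    rng = np.random.default_rng(seed + 1)
    split = build_holdout(
        list(fixture.db.seqs), fixture.truth, scheme, seed=seed + 2,
        **scheme_params,
    )
    sl = fixture.region_slice()
    queries: dict[str, str] = {}
    for qid in split.query_ids:
        if qid not in sl.seqs:
            continue  # region was all-gap
        seq = sl.degapped(qid)
        if mutation_rate > 0:
            arr = np.frombuffer(seq.encode(), dtype="S1").copy()
            hit = np.where(rng.random(arr.size) < mutation_rate)[0]
            for i in hit:
                others = BASES[BASES != arr[i]]
                arr[i] = others[rng.integers(3)]
            seq = arr.tobytes().decode()
        if "N" in seq:
            continue
        queries[qid] = seq
    return QuerySet(
        queries=queries,
        truth=fixture.truth.subset(queries),
        reference_ids=split.reference_ids,
        split=split,
    )


def write_fixture(fixture: Fixture, outdir) -> None:
    """Emit standard files: aligned FASTA, taxonomy TSV, Newick, primers."""
    from pathlib import Path
    from .taxonomy import write_taxonomy_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fixture.db.write_fasta(outdir / "reference.align.fasta")
    write_taxonomy_tsv(fixture.taxonomy, outdir / "taxonomy.tsv")
    write_taxonomy_tsv(fixture.truth, outdir / "truth.tsv")
    fixture.tree.write(str(outdir / "true_tree.nwk"), format="newick")
    with open(outdir / "primers.tsv", "w") as fh:
        fh.write(f"{fixture.primers.name}\t{fixture.primers.forward}\t"
                 f"{fixture.primers.reverse}\n")
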