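"""Trim an aligned full-length reference database to a primer-defined
region and build the region-specific tree inputs.

The in-silico PCR step scans each sequence's ungapped text for an
IUPAC-compatible primer match, maps the hit back to alignment columns,
and takes the modal column interval across sequences. Trimming is a pure
column slice, so trimmed sequences stay aligned. The internal tree path
computes Jukes-Cantor distances (pairwise deletion of gap columns) and
runs neighbor joining with midpoint rooting; a user-supplied Newick tree
(e.g. from FastTree, which estimates GTR branch lengths) is the
higher-fidelity alternative and is ingested verbatim.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from skbio import DistanceMatrix
from skbio.tree import nj

from .taxonomy import TaxonomyTable
from .tree import RegionTree

log = logging.getLogger(__name__)

GAP_CHARS = ".-"

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("GC"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class PrimerNotFoundError(ValueError):
    pass


class ReferencePrepError(ValueError):
    pass


def normalize_sequence(seq: str) -> str:
    """Uppercase, U->T, '.'->'-'."""
    return seq.upper().replace("U", "T").replace(".", "-")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_match(primer: str, text: str, start: int, max_mismatches: int = 0) -> bool:
    """True if `primer` matches `text[start:]` with <= max_mismatches
    IUPAC-incompatible positions."""
    mism = 0
    for i, code in enumerate(primer):
        base = text[start + i]
        if base not in IUPAC.get(code, frozenset()):
            mism += 1
            if mism > max_mismatches:
                return False
    return True


@dataclass
class AlignedDatabase:
    """Aligned reference sequences: ID -> gapped sequence, uniform length."""

    seqs: dict[str, str]

    def __post_init__(self):
        lengths = {len(s) for s in self.seqs.values()}
        if len(lengths) > 1:
            raise ReferencePrepError(
                f"alignment is ragged: lengths {sorted(lengths)}"
            )
        self.seqs = {i: normalize_sequence(s) for i, s in self.seqs.items()}

    @property
    def width(self) -> int:
        return len(next(iter(self.seqs.values()))) if self.seqs else 0

    @property
    def ids(self) -> list[str]:
        return list(self.seqs)

    def __len__(self):
        return len(self.seqs)

    @classmethod
    def read_fasta(cls, path) -> "AlignedDatabase":
        seqs: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seqs:
                raise ReferencePrepError(f"duplicate sequence ID {rec.id!r}")
            seqs[rec.id] = str(rec.seq)
        if not seqs:
            raise ReferencePrepError(f"no sequences in {path}")
        return cls(seqs)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for seq_id, seq in self.seqs.items():
                fh.write(f">{seq_id}\n{seq}\n")


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward: str   # 5'->3' on the forward strand
    reverse: str   # 5'->3' on the reverse strand (as synthesised)

    def __post_init__(self):
        for seq in (self.forward, self.reverse):
            if not seq:
                raise ReferencePrepError("empty primer sequence")
            bad = set(seq.upper().replace("U", "T")) - set(IUPAC)
            if bad:
                raise ReferencePrepError(f"non-IUPAC codes in primer: {bad}")


def read_primer_tsv(path) -> list[PrimerPair]:
    """Read a primer file: TSV with columns name, forward, reverse."""
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ReferencePrepError(f"primer line needs 3 columns: {line!r}")
            pairs.append(PrimerPair(parts[0], parts[1].upper(), parts[2].upper()))
    if not pairs:
        raise ReferencePrepError(f"no primers in {path}")
    return pairs


def _degap_with_map(seq: str) -> tuple[str, list[int]]:
    """Return (ungapped sequence, ungapped position -> alignment column)."""
    text = []
    colmap = []
    for col, base in enumerate(seq):
        if base not in GAP_CHARS:
            text.append(base)
            colmap.append(col)
    return "".join(text), colmap


def find_primer_site(
    db: AlignedDatabase,
    primer: str,
    orientation: str = "forward",
    max_mismatches: int = 0,
    min_hit_fraction: float = 0.5,
) -> tuple[int, int]:
    """Locate the alignment-column interval of a primer binding site.

    Scans each sequence's ungapped text for the first IUPAC-compatible
    match (reverse primers are reverse-complemented first), maps hit
    coordinates back to alignment columns, and returns the modal
    half-open column interval across sequences.
    """
    if orientation not in ("forward", "reverse"):
        raise ValueError(f"orientation must be forward/reverse: {orientation!r}")
    pattern = normalize_sequence(primer).replace("-", "")
    if orientation == "reverse":
        pattern = reverse_complement(pattern)
    if not db.seqs:
        raise ReferencePrepError("empty database")

    intervals: Counter[tuple[int, int]] = Counter()
    n_hit = 0
    for seq in db.seqs.values():
        text, colmap = _degap_with_map(seq)
        hit = None
        for start in range(len(text) - len(pattern) + 1):
            if iupac_match(pattern, text, start, max_mismatches):
                hit = start
                break
        if hit is not None:
            n_hit += 1
            intervals[(colmap[hit], colmap[hit + len(pattern) - 1] + 1)] += 1
    frac = n_hit / len(db)
    if frac < min_hit_fraction:
        raise PrimerNotFoundError(
            f"primer not located: matched {frac:.1%} of sequences "
            f"(required {min_hit_fraction:.0%})"
        )
    return intervals.most_common(1)[0][0]


@dataclass
class RegionSlice:
    """A column slice of the alignment (0-based, half-open)."""

    start: int
    end: int
    seqs: dict[str, str]
    dropped: dict[str, int] = field(default_factory=dict)

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def ids(self) -> list[str]:
        return list(self.seqs)

    def __len__(self):
        return len(self.seqs)

    def degapped(self, seq_id: str) -> str:
        return self.seqs[seq_id].replace("-", "")

    def to_database(self) -> AlignedDatabase:
        return AlignedDatabase(dict(self.seqs))

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for seq_id, seq in self.seqs.items():
                fh.write(f">{seq_id}\n{seq}\n")


def trim_to_region(
    db: AlignedDatabase,
    fwd_site: tuple[int, int],
    rev_site: tuple[int, int],
    keep_primers: bool = False,
) -> RegionSlice:
    """Slice the alignment between the two primer sites.

    With ``keep_primers=False`` the slice spans (end of forward site,
    start of reverse site); sequences whose region is entirely gaps are
    dropped and counted.
    """
    if keep_primers:
        start, end = fwd_site[0], rev_site[1]
    else:
        start, end = fwd_site[1], rev_site[0]
    if not (0 <= start < end <= db.width):
        raise ReferencePrepError(
            f"inverted or out-of-range primer sites: [{start}, {end}) in "
            f"width-{db.width} alignment"
        )
    out: dict[str, str] = {}
    n_allgap = 0
    for seq_id, seq in db.seqs.items():
        region = seq[start:end]
        if region.replace("-", "") == "":
            n_allgap += 1
            continue
        out[seq_id] = region
    if n_allgap:
        log.info("dropped %d sequences with all-gap region", n_allgap)
    return RegionSlice(start=start, end=end, seqs=out,
                       dropped={"all_gap": n_allgap})


def filter_sequences(
    sl: RegionSlice,
    min_ungapped_len: int = 0,
    drop_N: bool = True,
) -> RegionSlice:
    """Remove sequences containing N (when drop_N) or shorter than
    `min_ungapped_len` ungapped bases."""
    out: dict[str, str] = {}
    n_with_n = n_short = 0
    for seq_id, seq in sl.seqs.items():
        ungapped = seq.replace("-", "")
        if drop_N and "N" in ungapped:
            n_with_n += 1
            continue
        if len(ungapped) < min_ungapped_len:
            n_short += 1
            continue
        out[seq_id] = seq
    if not out:
        raise ReferencePrepError("all sequences removed by filtering")
    if n_with_n or n_short:
        log.info("filtered %d sequences with N, %d short", n_with_n, n_short)
    dropped = dict(sl.dropped)
    dropped.update({"with_N": n_with_n, "too_short": n_short})
    return RegionSlice(start=sl.start, end=sl.end, seqs=out, dropped=dropped)


# -- distances & tree building -------------------------------------------

#: JC distance cap used when the observed mismatch fraction approaches or
#: exceeds the 3/4 saturation point.
MAX_JC_DISTANCE = 5.0


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor correction of an observed mismatch fraction."""
    if p <= 0:
        return 0.0
    if p >= 0.7499:
        return MAX_JC_DISTANCE
    return min(-0.75 * math.log(1.0 - 4.0 * p / 3.0), MAX_JC_DISTANCE)


def jc_distance_matrix(sl: RegionSlice) -> DistanceMatrix:
    """All-pairs Jukes-Cantor distances on the trimmed alignment with
    pairwise deletion of gap (and N) columns."""
    ids = sl.ids
    arrays = {
        i: np.frombuffer(sl.seqs[i].encode(), dtype="S1") for i in ids
    }
    valid = {
        i: (arrays[i] != b"-") & (arrays[i] != b"N") for i in ids
    }
    n = len(ids)
    dm = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            both = valid[ids[a]] & valid[ids[b]]
            m = int(both.sum())
            if m == 0:
                d = MAX_JC_DISTANCE
            else:
                p = float((arrays[ids[a]][both] != arrays[ids[b]][both]).sum()) / m
                d = jukes_cantor(p)
            dm[a, b] = dm[b, a] = d
    return DistanceMatrix(dm, ids)


def build_region_tree(
    sl: RegionSlice,
    taxonomy: TaxonomyTable,
    method: str = "internal-nj",
    newick=None,
) -> RegionTree:
    """Build (or ingest) the region-specific tree.

    ``internal-nj`` computes JC pairwise distances and runs neighbor
    joining, clamps negative branch lengths to zero, and roots at the
    midpoint. ``external-newick`` ingests a user-supplied tree (e.g. a
    FastTree product for the same slice) after validating that its tip
    names are a subset of the slice IDs.
    """
    if method == "internal-nj":
        if len(sl) < 3:
            raise ReferencePrepError("need >= 3 sequences to build a tree")
        dm = jc_distance_matrix(sl)
        # plain NJ estimates; negatives are clamped to zero below rather
        # than redistributed onto sibling branches, which would inflate
        # short within-taxon paths
        tree = nj(dm, neg_as_zero=False)
        for node in tree.traverse():
            if node.length is not None and node.length < 0:
                node.length = 0.0
        tree = tree.root_at_midpoint()
        return RegionTree(tree=tree, taxonomy=taxonomy)
    if method == "external-newick":
        if newick is None:
            raise ReferencePrepError("external-newick requires a tree source")
        rt = RegionTree.from_newick(
            newick, taxonomy, validate_tips=sorted(sl.seqs)
        )
        return rt
    raise ValueError(f"unknown tree method: {method!r}")
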