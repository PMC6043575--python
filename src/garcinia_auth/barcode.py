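"""DNA-barcode authentication against a species-labeled reference library.

Distances between aligned sequences use the Kimura two-parameter (K2P)
model, the de-facto standard in barcoding studies: with transition
proportion P and transversion proportion Q over the pairwise-comparable
sites,

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

Sites where either sequence carries a gap or an ambiguity code are dropped
pairwise.  Marker suitability is judged by the barcode gap: a marker whose
mean interspecific distance does not exceed the mean intraspecific distance
cannot separate species.  Trees come from canonical neighbor joining on the
K2P matrix, and a query is assigned to a species only when the nearest
reference and the smallest clade around the query in the joint tree agree.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (AlignmentError, FastaParseError, InsufficientDataError,
                     TreeError)

__all__ = [
    "SequenceRecord", "PairwiseDistance", "DistanceMatrix", "DistanceSummary",
    "PhyloTree", "AssignmentResult",
    "read_fasta", "write_fasta", "k2p_distance", "distance_matrix",
    "distance_summaries", "count_parsimony_informative", "nj_tree",
    "write_newick", "assign_query", "evaluate_markers",
]

IUPAC_CODES = set("ACGTRYSWKMBDHVN")
_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned sequence; ``species`` is None for query (unknown) records."""

    id: str
    residues: str
    species: str | None = None
    marker: str | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise FastaParseError(f"record {self.id!r} has an empty sequence")
        bad = set(self.residues.upper()) - IUPAC_CODES - {"-"}
        if bad:
            raise FastaParseError(
                f"record {self.id!r} holds non-IUPAC characters: {sorted(bad)}")
        object.__setattr__(self, "residues", self.residues.upper())


@dataclass(frozen=True)
class PairwiseDistance:
    """P, Q and the K2P distance for one sequence pair."""

    p: float
    q: float
    sites_compared: int
    d: float | None
    undefined_reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.d is not None


@dataclass
class DistanceSummary:
    """Barcode-gap summary of one marker's reference library."""

    marker: str
    intra_mean: float | None
    intra_sd: float | None
    inter_mean: float
    inter_sd: float
    n_intra_pairs: int
    n_inter_pairs: int
    suitable: bool
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# FASTA I/O — header dialect "id|species|marker"; missing fields allowed.

def read_fasta(path) -> list[SequenceRecord]:
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split("|")
        rid = parts[0].strip()
        species = parts[1].strip() if len(parts) > 1 and parts[1].strip() else None
        marker = parts[2].strip() if len(parts) > 2 and parts[2].strip() else None
        if rid in seen:
            raise FastaParseError(f"duplicate record id {rid!r}")
        seen.add(rid)
        records.append(SequenceRecord(rid, str(rec.seq), species, marker))
    if not records:
        raise FastaParseError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Sequence[SequenceRecord], path) -> None:
    out = []
    for r in records:
        header = "|".join([r.id, r.species or "", r.marker or ""]).rstrip("|")
        out.append(SeqRecord(Seq(r.residues), id=header, description=""))
    SeqIO.write(out, str(path), "fasta")


# ---------------------------------------------------------------------------
# K2P distances

def k2p_distance(a: SequenceRecord | str, b: SequenceRecord | str) -> PairwiseDistance:
    """K2P distance with pairwise deletion of gaps and ambiguity codes."""
    sa = a.residues if isinstance(a, SequenceRecord) else a.upper()
    sb = b.residues if isinstance(b, SequenceRecord) else b.upper()
    if len(sa) != len(sb):
        raise AlignmentError(
            f"aligned lengths differ: {len(sa)} vs {len(sb)}")
    transitions = transversions = sites = 0
    for x, y in zip(sa, sb):
        if x not in "ACGT" or y not in "ACGT":
            continue
        sites += 1
        if x == y:
            continue
        same_class = ((x in _PURINES) == (y in _PURINES))
        if same_class:
            transitions += 1
        else:
            transversions += 1
    if sites == 0:
        return PairwiseDistance(0.0, 0.0, 0, None, "no comparable sites")
    p = transitions / sites
    q = transversions / sites
    arg1 = 1.0 - 2.0 * p - q
    arg2 = 1.0 - 2.0 * q
    if arg1 <= 0 or arg2 <= 0:
        return PairwiseDistance(p, q, sites, None, "saturation (log argument <= 0)")
    d = -0.5 * math.log(arg1) - 0.25 * math.log(arg2)
    return PairwiseDistance(p, q, sites, d)


@dataclass
class DistanceMatrix:
    """Symmetric K2P distance matrix with per-cell detail records."""

    labels: list[str]
    values: np.ndarray  # NaN where undefined
    pairs: dict[tuple[str, str], PairwiseDistance]
    species: dict[str, str | None] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def get(self, a: str, b: str) -> PairwiseDistance:
        return self.pairs[(a, b) if (a, b) in self.pairs else (b, a)]

    @property
    def complete(self) -> bool:
        return not np.isnan(self.values).any()


def distance_matrix(records: Sequence[SequenceRecord]) -> DistanceMatrix:
    """All-pairs K2P matrix; per-pair failures become NaN cells, not aborts."""
    if len(records) < 2:
        raise InsufficientDataError("need >= 2 sequences")
    lengths = {len(r.residues) for r in records}
    if len(lengths) > 1:
        raise AlignmentError(f"mixed aligned lengths: {sorted(lengths)}")
    markers = {r.marker for r in records if r.marker is not None}
    if len(markers) > 1:
        raise AlignmentError(f"mixed markers in one matrix: {sorted(markers)}")
    labels = [r.id for r in records]
    n = len(records)
    values = np.zeros((n, n))
    pairs: dict[tuple[str, str], PairwiseDistance] = {}
    for i, j in itertools.combinations(range(n), 2):
        pd_ij = k2p_distance(records[i], records[j])
        pairs[(labels[i], labels[j])] = pd_ij
        values[i, j] = values[j, i] = pd_ij.d if pd_ij.defined else np.nan
    return DistanceMatrix(labels, values, pairs,
                          {r.id: r.species for r in records})


def distance_summaries(matrix: DistanceMatrix,
                       species: Mapping[str, str] | None = None,
                       marker: str = "marker") -> DistanceSummary:
    """Mean +/- SD of intra- and interspecific pairwise distances.

    SDs are population SDs over the defined pair distances.  A marker is
    suitable only when the mean interspecific distance exceeds the mean
    intraspecific one (the barcode gap on averages); with no intraspecific
    pairs the intra fields are absent and the row is flagged.
    """
    if species is None:
        species = {k: v for k, v in matrix.species.items() if v is not None}
    labels = [l for l in matrix.labels if l in species]
    if len({species[l] for l in labels}) < 2:
        raise InsufficientDataError("need >= 2 species for interspecific pairs")
    intra, inter = [], []
    for a, b in itertools.combinations(labels, 2):
        cell = matrix.get(a, b)
        if not cell.defined:
            continue
        (intra if species[a] == species[b] else inter).append(cell.d)
    if not inter:
        raise InsufficientDataError("no defined interspecific pairs")
    flags = []
    if intra:
        intra_mean, intra_sd = float(np.mean(intra)), float(np.std(intra))
    else:
        intra_mean = intra_sd = None
        flags.append("no_intraspecific_pairs")
    inter_mean, inter_sd = float(np.mean(inter)), float(np.std(inter))
    suitable = intra_mean is None or inter_mean > intra_mean
    if not suitable:
        flags.append("no_barcode_gap")
    return DistanceSummary(marker, intra_mean, intra_sd, inter_mean, inter_sd,
                           len(intra), len(inter), suitable, flags)


def count_parsimony_informative(records: Sequence[SequenceRecord]) -> int:
    """Columns with >= 2 distinct unambiguous states each in >= 2 sequences."""
    if len(records) < 4:
        raise InsufficientDataError("need >= 4 sequences")
    lengths = {len(r.residues) for r in records}
    if len(lengths) > 1:
        raise AlignmentError(f"mixed aligned lengths: {sorted(lengths)}")
    count = 0
    for col in zip(*(r.residues for r in records)):
        tallies: dict[str, int] = {}
        for ch in col:
            if ch in "ACGT":
                tallies[ch] = tallies.get(ch, 0) + 1
        if sum(1 for v in tallies.values() if v >= 2) >= 2:
            count += 1
    return count


# ---------------------------------------------------------------------------
# Neighbor joining

@dataclass
class PhyloTree:
    """Unrooted tree as an adjacency map with branch lengths.

    Leaves are the nodes named by their taxon labels; internal nodes carry
    synthetic names.  All NJ branch-length estimates are clamped at zero
    (any negative estimate's deficit moved to its sibling), so lengths are
    non-negative.
    """

    adjacency: dict[str, dict[str, float]]
    leaves: list[str]

    def neighbors(self, node: str) -> dict[str, float]:
        return self.adjacency[node]

    def leaves_beyond(self, start: str, blocked: str) -> list[str]:
        """Leaf labels reachable from ``start`` without crossing ``blocked``."""
        seen = {blocked, start}
        stack = [start]
        found = []
        while stack:
            node = stack.pop()
            if node in self.leaves:
                found.append(node)
            for nxt in self.adjacency[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return sorted(found)

    def path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths along the unique a-b path."""
        prev = {a: None}
        stack = [a]
        while stack:
            node = stack.pop()
            if node == b:
                break
            for nxt in self.adjacency[node]:
                if nxt not in prev:
                    prev[nxt] = node
                    stack.append(nxt)
        if b not in prev:
            raise TreeError(f"no path between {a!r} and {b!r}")
        total = 0.0
        node = b
        while prev[node] is not None:
            total += self.adjacency[node][prev[node]]
            node = prev[node]
        return total

    def path_length_matrix(self) -> pd.DataFrame:
        n = len(self.leaves)
        out = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            out[i, j] = out[j, i] = self.path_length(self.leaves[i],
                                                     self.leaves[j])
        return pd.DataFrame(out, index=self.leaves, columns=self.leaves)

    def to_newick(self) -> str:
        if not self.leaves:
            raise TreeError("empty tree")
        if len(self.leaves) == 1:
            return f"{self.leaves[0]};"
        # Root the unrooted tree at an internal node if one exists.
        internal = [n for n in self.adjacency if n not in self.leaves]
        root = internal[0] if internal else self.leaves[0]

        def render(node: str, parent: str | None) -> str:
            children = [c for c in sorted(self.adjacency[node]) if c != parent]
            if not children:
                return node
            inner = ",".join(
                f"{render(c, node)}:{self.adjacency[node][c]:.10g}"
                for c in children)
            return f"({inner}){node if node in self.leaves else ''}"

        return render(root, None) + ";"


def nj_tree(matrix: DistanceMatrix | pd.DataFrame) -> PhyloTree:
    """Canonical Saitou-Nei neighbor joining with deterministic tie-breaks.

    Ties in the Q criterion are broken toward the pair whose (sorted) label
    pair is lexicographically smallest, labelling every cluster by its
    smallest member leaf.  Negative branch-length estimates are clamped to
    zero with the deficit added to the sibling branch.
    """
    if isinstance(matrix, DistanceMatrix):
        if not matrix.complete:
            bad = [f"{a}~{b}" for (a, b), cell in matrix.pairs.items()
                   if not cell.defined]
            raise TreeError(f"matrix has undefined cells: {bad}")
        frame = matrix.to_frame()
    else:
        frame = matrix
    labels = list(frame.index)
    if len(labels) < 2:
        raise TreeError("need >= 2 taxa")
    dist = {(a, b): float(frame.loc[a, b])
            for a in labels for b in labels if a != b}

    adjacency: dict[str, dict[str, float]] = {l: {} for l in labels}
    leaves = list(labels)

    def connect(a: str, b: str, length: float) -> None:
        adjacency.setdefault(a, {})[b] = length
        adjacency.setdefault(b, {})[a] = length

    # cluster label -> representative (smallest leaf) for tie-breaking
    rep = {l: l for l in labels}
    active = list(labels)
    next_internal = 0

    while len(active) > 2:
        n = len(active)
        r = {a: sum(dist[(a, b)] for b in active if b != a) for a in active}
        best_pair = best_key = None
        best_q = math.inf
        for a, b in itertools.combinations(active, 2):
            qv = (n - 2) * dist[(a, b)] - r[a] - r[b]
            key = tuple(sorted((rep[a], rep[b])))
            if qv < best_q or (qv == best_q and key < best_key):
                best_q, best_key, best_pair = qv, key, (a, b)
        a, b = best_pair
        new = f"_nj{next_internal}"
        next_internal += 1
        la = 0.5 * dist[(a, b)] + (r[a] - r[b]) / (2 * (n - 2))
        lb = dist[(a, b)] - la
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        la = max(la, 0.0)
        lb = max(lb, 0.0)
        connect(a, new, la)
        connect(b, new, lb)
        for c in active:
            if c in (a, b):
                continue
            dist[(new, c)] = dist[(c, new)] = 0.5 * (
                dist[(a, c)] + dist[(b, c)] - dist[(a, b)])
        rep[new] = min(rep[a], rep[b])
        active = [c for c in active if c not in (a, b)] + [new]

    if len(active) == 2:
        a, b = active
        connect(a, b, max(dist.get((a, b), 0.0), 0.0))

    return PhyloTree(adjacency=adjacency, leaves=leaves)


def write_newick(tree: PhyloTree, path) -> str:
    text = tree.to_newick()
    Path(path).write_text(text + "\n")
    return text


# ---------------------------------------------------------------------------
# Query assignment

@dataclass
class AssignmentResult:
    query_id: str
    assigned_species: str  # species name, "ambiguous" or "no-match"
    nearest_distance: float | None
    clade_support: bool
    rationale: str

    @property
    def assigned(self) -> bool:
        return self.assigned_species not in ("ambiguous", "no-match")


def _smallest_sister_clade(tree: PhyloTree, query: str) -> list[str]:
    """Leaves of the smallest clade (beyond the query's own edge) holding it.

    On an unrooted tree, clades containing the query correspond to the
    query-side bipartition of each edge; the informative smallest one is the
    query plus the smallest subtree hanging off the query's attachment node.
    """
    (attach,) = tree.neighbors(query).keys()
    candidates = [tree.leaves_beyond(w, attach)
                  for w in tree.neighbors(attach) if w != query]
    if attach in tree.leaves:
        candidates.append([attach])
    candidates.sort(key=lambda ls: (len(ls), ls))
    return candidates[0]


def assign_query(query: SequenceRecord,
                 references: Sequence[SequenceRecord],
                 distance_ceiling: float = 0.2) -> AssignmentResult:
    """Assign a query to a species by agreement of two criteria.

    (a) nearest neighbor: the closest reference's species, required to be
    strictly closer than every other species's nearest reference; and
    (b) clade membership: the smallest clade around the query in the NJ
    tree of references plus query must hold only that species.  Distances
    above ``distance_ceiling`` yield "no-match"; conflicts or exact ties
    yield "ambiguous".
    """
    if not references:
        raise InsufficientDataError("empty reference library")
    by_species: dict[str, float] = {}
    dists: dict[str, float] = {}
    for ref in references:
        if ref.species is None:
            raise InsufficientDataError(f"reference {ref.id!r} lacks a species label")
        cell = k2p_distance(query, ref)
        if not cell.defined:
            continue
        dists[ref.id] = cell.d
        if ref.species not in by_species or cell.d < by_species[ref.species]:
            by_species[ref.species] = cell.d
    if not dists:
        return AssignmentResult(query.id, "no-match", None, False,
                                "no defined distance to any reference")
    nearest_species = min(by_species, key=lambda s: (by_species[s], s))
    nearest = by_species[nearest_species]
    if nearest > distance_ceiling:
        return AssignmentResult(
            query.id, "no-match", nearest, False,
            f"nearest reference at d={nearest:.4f} exceeds ceiling "
            f"{distance_ceiling}")
    others = [d for s, d in by_species.items() if s != nearest_species]
    if others and min(others) <= nearest:
        return AssignmentResult(
            query.id, "ambiguous", nearest, False,
            f"nearest distance {nearest:.4f} tied between species")

    matrix = distance_matrix([*references, query])
    if not matrix.complete:
        return AssignmentResult(
            query.id, "ambiguous", nearest, False,
            "distance matrix incomplete; clade criterion not evaluable")
    tree = nj_tree(matrix)
    sister = _smallest_sister_clade(tree, query.id)
    species_of = {r.id: r.species for r in references}
    sister_species = {species_of[l] for l in sister}
    clade_ok = sister_species == {nearest_species}
    if clade_ok:
        return AssignmentResult(
            query.id, nearest_species, nearest, True,
            f"nearest reference (d={nearest:.4f}) and smallest containing "
            f"clade both indicate {nearest_species}")
    return AssignmentResult(
        query.id, "ambiguous", nearest, False,
        f"nearest neighbor says {nearest_species} but sister clade holds "
        f"{sorted(s for s in sister_species if s)}")


def evaluate_markers(libraries: Mapping[str, Sequence[SequenceRecord]]
                     ) -> pd.DataFrame:
    """One barcode-gap summary row per marker, ranked by inter-species mean.

    Failures for a marker (too few species, undefined distances...) become
    flagged rows rather than aborting the table.
    """
    if not libraries:
        raise InsufficientDataError("no marker libraries supplied")
    rows = []
    for marker, records in libraries.items():
        row: dict[str, object] = {"marker": marker}
        try:
            matrix = distance_matrix(records)
            summ = distance_summaries(matrix, marker=marker)
            row.update(intra_mean=summ.intra_mean, intra_sd=summ.intra_sd,
                       inter_mean=summ.inter_mean, inter_sd=summ.inter_sd,
                       n_intra_pairs=summ.n_intra_pairs,
                       n_inter_pairs=summ.n_inter_pairs,
                       suitable=summ.suitable, flags=";".join(summ.flags))
            try:
                row["parsimony_informative"] = count_parsimony_informative(records)
            except InsufficientDataError:
                row["parsimony_informative"] = None
        except (InsufficientDataError, AlignmentError) as exc:
            row.update(suitable=False, flags=f"error: {exc}")
        rows.append(row)
    out = pd.DataFrame(rows)
    if "inter_mean" in out:
        out = out.sort_values("inter_mean", ascending=False,
                              na_position="last").reset_index(drop=True)
    return out
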