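"""Mapping identified proteins onto a protein-complex database.

Proteins identified by mass spectrometry in a chromatographic fraction are
mapped to a database of known/predicted complexes (CORUM-style: a named set
of subunit accessions per complex).  Complexes with at least half of their
subunits identified are kept as candidates.  Because many candidates are
variants of one another (sub-complexes, alternative compositions), candidates
are organised into hierarchies using a directed set-overlap similarity

    S(A, B) = |A ∩ B| / |A|

i.e. the fraction of A's subunits also present in B.  A sub-complex always
scores 1 toward any complex that contains it, so thresholding S at 0.9 and
taking connected components recovers subset-into-superset hierarchies.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import networkx as nx

if TYPE_CHECKING:  # pragma: no cover
    from .quant import ProteinObservation

__all__ = [
    "ComplexRecord",
    "SimilarityEdge",
    "ComplexGroup",
    "candidate_complexes",
    "similarity_score",
    "build_related_graph",
    "group_components",
    "export_network",
]


@dataclass
class ComplexRecord:
    """A named complex: its full subunit set plus what was observed.

    ``coverage`` is the identified fraction |identified_subunits| / |subunits|.
    """

    complex_id: str
    name: str
    subunits: frozenset[str]
    identified_subunits: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.subunits = frozenset(self.subunits)
        self.identified_subunits = frozenset(self.identified_subunits)
        if not self.subunits:
            raise ValueError(f"complex {self.complex_id!r} has no subunits")
        if not self.identified_subunits <= self.subunits:
            raise ValueError(
                f"complex {self.complex_id!r}: identified subunits are not a "
                "subset of the subunit list"
            )

    @property
    def coverage(self) -> float:
        return len(self.identified_subunits) / len(self.subunits)


@dataclass(frozen=True)
class SimilarityEdge:
    """Directed similarity edge: S = |source ∩ target| / |source|."""

    source: str
    target: str
    S: float

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("self-edges are not allowed")
        if not 0.0 <= self.S <= 1.0:
            raise ValueError(f"similarity {self.S} outside [0, 1]")


@dataclass(frozen=True)
class ComplexGroup:
    """A connected component of related complexes (size >= 2)."""

    members: frozenset[str]
    representative: str

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ValueError("representative must be a member")


def similarity_score(A: Iterable[str], B: Iterable[str]) -> float:
    """Directed similarity of complex A to complex B: |A ∩ B| / |A|.

    Asymmetric: a sub-complex scores 1.0 toward its parent while the parent
    scores |A|/|B| back.
    """
    sA, sB = set(A), set(B)
    if not sA:
        raise ValueError("similarity_score is undefined for an empty set A")
    return len(sA & sB) / len(sA)


def candidate_complexes(
    observations: Sequence["ProteinObservation"] | Iterable[str],
    db: Sequence[ComplexRecord],
    min_coverage: float = 0.5,
) -> list[ComplexRecord]:
    """Filter a complex database to candidates supported by observed proteins.

    A complex is a candidate when at least ``min_coverage`` of its subunits
    appear among the observed accessions (default: half).  Returns new
    records, sorted by complex_id, with ``identified_subunits`` populated.

    ``observations`` may be ProteinObservation objects or bare accessions.
    """
    ids = [c.complex_id for c in db]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate complex_ids in database")
    observed: set[str] = set()
    for obs in observations:
        observed.add(obs if isinstance(obs, str) else obs.accession)
    out = []
    for c in sorted(db, key=lambda c: c.complex_id):
        ident = c.subunits & observed
        if len(ident) / len(c.subunits) >= min_coverage:
            out.append(
                ComplexRecord(c.complex_id, c.name, c.subunits, frozenset(ident))
            )
    return out


def build_related_graph(
    complexes: Sequence[ComplexRecord], threshold: float = 0.9
) -> set[SimilarityEdge]:
    """All-by-all directed similarity edges at or above ``threshold``.

    The comparison is inclusive (S = threshold emits an edge), matching the
    "90% or greater" grouping rule.
    """
    edges: set[SimilarityEdge] = set()
    for a in complexes:
        for b in complexes:
            if a.complex_id == b.complex_id:
                continue
            s = similarity_score(a.subunits, b.subunits)
            if s >= threshold:
                edges.add(SimilarityEdge(a.complex_id, b.complex_id, s))
    return edges


def group_components(
    complexes: Sequence[ComplexRecord],
    edges: Iterable[SimilarityEdge],
    abundances: Mapping[str, float] | None = None,
) -> tuple[list[ComplexGroup], list[str]]:
    """Partition complexes into related groups and unique singletons.

    An edge in either direction connects a pair; undirected connected
    components of size >= 2 become groups, singletons are returned as the
    "unique" list.  The group representative is the highest-abundance member
    (ties and missing abundances resolved lexicographically by complex_id).
    """
    known = {c.complex_id for c in complexes}
    g = nx.Graph()
    g.add_nodes_from(sorted(known))
    for e in edges:
        if e.source not in known or e.target not in known:
            raise ValueError(f"edge references unknown complex: {e.source}->{e.target}")
        g.add_edge(e.source, e.target)
    groups: list[ComplexGroup] = []
    unique: list[str] = []
    for comp in nx.connected_components(g):
        if len(comp) == 1:
            unique.extend(comp)
        else:
            if abundances:
                rep = max(sorted(comp), key=lambda cid: abundances.get(cid, 0.0))
            else:
                rep = min(comp)
            groups.append(ComplexGroup(frozenset(comp), rep))
    groups.sort(key=lambda grp: min(grp.members))
    unique.sort()
    return groups, unique


def export_network(
    complexes: Sequence[ComplexRecord],
    edges: Iterable[SimilarityEdge],
    abundances: Mapping[str, float],
    edge_path: str,
    node_path: str,
) -> None:
    """Write Cytoscape-loadable edge and node tables (TSV).

    Edge table columns: source, target, S (4 decimal places).  Node table
    columns: complex_id, name, coverage, abundance.  Abundance 0 is written
    for complexes missing from ``abundances``.
    """
    with open(edge_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["source", "target", "S"])
        for e in sorted(edges, key=lambda e: (e.source, e.target)):
            w.writerow([e.source, e.target, f"{e.S:.4f}"])
    with open(node_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["complex_id", "name", "coverage", "abundance"])
        for c in sorted(complexes, key=lambda c: c.complex_id):
            w.writerow(
                [
                    c.complex_id,
                    c.name,
                    f"{c.coverage:.4f}",
                    repr(float(abundances.get(c.complex_id, 0.0))),
                ]
            )
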