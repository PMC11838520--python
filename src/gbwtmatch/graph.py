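"""Pangenome graph and path-string data model.

A pangenome graph is a node-labelled graph whose nodes carry DNA sequences;
a haplotype is stored as a *path-string*: the sequence of node-characters it
visits.  Node-characters double as alphabet symbols of the path-strings, so
the whole panel of haplotypes is a set of strings over the node id alphabet.

Internal node-character encoding (bidirectional-ready): an external segment
id ``n >= 1`` with orientation ``+``/``-`` maps to the internal id
``2n + (orient == '-')``.  Complementing a node is then ``id ^ 1`` and the
relative order of forward and backward nodes is preserved automatically.
Internal ids 0 and 1 are reserved; 0 is the endmarker that terminates every
indexed string and never occurs inside a path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set, Tuple

ENDMARKER = 0

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def encode_node(segment_id: int, orientation: str = "+") -> int:
    """Map an external (segment id, orientation) to the internal id space."""
    if segment_id < 1:
        raise ValueError(f"external segment ids start at 1, got {segment_id}")
    if orientation not in ("+", "-"):
        raise ValueError(f"orientation must be '+' or '-', got {orientation!r}")
    return 2 * segment_id + (1 if orientation == "-" else 0)


def decode_node(node: int) -> Tuple[int, str]:
    """Inverse of :func:`encode_node`."""
    if node < 2:
        raise ValueError(f"internal id {node} is reserved")
    return node // 2, "-" if node & 1 else "+"


def complement_node(node: int) -> int:
    """The opposite-orientation twin of a node-character (involution)."""
    if node < 2:
        raise ValueError("the endmarker has no complement")
    return node ^ 1


def reverse_complement_seq(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PangenomeGraph:
    """Node labels over {A,C,G,T}; edges are implied by the stored paths.

    ``labels`` maps *forward* internal node ids to their sequence.  Reverse
    nodes are labelled implicitly by reverse complement.  Node weight is the
    label length (base pairs); empty labels are allowed and weigh 0.
    """

    labels: Dict[int, str] = field(default_factory=dict)

    def add_node(self, node: int, seq: str) -> None:
        if node & 1:
            raise ValueError("labels are stored on forward nodes only")
        bad = set(seq.upper()) - set("ACGT")
        if bad:
            raise ValueError(f"non-ACGT characters in label: {sorted(bad)}")
        self.labels[node] = seq.upper()

    def has_node(self, node: int) -> bool:
        return (node & ~1) in self.labels

    def seq(self, node: int) -> str:
        """Label of a node-character; reverse nodes yield the reverse complement."""
        base = self.labels[node & ~1]
        return reverse_complement_seq(base) if node & 1 else base

    def weight(self, node: int) -> int:
        """Base-pair weight of a node-character; 0 for the endmarker and for
        nodes the graph does not label (they can never match anything)."""
        label = self.labels.get(node & ~1)
        return len(label) if label is not None else 0

    def path_seq(self, nodes: Iterable[int]) -> str:
        return "".join(self.seq(v) for v in nodes)

    def nodes(self) -> List[int]:
        return sorted(self.labels)


@dataclass
class PathString:
    """One haplotype's walk through the graph, as a string of node-characters."""

    seq_id: int
    nodes: List[int]
    orientation: str = "forward"
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.nodes:
            raise ValueError("path-strings must be non-empty")
        if ENDMARKER in self.nodes:
            raise ValueError("the endmarker may not occur inside a path")

    def __len__(self) -> int:
        return len(self.nodes)

    def __getitem__(self, i):
        return self.nodes[i]

    def reverse_complement(self, seq_id: int) -> "PathString":
        return PathString(
            seq_id=seq_id,
            nodes=[complement_node(v) for v in reversed(self.nodes)],
            orientation="reverse" if self.orientation == "forward" else "forward",
            name=self.name,
        )


@dataclass(frozen=True)
class Match:
    """A match (i, j, k) between a query and panel haplotype ``hap``.

    ``i`` is the 0-based start in the query, ``j`` the start in the haplotype
    (``None`` when the reporting structure cannot recover it), ``k`` the
    length in node-characters; all intervals are half-open.  ``weight`` is
    the optional total base-pair weight of the matched nodes.
    """

    hap: int
    i: int
    j: Optional[int]
    k: int
    weight: Optional[int] = None

    def key(self) -> Tuple[int, int, int]:
        """Location-free projection used when comparing across query versions."""
        return (self.hap, self.i, self.k)


def edges_of_paths(paths: Iterable[PathString]) -> Set[Tuple[int, int]]:
    """The implicit graph edge set: (u, v) iff uv occurs in some path-string."""
    edges: Set[Tuple[int, int]] = set()
    for p in paths:
        for u, v in zip(p.nodes, p.nodes[1:]):
            edges.add((u, v))
    return edges
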