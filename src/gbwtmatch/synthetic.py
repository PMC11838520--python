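"""Synthetic haplotype panel generator.

Emulates the backbone-plus-bubble structure of real pangenome haplotype
panels: a linear backbone of nodes with biallelic "bubbles" (two-branch
detours) inserted at random backbone positions.  Haplotypes are generated
from two latent founder allele vectors with recombination-style switching
between them, so that panels contain the long shared runs (IBD-like
segments) that make run-length compression of the GBWT effective.

The generator is fully deterministic given its seed and never requires
external data.
"""

from __future__ import annotations

import random
from typing import List, Tuple

from .graph import PangenomeGraph, PathString, encode_node

_BASES = "ACGT"


def generate_panel(
    n_backbone: int,
    n_bubbles: int,
    n_haps: int,
    bubble_alt_prob: float = 0.5,
    recomb_prob: float = 0.02,
    label_len_range: Tuple[int, int] = (1, 3),
    seed: int = 0,
) -> Tuple[PangenomeGraph, List[PathString]]:
    """Generate a graph with ``n_backbone`` chain nodes, ``n_bubbles``
    two-branch bubbles, and ``n_haps`` haplotype paths.

    Each bubble sits between two adjacent backbone nodes and offers a ref and
    an alt branch node.  Two founder allele vectors are drawn; each haplotype
    walks the backbone copying its current founder's allele at every bubble
    and switches founders with probability ``recomb_prob`` per bubble.
    """
    if n_backbone < 1:
        raise ValueError("n_backbone must be >= 1")
    if n_haps < 1:
        raise ValueError("n_haps must be >= 1")
    if not (0.0 <= bubble_alt_prob <= 1.0 and 0.0 <= recomb_prob <= 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    if n_bubbles > n_backbone - 1:
        raise ValueError(
            f"n_bubbles={n_bubbles} exceeds the {n_backbone - 1} backbone gaps"
        )
    lo, hi = label_len_range
    if lo < 0 or hi < lo:
        raise ValueError("label_len_range must be a nondecreasing pair of >= 0")

    rng = random.Random(seed)
    graph = PangenomeGraph()

    def random_label() -> str:
        return "".join(rng.choice(_BASES) for _ in range(rng.randint(lo, hi)))

    # Segment ids: backbone 1..n_backbone; bubble branch nodes follow.
    backbone = [encode_node(s) for s in range(1, n_backbone + 1)]
    for v in backbone:
        graph.add_node(v, random_label())

    gaps = sorted(rng.sample(range(n_backbone - 1), n_bubbles)) if n_bubbles else []
    next_seg = n_backbone + 1
    bubbles = {}  # gap index -> (ref_branch, alt_branch)
    for gap in gaps:
        ref = encode_node(next_seg)
        alt = encode_node(next_seg + 1)
        next_seg += 2
        graph.add_node(ref, random_label())
        graph.add_node(alt, random_label())
        bubbles[gap] = (ref, alt)

    founders = [
        [rng.random() < bubble_alt_prob for _ in gaps],
        [rng.random() < bubble_alt_prob for _ in gaps],
    ]

    paths: List[PathString] = []
    for h in range(n_haps):
        cur = rng.randint(0, 1)
        nodes = []
        bubble_idx = 0
        for i, v in enumerate(backbone):
            nodes.append(v)
            if i in bubbles:
                if rng.random() < recomb_prob:
                    cur = 1 - cur
                ref, alt = bubbles[i]
                nodes.append(alt if founders[cur][bubble_idx] else ref)
                bubble_idx += 1
        paths.append(PathString(seq_id=h, nodes=nodes, name=f"hap{h}"))
    return graph, paths
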