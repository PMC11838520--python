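"""Brute-force reference implementations.

Everything here is deliberately naive and shares no code with the main
index/query implementation: explicit suffix sorting, direct string
comparison, exhaustive match enumeration.  These routines define ground
truth for the property-based test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple

from .graph import ENDMARKER, Match, PathString


@dataclass
class NaiveSuffixStructures:
    """Suffix array, LCP array, document array and BWT of the reversed panel.

    Texts are the reversed path-strings with a trailing endmarker.  Suffixes
    are identified as (seq, offset) with offset the start position within the
    reversed text.  Equal suffixes (which can only happen for whole equal
    texts or trailing-endmarker suffixes) are ordered by sequence id.
    """

    texts: List[List[int]]
    suffixes: List[Tuple[int, int]]  # SA: rank -> (seq, offset)
    lcp: List[int]                   # LCP[rank] vs rank-1; LCP[0] = 0
    da: List[int]                    # document per rank
    bwt: List[int]                   # symbol preceding each suffix (cyclic)

    def rank_of(self, seq: int, offset: int) -> int:
        return self.suffixes.index((seq, offset))


def _suffix_lcp(a: Sequence[int], b: Sequence[int]) -> int:
    """LCP of two suffix symbol sequences; endmarkers never compare equal."""
    n = 0
    for x, y in zip(a, b):
        if x != y or x == ENDMARKER:
            break
        n += 1
    return n


def naive_suffix_structures(paths: Sequence[PathString]) -> NaiveSuffixStructures:
    if not paths:
        raise ValueError("empty panel")
    texts = [list(reversed(p.nodes)) + [ENDMARKER] for p in paths]
    entries = []
    for d, text in enumerate(texts):
        for off in range(len(text)):
            entries.append((tuple(text[off:]), d, off))
    entries.sort()
    suffixes = [(d, off) for _, d, off in entries]
    da = [d for _, d, off in entries]
    bwt = [texts[d][off - 1] if off > 0 else texts[d][-1] for d, off in suffixes]
    lcp = [0] * len(entries)
    for r in range(1, len(entries)):
        lcp[r] = _suffix_lcp(entries[r - 1][0], entries[r][0])
    return NaiveSuffixStructures(texts=texts, suffixes=suffixes, lcp=lcp, da=da, bwt=bwt)


def naive_locally_maximal(
    query: Sequence[int], paths: Sequence[PathString]
) -> List[Match]:
    """All locally maximal matches between ``query`` and each panel path,
    by direct definition: a shared substring extendable in neither direction
    between the two specific strings."""
    out: List[Match] = []
    A = list(query)
    for p in paths:
        B = p.nodes
        for i in range(len(A)):
            for j in range(len(B)):
                if A[i] != B[j]:
                    continue
                if i > 0 and j > 0 and A[i - 1] == B[j - 1]:
                    continue  # extendable left: not a match start
                k = 0
                while i + k < len(A) and j + k < len(B) and A[i + k] == B[j + k]:
                    k += 1
                out.append(Match(hap=p.seq_id, i=i, j=j, k=k))
    return out


def naive_matches(
    query: Sequence[int],
    paths: Sequence[PathString],
    mode: str = "local",
    L: Optional[float] = None,
    weight_fn: Optional[Callable[[int], float]] = None,
) -> List[Match]:
    """Exhaustive enumeration of local / set-maximal / long / weighted-long
    matches straight from the definitions."""
    local = naive_locally_maximal(query, paths)
    if mode == "local":
        matches = local
    elif mode == "smem":
        # set-maximal: query interval strictly contained in no other match's.
        intervals = {(m.i, m.k) for m in local}
        matches = [
            m
            for m in local
            if not any(
                i2 <= m.i and m.i + m.k <= i2 + k2 and (i2, k2) != (m.i, m.k)
                for (i2, k2) in intervals
            )
        ]
    elif mode == "long":
        if L is None:
            raise ValueError("mode='long' needs L")
        matches = [m for m in local if m.k >= L]
    elif mode == "long_weighted":
        if L is None or weight_fn is None:
            raise ValueError("mode='long_weighted' needs L and weight_fn")
        matches = []
        for m in local:
            w = sum(weight_fn(v) for v in query[m.i : m.i + m.k])
            if w >= L:
                matches.append(Match(hap=m.hap, i=m.i, j=m.j, k=m.k, weight=w))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return sorted(matches, key=lambda m: (m.i, m.hap, -1 if m.j is None else m.j))


def naive_all_vs_all(
    paths: Sequence[PathString],
    mode: str,
    L: Optional[float] = None,
    weight_fn: Optional[Callable[[int], float]] = None,
    twin: Optional[dict] = None,
) -> List[Tuple[int, Match]]:
    """Reference one-vs-all driver over every panel path, discarding the
    trivial full-length self-match of each query against itself (and, when
    ``twin`` maps a sequence to its opposite-orientation twin, the mirrored
    full-length match to that twin)."""
    out: List[Tuple[int, Match]] = []
    for p in paths:
        t = twin.get(p.seq_id) if twin else None
        for m in naive_matches(p.nodes, paths, mode=mode, L=L, weight_fn=weight_fn):
            if m.hap == p.seq_id and m.i == m.j and m.k == len(p.nodes):
                continue
            if t is not None and m.hap == t and m.k == len(p.nodes):
                continue
            out.append((p.seq_id, m))
    return out
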