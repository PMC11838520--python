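"""The GBWT-Index: run-length-compressed multi-string BWT of reversed path-strings.

The index stores one *record* per node-character ``v``: the slice of the BWT
whose suffixes begin with ``v``, run-length compressed over the record's
local alphabet, plus the outgoing rank offsets ``BWT.rank(v, w)`` (the count
of ``w`` in all records before ``v``).  Positions are (node, offset) pairs.

The indexed text is ``{rev(P) . 0 : P in panel}`` — plus the reverse
complements when the index is bidirectional — with the endmarker suffix of
sequence ``s`` ordering before that of ``t`` iff ``s < t`` (generalized
FM-index tie-breaking).  Because the texts are reversed, an LF step walks a
haplotype *forward*: the record local alphabet of ``v`` is exactly the set
of successors of ``v`` in the panel.

Construction is by explicit suffix sorting.  That is a deliberate choice:
no sub-quadratic construction is attempted; the target scale is panels of
tens of paths where the sort doubles as the structure's specification.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

from .graph import ENDMARKER, PathString, complement_node

Position = Tuple[int, int]  # (node, offset)


class GBWTError(Exception):
    pass


class UnknownNodeError(GBWTError, KeyError):
    pass


class NoPredecessorError(GBWTError):
    """The position is the start of an indexed string: inverse LF undefined."""


@dataclass
class GBWTRecord:
    """One node's BWT slice: local alphabet, outgoing ranks, runs."""

    node: int
    local_alphabet: List[int]          # sorted, strictly increasing
    out_rank: Dict[int, int]           # w -> occurrences of w in records < node
    runs: List[Tuple[int, int]]        # (local char index, length), length >= 1

    @property
    def size(self) -> int:
        return sum(l for _, l in self.runs)

    @property
    def num_runs(self) -> int:
        return len(self.runs)

    def decompress(self) -> List[int]:
        out: List[int] = []
        for ci, l in self.runs:
            out.extend([self.local_alphabet[ci]] * l)
        return out

    def char_at(self, offset: int) -> int:
        pos = 0
        for ci, l in self.runs:
            if offset < pos + l:
                return self.local_alphabet[ci]
            pos += l
        raise IndexError(f"offset {offset} out of record {self.node} (size {pos})")

    def rank_before(self, w: int, offset: int) -> int:
        """Occurrences of ``w`` in the record slice [0, offset) — linear run scan."""
        try:
            ci_w = self.local_alphabet.index(w)
        except ValueError:
            return 0
        n = 0
        pos = 0
        for ci, l in self.runs:
            if pos >= offset:
                break
            if ci == ci_w:
                n += min(l, offset - pos)
            pos += l
        return n

    def count(self, w: int) -> int:
        return self.rank_before(w, self.size)

    def select(self, w: int, q: int) -> int:
        """Offset of the (0-indexed) q-th occurrence of ``w`` in the record."""
        ci_w = self.local_alphabet.index(w)
        pos = 0
        for ci, l in self.runs:
            if ci == ci_w:
                if q < l:
                    return pos + q
                q -= l
            pos += l
        raise IndexError(f"record {self.node} has no occurrence {q} of {w}")

    def run_slices(self) -> Iterator[Tuple[int, int, int]]:
        """Yield (value, start_offset, length) per run."""
        pos = 0
        for ci, l in self.runs:
            yield self.local_alphabet[ci], pos, l
            pos += l

    def validate(self) -> None:
        assert self.local_alphabet == sorted(set(self.local_alphabet))
        assert all(l >= 1 for _, l in self.runs)
        assert all(a != b for (a, _), (b, _) in zip(self.runs, self.runs[1:]))


@dataclass
class SuffixView:
    """Construction-time view of the sorted suffixes (not serialized).

    ``suffixes[rank] = (seq, offset)`` with offset the start position in the
    reversed text; ``positions[rank]`` the (node, offset) BWT position;
    ``lcp[rank]`` the LCP with the suffix above (endmarkers never equal).
    """

    texts: List[List[int]]
    suffixes: List[Tuple[int, int]]
    positions: List[Position]
    lcp: List[int]
    rank_by_suffix: Dict[Tuple[int, int], int]
    text_starts: List[int]  # global (concatenated) text start per sequence

    def global_text_pos(self, seq: int, offset: int) -> int:
        return self.text_starts[seq] + offset

    def symbol(self, gpos: int) -> int:
        # binary search over text_starts
        s = bisect.bisect_right(self.text_starts, gpos) - 1
        return self.texts[s][gpos - self.text_starts[s]]


def _sorted_suffix_entries(texts: List[List[int]]):
    entries = []
    for d, text in enumerate(texts):
        for off in range(len(text)):
            entries.append((tuple(text[off:]), d, off))
    entries.sort()
    return entries


def _lcp_of(a: Tuple[int, ...], b: Tuple[int, ...]) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y or x == ENDMARKER:
            break
        n += 1
    return n


@dataclass
class GBWTIndex:
    records: Dict[int, GBWTRecord]
    num_sequences: int
    bidirectional: bool
    lmax: int
    n: int                              # total text length incl. endmarkers
    r: int                              # runs in the plain concatenated BWT
    o: int                              # GBWT runs (sum of per-record runs)
    seq_lengths: List[int]              # path length per sequence (no endmarker)
    path_start_docs: Dict[Position, int]  # positions reading the endmarker -> doc
    _view: Optional[SuffixView] = field(default=None, repr=False, compare=False)
    _preds: Optional[Dict[int, List[int]]] = field(default=None, repr=False, compare=False)
    _rec_starts: Optional[Tuple[List[int], List[int]]] = field(
        default=None, repr=False, compare=False
    )

    # -- basic accessors ---------------------------------------------------

    @property
    def node_order(self) -> List[int]:
        return sorted(self.records)

    def record(self, v: int) -> GBWTRecord:
        try:
            return self.records[v]
        except KeyError:
            raise UnknownNodeError(v) from None

    def record_size(self, v: int) -> int:
        return self.record(v).size

    def is_occupied(self, pos: Position) -> bool:
        v, i = pos
        return v in self.records and 0 <= i < self.records[v].size

    # -- navigation --------------------------------------------------------

    def _out_rank_resolved(self, v: int, w: int) -> int:
        """BWT.rank(v, w) even when w is not in v's local alphabet: the value
        at the next record after v containing w, saturating at |BWT_w|."""
        rec = self.record(v)
        if w in rec.out_rank:
            return rec.out_rank[w]
        for v2 in self.node_order:
            if v2 <= v:
                continue
            r2 = self.records[v2]
            if w in r2.out_rank:
                return r2.out_rank[w]
        return self.record(w).size  # w never occurs after v: saturate

    def generalized_lf(self, pos: Position, w: int) -> Position:
        """LF((v,i), w) = (w, BWT.rank(v,w) + rank of w in BWT_v[0,i))."""
        v, i = pos
        rec = self.record(v)
        if not (0 <= i <= rec.size):
            raise IndexError(f"offset {i} out of range for record {v}")
        if w not in self.records:
            raise UnknownNodeError(w)
        return (w, self._out_rank_resolved(v, w) + rec.rank_before(w, i))

    def lf_step(self, pos: Position) -> Tuple[Position, bool]:
        """Follow the stored character; at a sequence start, report the
        endmarker-record position of the walk's document."""
        v, i = pos
        rec = self.record(v)
        if not (0 <= i < rec.size):
            raise IndexError(f"unoccupied position {pos}")
        c = rec.char_at(i)
        if c == ENDMARKER:
            return ((ENDMARKER, self.path_start_docs[pos]), True)
        return (self.generalized_lf(pos, c), False)

    def _predecessor_nodes(self, w: int) -> List[int]:
        """Candidate records whose BWT may contain ``w``."""
        if self.bidirectional and w >= 2:
            wbar = complement_node(w)
            if wbar in self.records:
                cands = set()
                for u in self.records[wbar].local_alphabet:
                    cands.add(ENDMARKER if u == ENDMARKER else complement_node(u))
                return sorted(c for c in cands if c in self.records)
            return []
        # unidirectional fallback: scan all records once, cache.
        if self._preds is None:
            preds: Dict[int, List[int]] = {}
            for v in self.node_order:
                for u in self.records[v].local_alphabet:
                    preds.setdefault(u, []).append(v)
            self._preds = preds
        return self._preds.get(w, [])

    def inverse_lf(self, pos: Position) -> Position:
        """The unique occupied q with lf_step(q).position == pos."""
        w, i = pos
        if w == ENDMARKER:
            raise NoPredecessorError(pos)
        if not self.is_occupied(pos):
            raise IndexError(f"unoccupied position {pos}")
        for v in self._predecessor_nodes(w):
            rec = self.records[v]
            start = rec.out_rank.get(w)
            if start is None:
                continue
            cnt = rec.count(w)
            if start <= i < start + cnt:
                return (v, rec.select(w, i - start))
        raise NoPredecessorError(pos)

    def extract(self, seq_id: int) -> PathString:
        """Recover the original (un-reversed) path of a sequence by LF walk."""
        if not (0 <= seq_id < self.num_sequences):
            raise IndexError(f"seq_id {seq_id} out of range")
        nodes: List[int] = []
        pos: Position = (ENDMARKER, seq_id)
        while True:
            c = self.record(pos[0]).char_at(pos[1])
            if c == ENDMARKER:
                break
            nodes.append(c)
            pos = self.generalized_lf(pos, c)
        orientation = (
            "reverse" if self.bidirectional and seq_id % 2 == 1 else "forward"
        )
        return PathString(seq_id=seq_id, nodes=nodes, orientation=orientation)

    def find(self, pattern: Sequence[int]) -> Tuple[Optional[Tuple[Position, Position]], int]:
        """Suffix range of ``pattern`` as a path substring, and its count."""
        if not pattern:
            raise ValueError("empty pattern")
        if ENDMARKER in pattern:
            raise ValueError("pattern may not contain the endmarker")
        v0 = pattern[0]
        if v0 not in self.records:
            return None, 0
        lo: Position = (v0, 0)
        hi: Position = (v0, self.records[v0].size)
        for w in pattern[1:]:
            if w not in self.records:
                return None, 0
            lo = self.generalized_lf(lo, w)
            hi = self.generalized_lf(hi, w)
            if lo[1] >= hi[1]:
                return None, 0
        return (lo, hi), hi[1] - lo[1]

    def _starts(self) -> Tuple[List[int], List[int]]:
        """(node order, global BWT start rank per record), cached."""
        if self._rec_starts is None:
            order = self.node_order
            starts = []
            acc = 0
            for v in order:
                starts.append(acc)
                acc += self.records[v].size
            self._rec_starts = (order, starts)
        return self._rec_starts

    def global_rank(self, pos: Position) -> int:
        order, starts = self._starts()
        idx = bisect.bisect_left(order, pos[0])
        if idx >= len(order) or order[idx] != pos[0]:
            raise UnknownNodeError(pos[0])
        return starts[idx] + pos[1]

    def pos_of_rank(self, rank: int) -> Position:
        order, starts = self._starts()
        idx = bisect.bisect_right(starts, rank) - 1
        return (order[idx], rank - starts[idx])

    def position_below(self, pos: Position) -> Optional[Position]:
        """The next occupied position in global BWT order, or None at the end."""
        v, i = pos
        if i + 1 < self.records[v].size:
            return (v, i + 1)
        order, _ = self._starts()
        idx = bisect.bisect_left(order, v) + 1
        while idx < len(order) and self.records[order[idx]].size == 0:
            idx += 1
        return (order[idx], 0) if idx < len(order) else None

    def position_above(self, pos: Position) -> Optional[Position]:
        v, i = pos
        if i > 0:
            return (v, i - 1)
        order, _ = self._starts()
        idx = bisect.bisect_left(order, v) - 1
        while idx >= 0 and self.records[order[idx]].size == 0:
            idx -= 1
        return (order[idx], self.records[order[idx]].size - 1) if idx >= 0 else None

    def locate_slow(self, pos: Position) -> Tuple[int, int]:
        """Identify the suffix at an occupied position by walking LF to the
        sequence end; returns (seq, offset-in-reversed-text).  Linear in the
        path length — the documented fallback when sampled structures cannot
        answer (the rare 'iterate through the endmarker' case)."""
        count = 0
        while True:
            nxt, at_end = self.lf_step(pos)
            if at_end:
                return (nxt[1], count)
            pos = nxt
            count += 1

    # -- construction-time view (rebuilt on demand after deserialization) --

    def suffix_view(self) -> SuffixView:
        if self._view is None:
            texts = [
                list(reversed(self.extract(s).nodes)) + [ENDMARKER]
                for s in range(self.num_sequences)
            ]
            self._view = _make_view(texts)
        return self._view


def _make_view(texts: List[List[int]]) -> SuffixView:
    entries = _sorted_suffix_entries(texts)
    suffixes = [(d, off) for _, d, off in entries]
    lcp = [0] * len(entries)
    for rank in range(1, len(entries)):
        lcp[rank] = _lcp_of(entries[rank - 1][0], entries[rank][0])
    positions: List[Position] = []
    offset = 0
    prev_first = None
    for tup, _, _ in entries:
        first = tup[0]
        if first != prev_first:
            offset = 0
            prev_first = first
        positions.append((first, offset))
        offset += 1
    starts = []
    acc = 0
    for t in texts:
        starts.append(acc)
        acc += len(t)
    return SuffixView(
        texts=texts,
        suffixes=suffixes,
        positions=positions,
        lcp=lcp,
        rank_by_suffix={s: rk for rk, s in enumerate(suffixes)},
        text_starts=starts,
    )


def build_gbwt(paths: Sequence[PathString], bidirectional: bool = False) -> GBWTIndex:
    """Build the index by explicit suffix sorting of the reversed texts.

    With ``bidirectional=True`` every path contributes two sequences:
    2t (forward) and 2t+1 (its reverse complement).
    """
    if not paths:
        raise GBWTError("cannot build a GBWT from an empty path list")
    seqs: List[PathString] = []
    if bidirectional:
        for t, p in enumerate(paths):
            seqs.append(PathString(seq_id=2 * t, nodes=list(p.nodes), name=p.name))
            seqs.append(p.reverse_complement(seq_id=2 * t + 1))
    else:
        for t, p in enumerate(paths):
            seqs.append(PathString(seq_id=t, nodes=list(p.nodes), name=p.name))

    texts = [list(reversed(p.nodes)) + [ENDMARKER] for p in seqs]
    view = _make_view(texts)

    # Slice the sorted suffixes into per-node records.
    bwt_by_node: Dict[int, List[int]] = {}
    path_start_docs: Dict[Position, int] = {}
    for rank, ((d, off), pos) in enumerate(zip(view.suffixes, view.positions)):
        text = texts[d]
        c = text[off - 1] if off > 0 else text[-1]
        bwt_by_node.setdefault(pos[0], []).append(c)
        if off == 0:
            path_start_docs[pos] = d

    records: Dict[int, GBWTRecord] = {}
    running: Dict[int, int] = {}
    o = 0
    for v in sorted(bwt_by_node):
        body = bwt_by_node[v]
        sigma = sorted(set(body))
        out_rank = {w: running.get(w, 0) for w in sigma}
        runs: List[Tuple[int, int]] = []
        fmap = {w: k for k, w in enumerate(sigma)}
        for c in body:
            ci = fmap[c]
            if runs and runs[-1][0] == ci:
                runs[-1] = (ci, runs[-1][1] + 1)
            else:
                runs.append((ci, 1))
        records[v] = GBWTRecord(node=v, local_alphabet=sigma, out_rank=out_rank, runs=runs)
        o += len(runs)
        for w in sigma:
            running[w] = running.get(w, 0) + records[v].count(w)

    # Plain-BWT run count (runs may merge across record boundaries).
    flat: List[int] = []
    for v in sorted(bwt_by_node):
        flat.extend(bwt_by_node[v])
    r = sum(1 for a, b in zip(flat, flat[1:]) if a != b) + (1 if flat else 0)

    lmax = 2 + max(len(p) for p in seqs)
    index = GBWTIndex(
        records=records,
        num_sequences=len(seqs),
        bidirectional=bidirectional,
        lmax=lmax,
        n=sum(len(t) for t in texts),
        r=r,
        o=o,
        seq_lengths=[len(p) for p in seqs],
        path_start_docs=path_start_docs,
        _view=view,
    )
    return index
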