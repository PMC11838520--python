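"""Auxiliary indexes: sampled document array, FastLocate (phi^-1),
FastLCP (phi + LCP), and FastLF (logarithmic in-record rank).

Suffixes are identified as (seq, offset) pairs with offset the start
position inside the reversed text of the sequence; the linearized key is
``offset + seq * lmax``.  All static predecessor structures are sorted
arrays queried with binary search — any structure meeting the inclusive
predecessor contract would do.

The phi / phi^-1 formulas shift a sampled run-boundary suffix by the key
distance to the query suffix.  When a sequence has no sampled run boundary
at or before the query suffix (it happens, e.g. with duplicated paths whose
run boundaries all fall in one copy), the structures fall back to a slow
walk over the index; tests exercise this path deliberately.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .gbwt import GBWTIndex, Position
from .graph import ENDMARKER

SuffixId = Tuple[int, int]  # (seq, offset-in-reversed-text)


class LastSuffixError(Exception):
    """phi^-1 of the last suffix in BWT order is undefined."""


class FirstSuffixError(Exception):
    """phi of the first suffix in BWT order is undefined."""


# ---------------------------------------------------------------------------
# Document array


@dataclass
class DocArray:
    s: int
    samples: Dict[Position, int]


def build_doc_array(index: GBWTIndex, s: int) -> DocArray:
    if s < 1:
        raise ValueError("sample interval must be >= 1")
    view = index.suffix_view()
    samples: Dict[Position, int] = {}
    for rank in range(0, len(view.suffixes), s):
        samples[view.positions[rank]] = view.suffixes[rank][0]
    # the last position of every path (the position reading its endmarker)
    samples.update(index.path_start_docs)
    return DocArray(s=s, samples=samples)


def locate_da(index: GBWTIndex, da: DocArray, pos: Position) -> int:
    """Document id of the suffix at ``pos``: walk LF until a sample or the
    sequence end."""
    if not index.is_occupied(pos):
        raise IndexError(f"unoccupied position {pos}")
    while True:
        if pos[0] == ENDMARKER:
            return pos[1]
        hit = da.samples.get(pos)
        if hit is not None:
            return hit
        pos, at_end = index.lf_step(pos)
        if at_end:
            return pos[1]


# ---------------------------------------------------------------------------
# Run enumeration shared by FL / FLCP / FLF


def _gbwt_runs(index: GBWTIndex):
    """Yield (run_id, node, start_offset, length, top_rank) per GBWT run,
    in global order."""
    run_id = 0
    for v in index.node_order:
        rec = index.records[v]
        base = index.global_rank((v, 0)) if rec.size else 0
        for _, start, length in rec.run_slices():
            yield run_id, v, start, length, base + start
            run_id += 1


# ---------------------------------------------------------------------------
# FastLocate


@dataclass
class FastLocate:
    lmax: int
    samples: List[SuffixId]        # run id -> suffix at run top
    last_keys: List[int]           # sorted linearized keys of run-bottom suffixes
    last_runids: List[int]         # parallel run ids
    run_base: Dict[int, int]       # node -> global id of its first run
    _index: GBWTIndex = field(repr=False)

    def key(self, x: SuffixId) -> int:
        return x[0] * self.lmax + x[1]


def build_fast_locate(index: GBWTIndex) -> FastLocate:
    view = index.suffix_view()
    samples: List[SuffixId] = []
    bottoms: List[Tuple[int, int]] = []  # (key, run_id)
    lmax = index.lmax
    run_base: Dict[int, int] = {}
    for run_id, v, start, length, top_rank in _gbwt_runs(index):
        run_base.setdefault(v, run_id)
        samples.append(view.suffixes[top_rank])
        d, off = view.suffixes[top_rank + length - 1]
        bottoms.append((d * lmax + off, run_id))
    bottoms.sort()
    return FastLocate(
        lmax=lmax,
        samples=samples,
        last_keys=[k for k, _ in bottoms],
        last_runids=[r for _, r in bottoms],
        run_base=run_base,
        _index=index,
    )


def _stripe_pred(keys: List[int], runids: List[int], lmax: int, x: SuffixId):
    """Inclusive predecessor of x's key among keys of the same sequence."""
    key = x[0] * lmax + x[1]
    idx = bisect.bisect_right(keys, key) - 1
    if idx >= 0 and keys[idx] >= x[0] * lmax:
        return keys[idx] - x[0] * lmax, runids[idx]
    return None


def _bwt_position_of(index: GBWTIndex, x: SuffixId) -> Position:
    """BWT position of a suffix, by walking from its sequence's endmarker slot.
    Slow (linear in path length); used only by fallbacks."""
    d, off = x
    pos: Position = (ENDMARKER, d)
    for _ in range(index.seq_lengths[d] - off):
        pos, _ = index.lf_step(pos)
    return pos


def phi_inv(fl: FastLocate, x: SuffixId) -> SuffixId:
    """The suffix below ``x`` in BWT order (SA successor)."""
    index = fl._index
    pred = _stripe_pred(fl.last_keys, fl.last_runids, fl.lmax, x)
    if pred is not None:
        j_pred, run_id = pred
        if run_id + 1 < len(fl.samples):
            a, b = fl.samples[run_id + 1]
            return (a, b + (x[1] - j_pred))
        if x[1] == j_pred:
            raise LastSuffixError(x)
    # Fallback: locate the position directly and walk to the neighbor below.
    pos = _bwt_position_of(index, x)
    below = index.position_below(pos)
    if below is None:
        raise LastSuffixError(x)
    return index.locate_slow(below)


# ---------------------------------------------------------------------------
# FastLCP


@dataclass
class FastLCP:
    lmax: int
    samples_bot: List[SuffixId]    # run id -> suffix at run bottom
    samples_lcp: List[int]         # run id -> LCP of run-top suffix with the one above
    first_keys: List[int]          # sorted linearized keys of run-top suffixes
    first_runids: List[int]
    _index: GBWTIndex = field(repr=False)


def build_fast_lcp(index: GBWTIndex, fl: FastLocate) -> FastLCP:
    view = index.suffix_view()
    samples_bot: List[SuffixId] = []
    samples_lcp: List[int] = []
    tops: List[Tuple[int, int]] = []
    lmax = index.lmax
    for run_id, v, start, length, top_rank in _gbwt_runs(index):
        samples_bot.append(view.suffixes[top_rank + length - 1])
        samples_lcp.append(view.lcp[top_rank] if top_rank > 0 else 0)
        d, off = view.suffixes[top_rank]
        tops.append((d * lmax + off, run_id))
    tops.sort()
    return FastLCP(
        lmax=lmax,
        samples_bot=samples_bot,
        samples_lcp=samples_lcp,
        first_keys=[k for k, _ in tops],
        first_runids=[r for _, r in tops],
        _index=index,
    )


def phi(flcp: FastLCP, x: SuffixId) -> SuffixId:
    """The suffix above ``x`` in BWT order (SA predecessor)."""
    index = flcp._index
    pred = _stripe_pred(flcp.first_keys, flcp.first_runids, flcp.lmax, x)
    if pred is not None:
        j_pred, run_id = pred
        if run_id > 0:
            a, b = flcp.samples_bot[run_id - 1]
            return (a, b + (x[1] - j_pred))
        if x[1] == j_pred:
            raise FirstSuffixError(x)
    pos = _bwt_position_of(index, x)
    above = index.position_above(pos)
    if above is None:
        raise FirstSuffixError(x)
    return index.locate_slow(above)


def _lcp_by_walk(index: GBWTIndex, pa: Position, pb: Position) -> int:
    """LCP of the suffixes at two BWT positions, comparing record nodes while
    stepping forward in the text with inverse LF.  Fallback path."""
    n = 0
    while True:
        if pa[0] != pb[0] or pa[0] == ENDMARKER:
            return n
        n += 1
        pa = index.inverse_lf(pa)
        pb = index.inverse_lf(pb)


def lcp_above(flcp: FastLCP, x: SuffixId) -> int:
    """LCP of suffix ``x`` with the suffix above it; 0 for the first suffix."""
    index = flcp._index
    pred = _stripe_pred(flcp.first_keys, flcp.first_runids, flcp.lmax, x)
    if pred is not None:
        j_pred, run_id = pred
        if run_id > 0:
            return flcp.samples_lcp[run_id] - (x[1] - j_pred)
        if x[1] == j_pred:
            return 0  # globally first suffix
        # run 0: the chain would anchor at the global first suffix — fall back
    pos = _bwt_position_of(index, x)
    above = index.position_above(pos)
    if above is None:
        return 0
    return _lcp_by_walk(index, above, pos)


# ---------------------------------------------------------------------------
# FastLF


@dataclass
class _RecordRank:
    run_starts: List[int]            # predecessor structure over run starts
    run_vals: List[int]              # value (node char) of each run
    wruns: Dict[int, List[int]]      # value -> run indices containing it
    wcum: Dict[int, List[int]]       # value -> prefix occurrence counts per run
    size: int


@dataclass
class FastLF:
    recs: Dict[int, _RecordRank]
    _index: GBWTIndex = field(repr=False)


def build_fast_lf(index: GBWTIndex) -> FastLF:
    recs: Dict[int, _RecordRank] = {}
    for v in index.node_order:
        rec = index.records[v]
        run_starts: List[int] = []
        run_vals: List[int] = []
        wruns: Dict[int, List[int]] = {}
        wcum: Dict[int, List[int]] = {}
        for t, (val, start, length) in enumerate(rec.run_slices()):
            run_starts.append(start)
            run_vals.append(val)
            cum = wcum.setdefault(val, [0])
            wruns.setdefault(val, []).append(t)
            cum.append(cum[-1] + length)
        recs[v] = _RecordRank(
            run_starts=run_starts, run_vals=run_vals, wruns=wruns, wcum=wcum,
            size=rec.size,
        )
    return FastLF(recs=recs, _index=index)


def _flf_rank_before(rr: _RecordRank, w: int, i: int) -> int:
    """Occurrences of w in the record slice [0, i) via run-value rank."""
    if w not in rr.wruns or i <= 0:
        return 0
    if i >= rr.size:
        return rr.wcum[w][-1]
    t = bisect.bisect_right(rr.run_starts, i) - 1  # run containing i
    idx = bisect.bisect_left(rr.wruns[w], t)
    occ = rr.wcum[w][idx]
    if idx < len(rr.wruns[w]) and rr.wruns[w][idx] == t:
        occ += i - rr.run_starts[t]
    return occ


def _flf_select(rr: _RecordRank, w: int, q: int) -> int:
    cum = rr.wcum[w]
    idx = bisect.bisect_right(cum, q) - 1
    return rr.run_starts[rr.wruns[w][idx]] + (q - cum[idx])


def flf_lf(flf: FastLF, pos: Position, w: int) -> Position:
    """Drop-in replacement for GBWTIndex.generalized_lf."""
    index = flf._index
    v, i = pos
    rr = flf.recs.get(v)
    if rr is None:
        return index.generalized_lf(pos, w)  # raises UnknownNodeError
    if w not in rr.wruns:
        return index.generalized_lf(pos, w)  # shared w-not-local fallback
    return (w, index.records[v].out_rank[w] + _flf_rank_before(rr, w, i))


def flf_inverse_lf(flf: FastLF, pos: Position) -> Position:
    index = flf._index
    w, i = pos
    if w == ENDMARKER:
        return index.inverse_lf(pos)  # raises NoPredecessorError
    for v in index._predecessor_nodes(w):
        rr = flf.recs[v]
        if w not in rr.wruns:
            continue
        start = index.records[v].out_rank[w]
        cnt = rr.wcum[w][-1]
        if start <= i < start + cnt:
            return (v, _flf_select(rr, w, i - start))
    return index.inverse_lf(pos)  # shared boundary/error behavior
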