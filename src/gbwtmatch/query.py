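"""Set-maximal and long match queries on the GBWT.

The query machinery works on ``Q* = rev(Q) . 0``: each suffix of Q* is a
reversed prefix of the query, and *virtually inserting* Q* means computing,
for every suffix k, a position ``a[k]`` in the index adjacent to a suffix
achieving the maximum LCP with suffix k (a matching statistic, computed
without thresholds).  The LCPs with the suffix above and below ``a[k]``
(``lcpa``/``lcpb``) are then computed either by recovering neighbor text
through inverse LF (bidirectional index) or by random access to the text
(compressed text structure).  Set-maximal matches fall out of the scan of
``max(lcpa, lcpb)``; long matches are found by a sweep that maintains the
block of suffixes matching the current query suffix by at least the length
threshold, with a diagonal map recovering match lengths.

Six data-structure bundles are supported, mirroring the supported
combinations of DA / FL / FLCP / FLF / CT:

========================  =========================================
version                   structures required
========================  =========================================
``gbwt+da``               sampled document array (no hap positions)
``gbwt+fl``               FastLocate
``gbwt+fl+flcp``          FastLocate + FastLCP
``flf+fl+flcp``           FastLF for navigation
``flf+fl+flcp+ct``        LCPs via compressed-text access
``gbwt+fl+flcp+ct``       CT for LCPs, record-scan LF
========================  =========================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Set, Tuple

from .aux import (
    DocArray,
    FastLCP,
    FastLocate,
    FastLF,
    FirstSuffixError,
    LastSuffixError,
    SuffixId,
    flf_inverse_lf,
    flf_lf,
    lcp_above,
    locate_da,
    phi,
    phi_inv,
)
from .ctext import CompressedText, ct_access
from .gbwt import GBWTIndex, NoPredecessorError, Position, UnknownNodeError
from .graph import ENDMARKER, Match, PathString

SMEM_VERSIONS = (
    "gbwt+da",
    "gbwt+fl",
    "gbwt+fl+flcp",
    "flf+fl+flcp",
    "flf+fl+flcp+ct",
    "gbwt+fl+flcp+ct",
)
LONG_VERSIONS = (
    "gbwt+fl+flcp",
    "flf+fl+flcp",
    "flf+fl+flcp+ct",
    "gbwt+fl+flcp+ct",
)

_NEEDS = {
    "gbwt+da": ("da",),
    "gbwt+fl": ("fl",),
    "gbwt+fl+flcp": ("fl", "flcp"),
    "flf+fl+flcp": ("flf", "fl", "flcp"),
    "flf+fl+flcp+ct": ("flf", "fl", "flcp", "ct"),
    "gbwt+fl+flcp+ct": ("fl", "flcp", "ct"),
}


class ConfigurationError(Exception):
    """A query version was asked for without the structures it needs."""


@dataclass
class QueryStructures:
    """The index plus whichever auxiliary structures have been built."""

    index: GBWTIndex
    da: Optional[DocArray] = None
    fl: Optional[FastLocate] = None
    flcp: Optional[FastLCP] = None
    flf: Optional[FastLF] = None
    ct: Optional[CompressedText] = None

    def check(self, version: str, valid: Sequence[str]) -> None:
        if version not in valid:
            raise ConfigurationError(
                f"version {version!r} not supported here; choose from {list(valid)}"
            )
        missing = [name for name in _NEEDS[version] if getattr(self, name) is None]
        if missing:
            raise ConfigurationError(
                f"version {version!r} requires structures {list(_NEEDS[version])}; "
                f"missing: {missing}"
            )


@dataclass
class Counters:
    """Per-stage operation counts (instrumentation for complexity contracts)."""

    lf: int = 0
    inverse_lf: int = 0
    phi: int = 0
    phi_inv: int = 0
    lcp: int = 0
    text_access: int = 0
    slow_locates: int = 0


class _Nav:
    """Navigation facade: counts operations and dispatches LF / inverse LF to
    either the plain records or the FastLF structure."""

    def __init__(self, structures: QueryStructures, use_flf: bool):
        self.s = structures
        self.index = structures.index
        self.use_flf = use_flf
        self.counters = Counters()

    def lf(self, pos: Position, w: int) -> Position:
        self.counters.lf += 1
        if self.use_flf:
            return flf_lf(self.s.flf, pos, w)
        return self.index.generalized_lf(pos, w)

    def inverse_lf(self, pos: Position) -> Position:
        self.counters.inverse_lf += 1
        if self.use_flf:
            return flf_inverse_lf(self.s.flf, pos)
        return self.index.inverse_lf(pos)

    def phi(self, x: SuffixId) -> SuffixId:
        self.counters.phi += 1
        return phi(self.s.flcp, x)

    def phi_inv(self, x: SuffixId) -> SuffixId:
        self.counters.phi_inv += 1
        return phi_inv(self.s.fl, x)

    def lcp_above(self, x: SuffixId) -> int:
        self.counters.lcp += 1
        return lcp_above(self.s.flcp, x)

    def access(self, gpos: int) -> int:
        self.counters.text_access += 1
        return ct_access(self.s.ct, gpos)


@dataclass
class VirtualInsertion:
    """Per-suffix insertion positions for Q* = rev(Q) . 0, with optional
    tracked suffix identities and neighbor LCP arrays."""

    qstar: List[int]
    a: List[Position]
    s: Optional[List[Optional[SuffixId]]] = None
    lcpa: Optional[List[int]] = None
    lcpb: Optional[List[int]] = None

    def max_lcp(self, k: int) -> int:
        return max(self.lcpa[k], self.lcpb[k])


def _qstar(Q: Sequence[int]) -> List[int]:
    return list(reversed(list(Q))) + [ENDMARKER]


def virtual_insert(nav: _Nav, Q: Sequence[int]) -> VirtualInsertion:
    """Positions only; exactly |Q*|-1 generalized-LF calls."""
    qstar = _qstar(Q)
    m = len(qstar)
    a: List[Position] = [None] * m  # type: ignore[list-item]
    a[m - 1] = (ENDMARKER, 0)
    for k in range(m - 1, 0, -1):
        c = qstar[k - 1]
        try:
            a[k - 1] = nav.lf(a[k], c)
        except UnknownNodeError:
            a[k - 1] = (ENDMARKER, 0)  # restart: node absent from the index
    return VirtualInsertion(qstar=qstar, a=a)


def _first_value_run_at_or_after(index: GBWTIndex, v: int, offset: int, w: int):
    """(run start offset, global run id) of the first w-valued run starting at
    or after ``offset`` in record v, or None."""
    from .aux import _gbwt_runs  # noqa: F401 (documentation pointer)

    rec = index.records[v]
    local = 0
    for val, start, _length in rec.run_slices():
        if val == w and start >= offset:
            return start, local
        local += 1
    return None


def _lf_with_suffix(
    nav: _Nav, pos: Position, w: int, s: Optional[SuffixId]
) -> Tuple[Position, Optional[SuffixId]]:
    """One generalized LF step that also maintains the identity of the suffix
    at the resulting position (None when the result is one-past-the-end)."""
    index = nav.index
    fl = nav.s.fl
    newpos = nav.lf(pos, w)
    v, i = pos
    rec = index.records.get(v)
    size_w = index.records[w].size
    if newpos[1] >= size_w:
        return newpos, None
    if rec is not None and i < rec.size and s is not None and rec.char_at(i) == w:
        return newpos, (s[0], s[1] - 1)
    hit = _first_value_run_at_or_after(index, v, i, w) if rec is not None else None
    if hit is not None:
        _start, local_run = hit
        top = fl.samples[fl.run_base[v] + local_run]
        return newpos, (top[0], top[1] - 1)
    # Result position is fed by a later record: identify it the slow way.
    nav.counters.slow_locates += 1
    return newpos, index.locate_slow(newpos)


def virtual_insert_tracked(nav: _Nav, Q: Sequence[int]) -> VirtualInsertion:
    """Virtual insertion that also tracks the suffix at each a[k]."""
    fl = nav.s.fl
    if fl is None:
        raise ConfigurationError("tracked virtual insertion requires FastLocate")
    index = nav.index
    qstar = _qstar(Q)
    m = len(qstar)
    a: List[Position] = [None] * m  # type: ignore[list-item]
    s: List[Optional[SuffixId]] = [None] * m
    a[m - 1] = (ENDMARKER, 0)
    s[m - 1] = fl.samples[0]  # suffix at the top of the endmarker record
    for k in range(m - 1, 0, -1):
        c = qstar[k - 1]
        try:
            a[k - 1], s[k - 1] = _lf_with_suffix(nav, a[k], c, s[k])
        except UnknownNodeError:
            a[k - 1] = (ENDMARKER, 0)
            s[k - 1] = fl.samples[0]  # re-seed from the endmarker record sample
    return VirtualInsertion(qstar=qstar, a=a, s=s)


# ---------------------------------------------------------------------------
# LCP computation (two methods with identical contracts)


def _lcp_vs_query_by_walk(nav: _Nav, pos: Position, qstar: List[int], k: int) -> int:
    """LCP of the suffix at ``pos`` with suffix k of Q*, reading neighbor text
    through inverse LF; endmarkers never match."""
    n = 0
    while True:
        sym = pos[0]
        if sym == ENDMARKER or sym != qstar[k + n]:
            return n
        n += 1
        pos = nav.inverse_lf(pos)


def compute_lcps_bidirectional(nav: _Nav, vi: VirtualInsertion) -> VirtualInsertion:
    """Fill lcpa/lcpb by recovering neighbor suffix text via inverse LF.

    Requires a bidirectional index for the efficient inverse LF; on a
    unidirectional index the slower predecessor-scan inverse LF is used.
    """
    index = nav.index
    m = len(vi.qstar)
    lcpa = [0] * m
    lcpb = [0] * m
    for k in range(m):
        v, i = vi.a[k]
        rec = index.records.get(v)
        size = rec.size if rec is not None else 0
        if i >= 1:
            lcpa[k] = _lcp_vs_query_by_walk(nav, (v, i - 1), vi.qstar, k)
        if i < size:
            lcpb[k] = _lcp_vs_query_by_walk(nav, (v, i), vi.qstar, k)
    vi.lcpa, vi.lcpb = lcpa, lcpb
    return vi


def _lcp_vs_query_by_text(
    nav: _Nav, x: SuffixId, qstar: List[int], k: int
) -> int:
    """LCP of suffix ``x`` with suffix k of Q*, by compressed-text access."""
    ct = nav.s.ct
    g = ct.text_starts[x[0]] + x[1]
    n = 0
    while True:
        sym = nav.access(g + n)
        if sym == ENDMARKER or sym != qstar[k + n]:
            return n
        n += 1


def _suffix_above(nav: _Nav, k: int, vi: VirtualInsertion) -> Optional[SuffixId]:
    """Identity of the suffix just above a[k], or None when a[k] is at the top
    of its record (callers treat lcpa = 0 there)."""
    index = nav.index
    fl, flcp = nav.s.fl, nav.s.flcp
    v, i = vi.a[k]
    if i == 0:
        return None
    rec = index.records.get(v)
    if rec is None:
        return None
    if i >= rec.size:
        last_run = fl.run_base[v] + rec.num_runs - 1
        return flcp.samples_bot[last_run]
    s = vi.s[k]
    if s is None:  # occupied position whose identity was not tracked
        nav.counters.slow_locates += 1
        s = index.locate_slow((v, i))
    try:
        return nav.phi(s)
    except FirstSuffixError:
        return None


def compute_lcps_text(nav: _Nav, vi: VirtualInsertion) -> VirtualInsertion:
    """Same lcpa/lcpb contract as :func:`compute_lcps_bidirectional`, reading
    symbols with compressed-text random access; works on any index."""
    index = nav.index
    m = len(vi.qstar)
    lcpa = [0] * m
    lcpb = [0] * m
    for k in range(m):
        v, i = vi.a[k]
        rec = index.records.get(v)
        size = rec.size if rec is not None else 0
        if i < size:
            s = vi.s[k]
            if s is None:
                nav.counters.slow_locates += 1
                s = index.locate_slow((v, i))
            lcpb[k] = _lcp_vs_query_by_text(nav, s, vi.qstar, k)
        above = _suffix_above(nav, k, vi)
        if above is not None:
            lcpa[k] = _lcp_vs_query_by_text(nav, above, vi.qstar, k)
    vi.lcpa, vi.lcpb = lcpa, lcpb
    return vi


# ---------------------------------------------------------------------------
# Set-maximal match query


def _forward_coords(qlen: int, k: int, length: int) -> int:
    """Q* interval [k, k+length) -> forward query start index."""
    return qlen - k - length


def _hap_start(index: GBWTIndex, x: SuffixId, length: int) -> int:
    """Occurrence start on the forward haplotype for a match of ``length``
    node-characters beginning at suffix ``x`` of the reversed text."""
    return index.seq_lengths[x[0]] - x[1] - length


def _emission_points(vi: VirtualInsertion) -> List[Tuple[int, int]]:
    """(k, M) pairs at which a set-maximal match ends, per the scan rule
    M_k >= M_{k-1} (the next-longer reversed prefix cannot cover it)."""
    out = []
    m = len(vi.qstar)
    for k in range(m):
        M = vi.max_lcp(k)
        if M <= 0:
            continue
        if k == 0 or M >= vi.max_lcp(k - 1):
            out.append((k, M))
    return out


def _smem_emit_da(nav: _Nav, vi: VirtualInsertion, Q: Sequence[int]) -> List[Match]:
    """GBWT+DA output: find the pattern range, locate each position's document.
    Haplotype start positions are not recoverable from document samples."""
    index, da = nav.index, nav.s.da
    qlen = len(Q)
    out: List[Match] = []
    for k, M in _emission_points(vi):
        i_f = _forward_coords(qlen, k, M)
        rng, count = index.find(list(Q[i_f : i_f + M]))
        nav.counters.lf += max(0, M - 1)  # LF steps inside find
        assert rng is not None and count > 0
        (v, lo), (_, hi) = rng
        for off in range(lo, hi):
            hap = locate_da(index, da, (v, off))
            out.append(Match(hap=hap, i=i_f, j=None, k=M))
    return out


def _find_tracked(
    nav: _Nav, pattern: Sequence[int]
) -> Tuple[Tuple[Position, Position], SuffixId]:
    """find() that also returns the identity of the suffix at the range start."""
    index, fl = nav.index, nav.s.fl
    v0 = pattern[0]
    rec = index.records[v0]
    lo: Position = (v0, 0)
    hi: Position = (v0, rec.size)
    s: Optional[SuffixId] = fl.samples[fl.run_base[v0]]
    for w in pattern[1:]:
        lo, s = _lf_with_suffix(nav, lo, w, s)
        hi = nav.lf(hi, w)
    assert s is not None and lo[1] < hi[1]
    return (lo, hi), s


def _smem_emit_fl(nav: _Nav, vi: VirtualInsertion, Q: Sequence[int]) -> List[Match]:
    """GBWT+FL output: track the suffix during find, then walk phi^-1 down the
    range; haplotype start positions are recovered from the suffix samples."""
    index = nav.index
    qlen = len(Q)
    out: List[Match] = []
    for k, M in _emission_points(vi):
        i_f = _forward_coords(qlen, k, M)
        (lo, hi), s = _find_tracked(nav, list(Q[i_f : i_f + M]))
        cur = s
        for off in range(lo[1], hi[1]):
            out.append(
                Match(hap=cur[0], i=i_f, j=_hap_start(index, cur, M), k=M)
            )
            if off + 1 < hi[1]:
                cur = nav.phi_inv(cur)
    return out


def _smem_emit_flcp(nav: _Nav, vi: VirtualInsertion, Q: Sequence[int]) -> List[Match]:
    """FLCP output: no find; iterate up and down from the tracked suffix with
    phi / phi^-1, keeping the running minimum LCP with the query."""
    index = nav.index
    qlen = len(Q)
    out: Set[Match] = set()
    for k, M in _emission_points(vi):
        i_f = _forward_coords(qlen, k, M)

        def emit(x: SuffixId) -> None:
            out.add(Match(hap=x[0], i=i_f, j=_hap_start(index, x, M), k=M))

        # downward: the suffix at a[k] and below
        v, i = vi.a[k]
        rec = index.records.get(v)
        size = rec.size if rec is not None else 0
        if i < size and vi.lcpb[k] == M:
            cur = vi.s[k]
            if cur is None:
                nav.counters.slow_locates += 1
                cur = index.locate_slow((v, i))
            curlcp = vi.lcpb[k]
            while True:
                emit(cur)
                try:
                    nxt = nav.phi_inv(cur)
                except LastSuffixError:
                    break
                curlcp = min(curlcp, nav.lcp_above(nxt))
                if curlcp < M:
                    break
                cur = nxt
        # upward: the suffix above a[k] and further up
        if vi.lcpa[k] == M:
            cur = _suffix_above(nav, k, vi)
            curlcp = vi.lcpa[k]
            while cur is not None:
                emit(cur)
                step = min(curlcp, nav.lcp_above(cur))
                if step < M:
                    break
                try:
                    cur = nav.phi(cur)
                except FirstSuffixError:
                    break
                curlcp = step
    return sorted(out, key=lambda m: (m.i, m.hap, -1 if m.j is None else m.j))


def set_maximal_query(
    structures: QueryStructures,
    Q: PathString,
    version: str = "gbwt+fl+flcp",
) -> Tuple[List[Match], Counters]:
    """All set-maximal matches of ``Q`` against the indexed panel.

    Every version returns the same (hap, i, k) multiset; versions with
    suffix-array samples additionally report the haplotype start j.
    """
    structures.check(version, SMEM_VERSIONS)
    nav = _Nav(structures, use_flf=version.startswith("flf"))
    if version == "gbwt+da":
        vi = virtual_insert(nav, Q.nodes)
        compute_lcps_bidirectional(nav, vi)
        matches = _smem_emit_da(nav, vi, Q.nodes)
    elif version == "gbwt+fl":
        vi = virtual_insert_tracked(nav, Q.nodes)
        compute_lcps_bidirectional(nav, vi)
        matches = _smem_emit_fl(nav, vi, Q.nodes)
    else:
        vi = virtual_insert_tracked(nav, Q.nodes)
        if version.endswith("ct"):
            compute_lcps_text(nav, vi)
        else:
            compute_lcps_bidirectional(nav, vi)
        matches = _smem_emit_flcp(nav, vi, Q.nodes)
    matches = sorted(
        set(matches) if version not in ("gbwt+da",) else matches,
        key=lambda m: (m.i, m.hap, -1 if m.j is None else m.j),
    )
    return matches, nav.counters


# ---------------------------------------------------------------------------
# Long match query


def _length_thresholds(
    qstar: List[int], L: float, weight_fn: Optional[Callable[[int], float]]
) -> List[int]:
    """Per-suffix minimal match length L_i: the smallest l such that the
    weight of Q*[i, i+l) reaches L (node count when weight_fn is None).
    A sentinel larger than the query excludes suffixes that can never reach L.
    """
    m = len(qstar)
    sentinel = m + 1
    if weight_fn is None:
        if L < 1:
            raise ValueError("L must be >= 1")
        return [int(L)] * m
    w = [0.0] * m
    for i in range(m - 1):  # the endmarker weighs nothing
        wi = float(weight_fn(qstar[i]))
        if wi < 0:
            raise ValueError(f"negative weight for node {qstar[i]}")
        w[i] = wi
    pre = [0.0] * (m + 1)
    for i in range(m):
        pre[i + 1] = pre[i] + w[i]
    out = [sentinel] * m
    e = 0
    for i in range(m):
        if e < i + 1:
            e = i + 1
        while e <= m - 1 and pre[e] - pre[i] < L:
            e += 1
        if pre[e] - pre[i] >= L:
            out[i] = e - i
        # pointer e never moves left as i advances (two-pointer scan)
    return out


@dataclass
class _Block:
    """The live block [f, g) of suffixes matching the current query suffix by
    at least the threshold, in the record of the current query symbol."""

    node: int
    f: int
    ids: List[SuffixId] = field(default_factory=list)

    @property
    def g(self) -> int:
        return self.f + len(self.ids)


def long_match_query(
    structures: QueryStructures,
    Q: PathString,
    L: float,
    version: str = "gbwt+fl+flcp",
    weight_fn: Optional[Callable[[int], float]] = None,
) -> Tuple[List[Match], Counters]:
    """All locally maximal matches of ``Q`` against the panel whose length in
    node-characters (or total node weight, with ``weight_fn``) is at least L.

    Sweep from the last suffix of Q* to the first, maintaining the block of
    index suffixes matching the current suffix by >= L_i, a diagonal map from
    (suffix key - query index) to the match's right end, and emitting a match
    whenever a suffix leaves the block.
    """
    structures.check(version, LONG_VERSIONS)
    nav = _Nav(structures, use_flf=version.startswith("flf"))
    index = structures.index
    lmax = index.lmax

    vi = virtual_insert_tracked(nav, Q.nodes)
    if version.endswith("ct"):
        compute_lcps_text(nav, vi)
    else:
        compute_lcps_bidirectional(nav, vi)

    qstar = vi.qstar
    m = len(qstar)
    qlen = len(Q.nodes)
    thresholds = _length_thresholds(qstar, L, weight_fn)

    def key(x: SuffixId) -> int:
        return x[0] * lmax + x[1]

    diag: Dict[int, int] = {}  # (suffix key - query index) -> match right end
    block: Optional[_Block] = None
    out: List[Match] = []

    def emit(x: SuffixId, i_end: int) -> None:
        start = diag.pop(key(x) - i_end)
        length = start - i_end
        i_f = _forward_coords(qlen, i_end, length)
        j_f = _hap_start(index, x, length)
        weight = (
            sum(weight_fn(v) for v in Q.nodes[i_f : i_f + length])
            if weight_fn is not None
            else None
        )
        out.append(Match(hap=x[0], i=i_f, j=j_f, k=length, weight=weight))

    def extend(blk: _Block, L_cur: int, i_cur: int, m_top: float, m_bot: float) -> None:
        """Grow the block over adjacent suffixes still matching >= L_cur.
        m_top/m_bot are the query-LCPs of the boundary members (inf for
        members persisting from the previous block)."""
        while blk.ids:
            top = blk.ids[0]
            la = nav.lcp_above(top)
            entry = min(m_top, la)
            if entry < L_cur:
                break
            newtop = nav.phi(top)
            blk.ids.insert(0, newtop)
            blk.f -= 1
            diag[key(newtop) - i_cur] = i_cur + int(entry)
            m_top = entry
        while blk.ids:
            bot = blk.ids[-1]
            try:
                nxt = nav.phi_inv(bot)
            except LastSuffixError:
                break
            lb = nav.lcp_above(nxt)
            entry = min(m_bot, lb)
            if entry < L_cur:
                break
            blk.ids.append(nxt)
            diag[key(nxt) - i_cur] = i_cur + int(entry)
            m_bot = entry

    INF = float("inf")
    for i in range(m - 1, 0, -1):
        c = qstar[i - 1]
        i_cur = i - 1
        L_cur = thresholds[i_cur]
        # 1. emit leavers and push the survivors through LF
        if block is not None and block.ids:
            rec = index.records[block.node]
            kept: List[SuffixId] = []
            pos = 0
            chars: List[int] = []
            for val, start, length in rec.run_slices():
                lo = max(start, block.f)
                hi = min(start + length, block.g)
                if lo < hi:
                    chars.extend([val] * (hi - lo))
            for x, ch in zip(block.ids, chars):
                if ch == c:
                    kept.append((x[0], x[1] - 1))
                else:
                    emit(x, i)
            if kept and c in index.records:
                newf = nav.lf((block.node, block.f), c)
                nav.lf((block.node, block.g), c)  # range arithmetic (g image)
                block = _Block(node=c, f=newf[1], ids=kept)
            else:
                block = None
        else:
            block = None
        # 2. re-seed from the virtual insertion when empty
        if block is None or not block.ids:
            if max(vi.lcpa[i_cur], vi.lcpb[i_cur]) >= L_cur:
                v, off = vi.a[i_cur]
                block = _Block(node=v, f=off, ids=[])
                m_top: float = INF
                m_bot: float = INF
                if vi.lcpb[i_cur] >= L_cur:
                    s0 = vi.s[i_cur]
                    if s0 is None:
                        nav.counters.slow_locates += 1
                        s0 = index.locate_slow((v, off))
                    block.ids.append(s0)
                    diag[key(s0) - i_cur] = i_cur + vi.lcpb[i_cur]
                    m_bot = vi.lcpb[i_cur]
                if vi.lcpa[i_cur] >= L_cur:
                    above = _suffix_above(nav, i_cur, vi)
                    if above is not None:
                        block.ids.insert(0, above)
                        block.f -= 1
                        diag[key(above) - i_cur] = i_cur + vi.lcpa[i_cur]
                        m_top = vi.lcpa[i_cur]
                if block.ids:
                    extend(block, L_cur, i_cur, m_top, m_bot)
                else:
                    block = None
            else:
                block = None
        else:
            # 3. extend the LF image over newly qualifying adjacent suffixes
            extend(block, L_cur, i_cur, INF, INF)

    # 4. flush: matches alive at the first suffix of Q* reach the query end
    if block is not None:
        for x in block.ids:
            emit(x, 0)
    assert not diag, "diagonal map must empty with the block"
    return (
        sorted(out, key=lambda mt: (mt.i, mt.hap, -1 if mt.j is None else mt.j)),
        nav.counters,
    )


# ---------------------------------------------------------------------------
# One-vs-all / all-vs-all drivers


def query_vs_panel_all(
    structures: QueryStructures,
    mode: str = "smem",
    L: Optional[float] = None,
    version: Optional[str] = None,
    weight_fn: Optional[Callable[[int], float]] = None,
    forward_only: bool = False,
) -> List[Tuple[int, Match]]:
    """Run the one-vs-all query for every indexed path and pool the results.

    The trivial full-length self-match of each path (and, on a bidirectional
    index, the mirrored full-length match to the path's opposite-orientation
    twin) is discarded.  With ``forward_only`` on a bidirectional index, only
    forward-orientation sequences are queried.
    """
    index = structures.index
    if version is None:
        version = "gbwt+fl+flcp"
    out: List[Tuple[int, Match]] = []
    for t in range(index.num_sequences):
        if forward_only and index.bidirectional and t % 2 == 1:
            continue
        Q = index.extract(t)
        if mode == "smem":
            matches, _ = set_maximal_query(structures, Q, version=version)
        elif mode == "long":
            if L is None:
                raise ValueError("mode='long' needs L")
            matches, _ = long_match_query(
                structures, Q, L, version=version, weight_fn=weight_fn
            )
        else:
            raise ValueError(f"unknown mode {mode!r}")
        twin = t ^ 1 if index.bidirectional else None
        for mt in matches:
            if mt.hap == t and mt.i == mt.j and mt.k == len(Q.nodes):
                continue
            if twin is not None and mt.hap == twin and mt.k == len(Q.nodes):
                continue
            out.append((t, mt))
    return out
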