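"""Compressed random access to the concatenated reversed texts.

A leveled block structure in the spirit of the r-index block-tree variant:
sampled text locations are the text positions of GBWT run-top suffixes; at
every level each surviving sample keeps four non-overlapping half blocks
covering a window around it; a half block either points to an identical
occurrence inside some next-level sample's window (equal-content half
blocks share one target) or, at the bottom level, stores its symbols
explicitly.  Samples a level's half blocks never map to are pruned from the
next level.  A half block whose content has no occurrence near any sample
is stored literally; this keeps access exact on degenerate inputs at some
space cost.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .gbwt import GBWTIndex

LEAF_HALF = 4  # half-block size at or below which symbols are stored literally


@dataclass
class _HalfBlock:
    start: int                       # absolute text start of the half block
    length: int
    leaf: Optional[Tuple[int, ...]]  # explicit symbols, or None
    target: Optional[int]            # absolute start of the mapped occurrence


@dataclass
class _Level:
    half: int                               # half-block length at this level
    sample_pos: List[int]                   # sorted surviving sample positions
    blocks: Dict[int, List[_HalfBlock]]     # sample position -> 4 half blocks


@dataclass
class CompressedText:
    n: int
    levels: List[_Level]
    text_starts: List[int] = field(default_factory=list)  # per-seq global starts


def _window_blocks(pos: int, half: int, n: int) -> List[Tuple[int, int]]:
    """Four non-overlapping half-block intervals around a sample, clipped."""
    out = []
    for k in (-2, -1, 0, 1):
        s = pos + k * half
        e = s + half
        s, e = max(0, s), min(n, e)
        if s < e:
            out.append((s, e - s))
    return out


def build_compressed_text(
    index: GBWTIndex, texts: Optional[List[List[int]]] = None
) -> CompressedText:
    view = index.suffix_view()
    if texts is None:
        texts = view.texts
    flat: List[int] = []
    starts: List[int] = []
    for t in texts:
        starts.append(len(flat))
        flat.extend(t)
    n = len(flat)

    # Run-top-aligned sampled text locations.
    from .aux import _gbwt_runs  # local import to avoid a cycle

    base_samples = sorted(
        {
            view.global_text_pos(*view.suffixes[top_rank])
            for _, _, _, _, top_rank in _gbwt_runs(index)
        }
    )
    if not base_samples:
        base_samples = [0]

    # Top-level half size: every position must fall inside some sample window.
    def max_gap(samples: List[int]) -> int:
        g = max(samples[0] - 0, (n - 1) - samples[-1])
        for a, b in zip(samples, samples[1:]):
            g = max(g, (b - a) // 2 + (b - a) % 2)
        return g

    half = 1
    need = max(1, max_gap(base_samples))
    while 2 * half < need + 1:
        half *= 2

    levels: List[_Level] = []
    cur_samples = list(base_samples)
    while True:
        blocks: Dict[int, List[_HalfBlock]] = {}
        mapped_to: set = set()
        memo: Dict[Tuple[int, ...], int] = {}
        leaf_level = half <= LEAF_HALF
        next_half = half // 2
        for sp in cur_samples:
            hbs = []
            for s, ln in _window_blocks(sp, half, n):
                content = tuple(flat[s : s + ln])
                if leaf_level:
                    hbs.append(_HalfBlock(start=s, length=ln, leaf=content, target=None))
                    continue
                tgt = None
                if _any_covering_sample(base_samples, next_half, s, ln, n) is not None:
                    tgt = s  # the half block already sits inside a sample window
                else:
                    tgt = memo.get(content)
                    if tgt is None:
                        tgt = _find_occurrence(flat, content, base_samples, next_half, n)
                        if tgt is not None:
                            memo[content] = tgt
                if tgt is None:
                    hbs.append(_HalfBlock(start=s, length=ln, leaf=content, target=None))
                else:
                    hbs.append(_HalfBlock(start=s, length=ln, leaf=None, target=tgt))
                    cand = _any_covering_sample(base_samples, next_half, tgt, ln, n)
                    assert cand is not None
                    mapped_to.add(cand)
            blocks[sp] = hbs
        levels.append(_Level(half=half, sample_pos=sorted(blocks), blocks=blocks))
        if leaf_level:
            break
        cur_samples = sorted(mapped_to)
        half = next_half
        if not cur_samples:
            # nothing mapped forward: force leaves next round on base samples
            cur_samples = list(base_samples)
            half = LEAF_HALF
    return CompressedText(n=n, levels=levels, text_starts=starts)


def _covers(sample: int, half: int, s: int, ln: int, n: int) -> bool:
    """True if [s, s+ln) lies inside one of the sample's four half blocks."""
    for bs, bl in _window_blocks(sample, half, n):
        if bs <= s and s + ln <= bs + bl:
            return True
    return False


def _any_covering_sample(
    samples: List[int], half: int, s: int, ln: int, n: int
) -> Optional[int]:
    lo = bisect.bisect_left(samples, s - 2 * half)
    hi = bisect.bisect_right(samples, s + ln + 2 * half)
    for cand in samples[lo:hi]:
        if _covers(cand, half, s, ln, n):
            return cand
    return None


def _find_occurrence(
    flat: List[int], content: Tuple[int, ...], samples: List[int], half: int, n: int
) -> Optional[int]:
    """An occurrence of ``content`` contained in some sample's next-level
    window, or None."""
    ln = len(content)
    seen = set()
    for sp in samples:
        for t in range(max(0, sp - 2 * half), min(sp + 2 * half, n) - ln + 1):
            if t in seen:
                continue
            seen.add(t)
            if tuple(flat[t : t + ln]) == content and _covers(sp, half, t, ln, n):
                return t
    return None


def ct_access(ct: CompressedText, global_pos: int) -> int:
    """The symbol of the concatenated reversed-texts-with-endmarkers at
    ``global_pos``."""
    if not (0 <= global_pos < ct.n):
        raise IndexError(f"text position {global_pos} out of [0, {ct.n})")
    pos = global_pos
    for level in ct.levels:
        hb = _covering_block(level, pos)
        if hb.leaf is not None:
            return hb.leaf[pos - hb.start]
        pos = hb.target + (pos - hb.start)
    raise AssertionError("bottom level must be explicit")


def _covering_block(level: _Level, pos: int) -> _HalfBlock:
    lo = bisect.bisect_left(level.sample_pos, pos - 2 * level.half)
    hi = bisect.bisect_right(level.sample_pos, pos + 2 * level.half)
    for sp in level.sample_pos[lo:hi]:
        for hb in level.blocks[sp]:
            if hb.start <= pos < hb.start + hb.length:
                return hb
    raise AssertionError(f"position {pos} not covered at level half={level.half}")
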