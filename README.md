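# gbwtmatch

Haplotype matching on the **graph Burrows–Wheeler transform (GBWT)**: index a
panel of haplotypes stored as paths through a pangenome graph, then report
**set-maximal matches** (the graph analogue of maximal exact matches / PBWT
set-maximal matches) and **long matches** (locally maximal matches above a
length or base-pair threshold) between a query path and the panel — the core
primitive behind IBD-segment detection, genealogical search and imputation on
graph-based haplotype panels.

## The model

A pangenome graph is a node-labelled graph `(V, E, seq)`; a haplotype is a
*path-string* `P ∈ V*`, and its DNA sequence is the concatenation of node
labels along the path.  Node-characters act both as alphabet symbols and as
graph positions, so path-string matches are positionless in the strings but
positionally anchored in the graph.

The **GBWT-Index** is a run-length-compressed multi-string BWT of the
*reversed* path-strings (plus reverse complements in a bidirectional index).
The BWT is partitioned into per-node *records*: record `BWT_v` holds the BWT
slice whose suffixes begin with `v`, stored as runs over its local alphabet
`Σ_v` together with the outgoing rank offsets `BWT.rank(v, w)`.  Generalized
LF is

```
LF((v, i), w) = (w, BWT.rank(v, w) + rank_w(BWT_v[0, i)))
```

On top of the index, four r-index-style structures are provided:

| structure | contents | provides |
|---|---|---|
| DA | sampled document array | locate (haplotype id) |
| FastLocate (FL) | suffix samples at run tops + predecessor on run bottoms | φ⁻¹ (SA successor) |
| FastLCP (FLCP) | suffix samples at run bottoms, LCP samples at run tops | φ, LCP with suffix above |
| FastLF (FLF) | run-value rank structures per record | logarithmic LF / inverse LF |
| CompressedText (CT) | leveled half-block structure over the text | random access without bidirectionality |

Queries *virtually insert* `Q* = rev(Q)·0`: one LF step per query node yields,
for every suffix of Q*, a position whose neighbors achieve the maximal LCP with
the query — matching statistics without thresholds.  Set-maximal matches are
emitted where the per-suffix maximum LCP stops decreasing; long matches are
found by sweeping a block of suffixes matching the current query suffix by at
least `L`, with a diagonal map recovering each match's length when its suffix
leaves the block.  Five set-maximal query versions and four long-match
variants cover the different structure bundles; an additive non-negative
weight function (default: node label length in base pairs) turns the length
threshold into a base-pair threshold.

## Worked example

The bundled toy panel has five nodes labelled `A, CC, G, T, GG` and three
haplotypes `P0 = 1→2→3→4`, `P1 = 1→2→5→4`, `P2 = 1→2→3→4`:

```python
from gbwtmatch import *

g = PangenomeGraph()
for seg, lab in [(1, "A"), (2, "CC"), (3, "G"), (4, "T"), (5, "GG")]:
    g.add_node(encode_node(seg), lab)
P = lambda sid, segs: PathString(seq_id=sid, nodes=[encode_node(s) for s in segs])
paths = [P(0, [1, 2, 3, 4]), P(1, [1, 2, 5, 4]), P(2, [1, 2, 3, 4])]

index = build_gbwt(paths)
fl = build_fast_locate(index)
st = QueryStructures(index=index, fl=fl, flcp=build_fast_lcp(index, fl))

Q = P(0, [1, 2, 5, 4])
print(set_maximal_query(st, Q)[0])
print(long_match_query(st, Q, 2)[0])
print(long_match_query(st, Q, 4, weight_fn=g.weight)[0])
```

prints

```
[Match(hap=1, i=0, j=0, k=4, weight=None)]
[Match(hap=0, i=0, j=0, k=2, weight=None), Match(hap=1, i=0, j=0, k=4, weight=None), Match(hap=2, i=0, j=0, k=2, weight=None)]
[Match(hap=1, i=0, j=0, k=4, weight=6)]
```

The query equals `P1`, so its only set-maximal match is the full-length match
to `P1`.  At threshold `L = 2` the locally maximal length-2 prefix matches to
`P0` and `P2` (`1→2`, broken by the bubble `5` vs `3`) appear as well.  With
base-pair weights (`A·CC·GG·T` = 6 bp) and `L = 4` bp, only the full match
survives.  All coordinates are 0-based: `(hap, i, j, k)` is a match of `k`
nodes starting at query index `i` and haplotype index `j`.

The same is available from the shell:

```
gbwt-match build --input toy.gfa --out toy.idx --fl --flcp
gbwt-match query --index toy.idx --query q.gfa --mode long --L 2
gbwt-match allpairs --index toy.idx --mode long --L 2
gbwt-match stats --index toy.idx
```

Input is a GFA v1 subset (`S`/`P`/`W` lines; `L` lines are ignored since edges
are implied by paths) or a plain path list (one line of signed segment ids per
haplotype); output is TSV.

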