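# Methods

## Data model and conventions

External segment id `n ≥ 1` with orientation `o ∈ {+,−}` maps to internal
node-character `2n + (o = −)`; complementation is `id ^ 1`, which preserves
the relative order of forward and backward nodes automatically.  Ids 0 and 1
are reserved; 0 is the endmarker.  All coordinates are 0-based and half-open:
a match `(i, j, k)` covers query interval `[i, i+k)` and haplotype interval
`[j, j+k)` on the forward orientation.  Node weights are label lengths in
base pairs; empty labels are allowed and weigh 0, so they are inert in
weighted match lengths.

## Index construction

The index is built by explicit suffix sorting of the reversed path-strings
with one endmarker each: suffixes compare lexicographically with the
endmarker smallest, and equal suffixes (only possible for duplicated texts or
bare endmarkers) are ordered by sequence id — the generalized FM-index
tie-break, which makes the suffix and document arrays well defined.  The sort
is `O(n² log n)` in the worst case and deliberate: at the target scale
(panels of tens of paths, texts of a few thousand symbols) it is instant, and
the sorted-suffix view doubles as the construction source for every auxiliary
structure (run-top/bottom suffix samples, LCP samples, text positions).  No
sub-quadratic construction is attempted; construction algorithms are not the
package's contribution.

Because the indexed texts are reversed paths, the local alphabet of record
`v` is exactly the set of forward successors of `v` in the panel, and an LF
step walks a haplotype forward.  Two consequences used throughout:

* `extract(seq)` is an LF walk from the endmarker record position `(0, seq)`,
  reading one node per step until the stored character is the endmarker.
* Rank-based LF over the endmarker cannot recover the walk's document under
  the sequence-id tie-break, so the index stores the (position → document)
  map for the positions reading an endmarker.  These are exactly the per-path
  document samples ("last position of every path") that the sampled document
  array needs anyway; they cost `O(#sequences)`.

When `w ∉ Σ_v`, `BWT.rank(v, w)` is resolved by scanning records after `v`
for the next one containing `w`, saturating at `|BWT_w|` when none does.  The
query algorithms never need this branch for correctness-critical steps — it
is exactly the restart path of the matching statistics (see below).

## Suffix identity, φ / φ⁻¹ and LCP samples

Suffixes are `(seq, offset)` pairs, offset measured from the start of the
reversed text, linearized as `offset + seq·lmax` with
`lmax = 2 + max path length`.  FastLocate stores the suffix at the top of
every GBWT run plus an inclusive predecessor structure over the keys of
run-bottom suffixes; FastLCP mirrors it with run-bottom samples, a
predecessor over run-top keys, and per-run LCP samples.  Predecessor
structures are sorted arrays with binary search — any structure meeting the
inclusive-predecessor contract would do, and nothing in the package depends
on the `O(log log)` alternatives beyond constants.

φ⁻¹ shifts the sample below the predecessor run-bottom by the key distance;
φ and LCP shift symmetrically from run-top predecessors.  The formulas
require a sampled run boundary of the *same sequence* at or before the query
suffix.  That predecessor can be absent — duplicated paths concentrate every
run boundary in one copy — and the structures then fall back to a documented
slow path: walk LF from the sequence's endmarker slot to the suffix's BWT
position, step to the physical neighbor, and identify it by walking to its
sequence end (`locate_slow`).  The fallback is linear in path length, exact,
and exercised by tests with duplicated paths.  LCP values are measured in
node-characters; endmarkers never compare equal, so match lengths never count
the terminator (base pairs enter only through weights).

## FastLF and the compressed text

FastLF replaces the linear run scan inside a record with binary search over
run starts, per-value run-index lists (run-value rank) and per-value prefix
occurrence counts — the sorted-array equivalent of a wavelet tree over the
run-value sequence.  Its outputs are required to be pointwise identical to
the record-scan LF and inverse LF, including the `w ∉ Σ_v` fallback, and the
tests assert this over full cross products.

The compressed text gives random access to the concatenated reversed texts
without requiring bidirectionality.  Sampled locations are the text positions
of GBWT run-top suffixes.  Each level keeps, per surviving sample, four
non-overlapping half blocks covering `[pos − 2h, pos + 2h)`; a half block
either already lies inside some sample's next-level window (it maps to
itself), or maps to an identical occurrence found inside such a window
(equal-content half blocks share one target), or — when no such occurrence
exists, a degenerate case the repeat structure of run boundaries makes rare —
is stored literally so access stays total and exact.  Samples never mapped to
are pruned from the next level; half blocks of four symbols or fewer are
stored explicitly.  The greedy set-cover reduction of the sample set is not
implemented.

## Virtual insertion and matching statistics

For `Q* = rev(Q)·0`, position `a[|Q*|−1] = (0, 0)` and
`a[k−1] = LF(a[k], Q*[k−1])` — exactly `|Q*|−1` generalized-LF calls,
no thresholds.  When `Q*[k−1]` is missing from the index entirely the
position restarts at `(0, 0)` and the LCPs at that suffix are 0; when the
node exists but the edge context breaks (`w ∉ Σ_v`), the saturated-rank LF
lands at a boundary of record `w`, which is an admissible insertion position
for the restarted (length-≤1) context.  Tests validate `a[k]` by membership
in the oracle's admissible interval, not by exact equality, since any
position adjacent to a maximal-LCP suffix is legal.

`lcpa[k]`/`lcpb[k]` are the LCPs of suffix k of Q* with the suffixes above
and below `a[k]`, computed two ways with identical results: reading neighbor
text by inverse-LF walks (bidirectional route), or reading it by compressed
-text access at the neighbor's text position, with the neighbor identified
through the tracked suffix and φ (text route, no bidirectionality needed).
Both routes compare symbols from the suffix start; the monotone property
`lcp[k+1] ≥ lcp[k] − 1` is asserted as an output invariant rather than being
exploited for a carry-over scan — at desk scale the simpler full comparison
keeps both routes obviously equivalent, and the complexity contracts that are
asserted (below) do not involve the LCP inner loop.

## Set-maximal and long match queries

A set-maximal match ends at suffix k whenever
`max(lcpa[k], lcpb[k]) ≥ max(lcpa[k−1], lcpb[k−1])` (with a positive
maximum); the match is `Q*[k, k + max)`.  Occurrences are reported three
ways depending on the bundle: document-array locate after a find over the
matched substring (no haplotype positions), find with suffix tracking plus
φ⁻¹ down the range, or — with FLCP — φ/φ⁻¹ enumeration outward from the
tracked suffix, carrying the running minimum LCP and stopping when it drops
below the maximum.  All versions must produce identical `(hap, i, k)`
multisets; versions with suffix samples add the haplotype start
`j = |P| − offset − k`.

The long-match sweep runs over `i = |Q*|−1 → 0` maintaining the block
`[f, g)` of suffixes in the current record whose LCP with the current suffix
is at least the threshold, as a list of suffix identities plus a diagonal
map `key(suffix) − i → match right end`.  Per transition: members in runs
whose value differs from the next query symbol leave and are emitted with
length `right end − i`; survivors shift through two LF images (the only LF
calls of the sweep, hence ≤ 2 per query node); the block is re-seeded from
the virtual insertion when empty and extended over adjacent suffixes whose
chained LCP (running minimum of per-step LCP-above values) still meets the
threshold.  A fresh entrant's chained LCP is exact — its true LCP with the
query is provably at most the previous threshold bound, so the running
minimum is reached before any capping could matter — which is what makes the
recorded right end (`entry index + entry LCP`) correct.  Entries alive at
suffix 0 are flushed as matches reaching the end of the sweep.  With a
weight function, per-suffix thresholds `L_i` (minimal length reaching weight
`L`, computed by a two-pointer scan, `L_i ≤ L_{i+1} + 1`) replace the
constant; unit weights reduce the weighted query to the unweighted one
exactly.  The diagonal map needs only exact insert/lookup/delete, so a hash
map implements the dynamic-ordered-map contract's used subset.

One-vs-all drivers extract each indexed sequence, query it against the full
panel, and discard the trivial full-length self-match (and, bidirectionally,
a mirrored full-length match to the sequence's opposite-orientation twin —
only palindromic paths can produce one).  Because a path's full-length
self-match dominates set-maximal containment, all-vs-all set-maximal output
reduces to full-length matches between duplicate haplotypes; long matches
are unaffected.  Both orientations are queried by default on bidirectional
indexes; `forward_only` restricts to forward sequences.

## Synthetic panels

The generator emulates a biallelic pangenome panel: a backbone chain with
two-branch bubbles between adjacent backbone nodes, and haplotypes walking
the backbone copying bubble alleles from one of two latent founder vectors,
switching founders with a per-bubble recombination probability.  Defaults
(`bubble_alt_prob = 0.5`, `recomb_prob = 0.02`, labels of 1–3 bp) produce
the long shared founder segments that make run-length compression effective
and give non-trivial set-maximal/long match structure.  What it does not
emulate: inversions and reverse-orientation traversals within a haplotype,
nested or multiallelic bubbles, cycles, mutation on labels, and realistic
allele-frequency spectra.  Passing tests therefore demonstrate correctness
of the index and query algorithms on DAG-shaped biallelic panels — the
algorithms themselves never assume acyclicity or biallelism, but those
regimes are exercised only insofar as duplicated and trimmed paths cover
them.

## Test and measurement scales

Property suites run on seeded panels up to 30 paths × 60 backbone nodes
(texts to a few thousand symbols), where the brute-force oracle —
independent suffix sorting and exhaustive `(i, j, k)` enumeration straight
from the definitions, sharing no code with the implementation — is exact and
fast.  The oracle-equivalence suite covers 200 such instances across every
query version; structural suites are exhaustive over all suffixes and all
record positions.  Complexity contracts are asserted via instrumented
counters: virtual insertion performs exactly `|Q*|−1` LF calls, and the
long-match query's total LF count is at most `3(|Q|+1)` (insertion plus two
per sweep transition), checked together with a linear fit over query lengths
50–400 at relative residual below 5%.

## Known limitations

* Construction is by explicit suffix sort; million-path panels are out of
  scope, as are dynamic updates (path insertion/deletion) and merging.
* The serialized container stores the index and rebuilds auxiliary
  structures on load; it is not compatible with the published GBWT binary
  format.
* The compressed text's literal-fallback half blocks forfeit the space bound
  in degenerate cases (they never compromise correctness).
* The slow `locate_slow` fallback makes φ/φ⁻¹/LCP worst-case linear in path
  length when a sequence has no sampled run boundary before the query
  suffix; the sampled structures answer in logarithmic time otherwise.
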