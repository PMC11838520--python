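"""Virtual insertion, LCP computation, set-maximal / long match queries."""

import pytest
from hypothesis import given, settings, strategies as st

from gbwtmatch import (
    LONG_VERSIONS,
    SMEM_VERSIONS,
    ConfigurationError,
    PathString,
    QueryStructures,
    build_gbwt,
    encode_node,
    long_match_query,
    query_vs_panel_all,
    set_maximal_query,
)
from gbwtmatch.oracle import naive_all_vs_all, naive_matches, naive_suffix_structures
from gbwtmatch.query import (
    _Nav,
    compute_lcps_bidirectional,
    compute_lcps_text,
    virtual_insert,
    virtual_insert_tracked,
)

from conftest import build_structures, random_panel, random_query, toy_graph, toy_paths


def _toy():
    paths = toy_paths()
    idx = build_gbwt(paths)
    return paths, idx, build_structures(idx)


def _suffix_key(ns, rank):
    d, off = ns.suffixes[rank]
    return tuple(ns.texts[d][off:])


def _admissible_interval(ns, qstar, k):
    """Naive oracle: the interval of positions a[k] may legally take —
    the suffix range of the longest matching prefix of suffix k of Q*,
    extended by one at the bottom."""
    q = tuple(qstar[k:])

    def lcp(a, b):
        n = 0
        for x, y in zip(a, b):
            if x != y or x == 0:
                break
            n += 1
        return n

    best = max((lcp(_suffix_key(ns, r), q) for r in range(len(ns.suffixes))), default=0)
    if best == 0:
        return best, None
    ranks = [
        r for r in range(len(ns.suffixes)) if lcp(_suffix_key(ns, r), q) >= best
    ]
    return best, (min(ranks), max(ranks) + 1)  # positions [lo, hi+1] admissible


class TestVirtualInsertion:
    def test_exactly_qstar_minus_one_lf_calls(self):
        paths, idx, structures = _toy()
        for Q in (paths[1], PathString(seq_id=0, nodes=[encode_node(3)])):
            nav = _Nav(structures, use_flf=False)
            vi = virtual_insert(nav, Q.nodes)
            assert nav.counters.lf == len(vi.qstar) - 1
            nav2 = _Nav(structures, use_flf=False)
            virtual_insert_tracked(nav2, Q.nodes)
            assert nav2.counters.lf == len(vi.qstar) - 1

    @pytest.mark.parametrize("seed", range(6))
    def test_positions_lie_in_admissible_interval(self, seed):
        _, paths = random_panel(seed, max_paths=6, max_backbone=12)
        idx = build_gbwt(paths)
        structures = build_structures(idx)
        ns = naive_suffix_structures(paths)
        view = idx.suffix_view()
        rank_of_pos = {pos: r for r, pos in enumerate(view.positions)}
        Q = random_query(None, paths, seed + 1000, unknown_prob=0.0)
        nav = _Nav(structures, use_flf=False)
        vi = virtual_insert(nav, Q.nodes)
        for k in range(len(vi.qstar) - 1):
            best, interval = _admissible_interval(ns, vi.qstar, k)
            if best == 0:
                continue
            v, i = vi.a[k]
            size = idx.records[v].size if v in idx.records else 0
            rank = rank_of_pos[(v, i)] if i < size else idx.global_rank((v, size - 1)) + 1
            lo, hi = interval
            assert lo <= rank <= hi, (k, rank, interval)

    def test_tracked_suffix_equals_naive_sa(self):
        paths, idx, structures = _toy()
        ns = naive_suffix_structures(paths)
        view = idx.suffix_view()
        rank_of_pos = {pos: r for r, pos in enumerate(view.positions)}
        Q = paths[1]
        nav = _Nav(structures, use_flf=False)
        vi = virtual_insert_tracked(nav, Q.nodes)
        for k, (pos, s) in enumerate(zip(vi.a, vi.s)):
            v, i = pos
            if v in idx.records and i < idx.records[v].size:
                assert s == ns.suffixes[rank_of_pos[pos]], k

    def test_identity_query_tracks_to_its_sequence(self):
        paths, idx, structures = _toy()
        nav = _Nav(structures, use_flf=False)
        vi = virtual_insert_tracked(nav, paths[1].nodes)
        assert vi.s[0][0] == 1  # suffix at a[0] belongs to P1

    def test_unknown_node_resets_and_zeroes_lcps(self):
        paths, idx, structures = _toy()
        nodes = list(paths[0].nodes)
        nodes[2] = 99998
        Q = PathString(seq_id=0, nodes=nodes)
        nav = _Nav(structures, use_flf=False)
        vi = virtual_insert_tracked(nav, Q.nodes)
        compute_lcps_bidirectional(nav, vi)
        # Q*: [4', 9999*, 2', 1', 0] reversed query; reset at the unknown node
        k_unknown = vi.qstar.index(99998)
        assert vi.a[k_unknown] == (0, 0)
        assert vi.lcpa[k_unknown] == vi.lcpb[k_unknown] == 0

    def test_full_identity_query_reaches_full_length_lcp(self):
        paths, idx, structures = _toy()
        nav = _Nav(structures, use_flf=False)
        vi = virtual_insert_tracked(nav, paths[0].nodes)
        compute_lcps_bidirectional(nav, vi)
        assert vi.max_lcp(0) == 4

    @pytest.mark.parametrize("seed", range(6))
    def test_monotone_lcp_carry_over(self, seed):
        _, paths = random_panel(seed)
        idx = build_gbwt(paths)
        structures = build_structures(idx)
        Q = random_query(None, paths, seed)
        nav = _Nav(structures, use_flf=False)
        vi = virtual_insert_tracked(nav, Q.nodes)
        compute_lcps_bidirectional(nav, vi)
        for k in range(len(vi.qstar) - 1):
            assert vi.lcpa[k + 1] >= vi.lcpa[k] - 1
            assert vi.lcpb[k + 1] >= vi.lcpb[k] - 1


class TestLcpMethods:
    @pytest.mark.parametrize("seed", range(10))
    def test_text_method_identical_to_inverse_lf_method(self, seed):
        _, paths = random_panel(seed)
        idx = build_gbwt(paths, bidirectional=(seed % 2 == 0))
        structures = build_structures(idx)
        for qi in range(2):
            Q = random_query(None, paths, seed * 10 + qi)
            nav1 = _Nav(structures, use_flf=False)
            vi1 = virtual_insert_tracked(nav1, Q.nodes)
            compute_lcps_bidirectional(nav1, vi1)
            nav2 = _Nav(structures, use_flf=False)
            vi2 = virtual_insert_tracked(nav2, Q.nodes)
            compute_lcps_text(nav2, vi2)
            assert vi1.lcpa == vi2.lcpa
            assert vi1.lcpb == vi2.lcpb

    def test_text_method_works_on_unidirectional_index(self):
        # CT removes the bidirectional requirement: LCPs via text access only.
        _, paths = random_panel(2)
        idx = build_gbwt(paths, bidirectional=False)
        structures = build_structures(idx)
        Q = random_query(None, paths, 5)
        matches, _ = set_maximal_query(structures, Q, version="gbwt+fl+flcp+ct")
        expected = naive_matches(Q.nodes, paths, "smem")
        assert {(m.hap, m.i, m.j, m.k) for m in matches} == {
            (m.hap, m.i, m.j, m.k) for m in expected
        }


class TestSetMaximal:
    def test_toy_query_single_smem(self):
        paths, idx, structures = _toy()
        Q = PathString(seq_id=0, nodes=[encode_node(s) for s in (1, 2, 5, 4)])
        for ver in SMEM_VERSIONS:
            matches, _ = set_maximal_query(structures, Q, version=ver)
            assert [(m.hap, m.i, m.k) for m in matches] == [(1, 0, 4)]
            if ver != "gbwt+da":
                assert matches[0].j == 0

    def test_toy_identity_query_two_smems(self):
        paths, idx, structures = _toy()
        Q = PathString(seq_id=0, nodes=[encode_node(s) for s in (1, 2, 3, 4)])
        matches, _ = set_maximal_query(structures, Q)
        assert {(m.hap, m.i, m.j, m.k) for m in matches} == {(0, 0, 0, 4), (2, 0, 0, 4)}

    def test_da_version_reports_no_location(self):
        paths, idx, structures = _toy()
        Q = paths[1]
        matches, _ = set_maximal_query(structures, Q, version="gbwt+da")
        assert all(m.j is None for m in matches)

    def test_missing_structure_is_configuration_error(self):
        paths, idx, _ = _toy()
        bare = QueryStructures(index=idx)
        with pytest.raises(ConfigurationError, match="missing"):
            set_maximal_query(bare, paths[0], version="gbwt+fl+flcp")

    @pytest.mark.parametrize("seed", range(10))
    def test_all_versions_match_brute_force(self, seed):
        _, paths = random_panel(seed)
        idx = build_gbwt(paths, bidirectional=(seed % 3 == 0))
        seqs = [idx.extract(s) for s in range(idx.num_sequences)]
        structures = build_structures(idx)
        Q = random_query(None, paths, seed + 77)
        expected = {
            (m.hap, m.i, m.j, m.k) for m in naive_matches(Q.nodes, seqs, "smem")
        }
        for ver in SMEM_VERSIONS:
            matches, _ = set_maximal_query(structures, Q, version=ver)
            if ver == "gbwt+da":
                assert sorted((m.hap, m.i, m.k) for m in matches) == sorted(
                    (h, i, k) for h, i, j, k in expected
                )
            else:
                assert {(m.hap, m.i, m.j, m.k) for m in matches} == expected


class TestLongMatch:
    def test_toy_long_l2(self):
        paths, idx, structures = _toy()
        Q = PathString(seq_id=0, nodes=[encode_node(s) for s in (1, 2, 5, 4)])
        matches, _ = long_match_query(structures, Q, 2)
        assert {(m.hap, m.i, m.j, m.k) for m in matches} == {
            (1, 0, 0, 4),
            (0, 0, 0, 2),
            (2, 0, 0, 2),
        }

    def test_toy_long_l5_empty(self):
        paths, idx, structures = _toy()
        Q = PathString(seq_id=0, nodes=[encode_node(s) for s in (1, 2, 5, 4)])
        matches, _ = long_match_query(structures, Q, 5)
        assert matches == []

    def test_toy_weighted(self):
        paths, idx, structures = _toy()
        g = toy_graph()
        Q = PathString(seq_id=0, nodes=[encode_node(s) for s in (1, 2, 5, 4)])
        m3, _ = long_match_query(structures, Q, 3, weight_fn=g.weight)
        assert {(m.hap, m.i, m.j, m.k, m.weight) for m in m3} == {
            (1, 0, 0, 4, 6),
            (0, 0, 0, 2, 3),
            (2, 0, 0, 2, 3),
        }
        m4, _ = long_match_query(structures, Q, 4, weight_fn=g.weight)
        assert {(m.hap, m.i, m.j, m.k, m.weight) for m in m4} == {(1, 0, 0, 4, 6)}

    @pytest.mark.parametrize("seed", range(10))
    def test_all_variants_match_brute_force(self, seed):
        _, paths = random_panel(seed)
        idx = build_gbwt(paths, bidirectional=(seed % 3 == 1))
        seqs = [idx.extract(s) for s in range(idx.num_sequences)]
        structures = build_structures(idx)
        Q = random_query(None, paths, seed + 31)
        for L in (1, 2, 4):
            expected = {
                (m.hap, m.i, m.j, m.k)
                for m in naive_matches(Q.nodes, seqs, "long", L=L)
            }
            for ver in LONG_VERSIONS:
                matches, _ = long_match_query(structures, Q, L, version=ver)
                assert {(m.hap, m.i, m.j, m.k) for m in matches} == expected, (ver, L)

    @pytest.mark.parametrize("seed", range(6))
    def test_weighted_matches_brute_force(self, seed):
        g, paths = random_panel(seed)
        idx = build_gbwt(paths)
        structures = build_structures(idx)
        Q = random_query(None, paths, seed + 13)
        for L in (2, 5, 9):
            expected = {
                (m.hap, m.i, m.j, m.k)
                for m in naive_matches(
                    Q.nodes, paths, "long_weighted", L=L, weight_fn=g.weight
                )
            }
            matches, _ = long_match_query(structures, Q, L, weight_fn=g.weight)
            assert {(m.hap, m.i, m.j, m.k) for m in matches} == expected, L

    def test_negative_weight_is_contract_error(self):
        paths, idx, structures = _toy()
        with pytest.raises(ValueError, match="negative weight"):
            long_match_query(structures, paths[0], 2, weight_fn=lambda v: -1)


class TestTaxonomy:
    """Containment relations between the match classes."""

    @pytest.mark.parametrize("seed", range(6))
    def test_relations(self, seed):
        g, paths = random_panel(seed)
        idx = build_gbwt(paths)
        structures = build_structures(idx)
        Q = random_query(None, paths, seed + 3)
        smem, _ = set_maximal_query(structures, Q)
        long1, _ = long_match_query(structures, Q, 1)
        local = naive_matches(Q.nodes, paths, "local")
        local_set = {(m.hap, m.i, m.j, m.k) for m in local}
        # every set-maximal match is locally maximal
        assert {(m.hap, m.i, m.j, m.k) for m in smem} <= local_set
        # long matches at L=1 are exactly the locally maximal matches
        assert {(m.hap, m.i, m.j, m.k) for m in long1} == local_set
        # weighted query with unit weights reduces to the unweighted query
        for L in (1, 3):
            lw, _ = long_match_query(structures, Q, L, weight_fn=lambda v: 1)
            lu, _ = long_match_query(structures, Q, L)
            assert {(m.hap, m.i, m.j, m.k) for m in lw} == {
                (m.hap, m.i, m.j, m.k) for m in lu
            }

    @pytest.mark.parametrize("seed", range(4))
    def test_emitted_long_matches_pass_definition_predicates(self, seed):
        _, paths = random_panel(seed)
        idx = build_gbwt(paths)
        structures = build_structures(idx)
        Q = random_query(None, paths, seed + 8)
        A = Q.nodes
        matches, _ = long_match_query(structures, Q, 2)
        for m in matches:
            B = paths[m.hap].nodes
            i, j, k = m.i, m.j, m.k
            assert A[i : i + k] == B[j : j + k]
            assert k >= 2
            assert i == 0 or j == 0 or A[i - 1] != B[j - 1]
            assert i + k == len(A) or j + k == len(B) or A[i + k] != B[j + k]


class TestDrivers:
    def test_toy_all_vs_all_long(self):
        paths, idx, structures = _toy()
        results = query_vs_panel_all(structures, mode="long", L=2)
        got = {(t, m.hap, m.i, m.j, m.k) for t, m in results}
        expected = {
            (t, m.hap, m.i, m.j, m.k)
            for t, m in naive_all_vs_all(paths, "long", L=2)
        }
        assert got == expected
        # P0 and P2 report full-length matches with each other
        assert (0, 2, 0, 0, 4) in got and (2, 0, 0, 0, 4) in got

    def test_duplicated_panel_smem_reports_twin_full_length(self):
        v = [encode_node(s) for s in (1, 2, 3)]
        paths = [PathString(seq_id=0, nodes=v), PathString(seq_id=1, nodes=list(v))]
        idx = build_gbwt(paths)
        structures = build_structures(idx)
        results = query_vs_panel_all(structures, mode="smem")
        got = {(t, m.hap, m.i, m.j, m.k) for t, m in results}
        assert got == {(0, 1, 0, 0, 3), (1, 0, 0, 0, 3)}

    def test_single_path_panel_is_empty(self):
        _, paths = random_panel(4, max_paths=2)
        idx = build_gbwt([paths[0]])
        structures = build_structures(idx)
        assert query_vs_panel_all(structures, mode="smem") == []

    @pytest.mark.parametrize("seed,mode,L", [(0, "smem", None), (1, "long", 2), (2, "long", 3)])
    def test_matches_brute_force_all_pairs(self, seed, mode, L):
        _, paths = random_panel(seed, max_paths=6, max_backbone=12)
        bidir = seed % 2 == 0
        idx = build_gbwt(paths, bidirectional=bidir)
        seqs = [idx.extract(s) for s in range(idx.num_sequences)]
        structures = build_structures(idx)
        twin = {s: s ^ 1 for s in range(idx.num_sequences)} if bidir else None
        got = {
            (t, m.hap, m.i, m.j, m.k)
            for t, m in query_vs_panel_all(structures, mode=mode, L=L)
        }
        expected = {
            (t, m.hap, m.i, m.j, m.k)
            for t, m in naive_all_vs_all(seqs, mode, L=L, twin=twin)
        }
        assert got == expected

    def test_forward_only_restricts_queries(self):
        _, paths = random_panel(3, max_paths=4)
        idx = build_gbwt(paths, bidirectional=True)
        structures = build_structures(idx)
        results = query_vs_panel_all(structures, mode="long", L=2, forward_only=True)
        assert all(t % 2 == 0 for t, _ in results)


@settings(max_examples=20, derandomize=True, deadline=None)
@given(seed=st.integers(min_value=1000, max_value=3000))
def test_property_cross_version_agreement(seed):
    """All query versions agree with each other and the brute force on
    arbitrary seeded panels (hypothesis-driven seeds)."""
    _, paths = random_panel(seed, max_paths=8, max_backbone=16)
    idx = build_gbwt(paths)
    structures = build_structures(idx)
    Q = random_query(None, paths, seed)
    expected = {(m.hap, m.i, m.j, m.k) for m in naive_matches(Q.nodes, paths, "smem")}
    for ver in SMEM_VERSIONS:
        matches, _ = set_maximal_query(structures, Q, version=ver)
        if ver == "gbwt+da":
            assert sorted((m.hap, m.i, m.k) for m in matches) == sorted(
                (h, i, k) for h, i, j, k in expected
            )
        else:
            assert {(m.hap, m.i, m.j, m.k) for m in matches} == expected
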