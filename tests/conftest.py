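import random

import pytest

from gbwtmatch import (
    PangenomeGraph,
    PathString,
    QueryStructures,
    build_doc_array,
    build_fast_lcp,
    build_fast_lf,
    build_fast_locate,
    build_gbwt,
    build_compressed_text,
    encode_node,
    generate_panel,
)


def toy_paths():
    """The fixed worked panel: P0=[1,2,3,4], P1=[1,2,5,4], P2=[1,2,3,4]."""
    def P(sid, segs):
        return PathString(seq_id=sid, nodes=[encode_node(s) for s in segs])

    return [P(0, [1, 2, 3, 4]), P(1, [1, 2, 5, 4]), P(2, [1, 2, 3, 4])]


def toy_graph():
    g = PangenomeGraph()
    for seg, lab in [(1, "A"), (2, "CC"), (3, "G"), (4, "T"), (5, "GG")]:
        g.add_node(encode_node(seg), lab)
    return g


def build_structures(index, da_interval=4):
    fl = build_fast_locate(index)
    return QueryStructures(
        index=index,
        da=build_doc_array(index, da_interval),
        fl=fl,
        flcp=build_fast_lcp(index, fl),
        flf=build_fast_lf(index),
        ct=build_compressed_text(index),
    )


def random_panel(seed, max_paths=12, max_backbone=24, duplicate_prob=0.3):
    """A seeded random panel; occasionally duplicates a path so run-boundary
    sampling degeneracies (slow-locate fallbacks) are exercised."""
    rng = random.Random(seed)
    n_backbone = rng.randint(4, max_backbone)
    g, paths = generate_panel(
        n_backbone=n_backbone,
        n_bubbles=rng.randint(0, min(5, n_backbone - 1)),
        n_haps=rng.randint(2, max_paths),
        bubble_alt_prob=rng.choice([0.2, 0.5, 0.8]),
        recomb_prob=rng.choice([0.0, 0.05, 0.2]),
        label_len_range=(0, 3),
        seed=seed,
    )
    if rng.random() < duplicate_prob:
        paths.append(PathString(seq_id=len(paths), nodes=list(paths[0].nodes)))
    return g, paths


def random_query(g, paths, seed, unknown_prob=0.25):
    """A query path: a (possibly trimmed) panel path, sometimes with an
    unknown node spliced in to exercise matching-statistic restarts."""
    rng = random.Random(seed)
    base = list(rng.choice(paths).nodes)
    if rng.random() < 0.5 and len(base) > 3:
        a, b = sorted(rng.sample(range(len(base)), 2))
        if b > a:
            base = base[a : b + 1]
    if rng.random() < unknown_prob:
        base[rng.randrange(len(base))] = 99998  # even id: a forward node
    return PathString(seq_id=0, nodes=base)


@pytest.fixture(scope="session")
def toy():
    paths = toy_paths()
    index = build_gbwt(paths)
    return toy_graph(), paths, index, build_structures(index)


@pytest.fixture(scope="session")
def toy_bidir():
    paths = toy_paths()
    index = build_gbwt(paths, bidirectional=True)
    return toy_graph(), paths, index, build_structures(index)
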