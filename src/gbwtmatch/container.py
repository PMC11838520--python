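"""Versioned JSON container for a GBWT index and its panel/graph context.

The container stores the graph labels, the index records and metadata, and a
manifest of which auxiliary structures to materialize on load.  Auxiliary
structures are cheap to rebuild relative to their serialized size at the
scales this package targets, so the container records *which* structures a
build requested (plus the DA sample interval) and rebuilds them on load;
loading then re-saving is byte-stable.  The format is not compatible with
the published GBWT binary serialization.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import IO, Dict, List, Optional

from .aux import build_doc_array, build_fast_lcp, build_fast_lf, build_fast_locate
from .ctext import build_compressed_text
from .gbwt import GBWTIndex, GBWTRecord
from .graph import PangenomeGraph
from .query import QueryStructures

FORMAT_VERSION = 1


@dataclass
class IndexContainer:
    graph: PangenomeGraph
    structures: QueryStructures
    manifest: Dict[str, object] = field(default_factory=dict)
    provenance: Dict[str, object] = field(default_factory=dict)


def _index_payload(index: GBWTIndex) -> dict:
    return {
        "records": [
            {
                "node": rec.node,
                "alphabet": rec.local_alphabet,
                "out_rank": [rec.out_rank[w] for w in rec.local_alphabet],
                "runs": [[ci, ln] for ci, ln in rec.runs],
            }
            for _, rec in sorted(index.records.items())
        ],
        "num_sequences": index.num_sequences,
        "bidirectional": index.bidirectional,
        "lmax": index.lmax,
        "n": index.n,
        "r": index.r,
        "o": index.o,
        "seq_lengths": index.seq_lengths,
        "path_start_docs": [[v, i, d] for (v, i), d in sorted(index.path_start_docs.items())],
    }


def save_container(container: IndexContainer, stream: IO[str]) -> None:
    doc = {
        "format": "gbwtmatch-container",
        "format_version": FORMAT_VERSION,
        "graph": {str(k): v for k, v in sorted(container.graph.labels.items())},
        "index": _index_payload(container.structures.index),
        "manifest": container.manifest,
        "provenance": container.provenance,
    }
    json.dump(doc, stream, sort_keys=True, separators=(",", ":"))
    stream.write("\n")


def load_container(stream: IO[str]) -> IndexContainer:
    doc = json.load(stream)
    if doc.get("format") != "gbwtmatch-container":
        raise ValueError("not a gbwtmatch container")
    if doc.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"unsupported container version {doc.get('format_version')}")
    graph = PangenomeGraph(labels={int(k): v for k, v in doc["graph"].items()})
    ip = doc["index"]
    records = {}
    for r in ip["records"]:
        records[r["node"]] = GBWTRecord(
            node=r["node"],
            local_alphabet=list(r["alphabet"]),
            out_rank=dict(zip(r["alphabet"], r["out_rank"])),
            runs=[(ci, ln) for ci, ln in r["runs"]],
        )
    index = GBWTIndex(
        records=records,
        num_sequences=ip["num_sequences"],
        bidirectional=ip["bidirectional"],
        lmax=ip["lmax"],
        n=ip["n"],
        r=ip["r"],
        o=ip["o"],
        seq_lengths=list(ip["seq_lengths"]),
        path_start_docs={(v, i): d for v, i, d in ip["path_start_docs"]},
    )
    manifest = doc.get("manifest", {})
    structures = QueryStructures(index=index)
    if manifest.get("da"):
        structures.da = build_doc_array(index, int(manifest.get("da_interval", 4)))
    if manifest.get("fl") or manifest.get("flcp"):
        structures.fl = build_fast_locate(index)
    if manifest.get("flcp"):
        structures.flcp = build_fast_lcp(index, structures.fl)
    if manifest.get("flf"):
        structures.flf = build_fast_lf(index)
    if manifest.get("ct"):
        structures.ct = build_compressed_text(index)
    return IndexContainer(
        graph=graph,
        structures=structures,
        manifest=manifest,
        provenance=doc.get("provenance", {}),
    )


def container_digest(container: IndexContainer) -> str:
    import io

    buf = io.StringIO()
    save_container(container, buf)
    return hashlib.sha256(buf.getvalue().encode()).hexdigest()
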