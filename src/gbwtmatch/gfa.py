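"""I/O for the GFA v1 subset (S/P/W lines), the plain path-list format, and TSV match reports.

Only S (segment) and P (path) lines are honoured; W (walk) lines are mapped to
path semantics; L lines are read and ignored because edges are implied by the
paths.  External segment ids are remapped to the internal node-character space
(see :mod:`gbwtmatch.graph`).
"""

from __future__ import annotations

from typing import IO, List, Tuple

from .graph import Match, PangenomeGraph, PathString, encode_node


class GFAParseError(ValueError):
    pass


def read_gfa(stream: IO[str]) -> Tuple[PangenomeGraph, List[PathString]]:
    """Parse S/P/W lines into a graph and panel; seq_id follows file order."""
    graph = PangenomeGraph()
    paths: List[PathString] = []
    declared = set()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        tag = fields[0]
        if tag == "S":
            if len(fields) < 3:
                raise GFAParseError(f"line {lineno}: S line needs id and sequence")
            try:
                seg = int(fields[1])
            except ValueError as e:
                raise GFAParseError(f"line {lineno}: non-integer segment id {fields[1]!r}") from e
            seq = "" if fields[2] == "*" else fields[2]
            graph.add_node(encode_node(seg, "+"), seq)
            declared.add(seg)
        elif tag == "P":
            if len(fields) < 3:
                raise GFAParseError(f"line {lineno}: P line needs name and segment list")
            nodes = _parse_p_steps(fields[2], lineno, declared)
            paths.append(PathString(seq_id=len(paths), nodes=nodes, name=fields[1]))
        elif tag == "W":
            if len(fields) < 7:
                raise GFAParseError(f"line {lineno}: W line needs 6 fields before the walk")
            nodes = _parse_w_walk(fields[6], lineno, declared)
            paths.append(PathString(seq_id=len(paths), nodes=nodes, name=fields[1]))
        # L / H / other lines: ignored.
    return graph, paths


def _parse_p_steps(steps: str, lineno: int, declared) -> List[int]:
    nodes = []
    for step in steps.split(","):
        step = step.strip()
        if not step:
            continue
        seg_str, orient = step[:-1], step[-1]
        if orient not in "+-":
            raise GFAParseError(
                f"line {lineno}: path step {step!r} must end in '+' or '-'"
            )
        try:
            seg = int(seg_str)
        except ValueError as e:
            raise GFAParseError(f"line {lineno}: non-integer segment in step {step!r}") from e
        if seg not in declared:
            raise GFAParseError(f"line {lineno}: path references undeclared segment {seg}")
        nodes.append(encode_node(seg, orient))
    if not nodes:
        raise GFAParseError(f"line {lineno}: empty path")
    return nodes


def _parse_w_walk(walk: str, lineno: int, declared) -> List[int]:
    nodes = []
    i = 0
    while i < len(walk):
        orient = walk[i]
        if orient not in "><":
            raise GFAParseError(f"line {lineno}: walk step must start with '>' or '<'")
        j = i + 1
        while j < len(walk) and walk[j] not in "><":
            j += 1
        try:
            seg = int(walk[i + 1 : j])
        except ValueError as e:
            raise GFAParseError(f"line {lineno}: non-integer segment in walk") from e
        if seg not in declared:
            raise GFAParseError(f"line {lineno}: walk references undeclared segment {seg}")
        nodes.append(encode_node(seg, "+" if orient == ">" else "-"))
        i = j
    if not nodes:
        raise GFAParseError(f"line {lineno}: empty walk")
    return nodes


def write_gfa(graph: PangenomeGraph, paths: List[PathString], stream: IO[str]) -> None:
    stream.write("H\tVN:Z:1.0\n")
    for node in graph.nodes():
        seg = node // 2
        seq = graph.labels[node]
        stream.write(f"S\t{seg}\t{seq if seq else '*'}\n")
    for p in paths:
        steps = ",".join(f"{v // 2}{'-' if v & 1 else '+'}" for v in p.nodes)
        name = p.name if p.name is not None else f"path{p.seq_id}"
        stream.write(f"P\t{name}\t{steps}\t*\n")


def read_path_list(stream: IO[str]) -> List[PathString]:
    """One path per line: whitespace-separated signed external segment ids."""
    paths: List[PathString] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        nodes = []
        for tok in line.split():
            try:
                signed = int(tok)
            except ValueError as e:
                raise GFAParseError(f"line {lineno}: non-integer id {tok!r}") from e
            if signed == 0:
                raise GFAParseError(f"line {lineno}: segment id 0 is reserved")
            nodes.append(encode_node(abs(signed), "-" if signed < 0 else "+"))
        paths.append(PathString(seq_id=len(paths), nodes=nodes))
    return paths


def write_path_list(paths: List[PathString], stream: IO[str]) -> None:
    for p in paths:
        stream.write(" ".join(str(-(v // 2) if v & 1 else v // 2) for v in p.nodes) + "\n")


TSV_HEADER = "query_id\thap_id\tq_start\th_start\tlen\tweight"


def write_matches_tsv(matches: List[Tuple[str, Match]], stream: IO[str]) -> None:
    """Write (query_id, Match) rows, stably sorted by (hap_id, q_start, h_start)."""
    stream.write(TSV_HEADER + "\n")
    def sort_key(item):
        qid, m = item
        return (m.hap, m.i, -1 if m.j is None else m.j)
    for qid, m in sorted(matches, key=sort_key):
        j = "." if m.j is None else m.j
        w = "." if m.weight is None else m.weight
        stream.write(f"{qid}\t{m.hap}\t{m.i}\t{j}\t{m.k}\t{w}\n")
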