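"""Readers and writers for regulatory-network edge tables.

Three dialects are supported:

``TSV``
    Tab-separated edge table with mandatory header columns ``source``,
    ``target``, ``sign``, ``mechanism``, ``node_class_source``,
    ``node_class_target``, ``provenance`` (an optional ``evidence`` column
    is written and read back).  ``#`` lines are comments.  The writer also
    emits structured ``#!node`` comment lines carrying node origins and
    isolated nodes so that a write/read round trip is lossless; foreign
    files without them still parse, with node origins inferred from edge
    provenance.

``SIF``
    Simple interaction format, ``source<TAB>relation<TAB>target`` with
    relation ``activates`` or ``represses``.  Plain SIF carries no
    attributes, so the writer appends ``#!node`` / ``#!edge`` comment lines
    with the full attribute set; when present they are authoritative.
    Foreign SIF is read with inference: miRNA-looking symbols become MIRNA
    nodes acting post-transcriptionally, other sources become TF, pure
    targets PCG.

``GraphML``
    Via :mod:`networkx` (multigraph, edge key = mechanism), attributes
    stored natively.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import NetworkParseError, ValidationError
from .network import (
    MECHANISMS,
    NODE_CLASSES,
    MirnaTargetRecord,
    RegulatoryNetwork,
    canonical_symbol,
    looks_like_mirna,
)

log = logging.getLogger(__name__)

DIALECTS = ("TSV", "SIF", "GraphML")

_TSV_COLUMNS = (
    "source", "target", "sign", "mechanism",
    "node_class_source", "node_class_target", "provenance",
)

_SIGN_TOKENS = {
    "+1": 1, "1": 1, "+": 1, "activation": 1, "activates": 1,
    "-1": -1, "-": -1, "repression": -1, "represses": -1,
}

_EXT_TO_DIALECT = {
    ".tsv": "TSV", ".txt": "TSV", ".sif": "SIF",
    ".graphml": "GraphML", ".xml": "GraphML",
}


def _infer_dialect(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        d = dialect if dialect in DIALECTS else dialect.upper()
        if d == "GRAPHML":
            d = "GraphML"
        if d not in DIALECTS:
            raise ValidationError(f"unknown dialect {dialect!r}; use one of {DIALECTS}")
        return d
    ext = path.suffix.lower()
    if ext not in _EXT_TO_DIALECT:
        raise ValidationError(
            f"cannot infer dialect from extension {ext!r}; pass dialect="
        )
    return _EXT_TO_DIALECT[ext]


def _parse_sign(token: str, path, line: int) -> int:
    token = token.strip().lower()
    if token not in _SIGN_TOKENS:
        raise NetworkParseError(f"unknown sign token {token!r}", path, line)
    return _SIGN_TOKENS[token]


def _parse_class(token: str, path, line: int) -> str:
    token = token.strip().upper()
    if token not in NODE_CLASSES:
        raise NetworkParseError(f"unknown node class {token!r}", path, line)
    return token


def read_edge_table(path, dialect: str | None = None) -> RegulatoryNetwork:
    """Read a network file; dialect inferred from the extension if omitted."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = _infer_dialect(path, dialect)
    if dialect == "TSV":
        net = _read_tsv(path)
    elif dialect == "SIF":
        net = _read_sif(path)
    else:
        net = _read_graphml(path)
    net.validate()
    return net


def write_network(net: RegulatoryNetwork, path, dialect: str | None = None) -> Path:
    """Write a network file; ``read_edge_table`` reproduces the network."""
    path = Path(path)
    dialect = _infer_dialect(path, dialect)
    if dialect == "TSV":
        _write_tsv(net, path)
    elif dialect == "SIF":
        _write_sif(net, path)
    else:
        _write_graphml(net, path)
    return path


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------

def _node_directive(node) -> str:
    return "#!node\t{}\t{}\t{}".format(
        node.symbol, node.node_class, ";".join(sorted(node.origins))
    )


def _parse_node_directive(parts, net, path, line):
    if len(parts) < 3:
        raise NetworkParseError("malformed #!node directive", path, line)
    symbol, node_class = parts[1], _parse_class(parts[2], path, line)
    origins = set(filter(None, parts[3].split(";"))) if len(parts) > 3 else set()
    net.add_node(symbol, node_class, origins)


def _write_tsv(net: RegulatoryNetwork, path: Path) -> None:
    lines = ["# regulatory network edge table (tab-separated)"]
    for key in sorted(net.nodes):
        lines.append(_node_directive(net.nodes[key]))
    lines.append("\t".join(_TSV_COLUMNS + ("evidence",)))
    for key in sorted(net.edges):
        e = net.edges[key]
        src, tgt = net.nodes[e.source], net.nodes[e.target]
        lines.append(
            "\t".join(
                [
                    src.symbol, tgt.symbol, f"{e.sign:+d}", e.mechanism,
                    src.node_class, tgt.node_class,
                    ";".join(sorted(e.provenance)), e.evidence,
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _read_tsv(path: Path) -> RegulatoryNetwork:
    net = RegulatoryNetwork(name=path.stem)
    header: list[str] | None = None
    col: dict[str, int] = {}
    infer_origins = True
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#!node"):
                _parse_node_directive(line.split("\t"), net, path, lineno)
                infer_origins = False
                continue
            if line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = [p.strip() for p in parts]
                missing = [c for c in _TSV_COLUMNS if c not in header]
                if missing:
                    raise NetworkParseError(
                        f"missing required columns {missing}", path, lineno
                    )
                col = {name: i for i, name in enumerate(header)}
                continue
            if len(parts) < len(_TSV_COLUMNS):
                raise NetworkParseError(
                    f"malformed row ({len(parts)} fields, expected at least "
                    f"{len(_TSV_COLUMNS)})", path, lineno,
                )
            get = lambda name: parts[col[name]].strip() if name in col and col[name] < len(parts) else ""
            source, target = get("source"), get("target")
            if not source or not target:
                raise NetworkParseError("empty source or target", path, lineno)
            sign = _parse_sign(get("sign"), path, lineno)
            mechanism = get("mechanism")
            if mechanism not in MECHANISMS:
                raise NetworkParseError(
                    f"unknown mechanism {mechanism!r}", path, lineno
                )
            cls_s = _parse_class(get("node_class_source"), path, lineno)
            cls_t = _parse_class(get("node_class_target"), path, lineno)
            provenance = set(filter(None, get("provenance").split(";")))
            evidence = get("evidence")
            src_origins = provenance if infer_origins else set()
            net.add_node(source, cls_s, set(src_origins))
            net.add_node(target, cls_t, set(src_origins))
            net.add_edge(source, target, sign, mechanism, provenance, evidence)
    if header is None:
        raise NetworkParseError("no header line found", path)
    return net


# ---------------------------------------------------------------------------
# SIF
# ---------------------------------------------------------------------------

def _write_sif(net: RegulatoryNetwork, path: Path) -> None:
    body = []
    meta = []
    for key in sorted(net.nodes):
        meta.append(_node_directive(net.nodes[key]))
    for key in sorted(net.edges):
        e = net.edges[key]
        rel = "activates" if e.sign > 0 else "represses"
        src, tgt = net.nodes[e.source].symbol, net.nodes[e.target].symbol
        body.append(f"{src}\t{rel}\t{tgt}")
        meta.append(
            "#!edge\t{}\t{}\t{}\t{:+d}\t{}\t{}".format(
                src, tgt, e.mechanism, e.sign,
                ";".join(sorted(e.provenance)), e.evidence,
            )
        )
    path.write_text("\n".join(body + meta) + "\n", encoding="utf-8")


def _read_sif(path: Path) -> RegulatoryNetwork:
    net = RegulatoryNetwork(name=path.stem)
    body_rows: list[tuple[int, list[str]]] = []
    edge_meta: list[tuple[int, list[str]]] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#!node"):
                _parse_node_directive(line.split("\t"), net, path, lineno)
                continue
            if line.startswith("#!edge"):
                edge_meta.append((lineno, line.split("\t")))
                continue
            if line.startswith("#"):
                continue
            body_rows.append((lineno, line.split("\t")))
    if edge_meta:
        # structured metadata is authoritative for edges
        for lineno, parts in edge_meta:
            if len(parts) < 5:
                raise NetworkParseError("malformed #!edge directive", path, lineno)
            src, tgt, mech = parts[1], parts[2], parts[3]
            sign = _parse_sign(parts[4], path, lineno)
            provenance = set(filter(None, parts[5].split(";"))) if len(parts) > 5 else set()
            evidence = parts[6] if len(parts) > 6 else ""
            for sym in (src, tgt):
                if sym not in net:
                    net.add_node(sym, "MIRNA" if looks_like_mirna(sym) else "PCG")
            net.add_edge(src, tgt, sign, mech, provenance, evidence)
        return net
    for lineno, parts in body_rows:
        if len(parts) != 3:
            raise NetworkParseError(
                "SIF line must be 'source<TAB>relation<TAB>target'", path, lineno
            )
        src, rel, tgt = (p.strip() for p in parts)
        sign = _parse_sign(rel, path, lineno)
        for sym, is_source in ((src, True), (tgt, False)):
            if sym in net:
                continue
            if looks_like_mirna(sym):
                cls = "MIRNA"
            else:
                cls = "TF" if is_source else "PCG"
            net.add_node(sym, cls, {"sif"})
        net.add_edge(src, tgt, sign, None, {"sif"}, "")
    return net


# ---------------------------------------------------------------------------
# GraphML
# ---------------------------------------------------------------------------

def _write_graphml(net: RegulatoryNetwork, path: Path) -> None:
    nx.write_graphml(net.to_networkx(), path)


def _read_graphml(path: Path) -> RegulatoryNetwork:
    try:
        g = nx.read_graphml(path, force_multigraph=True)
    except Exception as exc:  # malformed XML or schema
        raise NetworkParseError(f"cannot parse GraphML: {exc}", path) from exc
    net = RegulatoryNetwork(name=g.graph.get("name", path.stem))
    for node_id, attrs in g.nodes(data=True):
        if "node_class" not in attrs:
            raise ValidationError(
                f"GraphML node {node_id!r} lacks node_class (dangling edge "
                "endpoint or missing annotation)"
            )
        net.add_node(
            attrs.get("symbol", node_id),
            attrs["node_class"],
            set(filter(None, str(attrs.get("origins", "")).split(";"))),
        )
    for src, tgt, key, attrs in g.edges(keys=True, data=True):
        mechanism = attrs.get("mechanism", key if key in MECHANISMS else None)
        net.add_edge(
            src,
            tgt,
            int(attrs["sign"]),
            mechanism,
            set(filter(None, str(attrs.get("provenance", "")).split(";"))),
            str(attrs.get("evidence", "")),
        )
    return net


# ---------------------------------------------------------------------------
# auxiliary inputs
# ---------------------------------------------------------------------------

def read_mirna_table(path) -> list[MirnaTargetRecord]:
    """Read a miRTarBase-like TSV with columns miRNA, target_gene, evidence."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    for column in ("miRNA", "target_gene"):
        if column not in frame.columns:
            raise NetworkParseError(f"missing column {column!r}", path)
    return [
        MirnaTargetRecord(
            row["miRNA"], row["target_gene"], row.get("evidence", "")
        )
        for _, row in frame.iterrows()
    ]


def write_mirna_table(records, path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(
        [(r.mirna, r.target_gene, r.evidence) for r in records],
        columns=["miRNA", "target_gene", "evidence"],
    )
    frame.to_csv(path, sep="\t", index=False)
    return path


def read_tf_list(path) -> set[str]:
    """Read a plain-text TF list, one symbol per line, ``#`` comments allowed."""
    symbols = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            symbols.add(canonical_symbol(line))
    return symbols
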