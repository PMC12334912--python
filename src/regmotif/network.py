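"""Typed, signed regulatory-network data model and assembly operations.

Nodes are genes classified as transcription factors (``TF``), microRNAs
(``MIRNA``) or other protein-coding genes (``PCG``), each carrying a set of
provenance *origins* (which source networks contributed it, e.g. melanoma,
astrocyte, pluripotency, oligodendrocyte).  Edges are signed, directed
regulatory interactions tagged with their mechanism: ``transcriptional`` for
TF-promoter regulation and ``post_transcriptional`` for miRNA-mRNA
repression.  An edge is identified by ``(source, target, mechanism)`` so a
pair of genes may carry parallel transcriptional and post-transcriptional
arms, which matter for motif dynamics.

The assembly operations mirror a network-reconstruction workflow: merge
source networks into a full network, extract the ego subnetwork of a focal
hub (SOX10 in the motivating application), expand it with experimentally
validated miRNA-target interactions, and annotate known human TFs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError

log = logging.getLogger(__name__)

NODE_CLASSES = ("TF", "MIRNA", "PCG")
MECHANISMS = ("transcriptional", "post_transcriptional")

#: resolution priority for node-class conflicts (higher wins)
_CLASS_PRIORITY = {"TF": 2, "MIRNA": 1, "PCG": 0}


def canonical_symbol(symbol: str) -> str:
    """Canonical matching key for a gene or miRNA symbol.

    Gene symbols are upper-cased HGNC style.  miRNA names are matched
    case-insensitively with hyphens and a leading ``hsa-`` prefix removed,
    so ``MIR155``, ``miR-155`` and ``hsa-miR-155`` all map to one node
    while ``miR-155-5p`` stays distinct (it names a specific mature arm).
    """
    s = symbol.strip()
    if not s:
        raise ValidationError("empty gene symbol")
    upper = s.upper()
    compact = upper.replace("-", "")
    if compact.startswith("HSAMIR") or compact.startswith("HSALET"):
        compact = compact[3:]
    if compact.startswith("MIR") or compact.startswith("LET7"):
        return compact
    return upper


def looks_like_mirna(symbol: str) -> bool:
    """Heuristic miRNA-name check used only when no class annotation exists."""
    key = canonical_symbol(symbol)
    return key.startswith("MIR") or key.startswith("LET7")


@dataclass
class GeneNode:
    """A gene in the network: display symbol, molecular class, origins."""

    symbol: str
    node_class: str
    origins: set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.node_class not in NODE_CLASSES:
            raise ValidationError(
                f"node_class of {self.symbol!r} must be one of {NODE_CLASSES}, "
                f"got {self.node_class!r}"
            )
        self.origins = set(self.origins)

    @property
    def key(self) -> str:
        return canonical_symbol(self.symbol)


@dataclass
class Interaction:
    """A signed, directed regulatory edge (endpoints are canonical keys)."""

    source: str
    target: str
    sign: int
    mechanism: str
    provenance: set[str] = field(default_factory=set)
    evidence: str = ""

    def __post_init__(self):
        if self.sign not in (1, -1):
            raise ValidationError(
                f"sign of {self.source}->{self.target} must be +1 or -1, "
                f"got {self.sign!r}"
            )
        if self.mechanism not in MECHANISMS:
            raise ValidationError(
                f"mechanism of {self.source}->{self.target} must be one of "
                f"{MECHANISMS}, got {self.mechanism!r}"
            )
        self.provenance = set(self.provenance)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.source, self.target, self.mechanism)


def _merge_evidence(old: str, new: str) -> str:
    """Concatenate evidence tags, deduplicating while preserving order."""
    parts = [p.strip() for p in (old + "; " + new).split(";")]
    seen, out = set(), []
    for p in parts:
        if p and p not in seen:
            seen.add(p)
            out.append(p)
    return "; ".join(out)


class RegulatoryNetwork:
    """A collection of :class:`GeneNode` and :class:`Interaction`.

    Nodes are keyed by canonical symbol; edges by
    ``(source, target, mechanism)``.  Self-loops are rejected unless
    ``allow_self_loops`` is set — none of the analyzed motifs contain any.
    """

    def __init__(self, name: str = "network", allow_self_loops: bool = False):
        self.name = name
        self.allow_self_loops = allow_self_loops
        self._nodes: dict[str, GeneNode] = {}
        self._edges: dict[tuple[str, str, str], Interaction] = {}

    # -- container basics -------------------------------------------------
    @property
    def nodes(self) -> dict[str, GeneNode]:
        return self._nodes

    @property
    def edges(self) -> dict[tuple[str, str, str], Interaction]:
        return self._edges

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def __contains__(self, symbol: str) -> bool:
        return canonical_symbol(symbol) in self._nodes

    def node(self, symbol: str) -> GeneNode:
        key = canonical_symbol(symbol)
        if key not in self._nodes:
            raise KeyError(f"gene {symbol!r} not in network {self.name!r}")
        return self._nodes[key]

    # -- construction ------------------------------------------------------
    def add_node(self, symbol: str, node_class: str, origins=()) -> GeneNode:
        """Add or merge a node; class conflicts resolve by TF > MIRNA > PCG."""
        key = canonical_symbol(symbol)
        display = symbol.strip() if looks_like_mirna(symbol) else key
        if key in self._nodes:
            node = self._nodes[key]
            if node.node_class != node_class:
                winner = max(
                    (node.node_class, node_class), key=_CLASS_PRIORITY.__getitem__
                )
                log.warning(
                    "node class conflict for %s: %s vs %s, keeping %s",
                    node.symbol, node.node_class, node_class, winner,
                )
                node.node_class = winner
            node.origins.update(origins)
            return node
        node = GeneNode(display, node_class, set(origins))
        self._nodes[key] = node
        return node

    def add_edge(
        self,
        source: str,
        target: str,
        sign: int,
        mechanism: str | None = None,
        provenance=(),
        evidence: str = "",
    ) -> Interaction:
        """Add or merge an edge; duplicates union provenance and evidence.

        The mechanism defaults to ``post_transcriptional`` for miRNA sources
        and ``transcriptional`` otherwise.  A duplicate with a conflicting
        sign raises :class:`ValidationError`.
        """
        src, tgt = canonical_symbol(source), canonical_symbol(target)
        for key in (src, tgt):
            if key not in self._nodes:
                raise ValidationError(
                    f"edge endpoint {key!r} not in network {self.name!r}"
                )
        if src == tgt and not self.allow_self_loops:
            raise ValidationError(f"self-loop on {src!r} rejected")
        src_is_mirna = self._nodes[src].node_class == "MIRNA"
        if mechanism is None:
            mechanism = "post_transcriptional" if src_is_mirna else "transcriptional"
        if src_is_mirna and mechanism != "post_transcriptional":
            raise ValidationError(
                f"miRNA {src!r} can only act post-transcriptionally"
            )
        edge = Interaction(src, tgt, int(sign), mechanism, set(provenance), evidence)
        if edge.key in self._edges:
            existing = self._edges[edge.key]
            if existing.sign != edge.sign:
                raise ValidationError(
                    f"conflicting signs for duplicate edge {src}->{tgt} "
                    f"({mechanism}): {existing.sign} vs {edge.sign}"
                )
            existing.provenance.update(edge.provenance)
            existing.evidence = _merge_evidence(existing.evidence, edge.evidence)
            return existing
        self._edges[edge.key] = edge
        return edge

    # -- topology ----------------------------------------------------------
    def successors(self, symbol: str) -> dict[str, list[Interaction]]:
        key = canonical_symbol(symbol)
        out: dict[str, list[Interaction]] = {}
        for (s, t, _m), e in self._edges.items():
            if s == key:
                out.setdefault(t, []).append(e)
        return out

    def predecessors(self, symbol: str) -> dict[str, list[Interaction]]:
        key = canonical_symbol(symbol)
        out: dict[str, list[Interaction]] = {}
        for (s, t, _m), e in self._edges.items():
            if t == key:
                out.setdefault(s, []).append(e)
        return out

    def in_degree(self, symbol: str) -> int:
        key = canonical_symbol(symbol)
        return sum(1 for (_s, t, _m) in self._edges if t == key)

    def out_degree(self, symbol: str) -> int:
        key = canonical_symbol(symbol)
        return sum(1 for (s, _t, _m) in self._edges if s == key)

    def degree(self, symbol: str) -> int:
        return self.in_degree(symbol) + self.out_degree(symbol)

    # -- conversion / comparison -------------------------------------------
    def copy(self, name: str | None = None) -> "RegulatoryNetwork":
        out = RegulatoryNetwork(name or self.name, self.allow_self_loops)
        for key, node in self._nodes.items():
            out._nodes[key] = GeneNode(node.symbol, node.node_class, set(node.origins))
        for key, e in self._edges.items():
            out._edges[key] = Interaction(
                e.source, e.target, e.sign, e.mechanism, set(e.provenance), e.evidence
            )
        return out

    def to_networkx(self):
        """Export as a :class:`networkx.MultiDiGraph` (edge key = mechanism)."""
        import networkx as nx

        g = nx.MultiDiGraph(name=self.name)
        for key, node in self._nodes.items():
            g.add_node(
                key,
                symbol=node.symbol,
                node_class=node.node_class,
                origins=";".join(sorted(node.origins)),
            )
        for (s, t, mech), e in self._edges.items():
            g.add_edge(
                s,
                t,
                key=mech,
                sign=e.sign,
                mechanism=mech,
                provenance=";".join(sorted(e.provenance)),
                evidence=e.evidence,
            )
        return g

    def __eq__(self, other) -> bool:
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        if set(self._nodes) != set(other._nodes):
            return False
        for key, node in self._nodes.items():
            o = other._nodes[key]
            if (node.symbol, node.node_class, node.origins) != (
                o.symbol, o.node_class, o.origins
            ):
                return False
        if set(self._edges) != set(other._edges):
            return False
        for key, e in self._edges.items():
            o = other._edges[key]
            if (e.sign, e.provenance, e.evidence) != (o.sign, o.provenance, o.evidence):
                return False
        return True

    def __repr__(self) -> str:
        return (
            f"<RegulatoryNetwork {self.name!r}: {self.n_nodes} nodes, "
            f"{self.n_edges} edges>"
        )

    def validate(self) -> None:
        """Check structural invariants; raises :class:`ValidationError`."""
        for (s, t, mech), e in self._edges.items():
            if s not in self._nodes or t not in self._nodes:
                raise ValidationError(f"dangling edge {s}->{t}")
            if s == t and not self.allow_self_loops:
                raise ValidationError(f"self-loop on {s}")
            if self._nodes[s].node_class == "MIRNA" and mech != "post_transcriptional":
                raise ValidationError(
                    f"miRNA source edge {s}->{t} must be post_transcriptional"
                )


# ---------------------------------------------------------------------------
# assembly operations
# ---------------------------------------------------------------------------

def merge_networks(
    nets: list[RegulatoryNetwork],
    labels: list[str],
    node_class_policy: str | None = "priority",
) -> RegulatoryNetwork:
    """Union of several source networks with provenance bookkeeping.

    Each node's ``origins`` becomes the set of labels of the source networks
    containing it (the ring-diagram annotation).  Node-class conflicts are
    resolved by priority TF > MIRNA > PCG when ``node_class_policy`` is
    ``"priority"``; with ``node_class_policy=None`` conflicts raise a
    :class:`ValidationError` listing the conflicting symbols.
    """
    if len(nets) != len(labels):
        raise ValidationError("labels must be the same length as nets")
    merged = RegulatoryNetwork(name="merged")
    conflicts: set[str] = set()
    for net, label in zip(nets, labels):
        for key, node in net.nodes.items():
            if key in merged.nodes and merged.nodes[key].node_class != node.node_class:
                conflicts.add(node.symbol)
                if node_class_policy is None:
                    merged.nodes[key].origins.add(label)
                    continue
            merged.add_node(node.symbol, node.node_class, {label})
    if conflicts and node_class_policy is None:
        raise ValidationError(
            "node class conflicts without a resolution policy: "
            + ", ".join(sorted(conflicts))
        )
    for net in nets:
        for e in net.edges.values():
            merged.add_edge(
                e.source, e.target, e.sign, e.mechanism, set(e.provenance), e.evidence
            )
    return merged


def extract_focal_subnetwork(
    net: RegulatoryNetwork, focal: str, radius: int = 1
) -> RegulatoryNetwork:
    """Induced ego subnetwork within ``radius`` hops (either direction).

    Radius 1 keeps the focal gene plus its direct regulators and targets;
    *all* edges among the retained nodes are kept (induced subgraph), since
    downstream motif search needs edges between the focal gene's neighbors.
    """
    if radius < 0:
        raise ValidationError("radius must be >= 0")
    focal_key = canonical_symbol(focal)
    if focal_key not in net.nodes:
        raise KeyError(f"focal gene {focal!r} not in network {net.name!r}")
    adj: dict[str, set[str]] = {k: set() for k in net.nodes}
    for (s, t, _m) in net.edges:
        adj[s].add(t)
        adj[t].add(s)
    kept = {focal_key}
    frontier = {focal_key}
    for _ in range(radius):
        frontier = set().union(*(adj[u] for u in frontier)) - kept
        if not frontier:
            break
        kept |= frontier
    sub = RegulatoryNetwork(
        name=f"{net.name}:ego({net.nodes[focal_key].symbol},r={radius})",
        allow_self_loops=net.allow_self_loops,
    )
    for key in kept:
        node = net.nodes[key]
        sub.add_node(node.symbol, node.node_class, set(node.origins))
    for (s, t, _m), e in net.edges.items():
        if s in kept and t in kept:
            sub.add_edge(s, t, e.sign, e.mechanism, set(e.provenance), e.evidence)
    return sub


@dataclass
class MirnaTargetRecord:
    """One validated miRNA-target interaction (miRTarBase-like layout)."""

    mirna: str
    target_gene: str
    evidence: str = ""
    sign: int | None = None  #: explicit sign override; None = default -1


def integrate_mirna_targets(
    net: RegulatoryNetwork,
    table,
    restrict_to_existing: bool = True,
    provenance_label: str = "mirna_targets",
) -> RegulatoryNetwork:
    """Expand a network with validated miRNA-target interactions.

    ``table`` is an iterable of :class:`MirnaTargetRecord` or a DataFrame
    with columns ``miRNA``, ``target_gene``, ``evidence``.  New edges default
    to sign -1 (canonical 3'-UTR repression); a per-record ``sign`` override
    of +1 is accepted but logged, since non-repressive miRNA binding is the
    exception.  With ``restrict_to_existing`` (the default, matching the
    expansion of an existing ego network) records whose target is absent are
    skipped and counted.
    """
    if isinstance(table, pd.DataFrame):
        records = [
            MirnaTargetRecord(
                str(row.miRNA),
                str(row.target_gene),
                str(getattr(row, "evidence", "") or ""),
            )
            for row in table.itertuples(index=False)
        ]
    else:
        records = list(table)
    out = net.copy()
    n_added = n_skipped = 0
    for rec in records:
        if not rec.mirna.strip() or not rec.target_gene.strip():
            raise ValidationError(
                f"miRNA-target record with empty field: {rec!r}"
            )
        target_key = canonical_symbol(rec.target_gene)
        if target_key not in out.nodes:
            if restrict_to_existing:
                n_skipped += 1
                continue
            out.add_node(rec.target_gene, "PCG", {provenance_label})
        out.add_node(rec.mirna, "MIRNA", {provenance_label})
        sign = -1 if rec.sign is None else int(rec.sign)
        if sign != -1:
            log.warning(
                "non-repressive miRNA edge %s->%s (sign %+d) accepted",
                rec.mirna, rec.target_gene, sign,
            )
        out.add_edge(
            rec.mirna,
            rec.target_gene,
            sign,
            "post_transcriptional",
            {provenance_label},
            rec.evidence,
        )
        n_added += 1
    log.info(
        "integrated %d miRNA-target records (%d skipped: target absent)",
        n_added, n_skipped,
    )
    return out


def annotate_tfs(net: RegulatoryNetwork, tf_symbols) -> RegulatoryNetwork:
    """Re-classify nodes against a list of known human TF symbols.

    Non-miRNA nodes found in ``tf_symbols`` become ``TF``; the rest become
    ``PCG``.  miRNA nodes are never reclassified (a miRNA symbol appearing
    in the TF list is logged and ignored).
    """
    tf_keys = {canonical_symbol(s) for s in tf_symbols}
    out = net.copy()
    n_changed = 0
    for key, node in out.nodes.items():
        if node.node_class == "MIRNA":
            if key in tf_keys:
                log.warning("miRNA %s listed as TF; keeping MIRNA class", node.symbol)
            continue
        new_class = "TF" if key in tf_keys else "PCG"
        if node.node_class != new_class:
            node.node_class = new_class
            n_changed += 1
    log.info("annotate_tfs reclassified %d nodes", n_changed)
    return out


def degree_summary(net: RegulatoryNetwork) -> pd.DataFrame:
    """Degree table (hub report), sorted descending by total degree."""
    rows = []
    for key, node in net.nodes.items():
        ind, outd = net.in_degree(key), net.out_degree(key)
        rows.append(
            {
                "symbol": node.symbol,
                "node_class": node.node_class,
                "in_degree": ind,
                "out_degree": outd,
                "total_degree": ind + outd,
                "n_origins": len(node.origins),
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "symbol", "node_class", "in_degree", "out_degree",
            "total_degree", "n_origins",
        ],
    )
    return frame.sort_values(
        ["total_degree", "symbol"], ascending=[False, True]
    ).reset_index(drop=True)
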