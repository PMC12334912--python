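"""Enumeration and sign-classification of small regulatory motifs.

Two motif families are covered:

* **Feedforward loops (FFL)** — ordered triples (regulator, intermediate,
  target) with edges regulator->intermediate, intermediate->target and
  regulator->target.  An FFL is *coherent* when the sign of the direct edge
  equals the product of the two indirect-arm signs, *incoherent* otherwise.
  Subtypes 1-4 follow the standard sign-pattern convention keyed on
  (regulator->intermediate, intermediate->target, regulator->target):
  coherent (+,+,+)=C1, (-,+,-)=C2, (+,-,-)=C3, (-,-,+)=C4; incoherent
  (+,-,+)=I1, (-,+,+)=I2, (+,+,-)=I3, (-,-,-)=I4.

* **Feedback loops (FBL)** — directed simple cycles of length 2 or 3,
  *positive* when the product of the cycle's edge signs is +1 (the
  switch-forming case), *negative* otherwise.

Composite TF/miRNA motifs arise when at least one member is a miRNA, e.g.
the coherent MIR155-SOX10-MITF FFL or the positive MIR204-SOX10-ATF2 FBL.
Parallel transcriptional and post-transcriptional arms between the same
gene pair yield distinct motif instances, since their signs and dynamics
may differ.  All enumeration output is deterministically ordered.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ValidationError
from .network import RegulatoryNetwork, canonical_symbol

FFL_ROLES = ("regulator", "intermediate", "target")

#: (reg->int, int->tgt, reg->tgt) sign pattern -> (sign_class, subtype)
FFL_SIGN_TABLE = {
    (1, 1, 1): ("coherent", 1),
    (-1, 1, -1): ("coherent", 2),
    (1, -1, -1): ("coherent", 3),
    (-1, -1, 1): ("coherent", 4),
    (1, -1, 1): ("incoherent", 1),
    (-1, 1, 1): ("incoherent", 2),
    (1, 1, -1): ("incoherent", 3),
    (-1, -1, -1): ("incoherent", 4),
}


@dataclass(frozen=True)
class MotifInstance:
    """One motif occurrence.

    ``members`` is ordered by role for FFLs (regulator, intermediate,
    target) and in canonical cycle rotation for FBLs (starting at the
    lexicographically smallest symbol, following edge direction).
    ``edge_signs`` and ``mechanisms`` follow the same edge order:
    FFL (reg->int, int->tgt, reg->tgt); FBL consecutive cycle edges.
    """

    kind: str  # FFL | FBL2 | FBL3
    members: tuple[str, ...]
    edge_signs: tuple[int, ...]
    mechanisms: tuple[str, ...]
    sign_class: str
    subtype: int | None = None

    @property
    def roles(self) -> dict[str, str]:
        if self.kind == "FFL":
            return dict(zip(FFL_ROLES, self.members))
        return {f"cycle_{i}": m for i, m in enumerate(self.members)}


def classify_ffl(motif: MotifInstance) -> tuple[str, int]:
    """Sign-classify an FFL: coherent/incoherent plus subtype index."""
    if motif.kind != "FFL":
        raise ValidationError(f"classify_ffl expects an FFL, got {motif.kind}")
    return FFL_SIGN_TABLE[motif.edge_signs]


def classify_fbl(motif: MotifInstance) -> str:
    """Sign-classify a feedback loop: positive iff the sign product is +1."""
    if motif.kind not in ("FBL2", "FBL3"):
        raise ValidationError(f"classify_fbl expects an FBL, got {motif.kind}")
    product = 1
    for s in motif.edge_signs:
        product *= s
    return "positive" if product == 1 else "negative"


def _ffl_instance(net, a, b, c, e_ab, e_bc, e_ac) -> MotifInstance:
    signs = (e_ab.sign, e_bc.sign, e_ac.sign)
    sign_class, subtype = FFL_SIGN_TABLE[signs]
    return MotifInstance(
        kind="FFL",
        members=(net.nodes[a].symbol, net.nodes[b].symbol, net.nodes[c].symbol),
        edge_signs=signs,
        mechanisms=(e_ab.mechanism, e_bc.mechanism, e_ac.mechanism),
        sign_class=sign_class,
        subtype=subtype,
    )


def _passes(net, keys, require_member, require_mirna) -> bool:
    if require_member is not None and require_member not in keys:
        return False
    if require_mirna and not any(
        net.nodes[k].node_class == "MIRNA" for k in keys
    ):
        return False
    return True


def _check_member(net, require_member):
    if require_member is None:
        return None
    key = canonical_symbol(require_member)
    if key not in net.nodes:
        raise KeyError(f"require_member {require_member!r} not in network")
    return key


def enumerate_ffls(
    net: RegulatoryNetwork,
    require_member: str | None = None,
    require_mirna: bool = False,
) -> list[MotifInstance]:
    """All feedforward loops, optionally constrained to a member gene and/or
    to triples containing at least one miRNA.

    Every combination of parallel (source, target, mechanism) arms yields
    its own instance.  Output is sorted lexicographically by member symbols
    then mechanisms, so identical inputs give byte-identical output.
    """
    member_key = _check_member(net, require_member)
    succ: dict[str, dict[str, list]] = {k: {} for k in net.nodes}
    for (s, t, _m), e in net.edges.items():
        succ[s].setdefault(t, []).append(e)
    for targets in succ.values():
        for edges in targets.values():
            edges.sort(key=lambda e: e.mechanism)
    out: list[MotifInstance] = []
    for a in sorted(succ):
        for b in sorted(succ[a]):
            if b == a:
                continue
            for c in sorted(succ[b]):
                if c == a or c == b or c not in succ[a]:
                    continue
                if not _passes(net, (a, b, c), member_key, require_mirna):
                    continue
                for e_ab, e_bc, e_ac in itertools.product(
                    succ[a][b], succ[b][c], succ[a][c]
                ):
                    out.append(_ffl_instance(net, a, b, c, e_ab, e_bc, e_ac))
    out.sort(key=lambda m: (m.members, m.mechanisms))
    return out


def enumerate_fbls(
    net: RegulatoryNetwork,
    max_len: int = 3,
    require_member: str | None = None,
    require_mirna: bool = False,
) -> list[MotifInstance]:
    """All directed simple cycles of length 2 (and 3 when ``max_len`` is 3).

    Each cycle is reported once, in the canonical rotation that starts at
    the lexicographically smallest member symbol and follows edge
    direction.  Parallel mechanism arms multiply into distinct instances.
    """
    if max_len not in (2, 3):
        raise ValidationError("max_len must be 2 or 3")
    member_key = _check_member(net, require_member)
    succ: dict[str, dict[str, list]] = {k: {} for k in net.nodes}
    for (s, t, _m), e in net.edges.items():
        succ[s].setdefault(t, []).append(e)
    for targets in succ.values():
        for edges in targets.values():
            edges.sort(key=lambda e: e.mechanism)
    out: list[MotifInstance] = []
    for a in sorted(succ):
        # 2-cycles: a < b, edges both ways
        for b in sorted(succ[a]):
            if b <= a or a not in succ.get(b, {}):
                continue
            if not _passes(net, (a, b), member_key, require_mirna):
                continue
            for e_ab, e_ba in itertools.product(succ[a][b], succ[b][a]):
                signs = (e_ab.sign, e_ba.sign)
                out.append(
                    MotifInstance(
                        kind="FBL2",
                        members=(net.nodes[a].symbol, net.nodes[b].symbol),
                        edge_signs=signs,
                        mechanisms=(e_ab.mechanism, e_ba.mechanism),
                        sign_class="positive" if signs[0] * signs[1] == 1 else "negative",
                    )
                )
        if max_len < 3:
            continue
        # 3-cycles with a as the lexicographically smallest member
        for b in sorted(succ[a]):
            if b <= a:
                continue
            for c in sorted(succ.get(b, {})):
                if c <= a or c == b or a not in succ.get(c, {}):
                    continue
                if not _passes(net, (a, b, c), member_key, require_mirna):
                    continue
                for e_ab, e_bc, e_ca in itertools.product(
                    succ[a][b], succ[b][c], succ[c][a]
                ):
                    signs = (e_ab.sign, e_bc.sign, e_ca.sign)
                    product = signs[0] * signs[1] * signs[2]
                    out.append(
                        MotifInstance(
                            kind="FBL3",
                            members=(
                                net.nodes[a].symbol,
                                net.nodes[b].symbol,
                                net.nodes[c].symbol,
                            ),
                            edge_signs=signs,
                            mechanisms=(e_ab.mechanism, e_bc.mechanism, e_ca.mechanism),
                            sign_class="positive" if product == 1 else "negative",
                        )
                    )
    out.sort(key=lambda m: (m.kind, m.members, m.mechanisms))
    return out


def motif_census(
    net: RegulatoryNetwork,
    require_member: str | None = None,
    require_mirna: bool = False,
    max_len: int = 3,
) -> pd.DataFrame:
    """Count motif instances per (kind, sign_class, subtype)."""
    instances = enumerate_ffls(net, require_member, require_mirna)
    instances += enumerate_fbls(net, max_len, require_member, require_mirna)
    counts: dict[tuple, int] = {}
    for m in instances:
        key = (m.kind, m.sign_class, m.subtype if m.subtype is not None else 0)
        counts[key] = counts.get(key, 0) + 1
    rows = [
        {"kind": k, "sign_class": sc, "subtype": st, "count": n}
        for (k, sc, st), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["kind", "sign_class", "subtype", "count"])


def motif_table(instances) -> pd.DataFrame:
    """Tabulate motif instances (role-annotated members, signs, classes)."""
    rows = []
    for m in instances:
        rows.append(
            {
                "kind": m.kind,
                "members": ";".join(f"{r}={s}" for r, s in m.roles.items()),
                "edge_signs": ",".join(f"{s:+d}" for s in m.edge_signs),
                "mechanisms": ",".join(m.mechanisms),
                "sign_class": m.sign_class,
                "subtype": "" if m.subtype is None else m.subtype,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["kind", "members", "edge_signs", "mechanisms", "sign_class", "subtype"],
    )


def write_motif_table(instances, path) -> Path:
    path = Path(path)
    motif_table(instances).to_csv(path, sep="\t", index=False)
    return path
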