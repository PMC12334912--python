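"""Synthetic networks, miRNA-target tables and circuit fixtures.

These generators emulate the inputs of the network-assembly workflow —
multi-origin signed regulatory networks over TF/miRNA/PCG nodes, a
miRTarBase-like interaction table, and the two named melanoma circuits —
with known ground truth, so the whole pipeline is testable without any
external download.  Everything is deterministic under a fixed seed.

Generated PCG nodes are pure targets (no outgoing edges): only TFs and
miRNAs regulate.  miRNA out-edges are always repressive (sign -1) and
post-transcriptional.  Realistic degree distributions are out of scope.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import CapacityError, ValidationError
from .io import write_mirna_table
from .motifs import FFL_SIGN_TABLE, MotifInstance
from .network import MirnaTargetRecord, RegulatoryNetwork

EVIDENCE_VOCAB = ("reporter_assay", "western_blot", "qPCR")

_COLLISION_RETRY_CAP = 1000


# ---------------------------------------------------------------------------
# random networks
# ---------------------------------------------------------------------------

def generate_random_network(
    n_tf: int,
    n_mirna: int,
    n_pcg: int,
    edge_prob: float,
    p_activation: float = 0.6,
    seed: int = 0,
    name: str = "synthetic",
) -> RegulatoryNetwork:
    """Erdos-Renyi-style signed regulatory network over typed nodes.

    Each (regulator, target) pair with regulator a TF or miRNA is included
    independently with probability ``edge_prob``.  TF edges are activating
    with probability ``p_activation``; miRNA edges are always repressive
    and post-transcriptional.  Self-loops are never drawn.
    """
    if min(n_tf, n_mirna, n_pcg) < 0:
        raise ValidationError("node counts must be >= 0")
    if not (0 <= edge_prob <= 1 and 0 <= p_activation <= 1):
        raise ValidationError("probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    net = RegulatoryNetwork(name=name)
    tfs = [f"TF{i + 1:03d}" for i in range(n_tf)]
    mirnas = [f"MIR{900 + i + 1}" for i in range(n_mirna)]
    pcgs = [f"GENE{i + 1:03d}" for i in range(n_pcg)]
    for sym in tfs:
        net.add_node(sym, "TF", {name})
    for sym in mirnas:
        net.add_node(sym, "MIRNA", {name})
    for sym in pcgs:
        net.add_node(sym, "PCG", {name})
    regulators = tfs + mirnas
    targets = tfs + mirnas + pcgs
    for src in regulators:
        is_mirna = src in mirnas
        for tgt in targets:
            if src == tgt:
                continue
            if rng.random() >= edge_prob:
                continue
            if is_mirna:
                sign, mech = -1, "post_transcriptional"
            else:
                sign = 1 if rng.random() < p_activation else -1
                mech = "transcriptional"
            net.add_edge(src, tgt, sign, mech, {name})
    return net


# ---------------------------------------------------------------------------
# independent brute-force motif scan (kept separate from regmotif.motifs)
# ---------------------------------------------------------------------------

def brute_force_motif_counts(net: RegulatoryNetwork) -> dict[str, int]:
    """Exhaustive scan over all ordered node pairs/triples.

    Deliberately naive and independent of the enumeration module: used to
    verify collision-free planting at generation time.  Counts instances
    including parallel-mechanism arm combinations.
    """
    keys = sorted(net.nodes)
    edges: dict[tuple[str, str], list] = {}
    for (s, t, _m), e in net.edges.items():
        edges.setdefault((s, t), []).append(e)

    def n_arms(a, b):
        return len(edges.get((a, b), ()))

    counts = {"FFL": 0, "FBL2": 0, "FBL3": 0}
    for a, b, c in itertools.permutations(keys, 3):
        counts["FFL"] += n_arms(a, b) * n_arms(b, c) * n_arms(a, c)
    for a, b in itertools.combinations(keys, 2):
        counts["FBL2"] += n_arms(a, b) * n_arms(b, a)
    for trio in itertools.combinations(keys, 3):
        for a, b, c in ((trio[0], trio[1], trio[2]), (trio[0], trio[2], trio[1])):
            counts["FBL3"] += n_arms(a, b) * n_arms(b, c) * n_arms(c, a)
    return counts


# ---------------------------------------------------------------------------
# motif planting
# ---------------------------------------------------------------------------

@dataclass
class PlantedGroundTruth:
    """Exact members and signs of every planted motif, plus the generator
    parameters, serializable to JSON for downstream comparisons."""

    instances: list[MotifInstance]
    params: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "params": self.params,
            "instances": [
                {
                    "kind": m.kind,
                    "members": list(m.members),
                    "edge_signs": list(m.edge_signs),
                    "mechanisms": list(m.mechanisms),
                    "sign_class": m.sign_class,
                    "subtype": m.subtype,
                }
                for m in self.instances
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text


def _plant_ffl(net, idx, coherent, rng):
    """Plant one miRNA-regulated FFL on three fresh nodes.

    The regulator is a miRNA (both of its arms repressive); the
    intermediate TF->target sign sets coherence: with the direct arm at
    -1, an activating intermediate arm gives (-1)(+1) = -1 = coherent,
    a repressing one (-1)(-1) = +1 != -1 = incoherent.
    """
    tag = f"{'C' if coherent else 'I'}{idx:02d}"
    mir, tf, tgt = f"MIR7{tag}", f"TFP{tag}", f"GENEP{tag}"
    net.add_node(mir, "MIRNA", {"planted"})
    net.add_node(tf, "TF", {"planted"})
    net.add_node(tgt, "PCG", {"planted"})
    s_mid = 1 if coherent else -1
    net.add_edge(mir, tf, -1, "post_transcriptional", {"planted"})
    net.add_edge(tf, tgt, s_mid, "transcriptional", {"planted"})
    net.add_edge(mir, tgt, -1, "post_transcriptional", {"planted"})
    signs = (-1, s_mid, -1)
    sign_class, subtype = FFL_SIGN_TABLE[signs]
    return MotifInstance(
        kind="FFL",
        members=(mir, tf, tgt),
        edge_signs=signs,
        mechanisms=("post_transcriptional", "transcriptional", "post_transcriptional"),
        sign_class=sign_class,
        subtype=subtype,
    )


def _plant_fbl3(net, idx, positive, rng):
    """Plant one 3-node cycle through a miRNA on fresh nodes.

    Positive: miR -| A, A -| B, B -> miR (product +1); negative: miR -| A,
    A -> B, B -> miR (product -1).  Cycle members are recorded in the
    canonical rotation (lexicographically smallest symbol first).
    """
    tag = f"{'P' if positive else 'N'}{idx:02d}"
    mir, a, b = f"MIR8{tag}", f"TFQ{tag}", f"TFR{tag}"
    net.add_node(mir, "MIRNA", {"planted"})
    net.add_node(a, "TF", {"planted"})
    net.add_node(b, "TF", {"planted"})
    s_ab = -1 if positive else 1
    net.add_edge(mir, a, -1, "post_transcriptional", {"planted"})
    net.add_edge(a, b, s_ab, "transcriptional", {"planted"})
    net.add_edge(b, mir, 1, "transcriptional", {"planted"})
    # canonical rotation: MIR8... < TFQ... < TFR...
    members = (mir, a, b)
    signs = (-1, s_ab, 1)
    mechs = ("post_transcriptional", "transcriptional", "transcriptional")
    product = signs[0] * signs[1] * signs[2]
    return MotifInstance(
        kind="FBL3",
        members=members,
        edge_signs=signs,
        mechanisms=mechs,
        sign_class="positive" if product == 1 else "negative",
    )


def plant_motifs(
    net: RegulatoryNetwork,
    k_coherent_ffl: int = 0,
    k_incoherent_ffl: int = 0,
    k_positive_fbl3: int = 0,
    k_negative_fbl3: int = 0,
    seed: int = 0,
    collision_free: bool = True,
) -> tuple[RegulatoryNetwork, PlantedGroundTruth]:
    """Add motifs with known ground truth on fresh nodes.

    With ``collision_free`` the output is re-scanned by the independent
    brute-force counter and must contain exactly the planted motifs on top
    of whatever the base network already had; a base network that already
    obscures the planted counts exhausts the retry budget and raises
    :class:`CapacityError`.
    """
    rng = np.random.default_rng(seed)
    if collision_free:
        base_counts = brute_force_motif_counts(net)
        if any(base_counts.values()):
            raise CapacityError(
                "collision_free planting requires a motif-free base network; "
                f"base already contains {base_counts}"
            )
    for _attempt in range(_COLLISION_RETRY_CAP):
        out = net.copy()
        planted: list[MotifInstance] = []
        for i in range(k_coherent_ffl):
            planted.append(_plant_ffl(out, i + 1, True, rng))
        for i in range(k_incoherent_ffl):
            planted.append(_plant_ffl(out, i + 1, False, rng))
        for i in range(k_positive_fbl3):
            planted.append(_plant_fbl3(out, i + 1, True, rng))
        for i in range(k_negative_fbl3):
            planted.append(_plant_fbl3(out, i + 1, False, rng))
        truth = PlantedGroundTruth(
            instances=planted,
            params={
                "k_coherent_ffl": k_coherent_ffl,
                "k_incoherent_ffl": k_incoherent_ffl,
                "k_positive_fbl3": k_positive_fbl3,
                "k_negative_fbl3": k_negative_fbl3,
                "seed": seed,
                "collision_free": collision_free,
            },
        )
        if not collision_free:
            return out, truth
        counts = brute_force_motif_counts(out)
        expected = {
            "FFL": k_coherent_ffl + k_incoherent_ffl,
            "FBL2": 0,
            "FBL3": k_positive_fbl3 + k_negative_fbl3,
        }
        if counts == expected:
            return out, truth
    raise CapacityError(
        f"could not plant motifs collision-free in {_COLLISION_RETRY_CAP} attempts"
    )


# ---------------------------------------------------------------------------
# named circuits fixture
# ---------------------------------------------------------------------------

def fixture_melanoma_circuits() -> RegulatoryNetwork:
    """The two named melanoma circuits in one five-gene network.

    Contains the coherent feedforward loop miR-155 -| SOX10, SOX10 -> MITF,
    miR-155 -| MITF, and the positive feedback loop ATF2 -| SOX10,
    SOX10 -> miR-204, miR-204 -| ATF2.
    """
    net = RegulatoryNetwork(name="melanoma_circuits")
    net.add_node("SOX10", "TF", {"melanoma"})
    net.add_node("MITF", "TF", {"melanoma"})
    net.add_node("ATF2", "TF", {"melanoma"})
    net.add_node("miR-155", "MIRNA", {"melanoma"})
    net.add_node("miR-204", "MIRNA", {"melanoma"})
    net.add_edge("miR-155", "SOX10", -1, "post_transcriptional", {"melanoma"})
    net.add_edge("miR-155", "MITF", -1, "post_transcriptional", {"melanoma"})
    net.add_edge("SOX10", "MITF", 1, "transcriptional", {"melanoma"})
    net.add_edge("miR-204", "ATF2", -1, "post_transcriptional", {"melanoma"})
    net.add_edge("ATF2", "SOX10", -1, "transcriptional", {"melanoma"})
    net.add_edge("SOX10", "miR-204", 1, "transcriptional", {"melanoma"})
    return net


# ---------------------------------------------------------------------------
# miRNA-target table
# ---------------------------------------------------------------------------

def generate_mirna_target_table(
    mirnas,
    targets_per_mirna: int,
    seed: int = 0,
    target_pool=None,
    path=None,
) -> list[MirnaTargetRecord]:
    """Random miRTarBase-like records, reproducible under a fixed seed.

    Targets are sampled without replacement per miRNA from ``target_pool``
    (default: a synthetic gene universe); evidence tags come from a small
    fixed vocabulary so downstream dedup/concat logic gets exercised.
    Writes a TSV when ``path`` is given.
    """
    if targets_per_mirna < 0:
        raise ValidationError("targets_per_mirna must be >= 0")
    rng = np.random.default_rng(seed)
    pool = list(target_pool) if target_pool is not None else [
        f"GENE{i + 1:03d}" for i in range(max(50, targets_per_mirna))
    ]
    if targets_per_mirna > len(pool):
        raise ValidationError("target pool smaller than targets_per_mirna")
    records = []
    for mirna in mirnas:
        chosen = rng.choice(len(pool), size=targets_per_mirna, replace=False)
        for j in sorted(chosen):
            records.append(
                MirnaTargetRecord(
                    mirna=mirna,
                    target_gene=pool[j],
                    evidence=EVIDENCE_VOCAB[int(rng.integers(len(EVIDENCE_VOCAB)))],
                )
            )
    if path is not None:
        write_mirna_table(records, path)
    return records
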