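"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive and written against the raw edge
dictionaries, not against the enumeration or root-finding code paths it
validates.
"""

from __future__ import annotations

import itertools

import numpy as np


def _arm_map(net):
    arms: dict[tuple[str, str], list] = {}
    for (s, t, _m), e in net.edges.items():
        arms.setdefault((s, t), []).append(e)
    for lst in arms.values():
        lst.sort(key=lambda e: e.mechanism)
    return arms


def _display(net, key):
    return net.nodes[key].symbol


def brute_ffls(net, require_member=None, require_mirna=False):
    """All FFL instances as comparable tuples, by exhaustive triple scan."""
    arms = _arm_map(net)
    keys = sorted(net.nodes)
    out = set()
    for a, b, c in itertools.permutations(keys, 3):
        if (a, b) not in arms or (b, c) not in arms or (a, c) not in arms:
            continue
        if require_member is not None and require_member not in (a, b, c):
            continue
        if require_mirna and not any(
            net.nodes[k].node_class == "MIRNA" for k in (a, b, c)
        ):
            continue
        for e1, e2, e3 in itertools.product(arms[a, b], arms[b, c], arms[a, c]):
            out.add(
                (
                    "FFL",
                    (_display(net, a), _display(net, b), _display(net, c)),
                    (e1.sign, e2.sign, e3.sign),
                    (e1.mechanism, e2.mechanism, e3.mechanism),
                )
            )
    return out


def brute_fbls(net, max_len=3, require_member=None, require_mirna=False):
    """All 2- and 3-cycles in canonical rotation, by exhaustive scan."""
    arms = _arm_map(net)
    keys = sorted(net.nodes)
    out = set()
    for a, b in itertools.combinations(keys, 2):
        if (a, b) not in arms or (b, a) not in arms:
            continue
        if require_member is not None and require_member not in (a, b):
            continue
        if require_mirna and not any(
            net.nodes[k].node_class == "MIRNA" for k in (a, b)
        ):
            continue
        for e1, e2 in itertools.product(arms[a, b], arms[b, a]):
            out.add(
                (
                    "FBL2",
                    (_display(net, a), _display(net, b)),
                    (e1.sign, e2.sign),
                    (e1.mechanism, e2.mechanism),
                )
            )
    if max_len < 3:
        return out
    for trio in itertools.combinations(keys, 3):
        for a, b, c in (
            (trio[0], trio[1], trio[2]),
            (trio[0], trio[2], trio[1]),
        ):
            # a is the lexicographically smallest of the trio by construction
            if (a, b) not in arms or (b, c) not in arms or (c, a) not in arms:
                continue
            if require_member is not None and require_member not in (a, b, c):
                continue
            if require_mirna and not any(
                net.nodes[k].node_class == "MIRNA" for k in (a, b, c)
            ):
                continue
            for e1, e2, e3 in itertools.product(
                arms[a, b], arms[b, c], arms[c, a]
            ):
                out.add(
                    (
                        "FBL3",
                        (_display(net, a), _display(net, b), _display(net, c)),
                        (e1.sign, e2.sign, e3.sign),
                        (e1.mechanism, e2.mechanism, e3.mechanism),
                    )
                )
    return out


def instances_as_tuples(instances):
    """Project MotifInstance objects onto the oracle tuple format."""
    return {
        (m.kind, m.members, m.edge_signs, m.mechanisms) for m in instances
    }


def fbl_steady_sox10_1d(params, atf2, n_grid=6000):
    """Steady SOX10 levels of the feedback loop by dense-grid sign change.

    Reduces the loop to a scalar fixed-point equation g(S) = S using the
    quasi-steady miR-204 level, then brackets every root by sign change and
    refines with bisection — no Newton iteration, no shared code with
    ``find_steady_states``.
    """
    def g(S):
        M = (params.beta_mir / params.delta_mir) * S ** params.n_sox_mir / (
            params.k_sox_mir ** params.n_sox_mir + S ** params.n_sox_mir
        )
        a_eff = (atf2 + params.atf2_basal) * params.k_mir_atf ** params.n_mir_atf / (
            params.k_mir_atf ** params.n_mir_atf + M ** params.n_mir_atf
        )
        return (params.beta_sox / params.delta_sox) * (
            params.k_atf_sox ** params.n_atf_sox
            / (params.k_atf_sox ** params.n_atf_sox + a_eff ** params.n_atf_sox)
        )

    hi = 1.05 * params.beta_sox / params.delta_sox
    grid = np.linspace(0.0, hi, n_grid)
    f = np.array([g(s) - s for s in grid])
    roots = []
    for i in range(n_grid - 1):
        if np.sign(f[i]) != np.sign(f[i + 1]):
            lo_x, hi_x = grid[i], grid[i + 1]
            for _ in range(60):
                mid = 0.5 * (lo_x + hi_x)
                if np.sign(g(mid) - mid) == np.sign(g(lo_x) - lo_x):
                    lo_x = mid
                else:
                    hi_x = mid
            roots.append(0.5 * (lo_x + hi_x))
    return roots
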