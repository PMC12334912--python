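"""End-to-end pipeline runs behind the command-line interface.

Each scenario loads its versioned config (packaged YAML, overridable from a
user file), runs the corresponding analysis, writes tabular outputs plus a
JSON summary into the output directory, and echoes the full configuration
and seed to a run manifest so every run is reproducible and auditable.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .analysis import (
    find_steady_states,
    hysteresis_sweep,
    leaky_transcript_comparison,
    measure_response_delay,
    phase_report,
    pulse_rejection,
    scan_bifurcation,
)
from .circuits import (
    FblParams,
    InputFunctionSpec,
    LeakParams,
    PhenotypeMap,
    SignalProfile,
    build_fbl_model,
    build_ffl_model,
    classify_phenotype,
    input_response,
    melanoma_state_map,
    response_sensitivity,
    sample_ffl_params,
    simulate,
)
from .errors import ValidationError
from .io import read_edge_table, read_mirna_table, read_tf_list, write_network
from .motifs import enumerate_fbls, enumerate_ffls, motif_census, write_motif_table
from .network import (
    annotate_tfs,
    degree_summary,
    extract_focal_subnetwork,
    integrate_mirna_targets,
    merge_networks,
)

SCENARIOS = (
    "input-functions",
    "leak-suppression",
    "delay-and",
    "delay-or",
    "bifurcation",
    "hysteresis",
)

_SCENARIO_FILES = {name: name.replace("-", "_") + ".yaml" for name in SCENARIOS}


def load_scenario_config(scenario: str, override_path=None) -> dict:
    """Packaged scenario defaults, optionally overlaid by a user YAML."""
    if scenario not in SCENARIOS:
        raise ValidationError(
            f"unknown scenario {scenario!r}; choose from {SCENARIOS}"
        )
    ref = resources.files("regmotif.scenarios") / _SCENARIO_FILES[scenario]
    cfg = yaml.safe_load(ref.read_text(encoding="utf-8"))
    if override_path is not None:
        user = yaml.safe_load(Path(override_path).read_text(encoding="utf-8")) or {}
        cfg.update(user)
    return cfg


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=_jsonable) + "\n",
        encoding="utf-8",
    )


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _manifest(outdir: Path, scenario: str, seed: int, cfg: dict) -> None:
    _write_json(
        {
            "tool": "regmotif",
            "version": __version__,
            "scenario": scenario,
            "seed": seed,
            "config": cfg,
        },
        outdir / "manifest.json",
    )


def _grid(spec: dict) -> np.ndarray:
    return np.linspace(spec["start"], spec["stop"], int(spec["num"]))


# ---------------------------------------------------------------------------
# network pipeline commands
# ---------------------------------------------------------------------------

def run_build_network(
    edge_inputs: list[tuple[str, str]],
    outdir,
    focal: str | None = None,
    radius: int = 1,
    mirna_table=None,
    tf_list=None,
    seed: int = 0,
) -> dict:
    """Merge labeled source networks, optionally extract a focal ego
    subnetwork, integrate miRNA targets, and annotate TFs.

    Writes the result as GraphML and TSV plus a degree summary and a run
    manifest; returns a small report dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nets = [read_edge_table(path) for _label, path in edge_inputs]
    labels = [label for label, _path in edge_inputs]
    net = merge_networks(nets, labels) if len(nets) > 1 else nets[0].copy()
    if len(nets) == 1:
        for node in net.nodes.values():
            node.origins.add(labels[0])
    if focal is not None:
        net = extract_focal_subnetwork(net, focal, radius)
    if mirna_table is not None:
        net = integrate_mirna_targets(net, read_mirna_table(mirna_table))
    if tf_list is not None:
        net = annotate_tfs(net, read_tf_list(tf_list))
    net.name = "assembled"
    write_network(net, outdir / "network.graphml", "GraphML")
    write_network(net, outdir / "network.tsv", "TSV")
    degrees = degree_summary(net)
    degrees.to_csv(outdir / "degree_summary.tsv", sep="\t", index=False)
    report = {
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "focal": focal,
        "radius": radius,
        "top_hubs": degrees.head(5)["symbol"].tolist(),
    }
    _manifest(
        outdir, "build-network", seed,
        {
            "edge_inputs": [list(pair) for pair in edge_inputs],
            "focal": focal, "radius": radius,
            "mirna_table": str(mirna_table) if mirna_table else None,
            "tf_list": str(tf_list) if tf_list else None,
        },
    )
    _write_json(report, outdir / "summary.json")
    return report


def run_find_motifs(
    network_path,
    outdir,
    require_member: str | None = None,
    require_mirna: bool = False,
    max_len: int = 3,
    seed: int = 0,
) -> dict:
    """Enumerate FFL/FBL motifs in a network file and write list + census."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net = read_edge_table(network_path)
    ffls = enumerate_ffls(net, require_member, require_mirna)
    fbls = enumerate_fbls(net, max_len, require_member, require_mirna)
    write_motif_table(ffls + fbls, outdir / "motifs.tsv")
    census = motif_census(net, require_member, require_mirna, max_len)
    census.to_csv(outdir / "census.tsv", sep="\t", index=False)
    report = {
        "n_ffl": len(ffls),
        "n_fbl": len(fbls),
        "n_coherent_ffl": sum(m.sign_class == "coherent" for m in ffls),
        "n_positive_fbl": sum(m.sign_class == "positive" for m in fbls),
    }
    _manifest(
        outdir, "find-motifs", seed,
        {
            "network": str(network_path), "require_member": require_member,
            "require_mirna": require_mirna, "max_len": max_len,
        },
    )
    _write_json(report, outdir / "summary.json")
    return report


# ---------------------------------------------------------------------------
# simulation scenarios
# ---------------------------------------------------------------------------

def run_scenario(scenario: str, seed: int, outdir, config_path=None) -> dict:
    """Dispatch a simulation scenario; returns its summary dict."""
    cfg = load_scenario_config(scenario, config_path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    runner = {
        "input-functions": _run_input_functions,
        "leak-suppression": _run_leak_suppression,
        "delay-and": _run_delay,
        "delay-or": _run_delay,
        "bifurcation": _run_bifurcation,
        "hysteresis": _run_hysteresis,
    }[scenario]
    summary = runner(cfg, seed, outdir)
    _manifest(outdir, scenario, seed, cfg)
    _write_json(summary, outdir / "summary.json")
    return summary


def _run_input_functions(cfg: dict, seed: int, outdir: Path) -> dict:
    import pandas as pd

    specs = {
        "linear": InputFunctionSpec("linear", **cfg["linear"]),
        "saturated": InputFunctionSpec("saturated", **cfg["saturated"]),
        "sigmoidal": InputFunctionSpec("sigmoidal", **cfg["sigmoidal"]),
    }
    grid = _grid(cfg["grid"])
    frame = pd.DataFrame({"sox10": grid})
    for name, spec in specs.items():
        frame[name] = input_response(spec, grid)
        frame[name + "_sensitivity"] = response_sensitivity(spec, grid)
    frame.to_csv(outdir / "input_functions.tsv", sep="\t", index=False)
    pm_cfg = cfg["phenotype_map"]
    pmap = PhenotypeMap(
        tuple(pm_cfg["boundaries"]),
        ("senescence", "invasion", "proliferation", "differentiation"),
        pm_cfg["gray_width"],
    )
    sig = specs["sigmoidal"]
    mitf_sweep = input_response(sig, grid)
    calls = classify_phenotype(mitf_sweep, pmap)
    pd.DataFrame({"sox10": grid, "mitf": mitf_sweep, "phenotype": calls}).to_csv(
        outdir / "phenotype_sweep.tsv", sep="\t", index=False
    )
    sat_equiv = InputFunctionSpec(
        "sigmoidal", v_max=cfg["saturated"]["v_max"],
        k_half=cfg["saturated"]["k_half"], hill_n=1.0,
    )
    max_diff = float(
        np.max(np.abs(input_response(sat_equiv, grid) - input_response(specs["saturated"], grid)))
    )
    return {
        "sigmoidal_midpoint": float(input_response(sig, sig.k_half)),
        "sigmoidal_v_max_half": sig.v_max / 2.0,
        "sigmoidal_sensitivity_argmax": float(
            sig.k_half * ((sig.hill_n - 1) / (sig.hill_n + 1)) ** (1 / sig.hill_n)
        ),
        "saturated_vs_hill1_max_abs_diff": max_diff,
        "phenotype_calls": sorted(set(calls), key=calls.index),
    }


def _run_leak_suppression(cfg: dict, seed: int, outdir: Path) -> dict:
    import pandas as pd

    base = LeakParams(**cfg["params"])
    signal = SignalProfile.step(float(cfg["hypoxia_onset"]), 0.0, 1.0)
    t_end = float(cfg["t_end"])
    rows = []
    for lam in cfg["lam_grid"]:
        p = LeakParams(
            beta_mrna=base.beta_mrna, delta_mrna=base.delta_mrna, lam=float(lam),
            beta_mir=base.beta_mir, delta_mir=base.delta_mir,
        )
        comp = leaky_transcript_comparison(p, signal, t_end)
        rows.append(
            {
                "lam": lam,
                "auc_with": comp.auc_with,
                "auc_without": comp.auc_without,
                "t10_with": comp.t10_with,
                "t10_without": comp.t10_without,
            }
        )
    frame = pd.DataFrame(rows)
    frame.to_csv(outdir / "leak_metrics.tsv", sep="\t", index=False)
    comp = leaky_transcript_comparison(base, signal, t_end)
    comp.with_mirna.to_tsv(outdir / "trajectory_with_mirna.tsv")
    comp.without_mirna.to_tsv(outdir / "trajectory_without_mirna.tsv")
    aucs = frame["auc_with"].to_numpy()
    return {
        "auc_without_mirna": float(frame["auc_without"].iloc[0]),
        "auc_with_mirna": aucs.tolist(),
        "all_below_control": bool((aucs < frame["auc_without"].to_numpy()).all()),
        "monotone_decreasing_in_lam": bool((np.diff(aucs) < 0).all()),
        "auc_ratio_at_max_lam": float(aucs[-1] / frame["auc_without"].iloc[-1]),
    }


def _run_delay(cfg: dict, seed: int, outdir: Path) -> dict:
    import pandas as pd

    gate = cfg["gate"]
    durations = cfg["signal"]
    t_off = float(durations["phase_on"])
    t_on = t_off + float(durations["phase_off"])
    t_end = t_on + float(durations["phase_tail"])
    signal = SignalProfile((t_off, t_on), (1.0, 0.0, 1.0))
    model = build_ffl_model(gate=gate, logic_mode=cfg["logic_mode"])
    traj = simulate(model, signal, t_end)
    traj.to_tsv(outdir / "trajectory_default.tsv")

    def delay_diffs(m):
        tr = simulate(m, signal, t_end)
        off = measure_response_delay(tr, "MITF", t_off) - measure_response_delay(
            tr, "SOX10", t_off
        )
        on = measure_response_delay(tr, "MITF", t_on) - measure_response_delay(
            tr, "SOX10", t_on
        )
        return off, on

    off_default, on_default = delay_diffs(model)
    eps = float(cfg["epsilon"])
    pulse = float(cfg["short_pulse"])
    pr_default = pulse_rejection(model, [pulse], epsilon=eps)
    rng = np.random.default_rng(seed)
    rows = []
    for draw in range(int(cfg["n_draws"])):
        params = sample_ffl_params(rng)
        m = build_ffl_model(params, gate=gate, logic_mode=cfg["logic_mode"])
        off, on = delay_diffs(m)
        exc = float(pulse_rejection(m, [pulse], epsilon=eps).excursions[0])
        rows.append(
            {"draw": draw, "off_diff": off, "on_diff": on, "pulse_excursion": exc}
        )
    frame = pd.DataFrame(rows)
    frame.to_csv(outdir / "delay_sweep.tsv", sep="\t", index=False)
    if gate == "AND":
        asym_rate = float((frame["off_diff"] > frame["on_diff"]).mean())
        pulse_rate = float((frame["pulse_excursion"] < eps).mean())
    else:
        asym_rate = float((frame["on_diff"] > frame["off_diff"]).mean())
        pulse_rate = float((frame["pulse_excursion"] > eps).mean())
    return {
        "gate": gate,
        "off_delay_difference": off_default,
        "on_delay_difference": on_default,
        "short_pulse_excursion": float(pr_default.excursions[0]),
        "epsilon": eps,
        "n_draws": int(cfg["n_draws"]),
        "delay_asymmetry_rate": asym_rate,
        "pulse_behavior_rate": pulse_rate,
    }


def _run_bifurcation(cfg: dict, seed: int, outdir: Path) -> dict:
    grid = _grid(cfg["grid"])
    phys = (float(cfg["physical_min"]), float("inf"))
    base = FblParams(**cfg["params"]) if cfg["params"] else FblParams()
    model = build_fbl_model(base)
    diag = scan_bifurcation(model, grid, phys, seed=seed)
    diag.frame().to_csv(outdir / "bifurcation.tsv", sep="\t", index=False)

    hill1 = FblParams(
        **{
            **base.__dict__,
            "n_atf_sox": 1.0, "n_sox_mir": 1.0, "n_mir_atf": 1.0, "n_sox_mitf": 1.0,
        }
    )
    diag1 = scan_bifurcation(build_fbl_model(hill1), grid, phys, seed=seed)
    irrev = FblParams(
        **{**base.__dict__, "atf2_basal": float(cfg["irreversible_basal"])}
    )
    diag_irrev = scan_bifurcation(build_fbl_model(irrev), grid, phys, seed=seed)
    diag_irrev.frame().to_csv(
        outdir / "bifurcation_basal_variant.tsv", sep="\t", index=False
    )
    return {
        "default": diag.summary(),
        "hill1_variant": diag1.summary(),
        "basal_variant": diag_irrev.summary(),
    }


def _run_hysteresis(cfg: dict, seed: int, outdir: Path) -> dict:
    import pandas as pd

    grid = _grid(cfg["grid"])
    base = FblParams(**cfg["params"]) if cfg["params"] else FblParams()
    model = build_fbl_model(base)
    sweep = hysteresis_sweep(model, grid, dwell=float(cfg["dwell"]))
    pd.DataFrame(
        {
            "parameter_up": sweep.grid_up,
            "sox10_up": sweep.sox10_up,
            "parameter_down": sweep.grid_down,
            "sox10_down": sweep.sox10_down,
        }
    ).to_csv(outdir / "hysteresis.tsv", sep="\t", index=False)
    diag = scan_bifurcation(model, grid, seed=seed)
    step = float(grid[1] - grid[0])

    replay = cfg["replay"]
    duration = float(replay["duration"])
    levels = [float(v) for v in replay["levels"]]
    breaks = tuple(duration * (i + 1) for i in range(len(levels) - 1))
    signal = SignalProfile(breaks, tuple(levels))
    fps = find_steady_states(model, levels[0], seed=seed)
    on_state = max((f for f in fps if f.stable), key=lambda f: f.sox10).state
    traj = simulate(model, signal, duration * len(levels), initial_state=on_state)
    traj.to_tsv(outdir / "replay_trajectory.tsv")
    smap = melanoma_state_map(
        tuple(cfg["state_map"]["boundaries"]), cfg["state_map"]["gray_width"]
    )
    report = phase_report(traj, smap, species="MITF")
    report.to_csv(outdir / "replay_phenotypes.tsv", sep="\t", index=False)
    mid = 0.5 * (sweep.sox10_up.max() + sweep.sox10_up.min())
    plateaus = [
        float(
            np.mean(
                traj.series("SOX10")[
                    (traj.t >= (i + 0.9) * duration) & (traj.t <= (i + 1) * duration)
                ]
            )
        )
        for i in range(len(levels))
    ]
    return {
        "threshold_up": sweep.threshold_up,
        "threshold_down": sweep.threshold_down,
        "loop_width": sweep.loop_width,
        "fold_left": diag.fold_left,
        "fold_right": diag.fold_right,
        "grid_step": step,
        "up_matches_right_fold": bool(
            sweep.threshold_up is not None
            and diag.fold_right is not None
            and abs(sweep.threshold_up - diag.fold_right) <= 2 * step
        ),
        "down_matches_left_fold": bool(
            sweep.threshold_down is not None
            and diag.fold_left is not None
            and abs(sweep.threshold_down - diag.fold_left) <= 2 * step
        ),
        "replay_sox10_plateaus": plateaus,
        "replay_states": ["ON" if p > mid else "OFF" for p in plateaus],
        "replay_phenotypes": report["phenotype"].tolist(),
    }
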