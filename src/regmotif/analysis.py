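"""Dynamical analyses of the simulated circuits.

Covers the response-delay metric behind the sign-sensitive-delay property
of coherent feedforward loops, transient-pulse rejection, the leaky-
transcript comparison, and the fixed-point machinery for the positive
feedback loop: multi-start steady-state solving, saddle-node (fold)
bracketing across a scanned parameter, reversibility classification, and
quasi-static hysteresis sweeps.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .circuits import (
    CircuitModel,
    FflCircuit,
    LeakCircuit,
    LeakParams,
    PhenotypeMap,
    SignalProfile,
    Trajectory,
    classify_phenotype,
    simulate,
)
from .errors import AnalysisError, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "measure_response_delay", "pulse_rejection", "PulseRejectionResult",
    "leaky_transcript_comparison", "LeakComparison",
    "FixedPoint", "find_steady_states", "BifurcationDiagram",
    "scan_bifurcation", "HysteresisResult", "hysteresis_sweep",
    "phase_report",
]


# ---------------------------------------------------------------------------
# response delay
# ---------------------------------------------------------------------------

def _plateau(t, x, a, b, fraction=0.1, cv_tol=0.02, what="", scale_floor=0.0):
    """Mean of the trailing ``fraction`` of ``[a, b]``; checks flatness.

    Flatness is judged relative to the larger of the plateau level and
    ``scale_floor`` (typically the species' full dynamic range), so
    near-zero plateaus do not fail on numerically tiny fluctuations.
    """
    lo = b - fraction * (b - a)
    mask = (t >= lo) & (t <= b)
    if mask.sum() < 3:
        raise AnalysisError(f"too few samples to estimate a plateau {what}")
    window = x[mask]
    mean = float(window.mean())
    scale = max(abs(mean), scale_floor, 1e-12)
    if window.std() / scale > cv_tol:
        raise AnalysisError(
            f"no steady plateau detected {what}; extend the interval or t_end"
        )
    return mean


def measure_response_delay(
    traj: Trajectory,
    species: str,
    transition_time: float,
    direction: str = "auto",
) -> float:
    """Time from a signal transition until a species crosses the midpoint
    between its pre- and post-transition steady levels.

    Steady levels are estimated from plateau windows: the trailing 10 % of
    the signal interval before the transition and of the interval after it
    (up to the next breakpoint or the end of the trajectory).  For a lone
    first-order gene switched on, the metric reduces to the half-life
    ``ln 2 / delta``.
    """
    x = traj.series(species)
    t = traj.t
    breaks = sorted(traj.meta.get("breakpoints", ()))
    if not any(math.isclose(b, transition_time, rel_tol=1e-9) for b in breaks):
        breaks = sorted(set(breaks) | {transition_time})
    if not (t[0] < transition_time < t[-1]):
        raise AnalysisError("transition_time outside the trajectory span")
    pre_start = max([t[0]] + [b for b in breaks if b < transition_time])
    post_end = min([t[-1]] + [b for b in breaks if b > transition_time])
    floor = 0.05 * float(np.ptp(x))
    pre = _plateau(
        t, x, pre_start, transition_time,
        what=f"before t={transition_time:g}", scale_floor=floor,
    )
    post = _plateau(
        t, x, transition_time, post_end,
        what=f"after t={transition_time:g}", scale_floor=floor,
    )
    if direction == "auto":
        direction = "up" if post > pre else "down"
    if direction not in ("up", "down"):
        raise ValidationError("direction must be 'up', 'down' or 'auto'")
    mid = 0.5 * (pre + post)
    mask = (t >= transition_time) & (t <= post_end)
    tt, xx = t[mask], x[mask]
    crossed = xx >= mid if direction == "up" else xx <= mid
    idx = np.argmax(crossed)
    if not crossed.any():
        raise AnalysisError(
            f"{species} never crosses its midpoint after t={transition_time:g}"
        )
    if idx == 0:
        return 0.0
    # linear interpolation between the bracketing samples
    t0, t1 = tt[idx - 1], tt[idx]
    x0, x1 = xx[idx - 1], xx[idx]
    if x1 == x0:
        t_cross = t1
    else:
        t_cross = t0 + (mid - x0) * (t1 - t0) / (x1 - x0)
    return float(t_cross - transition_time)


# ---------------------------------------------------------------------------
# transient-pulse rejection
# ---------------------------------------------------------------------------

@dataclass
class PulseRejectionResult:
    """Excursion of the target per tested pulse duration.

    ``excursions`` are normalized by the sustained-step dynamic range, so
    ``epsilon`` is a fraction of full range.  ``minimal_duration`` is the
    shortest pulse whose excursion exceeds ``epsilon`` (None if no pulse
    in the grid does).
    """

    durations: np.ndarray
    excursions: np.ndarray
    epsilon: float
    minimal_duration: float | None
    dynamic_range: float


def pulse_rejection(
    model: FflCircuit,
    pulse_durations,
    baseline_level: float = 1.0,
    epsilon: float = 0.05,
    species: str = "MITF",
    t_settle: float = 12.0,
    t_tail: float = 6.0,
) -> PulseRejectionResult:
    """Probe persistence detection: drop the signal for each pulse duration
    and measure the target's excursion relative to its sustained response.

    The AND-gated coherent loop rejects pulses shorter than the SOX10
    threshold-crossing time; the OR-gated loop responds to them.
    """
    durations = np.asarray(sorted(pulse_durations), dtype=float)
    if durations.size == 0:
        raise ValidationError("pulse_durations must be non-empty")
    if np.any(durations <= 0):
        raise ValidationError("pulse durations must be > 0")
    # baseline steady state under the sustained signal
    settle = simulate(model, SignalProfile.constant(baseline_level), t_settle)
    y0 = settle.states[-1]
    base = float(settle.series(species)[-1])
    # sustained removal defines the full dynamic range
    sustained = simulate(
        model,
        SignalProfile.step(0.0 + 1e-9, baseline_level, 0.0),
        t_settle,
        initial_state=y0,
    )
    full = float(sustained.series(species)[-1])
    dynamic_range = abs(full - base)
    if dynamic_range <= 0:
        raise AnalysisError("target does not respond to sustained signal removal")
    excursions = np.empty_like(durations)
    for i, d in enumerate(durations):
        profile = SignalProfile(
            (t_settle, t_settle + d), (baseline_level, 0.0, baseline_level)
        )
        traj = simulate(model, profile, t_settle + d + t_tail, initial_state=y0)
        after = traj.t >= t_settle
        excursions[i] = np.max(np.abs(traj.series(species)[after] - base)) / dynamic_range
    exceed = excursions > epsilon
    minimal = float(durations[np.argmax(exceed)]) if exceed.any() else None
    return PulseRejectionResult(durations, excursions, epsilon, minimal, dynamic_range)


# ---------------------------------------------------------------------------
# leaky-transcript comparison
# ---------------------------------------------------------------------------

@dataclass
class LeakComparison:
    """Paired hypoxia runs with and without miRNA-enhanced degradation."""

    with_mirna: Trajectory
    without_mirna: Trajectory
    onset: float
    auc_with: float
    auc_without: float
    t10_with: float
    t10_without: float

    def time_to_fraction(self, fraction: float, which: str = "with") -> float:
        traj = self.with_mirna if which == "with" else self.without_mirna
        return _time_to_fraction(traj, "MITF_MRNA", self.onset, fraction)


def _time_to_fraction(traj, species, onset, fraction):
    x = traj.series(species)
    t = traj.t
    start = np.searchsorted(t, onset)
    ref = x[start]
    target = fraction * ref
    below = np.nonzero(x[start:] <= target)[0]
    if below.size == 0:
        raise AnalysisError(
            f"{species} never decays to {fraction:.0%} of its onset level"
        )
    j = start + below[0]
    if j == start:
        return 0.0
    t0, t1, x0, x1 = t[j - 1], t[j], x[j - 1], x[j]
    t_cross = t0 + (target - x0) * (t1 - t0) / (x1 - x0) if x1 != x0 else t1
    return float(t_cross - onset)


def leaky_transcript_comparison(
    params: LeakParams,
    hypoxia_signal: SignalProfile | None = None,
    t_end: float = 20.0,
) -> LeakComparison:
    """Compare MITF transcript clearance with and without miR-155.

    Hypoxia (the signal stepping high) shuts MITF transcription and drives
    miR-155, whose enhanced-degradation arm clears the residual (leaky)
    transcripts at rate ``delta + lam * miR`` instead of the bare
    half-life.  Reports the post-onset mRNA area under the curve and the
    time to decay to 10 % for both arms; any positive ``lam`` strictly
    shrinks the AUC.
    """
    if hypoxia_signal is None:
        hypoxia_signal = SignalProfile.step(5.0, 0.0, 1.0)
    if not hypoxia_signal.breakpoints:
        raise ValidationError("hypoxia_signal needs at least one breakpoint")
    onset = hypoxia_signal.breakpoints[0]
    runs = {}
    for label, lam in (("with", params.lam), ("without", 0.0)):
        p = LeakParams(
            beta_mrna=params.beta_mrna,
            delta_mrna=params.delta_mrna,
            lam=lam,
            beta_mir=params.beta_mir,
            delta_mir=params.delta_mir,
            mir_clamp=params.mir_clamp,
        )
        runs[label] = simulate(LeakCircuit(p), hypoxia_signal, t_end)
    aucs = {}
    for label, traj in runs.items():
        mask = traj.t >= onset
        aucs[label] = float(
            np.trapezoid(traj.series("MITF_MRNA")[mask], traj.t[mask])
        )
    return LeakComparison(
        with_mirna=runs["with"],
        without_mirna=runs["without"],
        onset=onset,
        auc_with=aucs["with"],
        auc_without=aucs["without"],
        t10_with=_time_to_fraction(runs["with"], "MITF_MRNA", onset, 0.1),
        t10_without=_time_to_fraction(runs["without"], "MITF_MRNA", onset, 0.1),
    )


# ---------------------------------------------------------------------------
# fixed points
# ---------------------------------------------------------------------------

@dataclass
class FixedPoint:
    """A steady state with its linear stability."""

    state: np.ndarray
    stable: bool
    eigenvalues: np.ndarray

    @property
    def sox10(self) -> float:
        return float(self.state[0])


def _numerical_jacobian(fun, y, eps=1e-7):
    n = len(y)
    jac = np.empty((n, n))
    f0 = fun(y)
    for j in range(n):
        step = eps * max(abs(y[j]), 1.0)
        yp = y.copy()
        yp[j] += step
        jac[:, j] = (fun(yp) - f0) / step
    return jac


def find_steady_states(
    model: CircuitModel,
    input_value: float,
    n_starts: int = 16,
    seed: int = 0,
    extra_starts=None,
    merge_tol: float = 1e-6,
) -> list[FixedPoint]:
    """Multi-start Newton search for the fixed points of an autonomous
    circuit at a fixed input value.

    Starts combine a deterministic coarse grid over each species' maximal
    range (production over turnover), seeded uniform draws, optional
    caller-supplied warm starts, and midpoints between distinct roots
    already found (which reliably picks up the saddle between two stable
    states).  Duplicates are merged at relative tolerance ``merge_tol``;
    stability comes from the eigenvalues of a finite-difference Jacobian.
    """
    fun = lambda y: model.rhs(0.0, y, input_value)
    n = len(model.species)
    scale = np.ones(n)
    params = getattr(model, "params", None)
    if params is not None:
        guesses = []
        for name in model.species:
            beta = getattr(params, "beta_" + _species_rate_suffix(name), None)
            delta = getattr(params, "delta_" + _species_rate_suffix(name), None)
            guesses.append(beta / delta if beta and delta else 1.0)
        scale = np.asarray(guesses)
    rng = np.random.default_rng(seed)
    starts = [np.zeros(n), scale.copy(), 0.5 * scale]
    for frac in (0.1, 0.9):
        starts.append(frac * scale)
    while len(starts) < n_starts:
        starts.append(rng.uniform(0.0, 1.05, size=n) * scale)
    if extra_starts is not None:
        starts.extend(np.asarray(s, dtype=float) for s in extra_starts)
    roots: list[np.ndarray] = []

    def try_start(y0):
        sol = root(fun, y0, method="hybr", tol=1e-12)
        if not sol.success:
            return
        y = sol.x
        if np.any(y < -1e-7):
            return
        y = np.maximum(y, 0.0)
        if np.max(np.abs(fun(y))) > 1e-8:
            return
        for r in roots:
            if np.max(np.abs(r - y)) <= merge_tol * max(1.0, np.max(np.abs(r))):
                return
        roots.append(y)

    for y0 in starts:
        try_start(y0)
    # interior points between distinct roots pick up the saddle between
    # two stable states
    for i in range(len(roots)):
        for j in range(i + 1, len(roots)):
            for frac in (0.5, 0.3, 0.7, 0.4, 0.6, 0.45, 0.55):
                n_before = len(roots)
                try_start((1 - frac) * roots[i] + frac * roots[j])
                if len(roots) > n_before:
                    break
    if not roots:
        raise AnalysisError(
            f"no steady state found at input {input_value:g} from any start"
        )
    out = []
    for y in sorted(roots, key=lambda r: r[0]):
        eig = np.linalg.eigvals(_numerical_jacobian(fun, y))
        out.append(FixedPoint(state=y, stable=bool(np.max(eig.real) < 0), eigenvalues=eig))
    return out


def _species_rate_suffix(name: str) -> str:
    mapping = {
        "SOX10": "sox", "MIR204": "mir", "MIR155": "mir",
        "MITF": "mitf", "MITF_MRNA": "mrna", "ATF2": "atf", "X": "x",
    }
    return mapping.get(name, name.lower())


# ---------------------------------------------------------------------------
# bifurcation scan
# ---------------------------------------------------------------------------

@dataclass
class BifurcationDiagram:
    """Fixed points across a scanned parameter with fold-point estimates.

    ``reversibility`` is ``"irreversible"`` when the left fold lies outside
    (below) the physically admissible parameter interval — the switched-off
    state then cannot be exited by lowering the parameter within its
    meaningful range — and ``"reversible"`` otherwise.
    """

    parameter: str
    grid: np.ndarray
    fixed_points: list[list[FixedPoint]]
    fold_left: float | None
    fold_right: float | None
    physical_range: tuple[float, float]
    reversibility: str
    fold_tol: float = 0.0

    @property
    def n_fixed_points(self) -> np.ndarray:
        return np.array([len(fps) for fps in self.fixed_points])

    @property
    def n_stable(self) -> np.ndarray:
        return np.array(
            [sum(fp.stable for fp in fps) for fps in self.fixed_points]
        )

    def frame(self) -> pd.DataFrame:
        rows = []
        for value, fps in zip(self.grid, self.fixed_points):
            for fp in fps:
                rows.append(
                    {
                        "parameter": value,
                        "sox10": fp.sox10,
                        "stability": "stable" if fp.stable else "unstable",
                    }
                )
        return pd.DataFrame(rows, columns=["parameter", "sox10", "stability"])

    def summary(self) -> dict:
        return {
            "parameter": self.parameter,
            "fold_left": self.fold_left,
            "fold_right": self.fold_right,
            "n_folds": int(self.fold_left is not None) + int(self.fold_right is not None),
            "bistable": bool((self.n_fixed_points >= 3).any()),
            "physical_range": [
                v if math.isfinite(v) else None for v in self.physical_range
            ],
            "reversibility": self.reversibility,
        }


def _count_fps(model, value, seed, warm):
    fps = find_steady_states(model, value, seed=seed, extra_starts=warm)
    return fps


def scan_bifurcation(
    model: CircuitModel,
    grid,
    physical_range: tuple[float, float] = (0.0, math.inf),
    parameter: str = "atf2_activity",
    seed: int = 0,
    fold_rel_tol: float = 1e-4,
    max_refine: int = 6,
) -> BifurcationDiagram:
    """Track fixed points over a parameter grid and bracket the folds.

    Saddle-node (fold) points are located by bisection on the fixed-point
    count between neighboring grid values where the count changes, to a
    parameter tolerance of ``fold_rel_tol`` times the grid span.  If the
    count changes by more than 2 between neighbors the interval is refined
    (the grid was too coarse to see each fold separately); persistent
    jumps raise :class:`AnalysisError`.
    """
    grid = np.asarray(sorted(grid), dtype=float)
    if grid.size < 3:
        raise ValidationError("grid needs at least 3 points")
    span = float(grid[-1] - grid[0])
    tol = fold_rel_tol * span
    warm: list[np.ndarray] = []
    fixed_points: list[list[FixedPoint]] = []
    for value in grid:
        fps = _count_fps(model, value, seed, warm)
        warm = [fp.state for fp in fps]
        fixed_points.append(fps)
    counts = [len(fps) for fps in fixed_points]

    def bisect_fold(lo, hi, n_lo, seed=seed) -> float:
        """Parameter where the fixed-point count changes between lo and hi."""
        warm_local = [fp.state for fp in _count_fps(model, lo, seed, None)]
        a, b = lo, hi
        for _ in range(200):
            if b - a <= tol:
                break
            mid = 0.5 * (a + b)
            n_mid = len(_count_fps(model, mid, seed, warm_local))
            if n_mid == n_lo:
                a = mid
            else:
                b = mid
        return 0.5 * (a + b)

    folds: list[float] = []
    for i in range(len(grid) - 1):
        diff = counts[i + 1] - counts[i]
        if diff == 0:
            continue
        if abs(diff) > 2:
            # refine: the coarse grid straddled more than one fold
            refined = np.linspace(grid[i], grid[i + 1], max_refine + 2)
            sub_counts = [len(_count_fps(model, v, seed, None)) for v in refined]
            ok = all(
                abs(c2 - c1) <= 2 for c1, c2 in zip(sub_counts, sub_counts[1:])
            )
            if not ok:
                raise AnalysisError(
                    "fixed-point count changes by more than one fold between "
                    f"{grid[i]:g} and {grid[i + 1]:g}; use a denser grid"
                )
            for j in range(len(refined) - 1):
                if sub_counts[j + 1] != sub_counts[j]:
                    folds.append(
                        bisect_fold(refined[j], refined[j + 1], sub_counts[j])
                    )
            continue
        folds.append(bisect_fold(grid[i], grid[i + 1], counts[i]))
    folds.sort()

    bistable_mask = np.array(counts) >= 3
    fold_left = fold_right = None
    if folds:
        if bistable_mask[0]:
            # the bistable window runs off the low end of the grid: the left
            # fold is below everything we scanned
            fold_right = folds[-1]
        elif bistable_mask[-1]:
            fold_left = folds[0]
        else:
            fold_left, fold_right = folds[0], folds[-1]
    lo_phys, _hi_phys = physical_range
    if bistable_mask.any():
        left_inside = fold_left is not None and fold_left >= lo_phys
        # bistability extending down to the bottom of the physical range
        # means the exit fold lies below it
        touches_floor = bistable_mask[0] and grid[0] <= lo_phys + tol
        reversibility = (
            "reversible" if left_inside and not touches_floor else "irreversible"
        )
    else:
        reversibility = "reversible"
    return BifurcationDiagram(
        parameter=parameter,
        grid=grid,
        fixed_points=fixed_points,
        fold_left=fold_left,
        fold_right=fold_right,
        physical_range=physical_range,
        reversibility=reversibility,
        fold_tol=tol,
    )


# ---------------------------------------------------------------------------
# hysteresis
# ---------------------------------------------------------------------------

@dataclass
class HysteresisResult:
    """Quasi-static up/down parameter sweep of the switch state."""

    grid_up: np.ndarray
    sox10_up: np.ndarray
    grid_down: np.ndarray
    sox10_down: np.ndarray
    threshold_up: float | None
    threshold_down: float | None
    loop_width: float
    transition: bool


def _relax(model, value, y0, dwell, rtol, atol):
    sol = solve_ivp(
        lambda t, y: model.rhs(t, y, value),
        (0.0, dwell),
        y0,
        method="LSODA",
        rtol=rtol,
        atol=atol,
        t_eval=np.linspace(0.9 * dwell, dwell, 8),
    )
    if not sol.success:
        raise AnalysisError(f"relaxation failed at parameter {value:g}")
    tail = sol.y[0]
    scale = max(abs(tail[-1]), 1e-9)
    if np.ptp(tail) / scale > 1e-3:
        log.warning(
            "state not fully relaxed at parameter %.4g; consider a longer dwell",
            value,
        )
    return sol.y[:, -1]


def _crossing(grid, values, mid, downward):
    """First parameter at which the state crosses the midline."""
    for i in range(1, len(grid)):
        if downward and values[i - 1] > mid >= values[i]:
            return 0.5 * (grid[i - 1] + grid[i])
        if not downward and values[i - 1] < mid <= values[i]:
            return 0.5 * (grid[i - 1] + grid[i])
    return None


def hysteresis_sweep(
    model: CircuitModel,
    grid,
    dwell: float = 30.0,
    initial_state=None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> HysteresisResult:
    """Ramp the control parameter up then down, carrying the state over.

    The dwell at each step must exceed the slowest relaxation time (checked
    by a plateau criterion on SOX10, warning if violated).  The up- and
    down-thresholds are the parameter values at which SOX10 leaves and
    rejoins the ON branch; their separation is the hysteresis loop width,
    zero (within a grid step) for a monostable circuit.
    """
    grid = np.asarray(sorted(grid), dtype=float)
    if grid.size < 3:
        raise ValidationError("grid needs at least 3 points")
    y = (
        np.asarray(initial_state, dtype=float)
        if initial_state is not None
        else None
    )
    if y is None:
        fps = find_steady_states(model, grid[0])
        stable = [fp for fp in fps if fp.stable]
        y = max(stable, key=lambda fp: fp.sox10).state
    sox_up = np.empty_like(grid)
    for i, value in enumerate(grid):
        y = _relax(model, value, y, dwell, rtol, atol)
        sox_up[i] = y[0]
    grid_down = grid[::-1]
    sox_down = np.empty_like(grid)
    for i, value in enumerate(grid_down):
        y = _relax(model, value, y, dwell, rtol, atol)
        sox_down[i] = y[0]
    all_vals = np.concatenate([sox_up, sox_down])
    mid = 0.5 * (all_vals.min() + all_vals.max())
    # up sweep: the ON branch is lost (downward crossing as the parameter
    # rises); down sweep: the ON branch is regained (upward crossing as the
    # parameter falls) — both scanned in traversal order
    threshold_up = _crossing(grid, sox_up, mid, downward=True)
    threshold_down = _crossing(grid_down, sox_down, mid, downward=False)
    transition = threshold_up is not None and threshold_down is not None
    width = (
        max(threshold_up - threshold_down, 0.0) if transition else 0.0
    )
    if not transition:
        log.info("no transition in range for the swept parameter")
    return HysteresisResult(
        grid_up=grid,
        sox10_up=sox_up,
        grid_down=grid_down,
        sox10_down=sox_down,
        threshold_up=threshold_up,
        threshold_down=threshold_down,
        loop_width=width,
        transition=transition,
    )


# ---------------------------------------------------------------------------
# phenotype calls per signal interval
# ---------------------------------------------------------------------------

def phase_report(
    traj: Trajectory,
    pmap: PhenotypeMap,
    species: str = "MITF",
) -> pd.DataFrame:
    """Phenotype call for each signal interval of a trajectory.

    The plateau MITF level (trailing 10 % of each interval) is read
    through the phenotype map; intervals too short to settle surface as
    ``"transition"`` or raise through the plateau check.
    """
    edges = [float(traj.t[0])] + list(traj.meta.get("breakpoints", ())) + [
        float(traj.t[-1])
    ]
    x = traj.series(species)
    rows = []
    for a, b in zip(edges, edges[1:]):
        level = _plateau(traj.t, x, a, b, cv_tol=np.inf)
        rows.append(
            {
                "t_start": a,
                "t_end": b,
                "level": level,
                "phenotype": classify_phenotype(level, pmap),
            }
        )
    return pd.DataFrame(rows, columns=["t_start", "t_end", "level", "phenotype"])
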