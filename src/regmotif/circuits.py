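"""Hill-kinetics gene-circuit models for the SOX10/MITF regulatory studies.

Three model families are provided, all built from standard
production-degradation ODEs with Hill regulation
(activation ``H+(x) = x^n / (k^n + x^n)``, repression
``H-(x) = k^n / (k^n + x^n)``):

* **Input functions** — the steady-state SOX10->MITF transfer curve in
  linear, saturated (Michaelis-Menten) and sigmoidal (cooperative Hill)
  form, together with the rheostat phenotype map that reads graded MITF
  levels as melanoma phenotypes.

* **FFL circuit** — the coherent MIR155-SOX10-MITF feedforward loop: an
  upstream signal drives miR-155, miR-155 represses SOX10
  post-transcriptionally, SOX10 activates MITF transcription, and miR-155
  additionally represses MITF directly.  The two repressive routes combine
  on the MITF promoter through an AND or an OR gate, either as literal
  threshold logic (production on iff SOX10 above its activation threshold
  AND/OR miR-155 below its repression threshold) or as smooth Hill terms
  (product for AND, probabilistic sum for OR).

* **FBL circuit** — the positive MIR204-SOX10-ATF2 feedback loop: ATF2
  represses SOX10, SOX10 activates miR-204, and miR-204 represses ATF2
  post-transcriptionally (cycle sign product (-)(-)(+) = +1).  MITF is a
  SOX10-driven reporter and does not feed back.  ATF2 activity is the
  scanned control parameter by default; a dynamic-ATF2 mode is available.

Time and concentration units are arbitrary; all default rates are order 1
and species are normalized so their dynamic ranges are about [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import AnalysisError, ValidationError

__all__ = [
    "InputFunctionSpec", "input_response", "response_sensitivity",
    "sensitivity_argmax", "PhenotypeMap", "rheostat_map",
    "melanoma_state_map", "classify_phenotype", "zone_rank",
    "SignalProfile", "Trajectory", "CircuitModel", "SingleGeneCircuit",
    "FflParams", "FflCircuit", "build_ffl_model", "sample_ffl_params",
    "FblParams", "FblCircuit", "build_fbl_model",
    "LeakParams", "LeakCircuit", "simulate",
]


def hill_act(x, k, n):
    x = np.maximum(x, 0.0)
    xn = x ** n
    return xn / (k ** n + xn)


def hill_rep(x, k, n):
    x = np.maximum(x, 0.0)
    kn = k ** n
    return kn / (kn + x ** n)


# ---------------------------------------------------------------------------
# input functions and phenotype map
# ---------------------------------------------------------------------------

INPUT_MODELS = ("linear", "saturated", "sigmoidal")


@dataclass(frozen=True)
class InputFunctionSpec:
    """Steady-state transfer function for TF-activated transcription.

    ``a`` is the linear slope (output per input unit); ``v_max`` the
    saturating output; ``k_half`` the half-effect input level; ``hill_n``
    the cooperativity (only used by the sigmoidal model, which reduces to
    the saturated model at ``hill_n = 1``).
    """

    model: str
    a: float = 1.0
    v_max: float = 1.0
    k_half: float = 1.0
    hill_n: float = 2.0

    def __post_init__(self):
        if self.model not in INPUT_MODELS:
            raise ValidationError(f"model must be one of {INPUT_MODELS}")
        for name in ("a", "v_max", "k_half"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        if self.model == "sigmoidal" and self.hill_n < 1:
            raise ValidationError("hill_n must be >= 1")


def _check_nonneg(level):
    arr = np.asarray(level, dtype=float)
    if np.any(arr < 0):
        raise ValidationError("input level must be non-negative")
    return arr


def input_response(spec: InputFunctionSpec, level):
    """Steady MITF output for a given SOX10 level (scalar or grid)."""
    s = _check_nonneg(level)
    if spec.model == "linear":
        out = spec.a * s
    elif spec.model == "saturated" or spec.hill_n == 1:
        # the n = 1 sigmoidal is the saturated form; share the expression
        # so the limit holds exactly, not just to rounding
        out = spec.v_max * s / (spec.k_half + s)
    else:
        out = spec.v_max * hill_act(s, spec.k_half, spec.hill_n)
    return out if out.shape else float(out)


def response_sensitivity(spec: InputFunctionSpec, level):
    """Closed-form derivative of the transfer function w.r.t. the input."""
    s = _check_nonneg(level)
    if spec.model == "linear":
        out = np.full_like(s, spec.a)
    elif spec.model == "saturated":
        out = spec.v_max * spec.k_half / (spec.k_half + s) ** 2
    else:
        n, k = spec.hill_n, spec.k_half
        with np.errstate(divide="ignore", invalid="ignore"):
            out = spec.v_max * n * k ** n * s ** (n - 1) / (k ** n + s ** n) ** 2
        if n == 1:
            out = spec.v_max * k / (k + s) ** 2
        else:
            out = np.where(s == 0, 0.0, out)
    return out if out.shape else float(out)


def sensitivity_argmax(spec: InputFunctionSpec) -> float:
    """Input level at which the sensitivity is maximal.

    Linear sensitivity is flat; the saturated and n=1 sigmoidal curves are
    steepest at zero; the cooperative sigmoidal curve is steepest at the
    interior level ``k_half * ((n-1)/(n+1))**(1/n)``.
    """
    if spec.model == "sigmoidal" and spec.hill_n > 1:
        n = spec.hill_n
        return spec.k_half * ((n - 1) / (n + 1)) ** (1 / n)
    return 0.0


@dataclass(frozen=True)
class PhenotypeMap:
    """Ordered zone boundaries on the MITF axis with gray transition bands.

    ``zones`` has one more entry than ``boundaries``; a level within
    ``gray_width`` of any boundary (inclusive) is called ``"transition"``.
    """

    boundaries: tuple[float, ...]
    zones: tuple[str, ...]
    gray_width: float = 0.0

    def __post_init__(self):
        b = self.boundaries
        if len(self.zones) != len(b) + 1:
            raise ValidationError("need len(zones) == len(boundaries) + 1")
        if any(b2 <= b1 for b1, b2 in zip(b, b[1:])):
            raise ValidationError("boundaries must be strictly increasing")
        if self.gray_width < 0:
            raise ValidationError("gray_width must be >= 0")
        if any(
            b2 - b1 <= 2 * self.gray_width for b1, b2 in zip(b, b[1:])
        ):
            raise ValidationError("gray zones overlap; reduce gray_width")


def rheostat_map(
    boundaries=(0.25, 0.5, 0.75), gray_width=0.03
) -> PhenotypeMap:
    """Four-phenotype rheostat reading of graded MITF levels.

    Increasing MITF maps to senescence, invasion, proliferation and
    differentiation; boundary values are configuration, not measurements.
    """
    return PhenotypeMap(
        tuple(boundaries),
        ("senescence", "invasion", "proliferation", "differentiation"),
        gray_width,
    )


def melanoma_state_map(boundaries=(0.33, 0.66), gray_width=0.03) -> PhenotypeMap:
    """Three-state map (mesenchymal / intermediate / melanocytic)."""
    return PhenotypeMap(
        tuple(boundaries), ("mesenchymal", "intermediate", "melanocytic"), gray_width
    )


def classify_phenotype(level, pmap: PhenotypeMap):
    """Zone label for an MITF level, or ``"transition"`` in a gray band."""

    def one(x: float) -> str:
        for b in pmap.boundaries:
            if abs(x - b) <= pmap.gray_width:
                return "transition"
        i = sum(x > b for b in pmap.boundaries)
        return pmap.zones[i]

    arr = np.asarray(level, dtype=float)
    if arr.shape:
        return [one(float(x)) for x in arr]
    return one(float(arr))


def zone_rank(label: str, pmap: PhenotypeMap, level: float | None = None) -> float:
    """Numeric rank of a zone call for monotonicity checks.

    ``"transition"`` ranks halfway between its flanking zones, which needs
    the level to locate the boundary.
    """
    if label == "transition":
        if level is None:
            raise ValidationError("level required to rank a transition call")
        i = min(
            range(len(pmap.boundaries)),
            key=lambda j: abs(level - pmap.boundaries[j]),
        )
        return i + 0.5
    return float(pmap.zones.index(label))


# ---------------------------------------------------------------------------
# signals and trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignalProfile:
    """Piecewise-constant input signal.

    ``levels[i]`` holds on ``[breakpoints[i-1], breakpoints[i])`` with the
    obvious open ends; ``len(levels) == len(breakpoints) + 1``.
    """

    breakpoints: tuple[float, ...] = ()
    levels: tuple[float, ...] = (0.0,)

    def __post_init__(self):
        if len(self.levels) != len(self.breakpoints) + 1:
            raise ValidationError("need len(levels) == len(breakpoints) + 1")
        if any(
            t2 <= t1 for t1, t2 in zip(self.breakpoints, self.breakpoints[1:])
        ):
            raise ValidationError("breakpoints must be strictly increasing")
        if any(v < 0 for v in self.levels):
            raise ValidationError("signal levels must be >= 0")

    @classmethod
    def constant(cls, level: float) -> "SignalProfile":
        return cls((), (float(level),))

    @classmethod
    def step(cls, t_switch: float, before: float, after: float) -> "SignalProfile":
        return cls((float(t_switch),), (float(before), float(after)))

    def value(self, t: float) -> float:
        i = int(np.searchsorted(self.breakpoints, t, side="right"))
        return self.levels[i]

    def segments(self, t0: float, t_end: float):
        """Yield (start, stop, level) covering [t0, t_end]."""
        edges = [t0] + [b for b in self.breakpoints if t0 < b < t_end] + [t_end]
        for a, b in zip(edges, edges[1:]):
            yield a, b, self.value(0.5 * (a + b))


@dataclass
class Trajectory:
    """A simulated time course: time grid, state matrix, species names."""

    t: np.ndarray
    states: np.ndarray  # shape (len(t), n_species)
    species: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def series(self, name: str) -> np.ndarray:
        return self.states[:, self.species.index(name)]

    def frame(self) -> pd.DataFrame:
        data = {"time": self.t}
        data.update({s: self.states[:, i] for i, s in enumerate(self.species)})
        return pd.DataFrame(data)

    def to_tsv(self, path) -> None:
        self.frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# circuit models
# ---------------------------------------------------------------------------

class CircuitModel:
    """Base class: a named ODE system driven by a scalar input ``u``."""

    species: tuple[str, ...] = ()

    def rhs(self, t: float, y: np.ndarray, u: float) -> np.ndarray:
        raise NotImplementedError

    def initial_state(self) -> np.ndarray:
        return np.zeros(len(self.species))


def _require_positive(params, names):
    for name in names:
        value = getattr(params, name)
        if value is None or not np.isfinite(value) or value <= 0:
            raise ValidationError(
                f"parameter {name!r} must be a positive number, got {value!r}"
            )


def _params_from_mapping(cls, mapping):
    valid = {f.name for f in fields(cls)}
    unknown = set(mapping) - valid
    if unknown:
        raise ValidationError(
            f"unknown parameter(s) {sorted(unknown)} for {cls.__name__}"
        )
    return cls(**mapping)


class SingleGeneCircuit(CircuitModel):
    """One gene with signal-proportional production and linear decay.

    ``dx/dt = beta * u(t) - delta * x`` — the closed-form step response
    ``x(t) = (beta/delta) * (1 - exp(-delta t))`` anchors solver checks.
    """

    species = ("X",)

    def __init__(self, beta: float = 1.0, delta: float = 1.0):
        if beta < 0 or delta <= 0:
            raise ValidationError("need beta >= 0 and delta > 0")
        self.beta = beta
        self.delta = delta

    def rhs(self, t, y, u):
        return np.array([self.beta * u - self.delta * max(y[0], 0.0)])


GATES = ("AND", "OR")
LOGIC_MODES = ("continuous", "threshold")
MIRNA_ACTIONS = ("none", "translational_repression", "enhanced_degradation", "both")


@dataclass(frozen=True)
class FflParams:
    """Rate constants for the signal->miR-155->SOX10->MITF circuit.

    All rates are per arbitrary time unit; abundances are scaled so that
    each species' dynamic range is about [0, 1] with the defaults.
    ``theta_sox``/``theta_mir`` are the threshold-logic switch points,
    ``leak`` a basal transcription fraction, ``lam`` the miRNA-enhanced
    mRNA degradation strength (per miRNA unit).
    """

    beta_mir: float = 6.0       #: miR-155 production at unit signal
    delta_mir: float = 6.0      #: miR-155 turnover (fast)
    beta_sox: float = 1.0       #: SOX10 maximal production
    delta_sox: float = 1.0      #: SOX10 turnover
    k_mir_sox: float = 0.4      #: miR-155 half-repression of SOX10
    n_mir_sox: float = 2.0
    beta_mrna: float = 1.0      #: MITF transcription rate
    delta_mrna: float = 3.0     #: MITF mRNA turnover
    lam: float = 0.0            #: miRNA-enhanced mRNA degradation strength
    beta_prot: float = 3.0      #: MITF translation rate
    delta_prot: float = 1.0     #: MITF protein turnover
    k_sox_mitf: float = 0.5     #: SOX10 half-activation of MITF
    n_sox_mitf: float = 2.0
    k_mir_mitf: float = 0.4     #: miR-155 half-repression of MITF
    n_mir_mitf: float = 2.0
    theta_sox: float = 0.6      #: SOX10 activation threshold (threshold mode)
    theta_mir: float = 0.5      #: miR-155 repression threshold (threshold mode)
    leak: float = 0.0           #: basal transcription fraction when gated off


class FflCircuit(CircuitModel):
    """The coherent MIR155-SOX10-MITF feedforward loop.

    Species: miR-155 (signal-driven), SOX10 (repressed by miR-155),
    MITF mRNA (gated transcription, optional miRNA-enhanced degradation)
    and MITF protein (optional translational repression by miR-155).
    """

    species = ("MIR155", "SOX10", "MITF_MRNA", "MITF")

    def __init__(
        self,
        params: FflParams,
        gate: str = "AND",
        logic_mode: str = "threshold",
        mirna_action: str | None = None,
    ):
        if gate not in GATES:
            raise ValidationError(f"gate must be one of {GATES}")
        if logic_mode not in LOGIC_MODES:
            raise ValidationError(f"logic_mode must be one of {LOGIC_MODES}")
        if mirna_action is None:
            # the threshold gate already encodes the direct miRNA arm;
            # continuous analyses default to both post-transcriptional arms
            mirna_action = "none" if logic_mode == "threshold" else "both"
        if mirna_action not in MIRNA_ACTIONS:
            raise ValidationError(f"mirna_action must be one of {MIRNA_ACTIONS}")
        _require_positive(
            params,
            [
                "beta_mir", "delta_mir", "beta_sox", "delta_sox", "k_mir_sox",
                "n_mir_sox", "beta_mrna", "delta_mrna", "beta_prot",
                "delta_prot", "k_sox_mitf", "n_sox_mitf", "k_mir_mitf",
                "n_mir_mitf", "theta_sox", "theta_mir",
            ],
        )
        if params.lam < 0 or params.leak < 0:
            raise ValidationError("lam and leak must be >= 0")
        self.params = params
        self.gate = gate
        self.logic_mode = logic_mode
        self.mirna_action = mirna_action

    # -- promoter logic ----------------------------------------------------
    def gate_term(self, sox: float, mir: float) -> float:
        """Normalized MITF transcription activity in [leak, 1]."""
        p = self.params
        if self.logic_mode == "threshold":
            sox_ok = sox > p.theta_sox
            mir_ok = mir < p.theta_mir
            on = (sox_ok and mir_ok) if self.gate == "AND" else (sox_ok or mir_ok)
            return 1.0 if on else p.leak
        act = float(hill_act(sox, p.k_sox_mitf, p.n_sox_mitf))
        rep = float(hill_rep(mir, p.k_mir_mitf, p.n_mir_mitf))
        if self.gate == "AND":
            term = act * rep
        else:
            term = act + rep - act * rep
        return max(term, p.leak)

    def rhs(self, t, y, u):
        p = self.params
        mir, sox, mrna, prot = (max(v, 0.0) for v in y)
        d_mir = p.beta_mir * u - p.delta_mir * mir
        d_sox = (
            p.beta_sox * float(hill_rep(mir, p.k_mir_sox, p.n_mir_sox))
            - p.delta_sox * sox
        )
        production = p.beta_mrna * self.gate_term(sox, mir)
        degradation = p.delta_mrna
        if self.mirna_action in ("enhanced_degradation", "both"):
            degradation = degradation + p.lam * mir
        d_mrna = production - degradation * mrna
        translation = p.beta_prot
        if self.mirna_action in ("translational_repression", "both"):
            translation = translation * float(
                hill_rep(mir, p.k_mir_mitf, p.n_mir_mitf)
            )
        d_prot = translation * mrna - p.delta_prot * prot
        return np.array([d_mir, d_sox, d_mrna, d_prot])


def build_ffl_model(
    params=None, gate: str = "AND", logic_mode: str = "threshold",
    mirna_action: str | None = None,
) -> FflCircuit:
    """Construct the FFL circuit from an :class:`FflParams` or a mapping."""
    if params is None:
        params = FflParams()
    elif isinstance(params, dict):
        params = _params_from_mapping(FflParams, params)
    return FflCircuit(params, gate, logic_mode, mirna_action)


def sample_ffl_params(rng: np.random.Generator) -> FflParams:
    """Draw a randomized FFL parameter set within the stable design ranges.

    Productions are tied to turnovers so every species' dynamic range stays
    normalized near [0, 1]; thresholds stay inside the SOX10 and miR-155
    excursions, which is the regime in which the gate logic is meaningful.
    """
    delta_mir = rng.uniform(5.0, 8.0)
    delta_sox = rng.uniform(0.7, 1.3)
    delta_mrna = rng.uniform(2.5, 4.0)
    delta_prot = rng.uniform(0.7, 1.3)
    return FflParams(
        beta_mir=delta_mir,
        delta_mir=delta_mir,
        beta_sox=delta_sox,
        delta_sox=delta_sox,
        k_mir_sox=rng.uniform(0.3, 0.5),
        beta_mrna=delta_mrna / 3.0,
        delta_mrna=delta_mrna,
        beta_prot=3.0 * delta_prot,
        delta_prot=delta_prot,
        theta_sox=rng.uniform(0.45, 0.7),
        theta_mir=rng.uniform(0.35, 0.6),
    )


@dataclass(frozen=True)
class FblParams:
    """Rate constants for the ATF2 -| SOX10 -> miR-204 -| ATF2 loop.

    The controlled ATF2 activity is the model input ``u``; ``atf2_basal``
    is a miR-204-independent activity offset added to it.  Cooperativity
    ``n >= 2`` on the repressive arms is required for bistability.
    """

    beta_sox: float = 1.0
    delta_sox: float = 1.0
    k_atf_sox: float = 0.3     #: ATF2 half-repression of SOX10
    n_atf_sox: float = 2.0
    beta_mir: float = 1.0
    delta_mir: float = 1.0
    k_sox_mir: float = 0.3     #: SOX10 half-activation of miR-204
    n_sox_mir: float = 2.0
    k_mir_atf: float = 0.3     #: miR-204 half-repression of ATF2 activity
    n_mir_atf: float = 2.0
    beta_mitf: float = 1.0
    delta_mitf: float = 1.0
    k_sox_mitf: float = 0.5    #: SOX10 half-activation of the MITF reporter
    n_sox_mitf: float = 2.0
    atf2_basal: float = 0.0
    delta_atf: float = 2.0     #: ATF2 relaxation rate (dynamic mode only)


class FblCircuit(CircuitModel):
    """The positive MIR204-SOX10-ATF2 feedback loop with an MITF reporter.

    In the default scanned-input mode the effective ATF2 activity is
    ``(u + atf2_basal) * H-(miR-204)``; in dynamic mode ATF2 is a state
    relaxing toward ``u + atf2_basal`` and the same miR-204 repression
    applies to its activity.
    """

    def __init__(self, params: FblParams, atf2_dynamic: bool = False):
        _require_positive(
            params,
            [
                "beta_sox", "delta_sox", "k_atf_sox", "n_atf_sox", "beta_mir",
                "delta_mir", "k_sox_mir", "n_sox_mir", "k_mir_atf",
                "n_mir_atf", "beta_mitf", "delta_mitf", "k_sox_mitf",
                "n_sox_mitf", "delta_atf",
            ],
        )
        if params.atf2_basal < 0:
            raise ValidationError("atf2_basal must be >= 0")
        self.params = params
        self.atf2_dynamic = atf2_dynamic
        self.species = (
            ("SOX10", "MIR204", "MITF", "ATF2")
            if atf2_dynamic
            else ("SOX10", "MIR204", "MITF")
        )
        if max(params.n_atf_sox, params.n_mir_atf) < 2:
            import logging

            logging.getLogger(__name__).warning(
                "no repressive arm has hill_n >= 2: bistability unlikely"
            )

    def cycle_sign_product(self) -> int:
        """Sign product of the loop: (-1) * (-1) * (+1) = +1 (positive)."""
        return (-1) * (-1) * (+1)

    def rhs(self, t, y, u):
        p = self.params
        if self.atf2_dynamic:
            sox, mir, mitf, atf = (max(v, 0.0) for v in y)
            a_eff = atf * float(hill_rep(mir, p.k_mir_atf, p.n_mir_atf))
            d_atf = p.delta_atf * (u + p.atf2_basal - atf)
        else:
            sox, mir, mitf = (max(v, 0.0) for v in y)
            a_eff = (u + p.atf2_basal) * float(
                hill_rep(mir, p.k_mir_atf, p.n_mir_atf)
            )
            d_atf = None
        d_sox = (
            p.beta_sox * float(hill_rep(a_eff, p.k_atf_sox, p.n_atf_sox))
            - p.delta_sox * sox
        )
        d_mir = (
            p.beta_mir * float(hill_act(sox, p.k_sox_mir, p.n_sox_mir))
            - p.delta_mir * mir
        )
        d_mitf = (
            p.beta_mitf * float(hill_act(sox, p.k_sox_mitf, p.n_sox_mitf))
            - p.delta_mitf * mitf
        )
        if self.atf2_dynamic:
            return np.array([d_sox, d_mir, d_mitf, d_atf])
        return np.array([d_sox, d_mir, d_mitf])


def build_fbl_model(params=None, atf2_dynamic: bool = False) -> FblCircuit:
    """Construct the FBL circuit from an :class:`FblParams` or a mapping."""
    if params is None:
        params = FblParams()
    elif isinstance(params, dict):
        params = _params_from_mapping(FblParams, params)
    return FblCircuit(params, atf2_dynamic)


@dataclass(frozen=True)
class LeakParams:
    """Leaky-transcript model: hypoxia shuts MITF transcription and drives
    miR-155, which clears residual MITF mRNA at rate ``delta + lam * miR``.

    ``mir_clamp`` pins the miRNA at a constant level (analytic checks).
    """

    beta_mrna: float = 1.0
    delta_mrna: float = 0.5
    lam: float = 2.0
    beta_mir: float = 1.0
    delta_mir: float = 1.0
    mir_clamp: float | None = None


class LeakCircuit(CircuitModel):
    """Two-species hypoxia model: miR-155 and the leaky MITF transcript."""

    species = ("MIR155", "MITF_MRNA")

    def __init__(self, params: LeakParams):
        _require_positive(params, ["beta_mrna", "delta_mrna", "beta_mir", "delta_mir"])
        if params.lam < 0:
            raise ValidationError("lam must be >= 0")
        self.params = params

    def initial_state(self) -> np.ndarray:
        p = self.params
        mir0 = p.mir_clamp if p.mir_clamp is not None else 0.0
        # pre-hypoxia steady state of the transcript
        mrna0 = p.beta_mrna / (p.delta_mrna + p.lam * mir0)
        return np.array([mir0, mrna0])

    def rhs(self, t, y, u):
        p = self.params
        mir, mrna = (max(v, 0.0) for v in y)
        if p.mir_clamp is not None:
            mir = p.mir_clamp
            d_mir = 0.0
        else:
            d_mir = p.beta_mir * u - p.delta_mir * mir
        d_mrna = p.beta_mrna * (1.0 - min(u, 1.0)) - (p.delta_mrna + p.lam * mir) * mrna
        return np.array([d_mir, d_mrna])


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate(
    model: CircuitModel,
    signal: SignalProfile,
    t_end: float,
    initial_state=None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    samples_per_unit: float = 40.0,
) -> Trajectory:
    """Integrate a circuit under a piecewise-constant signal.

    Integration restarts at every signal breakpoint so discontinuities in
    the input never straddle a solver step.  States stay non-negative to
    within solver tolerance for non-negative initial conditions.
    """
    if t_end <= 0:
        raise ValidationError("t_end must be > 0")
    y = (
        np.asarray(initial_state, dtype=float)
        if initial_state is not None
        else model.initial_state()
    )
    if y.shape != (len(model.species),):
        raise ValidationError(
            f"initial_state must have {len(model.species)} entries"
        )
    if np.any(y < -1e-9):
        raise ValidationError("initial_state must be non-negative")
    y = np.maximum(y, 0.0)
    times = [np.array([0.0])]
    states = [y[None, :]]
    for a, b, level in signal.segments(0.0, float(t_end)):
        n_pts = max(int(math.ceil((b - a) * samples_per_unit)), 20)
        t_eval = np.linspace(a, b, n_pts + 1)[1:]
        sol = solve_ivp(
            lambda t, yy: model.rhs(t, yy, level),
            (a, b),
            y,
            method=method,
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            last = sol.t[-1] if sol.t.size else a
            raise AnalysisError(
                f"solver failed at t={last:.6g}: {sol.message}"
            )
        y = sol.y[:, -1]
        times.append(sol.t)
        states.append(sol.y.T)
    t = np.concatenate(times)
    matrix = np.vstack(states)
    return Trajectory(
        t=t,
        states=matrix,
        species=tuple(model.species),
        meta={
            "breakpoints": tuple(b for b in signal.breakpoints if 0.0 < b < t_end),
            "levels": tuple(signal.levels),
            "rtol": rtol,
            "atol": atol,
            "method": method,
        },
    )
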