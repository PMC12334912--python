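# Methods

This note documents the models, conventions and numerical choices behind
`regmotif`, in the order of the pipeline.

## Network model

A network holds typed nodes — transcription factors (`TF`), microRNAs
(`MIRNA`), other protein-coding genes (`PCG`) — and signed, directed edges
keyed by `(source, target, mechanism)`. Mechanisms are `transcriptional`
(promoter-level regulation) and `post_transcriptional` (miRNA action on the
mRNA); a miRNA source always acts post-transcriptionally and defaults to
sign −1, reflecting canonical 3′-UTR repression. A per-record sign override
is accepted when integrating target tables but is logged, since
non-repressive miRNA binding is the exception. Self-loops are rejected
unless explicitly enabled; none of the modeled motifs contain one.

Symbols are matched on a canonical key: gene symbols upper-case, miRNA names
case-insensitive with hyphens and a leading `hsa-` stripped, so `MIR155`,
`miR-155` and `hsa-miR-155` are one node while `miR-155-5p` (a specific
mature arm) stays distinct. The first-seen miRNA spelling is preserved for
display.

**Assembly.** `merge_networks` unions nodes and edges and sets each node's
`origins` to the labels of the source networks containing it (the basis of
ring-diagram provenance summaries). Node-class conflicts resolve by priority
TF > MIRNA > PCG with a logged warning, or raise when no policy is given.
Duplicate edges union provenance and concatenate deduplicated evidence;
duplicate edges with contradictory signs are an error rather than a silent
choice. `extract_focal_subnetwork` takes the *induced* subgraph on all nodes
within the hop radius (edges between the focal gene's neighbors are kept):
motif search downstream needs exactly those neighbor–neighbor edges.
`annotate_tfs` reclassifies non-miRNA nodes against a TF symbol list; miRNAs
are never reclassified.

**I/O.** GraphML (via networkx, multigraph with the mechanism as edge key)
carries all attributes natively. Plain TSV edge tables and SIF cannot
represent isolated nodes or node attributes, so the writers add structured
`#!node` / `#!edge` comment lines carrying the full attribute set; the
readers honor them when present, making write→read the identity for every
dialect. Foreign files without the directives still parse: TSV node origins
default to the union of incident edge provenances; SIF infers miRNA-looking
symbols as `MIRNA` (post-transcriptional, −1), other sources as `TF`, pure
targets as `PCG`.

## Motif detection

Feedforward loops are ordered triples (regulator, intermediate, target) with
edges regulator→intermediate, intermediate→target, regulator→target.
Feedback loops are directed simple cycles of length 2 or 3, reported once in
the canonical rotation starting at the lexicographically smallest member.
Parallel transcriptional/post-transcriptional arms between the same pair
produce distinct instances — their signs and kinetics can differ, and the
dynamics layer treats them differently. Enumeration iterates sorted
adjacency, so identical inputs give byte-identical output.

Classification is by sign products: an FFL is coherent iff the direct-edge
sign equals the product of the two indirect-arm signs; an FBL is positive
iff its cycle sign product is +1. FFL subtypes follow the standard
sign-pattern table — coherent C1 (+,+,+), C2 (−,+,−), C3 (+,−,−),
C4 (−,−,+); incoherent I1 (+,−,+), I2 (−,+,+), I3 (+,+,−), I4 (−,−,−) —
keyed on (regulator→intermediate, intermediate→target, regulator→target).
The subtype is informational; all analyses key on coherent/incoherent and
positive/negative.

The test suite verifies enumeration against an independent exhaustive scan
over all ordered triples/pairs (`tests/oracles.py`), and the synthetic
planter re-verifies collision-freeness with its own brute-force counter —
the enumeration path is never its own oracle.

## Circuit models

The dynamics layer uses production–degradation ODEs with Hill regulation:
activation `H+(x) = x^n/(k^n + x^n)`, repression `H−(x) = k^n/(k^n + x^n)`.
Time and concentrations are in arbitrary units; all default rates are order
one and productions are tied to turnovers so each species' dynamic range is
≈ [0, 1]. No biological timescale is asserted.

### Input functions and the rheostat map

The steady SOX10→MITF transfer curve comes in three forms: linear `a·S`,
saturated `v_max·S/(k+S)`, sigmoidal `v_max·S^n/(k^n+S^n)`. The sigmoidal
form with `n = 1` *is* the saturated form and is evaluated through the same
expression so the identity holds exactly, not merely to rounding. Closed-form
sensitivities are provided; the cooperative curve is steepest at
`k·((n−1)/(n+1))^(1/n)`, the saturated curve at zero — the source of
cell-to-cell response heterogeneity when cells sit at different SOX10 levels.
The phenotype map places ordered boundaries on the MITF axis with symmetric
gray transition bands (calls within `gray_width` of a boundary return
`"transition"`); zone boundaries are configuration, not measurements — no
quantitative boundary values exist to calibrate against.

### The coherent FFL (miR-155 ⊣ SOX10 → MITF)

Species: miR-155 (driven by an upstream signal such as TGF-β or hypoxia),
SOX10 (repressed by miR-155), MITF mRNA and MITF protein. The two repressive
routes onto MITF combine at the promoter through a gate:

* **threshold mode** (default, the sharp-logic reading): transcription runs
  at `beta` iff `SOX10 > theta_sox AND miR-155 < theta_mir` (AND gate) or
  `SOX10 > theta_sox OR miR-155 < theta_mir` (OR gate), else at the basal
  `leak` fraction. In this mode the gate already encodes the direct miRNA
  arm, so the separate translational-repression term defaults off — keeping
  it would short-circuit the OR gate's ON-delay through the protein stage.
* **continuous mode**: product `H+(SOX10)·H−(miR)` for AND, probabilistic
  sum `H+ + H− − H+·H−` for OR; the direct miRNA arm defaults to acting on
  both translation (`·H−(miR)`) and mRNA turnover (`delta + lam·miR`).

With fast miRNA turnover and an activation threshold at ~60 % of the SOX10
range, the AND gate delays the MITF response to signal *removal* (SOX10 must
climb past threshold first) while responding promptly to signal return —
the sign-sensitive delay — and rejects OFF-pulses shorter than the SOX10
threshold-crossing time (persistence detection). The OR gate mirrors both
properties. The delay difference is defined below; the pulse-rejection
threshold ε defaults to 5 % of the target's sustained dynamic range.

The leaky-transcript analysis is the two-species reduction: hypoxia
simultaneously shuts MITF transcription and drives miR-155, and the residual
mRNA decays at `delta + lam·[miR]` (enhanced degradation) versus bare
`delta`; reported metrics are the post-onset AUC and time-to-10 %. A
`mir_clamp` option pins the miRNA level so the exponential closed forms
`ln2/(delta + lam·m)` are testable exactly.

### The positive FBL (ATF2 ⊣ SOX10 → miR-204 ⊣ ATF2)

ATF2 activity is the control parameter `u` (scanned-input mode, the
default); miR-204 reduces the *effective* activity,
`A_eff = (u + atf2_basal)·H−(miR-204)`, which represses SOX10; SOX10
activates miR-204, closing a cycle of sign (−)(−)(+) = +1. MITF is a
SOX10-driven reporter and does not feed back. A dynamic-ATF2 mode (ATF2
relaxing toward `u + atf2_basal`) is available for time-course work.

Bistability requires cooperativity; the default puts `hill_n = 2` on every
arm and `k = 0.3` on the loop arms, chosen by a reduced-map scan so the
default bistable window (folds near ATF2 ≈ 0.98 and ≈ 2.11) is wide enough
that the four-phase replay can return ATF2 to an interior level and
demonstrate the trapped-OFF state. With all `hill_n = 1` the loop's
logarithmic gain is below one everywhere, so it is monostable at every
scanned value — the test suite checks this across random parameterizations.

`atf2_basal` models miR-204-independent ATF2 activation. Because only
`u ≥ 0` is biologically meaningful, a basal offset larger than the left
fold's total-activity position leaves the bistable window touching `u = 0`:
the OFF state can then never be exited by lowering the controllable
activity, and the switching verdict becomes *irreversible*.

## Numerical choices

* **Integration**: `scipy.integrate.solve_ivp` (LSODA), `rtol 1e-8` /
  `atol 1e-10`, restarted at every signal breakpoint so input
  discontinuities never straddle a step. Hill terms clamp their argument at
  zero, so trajectories from non-negative states stay above −1e−9.
  Threshold-mode gates are genuine step functions; their switching happens
  mid-trajectory and does not affect steady levels, which are the quantities
  compared across tolerances (halving tolerances moves them < 1e−6
  relative).
* **Delay metric**: time from the signal transition until the species
  crosses the midpoint between its pre- and post-transition steady levels,
  linearly interpolated between samples. Steady levels are plateau means
  over the trailing 10 % of the adjacent signal intervals; flatness is
  required relative to the larger of the plateau level and 5 % of the
  species' full excursion (so near-zero plateaus don't fail on tiny
  absolute noise), and a failed plateau raises an error instructing a longer
  interval. For a lone first-order gene the metric reduces to `ln2/delta`.
  Because MITF sits one translation stage downstream, it always lags SOX10
  by a small constant; the sign-sensitive-delay claim is therefore stated
  (and tested) as the OFF-step delay difference strictly exceeding the
  ON-step difference for AND, mirrored for OR.
* **Fixed points**: multi-start Newton (`scipy.optimize.root`, hybr) from a
  deterministic coarse grid over each species' `beta/delta` range plus
  seeded uniform draws; after the first pass, interior points between found
  roots are tried, which reliably captures the saddle between two stable
  states. Roots merge at 1e−6 relative tolerance; stability is the sign of
  the largest real eigenvalue part of a finite-difference Jacobian. The test
  suite cross-checks against a dense-grid sign-change scan of the 1-D
  reduced steady-state equation.
* **Fold bracketing**: bisection on the fixed-point count between grid
  neighbors where the count changes, to 1e−4 of the grid span. A count
  change of ±2 is one fold; a larger jump triggers local grid refinement and
  then a hard error, since it means two folds hide between neighbors.
  If the bistable window runs off the low end of the scan at the physical
  floor, the left fold is reported as unresolved (below range) and the
  verdict is irreversible.
* **Hysteresis**: quasi-static stepping with the state carried over, dwell
  30 time units per step (checked by a relaxation criterion on SOX10, with a
  warning near folds where critical slowing makes full relaxation slow);
  switching thresholds are midpoints of the bracketing grid step, so they
  carry ±1-grid-step uncertainty by construction.

## What the synthetic data does and does not emulate

The generators reproduce the *structural* features the pipeline consumes:
typed nodes with origins, repressive post-transcriptional miRNA edges,
regulator/target asymmetry (generated PCGs are sinks), plantable motifs with
exact ground truth, and miRTarBase-like evidence annotations drawn from a
small fixed vocabulary to exercise dedup logic. They do not emulate
scale-free degree distributions, expression data, database-scale curation
noise, or the actual curated melanoma networks; passing tests demonstrate
algorithmic correctness on networks with known truth, not recovery of any
specific biological network. Likewise the circuit parameterizations are
normalized design points exhibiting the qualitative regimes (delay,
rejection, bistability), not fitted kinetic constants — no kinetic data
exist in the source material to fit.

## Known limitations

* Motifs larger than three nodes, motif-enrichment null models
  (degree-preserving randomization), and expression-based member filtering
  are out of scope.
* Stochastic simulation, parameter fitting, and the tristability of coupled
  FFL+FBL systems are not implemented; the deterministic ODE treatment
  cannot speak to noise-induced state transitions.
* Threshold-mode gates are idealized step logic; real promoters interpolate
  between the threshold and continuous readings.
* The hysteresis sweep assumes the dwell exceeds the slowest relaxation
  time; arbitrarily close to a fold this fails for any finite dwell
  (critical slowing down), which the ±2-grid-step agreement tolerance with
  the bifurcation folds absorbs.
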