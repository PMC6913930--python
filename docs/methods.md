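# Methods

This note documents the modeling conventions, numerical choices, and
design decisions behind `ratesim`, in the order the pipeline runs.

## Equation language

Operator equations are strings with Python-flavoured syntax.  Precedence,
loosest to tightest: comparisons; `+ -`; `* /`; unary minus; `**`
(right-associative, `^` synonymous).  Unary minus binds tighter than
multiplication but looser than the power operator, so `-a**b` is
`-(a**b)` — the convention of the host language, locked in by an oracle
test that evaluates 1000 randomly generated expressions through CPython's
own parser and compares results.

Only first-order derivatives may appear on the left-hand side (`d/dt * x`
or `x'`); higher orders are rejected with a message directing users to
rewrite as coupled first-order equations, which is also how the shipped
synapse kernel is expressed.  Identifiers are
letter/digit/underscore, not digit-initial; `PI` is predefined.
Comparisons return boolean masks (usable for indexing); wrapping in
`float(...)` yields 0.0/1.0.  The function registry covers the
elementwise functions named in the template equations (exp, sin, cos,
tan(h), sinh, cosh, sqrt, log, abs, sigmoid, float) plus `sum(A[, axis])`
and one/two-argument `max`/`min`; it is a plain dict and extensible.
There is no computer-algebra layer: equations are evaluated, never
simplified or differentiated symbolically.

## Template language

Templates are YAML mappings (or structurally identical Python dicts — the
loader does not require file I/O).  A template's `base` is either a root
kind (`OperatorTemplate`, `NodeTemplate`, `EdgeTemplate`,
`CircuitTemplate`) or a parent template.  Child fields override parents;
variable declarations merge key-by-key with the child's value winning and
the role inherited when the child states only a number.  A child *may*
change a variable's role, but this is flagged with a warning since it
usually signals a modeling mistake.

Equation adaptation via `replace` is **token-level**, never substring:
replacing `V` cannot corrupt `V_t`.  Substituted equations are re-parsed
immediately; new free variables must be declared in the same adaptation.

Node templates map operator *labels* to operator templates
(`RPO_e: ExcitatorySynapse`), so one template can appear twice in a node
under different labels with different constants; edge paths
(`PC/RPO_e/r_in`) use these labels.  Edges are 2-4 element lists
`[source, target, edge-template-or-null, attributes]`; `weight` defaults
to 1.0, `delay` (seconds) to none, and any further attribute keys set
constants of operators inside the edge.

## Graph representation and scheduling

`apply()` instantiates a hierarchical circuit; `flatten()` promotes
sub-circuit contents to label-prefixed top-level paths (`JRC1/PC`) and is
idempotent.  Within a node, operators are sorted into **stages**: operator
B runs after operator A when one of B's input variables carries the name
of A's output.  Equations inside one operator are evaluated together;
several producers of one input name sum — this is how the pyramidal
cells' excitatory and inhibitory PSPs combine into one membrane potential.
Cyclic operator dependencies are an error; self-edges on the node are the
sanctioned way to close such loops.  Everything iterates in lexicographic
path order so compiled layouts are reproducible.

`add_edges_from_matrix` uses row = source, column = target; zero entries
create no edge (sparse graphs stay sparse).  Edges may only *feed*
variables with role `input`; they may *read* any source variable.

Edges carrying operators are compiled by splicing the operator chain in as
a mini-node between source and target (weight applied on the outgoing
hop, delay on the incoming hop).  This keeps the synchronous update
semantics uniform at the cost of one extra integration step of transfer
latency through such edges — an acceptable, documented bias of order dt.

## Compiled engine

With vectorization enabled, nodes with identical operator structure (same
equations and roles; constants may differ) merge into one vector-valued
node; per-instance constants become vectors.  Grouping never changes
results: vectorized and non-vectorized runs agree to machine precision,
which the test suite checks at 1e-10 relative tolerance.

The per-step schedule is strictly synchronous:

1. every edge reads its source value *from the previous step* — or from
   `round(delay/dt)` steps back through a per-edge ring buffer — scales it
   by the weight, and accumulates into the target input; extrinsic
   per-step arrays are added on top.  Because no same-step cross-node
   reads exist, evaluation order across nodes cannot affect results;
2. node stages evaluate: algebraic equations assign, differential
   equations produce derivatives;
3. states advance by the chosen solver;
4. algebraic variables are refreshed at the new state (these post-update
   values are what edges and samplers see);
5. outputs are sampled every `round(sampling_step_size/dt)` steps.  t = 0
   is not stored; the first row lies one sampling interval in.  Sampling
   takes instantaneous values, no averaging.

Delay ring buffers start zero-filled; undelayed transfer uses the value
from the algebraic refresh of the previous step (at t = 0: the initial
state).  A positive delay shorter than dt is promoted to one step with a
warning; otherwise delays round to the nearest whole step.  A delayed
trace therefore lags the equivalent undelayed trace by
`round(delay/dt) − 1` samples.

Solvers are fixed-step explicit schemes: Euler (`y + dt f(y)`), midpoint
(`y + dt f(y + dt/2 f(y))`), and `rk23`, a fixed-step third-order
Bogacki-Shampine advance (`y + dt (2k₁ + 3k₂ + 4k₃)/9`).  Adaptive
stepping is deliberately absent: in delay-coupled networks it desynchronizes
nodes and the bookkeeping outweighs the gain.  Measured global-error
orders on dy/dt = −y are ≈1, ≈2, ≈3.

Extrinsic inputs are added verbatim, one value per integration step, with
no √dt rescaling — when driving a model with freshly drawn noise each
step, the response depends on dt; choose the drive with the step size in
mind.  Non-finite states are checked every 1000 steps and abort the run
with the step index and offending variable path.

For each run a specialized step-loop function is generated as Python
source from the parsed equations.  Constants, index vectors and buffers
are passed as arguments, so the source depends only on circuit structure,
solver and binding pattern; generated functions are cached by source
text, and runs above ~4·10⁵ step-instances are JIT-compiled with numba
(interpreted execution of the same source otherwise — results agree to
well below the 1e-10 equivalence tolerance).  Compiled equations are
restricted to scalar per-instance variables; array-valued state inside a
single operator is supported by the expression evaluator but not by the
engine.

## Shipped models

*Jansen-Rit.*  Excitatory synapses: h = 3.25 mV, τ = 10 ms (the classic
parametrization).  Inhibitory and sigmoid constants are not free choices
of this package but the standard literature values: |h_i| = 22 mV,
τ_i = 20 ms, r_max = 5 s⁻¹, s = 560 V⁻¹, V_thr = 6 mV.  The inhibitory
efficacy is stored as **−22 mV**: each population sums its synaptic PSP
outputs into one membrane potential, so hyperpolarization must enter
subtractively while all edge weights stay positive, matching the familiar
`y₁ − y₂` form of the classic equations.  The four internal weight ratios
(1, 0.8, 0.25, 0.25)·C are fixed by the canonical C = 135 weights
(135, 108, 33.75, 33.75).  Extrinsic drive enters the pyramidal cells'
excitatory synapse presynaptically (`r_in → r_in + u` via `replace`).

*Montbrió.*  Bistable-regime constants Δ = 1, η̄ = −5, J = 15 from the
model's source literature; τ = 1, so times are in units of τ and all
variables unit-less.

## Validation scenarios and detectors

*Connectivity sweep.*  Uniform random drive in [120, 320) Hz (the
distribution is assumed uniform; only the range is documented in the
source literature), one independent draw per integration step, fixed
seed.  Labels: **spiking** = peak-to-peak amplitude ≥ 3× the C = 135
alpha-regime amplitude *and* inter-peak-interval CV < 0.2; **alpha** =
Welch-PSD peak inside [8, 12) Hz exceeding 50× the 1-60 Hz median power;
**noise** otherwise.  The 50× clear-peak threshold was calibrated on the
estimator itself: under 2-s Welch windows the driven-but-aperiodic
regimes show max/median ratios around 25 while oscillatory regimes sit
orders of magnitude above 10³, so 50 separates the populations with wide
margins (a literal "5× median" rule would misclassify every driven
response as oscillatory).  Labels are stable across drive seeds and
across the three solvers.

*Timescale sweep.*  τ_e, τ_i ∈ [1, 60] ms with h·τ held constant
(`scale_efficacy`), all cells stacked into one edge-free vectorized run.
Dominant bands span gamma (fast synapses) through delta (slow synapses).
The hyper-signal label fires when the potential's peak-to-peak amplitude
exceeds 0.05 V — a descriptive, configurable heuristic.  Under h·τ
compensation the pyramidal potential stays below ~0.032 V over the whole
sweep, so the default threshold marks no cell; the underlying gradient is
still there (amplitude is maximal at high τ_i/τ_e) and the threshold can
be lowered per call to surface it as labels.

*Montbrió forcing.*  The constant-forcing scenario starts on the stable
focus and applies I = 30 during t ∈ [20, 60): the pulse drives the
population to the forced high-activity state (fast damped ringing at
onset) and releases it into the basin of the stable node — a robust
equilibrium switch.  The reverse (node → focus) direction under a
constant pulse exists only for finely tuned pulse durations (the release
phase of the fast forced-state spiral decides the basin) and flips with
solver and step size, so it is not part of the scenario.  Sinusoidal
forcing (I sin(πt/20), window [20, 60)) tips the node across the saddle
near the stimulus peak and the state spirals into the focus — the
slow-ringing episode the detector looks for.  Both terminal plateaus are
verified as equation roots by refining them with a root finder on the
mean-field right-hand side (residual < 1e-6); the tests repeat this
check against an independently hand-written right-hand side.

The damped-oscillation detector takes the trace after an event, measures
deviation from its final plateau, and requires at least three local
maxima with a decaying envelope (last < half the first).

## Problem sizes in the shipped tests

Spectral criteria that fix a duration use it (60 s at dt = 0.1 ms for the
alpha-peak checks).  The seed/solver robustness matrix of the regime
sweep uses 20-s runs — with 2-s Welch windows this keeps the 0.5 Hz
resolution of the full-length analysis while making the 5×6 run matrix
cheap; stacked-vs-sequential equivalence uses 0.5-s runs at a 3×3 grid,
where the 1e-10 tolerance makes longer runs uninformative.

## What the synthetic inputs do and do not emulate

All validation inputs are generated: uniform random rate drive and
deterministic forcing windows.  They emulate unspecific afferent input
and experimental stimulation protocols, not structured sensory input,
finite-size fluctuations, or measurement noise.  Passing tests therefore
certify the *model dynamics and their numerical treatment* — regime
boundaries, spectral content, bistability — not agreement with recorded
EEG beyond the qualitative band structure.

## Known limitations

- Explicit fixed-step solvers only; stiff parametrizations (τ ≲ 1 ms at
  dt = 0.1 ms) need smaller steps or the higher-order solvers.
- The engine evaluates scalar per-instance variables; vector/matrix state
  within one operator is parsed and evaluable but not compilable.
- Edge operators add one step of transfer latency (see above).
- One step-function source is generated per structure/binding pattern;
  models with thousands of *structurally distinct* nodes will compile
  slowly (structurally identical nodes are free).
- The hyper-signal criterion is an amplitude heuristic, not a dynamical
  classification.
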