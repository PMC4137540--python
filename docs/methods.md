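# Methods

This note documents the models, algorithms, defaults and numerical choices
behind each module, what the synthetic fixtures do and do not emulate, and
the design decisions taken where the problem was genuinely open.

## Continuous models and integration (`models`, `expressions`, `modelio`)

A `ReactionModel` is a list of species with one rate expression per species,
d x_i/dt = f_i(x, θ, u), over declared parameters θ and time-constant
external inputs u. Rate expressions use a restricted arithmetic grammar
(+, −, ×, /, **, parentheses, numeric literals) plus the activating Hill
function `hill(x, K, n) = xⁿ/(Kⁿ + xⁿ)`; expressions are parsed with the
Python `ast` module against a node whitelist, so model files cannot execute
code. Mass-action and Hill-type kinetics — all the fixtures need — are
expressible; arbitrary callables deliberately are not.

Integration uses SciPy's LSODA (implicit-capable; the apoptosis cascade is
stiff) with defaults rtol = 1e−8, atol = 1e−10. **Non-negativity policy:**
concentrations in [−1e−9, 0) are clipped to 0; anything below −1e−9 raises
a divergent-dynamics error naming the species, since a genuine mass-action
model cannot reach it. Time units are declared by the model and opaque to
the engine; all fixtures use minutes.

**Steady-state detection.** The normalized residual
r(t) = max_i |ẋ_i| / max(max_i |x_i|, 1e−6) must stay below `tol`
(default 1e−6) over a trailing window spanning 5% of elapsed time; the
reported settling time is the first crossing, refined by log-linear
interpolation of r(t) between integrator samples so that transition times
are continuous rather than quantized at the sampling resolution. Bounded
non-convergence by `t_max` (e.g. a sustained oscillation) is reported as
`converged=False` with the final residual, not an exception.

**Bifurcation scans** are quasi-static continuations: the input is stepped
along a grid and the model re-equilibrated from the previous steady state,
so up- and down-sweeps follow different branches exactly when the system is
hysteretic.

## Fixture models (`zoo`)

All fixtures are original minimal models built to satisfy stated
qualitative contracts; their defaults were tuned once against those
contracts and then pinned. They are deliberately small — the point is the
*workflow* (abstraction, sensitivity, composition), not quantitative organ
or pathway realism.

**Bistable G1/S switch** (3 species). C is cyclin-D-like: ´C = aC·S − dC·C,
linear in the growth signal S ∈ [0, 2], hence graded and monostable. E is
E2F-like with two positive feedback loops — Hill self-activation (gain aE)
and double inhibition through the Rb-like repressor R (E ⊣ R ⊣ E):

    Ė = (bE·C + aE·hill(E, KE, 4)) · (1 − hill(R, KR, 4)) − dE·E
    Ṙ = aR · (1 − hill(E, KI, 4)) − dR·R

With the pinned defaults (aC=dC=dE=dR=1, bE=1, aE=1.2, KE=1, aR=1.5, KR=1,
KI=0.4) the system has a unique low-E state at S=0, a unique high-E state
at S=2, and two stable branches over S ≈ [0.4, 1.0]; E shows hysteresis
under the scan while C does not. Setting aE=aR=0 recovers a linear,
monostable system. Both saddle-nodes lie inside (0, 2) so hysteresis is
finite: dropping S below ≈0.4 does revert the switch.

**Mini extrinsic-apoptosis cascade** (18 species, ~11 reactions, one
well-mixed volume — the membrane/cytosol/mitochondria compartments are
deliberately flattened). Ligand binds receptor reversibly (k1, k_1), the
complex activates the receptor (κ1), active receptor activates caspase-8
(k3); C8* is buffered by Bar (k4) and cleaves Bid (k10); Bcl2 buffers tBid
reversibly (k11, k_11); free tBid activates Bax (k12). Active Bax is the
irreversible permeabilization species: effector-caspase activation is gated
by a steep Hill term hill(Bax*, K_pore, 4) (k13), after which C3* cleaves
PARP (k14) and feeds back on caspase-8 (k15). The gate plus feedback yields
the characteristic time course: a long delay (≈200 min at defaults) while
buffers deplete, then near-complete PARP cleavage within minutes
(T_d ≈ 221 min, maximum cleavage rate well after a quarter of T_d).
Upstream rate-constant names (k1, k_1, κ1, k3, k4, k10, k11, k_11, k12)
follow the conventional labels of these steps so sensitivity tables read
naturally.

**Toy hepatic model** (3 species). Saturable (Michaelis–Menten) Taxol
metabolism, lactate production proportional to the metabolic flux, first-
order lactate clearance, plus a cumulative-metabolism accumulator used by
the co-simulation ledger. Defaults: Vmax=0.2/min, Km=0.5 (so therapeutic
concentrations saturate the enzyme and the uptake flow is *remote* with
respect to the pool), α=4, k_clear=0.1/min, basal production 0.1 (baseline
lactate 1), declared toxicity threshold 8. Because metabolism saturates,
peak lactate is governed by the *duration* of saturation, which is what
separates safe from toxic schedules.

**Random cascades.** Linear irreversible chains X0 → … → Xn with rate
constants log-uniform on [0.1, 1.0]/min — chosen so half-saturation times
stay at desk scale — except the planted limiting constant, divided by
`fold`. The generator returns the ground-truth annotation for recovery
tests.

## Timed-automaton abstraction (`abstraction`)

The abstract model is M = ⟨S, E, I⟩: abstract states (clusters of concrete
steady states with per-species mean and SD), input values, and edges
(s, s′, i) ↦ empirical transition-time distribution.

**Sampling protocol.** For every ordered pair (i₀, i₁) of distinct grid
values, the model is equilibrated at i₀ (from both the low initial state
and the high-input attractor, so coexisting branches are represented),
the start state and target input are jittered, the input switches to i₁,
and the model integrates back to steady state; each trace reduces to
(start state, end state, input, transition time). The concrete model is
deterministic, so the dispersion of the time distributions is *generated*
by the jitter: Gaussian input noise with SD 5% of the grid spacing
(truncated to the declared range) and multiplicative log-normal state noise
with SD 2% — both configurable and recorded. Non-convergent traces are
dropped and counted in a diagnostics report, never silently.

**Cluster-count selection.** Pooled start/end states are standardized to
unit pooled SD per species and clustered by seeded k-means++ (10 restarts)
for k = 1..k_max; the selected k is the smallest whose maximum
within-cluster per-species SD (standardized scale) falls below
`sd_threshold`. The threshold expresses the abstraction granularity in
pooled-SD units. The default is 0.75: steady states necessarily vary
*along* a stable branch as the input changes (the cyclin-D-like species
tracks S linearly by construction), giving within-branch standardized
spreads of ≈0.5–0.65, while the separation between branches is ≳1.5; 0.75
therefore merges input-conditioned variation within one dynamical branch
and still splits distinct branches, which is the granularity at which "the
states of the switch" is a meaningful question. A much smaller threshold
resolves input levels as separate states instead. If no k qualifies the
k_max clustering is returned with a warning flag.

**Edges.** Sample endpoints are assigned to the nearest centroid in the
standardized Euclidean metric (ties to the lowest state id). Edges are
bucketed by the *nominal* grid value of the perturbed input — jittered
values inherit their nominal bucket — because indexing edges by exact real
input values is impractical under jitter. Self-loops are retained as data
(perturbations that do not change the abstract state); event simulation
skips them, since a self-loop is by definition "no abstract state change".
Edge statistics (time mean/SD, input mean/SD, support count) are
recomputable from the raw samples, which are preserved in the JSON export.

**Event simulation** draws an outgoing edge for the current input bucket
with probability proportional to its support count (the sampling frequency
is the only available estimate of relative propensity) and a transition
time by resampling the edge's empirical distribution with replacement.
A state with no outgoing edge under the current input is absorbing for that
input.

**Hysteresis check.** "High" is the abstract state occupied after
equilibrating at the top of the input range, "low" the state reached at
the bottom from the initial state. Preservation requires (a) the concrete
high branch not to revert to the low abstract state anywhere in the query
window and (b) no supported high→low automaton edge inside the window.

**Trajectory distance.** Traces are linearly interpolated onto a common
grid over the overlap of their supports; the distance is the sup (maximum
over time) or L2 (time-normalized RMS) of the pointwise Euclidean
difference over the chosen observables. Abstract trajectories are lifted to
concrete space as piecewise-constant centroid paths. Identical traces give
0; symmetry and the triangle inequality hold by construction and are
re-checked on sampled triples in the tests.

## Sensitivity analysis (`sensitivity`)

T_d is the first time the product species crosses
`threshold_fraction × total` (default: half of the *initial* substrate
pool; a flag switches the basis to the final cleaved amount, since "half of
all PARP" admits both readings), located by linear interpolation between
bracketing time points; traces that never cross are *censored* and excluded
with a count — imputation would distort the linear response surface.

The perturbation design draws multiplicative factors log-uniform on
[1/f, f] (default f=4, n=500; the CLI and tests use smaller n where the
extra precision is not needed). PLSR is fit on standardized log2 factors
vs T_d; the component count is the first local maximum of cross-validated
predictive R² (5-fold); VIP scores come from the full-data refit,
VIP_j = sqrt(p · Σ_a SS_a (w_ja/‖w_a‖)² / Σ_a SS_a), which satisfies
mean(VIP²) = 1. Signed standardized coefficients give the direction of
influence. Rankings use descending VIP with name-alphabetical tie-break;
the "elbow" rule returns the prefix before the largest consecutive gap in
the sorted scores, as an alternative to the conventional VIP > 1 line.

## Co-simulation (`cosim`)

**Population model.** Cells carry a strategy and a lineage tag. Wild-type
per-cell rates are logistic-style, b(N) = b₀·max(0, 1 − N/2N*) and
d(N) = d₀·N/2N*, with b₀ = d₀ (= 0.1/min) so they balance exactly at the
homeostatic set point N* (= 200). "Constitutive proliferation" divides at
b₀ regardless of N; "apoptosis evasion" has death rate 0 — the strategies
are named behaviors, quantified here by deleting one regulatory arm. The
drug kills a cell when it *attempts to divide*, with saturating probability
p = T/(T + K_kill) (K_kill = 0.2), consuming a small fixed uptake from the
shared pool per kill. The default composite seeds an established 20-cell
mutant clone so that outcomes reflect the schedule rather than the ~50%
stochastic extinction of a single founder.

**Event loop.** Gillespie sampling over per-strategy group rates; between
events (and doses) the liver ODE integrates with its uptake species bound
to the shared pool, and the pool value plus ledger are exchanged at every
stop point. Doses are instantaneous boluses. The ledger balances
inflow − Σ outflows − value to integrator precision (~1e−15 relative in
practice) because the liver model carries an explicit cumulative-metabolism
accumulator integrated by the same solver. Interactions are typed by
numerical probing: *close* if the local elasticity
(∂log flow / ∂log variable) exceeds 0.15, *remote* if only a large (±100%)
perturbation moves the flow by more than 5%, *none* otherwise (symbolic
short-circuit when the variable is absent). Cross-boundary close
interactions are flagged at validation (warn level); remote interactions
carry a guard — when the pool moves more than the guard threshold
(default 25% relative) between stops, integration halts early and rates are
refreshed, which is statistically exact because exponential waiting times
are memoryless. In the default composite the population rates do not read
the pool between events (the kill probability is evaluated at the event),
so the guard affects efficiency, not correctness; the mechanism is tested
by refinement convergence.

**Outcomes.** tumor_cleared iff the final mutant-lineage count is at or
below the tumor-free threshold (default 0); liver_toxic iff peak lactate
exceeds the declared threshold. The four combinations are all realized by
the default composite under a small (dose, interval) grid: token dosing →
persists/safe, ~50% duty moderate dosing → cleared/safe (the optimal
outcome), dense or heavy dosing → cleared/toxic.

## Boolean networks (`boolnet`)

Asynchronous semantics: one node updates per transition, so every state-
graph edge flips at most one bit. Fixed points carry explicit self-loops
(rather than empty successor sets) so reachability and SCC analyses compose
without special cases. Reachability is breadth-first with shortest witness
paths; safety is AG-within-bound via reachability of the violation;
attractors are terminal SCCs of the full state graph (networkx), with a
hard cap of 24 nodes for exhaustive analyses — beyond that only bounded
search is allowed. The 10-node pathway fixture is an original illustrative
network (ligand→receptor→RAS→ERK proliferation arm gated by p21, a
P53–MDM2 negative feedback that sustains a cyclic attractor, and an
apoptosis readout); it is synthetic and stands for no published model.

## What the fixtures do and do not show

Passing tests demonstrate that the *methods* behave correctly on systems
with the stated qualitative structure: a genuine bistable switch is
abstracted to two states with preserved hysteresis; a cascade with an
irreversible commitment step yields sensitivity rankings concentrated
upstream of it; a conservative shared-pool composite stays conservative;
planted ground truth is recovered. They do not validate any quantitative
claim about real pathways: the fixtures have invented parameters, a single
compartment, no transport, no cell-cycle structure, and population dynamics
with only crowding feedback. Scale choices in tests and the acceptance
script (e.g. 150 traces per input level, 120–150-sample PLSR designs,
1000 Yule replicates) are the package's study sizes, chosen to make the
statistical assertions sharp at desk scale.

## Known limitations

- Rate expressions cover mass-action/Hill closed forms only; no events,
  delays, or spatial terms (the co-simulation guard mechanism is the only
  hybrid construct).
- The automaton's Δ(ℝ) edge distributions are empirical; no parametric
  family is fit, and a rare third state missed by sampling would be missed
  by the abstraction too — the selection margin is reported but the
  question is not resolved.
- `simulate_automaton` supports piecewise-constant input schedules only.
- The Taxol pool is well-mixed; diffusion is abstracted away.
- Unbounded Boolean analyses are capped at 24 nodes (bit-encoded states);
  no symbolic (BDD) model checking.
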