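"""Hybrid co-simulation: continuous (ODE) and discrete (agent-based)
sub-models coupled through shared variables.

The composite runs a kinetic-Monte-Carlo event loop: the agent population
takes discrete Gillespie steps while the continuous sub-models (e.g. a
hepatic pharmacokinetic model) are integrated between stops; every stop
point exchanges the shared-variable values (e.g. the plasma Taxol
concentration) and a conservation ledger tracks all inflows (doses) and
outflows (hepatic metabolism, per-cell uptake) so that the pool balances
exactly.

Interactions between a shared variable and a sub-model flow are classified
as close / remote / none (types I/II/III): a modular decomposition permits
only remote or empty interactions across sub-model boundaries, and each
remote interaction carries a guard — a relative-change threshold that forces
a rate refresh when crossed between stop points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .expressions import compile_expression
from .models import ReactionModel, simulate

__all__ = [
    "WILD_TYPE",
    "CONSTITUTIVE_PROLIFERATION",
    "APOPTOSIS_EVASION",
    "AgentPopulationModel",
    "SharedVariable",
    "CompositeModel",
    "CompositeTrace",
    "OutcomeClass",
    "classify_interaction",
    "cosimulate",
    "run_population",
    "classify_outcome",
]

WILD_TYPE = "wild_type"
CONSTITUTIVE_PROLIFERATION = "constitutive_proliferation"
APOPTOSIS_EVASION = "apoptosis_evasion"
STRATEGIES = (WILD_TYPE, CONSTITUTIVE_PROLIFERATION, APOPTOSIS_EVASION)


@dataclass
class AgentPopulationModel:
    """Homeostatic cell population with division/death controlled by size.

    Wild-type rates are logistic-style: per-cell division rate
    ``b(N) = b0 * max(0, 1 - N/(2 N*))`` and death rate
    ``d(N) = d0 * N / (2 N*)``; with ``b0 = d0`` these balance exactly at
    the homeostatic set point N*.  Mutant strategies deregulate one arm:
    constitutive proliferation divides at ``b0`` regardless of N; apoptosis
    evasion has death rate 0.  A drug in the environment kills a cell when
    it attempts to divide, with saturating probability
    ``p_kill = T / (T + K_kill)``, consuming ``uptake_per_kill`` of the
    shared pool per kill.
    """

    n_star: int = 200
    b0: float = 0.1          # max per-cell division rate (1/min)
    d0: float = 0.1          # death-rate scale (1/min); b0 == d0 for homeostasis
    k_kill: float = 0.2      # drug concentration at half-maximal kill probability
    uptake_per_kill: float = 0.01  # shared-pool consumption per killed cell
    drug_variable: str | None = "Taxol"

    def birth_rate(self, strategy: str, n_total: int) -> float:
        if strategy == CONSTITUTIVE_PROLIFERATION:
            return self.b0
        return self.b0 * max(0.0, 1.0 - n_total / (2.0 * self.n_star))

    def death_rate(self, strategy: str, n_total: int) -> float:
        if strategy == APOPTOSIS_EVASION:
            return 0.0
        return self.d0 * n_total / (2.0 * self.n_star)

    def p_kill(self, drug: float) -> float:
        if drug <= 0.0:
            return 0.0
        return drug / (drug + self.k_kill)


@dataclass
class SharedVariable:
    """A well-mixed pool read and written by several sub-models.

    The conservation ledger accumulates inflow (doses) and per-sub-model
    outflows; ``inflow - sum(outflows) - value`` must stay ~0.
    """

    name: str
    value: float = 0.0
    inflow: float = 0.0
    outflows: dict[str, float] = field(default_factory=dict)

    def dose(self, amount: float) -> None:
        self.value += amount
        self.inflow += amount

    def withdraw(self, sub_model: str, amount: float) -> float:
        amount = min(amount, self.value)
        self.value -= amount
        self.outflows[sub_model] = self.outflows.get(sub_model, 0.0) + amount
        return amount

    @property
    def imbalance(self) -> float:
        return self.inflow - sum(self.outflows.values()) - self.value

    def relative_imbalance(self) -> float:
        scale = max(self.inflow, abs(self.value), 1e-12)
        return abs(self.imbalance) / scale


@dataclass
class CompositeModel:
    """Registry of sub-models, shared wiring, guards and dosing schedule.

    ``liver`` couples through two designated species: one bound to the
    shared pool (its value synchronized at every stop point) and one
    accumulator integrating the metabolized amount for the ledger.
    """

    population: AgentPopulationModel
    liver: ReactionModel | None = None
    shared_name: str = "Taxol"
    liver_pool_species: str = "Tx"
    liver_cumulative_species: str = "Mcum"
    dosing_schedule: list[tuple[float, float]] = field(default_factory=list)
    guard_threshold: float = 0.25   # relative shared-variable change forcing refresh
    tumor_free_threshold: int = 0
    lactate_species: str = "Lac"
    lactate_toxic: float | None = None  # default: liver parameter "lactate_toxic"

    def validate(self) -> list[str]:
        """Warn-level validation of the modular decomposition."""
        warnings = []
        if abs(self.population.birth_rate(WILD_TYPE, self.population.n_star)
               - self.population.death_rate(WILD_TYPE, self.population.n_star)) > 1e-9:
            warnings.append("wild-type rates do not balance at N*")
        if self.liver is not None and self.dosing_schedule:
            # probe the uptake flow at the peak therapeutic concentration
            flow = self.liver.rates[self.liver_pool_species]
            kind = classify_interaction(
                flow, self.liver, self.liver_pool_species,
                at_value=max(d for _, d in self.dosing_schedule),
            )
            if kind == "close":
                warnings.append(
                    f"close (type I) interaction between shared {self.shared_name!r} "
                    "and the hepatic uptake flow crosses a sub-model boundary"
                )
        times = [t for t, _ in self.dosing_schedule]
        if any(b <= a for a, b in zip(times, times[1:])):
            warnings.append("dosing schedule times not increasing")
        return warnings


@dataclass
class CompositeTrace:
    events: list[tuple[float, str, str, str, int]]  # (time, kind, strategy, lineage, N)
    shared_history: list[tuple[float, float, float]]  # (time, value, imbalance)
    liver_times: np.ndarray | None
    liver_states: np.ndarray | None
    liver_species: tuple[str, ...] = ()
    t_end: float = 0.0
    final_counts: dict[tuple[str, str], int] = field(default_factory=dict)

    def lineage_count(self, lineage: str) -> int:
        return sum(n for (strat, lin), n in self.final_counts.items() if lin == lineage)

    def peak(self, species: str) -> float:
        if self.liver_states is None:
            return 0.0
        return float(self.liver_states[:, self.liver_species.index(species)].max())


@dataclass(frozen=True)
class OutcomeClass:
    label: str
    final_mutant_count: int
    peak_lactate: float
    tumor_free_threshold: int
    lactate_toxic: float


# ---------------------------------------------------------------------------
# Interaction classification (types I/II/III)
# ---------------------------------------------------------------------------


def classify_interaction(
    flow: str,
    model: ReactionModel,
    variable: str,
    *,
    at_state: Sequence[float] | None = None,
    at_value: float | None = None,
    epsilon: float = 0.01,
    delta_large: float = 1.0,
    gain_threshold: float = 0.15,
    significance: float = 0.05,
) -> str:
    """Classify the dependence of a flow expression on a variable.

    Numerically probes the flow at the operating point.  The small probe
    measures the local relative gain (elasticity): relative flow change per
    relative variable change under an ``epsilon`` perturbation; "close" if
    the gain exceeds *gain_threshold*.  Otherwise the large probe perturbs
    the variable by ``delta_large`` (relative, both directions): "remote"
    if the relative flow change then exceeds *significance*, "none" if even
    a large change leaves the flow essentially unaffected.  A variable
    absent from the expression short-circuits to "none".
    """
    from .expressions import expression_symbols

    if variable not in expression_symbols(flow):
        return "none"
    allowed = set(model.species) | set(model.parameters) | set(model.inputs)
    f = compile_expression(flow, allowed)
    state = np.asarray(
        at_state if at_state is not None else model.initial_state, dtype=float
    )
    ns = dict(zip(model.species, state))
    ns.update(model.parameters)
    ns.update(model.inputs)
    base_value = float(at_value if at_value is not None else ns.get(variable, 0.0))
    scale = abs(base_value) if base_value != 0.0 else 1.0
    ns[variable] = base_value
    f0 = f(ns)
    if not math.isfinite(f0):
        raise ValueError(f"flow non-finite at operating point ({flow!r})")
    flow_scale = abs(f0) if f0 != 0.0 else 1.0

    def rel_change(perturbation: float) -> float:
        ns[variable] = base_value + perturbation * scale
        f1 = f(ns)
        if not math.isfinite(f1):
            raise ValueError(f"flow non-finite at probe point ({flow!r})")
        return abs(f1 - f0) / flow_scale

    gain = max(rel_change(epsilon), rel_change(-epsilon)) / epsilon
    if gain > gain_threshold:
        return "close"
    large = max(rel_change(delta_large), rel_change(-delta_large))
    if large > significance:
        return "remote"
    return "none"


# ---------------------------------------------------------------------------
# Population-only Gillespie simulation
# ---------------------------------------------------------------------------


def _group_rates(
    pop: AgentPopulationModel, counts: dict[tuple[str, str], int]
) -> tuple[list[tuple[str, str]], np.ndarray, np.ndarray, int]:
    n_total = sum(counts.values())
    groups = [g for g, c in counts.items() if c > 0]
    births = np.array(
        [pop.birth_rate(g[0], n_total) * counts[g] for g in groups]
    )
    deaths = np.array(
        [pop.death_rate(g[0], n_total) * counts[g] for g in groups]
    )
    return groups, births, deaths, n_total


def run_population(
    pop: AgentPopulationModel,
    mutant_strategy: str | None = None,
    *,
    n_reps: int = 1,
    seed: int = 0,
    t_max: float = 10_000.0,
    offspring_target: int = 200,
    initial_counts: dict[tuple[str, str], int] | None = None,
    drug: Callable[[float], float] | None = None,
) -> list[tuple[float, bool]]:
    """Simulate the population alone; return (time, censored) per replicate.

    One mutant cell (carrying *mutant_strategy* and its own lineage tag) is
    seeded into a wild-type population at the homeostatic set point; each
    replicate runs until the mutant lineage reaches *offspring_target* cells
    or *t_max*.  With ``mutant_strategy=None`` the population is pure wild
    type and the replicate always runs to *t_max* (time reported censored).
    """
    results = []
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        if initial_counts is not None:
            counts = dict(initial_counts)
        else:
            counts = {(WILD_TYPE, "wt"): pop.n_star}
            if mutant_strategy is not None:
                counts[(WILD_TYPE, "wt")] -= 1
                counts[(mutant_strategy, "mutant")] = 1
        t = 0.0
        done = None
        while t < t_max:
            groups, births, deaths, n_total = _group_rates(pop, counts)
            total = births.sum() + deaths.sum()
            if total <= 0.0:
                break
            t += rng.exponential(1.0 / total)
            if t >= t_max:
                break
            weights = np.concatenate([births, deaths])
            i = rng.choice(weights.size, p=weights / weights.sum())
            g = groups[i % len(groups)]
            if i < len(groups):  # division attempt
                T = drug(t) if drug is not None else 0.0
                if T > 0 and rng.random() < pop.p_kill(T):
                    counts[g] -= 1
                else:
                    counts[g] += 1
            else:
                counts[g] -= 1
            mutant_count = sum(
                c for (s, lin), c in counts.items() if lin == "mutant"
            )
            if mutant_count >= offspring_target:
                done = t
                break
        results.append((done if done is not None else t_max, done is None))
    return results


# ---------------------------------------------------------------------------
# Full co-simulation
# ---------------------------------------------------------------------------


def cosimulate(
    composite: CompositeModel,
    t_end: float,
    seed: int = 0,
    *,
    initial_counts: dict[tuple[str, str], int] | None = None,
    record_liver_every: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> CompositeTrace:
    """KMC-style event loop coupling the population and the liver model.

    Between population events the liver ODE is integrated with the shared
    pool bound to its uptake species; shared-variable values are exchanged
    at every stop point (event, dose, guard check, or t_end) and the
    conservation ledger is updated from the liver's cumulative-metabolism
    accumulator.  Doses are instantaneous boluses into the shared pool.
    Fully reproducible under *seed*.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    pop = composite.population
    shared = SharedVariable(composite.shared_name)
    rng = np.random.default_rng(seed)

    counts: dict[tuple[str, str], int]
    if initial_counts is not None:
        counts = dict(initial_counts)
    else:
        # established mutant clone: large enough that stochastic extinction
        # without drug is negligible, so outcomes reflect the schedule
        counts = {(WILD_TYPE, "wt"): pop.n_star - 20,
                  (CONSTITUTIVE_PROLIFERATION, "mutant"): 20}

    liver = composite.liver
    liver_state = None
    i_pool = i_cum = None
    liver_times: list[float] = []
    liver_states: list[np.ndarray] = []
    if liver is not None:
        liver_state = liver.initial_state.copy()
        i_pool = liver.index(composite.liver_pool_species)
        i_cum = liver.index(composite.liver_cumulative_species)
        liver_times.append(0.0)
        liver_states.append(liver_state.copy())

    events: list[tuple[float, str, str, str, int]] = []
    shared_history: list[tuple[float, float, float]] = [(0.0, 0.0, 0.0)]
    doses = sorted(composite.dosing_schedule)
    dose_idx = 0
    t = 0.0
    last_record = 0.0

    def integrate_liver(t0: float, t1: float) -> float:
        """Advance the liver ODE on [t0, t1] with the pool synced to shared.

        Returns the time actually reached: integration stops early at the
        first recorded point where the shared pool has moved by more than
        the guard threshold (relative) since t0, forcing a rate refresh in
        the event loop (exact under the memoryless event-time draw).
        """
        nonlocal liver_state
        if liver is None or t1 <= t0:
            return t1
        liver_state[i_pool] = shared.value
        cum_before = liver_state[i_cum]
        ref = max(shared.value, 1e-3)
        n_rec = max(2, int((t1 - t0) / record_liver_every) + 1)
        sol = solve_ivp(
            liver.rhs, (t0, t1), liver_state, method="LSODA",
            t_eval=np.linspace(t0, t1, n_rec), rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"liver integration failed: {sol.message}")
        stop_idx = sol.t.size - 1
        if composite.guard_threshold is not None and shared.value > 0:
            for j in range(1, sol.t.size):
                if abs(sol.y[i_pool, j] - ref) / ref > composite.guard_threshold:
                    stop_idx = j
                    break
        liver_state = np.clip(sol.y[:, stop_idx], 0.0, None)
        for j in range(1, stop_idx + 1):
            liver_times.append(float(sol.t[j]))
            liver_states.append(np.clip(sol.y[:, j], 0.0, None))
        metabolized = float(liver_state[i_cum] - cum_before)
        shared.outflows["liver"] = shared.outflows.get("liver", 0.0) + metabolized
        shared.value = float(liver_state[i_pool])
        return float(sol.t[stop_idx])

    while t < t_end:
        groups, births, deaths, n_total = _group_rates(pop, counts)
        total = float(births.sum() + deaths.sum())
        next_dose = doses[dose_idx][0] if dose_idx < len(doses) else math.inf
        if total > 0.0:
            t_event = t + rng.exponential(1.0 / total)
        else:
            t_event = math.inf  # zero total rate: fast-forward
        t_stop = min(t_event, next_dose, t_end)
        t_reached = integrate_liver(t, t_stop)
        guard_tripped = t_reached < t_stop
        t = t_reached
        shared_history.append((t, shared.value, shared.imbalance))
        if shared.value < -1e-9:
            raise RuntimeError(
                f"conservation error: shared pool negative ({shared.value}); "
                f"ledger inflow={shared.inflow} outflows={shared.outflows}"
            )
        if t >= t_end:
            break
        if guard_tripped:
            continue  # refresh rates and redraw the event time
        if t == next_dose:
            shared.dose(doses[dose_idx][1])
            events.append((t, "dose", "", "", n_total))
            dose_idx += 1
            continue
        # population event
        weights = np.concatenate([births, deaths])
        i = rng.choice(weights.size, p=weights / weights.sum())
        g = groups[i % len(groups)]
        if i < len(groups):  # division attempt
            if shared.value > 0 and rng.random() < pop.p_kill(shared.value):
                counts[g] -= 1
                shared.withdraw("population", pop.uptake_per_kill)
                events.append((t, "drug_kill", g[0], g[1], n_total - 1))
            else:
                counts[g] += 1
                events.append((t, "division", g[0], g[1], n_total + 1))
        else:
            counts[g] -= 1
            events.append((t, "death", g[0], g[1], n_total - 1))

    return CompositeTrace(
        events=events,
        shared_history=shared_history,
        liver_times=np.asarray(liver_times) if liver is not None else None,
        liver_states=np.vstack(liver_states) if liver is not None else None,
        liver_species=liver.species if liver is not None else (),
        t_end=t_end,
        final_counts={g: c for g, c in counts.items() if c > 0},
    )


def classify_outcome(
    trace: CompositeTrace,
    *,
    tumor_free_threshold: int = 0,
    lactate_toxic: float = 8.0,
    lactate_species: str = "Lac",
) -> OutcomeClass:
    """Map a composite trace to one of the four dosing outcomes."""
    mutants = trace.lineage_count("mutant")
    peak_lac = trace.peak(lactate_species) if trace.liver_states is not None else 0.0
    cleared = mutants <= tumor_free_threshold
    toxic = peak_lac > lactate_toxic
    label = (
        f"tumor_{'cleared' if cleared else 'persists'}_"
        f"liver_{'toxic' if toxic else 'safe'}"
    )
    return OutcomeClass(label, mutants, peak_lac, tumor_free_threshold, lactate_toxic)
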