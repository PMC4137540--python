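"""Abstraction of a continuous model into a timed discrete-state automaton.

The abstract model is a 3-tuple M = (S, E, I): a set of abstract states S
(clusters of concrete steady states, each carrying per-species mean and SD),
a set of input values I, and edges E mapping (state, state, input) to an
empirical distribution over transition times.

The pipeline: sample transition traces of the concrete model (equilibrate at
one input, perturb to another, integrate back to steady state); pool the
start/end states and cluster them with k-means, choosing the smallest k whose
within-cluster spread falls below a threshold; then group samples by
(from-state, to-state, input) to estimate per-edge transition-time
statistics.  The resulting automaton can be event-simulated cheaply for
population-scale studies, and checked for preservation of bistability and
hysteresis against the concrete model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .models import ReactionModel, Trace, find_steady_state, simulate

__all__ = [
    "TransitionSample",
    "AbstractState",
    "EdgeDistribution",
    "TimedAutomaton",
    "SamplingReport",
    "sample_transitions",
    "cluster_states",
    "build_automaton",
    "abstract_model",
    "simulate_automaton",
    "check_hysteresis",
    "trajectory_distance",
    "automaton_to_json",
    "automaton_from_json",
    "automaton_to_dot",
]

# Jitter defaults: dispersion of the empirical transition-time distributions
# is generated by Gaussian noise on the perturbed input (SD = 5% of grid
# spacing, truncated to the declared range) and multiplicative log-normal
# noise on the start state (SD = 2%).
INPUT_JITTER_FRACTION = 0.05
STATE_JITTER_SD = 0.02


@dataclass(frozen=True)
class TransitionSample:
    """One sampled perturbation-response trace, reduced to its endpoints."""

    start_state: np.ndarray
    end_state: np.ndarray
    input_value: float        # actual (jittered) post-perturbation input
    nominal_input: float      # grid value the jittered input belongs to
    start_input: float        # pre-perturbation grid value
    transition_time: float


@dataclass(frozen=True)
class AbstractState:
    id: int
    members: np.ndarray               # (n_members, n_species)
    centroid: np.ndarray
    per_species_mean: np.ndarray
    per_species_sd: np.ndarray

    @property
    def size(self) -> int:
        return self.members.shape[0]


@dataclass
class EdgeDistribution:
    """Empirical transition-time distribution supporting one automaton edge."""

    samples: list[float]
    input_values: list[float]

    @property
    def support_count(self) -> int:
        return len(self.samples)

    @property
    def time_mean(self) -> float:
        return float(np.mean(self.samples))

    @property
    def time_sd(self) -> float:
        return float(np.std(self.samples))

    @property
    def input_mean(self) -> float:
        return float(np.mean(self.input_values))

    @property
    def input_sd(self) -> float:
        return float(np.std(self.input_values))


@dataclass
class TimedAutomaton:
    """The abstract model M = (S, E, I)."""

    states: list[AbstractState]
    inputs: list[float]
    edges: dict[tuple[int, int, float], EdgeDistribution]
    species: tuple[str, ...]
    scale: np.ndarray  # per-species standardization scale used for clustering
    warning: str | None = None

    def edges_from(self, state_id: int, input_bucket: float) -> list[tuple[int, int, float]]:
        return [k for k in self.edges if k[0] == state_id and k[2] == input_bucket]

    def state_for(self, concrete_state: np.ndarray) -> int:
        """Nearest abstract state under the standardized Euclidean metric."""
        z = np.asarray(concrete_state) / self.scale
        dists = [float(np.linalg.norm(z - s.centroid / self.scale)) for s in self.states]
        return int(np.argmin(dists))  # argmin breaks ties by lowest id


@dataclass
class SamplingReport:
    n_requested: int = 0
    n_converged: int = 0
    dropped: list[tuple[float, float, str]] = field(default_factory=list)


def sample_transitions(
    model: ReactionModel,
    input_name: str,
    input_grid: Sequence[float],
    n_per_input: int,
    *,
    input_jitter_fraction: float = INPUT_JITTER_FRACTION,
    state_jitter_sd: float = STATE_JITTER_SD,
    seed: int = 0,
    steady_tol: float = 1e-6,
    t_max: float = 1e4,
    report: SamplingReport | None = None,
) -> list[TransitionSample]:
    """Sample perturbation-response traces over all ordered grid pairs.

    For each ordered pair (i0, i1) of distinct grid values, *n_per_input*
    traces are drawn: equilibrate the model at i0, jitter the start state
    (multiplicative log-normal) and the target input (Gaussian, truncated to
    the declared range), switch the input, and integrate to steady state.
    Each trace is reduced to (start state, end state, input, transition
    time).  Non-convergent traces are dropped and counted in *report*.
    """
    if input_name not in model.inputs:
        raise KeyError(f"unknown input {input_name!r}")
    grid = [float(v) for v in input_grid]
    lo, hi = model.input_ranges.get(input_name, (min(grid), max(grid)))
    for v in grid:
        if not (lo <= v <= hi):
            raise ValueError(f"grid value {v} outside declared range [{lo}, {hi}]")
    if n_per_input < 1:
        raise ValueError("n_per_input must be >= 1")
    rng = np.random.default_rng(seed)
    spacing = min(np.diff(sorted(set(grid)))) if len(set(grid)) > 1 else 1.0
    input_sd = input_jitter_fraction * spacing

    # Equilibrate once per grid value, from both ends of the state space, so
    # coexisting branches are both represented as start states.
    anchors: dict[float, list[np.ndarray]] = {}
    hi_state = find_steady_state(
        model.with_inputs(**{input_name: max(grid)}), tol=steady_tol, t_max=t_max
    ).state
    for i0 in grid:
        m0 = model.with_inputs(**{input_name: i0})
        starts = []
        for init in (model.initial_state, hi_state):
            res = find_steady_state(m0, init, tol=steady_tol, t_max=t_max)
            if res.converged and not any(
                np.allclose(res.state, s, atol=1e-4) for s in starts
            ):
                starts.append(res.state)
        anchors[i0] = starts

    samples: list[TransitionSample] = []
    rep = report if report is not None else SamplingReport()
    for i0 in grid:
        for i1 in grid:
            if i0 == i1:
                continue
            for start in anchors[i0]:
                for _ in range(n_per_input):
                    rep.n_requested += 1
                    jittered_start = start * np.exp(
                        rng.normal(0.0, state_jitter_sd, size=start.shape)
                    )
                    jittered_input = float(
                        np.clip(rng.normal(i1, input_sd), lo, hi)
                    )
                    m1 = model.with_inputs(**{input_name: jittered_input})
                    res = find_steady_state(
                        m1, jittered_start, tol=steady_tol, t_max=t_max
                    )
                    if not res.converged:
                        rep.dropped.append((i0, i1, "no steady state by t_max"))
                        continue
                    rep.n_converged += 1
                    samples.append(
                        TransitionSample(
                            start_state=jittered_start,
                            end_state=res.state,
                            input_value=jittered_input,
                            nominal_input=i1,
                            start_input=i0,
                            transition_time=max(res.time_to_steady, 1e-12),
                        )
                    )
    return samples


def cluster_states(
    samples: Sequence[TransitionSample],
    k_max: int = 8,
    sd_threshold: float = 0.75,
    seed: int = 0,
) -> list[AbstractState]:
    """Cluster pooled start/end states; pick the smallest adequate k.

    All start and end states are pooled and standardized per species (unit
    pooled SD); k-means runs for k = 1..k_max with seeded k-means++ (10
    restarts).  The selected k is the smallest whose maximum within-cluster
    per-species SD, on the standardized scale, is below *sd_threshold* — the
    operational reading of "smallest within-cluster variance with the fewest
    clusters".  *sd_threshold* sets the abstraction granularity in pooled-SD
    units: the default 0.75 merges input-conditioned variation along a single
    dynamical branch (typically ≲0.6) while separating distinct branches
    (separation ≳1.5).  If no k qualifies, the k_max clustering is returned and the
    caller sees a warning flag via :func:`build_automaton`.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to cluster")
    points = np.vstack(
        [s.start_state for s in samples] + [s.end_state for s in samples]
    )
    scale = points.std(axis=0)
    scale[scale < 1e-12] = 1.0
    z = points / scale

    chosen_labels = None
    chosen_k = None
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(z)
        if len(set(labels)) < k:  # empty cluster: re-seed once, then give up on this k
            km = KMeans(n_clusters=k, n_init=10, random_state=seed + 1)
            labels = km.fit_predict(z)
            if len(set(labels)) < k:
                continue
        max_sd = max(z[labels == c].std(axis=0).max() for c in range(k))
        if max_sd < sd_threshold:
            chosen_labels, chosen_k = labels, k
            break
    if chosen_labels is None:
        km = KMeans(n_clusters=k_max, n_init=10, random_state=seed)
        chosen_labels, chosen_k = km.fit_predict(z), k_max

    states = []
    for c in range(chosen_k):
        members = points[chosen_labels == c]
        states.append(
            AbstractState(
                id=c,
                members=members,
                centroid=members.mean(axis=0),
                per_species_mean=members.mean(axis=0),
                per_species_sd=members.std(axis=0),
            )
        )
    # dense ids ordered by centroid norm for reproducibility across runs
    states.sort(key=lambda s: float(np.linalg.norm(s.centroid / scale)))
    return [
        AbstractState(i, s.members, s.centroid, s.per_species_mean, s.per_species_sd)
        for i, s in enumerate(states)
    ]


def build_automaton(
    samples: Sequence[TransitionSample],
    states: Sequence[AbstractState],
    species: Sequence[str] = (),
    *,
    selection_warning: str | None = None,
) -> TimedAutomaton:
    """Assemble the timed automaton from clustered states and samples.

    Sample endpoints are assigned to the nearest centroid (standardized
    Euclidean metric, ties to the lowest id); samples are grouped by
    (from, to, nominal input) and each group becomes an edge carrying the
    empirical transition-time distribution.  Self-loops (perturbations that
    do not change the abstract state) are retained.
    """
    if not states:
        raise ValueError("states must be nonempty")
    pooled = np.vstack([s.members for s in states])
    scale = pooled.std(axis=0)
    scale[scale < 1e-12] = 1.0
    auto = TimedAutomaton(
        states=list(states),
        inputs=sorted({s.nominal_input for s in samples}),
        edges={},
        species=tuple(species),
        scale=scale,
        warning=selection_warning,
    )
    for s in samples:
        a = auto.state_for(s.start_state)
        b = auto.state_for(s.end_state)
        key = (a, b, s.nominal_input)
        dist = auto.edges.setdefault(key, EdgeDistribution([], []))
        dist.samples.append(s.transition_time)
        dist.input_values.append(s.input_value)
    return auto


def abstract_model(
    model: ReactionModel,
    input_name: str,
    input_grid: Sequence[float],
    n_per_input: int,
    *,
    k_max: int = 8,
    sd_threshold: float = 0.75,
    seed: int = 0,
    **sampling_kwargs,
) -> tuple[TimedAutomaton, SamplingReport]:
    """End-to-end pipeline: sample, cluster, build."""
    report = SamplingReport()
    samples = sample_transitions(
        model, input_name, input_grid, n_per_input, seed=seed,
        report=report, **sampling_kwargs,
    )
    states = cluster_states(samples, k_max=k_max, sd_threshold=sd_threshold, seed=seed)
    automaton = build_automaton(samples, states, model.species)
    return automaton, report


def simulate_automaton(
    automaton: TimedAutomaton,
    start_id: int,
    input_schedule: Sequence[tuple[float, float]],
    seed: int = 0,
    t_end: float | None = None,
    max_events: int = 100_000,
) -> list[tuple[float, int]]:
    """Event-simulate the automaton under a piecewise-constant input schedule.

    At each epoch the current input selects the applicable edge family; an
    outgoing edge is drawn with probability proportional to its support
    count, and a transition time is resampled with replacement from its
    empirical distribution.  A state with no outgoing edge for the current
    input persists (absorbing for that input).
    """
    if not 0 <= start_id < len(automaton.states):
        raise ValueError("invalid start state id")
    times = [t for t, _ in input_schedule]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("schedule times must be increasing")
    rng = np.random.default_rng(seed)
    events: list[tuple[float, int]] = [(times[0] if input_schedule else 0.0, start_id)]
    state = start_id
    for idx, (t_start, value) in enumerate(input_schedule):
        t_stop = input_schedule[idx + 1][0] if idx + 1 < len(input_schedule) else t_end
        t = max(events[-1][0], t_start)
        while len(events) < max_events:
            keys = [
                k for k in automaton.edges_from(state, value) if k[1] != state
            ]
            if not keys:
                break  # absorbing under this input
            weights = np.array(
                [automaton.edges[k].support_count for k in keys], dtype=float
            )
            k = keys[rng.choice(len(keys), p=weights / weights.sum())]
            dist = automaton.edges[k]
            dt = float(rng.choice(dist.samples))
            if t_stop is not None and t + dt > t_stop:
                break  # transition would land beyond this epoch
            t += dt
            state = k[1]
            events.append((t, state))
    return events


def check_hysteresis(
    model: ReactionModel,
    automaton: TimedAutomaton,
    input_name: str,
    input_window: tuple[float, float],
    observable: str | None = None,
    *,
    steady_tol: float = 1e-6,
    t_max: float = 1e4,
) -> dict:
    """Check that hysteresis is preserved by the abstraction.

    True iff (a) the concrete model, equilibrated on the high branch at the
    top of the input range, does not revert to the low abstract state when
    the input is lowered into *input_window*, and (b) the automaton has no
    high-to-low edge supported at inputs inside the window.  "High" is the
    abstract state occupied after equilibrating at the top of the sampled
    input range, "low" the state occupied at the bottom starting from the
    model's initial state; the optional *observable* is reported for
    reference only.
    """
    lo, hi = input_window
    sampled = [v for v in automaton.inputs if lo <= v <= hi]
    grid_min, grid_max = min(automaton.inputs), max(automaton.inputs)
    if not (grid_min <= lo and hi <= grid_max):
        raise ValueError("window outside the sampled input grid")
    if len(automaton.states) < 2:
        return {"preserved": False, "reason": "fewer than 2 abstract states",
                "violating_edges": []}
    high_state = find_steady_state(
        model.with_inputs(**{input_name: grid_max}), tol=steady_tol, t_max=t_max
    ).state
    low_state = find_steady_state(
        model.with_inputs(**{input_name: grid_min}), model.initial_state,
        tol=steady_tol, t_max=t_max,
    ).state
    high_id = automaton.state_for(high_state)
    low_id = automaton.state_for(low_state)
    if high_id == low_id:
        return {"preserved": False, "reason": "high- and low-input attractors "
                "map to the same abstract state", "violating_edges": []}

    # (a) concrete check: high branch persists inside the window
    concrete_ok = True
    for v in sampled or [lo, hi]:
        res = find_steady_state(
            model.with_inputs(**{input_name: float(v)}), high_state,
            tol=steady_tol, t_max=t_max,
        )
        if automaton.state_for(res.state) == low_id:
            concrete_ok = False
    # (b) abstract check: no supported high->low edge inside the window
    violating = [
        k for k, d in automaton.edges.items()
        if k[0] == high_id and k[1] == low_id and lo <= k[2] <= hi
        and d.support_count > 0
    ]
    return {
        "preserved": concrete_ok and not violating,
        "observable": observable,
        "window": (lo, hi),
        "low_state": low_id,
        "high_state": high_id,
        "concrete_high_branch_persists": concrete_ok,
        "violating_edges": violating,
    }


def lift_automaton_events(
    automaton: TimedAutomaton,
    events: Sequence[tuple[float, int]],
    times: np.ndarray,
) -> np.ndarray:
    """Piecewise-constant centroid path of an automaton event list."""
    times = np.asarray(times, dtype=float)
    out = np.empty((times.size, len(automaton.species)))
    ev_times = np.array([t for t, _ in events])
    ev_states = [s for _, s in events]
    idx = np.clip(np.searchsorted(ev_times, times, side="right") - 1, 0, len(events) - 1)
    for i, j in enumerate(idx):
        out[i] = automaton.states[ev_states[j]].centroid
    return out


def trajectory_distance(
    trace_a: Trace,
    trace_b: Trace,
    observables: Sequence[str] | None = None,
    norm: str = "sup",
    n_grid: int = 512,
) -> float:
    """Distance between two trajectories on their common time support.

    Both traces are linearly interpolated onto a common grid over the
    overlap of their time supports; the distance is the chosen norm of the
    pointwise Euclidean difference over the observable species: ``sup`` is
    the maximum over the grid, ``L2`` the root mean square (time-normalized).
    """
    if norm not in ("sup", "L2"):
        raise ValueError("norm must be 'sup' or 'L2'")
    lo = max(trace_a.times[0], trace_b.times[0])
    hi = min(trace_a.times[-1], trace_b.times[-1])
    if hi <= lo:
        raise ValueError("traces have disjoint time supports")
    if observables is None:
        observables = [s for s in trace_a.species if s in trace_b.species]
    grid = np.linspace(lo, hi, n_grid)
    diffs = np.empty((n_grid, len(observables)))
    for j, sp in enumerate(observables):
        ya = np.interp(grid, trace_a.times, trace_a.column(sp))
        yb = np.interp(grid, trace_b.times, trace_b.column(sp))
        diffs[:, j] = ya - yb
    pointwise = np.linalg.norm(diffs, axis=1)
    if norm == "sup":
        return float(pointwise.max())
    return float(np.sqrt(np.mean(pointwise ** 2)))


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def automaton_to_json(automaton: TimedAutomaton, path: str | Path) -> None:
    payload = {
        "species": list(automaton.species),
        "inputs": automaton.inputs,
        "scale": automaton.scale.tolist(),
        "warning": automaton.warning,
        "states": [
            {
                "id": s.id,
                "centroid": s.centroid.tolist(),
                "per_species_mean": s.per_species_mean.tolist(),
                "per_species_sd": s.per_species_sd.tolist(),
                "members": s.members.tolist(),
            }
            for s in automaton.states
        ],
        "edges": [
            {
                "from": k[0], "to": k[1], "input": k[2],
                "samples": d.samples, "input_values": d.input_values,
                "time_mean": d.time_mean, "time_sd": d.time_sd,
                "input_mean": d.input_mean, "input_sd": d.input_sd,
                "support_count": d.support_count,
            }
            for k, d in sorted(automaton.edges.items())
        ],
    }
    Path(path).write_text(json.dumps(payload))


def automaton_from_json(path: str | Path) -> TimedAutomaton:
    data = json.loads(Path(path).read_text())
    states = [
        AbstractState(
            id=s["id"],
            members=np.asarray(s["members"]),
            centroid=np.asarray(s["centroid"]),
            per_species_mean=np.asarray(s["per_species_mean"]),
            per_species_sd=np.asarray(s["per_species_sd"]),
        )
        for s in data["states"]
    ]
    edges = {
        (e["from"], e["to"], e["input"]): EdgeDistribution(
            list(e["samples"]), list(e["input_values"])
        )
        for e in data["edges"]
    }
    return TimedAutomaton(
        states=states,
        inputs=list(data["inputs"]),
        edges=edges,
        species=tuple(data["species"]),
        scale=np.asarray(data["scale"]),
        warning=data.get("warning"),
    )


def automaton_to_dot(automaton: TimedAutomaton, observable: str | None = None) -> str:
    """GraphViz DOT rendering: states labeled by observable mean +/- SD,
    edges by input mean and transition-time mean."""
    species = list(automaton.species)
    obs_i = species.index(observable) if observable else 0
    obs = species[obs_i] if species else "x"
    lines = ["digraph automaton {", "  rankdir=LR;"]
    for s in automaton.states:
        mean = s.per_species_mean[obs_i] if species else 0.0
        sd = s.per_species_sd[obs_i] if species else 0.0
        lines.append(
            f'  s{s.id} [shape=circle, label="S{s.id}\\n{obs}={mean:.2f}±{sd:.2f}"];'
        )
    for (a, b, u), d in sorted(automaton.edges.items()):
        lines.append(
            f'  s{a} -> s{b} [label="u={d.input_mean:.2f}±{d.input_sd:.2f}\\n'
            f't={d.time_mean:.1f}±{d.time_sd:.1f} (n={d.support_count})"];'
        )
    lines.append("}")
    return "\n".join(lines)
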