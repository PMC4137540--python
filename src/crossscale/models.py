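"""Continuous-state reaction models: representation, simulation, steady states.

A :class:`ReactionModel` is a set of species with one rate expression per
species giving d(species)/dt as a function of the state, rate parameters and
time-constant external inputs (e.g. a growth signal).  Simulation uses an
implicit-capable stiff integrator (LSODA); steady-state detection uses a
normalized max-rate criterion over a sliding window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .expressions import ExpressionError, compile_expression, expression_symbols

__all__ = [
    "ReactionModel",
    "Trace",
    "SteadyStateResult",
    "DivergentDynamicsError",
    "simulate",
    "find_steady_state",
    "bifurcation_scan",
]

# Negative-value policy: values in [-NEG_TOL, 0) are clipped to zero; values
# below -NEG_TOL indicate a genuinely broken model and raise.
NEG_TOL = 1e-9

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class DivergentDynamicsError(RuntimeError):
    """Integration produced a non-finite state (rate blow-up)."""


@dataclass(frozen=True)
class Trace:
    """Time-stamped state matrix from a single simulation."""

    times: np.ndarray  # strictly increasing, shape (n_times,)
    states: np.ndarray  # shape (n_times, n_species)
    species: tuple[str, ...]
    inputs_used: dict[str, float] = field(default_factory=dict)
    model_name: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        states = np.asarray(self.states, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "states", states)
        if states.shape[0] != times.shape[0]:
            raise ValueError("states rows must match times length")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")

    def column(self, species: str) -> np.ndarray:
        return self.states[:, self.species.index(species)]

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]


@dataclass(frozen=True)
class SteadyStateResult:
    state: np.ndarray
    converged: bool
    residual: float
    time_to_steady: float | None  # None = not reached by t_max


class ReactionModel:
    """Continuous-state dynamical model defined by per-species rate expressions.

    Parameters
    ----------
    name : model identifier.
    species : ordered species names (unique).
    initial_state : non-negative initial concentration per species.
    parameters : rate constants, name -> positive real.
    inputs : time-constant external signals, name -> real.
    rates : per-species rate expression strings; each may reference any
        declared species, parameter or input plus ``hill(x, K, n)``.
    """

    def __init__(
        self,
        name: str,
        species: Sequence[str],
        initial_state: Sequence[float],
        parameters: Mapping[str, float] | None = None,
        inputs: Mapping[str, float] | None = None,
        rates: Mapping[str, str] | None = None,
        input_ranges: Mapping[str, tuple[float, float]] | None = None,
    ) -> None:
        self.name = name
        self.species = tuple(species)
        if len(set(self.species)) != len(self.species):
            raise ValueError("species names must be unique")
        self.initial_state = np.asarray(initial_state, dtype=float)
        if self.initial_state.shape != (len(self.species),):
            raise ValueError("initial_state length must equal species count")
        if np.any(self.initial_state < 0):
            raise ValueError("initial concentrations must be non-negative")
        self.parameters = dict(parameters or {})
        self.inputs = dict(inputs or {})
        self.input_ranges = dict(input_ranges or {})
        rates = dict(rates or {})
        missing = set(self.species) - set(rates)
        if missing:
            raise ValueError(f"missing rate expression for species {sorted(missing)}")
        allowed = set(self.species) | set(self.parameters) | set(self.inputs)
        self.rates = {sp: rates[sp] for sp in self.species}
        self._compiled = [compile_expression(rates[sp], allowed) for sp in self.species]

    # -- construction helpers -------------------------------------------------

    def with_parameters(self, **overrides: float) -> "ReactionModel":
        unknown = set(overrides) - set(self.parameters)
        if unknown:
            raise KeyError(f"unknown parameter(s) {sorted(unknown)}")
        params = {**self.parameters, **overrides}
        return ReactionModel(
            self.name, self.species, self.initial_state, params, self.inputs,
            self.rates, self.input_ranges,
        )

    def with_inputs(self, **overrides: float) -> "ReactionModel":
        unknown = set(overrides) - set(self.inputs)
        if unknown:
            raise KeyError(f"unknown input(s) {sorted(unknown)}")
        inputs = {**self.inputs, **overrides}
        return ReactionModel(
            self.name, self.species, self.initial_state, self.parameters, inputs,
            self.rates, self.input_ranges,
        )

    def with_initial_state(self, state: Sequence[float]) -> "ReactionModel":
        return ReactionModel(
            self.name, self.species, np.asarray(state, dtype=float),
            self.parameters, self.inputs, self.rates, self.input_ranges,
        )

    # -- evaluation -----------------------------------------------------------

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        ns = dict(zip(self.species, y))
        ns.update(self.parameters)
        ns.update(self.inputs)
        return np.array([f(ns) for f in self._compiled])

    def derivatives(self, state: Sequence[float]) -> np.ndarray:
        """d(state)/dt at a given state (time-autonomous)."""
        return self.rhs(0.0, np.asarray(state, dtype=float))

    def index(self, species: str) -> int:
        return self.species.index(species)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"ReactionModel({self.name!r}, {len(self.species)} species)"


def _clip_nonneg(states: np.ndarray, species: Sequence[str]) -> np.ndarray:
    worst = states.min(initial=0.0)
    if worst < -NEG_TOL:
        i = int(np.unravel_index(np.argmin(states), states.shape)[-1])
        raise DivergentDynamicsError(
            f"species {species[i]!r} went negative beyond tolerance ({worst:.3g})"
        )
    return np.clip(states, 0.0, None)


def simulate(
    model: ReactionModel,
    t_end: float,
    *,
    from_state: Sequence[float] | None = None,
    n_points: int = 200,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    t_eval: Sequence[float] | None = None,
    method: str = "LSODA",
) -> Trace:
    """Integrate the model over [0, t_end] and return a :class:`Trace`.

    States are clipped to zero within the negative-value tolerance; a state
    below ``-NEG_TOL`` or any non-finite value raises
    :class:`DivergentDynamicsError` naming the offending species.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    y0 = np.asarray(from_state if from_state is not None else model.initial_state, dtype=float)
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(
        model.rhs, (0.0, float(t_end)), y0, method=method,
        t_eval=np.asarray(t_eval, dtype=float), rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise DivergentDynamicsError(f"integration of {model.name!r} failed: {sol.message}")
    states = sol.y.T
    if not np.all(np.isfinite(states)):
        bad = int(np.argwhere(~np.isfinite(states))[0][1])
        raise DivergentDynamicsError(
            f"divergent dynamics: species {model.species[bad]!r} became non-finite"
        )
    states = _clip_nonneg(states, model.species)
    return Trace(
        times=sol.t,
        states=states,
        species=model.species,
        inputs_used=dict(model.inputs),
        model_name=model.name,
        metadata={"rtol": rtol, "atol": atol, "method": method},
    )


# Sliding window width for the steady-state criterion, as a fraction of the
# elapsed time: the normalized max rate must stay below tol across the window.
STEADY_WINDOW_FRACTION = 0.05
STEADY_FLOOR = 1e-6


def _normalized_residual(model: ReactionModel, state: np.ndarray) -> float:
    dx = model.derivatives(state)
    scale = max(float(np.max(np.abs(state))), STEADY_FLOOR)
    return float(np.max(np.abs(dx))) / scale


def find_steady_state(
    model: ReactionModel,
    from_state: Sequence[float] | None = None,
    *,
    tol: float = 1e-6,
    t_max: float = 1e5,
    chunk: float = 10.0,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> SteadyStateResult:
    """Integrate until the normalized max rate stays below *tol*.

    The criterion is ``max_i |dx_i/dt| / max(max_i |x_i|, floor) <= tol`` held
    over a trailing window of 5% of elapsed time.  A model that has not
    converged by *t_max* (e.g. a sustained oscillation) returns
    ``converged=False`` with the final residual, not an exception.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    y = np.asarray(from_state if from_state is not None else model.initial_state, dtype=float)
    t = 0.0
    window: list[tuple[float, float, np.ndarray]] = []  # (time, residual, state)
    history: list[tuple[float, float]] = []  # (time, residual), for refinement
    residual = _normalized_residual(model, y)
    if residual <= tol:
        return SteadyStateResult(y, True, residual, 0.0)
    while t < t_max:
        step = min(chunk, t_max - t)
        sol = solve_ivp(
            model.rhs, (t, t + step), y, method="LSODA", rtol=rtol, atol=atol,
            t_eval=np.linspace(t, t + step, 25)[1:],
        )
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise DivergentDynamicsError(
                f"steady-state search diverged for {model.name!r}"
            )
        for ti, yi in zip(sol.t, sol.y.T):
            yi = _clip_nonneg(yi[None, :], model.species)[0]
            ri = _normalized_residual(model, yi)
            history.append((ti, ri))
            window.append((ti, ri, yi))
            horizon = ti * (1.0 - STEADY_WINDOW_FRACTION)
            window = [w for w in window if w[0] >= horizon]
            if window and all(w[1] <= tol for w in window):
                t_first, r_first, y_first = window[0]
                # refine the crossing time by log-linear interpolation of the
                # residual between the last sample above tol and the first
                # qualifying one, so transition times are not quantized at
                # the integrator sampling resolution
                before = [h for h in history if h[0] < t_first and h[1] > tol]
                if before and r_first > 0:
                    t_prev, r_prev = before[-1]
                    frac = (np.log(r_prev) - np.log(tol)) / (
                        np.log(r_prev) - np.log(r_first)
                    )
                    frac = min(max(frac, 0.0), 1.0)
                    t_first = t_prev + frac * (t_first - t_prev)
                return SteadyStateResult(y_first, True, r_first, float(t_first))
        t += step
        y = _clip_nonneg(sol.y[:, -1][None, :], model.species)[0]
        chunk = min(chunk * 1.6, t_max)  # geometric growth for slow relaxations
    return SteadyStateResult(y, False, _normalized_residual(model, y), None)


def bifurcation_scan(
    model: ReactionModel,
    input_name: str,
    grid: Sequence[float],
    direction: str = "up",
    *,
    tol: float = 1e-6,
    t_max: float = 1e5,
) -> list[tuple[float, np.ndarray]]:
    """Quasi-static continuation: sweep *input_name* along *grid*.

    At each grid point the model is re-equilibrated from the previous steady
    state, so the branch followed depends on sweep ``direction`` ("up" or
    "down") — this is how hysteresis is detected.
    """
    if input_name not in model.inputs:
        raise KeyError(f"unknown input {input_name!r}")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    grid = list(grid)
    if direction == "down":
        grid = grid[::-1]
    lo, hi = model.input_ranges.get(input_name, (-math.inf, math.inf))
    branch: list[tuple[float, np.ndarray]] = []
    state = model.initial_state
    for value in grid:
        if not (lo <= value <= hi):
            raise ValueError(f"input value {value} outside declared range [{lo}, {hi}]")
        m = model.with_inputs(**{input_name: float(value)})
        res = find_steady_state(m, state, tol=tol, t_max=t_max)
        if not res.converged:
            raise RuntimeError(
                f"bifurcation_scan: no steady state at {input_name}={value}"
            )
        state = res.state
        branch.append((float(value), state))
    if direction == "down":
        branch = branch[::-1]
    return branch
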