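"""Fixture models: bistable G1/S switch, mini extrinsic-apoptosis cascade,
toy hepatic Taxol pharmacokinetics, and random enzymatic cascades with a
planted rate-limiting step.

Each constructor returns an ordinary :class:`~crossscale.models.ReactionModel`
whose default parameters are pinned to satisfy documented behavioral
contracts (bistability window and hysteresis for the switch; delay-then-snap
PARP cleavage for the cascade; transient lactate accumulation for the liver
model).  Overrides are accepted freely; ``validate_*`` helpers re-check the
contracts after overriding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import ReactionModel, bifurcation_scan, find_steady_state, simulate

__all__ = [
    "make_bistable_switch",
    "make_apoptosis_cascade",
    "make_liver_model",
    "sample_random_cascade",
    "validate_bistable_switch",
    "RandomCascade",
]


# ---------------------------------------------------------------------------
# Bistable G1/S switch
# ---------------------------------------------------------------------------

#: Pinned defaults for the three-species G1/S switch: C is a cyclin-D-like
#: species driven linearly by the growth signal S (graded, no feedback); E is
#: an E2F-like species with Hill self-activation and repression by R; R is an
#: Rb-like repressor inhibited by E (mutual antagonism E -| R -| E).
BISTABLE_DEFAULTS = {
    "aC": 1.0,   # C synthesis per unit growth signal (conc/min)
    "dC": 1.0,   # C decay (1/min)
    "bE": 1.0,   # E drive per unit C (1/min)
    "aE": 1.2,   # E self-activation gain (conc/min) -- feedback loop 1
    "KE": 1.0, "nE": 4.0,
    "aR": 1.5,   # R synthesis gain (conc/min) -- feedback loop 2
    "KR": 1.0, "nR": 4.0,   # repression of E by R
    "KI": 0.4, "nI": 4.0,   # inhibition of R by E
    "dE": 1.0, "dR": 1.0,
}


def make_bistable_switch(**overrides: float) -> ReactionModel:
    """Three-species bistable switch controlling the G1/S transition.

    The growth-signal input ``S`` ranges from 0 (no growth signal) to 2 (full
    saturation).  Two positive feedback loops (E self-activation; double
    inhibition E -| R -| E) produce two stable E branches over an intermediate
    window of S, with hysteresis in E but not in the graded species C.
    Setting both feedback gains ``aE`` and ``aR`` to 0 leaves a linear,
    monostable system.
    """
    params = {**BISTABLE_DEFAULTS, **overrides}
    unknown = set(overrides) - set(BISTABLE_DEFAULTS)
    if unknown:
        raise KeyError(f"unknown parameter(s) {sorted(unknown)}")
    return ReactionModel(
        name="bistable_switch",
        species=["C", "E", "R"],
        initial_state=[0.0, 0.0, params["aR"] / params["dR"]],
        parameters=params,
        inputs={"S": 0.0},
        input_ranges={"S": (0.0, 2.0)},
        rates={
            "C": "aC * S - dC * C",
            "E": "(bE * C + aE * hill(E, KE, nE)) * (1 - hill(R, KR, nR)) - dE * E",
            "R": "aR * (1 - hill(E, KI, nI)) - dR * R",
        },
    )


def validate_bistable_switch(
    model: ReactionModel,
    *,
    grid: np.ndarray | None = None,
    branch_tol: float = 0.05,
) -> dict:
    """Re-check the switch's behavioral contracts; returns a report dict.

    Contracts: unique low-E state at S=0, unique high-E state at S=2, a
    non-empty bistable sub-interval of (0, 2), hysteresis in E and none in C.
    """
    if grid is None:
        grid = np.linspace(0.0, 2.0, 21)
    iE, iC = model.index("E"), model.index("C")
    up = bifurcation_scan(model, "S", grid, "up")
    down = bifurcation_scan(model, "S", grid, "down")
    e_up = np.array([s[iE] for _, s in up])
    e_down = np.array([s[iE] for _, s in down])
    c_up = np.array([s[iC] for _, s in up])
    c_down = np.array([s[iC] for _, s in down])
    scale = max(e_up.max(), e_down.max(), 1e-9)
    bistable = np.abs(e_up - e_down) / scale > branch_tol
    hysteresis_width = float(np.sum(bistable) * (grid[1] - grid[0])) if bistable.any() else 0.0
    c_scale = max(c_up.max(), 1e-9)
    report = {
        "low_at_zero": bool(e_up[0] / scale < 0.1),
        "high_at_full": bool(abs(e_up[-1] - e_down[-1]) / scale < branch_tol
                             and e_up[-1] / scale > 0.5),
        "bistable_window": (float(grid[bistable][0]), float(grid[bistable][-1]))
        if bistable.any() else None,
        "hysteresis_width_E": hysteresis_width,
        "hysteresis_width_C": float(np.max(np.abs(c_up - c_down)) / c_scale),
        "grid": grid,
        "e_up": e_up, "e_down": e_down,
    }
    report["ok"] = bool(
        report["low_at_zero"] and report["high_at_full"]
        and report["bistable_window"] is not None
        and report["hysteresis_width_C"] < branch_tol
    )
    return report


# ---------------------------------------------------------------------------
# Mini extrinsic-apoptosis cascade
# ---------------------------------------------------------------------------

#: Rate constants for the mini cascade (per minute; bimolecular per
#: concentration per minute).  Names k1, k_1, kappa1, k3, k4, k10, k11, k_11,
#: k12 follow the conventional labels of the extrinsic-apoptosis steps they
#: implement (ligand-receptor binding/unbinding, receptor activation,
#: caspase-8 recruitment, Bar sequestration, Bid cleavage, Bcl2 buffering,
#: Bax activation); k13..k15 are the post-permeabilization steps.
APOPTOSIS_DEFAULTS = {
    "k1": 4e-3,     # L + R -> L:R
    "k_1": 1e-2,    # L:R -> L + R
    "kappa1": 1e-2, # L:R -> R*
    "k3": 1e-3,     # R* + C8 -> R* + C8*   (receptor-catalyzed activation)
    "k4": 1e-2,     # C8* + Bar -> inert complex
    "k10": 1e-4,    # C8* + Bid -> C8* + tBid
    "k11": 1e-2,    # tBid + Bcl2 -> tBid:Bcl2
    "k_11": 1e-3,   # tBid:Bcl2 -> tBid + Bcl2
    "k12": 1e-3,    # tBid + Bax -> tBid + Bax*  (permeabilization trigger)
    "k13": 1.0,     # Bax*-gated C3 activation (gated by hill(Bax*, K_pore, 4))
    "K_pore": 50.0,
    "k14": 1e-2,    # C3* + PARP -> C3* + cPARP
    "k15": 1e-3,    # C3* + C8 -> C3* + C8*   (feedback amplification)
}

#: Initial pools (arbitrary concentration units); one well-mixed volume.
APOPTOSIS_POOLS = {
    "L": 10.0, "R": 100.0, "C8": 100.0, "Bar": 30.0,
    "Bid": 100.0, "Bcl2": 30.0, "Bax": 100.0, "C3": 100.0, "PARP": 100.0,
}


def make_apoptosis_cascade(ligand: float | None = None, **overrides: float) -> ReactionModel:
    """Mini extrinsic-apoptosis cascade (~10 reactions, one compartment).

    Ligand binds receptor reversibly (k1/k_1); the complex activates the
    receptor (kappa1); active receptor activates caspase-8 (k3); C8* is
    sequestered by Bar (k4) and cleaves Bid to tBid (k10); Bcl2 buffers tBid
    reversibly (k11/k_11); free tBid activates Bax (k12).  Active Bax is the
    irreversible permeabilization species: it gates effector-caspase
    activation through a steep Hill term (k13, K_pore), after which C3*
    cleaves PARP (k14) and feeds back on caspase-8 (k15), producing the
    characteristic long-delay, sharp-snap cPARP time course.
    """
    params = {**APOPTOSIS_DEFAULTS, **overrides}
    unknown = set(overrides) - set(APOPTOSIS_DEFAULTS)
    if unknown:
        raise KeyError(f"unknown parameter(s) {sorted(unknown)}")
    pools = dict(APOPTOSIS_POOLS)
    if ligand is not None:
        pools["L"] = float(ligand)
    species = [
        "L", "R", "LR", "Ra", "C8", "C8a", "Bar", "C8aBar",
        "Bid", "tBid", "Bcl2", "tBidBcl2", "Bax", "aBax",
        "C3", "C3a", "PARP", "cPARP",
    ]
    init = [pools.get(sp, 0.0) for sp in species]
    rates = {
        "L": "-k1*L*R + k_1*LR",
        "R": "-k1*L*R + k_1*LR",
        "LR": "k1*L*R - k_1*LR - kappa1*LR",
        "Ra": "kappa1*LR",
        "C8": "-k3*Ra*C8 - k15*C3a*C8",
        "C8a": "k3*Ra*C8 + k15*C3a*C8 - k4*C8a*Bar",
        "Bar": "-k4*C8a*Bar",
        "C8aBar": "k4*C8a*Bar",
        "Bid": "-k10*C8a*Bid",
        "tBid": "k10*C8a*Bid - k11*tBid*Bcl2 + k_11*tBidBcl2",
        "Bcl2": "-k11*tBid*Bcl2 + k_11*tBidBcl2",
        "tBidBcl2": "k11*tBid*Bcl2 - k_11*tBidBcl2",
        "Bax": "-k12*tBid*Bax",
        "aBax": "k12*tBid*Bax",
        "C3": "-k13*hill(aBax, K_pore, 4)*C3",
        "C3a": "k13*hill(aBax, K_pore, 4)*C3",
        "PARP": "-k14*C3a*PARP",
        "cPARP": "k14*C3a*PARP",
    }
    return ReactionModel(
        name="apoptosis_cascade",
        species=species,
        initial_state=init,
        parameters=params,
        inputs={},
        rates=rates,
    )


#: Parameters upstream of the permeabilization step (tBid-activated Bax),
#: used by structural checks on sensitivity rankings.
APOPTOSIS_UPSTREAM = ("k1", "k_1", "kappa1", "k3", "k4", "k10", "k11", "k_11", "k12")


# ---------------------------------------------------------------------------
# Toy hepatic pharmacokinetic model
# ---------------------------------------------------------------------------

LIVER_DEFAULTS = {
    "Vmax": 0.2,     # max metabolic rate (conc/min); saturable clearance
    "Km": 0.5,       # Michaelis constant (conc); small, so therapeutic doses saturate
    "alpha": 4.0,    # lactate produced per unit Taxol metabolized
    "kclear": 0.1,   # lactate clearance (1/min)
    "p0": 0.1,       # basal lactate production (conc/min); baseline p0/kclear
    "lactate_toxic": 8.0,  # declared toxicity threshold on lactate (conc)
}


def make_liver_model(**overrides: float) -> ReactionModel:
    """Toy hepatic model: saturable Taxol metabolism drives lactate build-up.

    Taxol (``Tx``) is taken up from a plasma pool and metabolized with
    Michaelis-Menten kinetics; lactate is produced in proportion to the
    metabolic flux and cleared first order.  ``Mcum`` accumulates total
    metabolized Taxol so co-simulation can balance a conservation ledger.
    The toxicity threshold ``lactate_toxic`` is a declared parameter, not a
    dynamical quantity.
    """
    params = {**LIVER_DEFAULTS, **overrides}
    unknown = set(overrides) - set(LIVER_DEFAULTS)
    if unknown:
        raise KeyError(f"unknown parameter(s) {sorted(unknown)}")
    baseline = params["p0"] / params["kclear"]
    return ReactionModel(
        name="liver_pk",
        species=["Tx", "Lac", "Mcum"],
        initial_state=[0.0, baseline, 0.0],
        parameters=params,
        inputs={},
        rates={
            "Tx": "-Vmax * Tx / (Km + Tx)",
            "Lac": "p0 + alpha * Vmax * Tx / (Km + Tx) - kclear * Lac",
            "Mcum": "Vmax * Tx / (Km + Tx)",
        },
    )


# ---------------------------------------------------------------------------
# Random enzymatic cascades with a planted rate-limiting step
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RandomCascade:
    """A sampled linear cascade plus its planted ground truth."""

    model: ReactionModel
    limiting_parameter: str
    limiting_index: int
    fold: float
    seed: int


def sample_random_cascade(
    n_steps: int = 5,
    limiting_index: int = 3,
    fold: float = 100.0,
    seed: int = 0,
) -> RandomCascade:
    """Linear irreversible chain X0 -> X1 -> ... -> X_{n_steps}.

    Rate constants are log-uniform on [0.1, 1.0] per minute, except
    ``k{limiting_index}`` which is divided by *fold* — the planted
    rate-limiting step.  The half-saturation time of the terminal species is
    then dominated by the planted constant.
    """
    if n_steps < 3:
        raise ValueError("n_steps must be >= 3")
    if not 1 <= limiting_index <= n_steps:
        raise ValueError("limiting_index must lie in [1, n_steps]")
    if fold < 1:
        raise ValueError("fold must be >= 1")
    rng = np.random.default_rng(seed)
    ks = 10.0 ** rng.uniform(-1.0, 0.0, size=n_steps)
    ks[limiting_index - 1] /= fold
    species = [f"X{i}" for i in range(n_steps + 1)]
    params = {f"k{i + 1}": float(ks[i]) for i in range(n_steps)}
    rates = {}
    for i, sp in enumerate(species):
        terms = []
        if i > 0:
            terms.append(f"k{i} * X{i - 1}")
        if i < n_steps:
            terms.append(f"- k{i + 1} * X{i}")
        rates[sp] = " ".join(terms) if terms else "0"
    model = ReactionModel(
        name=f"random_cascade_seed{seed}",
        species=species,
        initial_state=[100.0] + [0.0] * n_steps,
        parameters=params,
        inputs={},
        rates=rates,
    )
    return RandomCascade(model, f"k{limiting_index}", limiting_index, float(fold), int(seed))
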