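"""Global sensitivity of apoptosis-commitment time to kinetic rate constants.

The readout T_d is the time from ligand-receptor binding until half of the
total PARP pool is cleaved.  Rate constants are perturbed multiplicatively
(log-uniform factors), the model is re-simulated per sample, and a partial
least squares regression of T_d on the log2 fold factors yields per-parameter
VIP importance scores and signed standardized coefficients.  VIP (Variable
Importance in Projection) satisfies mean(VIP^2) = 1; the conventional
"substantial influence" line is VIP > 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from .models import ReactionModel, Trace, simulate

__all__ = [
    "CENSORED",
    "TdReadout",
    "PerturbationDesign",
    "SensitivityResult",
    "compute_td",
    "run_design",
    "fit_plsr",
    "rank_parameters",
    "sensitivity_analysis",
]

CENSORED = "censored"


@dataclass(frozen=True)
class TdReadout:
    """Defines the commitment-time readout on a cleavage pair.

    threshold_basis selects whether the half-way point is taken on the
    initial substrate pool ("initial", the default reading of "half of all
    PARP is cleaved") or on the final cleaved amount ("final").
    """

    substrate: str = "PARP"
    product: str = "cPARP"
    total: float | None = None  # default: initial substrate pool of the trace
    threshold_fraction: float = 0.5
    threshold_basis: str = "initial"  # or "final"

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold_fraction < 1.0:
            raise ValueError("threshold_fraction must lie in (0, 1)")
        if self.threshold_basis not in ("initial", "final"):
            raise ValueError("threshold_basis must be 'initial' or 'final'")


@dataclass(frozen=True)
class PerturbationDesign:
    """Multiplicative log-uniform perturbation design over rate constants."""

    fold_range: float = 4.0   # factors log-uniform on [1/f, f]
    n_samples: int = 500
    seed: int = 0
    perturbed_set: tuple[str, ...] | None = None  # default: all rate constants

    def __post_init__(self) -> None:
        if self.fold_range < 1.0:
            raise ValueError("fold_range must be >= 1")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")

    def factors(self, parameter_names: list[str]) -> np.ndarray:
        """(n_samples, n_params) matrix of multiplicative factors."""
        rng = np.random.default_rng(self.seed)
        logf = np.log2(self.fold_range)
        return 2.0 ** rng.uniform(-logf, logf, size=(self.n_samples, len(parameter_names)))


@dataclass
class SensitivityResult:
    parameter_names: list[str]
    scores: np.ndarray          # VIP per parameter
    coefficients: np.ndarray    # standardized regression weights, signed
    r_squared: float            # cross-validated predictive R^2
    n_components: int
    predictions: np.ndarray     # (n_kept, 2): true T_d, cross-validated prediction
    censored_count: int = 0
    flags: list[str] = field(default_factory=list)


def compute_td(trace: Trace, readout: TdReadout) -> float | str:
    """First time the product crosses the threshold, by linear interpolation.

    Returns :data:`CENSORED` if the threshold is never reached by the end of
    the trace.  A non-monotone product is handled by taking the first upward
    crossing.
    """
    if readout.product not in trace.species:
        raise KeyError(f"product species {readout.product!r} not in trace")
    product = trace.column(readout.product)
    if readout.total is not None:
        total = readout.total
    elif readout.threshold_basis == "final":
        total = float(product[-1])
    elif readout.substrate in trace.species:
        total = float(trace.column(readout.substrate)[0]) + float(product[0])
    else:
        raise KeyError(
            f"substrate species {readout.substrate!r} not in trace and no total given"
        )
    threshold = readout.threshold_fraction * total
    if threshold <= 0:
        return CENSORED
    above = product >= threshold
    if not above.any():
        return CENSORED
    i = int(np.argmax(above))  # first index at/above threshold
    if i == 0:
        return float(trace.times[0])
    t0, t1 = trace.times[i - 1], trace.times[i]
    p0, p1 = product[i - 1], product[i]
    if p1 == p0:
        return float(t1)
    return float(t0 + (threshold - p0) / (p1 - p0) * (t1 - t0))


def run_design(
    model: ReactionModel,
    design: PerturbationDesign,
    readout: TdReadout,
    *,
    t_end: float = 2000.0,
    n_points: int = 400,
    max_censored_fraction: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Simulate the perturbation design; returns (X, y, censored_count).

    Row i of X holds log2 fold factors per perturbed parameter; y_i is the
    corresponding T_d.  Censored samples (threshold never reached by t_end)
    are excluded from X and y and counted.
    """
    names = list(design.perturbed_set or model.parameters)
    missing = set(names) - set(model.parameters)
    if missing:
        raise KeyError(f"perturbed parameters not in model: {sorted(missing)}")
    factors = design.factors(names)
    X_rows, y_rows = [], []
    censored = 0
    for row in factors:
        perturbed = {nm: model.parameters[nm] * f for nm, f in zip(names, row)}
        trace = simulate(model.with_parameters(**perturbed), t_end, n_points=n_points)
        td = compute_td(trace, readout)
        if td == CENSORED:
            censored += 1
            continue
        X_rows.append(np.log2(row))
        y_rows.append(td)
    if censored > max_censored_fraction * design.n_samples:
        raise RuntimeError(
            f"{censored}/{design.n_samples} samples censored; reduce fold_range "
            "or extend t_end"
        )
    return np.array(X_rows), np.array(y_rows), censored


def _vip(pls: PLSRegression) -> np.ndarray:
    """Variable Importance in Projection from a fitted PLS model.

    VIP_j = sqrt( p * sum_a (SS_a * (w_ja / ||w_a||)^2) / sum_a SS_a ) where
    SS_a is the y-variance explained by component a; mean(VIP^2) = 1.
    """
    T = pls.x_scores_          # (n, a)
    W = pls.x_weights_         # (p, a)
    Q = pls.y_loadings_        # (1, a)
    p = W.shape[0]
    ss = (T ** 2).sum(axis=0) * (Q[0] ** 2)  # explained y-SS per component
    w_norm = W / np.linalg.norm(W, axis=0, keepdims=True)
    return np.sqrt(p * (w_norm ** 2 @ ss) / ss.sum())


def fit_plsr(
    X: np.ndarray,
    y: np.ndarray,
    parameter_names: list[str] | None = None,
    *,
    max_components: int = 5,
    cv_folds: int = 5,
    censored_count: int = 0,
) -> SensitivityResult:
    """PLSR of the (standardized) response on standardized predictors.

    The number of latent components is the first local maximum of the
    cross-validated predictive R^2 over 1..max_components; VIP scores come
    from the refit on all data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if parameter_names is None:
        parameter_names = [f"p{j}" for j in range(p)]
    if n < 2 * max_components:
        max_components = max(1, n // 2)
    flags: list[str] = []
    if float(np.std(y)) < 1e-12:
        flags.append("zero-variance response")
        return SensitivityResult(
            parameter_names, np.zeros(p), np.zeros(p), 0.0, 0,
            np.column_stack([y, y]), censored_count, flags,
        )

    # cross-validated predictive R^2 per component count
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2cv = []
    max_components = min(max_components, p, n - 1)
    for a in range(1, max_components + 1):
        press = 0.0
        preds = np.empty_like(y)
        for train, test in KFold(cv_folds, shuffle=True, random_state=0).split(X):
            pls = PLSRegression(n_components=a, scale=True).fit(X[train], y[train])
            preds[test] = pls.predict(X[test]).ravel()
        press = float(((y - preds) ** 2).sum())
        r2cv.append((1.0 - press / ss_tot, preds))
    best = 0
    for a in range(1, len(r2cv)):
        if r2cv[a][0] > r2cv[best][0]:
            best = a
        else:
            break  # first local maximum
    n_components = best + 1
    r_squared, cv_predictions = r2cv[best]

    pls = PLSRegression(n_components=n_components, scale=True).fit(X, y)
    vip = _vip(pls)
    # standardized coefficients: effect of one SD of X_j on y in SD units
    x_sd = X.std(axis=0, ddof=1)
    x_sd[x_sd < 1e-12] = 1.0
    coef = pls.coef_.ravel() * x_sd / y.std(ddof=1)
    return SensitivityResult(
        list(parameter_names), vip, coef, float(r_squared), n_components,
        np.column_stack([y, cv_predictions]), censored_count, flags,
    )


def rank_parameters(
    result: SensitivityResult,
    rule: str = "elbow",
    top_k: int | None = None,
) -> list[tuple[str, float, int]]:
    """Rank parameters by VIP, descending; returns (name, VIP, sign) tuples.

    ``rule="top_k"`` returns the first *top_k* entries; ``rule="elbow"``
    returns the prefix before the largest consecutive gap in the sorted
    scores.  The sign comes from the standardized coefficient (+1 means the
    parameter increases T_d).  Ties in VIP are broken by parameter name.
    """
    if rule not in ("top_k", "elbow"):
        raise ValueError("rule must be 'top_k' or 'elbow'")
    order = sorted(
        range(len(result.parameter_names)),
        key=lambda j: (-result.scores[j], result.parameter_names[j]),
    )
    ranked = [
        (
            result.parameter_names[j],
            float(result.scores[j]),
            int(np.sign(result.coefficients[j])) or 1,
        )
        for j in order
    ]
    if rule == "top_k":
        return ranked[: top_k or len(ranked)]
    scores = [r[1] for r in ranked]
    if len(scores) < 2:
        return ranked
    gaps = [scores[i] - scores[i + 1] for i in range(len(scores) - 1)]
    cut = int(np.argmax(gaps)) + 1
    return ranked[:cut]


def sensitivity_analysis(
    model: ReactionModel,
    design: PerturbationDesign | None = None,
    readout: TdReadout | None = None,
    *,
    t_end: float = 2000.0,
    max_components: int = 5,
    cv_folds: int = 5,
) -> SensitivityResult:
    """Convenience pipeline: run the design, fit PLSR, return the result."""
    design = design or PerturbationDesign()
    readout = readout or TdReadout()
    names = list(design.perturbed_set or model.parameters)
    X, y, censored = run_design(model, design, readout, t_end=t_end)
    return fit_plsr(
        X, y, names, max_components=max_components, cv_folds=cv_folds,
        censored_count=censored,
    )
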