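"""One-way (tornado) and probabilistic sensitivity analysis for the decision tree.

The tornado analysis re-evaluates the ICER with each model parameter moved
+/- a fixed fraction (default 20%) around its base value, all else held at
base; probabilities are clipped to [0, 1] with a flag.  The probabilistic
sensitivity analysis draws every uncertain parameter independently — gamma
distributions (method of moments) for costs, beta for utilities and
probabilities — evaluates the tree per iteration, and summarizes the draws as
a cost-effectiveness plane and a cost-effectiveness acceptability curve
(CEAC): the probability, as a function of willingness to pay, that each
strategy has the highest net monetary benefit.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cea_tree import (
    DecisionTreeModel,
    ExpectedOutcome,
    StrategyBranches,
    default_model,
    evaluate_tree,
    incremental_analysis,
)
from .trial_data import TRIAL_SUMMARY

__all__ = [
    "TornadoEntry",
    "one_way_sensitivity",
    "tornado_analysis",
    "fit_gamma_moments",
    "fit_beta_moments",
    "PSAConfig",
    "default_psa_config",
    "PSADraws",
    "run_psa",
    "ceac",
    "ce_plane_export",
    "default_wtp_grid",
    "model_parameters",
]

#: tornado-variable fields per strategy; ``p_improve`` varies the improvement
#: probability (p_cure = 1 - p_improve), matching how the ranges are reported
_TORNADO_FIELDS = ("cost_cure", "cost_improve", "eff_cure", "eff_improve", "p_improve")


def model_parameters(model: DecisionTreeModel) -> list[str]:
    """All one-way-variable parameter names, as ``"<strategy>.<field>"``."""
    return [f"{s}.{f}" for s in model.strategies for f in _TORNADO_FIELDS]


def _get_param(model: DecisionTreeModel, parameter: str) -> float:
    try:
        strategy, fld = parameter.split(".", 1)
        s = model.strategies[strategy]
    except (ValueError, KeyError):
        raise KeyError(f"unknown parameter {parameter!r}") from None
    if fld == "p_improve":
        return 1.0 - s.p_cure
    if fld not in _TORNADO_FIELDS:
        raise KeyError(f"unknown parameter {parameter!r}")
    return getattr(s, fld)


def _with_param(
    model: DecisionTreeModel, parameter: str, value: float
) -> DecisionTreeModel:
    strategy, fld = parameter.split(".", 1)
    s = model.strategies[strategy]
    if fld == "p_improve":
        s2 = replace(s, p_cure=1.0 - value)
    else:
        s2 = replace(s, **{fld: value})
    strategies = dict(model.strategies)
    strategies[strategy] = s2
    return replace(model, strategies=strategies)


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low: float
    high: float
    icer_low: float
    icer_high: float
    width: float
    clipped: bool = False


def _icer(model: DecisionTreeModel) -> float:
    out = evaluate_tree(model)
    inc = incremental_analysis(out[model.reference], out[model.comparator])
    return math.nan if inc.icer is None else inc.icer


def one_way_sensitivity(
    model: DecisionTreeModel, parameter: str, fraction: float = 0.20
) -> TornadoEntry:
    """ICER at ``parameter * (1 -/+ fraction)``, everything else at base.

    Probabilities are clipped to [0, 1] (flagged).  ``icer_low``/``icer_high``
    are the ICERs at the low/high *parameter* values; the bar width is the
    absolute difference of the two ICERs.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    base = _get_param(model, parameter)
    low, high = base * (1.0 - fraction), base * (1.0 + fraction)
    clipped = False
    if parameter.endswith(".p_improve"):
        lo2, hi2 = max(low, 0.0), min(high, 1.0)
        clipped = (lo2, hi2) != (low, high)
        low, high = lo2, hi2
    icer_low = _icer(_with_param(model, parameter, low))
    icer_high = _icer(_with_param(model, parameter, high))
    return TornadoEntry(
        parameter=parameter,
        low=float(low),
        high=float(high),
        icer_low=float(icer_low),
        icer_high=float(icer_high),
        width=float(abs(icer_high - icer_low)),
        clipped=clipped,
    )


def tornado_analysis(
    model: DecisionTreeModel,
    fraction: float = 0.20,
    parameters: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """One-way sensitivity over all (or selected) parameters, ranked by bar width."""
    params = list(parameters) if parameters is not None else model_parameters(model)
    entries = [one_way_sensitivity(model, p, fraction) for p in params]
    df = pd.DataFrame([e.__dict__ for e in entries])
    df = df.sort_values("width", ascending=False, kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


# ---------------------------------------------------------------------------
# Distribution fitting (method of moments)


def fit_gamma_moments(mean: float, sd: float) -> tuple[float, float]:
    """Gamma (shape, scale) with the given mean and sd: shape=(mean/sd)^2, scale=sd^2/mean."""
    if mean <= 0 or sd <= 0:
        raise ValueError("gamma moments require mean > 0 and sd > 0")
    return (mean / sd) ** 2, sd**2 / mean


def fit_beta_moments(mean: float, sd: float) -> tuple[float, float]:
    """Beta (alpha, beta) with the given mean and sd.

    Feasibility requires ``sd^2 < mean (1 - mean)``.
    """
    if not 0 < mean < 1:
        raise ValueError("beta mean must lie in (0, 1)")
    if sd <= 0:
        raise ValueError("beta sd must be > 0")
    bound = mean * (1 - mean)
    if sd**2 >= bound:
        raise ValueError(
            f"infeasible beta variance: sd^2 = {sd**2:.6g} must be < mean(1-mean) = {bound:.6g}"
        )
    nu = bound / sd**2 - 1.0
    return mean * nu, (1 - mean) * nu


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis


@dataclass
class PSAConfig:
    """Distributional assumptions for the PSA.

    Parameter names follow the ``"<strategy>.<field>"`` convention of the
    tornado analysis (probabilities are specified on ``p_cure``).  Each entry
    is a (mean, sd) pair; ``sd = 0`` denotes a degenerate (point-mass)
    parameter.
    """

    cost_params: Mapping[str, tuple[float, float]]
    utility_params: Mapping[str, tuple[float, float]]
    prob_params: Mapping[str, tuple[float, float]]
    n_iterations: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        for name, (m, sd) in self.cost_params.items():
            if sd > 0:
                fit_gamma_moments(m, sd)
            elif m <= 0:
                raise ValueError(f"{name}: cost mean must be > 0")
        for group in (self.utility_params, self.prob_params):
            for name, (m, sd) in group.items():
                if sd > 0:
                    fit_beta_moments(m, sd)
                elif not 0 < m < 1:
                    raise ValueError(f"{name}: mean must lie in (0, 1)")


def default_psa_config(
    model: Optional[DecisionTreeModel] = None,
    n_iterations: int = 1000,
    seed: int = 0,
) -> PSAConfig:
    """PSA spec calibrated to the trial: gamma costs with the arm-level cost
    sds, beta branch utilities with the arm-level QALY sds, and beta cure
    probabilities with binomial standard errors at the arm sample sizes."""
    model = model or default_model()
    cost_params, utility_params, prob_params = {}, {}, {}
    for arm, s in model.strategies.items():
        summary = TRIAL_SUMMARY[arm]
        cost_params[f"{arm}.cost_cure"] = (s.cost_cure, summary["cost_sd"])
        cost_params[f"{arm}.cost_improve"] = (s.cost_improve, summary["cost_sd"])
        utility_params[f"{arm}.eff_cure"] = (s.eff_cure, summary["qaly_sd"])
        utility_params[f"{arm}.eff_improve"] = (s.eff_improve, summary["qaly_sd"])
        p = s.p_cure
        prob_params[f"{arm}.p_cure"] = (p, math.sqrt(p * (1 - p) / summary["n"]))
    return PSAConfig(
        cost_params=cost_params,
        utility_params=utility_params,
        prob_params=prob_params,
        n_iterations=n_iterations,
        seed=seed,
    )


@dataclass
class PSADraws:
    """Monte-Carlo parameter draws and per-strategy (cost, effect) pairs."""

    params: pd.DataFrame
    costs: Mapping[str, np.ndarray]
    effects: Mapping[str, np.ndarray]
    reference: str
    comparator: str

    @property
    def n_iterations(self) -> int:
        return len(self.params)

    @property
    def delta_cost(self) -> np.ndarray:
        return self.costs[self.comparator] - self.costs[self.reference]

    @property
    def delta_effect(self) -> np.ndarray:
        return self.effects[self.comparator] - self.effects[self.reference]


def run_psa(model: DecisionTreeModel, config: PSAConfig) -> PSADraws:
    """Sample all uncertain parameters independently and roll back the tree per draw.

    Deterministic under ``config.seed``: parameters are sampled in sorted name
    order within each distribution family (costs, then utilities, then
    probabilities).
    """
    model.validate()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_iterations
    samples: dict[str, np.ndarray] = {}
    for name in sorted(config.cost_params):
        m, sd = config.cost_params[name]
        if sd == 0:
            samples[name] = np.full(n, float(m))
        else:
            shape, scale = fit_gamma_moments(m, sd)
            samples[name] = rng.gamma(shape, scale, size=n)
    for group in (config.utility_params, config.prob_params):
        for name in sorted(group):
            m, sd = group[name]
            if sd == 0:
                samples[name] = np.full(n, float(m))
            else:
                a, b = fit_beta_moments(m, sd)
                samples[name] = rng.beta(a, b, size=n)
    costs, effects = {}, {}
    for arm, s in model.strategies.items():
        p = samples.get(f"{arm}.p_cure", np.full(n, s.p_cure))
        cc = samples.get(f"{arm}.cost_cure", np.full(n, s.cost_cure))
        ci = samples.get(f"{arm}.cost_improve", np.full(n, s.cost_improve))
        ec = samples.get(f"{arm}.eff_cure", np.full(n, s.eff_cure))
        ei = samples.get(f"{arm}.eff_improve", np.full(n, s.eff_improve))
        costs[arm] = p * cc + (1 - p) * ci
        effects[arm] = p * ec + (1 - p) * ei
    return PSADraws(
        params=pd.DataFrame(samples),
        costs=costs,
        effects=effects,
        reference=model.reference,
        comparator=model.comparator,
    )


def default_wtp_grid() -> np.ndarray:
    """0 to 50 000 EUR/QALY in steps of 500, always including 8732."""
    grid = np.arange(0, 50_001, 500, dtype=float)
    return np.unique(np.append(grid, 8732.0))


def ceac(draws: PSADraws, wtp_grid: Optional[Sequence[float]] = None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve for both strategies.

    At each willingness-to-pay threshold, the fraction of iterations in which
    each strategy attains the highest net monetary benefit; NMB ties are
    credited to the reference strategy, so the two probabilities sum to 1.
    """
    grid = default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid, float)
    if grid.size == 0:
        raise ValueError("willingness-to-pay grid is empty")
    if draws.n_iterations == 0:
        raise ValueError("no PSA draws")
    rows = []
    dc, de = draws.delta_cost, draws.delta_effect
    for wtp in grid:
        p_comp = float(np.mean(wtp * de - dc > 0))
        rows.append(
            {
                "wtp": float(wtp),
                f"p_{draws.comparator}": p_comp,
                f"p_{draws.reference}": 1.0 - p_comp,
            }
        )
    return pd.DataFrame(rows)


def ce_plane_export(draws: PSADraws) -> pd.DataFrame:
    """Per-iteration (dE, dC) scatter with compass quadrant labels.

    Quadrants follow the cost-effectiveness-plane convention (dE on x, dC on
    y): ``NE`` dE >= 0 & dC >= 0, ``SE`` dE >= 0 & dC < 0, ``NW`` dE < 0 &
    dC >= 0, ``SW`` otherwise.
    """
    if draws.n_iterations == 0:
        raise ValueError("no PSA draws")
    de, dc = draws.delta_effect, draws.delta_cost
    east = de >= 0
    north = dc >= 0
    quadrant = np.where(
        east, np.where(north, "NE", "SE"), np.where(north, "NW", "SW")
    )
    return pd.DataFrame(
        {
            "iteration": np.arange(draws.n_iterations),
            "delta_effect": de,
            "delta_cost": dc,
            "quadrant": quadrant,
        }
    )
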