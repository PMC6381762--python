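"""Model grid, composite-likelihood maximisation and AIC comparison.

The grid holds thirteen scenarios: strict divergence, isolation with
continuous unidirectional migration, and isolation with a discrete
admixture pulse, each with either a single effective-size class or one
species carrying a free relative size.  Each model is fitted by maximising
the linkage-corrected composite log-likelihood of the bSFS tally with a
seeded multi-start Nelder-Mead search over transformed parameters, and
models are ranked by AIC.

Linkage between adjacent blocks inflates the composite likelihood; two
corrections are provided: dividing lnCL by a fixed factor (default 1000)
or fitting on every 1000th block only (thinning, applied upstream of the
tally), in which case the factor is 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .likelihood import config_distribution, tally_loglik
from .models import FLOW_ADM, FLOW_IM, FLOW_NONE, DemographyModel
from .tabulate import BsfsTally

__all__ = [
    "OptimizerConfig",
    "FitResult",
    "model_grid",
    "fit_model",
    "compare_models",
]

#: admissible parameter region; the search is penalised outside it
PARAM_BOUNDS = {
    "theta": (1e-3, 10.0),
    "t_split": (0.01, 20.0),
    "c_x": (0.05, 20.0),
    "m": (1e-4, 10.0),
    "f": (0.01, 0.99),  # uniform on the logit scale
    "t_adm": (0.05, 0.95),  # as a fraction of t_split
}

#: multi-start draw region (log-uniform), interior to PARAM_BOUNDS; the
#: simplex can still leave it, but starting near the admissible extremes
#: makes every likelihood evaluation disproportionately expensive
START_BOUNDS = {
    "theta": (0.05, 5.0),
    "t_split": (0.1, 5.0),
    "c_x": (0.2, 5.0),
    "m": (0.01, 2.0),
    "f": (0.05, 0.95),
    "t_adm": (0.1, 0.9),
}


@dataclass(frozen=True)
class OptimizerConfig:
    n_starts: int = 10
    max_evals: int = 2000
    fatol: float = 1e-6
    xatol: float = 1e-4
    seed: int = 0


@dataclass
class FitResult:
    model_id: str
    model: DemographyModel
    mle: dict
    lnCL_raw: float
    lnCL_corrected: float
    aic: float
    n_free_params: int
    converged: bool
    n_starts_used: int
    linkage_factor: float
    k_max: int
    delta_aic: float | None = None
    boundary_degenerate: bool = False
    start_values: list = field(default_factory=list)
    start_initial_values: list = field(default_factory=list)


# ----------------------------------------------------------------------
# the 13-model grid
# ----------------------------------------------------------------------


def model_grid() -> list[DemographyModel]:
    """The thirteen divergence/migration/admixture scenarios.

    ``M1.*`` share one size class; ``M2.*``/``M4.*`` let species V deviate
    and ``M3.*``/``M5.*`` let species B deviate.  Suffix ``.1`` is strict
    divergence, ``.2`` gene flow from V into B, ``.3`` gene flow from B
    into V; ``M4``/``M5`` replace continuous migration with a pulse.
    """
    grid = []
    for k, deviating in ((1, None), (2, "V"), (3, "B")):
        grid.append(DemographyModel(f"M{k}.1", flow=FLOW_NONE, deviating=deviating))
        grid.append(
            DemographyModel(f"M{k}.2", flow=FLOW_IM, donor="V", deviating=deviating)
        )
        grid.append(
            DemographyModel(f"M{k}.3", flow=FLOW_IM, donor="B", deviating=deviating)
        )
    for k, deviating in ((4, "V"), (5, "B")):
        grid.append(
            DemographyModel(f"M{k}.2", flow=FLOW_ADM, donor="V", deviating=deviating)
        )
        grid.append(
            DemographyModel(f"M{k}.3", flow=FLOW_ADM, donor="B", deviating=deviating)
        )
    return grid


def model_by_id(model_id: str) -> DemographyModel:
    for m in model_grid():
        if m.model_id == model_id:
            return m
    raise KeyError(f"unknown model id {model_id!r}")


# ----------------------------------------------------------------------
# parameter transforms
# ----------------------------------------------------------------------
#
# The search runs unconstrained: log for positive parameters, logit for f,
# and t_adm encoded as a logit fraction of t_split so the pulse always
# stays inside the pre-split epoch.


def _sigmoid(u: float) -> float:
    if u >= 0:
        return 1.0 / (1.0 + math.exp(-u))
    e = math.exp(u)
    return e / (1.0 + e)


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _decode(x: np.ndarray, names) -> dict:
    vals = {}
    for u, name in zip(x, names):
        if name == "f":
            vals[name] = _sigmoid(u)
        elif name == "t_adm":
            vals[name] = None  # resolved below, needs t_split
        else:
            vals[name] = math.exp(u)
    if "t_adm" in names:
        frac = _sigmoid(x[list(names).index("t_adm")])
        vals["t_adm"] = frac * vals["t_split"]
    return vals


def _encode(vals: dict, names) -> np.ndarray:
    out = []
    for name in names:
        v = vals[name]
        if name == "f":
            out.append(_logit(v))
        elif name == "t_adm":
            out.append(_logit(v / vals["t_split"]))
        else:
            out.append(math.log(v))
    return np.array(out)


def _draw_start(rng: np.random.Generator, names) -> np.ndarray:
    x = []
    for name in names:
        lo, hi = START_BOUNDS[name]
        if name == "f":
            x.append(rng.uniform(_logit(lo), _logit(hi)))
        elif name == "t_adm":
            x.append(_logit(rng.uniform(lo, hi)))  # fraction of t_split
        else:
            x.append(rng.uniform(math.log(lo), math.log(hi)))
    return np.array(x)


def _heuristic_start(tally: BsfsTally, names) -> np.ndarray:
    """Data-driven first start: theta from the mean per-block mutation load
    on a panmictic-expectation tree length, neutral values elsewhere."""
    n = sum(tally.counts.values())
    load = sum(sum(cfg) * c for cfg, c in tally.counts.items()) / max(n, 1)
    theta0 = min(max(load / (11.0 / 3.0), START_BOUNDS["theta"][0]), START_BOUNDS["theta"][1])
    defaults = {"theta": theta0, "t_split": 1.0, "c_x": 1.0, "m": 0.2}
    x = []
    for name in names:
        if name == "f":
            x.append(_logit(0.5))
        elif name == "t_adm":
            x.append(_logit(0.5))
        else:
            x.append(math.log(defaults[name]))
    return np.array(x)


def _out_of_bounds(vals: dict) -> bool:
    for name, v in vals.items():
        lo, hi = PARAM_BOUNDS[name]
        if name == "t_adm":
            frac = v / vals["t_split"]
            if not lo <= frac <= hi:
                return True
        elif not lo <= v <= hi:
            return True
    return False


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------


def _bind(model: DemographyModel, vals: dict) -> tuple[DemographyModel, float]:
    theta = vals["theta"]
    mvals = {k: v for k, v in vals.items() if k != "theta"}
    return model.with_params(**mvals), theta


def fit_model(
    tally: BsfsTally,
    model: DemographyModel,
    k_max: int = 3,
    optimizer: OptimizerConfig | None = None,
    *,
    linkage_factor: float = 1000.0,
) -> FitResult:
    """Maximise the composite log-likelihood of ``tally`` under ``model``.

    Runs a seeded multi-start Nelder-Mead simplex on transformed
    parameters and returns the best start.  ``lnCL_corrected`` is
    ``lnCL_raw / linkage_factor``; pass ``linkage_factor=1`` when the
    tally was thinned to effectively unlinked blocks instead.  AIC uses
    the corrected score: ``2 * n_free_params - 2 * lnCL_corrected``.
    """
    if not tally.counts:
        raise ValueError("empty tally")
    if linkage_factor < 1:
        raise ValueError("linkage_factor must be >= 1")
    cfg = optimizer or OptimizerConfig()
    names = model.param_names
    rng = np.random.default_rng(cfg.seed)

    def objective(x: np.ndarray) -> float:
        try:
            vals = _decode(x, names)
            if _out_of_bounds(vals):
                return 1e12
            bound, theta = _bind(model, vals)
            tab = config_distribution(bound, theta, k_max)
        except (ArithmeticError, OverflowError, FloatingPointError, ValueError):
            return 1e12
        return -tally_loglik(tally.counts, tab)

    best_val = math.inf
    best_x = None
    start_vals = []
    any_converged = False
    start_initial = []
    for s in range(cfg.n_starts):
        x0 = _heuristic_start(tally, names) if s == 0 else _draw_start(rng, names)
        start_initial.append(float(-objective(x0)))
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={
                "maxfev": cfg.max_evals,
                "fatol": cfg.fatol,
                "xatol": cfg.xatol,
            },
        )
        start_vals.append(float(-res.fun))
        any_converged = any_converged or bool(res.success)
        if res.fun < best_val:
            best_val = float(res.fun)
            best_x = res.x

    vals = _decode(best_x, names)
    bound, theta = _bind(model, vals)
    lnCL_raw = -best_val
    lnCL_corr = lnCL_raw / linkage_factor
    mle = dict(vals)
    boundary = False
    if model.flow == FLOW_ADM and vals["t_adm"] > 0.99 * vals["t_split"]:
        boundary = True
    return FitResult(
        model_id=model.model_id,
        model=bound,
        mle=mle,
        lnCL_raw=lnCL_raw,
        lnCL_corrected=lnCL_corr,
        aic=2.0 * model.n_free_params - 2.0 * lnCL_corr,
        n_free_params=model.n_free_params,
        converged=any_converged,
        n_starts_used=cfg.n_starts,
        linkage_factor=linkage_factor,
        k_max=k_max,
        boundary_degenerate=boundary,
        start_values=start_vals,
        start_initial_values=start_initial,
    )


def compare_models(
    tally: BsfsTally,
    grid: list[DemographyModel] | None = None,
    k_max: int = 3,
    optimizer: OptimizerConfig | None = None,
    *,
    linkage_factor: float = 1000.0,
) -> list[FitResult]:
    """Fit every model in ``grid`` and rank by AIC.

    Returns results sorted best-first.  ``delta_aic`` follows the
    reporting convention ``aic_best - aic_model``: the best model scores
    exactly 0, all others are negative.  Individual fit failures are
    recorded, never propagated.
    """
    grid = model_grid() if grid is None else grid
    if len(grid) < 2:
        raise ValueError("need at least two models to compare")
    results = []
    for model in grid:
        try:
            results.append(
                fit_model(
                    tally, model, k_max, optimizer, linkage_factor=linkage_factor
                )
            )
        except Exception as exc:  # keep the table going
            results.append(
                FitResult(
                    model_id=model.model_id,
                    model=model,
                    mle={},
                    lnCL_raw=float("nan"),
                    lnCL_corrected=float("nan"),
                    aic=float("inf"),
                    n_free_params=model.n_free_params,
                    converged=False,
                    n_starts_used=0,
                    linkage_factor=linkage_factor,
                    k_max=k_max,
                )
            )
            results[-1].mle = {"error": str(exc)}
    results.sort(key=lambda r: r.aic)
    best = results[0].aic
    for r in results:
        r.delta_aic = best - r.aic
    return results


def report_rows(results: list[FitResult]) -> list[dict]:
    """Flatten fit results into report rows (one per model)."""
    rows = []
    for r in results:
        rows.append(
            {
                "model_id": r.model_id,
                "model_type": r.model.type_label,
                "n_free_params": r.n_free_params,
                "lnCL_raw": r.lnCL_raw,
                "lnCL_corrected": r.lnCL_corrected,
                "aic": r.aic,
                "delta_aic": r.delta_aic,
                "converged": r.converged,
                **{f"mle_{k}": v for k, v in r.mle.items()},
            }
        )
    return rows
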