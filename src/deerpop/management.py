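"""Forecasting under management actions and decision metrics.

Forecasts propagate every retained posterior draw forward from the final
survey year: each year the treatment event is applied right after census,
the density-dependent projection matrix for that draw's parameters
advances the population, and lognormal process noise is added.  The
resulting posterior predictive process distribution integrates over both
parameter and state uncertainty, and decision metrics (probability of
meeting a density objective, the net-effect ratio versus no action,
treatment effort, program cost) are Monte Carlo averages over it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .inference import PosteriorDraws
from .process import TreatmentSpec, TREATMENT_TYPES

__all__ = [
    "ManagementObjective",
    "ForecastEnsemble",
    "DecisionSummary",
    "UNIT_COSTS",
    "forecast",
    "objective_probabilities",
    "net_effect",
    "treatment_effort",
    "program_cost",
    "decision_summary",
]

#: default cost per treated doe, dollars
UNIT_COSTS = {"cull": 370.0, "sterilize": 750.0, "contracept1": 750.0, "contracept3": 750.0}

_FLOOR = 1e-6


@dataclass
class ManagementObjective:
    """A density band the manager wants the population inside.

    Bounds are deer/km^2; ``evaluation_year`` indexes forecast years
    (1-based; default = the horizon).  Boundary values count as within.
    """

    lower: float = 5.0
    upper: float = 15.0
    evaluation_year: int | None = None
    scope: str = "regional"

    def __post_init__(self) -> None:
        if not 0 <= self.lower < self.upper:
            raise ValueError("objective requires 0 <= lower < upper")
        if self.scope not in ("regional", "per_park"):
            raise ValueError("scope must be 'regional' or 'per_park'")


@dataclass
class ForecastEnsemble:
    """Posterior predictive forecast under one treatment schedule.

    states : (n_draws, horizon, n_parks, 4) stage abundances
        (n1, n2, n2s, n3) at each forecast census.
    treated : (n_draws, horizon, n_parks) animals treated each year.
    """

    states: np.ndarray
    treated: np.ndarray
    areas: np.ndarray
    schedule: list[TreatmentSpec]

    @property
    def n_draws(self) -> int:
        return self.states.shape[0]

    @property
    def horizon(self) -> int:
        return self.states.shape[1]

    def regional_density(self) -> np.ndarray:
        """(n_draws, horizon) pooled density: total abundance / total area."""
        return self.states.sum(axis=(2, 3)) / self.areas.sum()

    def park_density(self) -> np.ndarray:
        """(n_draws, horizon, n_parks) per-park density."""
        return self.states.sum(axis=3) / self.areas[None, None, :]


@dataclass
class DecisionSummary:
    """Decision metrics for one treatment regime at the evaluation year."""

    treatment: str
    proportion: float
    p_below: float
    p_in: float
    p_above: float
    net_effect: float
    median_total_treated: float
    program_cost: float
    p_in_by_year: list[float] = field(default_factory=list)


def _normalize_schedule(
    treatment: TreatmentSpec | Sequence[TreatmentSpec], horizon: int
) -> list[TreatmentSpec]:
    if isinstance(treatment, TreatmentSpec):
        return [
            treatment if treatment.applies_in(y) else TreatmentSpec(type="none")
            for y in range(horizon)
        ]
    schedule = list(treatment)
    if len(schedule) != horizon:
        raise ValueError("per-year schedule length must equal the horizon")
    return schedule


def forecast(
    draws: PosteriorDraws,
    horizon_years: int,
    treatment: TreatmentSpec | Sequence[TreatmentSpec] = TreatmentSpec(type="none"),
    rng: np.random.Generator | None = None,
    max_draws: int | None = None,
    process_noise: bool = True,
) -> ForecastEnsemble:
    """Propagate each posterior draw ``horizon_years`` into the future.

    Each year, per park and draw: the treatment event removes or transfers
    females immediately after census, the 4-stage density-dependent matrix
    built from that draw's park-level vital rates projects the population
    one year, and lognormal process noise with the draw's sigma_p2 is
    added (the sterile stage stays empty if it is exactly empty).
    Fecundity uses the post-treatment density.
    """
    if horizon_years < 1:
        raise ValueError("horizon must be at least one year")
    rng = rng or np.random.default_rng()
    v = draws.values
    C, S = v["m"].shape
    logN_last = v["logN"][:, :, :, -1, :]
    P = logN_last.shape[2]
    flat = lambda x: x.reshape(C * S, *x.shape[2:])
    sel = np.arange(C * S)
    if max_draws is not None and max_draws < sel.size:
        sel = np.linspace(0, sel.size - 1, max_draws).astype(int)
    n_draws = sel.size

    s = flat(v["s"])[sel]          # (R, P, 3)
    m = flat(v["m"])[sel][:, None]
    r_f = flat(v["r_f"])[sel][:, None]
    K_f = flat(v["K_f"])[sel][:, None]
    sig = np.sqrt(flat(v["sigma_p2"])[sel])[:, None, None]
    areas = draws.areas
    form = draws.fecundity_form
    fmax = np.exp(r_f) if form == "ricker_exp" else r_f

    # current state in 4-stage order (n1, n2, n2s, n3), sterile stage empty
    N3 = np.exp(flat(v["logN"][:, :, :, -1, :])[sel])  # (R, P, 3)
    cur = np.zeros((n_draws, P, 4))
    cur[:, :, 0] = N3[:, :, 0]
    cur[:, :, 1] = N3[:, :, 1]
    cur[:, :, 3] = N3[:, :, 2]

    schedule = _normalize_schedule(treatment, horizon_years)
    states = np.empty((n_draws, horizon_years, P, 4))
    treated = np.zeros((n_draws, horizon_years, P))

    for y, treat in enumerate(schedule):
        p = treat.proportion if treat.type != "none" else 0.0
        post = cur.copy()
        if treat.type == "cull" and p > 0:
            treated[:, y, :] = p * (cur[:, :, 1] + cur[:, :, 2])
            post[:, :, 1] = cur[:, :, 1] * (1.0 - p)
            post[:, :, 2] = cur[:, :, 2] * (1.0 - p)
        elif treat.type in ("sterilize", "contracept1", "contracept3") and p > 0:
            moved = p * cur[:, :, 1]
            treated[:, y, :] = moved
            post[:, :, 1] = cur[:, :, 1] - moved
            post[:, :, 2] = cur[:, :, 2] + moved
        r = treat.reversion_rate if treat.type != "none" else 0.0

        D = post.sum(axis=2) / areas[None, :]
        f = fmax * np.exp(-(r_f / K_f) * D)
        s1, s2, s3 = s[:, :, 0], s[:, :, 1], s[:, :, 2]
        nxt = np.empty_like(post)
        nxt[:, :, 0] = s2 * f * post[:, :, 1]
        nxt[:, :, 1] = s1 * m * post[:, :, 0] + s2 * post[:, :, 1] + s2 * r * post[:, :, 2]
        nxt[:, :, 2] = s2 * (1.0 - r) * post[:, :, 2]
        nxt[:, :, 3] = s1 * (1.0 - m) * post[:, :, 0] + s3 * post[:, :, 3]

        if process_noise:
            keep_zero = nxt[:, :, 2] == 0.0
            det = np.maximum(nxt, _FLOOR)
            nxt = np.exp(rng.normal(np.log(det), np.broadcast_to(sig, det.shape)))
            nxt[:, :, 2] = np.where(keep_zero, 0.0, nxt[:, :, 2])
        states[:, y] = nxt
        cur = nxt

    return ForecastEnsemble(states=states, treated=treated, areas=areas, schedule=schedule)


def objective_probabilities(
    ens: ForecastEnsemble, obj: ManagementObjective
) -> tuple[float, float, float]:
    """Fractions of draws below / within / above the objective band.

    Evaluated on pooled regional density at ``obj.evaluation_year`` (the
    horizon by default); boundary values count as within.
    """
    if ens.n_draws == 0:
        raise ValueError("empty forecast ensemble")
    year = obj.evaluation_year or ens.horizon
    if not 1 <= year <= ens.horizon:
        raise ValueError(f"evaluation year {year} outside horizon {ens.horizon}")
    if obj.scope == "regional":
        d = ens.regional_density()[:, year - 1]
    else:
        d = ens.park_density()[:, year - 1, :].mean(axis=1)
    p_below = float(np.mean(d < obj.lower))
    p_above = float(np.mean(d > obj.upper))
    p_in = 1.0 - p_below - p_above
    return p_below, p_in, p_above


def net_effect(p_action: float, p_no_action: float) -> float:
    """Ratio of objective probabilities: treatment vs no action.

    A value of 10 reads "ten times more likely to meet the objective with
    the treatment than with no action".  Returns ``inf`` (with a warning)
    when no action has zero probability but the action does not.
    """
    if p_action < 0 or p_no_action < 0:
        raise ValueError("probabilities must be non-negative")
    if p_no_action == 0:
        if p_action == 0:
            return np.nan
        import warnings

        warnings.warn("no-action probability is zero; net effect is infinite")
        return np.inf
    return p_action / p_no_action


def treatment_effort(ens: ForecastEnsemble) -> dict:
    """Median numbers of animals that must be treated under the regime.

    Returns the median (over draws) of the cumulative total across parks
    and years, plus per-year and per-park medians of cumulative counts.
    """
    per_draw_total = ens.treated.sum(axis=(1, 2))
    cum_by_year = ens.treated.sum(axis=2).cumsum(axis=1)
    return {
        "median_total": float(np.median(per_draw_total)),
        "median_cumulative_by_year": np.median(cum_by_year, axis=0),
        "median_total_by_park": np.median(ens.treated.sum(axis=1), axis=0),
    }


def program_cost(effort_by_type: dict[str, float], unit_costs: dict[str, float] | None = None) -> float:
    """Total program cost in dollars: sum of counts times per-doe unit costs.

    Defaults: culling $370/doe, fertility control (sterilization or
    contraception) $750/doe.
    """
    costs = dict(UNIT_COSTS)
    if unit_costs:
        costs.update(unit_costs)
    total = 0.0
    for ttype, count in effort_by_type.items():
        if ttype == "none":
            continue
        if ttype not in TREATMENT_TYPES:
            raise ValueError(f"unknown treatment type {ttype!r}")
        if count < 0:
            raise ValueError("treatment counts must be non-negative")
        total += count * costs[ttype]
    return float(total)


def decision_summary(
    draws: PosteriorDraws,
    treatment: TreatmentSpec | Sequence[TreatmentSpec],
    obj: ManagementObjective,
    horizon_years: int = 5,
    rng: np.random.Generator | None = None,
    baseline: ForecastEnsemble | None = None,
    max_draws: int | None = 2000,
    unit_costs: dict[str, float] | None = None,
) -> DecisionSummary:
    """Full decision report for one treatment regime.

    Uses matched draws (and a shared no-action baseline when supplied) so
    regimes are compared on the same posterior sample.
    """
    rng = rng or np.random.default_rng()
    ens = forecast(draws, horizon_years, treatment, rng=rng, max_draws=max_draws)
    if baseline is None:
        baseline = forecast(
            draws, horizon_years, TreatmentSpec(type="none"),
            rng=np.random.default_rng(rng.integers(2**31 - 1)), max_draws=max_draws,
        )
    p_below, p_in, p_above = objective_probabilities(ens, obj)
    _, p_in0, _ = objective_probabilities(baseline, obj)
    eff = treatment_effort(ens)
    schedule = ens.schedule
    by_type: dict[str, float] = {}
    # attribute per-year median effort to that year's treatment type
    per_year = np.median(ens.treated.sum(axis=2), axis=0)
    for y, tr in enumerate(schedule):
        if tr.type != "none" and tr.proportion > 0:
            by_type[tr.type] = by_type.get(tr.type, 0.0) + float(per_year[y])
    lead = next((t for t in schedule if t.type != "none"), schedule[0])
    p_in_by_year = []
    for yr in range(1, ens.horizon + 1):
        o = ManagementObjective(obj.lower, obj.upper, evaluation_year=yr, scope=obj.scope)
        p_in_by_year.append(objective_probabilities(ens, o)[1])
    return DecisionSummary(
        treatment=lead.type,
        proportion=lead.proportion,
        p_below=p_below,
        p_in=p_in,
        p_above=p_above,
        net_effect=net_effect(p_in, p_in0),
        median_total_treated=eff["median_total"],
        program_cost=program_cost(by_type, unit_costs),
        p_in_by_year=p_in_by_year,
    )


def experiment_table(
    draws: PosteriorDraws,
    obj: ManagementObjective | None = None,
    treatments: dict[str, list[float]] | None = None,
    horizon_years: int = 5,
    seed: int = 0,
    max_draws: int | None = 2000,
    unit_costs: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Decision summaries for a grid of treatment types and proportions."""
    obj = obj or ManagementObjective()
    treatments = treatments or {
        "cull": [0.2, 0.4, 0.6, 0.9],
        "sterilize": [0.2, 0.4, 0.6, 0.9],
        "contracept1": [0.2, 0.4, 0.6, 0.9],
        "contracept3": [0.2, 0.4, 0.6, 0.9],
    }
    base = forecast(
        draws, horizon_years, TreatmentSpec(type="none"),
        rng=np.random.default_rng(seed), max_draws=max_draws,
    )
    _, p_in0, _ = objective_probabilities(base, obj)
    rows = [
        dict(treatment="none", percent_treated=0.0, p_below=objective_probabilities(base, obj)[0],
             p_in=p_in0, p_above=objective_probabilities(base, obj)[2], net_effect=1.0,
             median_total_treated=0.0, program_cost=0.0)
    ]
    for ttype, props in treatments.items():
        for k, p in enumerate(props):
            ds = decision_summary(
                draws, TreatmentSpec(type=ttype, proportion=p), obj,
                horizon_years=horizon_years,
                rng=np.random.default_rng([seed, hash(ttype) % 2**16, k]),
                baseline=base, max_draws=max_draws, unit_costs=unit_costs,
            )
            rows.append(
                dict(treatment=ttype, percent_treated=100 * p, p_below=ds.p_below,
                     p_in=ds.p_in, p_above=ds.p_above, net_effect=ds.net_effect,
                     median_total_treated=ds.median_total_treated,
                     program_cost=ds.program_cost)
            )
    return pd.DataFrame(rows)
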