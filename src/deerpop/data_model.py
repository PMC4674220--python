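"""Survey data container, likelihoods, and the joint log density.

Two data streams inform the latent states: spotlight-survey
classification counts (juvenile / adult female / adult male), modelled as
multinomial draws from the latent stage proportions, and distance-sampling
density estimates with their standard errors, modelled as normal around
the latent total density.  Year-1 observations inform the
initial-condition prior (Dirichlet on stage proportions, normal on
density) and are therefore excluded from the likelihood terms, which run
over years 2..T.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .priors import PriorConfig, STAGE_CLASSES, log_prior

__all__ = [
    "SurveyDataset",
    "ModelParams",
    "InitialStateModel",
    "classification_proportions",
    "classification_loglik",
    "density_loglik",
    "initial_state_draw",
    "joint_log_density",
]


@dataclass
class SurveyDataset:
    """Park-by-year survey data for a region.

    Attributes
    ----------
    park_ids : list of str, length P
    areas : (P,) park areas in km^2
    years : (T,) calendar years, consecutive
    density : (P, T) density estimates in deer/km^2; NaN where missing
    density_se : (P, T) standard errors of the density estimates; NaN
        where density is missing
    counts : (P, T, 3) classification counts in class order
        (juvenile, adult female, adult male); rows of zeros where missing
    """

    park_ids: list[str]
    areas: np.ndarray
    years: np.ndarray
    density: np.ndarray
    density_se: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        self.years = np.asarray(self.years, dtype=int)
        self.density = np.asarray(self.density, dtype=float)
        self.density_se = np.asarray(self.density_se, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        P, T = len(self.park_ids), len(self.years)
        if self.areas.shape != (P,) or np.any(self.areas <= 0):
            raise ValueError("areas must be positive, one per park")
        for name in ("density", "density_se"):
            if getattr(self, name).shape != (P, T):
                raise ValueError(f"{name} must have shape (n_parks, n_years)")
        if self.counts.shape != (P, T, 3):
            raise ValueError("counts must have shape (n_parks, n_years, 3)")
        if np.any(self.counts < 0) or np.any(self.counts != np.round(self.counts)):
            raise ValueError("classification counts must be non-negative integers")
        obs = np.isfinite(self.density)
        if np.any(self.density[obs] < 0):
            raise ValueError("density estimates must be non-negative")
        if np.any(~np.isfinite(self.density_se[obs])) or np.any(self.density_se[obs] <= 0):
            raise ValueError("density SEs must be positive wherever density is observed")

    @property
    def n_parks(self) -> int:
        return len(self.park_ids)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def y_N(self) -> np.ndarray:
        """(P, T) total classified animals per park-year."""
        return self.counts.sum(axis=2)

    @property
    def density_observed(self) -> np.ndarray:
        """(P, T) boolean mask of park-years with a density estimate."""
        return np.isfinite(self.density)

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    def to_frames(self) -> dict[str, pd.DataFrame]:
        """Tidy DataFrames matching the CSV schemas (parks, density, classification)."""
        parks = pd.DataFrame({"park_id": self.park_ids, "area_km2": self.areas})
        rows_d, rows_c = [], []
        for i, pid in enumerate(self.park_ids):
            for t, yr in enumerate(self.years):
                if np.isfinite(self.density[i, t]):
                    rows_d.append(
                        dict(park_id=pid, year=int(yr),
                             density_per_km2=self.density[i, t], se=self.density_se[i, t])
                    )
                if self.y_N[i, t] > 0:
                    rows_c.append(
                        dict(park_id=pid, year=int(yr),
                             n_juvenile=int(self.counts[i, t, 0]),
                             n_female=int(self.counts[i, t, 1]),
                             n_male=int(self.counts[i, t, 2]))
                    )
        return {
            "parks": parks,
            "density": pd.DataFrame(rows_d),
            "classification": pd.DataFrame(rows_c),
        }


@dataclass
class ModelParams:
    """One point in parameter space for the hierarchical model.

    s : (P, 3) park-level survival, class order (juvenile, female, male)
    a, b : (3,) beta hyperparameters per class
    m, r_f, K_f, sigma_p2 : global scalars
    d1 : (P,) initial total density per park
    gamma1 : (P, 3) initial stage proportions per park (rows on the simplex)
    """

    s: np.ndarray
    a: np.ndarray
    b: np.ndarray
    m: float
    r_f: float
    K_f: float
    sigma_p2: float
    d1: np.ndarray
    gamma1: np.ndarray

    def initial_states(self, areas: np.ndarray) -> np.ndarray:
        """(P, 3) initial stage abundances n_i1 = d_i1 * gamma_i1 * area_i."""
        return self.d1[:, None] * np.asarray(self.gamma1) * np.asarray(areas)[:, None]


@dataclass
class InitialStateModel:
    """Initial conditions for one park: proportions, density, abundances."""

    gamma1: np.ndarray
    d1: float
    n1: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.gamma1, dtype=float)
        if g.shape != (3,) or np.any(g < 0) or abs(g.sum() - 1.0) > 1e-9:
            raise ValueError("gamma1 must be a 3-simplex vector")


def classification_proportions(n) -> np.ndarray:
    """Latent stage proportions pi = n / sum(n) over (juvenile, female, male).

    Accepts a ``StageVector`` or 3-/4-array; in the treated (4-stage)
    system fertile and sterile/contracepted does are pooled into the
    female class, since field observers cannot tell them apart.
    """
    from .process import StageVector

    if isinstance(n, StageVector):
        vec = np.array([n.n1, n.n2 + n.n2s, n.n3])
    else:
        arr = np.asarray(n, dtype=float)
        if arr.shape[-1] == 4:
            vec = np.stack(
                [arr[..., 0], arr[..., 1] + arr[..., 2], arr[..., 3]], axis=-1
            )
        elif arr.shape[-1] == 3:
            vec = arr
        else:
            raise ValueError("expected a 3- or 4-stage vector")
    tot = vec.sum(axis=-1, keepdims=True)
    if np.any(tot <= 0):
        raise ValueError("total abundance must be positive to form proportions")
    return vec / tot


def classification_loglik(y_alpha, y_N: float, pi) -> float:
    """Multinomial log-pmf of classification counts given proportions."""
    y = np.asarray(y_alpha, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if y.shape != (3,) or pi.shape != (3,):
        raise ValueError("y_alpha and pi must be 3-vectors")
    if abs(y.sum() - y_N) > 1e-9:
        raise ValueError(f"y_N={y_N} does not equal sum(y_alpha)={y.sum()}")
    if y_N == 0:
        return 0.0
    if np.any((pi == 0) & (y > 0)):
        return -np.inf
    return float(stats.multinomial.logpmf(y, int(round(y_N)), pi))


def density_loglik(y_d: float, se: float, n, area: float) -> float:
    """Normal log-density of the observed density around latent total density.

    ``se`` is the plug-in standard error from the upstream distance-sampling
    analysis, treated as known.  A missing observation (NaN) contributes 0.
    """
    if np.isnan(y_d):
        return 0.0
    if se <= 0 or area <= 0:
        raise ValueError("se and area must be positive")
    from .process import StageVector

    total = n.total if isinstance(n, StageVector) else float(np.sum(n))
    return float(stats.norm.logpdf(y_d, total / area, se))


def initial_state_draw(
    y_alpha, y_d: float, se: float, area: float, rng: np.random.Generator
) -> InitialStateModel:
    """Draw initial conditions for one park from the year-1 data model.

    gamma ~ Dirichlet(y_alpha + 1); d ~ Normal(y_d, se^2) truncated below
    at 0; n = d * gamma * area.
    """
    y = np.asarray(y_alpha, dtype=float)
    if y.shape != (3,) or np.isnan(y_d):
        raise ValueError(
            "year-1 classification and density data are required to draw initial "
            "conditions; supply them or configure a fallback"
        )
    gamma = rng.dirichlet(y + 1.0)
    lo = (0.0 - y_d) / se
    d = float(stats.truncnorm.rvs(lo, np.inf, loc=y_d, scale=se, random_state=rng))
    return InitialStateModel(gamma1=gamma, d1=d, n1=d * gamma * area)


def _initial_logpdf(params: ModelParams, data: SurveyDataset) -> float:
    """Log density of (gamma1, d1) under the year-1 empirical prior."""
    lp = 0.0
    for i in range(data.n_parks):
        alpha = data.counts[i, 0] + 1.0
        g = np.asarray(params.gamma1[i], dtype=float)
        if np.any(g <= 0) or abs(g.sum() - 1.0) > 1e-8:
            return -np.inf
        lp += float(stats.dirichlet.logpdf(g / g.sum(), alpha))
        y_d, se = data.density[i, 0], data.density_se[i, 0]
        if np.isfinite(y_d):
            lo = (0.0 - y_d) / se
            lp += float(stats.truncnorm.logpdf(params.d1[i], lo, np.inf, loc=y_d, scale=se))
        elif params.d1[i] <= 0:
            return -np.inf
    return lp


def joint_log_density(
    params: ModelParams,
    log_states: np.ndarray,
    data: SurveyDataset,
    prior_config: PriorConfig | None = None,
    fecundity_form: str = "ricker_exp",
) -> float:
    """Unnormalized log posterior of parameters and latent states.

    ``log_states`` holds log stage abundances with shape (P, T, 3); column
    t=0 is ignored and replaced by the deterministic initial state implied
    by (d1, gamma1).  The density is the sum of the parameter log prior,
    the initial-condition terms, the lognormal process transitions for
    t=1..T-1, and the two data likelihoods for t=1..T-1.
    """
    from .inference import _loglik_terms  # vectorized kernel shared with the sampler

    prior_config = prior_config or PriorConfig()
    lp = log_prior(params, prior_config)
    if not np.isfinite(lp):
        return -np.inf
    lp += _initial_logpdf(params, data)
    if not np.isfinite(lp):
        return -np.inf
    n0 = params.initial_states(data.areas)
    if np.any(n0 <= 0):
        return -np.inf
    logN = np.array(log_states, dtype=float)
    logN[:, 0, :] = np.log(n0)
    proc, dat = _loglik_terms(params, logN, data, fecundity_form)
    return float(lp + proc.sum() + dat.sum())
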