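"""Stage-structured projection of white-tailed deer populations.

The population is censused once a year, six months after the birth pulse,
in three stages: juveniles of both sexes (``n1``), adult females (``n2``)
and adult males (``n3``).  Dynamics follow a Lefkovitch projection matrix
whose fecundity entry declines with total deer density, plus lognormal
process noise.  Management experiments add a fourth stage ``n2s`` of
sterilized or contracepted females that survive like adult females but do
not reproduce.

Stage order is always ``(n1, n2, n2s, n3)`` for treated (4-stage) systems
and ``(n1, n2, n3)`` for the untreated 3-stage system.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "StageVector",
    "VitalRates",
    "TreatmentSpec",
    "TREATMENT_TYPES",
    "fecundity",
    "build_projection_matrix",
    "build_treated_matrix",
    "apply_treatment_event",
    "project",
    "add_process_noise",
]

#: floor applied to deterministic stage means before taking logs, so that
#: extreme culls cannot produce log(0) in the process-noise step
POSITIVITY_FLOOR = 1e-6

TREATMENT_TYPES = ("none", "cull", "sterilize", "contracept1", "contracept3")

FecundityForm = Literal["ricker_exp", "scaled"]


@dataclass
class StageVector:
    """Latent true abundance by stage for one park-year.

    ``n2s`` is the sterile/contracepted female class; it is identically 0
    in the untreated model.
    """

    n1: float
    n2: float
    n3: float
    n2s: float = 0.0
    park_id: str | None = None
    year: int | None = None

    def __post_init__(self) -> None:
        arr = np.array([self.n1, self.n2, self.n2s, self.n3], dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError("stage abundances must be finite and non-negative")

    @property
    def total(self) -> float:
        return self.n1 + self.n2 + self.n2s + self.n3

    @property
    def females(self) -> float:
        """All adult females, fertile plus treated."""
        return self.n2 + self.n2s

    def as_array(self, treated: bool = False) -> np.ndarray:
        """Stage abundances as a vector, ``(n1,n2,n2s,n3)`` when treated."""
        if treated:
            return np.array([self.n1, self.n2, self.n2s, self.n3], dtype=float)
        if self.n2s != 0:
            raise ValueError("untreated stage vector requires n2s == 0")
        return np.array([self.n1, self.n2, self.n3], dtype=float)

    @classmethod
    def from_array(
        cls,
        arr: Sequence[float],
        park_id: str | None = None,
        year: int | None = None,
    ) -> "StageVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape == (3,):
            return cls(n1=arr[0], n2=arr[1], n3=arr[2], park_id=park_id, year=year)
        if arr.shape == (4,):
            return cls(
                n1=arr[0], n2=arr[1], n2s=arr[2], n3=arr[3], park_id=park_id, year=year
            )
        raise ValueError(f"expected 3- or 4-vector, got shape {arr.shape}")


@dataclass
class VitalRates:
    """Annual vital rates for one park.

    s1, s2, s3
        Survival probabilities of juveniles, adult females and adult males
        over the census-to-census year (harvest mortality folded in).
    m
        Juvenile sex ratio: proportion of surviving juveniles recruiting
        into the adult-female stage.
    r_f
        Low-density fecundity parameter (fawns surviving to census per doe;
        see :func:`fecundity` for the two supported functional forms).
    K_f
        Density (deer/km^2) at which the fecundity exponent vanishes.
    sigma_p2
        Process variance on the log scale, shared across stages and parks.
    """

    s1: float
    s2: float
    s3: float
    m: float
    r_f: float
    K_f: float
    sigma_p2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("s1", "s2", "s3", "m"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.r_f <= 0:
            raise ValueError(f"r_f must be positive, got {self.r_f}")
        if self.K_f <= 0:
            raise ValueError(f"K_f must be positive, got {self.K_f}")
        if self.sigma_p2 < 0:
            raise ValueError("sigma_p2 must be non-negative")

    def with_(self, **kwargs) -> "VitalRates":
        return replace(self, **kwargs)


@dataclass
class TreatmentSpec:
    """A fertility-control or culling regime applied to adult females.

    ``proportion`` of adult females is treated immediately after each
    annual census, in every year listed in ``years`` (``None`` = every
    forecast year).  Contraceptives last one year exactly
    (``contracept1``) or an average of three years, modelled as geometric
    reversion with annual probability 1/3 (``contracept3``).
    """

    type: str
    proportion: float = 0.0
    years: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.type not in TREATMENT_TYPES:
            raise ValueError(
                f"unknown treatment type {self.type!r}; expected one of {TREATMENT_TYPES}"
            )
        if not 0.0 <= self.proportion <= 1.0:
            raise ValueError(f"treatment proportion must lie in [0, 1], got {self.proportion}")
        if self.years is not None:
            self.years = tuple(int(y) for y in self.years)

    def applies_in(self, year_index: int) -> bool:
        """Whether the treatment is administered in forecast year ``year_index`` (0-based)."""
        if self.type == "none" or self.proportion == 0.0:
            return False
        return self.years is None or year_index in self.years

    @property
    def reversion_rate(self) -> float:
        """Annual probability that a surviving treated doe becomes fertile again."""
        return {"contracept1": 1.0, "contracept3": 1.0 / 3.0}.get(self.type, 0.0)


NO_ACTION = TreatmentSpec(type="none")


def fecundity(
    r_f: float,
    K_f: float,
    total_density: float | np.ndarray,
    form: FecundityForm = "ricker_exp",
):
    """Density-dependent fecundity: fawns per doe surviving to census.

    Two forms are supported.  ``ricker_exp`` is
    ``f(D) = exp(r_f - (r_f/K_f) * D)``, which equals 1 at ``D = K_f`` and
    ``exp(r_f)`` at zero density.  ``scaled`` is
    ``f(D) = r_f * exp(-(r_f/K_f) * D)``, under which ``r_f`` itself is the
    maximum number of fawns per doe.  Both are positive and strictly
    decreasing in density.

    Parameters
    ----------
    r_f, K_f
        Fecundity parameters, both > 0.
    total_density
        Total deer density D (all stages summed over park area), >= 0.
        May be an array.
    form
        Functional form, ``"ricker_exp"`` (default) or ``"scaled"``.
    """
    if r_f <= 0 or K_f <= 0:
        raise ValueError("r_f and K_f must be positive")
    D = np.asarray(total_density, dtype=float)
    if np.any(D < 0):
        raise ValueError("total density must be non-negative")
    expo = np.exp(-(r_f / K_f) * D)
    if form == "ricker_exp":
        out = np.exp(r_f) * expo
    elif form == "scaled":
        out = r_f * expo
    else:
        raise ValueError(f"unknown fecundity form {form!r}")
    return float(out) if out.ndim == 0 else out


def build_projection_matrix(vitals: VitalRates, f: float) -> np.ndarray:
    """Untreated 3x3 Lefkovitch matrix in stage order (n1, n2, n3).

    Columns map this year's stages to next year's:
    fawns are produced by surviving does (``s2*f``), surviving juveniles
    recruit to females with probability ``m`` and to males with ``1-m``.
    """
    if f < 0:
        raise ValueError("fecundity must be non-negative")
    s1, s2, s3, m = vitals.s1, vitals.s2, vitals.s3, vitals.m
    return np.array(
        [
            [0.0, s2 * f, 0.0],
            [s1 * m, s2, 0.0],
            [s1 * (1.0 - m), 0.0, s3],
        ]
    )


def build_treated_matrix(
    vitals: VitalRates, f: float, treatment: TreatmentSpec
) -> np.ndarray:
    """4x4 projection matrix with a sterile/contracepted female stage.

    Stage order (n1, n2 fertile, n2s treated, n3).  Treated females survive
    at ``s2`` with zero fecundity.  Contraceptives revert: a surviving
    treated doe returns to the fertile stage with annual probability 1
    (``contracept1``) or 1/3 (``contracept3``); sterilization is absorbing.
    Culling uses the same matrix as sterilization structure-wise (removal
    itself is an event, see :func:`apply_treatment_event`).
    """
    if treatment.type == "none":
        raise ValueError("treated matrix requires a treatment; use build_projection_matrix")
    if f < 0:
        raise ValueError("fecundity must be non-negative")
    s1, s2, s3, m = vitals.s1, vitals.s2, vitals.s3, vitals.m
    r = treatment.reversion_rate
    return np.array(
        [
            [0.0, s2 * f, 0.0, 0.0],
            [s1 * m, s2, s2 * r, 0.0],
            [0.0, 0.0, s2 * (1.0 - r), 0.0],
            [s1 * (1.0 - m), 0.0, 0.0, s3],
        ]
    )


def apply_treatment_event(
    n: StageVector, treatment: TreatmentSpec
) -> tuple[StageVector, float]:
    """Apply one post-census treatment event.

    Culling removes the proportion ``p`` of all adult females (fertile and
    previously treated alike).  Sterilization and contraception transfer
    ``p`` of the currently fertile females into the treated stage; animals
    already treated are assumed identifiable and are not re-treated.
    Juveniles and males are never treated.

    Returns the post-treatment state and the number of animals treated
    (culled, sterilized, or dosed) in this event.
    """
    p = treatment.proportion
    if treatment.type == "none" or p == 0.0:
        return n, 0.0
    if treatment.type == "cull":
        n_treated = p * (n.n2 + n.n2s)
        new = replace(n, n2=n.n2 * (1.0 - p), n2s=n.n2s * (1.0 - p))
    elif treatment.type in ("sterilize", "contracept1", "contracept3"):
        moved = p * n.n2
        new = replace(n, n2=n.n2 - moved, n2s=n.n2s + moved)
        n_treated = moved
    else:  # pragma: no cover - guarded by TreatmentSpec
        raise ValueError(f"unknown treatment type {treatment.type!r}")
    return new, float(n_treated)


def project(A: np.ndarray, n: StageVector | np.ndarray) -> StageVector | np.ndarray:
    """One deterministic annual step ``n_t = A n_{t-1}``."""
    A = np.asarray(A, dtype=float)
    if isinstance(n, StageVector):
        vec = n.as_array(treated=A.shape[0] == 4)
        if A.shape != (vec.size, vec.size):
            raise ValueError(f"matrix shape {A.shape} does not match state length {vec.size}")
        out = A @ vec
        year = None if n.year is None else n.year + 1
        return StageVector.from_array(out, park_id=n.park_id, year=year)
    vec = np.asarray(n, dtype=float)
    if A.shape[1] != vec.shape[0]:
        raise ValueError(f"matrix shape {A.shape} does not match state length {vec.shape}")
    return A @ vec


def add_process_noise(
    n_det: StageVector | np.ndarray,
    sigma_p2: float,
    rng: np.random.Generator,
) -> StageVector | np.ndarray:
    """Lognormal process noise around a deterministic projection.

    The true state is ``exp(z)`` with ``z ~ Normal(log(n_det), sigma_p2 I)``,
    so ``n_det`` is the elementwise *median* of the stochastic state.
    Deterministic means are floored at ``POSITIVITY_FLOOR`` before the log.
    """
    if sigma_p2 < 0:
        raise ValueError("sigma_p2 must be non-negative")
    is_sv = isinstance(n_det, StageVector)
    vec = n_det.as_array(treated=True) if is_sv else np.asarray(n_det, dtype=float)
    # a treated stage that is exactly empty stays empty: noise cannot
    # create sterile does out of nothing
    keep_zero = is_sv and n_det.n2s == 0.0
    vec = np.maximum(vec, POSITIVITY_FLOOR)
    if np.any(~np.isfinite(vec)) or np.any(vec <= 0):
        raise ValueError("deterministic stage means must be positive and finite")
    if sigma_p2 == 0:
        out = vec.copy()
    else:
        out = np.exp(rng.normal(np.log(vec), np.sqrt(sigma_p2)))
    if is_sv:
        if keep_zero:
            out[2] = 0.0
        return StageVector.from_array(out, park_id=n_det.park_id, year=n_det.year)
    return out
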