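"""Eigenanalysis of posterior projection matrices.

The asymptotic growth rate lambda of a treatment regime is the dominant
eigenvalue of the annual projection matrix linearized at zero density
(fecundity at its maximum), so it upper-bounds realized growth at any
positive density and puts all treatments on a common scale.  Because every
posterior draw carries its own matrix, lambda inherits a full posterior
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import PosteriorDraws
from .process import TreatmentSpec, VitalRates, build_projection_matrix, build_treated_matrix, fecundity

__all__ = [
    "LambdaPosterior",
    "dominant_eigenvalue",
    "treated_annual_matrix",
    "lambda_posterior",
    "sensitivities",
]


def dominant_eigenvalue(A: np.ndarray) -> float:
    """Spectral radius of a non-negative projection matrix.

    For the non-negative matrices arising here the dominant eigenvalue is
    real (Perron-Frobenius), so the magnitude of the largest-modulus
    eigenvalue is returned.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A must be square")
    if not np.all(np.isfinite(A)):
        raise ValueError("A must have finite entries")
    return float(np.max(np.abs(np.linalg.eigvals(A))))


def _treatment_transfer(treatment: TreatmentSpec) -> np.ndarray:
    """Post-census treatment operator on the 4-stage state."""
    p = treatment.proportion
    C = np.eye(4)
    if treatment.type == "cull":
        C[1, 1] = 1.0 - p
        C[2, 2] = 1.0 - p
    elif treatment.type in ("sterilize", "contracept1", "contracept3"):
        C[1, 1] = 1.0 - p
        C[2, 1] = p
    return C


def treated_annual_matrix(
    vitals: VitalRates, f: float, treatment: TreatmentSpec
) -> np.ndarray:
    """Annual matrix of the repeatedly treated system: projection after treatment.

    The treatment event acts immediately after census, so the matrix for a
    full census-to-census year is ``A_4 @ C`` where ``C`` transfers (or
    removes) the treated share of females and ``A_4`` is the 4-stage
    projection.  With ``treatment.type == "none"`` the 3-stage matrix is
    returned.
    """
    if treatment.type == "none":
        return build_projection_matrix(vitals, f)
    A = build_treated_matrix(vitals, f, treatment)
    return A @ _treatment_transfer(treatment)


@dataclass
class LambdaPosterior:
    """Posterior samples of lambda under one treatment regime."""

    treatment: TreatmentSpec
    samples: np.ndarray
    baseline: np.ndarray | None = None

    @property
    def median(self) -> float:
        return float(np.median(self.samples))

    @property
    def interval(self) -> tuple[float, float]:
        return tuple(np.quantile(self.samples, [0.025, 0.975]))

    @property
    def difference(self) -> np.ndarray | None:
        """Per-draw difference no-action minus treated (positive = treatment slows growth)."""
        if self.baseline is None:
            return None
        return self.baseline - self.samples

    def summary_row(self) -> dict:
        lo, hi = self.interval
        row = dict(
            treatment=self.treatment.type,
            percent_treated=100.0 * self.treatment.proportion,
            q2_5=lo,
            median=self.median,
            q97_5=hi,
        )
        diff = self.difference
        if diff is not None:
            row.update(
                diff_q2_5=float(np.quantile(diff, 0.025)),
                diff_median=float(np.median(diff)),
                diff_q97_5=float(np.quantile(diff, 0.975)),
            )
        return row


def _draw_vitals(draws: PosteriorDraws, chain: int, k: int) -> VitalRates:
    v = draws.values
    s = v["s"][chain, k].mean(axis=0)  # across-park mean survivals
    return VitalRates(
        s1=float(s[0]), s2=float(s[1]), s3=float(s[2]),
        m=float(v["m"][chain, k]), r_f=float(v["r_f"][chain, k]),
        K_f=float(v["K_f"][chain, k]), sigma_p2=float(v["sigma_p2"][chain, k]),
    )


def lambda_posterior(
    draws: PosteriorDraws,
    treatment: TreatmentSpec = TreatmentSpec(type="none"),
    baseline: np.ndarray | None = None,
    max_draws: int | None = None,
    fecundity_form: str | None = None,
) -> LambdaPosterior:
    """Posterior distribution of the asymptotic growth rate lambda.

    One lambda per retained draw: the projection matrix is built from that
    draw's (across-park mean) vital rates at maximum fecundity (density
    zero), treatment folded in as an annual matrix modification, and its
    dominant eigenvalue extracted.  ``fecundity_form`` defaults to the
    form the draws were fitted under.
    """
    form = fecundity_form or draws.fecundity_form
    C, S = draws.values["m"].shape
    pairs = [(c, k) for c in range(C) for k in range(S)]
    if max_draws is not None and max_draws < len(pairs):
        idx = np.linspace(0, len(pairs) - 1, max_draws).astype(int)
        pairs = [pairs[i] for i in idx]
    lams = np.empty(len(pairs))
    for n, (c, k) in enumerate(pairs):
        vit = _draw_vitals(draws, c, k)
        f0 = fecundity(vit.r_f, vit.K_f, 0.0, form=form)
        A = treated_annual_matrix(vit, f0, treatment)
        lams[n] = dominant_eigenvalue(A)
    return LambdaPosterior(treatment=treatment, samples=lams, baseline=baseline)


def lambda_table(
    draws: PosteriorDraws,
    treatments: dict[str, list[float]] | None = None,
    max_draws: int | None = 2000,
) -> pd.DataFrame:
    """Lambda summaries for a grid of treatments, with differences vs no action."""
    treatments = treatments or {
        "cull": [0.2, 0.4, 0.6, 0.9],
        "sterilize": [0.2, 0.4, 0.6, 0.9],
        "contracept1": [0.2, 0.4, 0.6, 0.9],
        "contracept3": [0.2, 0.4, 0.6, 0.9],
    }
    base = lambda_posterior(draws, TreatmentSpec(type="none"), max_draws=max_draws)
    rows = [base.summary_row()]
    for ttype, props in treatments.items():
        for p in props:
            lp = lambda_posterior(
                draws, TreatmentSpec(type=ttype, proportion=p),
                baseline=base.samples, max_draws=max_draws,
            )
            rows.append(lp.summary_row())
    return pd.DataFrame(rows)


def sensitivities(A: np.ndarray) -> np.ndarray:
    """Sensitivity matrix d(lambda)/d(a_kl) of the dominant eigenvalue.

    Computed from the right (w) and left (v) eigenvectors of the dominant
    eigenvalue as ``v_k w_l / <v, w>``.
    """
    A = np.asarray(A, dtype=float)
    vals, right = np.linalg.eig(A)
    lvals, left = np.linalg.eig(A.T)
    k_r = int(np.argmax(np.abs(vals)))
    k_l = int(np.argmin(np.abs(lvals - vals[k_r])))
    mags = np.sort(np.abs(vals))[::-1]
    if A.shape[0] > 1 and abs(mags[0] - mags[1]) < 1e-12 * max(mags[0], 1.0):
        raise ValueError("dominant eigenvalue is not simple; sensitivities undefined")
    w = np.real(right[:, k_r])
    v = np.real(left[:, k_l])
    denom = v @ w
    if abs(denom) < 1e-12:
        raise ValueError("defective matrix: left/right eigenvectors orthogonal")
    S = np.outer(v, w) / denom
    return S
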