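"""Posterior predictive goodness-of-fit checking.

For each retained posterior draw the model-predicted density of every
observed park-year is compared with the real density estimate through a
sum-of-squares discrepancy; the same discrepancy is computed on data
replicated from the observation model.  The Bayesian P-value is the
fraction of draws in which the replicated discrepancy is at least as
large as the observed one — values near 0 or 1 flag lack of fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import SurveyDataset
from .inference import PosteriorDraws

__all__ = ["PpcResult", "posterior_predictive_pvalue"]


@dataclass
class PpcResult:
    """Discrepancy samples and the Bayesian P-value P_B = Pr(T_rep >= T_obs)."""

    T_obs: np.ndarray
    T_rep: np.ndarray
    P_B: float

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"T_obs": self.T_obs, "T_rep": self.T_rep})

    def to_csv(self, path) -> None:
        df = self.summary_frame()
        df.attrs["P_B"] = self.P_B
        df.to_csv(path, index=False)


def posterior_predictive_pvalue(
    draws: PosteriorDraws,
    data: SurveyDataset,
    rng: np.random.Generator,
    max_draws: int | None = None,
) -> PpcResult:
    """Posterior predictive check on the density data.

    Per draw: mu_it = predicted density (total latent abundance / area)
    for every park-year carrying a density observation in the likelihood
    (years 2..T); T_obs sums the squared residuals of the real estimates,
    while replicated estimates y_rep ~ Normal(mu_it, se_it^2) give T_rep.
    Missing park-years are skipped in both sums.  ``max_draws`` caps the
    number of posterior draws used (evenly spaced over the chains).
    """
    logN = draws.values["logN"]
    C, S = logN.shape[:2]
    flat = logN.reshape(C * S, *logN.shape[2:])
    if max_draws is not None and max_draws < flat.shape[0]:
        idx = np.linspace(0, flat.shape[0] - 1, max_draws).astype(int)
        flat = flat[idx]
    # likelihood cells: years 1..T-1 (year 0 informs the initial conditions)
    mask = data.density_observed[:, 1:]
    if not np.any(mask):
        raise ValueError("no observed density cells to check")
    y = data.density[:, 1:][mask]
    se = data.density_se[:, 1:][mask]
    mu = np.exp(flat[:, :, 1:, :]).sum(axis=3) / draws.areas[None, :, None]
    mu = mu[:, mask]
    T_obs = ((y[None, :] - mu) ** 2).sum(axis=1)
    y_rep = rng.normal(mu, se[None, :])
    T_rep = ((y_rep - mu) ** 2).sum(axis=1)
    return PpcResult(T_obs=T_obs, T_rep=T_rep, P_B=float(np.mean(T_rep >= T_obs)))
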