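"""File formats and run configuration.

CSV schemas
-----------
parks.csv           park_id, area_km2
density.csv         park_id, year, density_per_km2, se
classification.csv  park_id, year, n_juvenile, n_female, n_male
                    [, n_unknown] [, y_N]

Years are calendar integers; densities deer/km^2; counts integers.
"Unknown" classifications are carried in the files but excluded from the
modelled counts and totals, since the likelihood is defined over the
three identifiable classes.  Missing park-years are simply absent rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data_model import SurveyDataset
from .inference import McmcConfig, PosteriorDraws
from .priors import PriorConfig, LiteratureSummary

__all__ = ["RunConfig", "load_survey_data", "write_survey_data", "save_draws", "load_draws"]


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{name}: missing required column(s) {missing}")


def load_survey_data(density_csv, classification_csv, parks_csv) -> SurveyDataset:
    """Read and validate the three survey CSVs into a :class:`SurveyDataset`.

    Schema violations raise with the offending file, row and column named;
    park-years absent from either table are flagged as missing, not errors.
    """
    parks = pd.read_csv(parks_csv)
    _require_columns(parks, ["park_id", "area_km2"], "parks.csv")
    if (parks["area_km2"] <= 0).any():
        bad = parks.index[parks["area_km2"] <= 0][0]
        raise ValueError(f"parks.csv row {bad}: non-positive area_km2")
    park_ids = [str(p) for p in parks["park_id"]]
    areas = parks["area_km2"].to_numpy(dtype=float)
    index = {p: i for i, p in enumerate(park_ids)}

    dens = pd.read_csv(density_csv)
    _require_columns(dens, ["park_id", "year", "density_per_km2", "se"], "density.csv")
    clas = pd.read_csv(classification_csv)
    _require_columns(
        clas, ["park_id", "year", "n_juvenile", "n_female", "n_male"], "classification.csv"
    )
    years = np.unique(np.concatenate([dens["year"].to_numpy(), clas["year"].to_numpy()]))
    years = np.arange(years.min(), years.max() + 1)
    t_index = {int(y): t for t, y in enumerate(years)}
    P, T = len(park_ids), len(years)

    density = np.full((P, T), np.nan)
    density_se = np.full((P, T), np.nan)
    for row in dens.itertuples():
        if str(row.park_id) not in index:
            raise ValueError(f"density.csv row {row.Index}: unknown park_id {row.park_id!r}")
        if not np.isfinite(row.se) or row.se <= 0:
            raise ValueError(f"density.csv row {row.Index}: se must be positive")
        if row.density_per_km2 < 0:
            raise ValueError(f"density.csv row {row.Index}: negative density")
        density[index[str(row.park_id)], t_index[int(row.year)]] = row.density_per_km2
        density_se[index[str(row.park_id)], t_index[int(row.year)]] = row.se

    counts = np.zeros((P, T, 3))
    for row in clas.itertuples():
        if str(row.park_id) not in index:
            raise ValueError(f"classification.csv row {row.Index}: unknown park_id {row.park_id!r}")
        trio = [row.n_juvenile, row.n_female, row.n_male]
        for col, v in zip(("n_juvenile", "n_female", "n_male"), trio):
            if v < 0 or float(v) != int(v):
                raise ValueError(
                    f"classification.csv row {row.Index}: {col} must be a non-negative integer"
                )
        if hasattr(row, "y_N") and not pd.isna(row.y_N):
            declared = int(row.y_N)
            if declared != int(sum(trio)):
                raise ValueError(
                    f"classification.csv row {row.Index}: y_N={declared} does not match "
                    f"sum of class counts {int(sum(trio))}"
                )
        counts[index[str(row.park_id)], t_index[int(row.year)]] = trio

    return SurveyDataset(
        park_ids=park_ids, areas=areas, years=years,
        density=density, density_se=density_se, counts=counts,
    )


def write_survey_data(data: SurveyDataset, outdir, truth=None) -> dict[str, Path]:
    """Write parks/density/classification CSVs (and optional truth.json)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = data.to_frames()
    paths = {}
    for name, fname in (("parks", "parks.csv"), ("density", "density.csv"),
                        ("classification", "classification.csv")):
        path = outdir / fname
        frames[name].to_csv(path, index=False)
        paths[name] = path
    if truth is not None:
        path = outdir / "truth.json"
        path.write_text(json.dumps(truth.to_dict(), indent=1))
        paths["truth"] = path
    return paths


@dataclass
class RunConfig:
    """Top-level configuration for a model run (YAML/JSON loadable)."""

    density_csv: str | None = None
    classification_csv: str | None = None
    parks_csv: str | None = None
    prior: PriorConfig = field(default_factory=PriorConfig)
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    fecundity_form: str = "ricker_exp"
    objective_lower: float = 5.0
    objective_upper: float = 15.0
    horizon_years: int = 5
    treatment_proportions: tuple[float, ...] = (0.2, 0.4, 0.6, 0.9)
    unit_costs: dict = field(
        default_factory=lambda: {"cull": 370.0, "sterilize": 750.0,
                                 "contracept1": 750.0, "contracept3": 750.0}
    )
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        prior_raw = raw.pop("prior", {})
        lit_raw = prior_raw.pop("literature", None)
        prior_kwargs = dict(prior_raw)
        if lit_raw:
            prior_kwargs["literature"] = {
                k: LiteratureSummary(**v) for k, v in lit_raw.items()
            }
        for key in ("k_f_range", "sigma_p_range"):
            if key in prior_kwargs:
                prior_kwargs[key] = tuple(prior_kwargs[key])
        mcmc_raw = raw.pop("mcmc", {})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "treatment_proportions" in raw:
            raw["treatment_proportions"] = tuple(raw["treatment_proportions"])
        return cls(prior=PriorConfig(**prior_kwargs), mcmc=McmcConfig(**mcmc_raw), **raw)


def save_draws(draws: PosteriorDraws, path) -> Path:
    """Persist posterior draws (npz with JSON metadata sidecar keys)."""
    path = Path(path)
    meta = dict(
        park_ids=draws.park_ids,
        years=draws.years.tolist(),
        areas=draws.areas.tolist(),
        seed=draws.seed,
        fecundity_form=draws.fecundity_form,
        n_chains=draws.config.n_chains,
        n_burnin=draws.config.n_burnin,
        n_samples=draws.config.n_samples,
        thinning=draws.config.thinning,
    )
    np.savez_compressed(path, __meta__=json.dumps(meta), **draws.values)
    return path


def load_draws(path) -> PosteriorDraws:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        values = {k: z[k] for k in z.files if k != "__meta__"}
    cfg = McmcConfig(
        n_chains=meta["n_chains"], n_burnin=meta["n_burnin"],
        n_samples=meta["n_samples"], thinning=meta["thinning"], seed=meta["seed"],
    )
    return PosteriorDraws(
        values=values, park_ids=meta["park_ids"], years=np.asarray(meta["years"]),
        areas=np.asarray(meta["areas"]), seed=meta["seed"], config=cfg,
        fecundity_form=meta["fecundity_form"],
    )
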