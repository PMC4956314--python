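"""End-to-end orchestration: ingest -> impute -> aggregate -> fit -> report.

A run consumes the three input CSV families (per-stream discharge, daily
temperature, limnological profiles), reconstructs the latent log-discharge
curve for every stream-season with the GMRF sampler, aggregates the Oct-Dec
above-chemocline responses, fits the per-stream scalar-on-function models
for PPR and CHL with a one-year lag, and writes per-stage artifacts plus a
summary JSON.  Identical config + seed gives a byte-identical summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import HydrofdaError, ParameterError
from .funreg import (
    DEFAULT_FAMILY,
    DEFAULT_K,
    DEFAULT_LAMBDA_GRID,
    ensemble_predict,
    fit_per_stream_models,
    make_basis,
)
from .gmrf import GmrfPriors, impute_all
from .io_ingest import (
    DEFAULT_STREAMS,
    DEFAULT_ZETA,
    daily_average,
    log_transform,
    read_discharge,
    read_limno_profiles,
    read_temperature,
    season_grid,
)
from .responses import DEFAULT_DEPTH_CUTOFF, aggregate_seasons, build_lagged_design

logger = logging.getLogger(__name__)

VARIABLES = ("ppr", "chl")


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run."""

    data_dir: str
    outdir: str
    streams: tuple[str, ...] = DEFAULT_STREAMS
    first_discharge_season: int = 1994
    n_seasons: int = 17
    seed: int = 0
    zeta: float = DEFAULT_ZETA
    depth_cutoff: float = DEFAULT_DEPTH_CUTOFF
    basis_family: str = DEFAULT_FAMILY
    basis_k: int = DEFAULT_K
    covariate_scale: str = "log"
    lam: float | None = None  # None -> LOOCV selection
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    gmrf_n_draws: int = 2000
    gmrf_burn_in: int = 1000
    gmrf_order: int = 1
    gmrf_l_min: int = 5
    temperature_max_gap_days: int = 3

    @property
    def discharge_seasons(self) -> range:
        return range(
            self.first_discharge_season,
            self.first_discharge_season + self.n_seasons,
        )

    @property
    def bio_seasons(self) -> range:
        return range(
            self.first_discharge_season + 1,
            self.first_discharge_season + 1 + self.n_seasons,
        )

    def validate(self) -> None:
        """Fail fast before any computation."""
        if self.n_seasons < 1:
            raise ParameterError("season range is empty")
        if not self.streams:
            raise ParameterError("stream set is empty")
        if self.covariate_scale not in ("log", "linear"):
            raise ParameterError("covariate_scale must be 'log' or 'linear'")
        d = Path(self.data_dir)
        missing = [
            str(p)
            for p in [d / "temperature.csv", d / "limno.csv"]
            + [d / f"discharge_{s}.csv" for s in self.streams]
            if not p.exists()
        ]
        if missing:
            raise ParameterError(f"unresolvable inputs: {', '.join(missing)}")

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["streams"] = list(self.streams)
        out["lambda_grid"] = list(self.lambda_grid)
        return out

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "streams" in raw:
            raw["streams"] = tuple(raw["streams"])
        if "lambda_grid" in raw:
            raw["lambda_grid"] = tuple(raw["lambda_grid"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _ingest_and_impute(cfg: PipelineConfig):
    """Stages 1-2: read inputs, build grids, fit the GMRF per pair."""
    d = Path(cfg.data_dir)
    grids = {s: season_grid(s) for s in cfg.discharge_seasons}
    temps = {}
    for s in cfg.discharge_seasons:
        temps[s] = read_temperature(
            d / "temperature.csv", grids[s], cfg.temperature_max_gap_days
        )
    obs_map = {}
    for stream in cfg.streams:
        records = read_discharge(d / f"discharge_{stream}.csv", stream)
        for s in cfg.discharge_seasons:
            daily = daily_average(records, grids[s])
            ob = log_transform(
                daily, cfg.zeta, stream_id=stream, season_label=s
            )
            logger.info(
                "ingest: %s/%d L=%d of %d nodes", stream, s, ob.L,
                grids[s].n_nodes,
            )
            obs_map[(stream, s)] = ob
    latents = impute_all(
        obs_map,
        temps,
        grids,
        priors=GmrfPriors(),
        seed=cfg.seed,
        n_draws=cfg.gmrf_n_draws,
        burn_in=cfg.gmrf_burn_in,
        order=cfg.gmrf_order,
        l_min=cfg.gmrf_l_min,
    )
    return grids, temps, latents


def _write_latents(latents, grids, outdir: Path) -> None:
    lat_dir = outdir / "latents"
    lat_dir.mkdir(parents=True, exist_ok=True)
    for (stream, s), lat in sorted(latents.items()):
        pd.DataFrame(
            {
                "t": grids[s].t,
                "posterior_mean": lat.mean,
                "posterior_sd": lat.sd,
            }
        ).to_csv(lat_dir / f"{stream}_{s}.csv", index=False)


def _fit_variable(cfg: PipelineConfig, latents, responses):
    basis = make_basis(
        cfg.basis_family, cfg.basis_k, season_grid(cfg.first_discharge_season)
    )
    design = build_lagged_design(responses, latents, cfg.streams)
    fits = fit_per_stream_models(
        design,
        basis,
        covariate_scale=cfg.covariate_scale,
        lam=cfg.lam,
        lambda_grid=cfg.lambda_grid,
        zeta=cfg.zeta,
    )
    ens = ensemble_predict(fits)
    return basis, design, fits, ens


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages and write artifacts; returns the summary dict."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grids, temps, latents = _ingest_and_impute(cfg)
    _write_latents(latents, grids, outdir)

    profiles = read_limno_profiles(Path(cfg.data_dir) / "limno.csv")
    summary: dict = {
        "manifest": {
            "config": cfg.to_dict(),
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "version": __version__,
        },
        "variables": {},
    }
    resp_rows = []
    for var in VARIABLES:
        responses = aggregate_seasons(
            profiles, var, cfg.bio_seasons, cfg.depth_cutoff
        )
        for s, r in sorted(responses.items()):
            resp_rows.append((var, s, r.y, r.n_obs))
        basis, design, fits, ens = _fit_variable(cfg, latents, responses)
        per_model_rows = []
        for stream, f in fits.items():
            for i, s in enumerate(f.seasons):
                per_model_rows.append(
                    (var, stream, s, f.y[i], f.fitted[i], f.se_fit[i],
                     f.residuals[i])
                )
        pd.DataFrame(
            per_model_rows,
            columns=[
                "variable", "stream", "season", "y", "fitted", "se",
                "residual",
            ],
        ).to_csv(outdir / f"per_model_{var}.csv", index=False)
        beta_rows = []
        for stream, f in fits.items():
            for t, b in zip(basis.grid.t, f.beta_curves[stream]):
                beta_rows.append((var, stream, t, b))
        pd.DataFrame(
            beta_rows, columns=["variable", "stream", "t", "beta"]
        ).to_csv(outdir / f"beta_{var}.csv", index=False)
        summary["variables"][var] = {
            "n": len(design),
            "r2_by_stream": {s: round(f.r2, 10) for s, f in fits.items()},
            "r2_avg": round(ens.r2_avg, 10),
            "lambda_by_stream": {s: f.lam for s, f in fits.items()},
            "alpha_by_stream": {
                s: round(f.alpha, 10) for s, f in fits.items()
            },
            "predictions": [
                {
                    "season": int(s),
                    "y": round(float(yv), 10),
                    "predicted": round(float(p), 10),
                    "se": round(float(e), 10),
                    "lower": round(float(lo), 10),
                    "upper": round(float(hi), 10),
                }
                for s, yv, p, e, lo, hi in zip(
                    ens.seasons, ens.y, ens.predicted, ens.se, ens.lower,
                    ens.upper,
                )
            ],
        }
    pd.DataFrame(
        resp_rows, columns=["variable", "season", "y", "n_obs"]
    ).to_csv(outdir / "responses.csv", index=False)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def sweep(
    cfg: PipelineConfig,
    ks: tuple[int, ...] = (3, 5, 7),
    scales: tuple[str, ...] = ("log", "linear"),
    lams: tuple[float | None, ...] = (None,),
) -> pd.DataFrame:
    """Averaged R^2 per (K, covariate_scale, lambda) setting.

    Imputation does not depend on the basis or penalty, so the latent
    curves are computed once and reused across settings.
    """
    cfg.validate()
    grids, temps, latents = _ingest_and_impute(cfg)
    profiles = read_limno_profiles(Path(cfg.data_dir) / "limno.csv")
    rows = []
    for var in VARIABLES:
        responses = aggregate_seasons(
            profiles, var, cfg.bio_seasons, cfg.depth_cutoff
        )
        for k in ks:
            for scale in scales:
                for lam in lams:
                    sub = dataclasses.replace(
                        cfg, basis_k=k, covariate_scale=scale, lam=lam
                    )
                    _, design, fits, ens = _fit_variable(
                        sub, latents, responses
                    )
                    rows.append(
                        {
                            "variable": var,
                            "K": k,
                            "covariate_scale": scale,
                            "lambda": "loocv" if lam is None else lam,
                            "n": len(design),
                            "r2_avg": ens.r2_avg,
                        }
                    )
    df = pd.DataFrame(rows)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df.to_csv(outdir / "sweep.csv", index=False)
    return df
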