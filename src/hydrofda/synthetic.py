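"""Seeded synthetic data with the statistical structure the pipeline assumes.

The generator emulates the study system: daily air temperature with a
mid-summer peak, stream discharge coupled to temperature on the log scale
(latent = delta0 + delta1*T plus AR(1) deviations, observed with Gaussian
noise and contiguous missing blocks from a few days to a couple of weeks),
zero-flow intervals via the log(zeta + .) floor, and seasonal biological
responses built from a known coefficient function beta_true through the
exact quadrature, plus Gaussian noise.

Defaults mirror the scale of the real study: 17 response seasons, 3
streams, a 62-node daily Dec-Jan grid.  The AR(1) latent deviation is a
deliberate, mild misspecification of the random-walk prior used in
fitting.  True latent curves are returned alongside the masked
observations so recovery can be measured.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .funreg import BasisSpec
from .gmrf import LatentDischarge, derive_seed
from .io_ingest import (
    DEFAULT_STREAMS,
    DEFAULT_ZETA,
    LimnoProfileRecord,
    LogDischargeObs,
    SeasonGrid,
    TemperatureSeries,
    season_grid,
)


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of the generative model; defaults are the study scale."""

    seed: int = 0
    n_seasons: int = 17  # number of bio (response) seasons
    first_discharge_season: int = 1994
    streams: tuple[str, ...] = DEFAULT_STREAMS
    delta0: float = -2.0  # latent-mean intercept, log-discharge units
    delta1: float = 0.8  # log-discharge per degC
    ar_rho: float = 0.8  # AR(1) coefficient of latent deviations
    ar_sigma: float = 0.5  # AR(1) innovation sd
    sigma_e: float = 0.3  # observation noise sd on log scale
    n_gaps: int = 2  # contiguous missing blocks per stream-season
    gap_len_range: tuple[int, int] = (3, 14)  # days, inclusive
    alpha_true: float = 8.0
    gamma_true: np.ndarray | None = None  # (J, K); default set below
    snr: float = 3.0  # signal-to-noise used when response_sigma is None
    response_sigma: float | None = None
    zeta: float = DEFAULT_ZETA
    temp_noise_sd: float = 1.5  # day-to-day weather noise
    season_offset_sd: float = 1.5  # interannual mean-temperature anomaly, degC
    peak_shift_sd: float = 5.0  # interannual shift of the melt peak, days
    amp_jitter: float = 0.2  # relative interannual amplitude variation
    profile_noise_sd: float = 0.3
    deep_offset: float = 3.0  # below-chemocline shift, exercises the cutoff

    def __post_init__(self):
        if not abs(self.ar_rho) < 1:
            raise ValueError("|ar_rho| must be < 1")
        if self.gamma_true is None:
            J = len(self.streams)
            base = np.array([0.02, 0.015, -0.01, 0.0075, -0.005])
            g = np.array([base * (1.0 + 0.5 * j) for j in range(J)])
            object.__setattr__(self, "gamma_true", g)

    @property
    def bio_seasons(self) -> range:
        s0 = self.first_discharge_season + 1
        return range(s0, s0 + self.n_seasons)

    @property
    def discharge_seasons(self) -> range:
        return range(
            self.first_discharge_season,
            self.first_discharge_season + self.n_seasons,
        )


def _temp_curve(
    t: np.ndarray, offset: float = 0.0, peak: float = 30.0, amp: float = 9.0
) -> np.ndarray:
    """Deterministic seasonal temperature shape, peak near Dec 31 (t=30)."""
    return -7.0 + offset + amp * np.exp(-0.5 * ((t - peak) / 12.0) ** 2)


def gen_temperature(scenario: SyntheticScenario, season: int) -> TemperatureSeries:
    """Daily mean air temperature for one season; seeded and reproducible.

    Each season draws its own mean anomaly, melt-peak timing and amplitude
    (interannual climate variability: warm vs cold summers, early vs late
    melt) before adding day-to-day weather noise.
    """
    grid = season_grid(season)
    rng = np.random.default_rng(derive_seed(scenario.seed, "temp", season))
    offset = scenario.season_offset_sd * rng.standard_normal()
    peak = 30.0 + scenario.peak_shift_sd * rng.standard_normal()
    amp = 9.0 * (1.0 + scenario.amp_jitter * rng.standard_normal())
    vals = _temp_curve(grid.t, offset, peak, amp)
    vals = vals + scenario.temp_noise_sd * rng.standard_normal(grid.n_nodes)
    return TemperatureSeries(season_label=season, values=vals)


def gen_discharge(
    scenario: SyntheticScenario,
    temp: TemperatureSeries,
    stream_id: str,
) -> tuple[np.ndarray, LogDischargeObs]:
    """True latent DR curve plus masked noisy observations for one stream.

    The latent is delta0 + delta1*T plus a stationary AR(1) deviation,
    floored at log(zeta) (zero flow).  Observations add iid Gaussian noise
    (same floor) and lose ``n_gaps`` contiguous blocks of days.
    """
    grid = season_grid(temp.season_label)
    rng = np.random.default_rng(
        derive_seed(scenario.seed, "discharge", stream_id, temp.season_label)
    )
    n = grid.n_nodes
    e = np.empty(n)
    e[0] = rng.normal(0, scenario.ar_sigma / np.sqrt(1 - scenario.ar_rho**2))
    for i in range(1, n):
        e[i] = scenario.ar_rho * e[i - 1] + rng.normal(0, scenario.ar_sigma)
    floor = np.log(scenario.zeta)
    latent = np.maximum(
        scenario.delta0 + scenario.delta1 * temp.values + e, floor
    )
    obs_vals = np.maximum(
        latent + scenario.sigma_e * rng.standard_normal(n), floor
    )
    mask = np.ones(n, dtype=bool)  # True = observed
    lo, hi = scenario.gap_len_range
    for _ in range(scenario.n_gaps):
        length = int(rng.integers(lo, hi + 1))
        length = min(length, n - 1)  # never cover every node
        start = int(rng.integers(0, n - length + 1))
        cand = mask.copy()
        cand[start : start + length] = False
        if cand.any():
            mask = cand
    idx = np.flatnonzero(mask)
    obs = LogDischargeObs(
        stream_id=stream_id,
        season_label=temp.season_label,
        obs_idx=idx,
        values=obs_vals[idx],
        zeta=scenario.zeta,
    )
    return latent, obs


def true_beta_curves(
    scenario: SyntheticScenario, basis: BasisSpec
) -> dict[str, np.ndarray]:
    """beta_true per stream on the grid nodes, from gamma_true."""
    g = scenario.gamma_true
    if g.shape[1] != basis.K:
        raise ValueError("gamma_true column count must equal basis K")
    return {s: g[j] @ basis.values for j, s in enumerate(scenario.streams)}


def gen_responses(
    scenario: SyntheticScenario,
    latents: dict[tuple[str, int], np.ndarray],
    basis: BasisSpec,
) -> dict[int, float]:
    """Scalar responses per bio season from the exact quadrature of beta_true.

    Y_{s+1} = alpha_true + sum_j <beta_true_j, X_j(season s)> + noise.  When
    ``response_sigma`` is None the noise sd is sd(signal)/snr, computed from
    the realised signal across seasons.
    """
    rng = np.random.default_rng(derive_seed(scenario.seed, "responses"))
    signal = {}
    for s in scenario.discharge_seasons:
        tot = scenario.alpha_true
        for j, stream in enumerate(scenario.streams):
            x = latents[(stream, s)]
            tot += float(scenario.gamma_true[j] @ basis.quadrature(x))
        signal[s + 1] = tot
    vals = np.array(list(signal.values()))
    sigma = (
        scenario.response_sigma
        if scenario.response_sigma is not None
        else float(vals.std(ddof=0)) / scenario.snr
    )
    return {
        s: float(v + sigma * rng.standard_normal())
        for s, v in signal.items()
    }


def gen_limno_profiles(
    scenario: SyntheticScenario,
    responses_by_var: dict[str, dict[int, float]],
    depth_cutoff: float = 11.0,
) -> list[LimnoProfileRecord]:
    """Depth profiles whose above-chemocline Oct-Dec mean recovers Y.

    Per season, 3-4 sampling dates in Oct-Dec; depths 0.5..18 m at 0.5-m
    steps.  Above-cutoff values scatter around the season's Y; below-cutoff
    depths carry Y plus ``deep_offset`` so the cutoff filter is exercised.
    Values are clipped at zero (concentrations are non-negative).
    """
    rng = np.random.default_rng(derive_seed(scenario.seed, "limno"))
    depths = np.arange(0.5, 18.0 + 1e-9, 0.5)
    seasons = sorted(
        set().union(*(set(d) for d in responses_by_var.values()))
    )
    records: list[LimnoProfileRecord] = []
    for s in seasons:
        n_dates = int(rng.integers(3, 5))
        doys = sorted(rng.choice(92, size=n_dates, replace=False))
        dates = [date(s, 10, 1) + timedelta(days=int(d)) for d in doys]
        for d in dates:
            for depth in depths:
                vals = {}
                for var, resp in responses_by_var.items():
                    if s not in resp:
                        vals[var] = None
                        continue
                    base = resp[s]
                    if depth > depth_cutoff:
                        base = base + scenario.deep_offset
                    v = base + scenario.profile_noise_sd * rng.standard_normal()
                    vals[var] = float(max(v, 0.0))
                records.append(
                    LimnoProfileRecord(
                        date=d,
                        depth=float(depth),
                        ppr=vals.get("ppr"),
                        chl=vals.get("chl"),
                    )
                )
    return records


@dataclass
class SyntheticDataset:
    """Everything the generator produced, truths included."""

    scenario: SyntheticScenario
    grids: dict[int, SeasonGrid]
    temps: dict[int, TemperatureSeries]
    true_latents: dict[tuple[str, int], np.ndarray]
    obs: dict[tuple[str, int], LogDischargeObs]
    basis: BasisSpec
    responses: dict[str, dict[int, float]]  # variable -> season -> Y
    profiles: list[LimnoProfileRecord]

    def true_latent_objects(self) -> dict[tuple[str, int], LatentDischarge]:
        """True curves wrapped as zero-sd LatentDischarge, for oracle fits."""
        return {
            (st, s): LatentDischarge(
                stream_id=st,
                season_label=s,
                mean=x.copy(),
                sd=np.zeros_like(x),
            )
            for (st, s), x in self.true_latents.items()
        }


def generate(scenario: SyntheticScenario, basis: BasisSpec | None = None) -> SyntheticDataset:
    """Run every generator stage for the scenario; fully seeded."""
    from .funreg import make_basis

    grids = {s: season_grid(s) for s in scenario.discharge_seasons}
    if basis is None:
        any_grid = next(iter(grids.values()))
        basis = make_basis("fourier", scenario.gamma_true.shape[1], any_grid)
    temps = {s: gen_temperature(scenario, s) for s in scenario.discharge_seasons}
    true_latents = {}
    obs = {}
    for s in scenario.discharge_seasons:
        for stream in scenario.streams:
            lat, ob = gen_discharge(scenario, temps[s], stream)
            true_latents[(stream, s)] = lat
            obs[(stream, s)] = ob
    resp = gen_responses(scenario, true_latents, basis)
    # PPR and CHL share the latent signal mechanism; CHL gets its own noise
    chl_scn = replace(scenario, seed=derive_seed(scenario.seed, "chl"))
    resp_chl = gen_responses(chl_scn, true_latents, basis)
    responses = {"ppr": resp, "chl": resp_chl}
    profiles = gen_limno_profiles(scenario, responses)
    return SyntheticDataset(
        scenario=scenario,
        grids=grids,
        temps=temps,
        true_latents=true_latents,
        obs=obs,
        basis=basis,
        responses=responses,
        profiles=profiles,
    )


# ---------------------------------------------------------------------------
# CSV export in the exact dialects io_ingest reads


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write discharge/temperature/limno CSVs for the whole scenario.

    Discharge is written as 3-hourly records carrying each day's mean flow
    so the daily-average ingest step is exercised; missing days are absent
    rows.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    for stream in ds.scenario.streams:
        rows = []
        for s in ds.scenario.discharge_seasons:
            grid = ds.grids[s]
            ob = ds.obs[(stream, s)]
            dates = grid.dates()
            for i, v in zip(ob.obs_idx, ob.values):
                q = max(np.exp(v) - ds.scenario.zeta, 0.0)
                d = dates[int(i)]
                for hour in range(0, 24, 3):
                    rows.append(
                        (f"{d.isoformat()}T{hour:02d}:00:00", q)
                    )
        p = outdir / f"discharge_{stream}.csv"
        pd.DataFrame(rows, columns=["timestamp", "discharge"]).to_csv(
            p, index=False
        )
        paths[f"discharge_{stream}"] = p

    temp_rows = []
    for s in ds.scenario.discharge_seasons:
        for d, v in zip(ds.grids[s].dates(), ds.temps[s].values):
            temp_rows.append((d.isoformat(), v))
    p = outdir / "temperature.csv"
    pd.DataFrame(temp_rows, columns=["date", "mean_temp_c"]).to_csv(
        p, index=False
    )
    paths["temperature"] = p

    limno_rows = [
        (r.date.isoformat(), r.depth, r.ppr, r.chl) for r in ds.profiles
    ]
    p = outdir / "limno.csv"
    pd.DataFrame(
        limno_rows, columns=["date", "depth_m", "ppr", "chl"]
    ).to_csv(p, index=False)
    paths["limno"] = p
    return paths
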