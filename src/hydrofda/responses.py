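"""Seasonal aggregation of limnological profiles and lag-1 design assembly.

The biological response for a season is the plain mean of all PPR (or CHL)
measurements taken October through December of that calendar year at depths
above the chemocline (default cutoff 11 m).  Each response is paired with
the *previous* season's reconstructed discharge curves: lake biology in the
austral spring is fed by nutrients delivered by the prior summer's flow, so
bio year s uses the discharge season labelled s - 1 (Dec of year s-1 through
Jan of year s).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import InsufficientDataError, MissingSeasonError
from .gmrf import LatentDischarge
from .io_ingest import LimnoProfileRecord

logger = logging.getLogger(__name__)

DEFAULT_DEPTH_CUTOFF = 11.0  # m; chemocline depth in Lake Fryxell
RESPONSE_WINDOW = (10, 12)  # October .. December inclusive


@dataclass(frozen=True)
class SeasonalResponse:
    variable: str  # "ppr" | "chl"
    season_label: int  # calendar year of the Oct-Dec window
    y: float
    n_obs: int


@dataclass(frozen=True)
class LaggedDesignRow:
    """One regression row: response for season s, discharge curves for s-1."""

    response: SeasonalResponse
    covariates: dict[str, LatentDischarge]

    def __post_init__(self):
        for lat in self.covariates.values():
            if self.response.season_label - lat.season_label != 1:
                raise AssertionError(
                    "lag-1 violated: response %d vs covariate %d"
                    % (self.response.season_label, lat.season_label)
                )


def seasonal_response(
    profiles: Sequence[LimnoProfileRecord],
    variable: str,
    season_label: int,
    depth_cutoff: float = DEFAULT_DEPTH_CUTOFF,
) -> SeasonalResponse:
    """Oct–Dec above-chemocline mean of one variable for one season.

    Raises :class:`MissingSeasonError` when no measurement qualifies, so the
    caller can exclude the season from the design rather than zero-fill it.
    """
    if variable not in ("ppr", "chl"):
        raise ValueError("variable must be 'ppr' or 'chl'")
    lo, hi = RESPONSE_WINDOW
    vals = [
        getattr(r, variable)
        for r in profiles
        if r.date.year == season_label
        and lo <= r.date.month <= hi
        and r.depth <= depth_cutoff
        and getattr(r, variable) is not None
    ]
    if not vals:
        raise MissingSeasonError(
            f"no {variable} measurements for season {season_label}"
        )
    return SeasonalResponse(
        variable=variable,
        season_label=season_label,
        y=float(np.mean(vals)),
        n_obs=len(vals),
    )


def aggregate_seasons(
    profiles: Sequence[LimnoProfileRecord],
    variable: str,
    seasons: Iterable[int],
    depth_cutoff: float = DEFAULT_DEPTH_CUTOFF,
) -> dict[int, SeasonalResponse]:
    """Per-season responses; seasons with no qualifying data are logged out."""
    out: dict[int, SeasonalResponse] = {}
    for s in seasons:
        try:
            out[s] = seasonal_response(profiles, variable, s, depth_cutoff)
        except MissingSeasonError as e:
            logger.warning("aggregate_seasons: %s", e)
    return out


def build_lagged_design(
    responses: Mapping[int, SeasonalResponse],
    latents: Mapping[tuple[str, int], LatentDischarge],
    streams: Sequence[str],
    min_rows: int = 3,
) -> list[LaggedDesignRow]:
    """Pair each response season s with latent discharge season s-1.

    Rows are included only when the response and the lagged curve for every
    requested stream exist; fewer than ``min_rows`` complete rows raises
    :class:`InsufficientDataError`.
    """
    rows: list[LaggedDesignRow] = []
    for s in sorted(responses):
        covs = {}
        for stream in streams:
            lat = latents.get((stream, s - 1))
            if lat is None:
                break
            covs[stream] = lat
        else:
            rows.append(LaggedDesignRow(response=responses[s], covariates=covs))
            continue
        logger.info(
            "build_lagged_design: dropping season %d (missing lagged curve)", s
        )
    if len(rows) < min_rows:
        raise InsufficientDataError(
            f"only {len(rows)} complete design rows (< {min_rows})"
        )
    return rows
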