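"""Nightly covariate table and design-matrix construction.

Each night carries two environmental covariates: sea-surface temperature
(deg C) and the fraction of the moon illuminated (0 new to 1 full). The
design row for a bird-night is (1, sst, moon_fraction); SST is left on its
natural scale by default so fitted coefficients are directly interpretable
per deg C.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .logger_processing import NightObservation

logger = logging.getLogger(__name__)

SST_RANGE = (10.0, 35.0)  # plausible tropical-ocean bounds, deg C


class CovariateError(ValueError):
    pass


@dataclass(frozen=True)
class NightCovariates:
    """SST and moon fraction for one calendar night."""

    night_date: dt.date
    sst: float
    moon_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.moon_fraction <= 1.0:
            raise CovariateError(
                f"moon_fraction {self.moon_fraction} outside [0, 1] "
                f"on {self.night_date}"
            )
        lo, hi = SST_RANGE
        if not lo <= self.sst <= hi:
            raise CovariateError(
                f"sst {self.sst} outside physical range [{lo}, {hi}] "
                f"on {self.night_date}"
            )


@dataclass(frozen=True)
class ModelDataset:
    """Model-ready bird-night data: counts plus design rows.

    Arrays are aligned row-wise over bird-nights; ``X`` has columns
    (intercept, sst, moon_fraction) and ``bird_index`` maps each row to its
    position in ``bird_ids``.
    """

    bird_ids: tuple[str, ...]
    bird_index: np.ndarray  # (N,) int
    night_dates: tuple[dt.date, ...]
    y: np.ndarray  # (N,) int
    n: np.ndarray  # (N,) int
    X: np.ndarray  # (N, 3) float

    @property
    def n_birds(self) -> int:
        return len(self.bird_ids)

    @property
    def n_obs(self) -> int:
        return len(self.y)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bird_id": [self.bird_ids[i] for i in self.bird_index],
                "night_date": [d.isoformat() for d in self.night_dates],
                "y": self.y,
                "n": self.n,
                "sst_c": self.X[:, 1],
                "moon_fraction": self.X[:, 2],
            }
        )


def read_covariates(path) -> list[NightCovariates]:
    """Read the nightly covariate CSV ``date,sst_c,moon_fraction``.

    Missing dates are allowed (the join decides what to do with uncovered
    nights); out-of-range values raise `CovariateError`.
    """
    df = pd.read_csv(path)
    expected = ["date", "sst_c", "moon_fraction"]
    if list(df.columns) != expected:
        raise CovariateError(f"expected header {expected}, got {list(df.columns)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            NightCovariates(
                night_date=dt.date.fromisoformat(str(row.date)),
                sst=float(row.sst_c),
                moon_fraction=float(row.moon_fraction),
            )
        )
    return out


def write_covariates(covs: Iterable[NightCovariates], path) -> None:
    df = pd.DataFrame(
        {
            "date": [c.night_date.isoformat() for c in covs],
            "sst_c": [c.sst for c in covs],
            "moon_fraction": [c.moon_fraction for c in covs],
        }
    )
    df.to_csv(path, index=False)


def join_design(
    nights: Sequence[NightObservation],
    covs: Sequence[NightCovariates],
    policy: str = "drop",
    standardize_sst: bool = False,
) -> ModelDataset:
    """Pair each night observation with its design row (1, sst, moon).

    policy="drop" (default) discards nights whose date has no covariate row
    and logs how many were dropped; policy="interpolate" fills gaps by
    linear interpolation in time between surrounding covariate dates (gaps
    outside the covariate date range are still dropped).

    Raises
    ------
    CovariateError
        If the joined dataset is empty, or the policy is unknown.
    """
    if policy not in ("drop", "interpolate"):
        raise CovariateError(f"unknown missing-data policy {policy!r}")
    cov_map = {c.night_date: (c.sst, c.moon_fraction) for c in covs}
    if policy == "interpolate" and cov_map:
        dates = sorted(cov_map)
        t = np.array([d.toordinal() for d in dates], dtype=float)
        sst = np.array([cov_map[d][0] for d in dates])
        moon = np.array([cov_map[d][1] for d in dates])
        needed = {o.night_date for o in nights} - set(cov_map)
        for d in needed:
            o = d.toordinal()
            if t[0] <= o <= t[-1]:
                cov_map[d] = (
                    float(np.interp(o, t, sst)),
                    float(np.interp(o, t, moon)),
                )

    kept = [o for o in nights if o.night_date in cov_map]
    n_dropped = len(nights) - len(kept)
    if n_dropped:
        logger.info("join_design: %d night(s) dropped (no covariates)", n_dropped)
    if not kept:
        raise CovariateError("joined dataset is empty: no covariate cover")

    bird_ids = tuple(sorted({o.bird_id for o in kept}))
    idx = {b: i for i, b in enumerate(bird_ids)}
    X = np.array(
        [[1.0, cov_map[o.night_date][0], cov_map[o.night_date][1]] for o in kept]
    )
    if standardize_sst:
        mu, sd = X[:, 1].mean(), X[:, 1].std()
        if sd > 0:
            X[:, 1] = (X[:, 1] - mu) / sd
    return ModelDataset(
        bird_ids=bird_ids,
        bird_index=np.array([idx[o.bird_id] for o in kept], dtype=int),
        night_dates=tuple(o.night_date for o in kept),
        y=np.array([o.y for o in kept], dtype=int),
        n=np.array([o.n for o in kept], dtype=int),
        X=X,
    )
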