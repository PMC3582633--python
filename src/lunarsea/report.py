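"""Posterior summaries, posterior predictive bands, and study bookkeeping.

Population-level coefficients are summarised by posterior mean, SD and the
equal-tailed 95% credible interval; an effect is called significant when
that interval excludes zero. The posterior predictive distribution of the
nightly wet probability p propagates each retained draw of (mu_beta, Sigma)
through a fresh bird-level coefficient draw and the logit link.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .covariates import NightCovariates
from .logger_processing import (
    MAX_WET_COUNT,
    NIGHT_END,
    NIGHT_START,
    BlockRecord,
    assign_night,
)
from .model import PARAM_NAMES, PosteriorSamples, inv_logit


@dataclass(frozen=True)
class CoefficientSummary:
    parameter: str
    posterior_mean: float
    posterior_sd: float
    ci_lower: float
    ci_upper: float

    @property
    def excludes_zero(self) -> bool:
        return not (self.ci_lower <= 0.0 <= self.ci_upper)


@dataclass(frozen=True)
class PredictiveBand:
    """Posterior predictive mean and 95% band of p for one night."""

    night_date: dt.date
    mean_p: float
    ci_lower_p: float
    ci_upper_p: float

    def __post_init__(self) -> None:
        ok = 0.0 <= self.ci_lower_p <= self.mean_p <= self.ci_upper_p <= 1.0
        if not ok:
            raise ValueError(f"predictive band violates ordering: {self}")


def summarize_population(
    samples: PosteriorSamples, min_draws: int = 100
) -> list[CoefficientSummary]:
    """Posterior mean, SD and equal-tailed 95% CrI per mu_beta component."""
    draws = samples.mu_beta_draws
    if draws.shape[0] < min_draws:
        raise ValueError(
            f"need >= {min_draws} retained draws, got {draws.shape[0]}"
        )
    out = []
    for j, name in enumerate(PARAM_NAMES):
        col = draws[:, j]
        lo, hi = np.percentile(col, [2.5, 97.5])
        out.append(
            CoefficientSummary(
                parameter=name,
                posterior_mean=float(col.mean()),
                posterior_sd=float(col.std(ddof=1)),
                ci_lower=float(lo),
                ci_upper=float(hi),
            )
        )
    return out


def summary_to_frame(summaries: Sequence[CoefficientSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [s.parameter for s in summaries],
            "mean": [s.posterior_mean for s in summaries],
            "sd": [s.posterior_sd for s in summaries],
            "ci_low": [s.ci_lower for s in summaries],
            "ci_high": [s.ci_upper for s in summaries],
            "excludes_zero": [s.excludes_zero for s in summaries],
        }
    )


def posterior_predictive_p(
    samples: PosteriorSamples,
    covs: Sequence[NightCovariates],
    mode: str = "population",
    bird_id: str | None = None,
    seed: int = 0,
) -> list[PredictiveBand]:
    """Posterior predictive mean and 95% band of the wet probability p.

    mode="population" (default): for each retained draw, sample a new-bird
    coefficient vector beta* ~ MVN(mu_beta, Sigma) and evaluate
    p = inv_logit(x' beta*) for each night's design row -- the band for an
    exchangeable bird. mode="bird": use the stored beta_i draws of
    ``bird_id`` instead.
    """
    if mode not in ("population", "bird"):
        raise ValueError(f"unknown mode {mode!r}")
    X = np.array([[1.0, c.sst, c.moon_fraction] for c in covs])
    d = samples.n_draws
    if mode == "population":
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((d, 3))
        chols = np.linalg.cholesky(samples.sigma_draws)
        beta_star = samples.mu_beta_draws + np.einsum("dij,dj->di", chols, z)
    else:
        if bird_id is None or bird_id not in samples.bird_ids:
            raise KeyError(f"unknown bird_id {bird_id!r}")
        i = samples.bird_ids.index(bird_id)
        beta_star = samples.beta_draws[:, i, :]
    p = inv_logit(X @ beta_star.T)  # (nights, draws)
    lo, hi = np.percentile(p, [2.5, 97.5], axis=1)
    mean = p.mean(axis=1)
    return [
        PredictiveBand(c.night_date, float(mean[k]), float(lo[k]), float(hi[k]))
        for k, c in enumerate(covs)
    ]


def bands_to_frame(bands: Sequence[PredictiveBand]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "night_date": [b.night_date.isoformat() for b in bands],
            "mean_p": [b.mean_p for b in bands],
            "ci_lower_p": [b.ci_lower_p for b in bands],
            "ci_upper_p": [b.ci_upper_p for b in bands],
        }
    )


def export_actogram_matrix(records: Sequence[BlockRecord]) -> pd.DataFrame:
    """Night x block-of-night matrix of mean wet fraction across birds.

    Rows are nights (evening dates), columns the 72 ten-minute blocks from
    18:00 to 05:50; each cell is the mean wet_count/200 over all birds with
    that block observed. Daytime blocks are ignored.
    """
    cells: dict[tuple[dt.date, int], list[float]] = {}
    for rec in records:
        night = assign_night(rec.block_start, (NIGHT_START, NIGHT_END))
        if night is None:
            continue
        t = rec.block_start
        ref = dt.datetime.combine(night, NIGHT_START, tzinfo=t.tzinfo)
        block_of_night = int((t - ref).total_seconds() // 600)
        cells.setdefault((night, block_of_night), []).append(
            rec.wet_count / MAX_WET_COUNT
        )
    if not cells:
        raise ValueError("no night blocks in input")
    nights = sorted({k[0] for k in cells})
    mat = pd.DataFrame(
        np.nan, index=[d.isoformat() for d in nights], columns=range(72)
    )
    for (night, b), vals in cells.items():
        mat.loc[night.isoformat(), b] = float(np.mean(vals))
    return mat


def percent(numerator: int, denominator: int, ndigits: int = 0) -> float:
    """Percentage rounded for reporting (e.g. 46/50 -> 92.0, 37/45 -> 82.0)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * numerator / denominator, ndigits)


def deployment_summary(
    deployed: int, recovered: int, uploaded: int, breeding: int
) -> dict[str, float]:
    """Study bookkeeping: recovery, upload, and breeding-logger percentages."""
    return {
        "recovered_pct": percent(recovered, deployed),
        "uploaded_pct": percent(uploaded, recovered),
        "breeding_pct": percent(breeding, uploaded),
    }
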