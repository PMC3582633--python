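"""Synthetic immersion-logger and covariate data with known truth.

Generates block streams and nightly covariate tables with the statistical
structure the hierarchical model assumes: bird-level coefficient vectors
drawn from MVN(mu_beta, Sigma), nightly wet counts Binomial(14,400, p) with
logit(p) = x' beta_i, and block-level wet runs laid out so bout detection
has realistic structure. The generating truth is returned (and can be
serialised) so parameter-recovery studies are self-contained.

Defaults put the simulation on the scale of a tropical-seabird breeding
study: ~20 birds followed for ~180 nights, a 29.53-day raised-cosine lunar
cycle, and a slowly cooling SST series in the low-to-mid 20s deg C.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .covariates import NightCovariates
from .logger_processing import BLOCKS_PER_NIGHT, MAX_WET_COUNT, BlockRecord
from .model import inv_logit

SYNODIC_MONTH_DAYS = 29.53


class SimulationConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic deployment.

    true_mu_beta and true_sigma sit on the natural-units scale of the model
    (logit intercept; per deg C; per unit moon fraction).
    """

    n_birds: int = 20
    n_nights: int = 180
    true_mu_beta: tuple[float, float, float] = (-5.8, 0.04, -0.74)
    true_sigma: np.ndarray = field(
        default_factory=lambda: np.diag([0.25, 0.0004, 0.04])
    )
    lunar_period_days: float = SYNODIC_MONTH_DAYS
    sst_mean: float = 24.5
    sst_amplitude: float = 2.5
    sst_trend_per_day: float = -0.02
    sst_noise_sd: float = 0.3
    start_date: dt.date = dt.date(2010, 3, 1)
    seed: int = 0
    missing_block_rate: float = 0.0
    day_rest_rate: float = 0.0025
    include_daytime: bool = True
    tz_offset_hours: float = -6.0
    mean_bouts_per_wet_night: float = 3.0

    def __post_init__(self) -> None:
        if self.n_birds < 1 or self.n_nights < 1:
            raise SimulationConfigError("need n_birds >= 1 and n_nights >= 1")
        if self.lunar_period_days <= 0:
            raise SimulationConfigError("lunar period must be positive")
        sig = np.asarray(self.true_sigma, dtype=float)
        if sig.shape != (3, 3) or np.linalg.eigvalsh(sig).min() <= 0:
            raise SimulationConfigError("true_sigma must be 3x3 positive definite")
        object.__setattr__(self, "true_sigma", sig)
        if not 0.0 <= self.missing_block_rate <= 1.0:
            raise SimulationConfigError("missing_block_rate must be in [0, 1]")
        if not 0.0 <= self.day_rest_rate <= 1.0:
            raise SimulationConfigError("day_rest_rate must be in [0, 1]")


@dataclass(frozen=True)
class SimulationTruth:
    """The generating parameters and drawn quantities behind a dataset."""

    mu_beta: np.ndarray  # (3,)
    sigma: np.ndarray  # (3, 3)
    betas: np.ndarray  # (n_birds, 3)
    bird_ids: tuple[str, ...]
    night_y: pd.DataFrame  # bird_id, night_date, y, p

    def save(self, path) -> None:
        payload = {
            "mu_beta": self.mu_beta.tolist(),
            "sigma": self.sigma.tolist(),
            "betas": self.betas.tolist(),
            "bird_ids": list(self.bird_ids),
            "night_y": self.night_y.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def load(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            mu_beta=np.asarray(payload["mu_beta"]),
            sigma=np.asarray(payload["sigma"]),
            betas=np.asarray(payload["betas"]),
            bird_ids=tuple(payload["bird_ids"]),
            night_y=pd.DataFrame(payload["night_y"]),
        )


def night_dates(spec: SimulationSpec) -> list[dt.date]:
    return [spec.start_date + dt.timedelta(days=k) for k in range(spec.n_nights)]


def lunar_fraction(t, period: float = SYNODIC_MONTH_DAYS):
    """Raised-cosine moon-illumination fraction at t days past new moon.

    fraction(t) = (1 - cos(2 pi t / period)) / 2: 0 at new moon,
    1 at t = period/2 (full), period ~= 29.53 days (synodic month).
    """
    if period <= 0:
        raise SimulationConfigError("lunar period must be positive")
    t = np.asarray(t, dtype=float)
    frac = 0.5 * (1.0 - np.cos(2.0 * np.pi * t / period))
    return np.clip(frac, 0.0, 1.0)


def simulate_lunar_series(spec: SimulationSpec) -> pd.Series:
    """Nightly moon fraction, sampled from `lunar_fraction` at integer days
    with a new moon on the start date."""
    t = np.arange(spec.n_nights, dtype=float)
    frac = lunar_fraction(t, spec.lunar_period_days)
    return pd.Series(frac, index=night_dates(spec), name="moon_fraction")


def simulate_sst_series(
    spec: SimulationSpec, rng: np.random.Generator | None = None
) -> pd.Series:
    """Seasonal sinusoid + linear trend + Gaussian noise, seeded."""
    rng = rng or np.random.default_rng(spec.seed)
    t = np.arange(spec.n_nights, dtype=float)
    sst = (
        spec.sst_mean
        + spec.sst_amplitude * np.sin(2.0 * np.pi * t / 365.25)
        + spec.sst_trend_per_day * t
        + spec.sst_noise_sd * rng.standard_normal(spec.n_nights)
    )
    return pd.Series(sst, index=night_dates(spec), name="sst_c")


def build_covariates(
    spec: SimulationSpec, rng: np.random.Generator | None = None
) -> list[NightCovariates]:
    """Combined nightly covariate table for the simulated deployment."""
    moon = simulate_lunar_series(spec)
    sst = simulate_sst_series(spec, rng)
    return [
        NightCovariates(night_date=d, sst=float(sst[d]), moon_fraction=float(moon[d]))
        for d in night_dates(spec)
    ]


def simulate_deployment(
    spec: SimulationSpec,
) -> tuple[list[BlockRecord], list[NightCovariates], "SimulationTruth"]:
    """Generate one full deployment: block records, covariates, and truth.

    Uses a single seeded random stream so the covariates returned are
    exactly those the birds responded to.
    """
    rng = np.random.default_rng(spec.seed)
    covs = build_covariates(spec, rng)
    records, truth = simulate_birds(spec, covs, rng)
    return records, covs, truth


def _allocate_wet_blocks(
    y: int, rng: np.random.Generator, mean_bouts: float
) -> np.ndarray:
    """Lay a nightly total y out over 72 blocks as contiguous wet runs.

    Wet blocks are filled to 200 except one remainder block, grouped into a
    geometric number of bouts placed uniformly with dry gaps between them.
    The block sum always equals y exactly.
    """
    blocks = np.zeros(BLOCKS_PER_NIGHT, dtype=int)
    if y <= 0:
        return blocks
    full, rem = divmod(y, MAX_WET_COUNT)
    w = full + (1 if rem else 0)  # wet blocks needed
    counts = np.full(w, MAX_WET_COUNT)
    if rem:
        counts[-1] = rem
    max_bouts = min(w, BLOCKS_PER_NIGHT - w + 1)
    k = min(int(rng.geometric(min(1.0, 1.0 / mean_bouts))), max_bouts)
    # composition of w wet blocks into k runs
    if k > 1:
        cuts = np.sort(rng.choice(np.arange(1, w), size=k - 1, replace=False))
        run_lens = np.diff(np.concatenate(([0], cuts, [w])))
    else:
        run_lens = np.array([w])
    # dry gaps: k-1 interior gaps of >= 1 block, remainder spread uniformly
    extra = BLOCKS_PER_NIGHT - w - (k - 1)
    gap_extra = rng.multinomial(extra, np.full(k + 1, 1.0 / (k + 1)))
    pos = 0
    ci = 0
    for run, ge in zip(run_lens, gap_extra[:-1]):
        pos += ge if ci == 0 else ge + 1
        blocks[pos : pos + run] = counts[ci : ci + run]
        pos += run
        ci += run
    return blocks


def simulate_birds(
    spec: SimulationSpec,
    covariates: Sequence[NightCovariates] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[BlockRecord], SimulationTruth]:
    """Draw bird coefficients, nightly counts, and block-level records.

    beta_i ~ MVN(true_mu_beta, true_sigma); p_{i,t} = inv_logit(x' beta_i);
    y_{i,t} ~ Binomial(14,400, p_{i,t}), distributed over the night's 72
    blocks as contiguous wet runs. Blocks are then dropped independently at
    missing_block_rate. Daytime blocks (all dry, except rare rest-on-water
    days spent sitting on the sea surface) are emitted when
    ``include_daytime`` is set.
    """
    rng = rng or np.random.default_rng(spec.seed)
    if covariates is None:
        covariates = build_covariates(spec, rng)
    cov_map = {c.night_date: c for c in covariates}
    missing = [d for d in night_dates(spec) if d not in cov_map]
    if missing:
        raise SimulationConfigError(
            f"covariates do not cover {len(missing)} night(s), first {missing[0]}"
        )

    mu = np.asarray(spec.true_mu_beta, dtype=float)
    betas = rng.multivariate_normal(mu, spec.true_sigma, size=spec.n_birds)
    bird_ids = tuple(f"bird{i + 1:03d}" for i in range(spec.n_birds))
    tz = dt.timezone(dt.timedelta(hours=spec.tz_offset_hours))

    records: list[BlockRecord] = []
    rows: list[tuple[str, str, int, float]] = []
    for i, bird in enumerate(bird_ids):
        for d in night_dates(spec):
            c = cov_map[d]
            x = np.array([1.0, c.sst, c.moon_fraction])
            p = float(inv_logit(x @ betas[i]))
            y = int(rng.binomial(BLOCKS_PER_NIGHT * MAX_WET_COUNT, p))
            rows.append((bird, d.isoformat(), y, p))
            blocks = _allocate_wet_blocks(y, rng, spec.mean_bouts_per_wet_night)
            night_start = dt.datetime.combine(d, dt.time(18, 0), tzinfo=tz)
            keep = (
                rng.uniform(size=BLOCKS_PER_NIGHT) >= spec.missing_block_rate
                if spec.missing_block_rate > 0
                else np.ones(BLOCKS_PER_NIGHT, dtype=bool)
            )
            for b in range(BLOCKS_PER_NIGHT):
                if keep[b]:
                    records.append(
                        BlockRecord(
                            bird_id=bird,
                            block_start=night_start + dt.timedelta(minutes=10 * b),
                            wet_count=int(blocks[b]),
                        )
                    )
            if spec.include_daytime:
                rest_day = rng.uniform() < spec.day_rest_rate
                day_start = dt.datetime.combine(d, dt.time(6, 0), tzinfo=tz)
                day_counts = (
                    rng.integers(150, 201, size=BLOCKS_PER_NIGHT)
                    if rest_day
                    else np.zeros(BLOCKS_PER_NIGHT, dtype=int)
                )
                for b in range(BLOCKS_PER_NIGHT):
                    records.append(
                        BlockRecord(
                            bird_id=bird,
                            block_start=day_start + dt.timedelta(minutes=10 * b),
                            wet_count=int(day_counts[b]),
                        )
                    )

    records.sort(key=lambda r: (r.bird_id, r.block_start))
    truth = SimulationTruth(
        mu_beta=mu,
        sigma=spec.true_sigma.copy(),
        betas=betas,
        bird_ids=bird_ids,
        night_y=pd.DataFrame(rows, columns=["bird_id", "night_date", "y", "p"]),
    )
    return records, truth
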