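"""Growth-stage window covariates and their between-environment similarity.

The growth period of each trial record is tiled into ``n_pre`` equal-sized
stages from sowing to flowering and ``n_post`` from flowering to maturity
(30 = 10 + 20 by default). Daily weather is averaged within stages, stage
means are averaged over all records of an environment, and every
contiguous stage span (a, b) yields one covariate — S + S(S-1)/2 per
meteorological factor (465 for S = 30). The between-environment similarity
of a covariate is the rank-one linear kernel of its mean-centred values.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_config import RunConfig, check_weather_coverage

logger = logging.getLogger("ecgc")


# ---------------------------------------------------------------------------
# covariate ids

def covariate_id(factor: str, start_stage: int, end_stage: int) -> str:
    return f"{factor}_s{start_stage}_e{end_stage}"


_COV_RE = re.compile(r"^(?P<factor>.+)_s(?P<a>\d+)_e(?P<b>\d+)$")


def parse_covariate_id(cov_id: str) -> tuple[str, int, int]:
    m = _COV_RE.match(cov_id)
    if m is None:
        raise ValueError(f"malformed covariate id: {cov_id!r}")
    return m["factor"], int(m["a"]), int(m["b"])


# ---------------------------------------------------------------------------
# stage assignment

@dataclass
class StagePartition:
    """Day ranges of the 1..(n_pre+n_post) growth stages of one record.

    ``stages[s]`` is the DatetimeIndex of days in stage s+1. Stages tile
    [sowing, maturity] with no gaps or overlaps; the flowering day closes
    the last pre-flowering stage and the maturity day the last stage.
    """

    stages: list[pd.DatetimeIndex]
    n_pre: int
    n_post: int

    @property
    def n_stages(self) -> int:
        return self.n_pre + self.n_post


def _tile(days: pd.DatetimeIndex, n_blocks: int, label: str) -> list[pd.DatetimeIndex]:
    L = len(days)
    if L < n_blocks:
        raise ValueError(f"too few days: {label} period has {L} days for {n_blocks} stages")
    bounds = [int(np.floor(b * L / n_blocks)) for b in range(n_blocks + 1)]
    return [days[bounds[b]:bounds[b + 1]] for b in range(n_blocks)]


def assign_stages(sowing, flowering, maturity, n_pre: int, n_post: int) -> StagePartition:
    """Partition [sowing, maturity] into n_pre + n_post near-equal stages."""
    sowing, flowering, maturity = map(pd.Timestamp, (sowing, flowering, maturity))
    if not sowing < flowering < maturity:
        raise ValueError("require sowing < flowering < maturity")
    pre_days = pd.date_range(sowing, flowering, freq="D")
    post_days = pd.date_range(flowering + pd.Timedelta(days=1), maturity, freq="D")
    stages = _tile(pre_days, n_pre, "pre-flowering") + _tile(post_days, n_post, "post-flowering")
    return StagePartition(stages, n_pre, n_post)


def stage_means(daily: pd.Series, partition: StagePartition) -> np.ndarray:
    """Mean of a daily series (indexed by date) over each stage's days."""
    out = np.empty(partition.n_stages)
    for s, days in enumerate(partition.stages):
        try:
            vals = daily.loc[days]
        except KeyError as exc:
            raise ValueError(f"weather day missing in stage {s + 1}: {exc}") from exc
        out[s] = float(np.mean(vals.to_numpy()))
    return out


# ---------------------------------------------------------------------------
# covariate table

def span_covariates(means: np.ndarray) -> dict[tuple[int, int], float]:
    """All contiguous span means (a, b), 1-based inclusive, from stage means."""
    S = len(means)
    cum = np.concatenate([[0.0], np.cumsum(means)])
    out: dict[tuple[int, int], float] = {}
    for a in range(1, S + 1):
        for b in range(a, S + 1):
            out[(a, b)] = (cum[b] - cum[a - 1]) / (b - a + 1)
    return out


def build_covariate_table(trials: pd.DataFrame, weather: pd.DataFrame,
                          config: RunConfig,
                          factors: list[str] | None = None) -> pd.DataFrame:
    """Environments x covariates table of stage-span weather means.

    Stage means are computed per trial record (variety-year), averaged with
    equal weight over all records of the environment, then averaged over
    each contiguous stage span. Records lacking a phenology date are
    skipped; environments with no usable record are excluded with a
    warning.
    """
    if factors is None:
        factors = sorted(weather["factor"].unique())
    S = config.n_pre_stages + config.n_post_stages

    # per (environment, factor) daily series for O(1) lookups
    daily: dict[tuple[str, str], pd.Series] = {}
    for (env, fac), sub in weather.groupby(["environment_id", "factor"], sort=False):
        daily[(env, fac)] = sub.set_index("date")["value"].sort_index()

    rows = {}
    for env, recs in trials.groupby("environment_id", sort=True):
        sums = {fac: np.zeros(S) for fac in factors}
        n_used = 0
        complete = recs.dropna(subset=["sowing_date", "flowering_date", "maturity_date"])
        # records sharing a phenology have identical stage means; compute once
        pheno_counts = complete.groupby(
            ["sowing_date", "flowering_date", "maturity_date"]).size()
        for (sow, flw, mat), count in pheno_counts.items():
            part = assign_stages(sow, flw, mat,
                                 config.n_pre_stages, config.n_post_stages)
            for fac in factors:
                if (env, fac) not in daily:
                    check_weather_coverage(weather, env, sow, mat, fac)
                sums[fac] += count * stage_means(daily[(env, fac)], part)
            n_used += count
        if n_used == 0:
            logger.warning("environment %r has no record with complete phenology; excluded", env)
            continue
        row = {}
        for fac in factors:
            for (a, b), v in span_covariates(sums[fac] / n_used).items():
                row[covariate_id(fac, a, b)] = v
        rows[env] = row

    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "environment_id"
    expected = len(factors) * (S + S * (S - 1) // 2)
    assert table.shape[1] == expected, (table.shape, expected)
    return table


# ---------------------------------------------------------------------------
# photoperiod

def photoperiod(latitude_deg: float, date) -> float:
    """Astronomical daylength (sunrise to sunset) in hours.

    Uses the standard solar-declination approximation with a zero-elevation
    sun; valid outside the polar circles.
    """
    if abs(latitude_deg) >= 66.5:
        raise ValueError("photoperiod undefined at polar latitudes")
    doy = pd.Timestamp(date).dayofyear
    decl = -np.deg2rad(23.44) * np.cos(2 * np.pi * (doy + 10) / 365.2422)
    lat = np.deg2rad(latitude_deg)
    cos_h = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
    return float(24.0 / np.pi * np.arccos(cos_h))


# ---------------------------------------------------------------------------
# similarity

@dataclass
class SimilarityMatrix:
    """Rank-one linear-kernel similarity of one covariate across environments."""

    matrix: pd.DataFrame
    covariate: str
    degenerate: bool = False


def similarity_kernel(cov_table: pd.DataFrame, cov_id: str) -> SimilarityMatrix:
    """s_jk = (x_j - xbar)(x_k - xbar) over the environments in the table."""
    if cov_id not in cov_table.columns:
        raise KeyError(f"unknown covariate: {cov_id}")
    x = cov_table[cov_id].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("similarity kernel needs >= 3 environments")
    xc = x - x.mean()
    S = np.outer(xc, xc)
    degenerate = bool(np.allclose(xc, 0.0))
    ids = cov_table.index
    return SimilarityMatrix(pd.DataFrame(S, index=ids, columns=ids), cov_id, degenerate)


# ---------------------------------------------------------------------------
# phenotype cleaning

def mask_outliers(trials: pd.DataFrame, trait: str,
                  group_col: str = "environment_id") -> pd.DataFrame:
    """Set trait values strictly outside the per-group mean +/- 3 SD to missing.

    Groups with fewer than 3 non-missing values are left untouched. The SD
    uses the n-1 denominator; boundary values exactly at mean +/- 3 SD are
    kept.
    """
    out = trials.copy()
    for g, sub in out.groupby(group_col):
        vals = sub[trait].dropna()
        if len(vals) < 3:
            logger.info("group %r has <3 values for %s; outlier mask skipped", g, trait)
            continue
        mu, sd = vals.mean(), vals.std(ddof=1)
        lo, hi = mu - 3 * sd, mu + 3 * sd
        mask = sub[trait].notna() & ((sub[trait] < lo) | (sub[trait] > hi))
        if mask.any():
            out.loc[sub.index[mask], trait] = np.nan
    return out
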