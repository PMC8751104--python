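"""Run configuration, tabular input/output, RNG substreams and logging.

All tables travel as pandas DataFrames with documented column sets; square
matrices (GRMs, similarity and genetic-correlation matrices) are written as
CSV with ids on both axes so that write -> read round-trips are
value-identical.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("ecgc")

TRIAL_DATE_COLS = ["sowing_date", "flowering_date", "maturity_date"]
TRIAL_KEY_COLS = ["variety_id", "environment_id", "year"]
WEATHER_COLS = ["environment_id", "date", "factor", "value"]


@dataclass
class RunConfig:
    """Pipeline constants.

    Defaults encode the reference protocol: 10 pre-flowering and 20
    post-flowering growth stages, a strict MAF floor of 0.05, 0.05
    significance levels for the covariate scan (Bonferroni) and the GWAS
    (FDR), a 100-kb region-merging gap, and the 80% x 10 subsampling scheme
    with a "more than 4 hits" reliability rule.
    """

    n_pre_stages: int = 10
    n_post_stages: int = 20
    maf_min: float = 0.05
    scan_alpha: float = 0.05
    fdr_level: float = 0.05
    region_gap_bp: int = 100_000
    subsample_fraction: float = 0.8
    subsample_reps: int = 10
    subsample_min_count: int = 5
    rng_seed: int = 0
    reml_tol: float = 1e-8
    reml_max_iter: int = 200

    def __post_init__(self) -> None:
        for name in ("maf_min", "scan_alpha", "fdr_level", "subsample_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.n_pre_stages < 1 or self.n_post_stages < 1:
            raise ValueError("stage counts must be >= 1")
        if self.region_gap_bp <= 0:
            raise ValueError("region_gap_bp must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({f.name: getattr(self, f.name) for f in fields(self)}, fh)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Named RNG substream: one master seed, independent per-stage streams.

    The stage name is hashed with CRC32 so the stream depends only on the
    (seed, name) pair, never on call order.
    """
    key = zlib.crc32(stage.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


@dataclass
class GenotypeMatrix:
    """Allele-dose matrix (varieties x SNPs) with a physical marker map."""

    doses: pd.DataFrame  # index variety_id, columns snp ids; values in {0,1,2} or NaN
    snp_map: pd.DataFrame  # index snp id, columns chrom, bp

    def __post_init__(self) -> None:
        if self.doses.index.duplicated().any():
            dup = self.doses.index[self.doses.index.duplicated()][0]
            raise ValueError(f"duplicated variety id: {dup}")
        missing = [s for s in self.doses.columns if s not in self.snp_map.index]
        if missing:
            raise ValueError(f"SNPs absent from map: {missing[:5]}")
        self.snp_map = self.snp_map.loc[self.doses.columns]

    @property
    def n_varieties(self) -> int:
        return self.doses.shape[0]

    @property
    def n_snps(self) -> int:
        return self.doses.shape[1]

    @property
    def maf(self) -> pd.Series:
        p = self.doses.mean(axis=0) / 2.0
        return np.minimum(p, 1 - p)

    def sorted_by_position(self) -> "GenotypeMatrix":
        order = self.snp_map.sort_values(["chrom", "bp"]).index
        return GenotypeMatrix(self.doses[order], self.snp_map.loc[order])


def read_genotypes(path: str | Path, format: str = "csv",
                   map_path: str | Path | None = None) -> GenotypeMatrix:
    """Read genotypes from CSV (doses + side map) or VCF (GT dosage import)."""
    if format == "csv":
        return _read_genotypes_csv(path, map_path)
    if format == "vcf":
        return _read_genotypes_vcf(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def _read_genotypes_csv(path, map_path) -> GenotypeMatrix:
    doses = pd.read_csv(path, index_col=0)
    doses.index = doses.index.astype(str)
    vals = doses.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size and not np.isin(finite, [0.0, 1.0, 2.0]).all():
        bad = finite[~np.isin(finite, [0.0, 1.0, 2.0])][0]
        raise ValueError(f"invalid dose {bad!r}: doses must be 0, 1 or 2")
    if map_path is None:
        raise ValueError("map_path is required for CSV genotypes")
    snp_map = pd.read_csv(map_path, index_col=0)
    snp_map.index = snp_map.index.astype(str)
    if not {"chrom", "bp"} <= set(snp_map.columns):
        raise ValueError("marker map needs 'chrom' and 'bp' columns")
    return GenotypeMatrix(doses, snp_map[["chrom", "bp"]])


def _read_genotypes_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = [str(s) for s in vcf.samples]
    rows, ids, chroms, bps = [], [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            logger.warning("skipping non-biallelic record %s:%s", rec.CHROM, rec.POS)
            continue
        gts = np.asarray(rec.genotypes, dtype=object)
        dose = np.full(len(samples), np.nan)
        for i, g in enumerate(gts):
            a, b = g[0], g[1]
            if a >= 0 and b >= 0:
                dose[i] = a + b
        rows.append(dose)
        ids.append(rec.ID or f"{rec.CHROM}_{rec.POS}")
        chroms.append(str(rec.CHROM))
        bps.append(int(rec.POS))
    doses = pd.DataFrame(np.array(rows).T, index=samples, columns=ids)
    snp_map = pd.DataFrame({"chrom": chroms, "bp": bps}, index=ids)
    return GenotypeMatrix(doses, snp_map)


def write_genotypes(gm: GenotypeMatrix, path: str | Path, map_path: str | Path) -> None:
    gm.doses.to_csv(path)
    gm.snp_map.to_csv(map_path)


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read trial phenotype records; invalid phenology rows are dropped.

    Returns a TrialTable: variety_id, environment_id, year, the three
    phenology dates (datetime64, possibly NaT for maturity) and one column
    per trait.
    """
    df = pd.read_csv(path)
    required = TRIAL_KEY_COLS + TRIAL_DATE_COLS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    for c in TRIAL_DATE_COLS:
        df[c] = pd.to_datetime(df[c], format="ISO8601")
    bad = (df["flowering_date"] <= df["sowing_date"]) | (
        df["maturity_date"].notna() & (df["maturity_date"] <= df["flowering_date"])
    )
    if bad.any():
        logger.warning("excluding %d records with inconsistent phenology dates", int(bad.sum()))
        df = df[~bad]
    return df.reset_index(drop=True)


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    out = trials.copy()
    for c in TRIAL_DATE_COLS:
        out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_weather(path: str | Path) -> pd.DataFrame:
    """Read long-format daily weather: environment_id, date, factor, value."""
    df = pd.read_csv(path)
    missing = [c for c in WEATHER_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"weather table missing columns: {missing}")
    df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    dup = df.duplicated(subset=["environment_id", "date", "factor"])
    if dup.any():
        raise ValueError("duplicate (environment, date, factor) weather entries")
    return df


def write_weather(weather: pd.DataFrame, path: str | Path) -> None:
    out = weather.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def check_weather_coverage(weather: pd.DataFrame, environment_id: str,
                           start, end, factor: str) -> None:
    """Require a contiguous daily series for one factor over [start, end]."""
    sub = weather[(weather["environment_id"] == environment_id)
                  & (weather["factor"] == factor)]
    have = set(pd.to_datetime(sub["date"]))
    need = pd.date_range(start, end, freq="D")
    gaps = [d for d in need if d not in have]
    if gaps:
        raise ValueError(
            f"weather gap for environment {environment_id!r}, factor {factor!r}: "
            f"missing {gaps[0].date()}" + (f" and {len(gaps) - 1} more days" if len(gaps) > 1 else "")
        )


def read_square_matrix(path: str | Path) -> pd.DataFrame:
    m = pd.read_csv(path, index_col=0)
    m.index = m.index.astype(str)
    m.columns = m.columns.astype(str)
    if list(m.index) != list(m.columns):
        raise ValueError("square matrix CSV must have identical row/column ids")
    return m


def write_square_matrix(m: pd.DataFrame, path: str | Path) -> None:
    m.to_csv(path)
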