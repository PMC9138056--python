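"""Turn raw observation tables into model-ready series.

Covers lipid normalization of delta values (triggered by the C:N proxy for
lipid content), weight ratios relative to the diet-switch day, per-replicate
exponential growth rates, replicate-mean aggregation, and prey isotope
baselines.  Observation tables are plain CSV with columns::

    diet_group, replicate, day, dry_weight_mg, d13C, d15N, C_N

and prey tables ``prey, d13C, d15N`` (one row per measured sample, or means).
Missing values are empty fields.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import WeightRatio, growth_rate_k

logger = logging.getLogger("isoturn")

OBSERVATION_COLUMNS = ["diet_group", "replicate", "day", "dry_weight_mg", "d13C", "d15N", "C_N"]
PREY_COLUMNS = ["prey", "d13C", "d15N"]

#: C:N mass ratio above which tissue is lipid-rich enough to bias d13C.
CN_LIPID_THRESHOLD = 3.56


@dataclass(frozen=True)
class LipidNormalizationFactors:
    """Multiplicative lipid-normalization factors for one taxon.

    The factors are dimensionless scalars applied to the raw delta value
    (``delta_norm = f * delta_raw``).  This multiplicative convention is the
    one consistent with dimensionless factors; an additive-offset convention
    can be swapped in by supplying a custom normalizer (see docs/methods.md,
    which flags this convention choice prominently).
    """

    taxon: str
    f_d13c: float
    f_d15n: float

    def __post_init__(self) -> None:
        for f in (self.f_d13c, self.f_d15n):
            if not 0.5 < f < 2.0:
                raise ValueError(f"implausible lipid factor {f} for taxon {self.taxon!r}")

    def factor(self, isotope: str) -> float:
        if isotope == "d13C":
            return self.f_d13c
        if isotope == "d15N":
            return self.f_d15n
        raise KeyError(f"no lipid factor for taxon {self.taxon!r}, isotope {isotope!r}")


#: Internal conversion factors for the diet-switch study's three taxa.
DEFAULT_LIPID_FACTORS = {
    "copepod": LipidNormalizationFactors("copepod", f_d13c=0.940, f_d15n=1.370),
    "artemia": LipidNormalizationFactors("artemia", f_d13c=0.922, f_d15n=1.059),
    "seahorse": LipidNormalizationFactors("seahorse", f_d13c=0.903, f_d15n=1.019),
}


@dataclass
class PreyBaseline:
    """Mean +/- sd isotope values of one prey type (the diet end-member)."""

    prey: str
    d13c_mean: float
    d13c_sd: float
    d15n_mean: float
    d15n_sd: float

    def __post_init__(self) -> None:
        if self.d13c_sd < 0 or self.d15n_sd < 0:
            raise ValueError("standard deviations must be >= 0")

    def mean(self, isotope: str) -> float:
        return self.d13c_mean if isotope == "d13C" else self.d15n_mean


def needs_lipid_correction(c_n: float) -> bool:
    """True when the C:N mass ratio indicates lipid-rich tissue (C:N > 3.56)."""
    if c_n <= 0:
        raise ValueError(f"C:N ratio must be positive; got {c_n}")
    return c_n > CN_LIPID_THRESHOLD


def lipid_normalize(
    delta_raw: float,
    taxon: str,
    isotope: str,
    factors: dict[str, LipidNormalizationFactors] | None = None,
) -> float:
    """Lipid-normalized delta value: ``factor(taxon, isotope) * delta_raw``."""
    factors = DEFAULT_LIPID_FACTORS if factors is None else factors
    if taxon not in factors:
        raise KeyError(f"no lipid-normalization factor for taxon {taxon!r}, isotope {isotope!r}")
    return factors[taxon].factor(isotope) * delta_raw


def apply_lipid_normalization(
    obs: pd.DataFrame,
    taxon: str = "seahorse",
    factors: dict[str, LipidNormalizationFactors] | None = None,
) -> pd.DataFrame:
    """Normalize d13C/d15N in an observation table where C:N flags lipid bias.

    Rows with C:N <= 3.56 pass through unchanged, mirroring a correction
    applied only where the lipid proxy demands it.
    """
    out = obs.copy()
    mask = out["C_N"].map(needs_lipid_correction)
    n = int(mask.sum())
    if n:
        logger.info("lipid-normalizing %d/%d observations (C:N > %.2f)", n, len(out), CN_LIPID_THRESHOLD)
    for iso in ("d13C", "d15N"):
        out.loc[mask, iso] = [
            lipid_normalize(v, taxon, iso, factors) for v in out.loc[mask, iso]
        ]
    return out


# --- weight ratios and growth rates ------------------------------------------

def _weight_at(series: pd.DataFrame, day: float) -> float:
    rows = series.loc[series["day"] == day, "dry_weight_mg"]
    if rows.empty:
        raise ValueError(f"no observation at day {day}; weights are not imputed")
    return float(rows.mean())


def weight_ratios(series: pd.DataFrame, switch_day: float) -> list[WeightRatio]:
    """Weight ratios ``W_t / W_i`` for each observation at or after the switch.

    ``series`` holds one replicate's (or the replicate-mean) observations; an
    observation must exist at ``switch_day`` (the ratio is exactly 1 there).
    """
    w_i = _weight_at(series, switch_day)
    post = series.loc[series["day"] >= switch_day].sort_values("day")
    return [WeightRatio(w_i=w_i, w_t=float(w)) for w in post["dry_weight_mg"]]


def replicate_growth_rate(series: pd.DataFrame, switch_day: float, final_day: float) -> float:
    """Endpoint growth rate ``k = ln(W_final / W_switch) / (final - switch)``.

    Uses only the two endpoint weights, not a regression through all days;
    see :func:`regression_growth_rate` for the alternative.
    """
    w_i = _weight_at(series, switch_day)
    w_t = _weight_at(series, final_day)
    return growth_rate_k(w_i, w_t, final_day - switch_day)


def regression_growth_rate(series: pd.DataFrame, switch_day: float) -> float:
    """Growth rate from an OLS fit of ln(weight) on day (optional alternative)."""
    post = series.loc[series["day"] >= switch_day]
    if post["day"].nunique() < 2:
        raise ValueError("need at least two distinct days for a regression growth rate")
    slope, _ = np.polyfit(post["day"].to_numpy(float), np.log(post["dry_weight_mg"].to_numpy(float)), 1)
    return float(slope)


def replicate_means(obs: pd.DataFrame) -> pd.DataFrame:
    """Average observations across replicates per (diet_group, day).

    Models are fitted per diet group on these replicate means; the growth
    rate entering model D is the mean of per-replicate endpoint rates.
    """
    return (
        obs.groupby(["diet_group", "day"], as_index=False)[["dry_weight_mg", "d13C", "d15N", "C_N"]]
        .mean()
        .sort_values(["diet_group", "day"], ignore_index=True)
    )


def mean_growth_rate(obs: pd.DataFrame, diet: str, switch_day: float, final_day: float) -> float:
    """Mean of per-replicate endpoint growth rates for one diet group."""
    sub = obs.loc[obs["diet_group"] == diet]
    ks = [
        replicate_growth_rate(rep_df, switch_day, final_day)
        for _, rep_df in sub.groupby("replicate")
    ]
    if not ks:
        raise ValueError(f"no observations for diet group {diet!r}")
    return float(np.mean(ks))


# --- I/O ----------------------------------------------------------------------

def read_observations(path) -> pd.DataFrame:
    """Read an observation CSV, checking the schema."""
    obs = pd.read_csv(path)
    missing = [c for c in OBSERVATION_COLUMNS if c not in obs.columns]
    if missing:
        raise ValueError(f"observation table missing columns: {missing}")
    bad = obs.loc[(obs["day"] < 0) | (obs["dry_weight_mg"] <= 0) | (obs["C_N"] <= 0)]
    if not bad.empty:
        raise ValueError(f"{len(bad)} observation rows violate day>=0, weight>0, C:N>0")
    return obs


def read_prey(path) -> pd.DataFrame:
    prey = pd.read_csv(path)
    missing = [c for c in PREY_COLUMNS if c not in prey.columns]
    if missing:
        raise ValueError(f"prey table missing columns: {missing}")
    return prey


def prey_baseline(prey: pd.DataFrame, name: str) -> PreyBaseline:
    """Mean +/- sd baseline for one prey type from a prey table.

    A single-row table yields sd = 0 (means were supplied directly).
    """
    sub = prey.loc[prey["prey"] == name]
    if sub.empty:
        raise ValueError(f"prey table has no rows for prey {name!r}")
    def _sd(col):
        return 0.0 if len(sub) < 2 else float(sub[col].std(ddof=1))
    return PreyBaseline(
        prey=name,
        d13c_mean=float(sub["d13C"].mean()),
        d13c_sd=_sd("d13C"),
        d15n_mean=float(sub["d15N"].mean()),
        d15n_sd=_sd("d15N"),
    )
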