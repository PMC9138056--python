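"""Simulated diet-switch experiments with known ground truth.

The generator emulates the juvenile-seahorse diet-switch design: two diet
groups switched from copepods to *Artemia* at day 6 (A6) or day 11 (A11)
after pouch release, two replicate tanks per diet, pooled tissue samples at
fixed sampling days, near-exponential dry-weight growth, and isotope
relaxation toward diet equilibrium following the time-based model
``delta(t) = delta_eq + a * exp(-(m + k) t)`` with i.i.d. Gaussian
analytical noise on delta.  Under exponential growth this forward process is
exactly the growth-based model as well, with ``c = -(m + k) / k``, so one
truth set implies both models' parameters.

Randomness is fully reproducible: one root seed, with per-replicate streams
derived deterministically (adding a replicate never perturbs existing ones).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import reference
from .preprocessing import OBSERVATION_COLUMNS

logger = logging.getLogger("isoturn")

ISOTOPES = ("d13C", "d15N")


@dataclass
class DietTruth:
    """Ground-truth kinetics for one diet group.

    ``delta_init`` is the tissue value at the switch day (tissue in
    equilibrium with the pre-switch copepod diet); the model offset is
    ``a = delta_init - delta_eq``.
    """

    label: str
    switch_day: int
    w0_mg: float                 # dry weight at the switch (mg)
    k: float                     # exponential growth rate (per day)
    delta_eq: dict[str, float]   # per isotope, permil
    m: dict[str, float]          # metabolic constant per isotope, per day
    delta_init: dict[str, float]

    def a(self, isotope: str) -> float:
        return self.delta_init[isotope] - self.delta_eq[isotope]

    def c(self, isotope: str) -> float:
        """Growth-model decay constant implied by exponential growth."""
        return -(self.m[isotope] + self.k) / self.k


@dataclass
class ExperimentConfig:
    """Full specification of a simulated diet-switch experiment."""

    diets: list[DietTruth]
    sampling_days: tuple[int, ...] = reference.SAMPLING_DAYS
    replicates_per_diet: int = 2
    n_pooled: int = 4            # individuals pooled per tank sample (metadata)
    noise_sd: float = reference.ANALYTICAL_SD   # permil, 1-sigma analytical
    weight_cv: float = 0.15      # lognormal tank-level weight variation
    seed: int = 0

    def __post_init__(self) -> None:
        self.sampling_days = tuple(int(d) for d in self.sampling_days)
        if list(self.sampling_days) != sorted(set(self.sampling_days)):
            raise ValueError("sampling_days must be sorted ascending without duplicates")
        if self.noise_sd < 0 or self.weight_cv < 0:
            raise ValueError("noise_sd and weight_cv must be >= 0")
        if self.replicates_per_diet < 1:
            raise ValueError("need at least one replicate per diet")
        for diet in self.diets:
            if diet.switch_day not in self.sampling_days:
                raise ValueError(
                    f"switch day {diet.switch_day} of diet {diet.label!r} not a sampling day"
                )

    def diet(self, label: str) -> DietTruth:
        for d in self.diets:
            if d.label == label:
                return d
        raise KeyError(f"no diet labelled {label!r}")

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["sampling_days"] = list(self.sampling_days)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        doc["diets"] = [DietTruth(**d) for d in doc["diets"]]
        return cls(**doc)


@dataclass
class SyntheticExperiment:
    """Generated observations plus the truth that produced them."""

    observations: pd.DataFrame
    truth: ExperimentConfig
    prey: pd.DataFrame = field(repr=False, default=None)


def paper_default_config(seed: int = 0, noise_sd: float | None = None,
                         weight_cv: float | None = None) -> ExperimentConfig:
    """Default configuration reproducing the study's mean trajectories.

    Switch days 6/11, sampling at {6, 11, 18, 25, 32, 46, 60} DAR, initial
    dry weights 0.80/2.20 mg, endpoint growth rates derived from the reported
    mean weights, equilibrium values and metabolic constants from the
    time-based model estimates, and switch-day tissue values set to the
    copepod baseline plus the diet's discrimination factor (tissue assumed in
    equilibrium with copepods before the switch).
    """
    diets = []
    for label in reference.DIETS:
        switch = reference.SWITCH_DAY[label]
        k = reference.reference_growth_rate(label)
        delta_eq = {iso: reference.MODEL_D_ESTIMATES[(label, iso)]["delta_eq"] for iso in ISOTOPES}
        m = {iso: reference.MODEL_D_ESTIMATES[(label, iso)]["m"] for iso in ISOTOPES}
        delta_init = {
            iso: reference.PREY_VALUES["copepod"][iso][0]
            + (delta_eq[iso] - reference.ARTEMIA_BASELINE[iso])
            for iso in ISOTOPES
        }
        diets.append(
            DietTruth(
                label=label,
                switch_day=switch,
                w0_mg=reference.MEAN_DRY_WEIGHT_MG[label][switch],
                k=k,
                delta_eq=delta_eq,
                m=m,
                delta_init=delta_init,
            )
        )
    kwargs = {}
    if noise_sd is not None:
        kwargs["noise_sd"] = noise_sd
    if weight_cv is not None:
        kwargs["weight_cv"] = weight_cv
    return ExperimentConfig(diets=diets, seed=seed, **kwargs)


# --- simulation ---------------------------------------------------------------

def _replicate_rng(config: ExperimentConfig, diet_index: int, replicate: int, stream: int):
    """Deterministic per-replicate RNG stream (stream 0: weights, 1: isotopes)."""
    return np.random.default_rng([config.seed, diet_index, replicate, stream])


def diet_sampling_days(config: ExperimentConfig, diet: DietTruth) -> np.ndarray:
    """Sampling days at or after the diet's switch day."""
    return np.array([d for d in config.sampling_days if d >= diet.switch_day], dtype=float)


def simulate_growth(config: ExperimentConfig, diet: DietTruth, rng) -> np.ndarray:
    """Dry weights (mg) per sampling day for one replicate tank.

    ``W(day) = w0 * exp(k (day - switch)) * lognormal(0, weight_cv)``.
    """
    days = diet_sampling_days(config, diet)
    w = diet.w0_mg * np.exp(diet.k * (days - diet.switch_day))
    if config.weight_cv > 0:
        w = w * rng.lognormal(0.0, config.weight_cv, size=days.size)
    return w


def simulate_isotopes(config: ExperimentConfig, diet: DietTruth, rng) -> dict[str, np.ndarray]:
    """Delta values (permil) per sampling day for one replicate tank.

    ``delta(day) = delta_eq + a * exp(-(m + k)(day - switch)) + N(0, noise_sd)``.
    """
    days = diet_sampling_days(config, diet)
    t = days - diet.switch_day
    out = {}
    for iso in ISOTOPES:
        clean = diet.delta_eq[iso] + diet.a(iso) * np.exp(-(diet.m[iso] + diet.k) * t)
        noise = rng.normal(0.0, config.noise_sd, size=t.size) if config.noise_sd > 0 else 0.0
        out[iso] = clean + noise
    return out


def _cn_series(diet: DietTruth, days: np.ndarray) -> np.ndarray:
    ref = reference.MEAN_CN.get(diet.label, {})
    # fall back to a generic post-switch decline when the day is not tabulated
    return np.array([ref.get(int(d), 3.0 + 2.7 * math.exp(-0.5 * (d - diet.switch_day))) for d in days])


def simulate_experiment(config: ExperimentConfig, raw_measurements: bool = True) -> SyntheticExperiment:
    """Generate a complete experiment: observations table plus prey baselines.

    With ``raw_measurements=True`` (default) the delta columns emulate what
    the mass spectrometer reports for lipid-rich samples: wherever C:N
    exceeds the lipid threshold the tissue-model value is divided by the
    taxon's lipid-normalization factor, so the preprocessing stage's
    normalization recovers the model value exactly.  With ``False`` the
    deltas are the already-normalized model values.
    """
    from .preprocessing import DEFAULT_LIPID_FACTORS, needs_lipid_correction

    rows = []
    for di, diet in enumerate(config.diets):
        days = diet_sampling_days(config, diet)
        cn = _cn_series(diet, days)
        for rep in range(1, config.replicates_per_diet + 1):
            w = simulate_growth(config, diet, _replicate_rng(config, di, rep, 0))
            deltas = simulate_isotopes(config, diet, _replicate_rng(config, di, rep, 1))
            for j, day in enumerate(days):
                row = {
                    "diet_group": diet.label,
                    "replicate": rep,
                    "day": int(day),
                    "dry_weight_mg": w[j],
                    "d13C": deltas["d13C"][j],
                    "d15N": deltas["d15N"][j],
                    "C_N": cn[j],
                }
                if raw_measurements and needs_lipid_correction(cn[j]):
                    factors = DEFAULT_LIPID_FACTORS["seahorse"]
                    row["d13C"] /= factors.f_d13c
                    row["d15N"] /= factors.f_d15n
                rows.append(row)
    obs = pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)
    prey = pd.DataFrame(
        [
            {"prey": "copepod",
             "d13C": reference.PREY_VALUES["copepod"]["d13C"][0],
             "d15N": reference.PREY_VALUES["copepod"]["d15N"][0]},
            {"prey": "artemia",
             "d13C": reference.ARTEMIA_BASELINE["d13C"],
             "d15N": reference.ARTEMIA_BASELINE["d15N"]},
        ]
    )
    logger.info(
        "simulated %d observations (%d diets x %d replicates), noise_sd=%.3f, weight_cv=%.3f, seed=%s",
        len(obs), len(config.diets), config.replicates_per_diet,
        config.noise_sd, config.weight_cv, config.seed,
    )
    return SyntheticExperiment(observations=obs, truth=config, prey=prey)


def write_experiment(exp: SyntheticExperiment, obs_path, prey_path=None, config_path=None) -> None:
    """Write observations (and optionally prey/config) in the pipeline's CSV schema."""
    exp.observations.to_csv(obs_path, index=False)
    if prey_path is not None:
        exp.prey.to_csv(prey_path, index=False)
    if config_path is not None:
        exp.truth.to_yaml(config_path)
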