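"""Seeded synthetic cohorts emulating an OA knee-imaging feature table.

Each cohort row carries the three osteoarthritis risk factors (age, gender,
BMI), nine serum adipokine / inflammatory-factor concentrations, and an
infrapatellar fat pad (IPFP) volume target in mm³.  The target is generated
from a known ("planted") linear model in gender, BMI, age and one biomarker
ratio, plus Gaussian noise, so that downstream variable selection and
regression can be validated against a recoverable truth.

Structural choices mirror the cohort the analysis assumes:

* age uniform on [45, 79] years;
* gender Bernoulli, coded 0 = female, 1 = male, with a male-majority default
  split (290 F / 388 M out of 678);
* BMI a two-component normal mixture straddling the 30 kg/m² obesity cut so
  both High-BMI and Low-BMI strata are populated roughly equally;
* biomarkers log-normal (strictly positive, right-skewed, coefficient of
  variation ≈ 0.5 by default) with a planted correlation between the two
  adiponectin isoforms (HMW and LMW) induced on the log scale;
* males receive a positive IPFP-volume offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Canonical biomarker order used for feature construction everywhere.
BIOMARKERS: tuple[str, ...] = (
    "adiponectin_HMW",
    "adiponectin_LMW",
    "adipsin",
    "chemerin",
    "leptin",
    "visfatin",
    "CRP",
    "IL8",
    "MCP1",
)

#: Cohort CSV column order (the documented header).
COHORT_COLUMNS: tuple[str, ...] = (
    ("subject_id", "age", "gender", "bmi") + BIOMARKERS + ("ipfp_volume",)
)

# Default log-scale parameters: medians are plausible serum concentrations
# (assay units differ per analyte); log-sd 0.472 gives CV ≈ 0.5.
_LOG_SD = 0.472
DEFAULT_BIOMARKER_PARAMS: dict[str, tuple[float, float]] = {
    "adiponectin_HMW": (np.log(2.0), _LOG_SD),
    "adiponectin_LMW": (np.log(3.0), _LOG_SD),
    "adipsin": (np.log(4.0), _LOG_SD),
    "chemerin": (np.log(150.0), _LOG_SD),
    "leptin": (np.log(15.0), _LOG_SD),
    "visfatin": (np.log(2.0), _LOG_SD),
    "CRP": (np.log(3.0), _LOG_SD),
    "IL8": (np.log(8.0), _LOG_SD),
    "MCP1": (np.log(200.0), _LOG_SD),
}


@dataclass(frozen=True)
class EffectCoefs:
    """Coefficients of the planted IPFP-volume generator.

    Units: intercept and gender effect in mm³; bmi_slope mm³ per kg/m²;
    age_slope mm³ per year; ratio_effect mm³ per unit of the planted ratio.
    """

    intercept: float = 20000.0
    gender_effect: float = 7000.0  # added for males (code 1)
    bmi_slope: float = 250.0
    age_slope: float = -50.0
    ratio_effect: float = 1500.0


@dataclass(frozen=True)
class CohortSpec:
    """Full specification of a synthetic cohort draw."""

    n_subjects: int = 678
    female_fraction: float = 290 / 678
    age_range: tuple[float, float] = (45.0, 79.0)
    # ((low-BMI mean, sd), (high-BMI mean, sd), weight of the high component)
    bmi_params: tuple[tuple[float, float], tuple[float, float], float] = (
        (26.5, 2.5),
        (34.0, 3.0),
        0.5,
    )
    biomarker_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BIOMARKER_PARAMS)
    )
    adiponectin_hmw_lmw_corr: float = 0.58
    effect_coefs: EffectCoefs = EffectCoefs()
    #: (numerator, denominator) biomarkers of the planted ratio.
    ratio_feature: tuple[str, str] = ("adipsin", "CRP")
    #: Extra mm³-per-ratio-unit effect applied to males only; 0 disables the
    #: gender×ratio interaction used by the gender-separation study.
    gender_ratio_interaction: float = 0.0
    noise_sd: float = 1500.0
    seed: int = 0
    id_prefix: str = "OAI"

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError(f"n_subjects must be positive, got {self.n_subjects}")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must lie in [0, 1]")
        if not -1.0 <= self.adiponectin_hmw_lmw_corr <= 1.0:
            raise ValueError("adiponectin_hmw_lmw_corr must lie in [-1, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be increasing")
        missing = set(BIOMARKERS) - set(self.biomarker_params)
        if missing:
            raise ValueError(f"biomarker_params missing entries for {sorted(missing)}")
        for name in self.ratio_feature:
            if name not in BIOMARKERS:
                raise ValueError(f"unknown ratio biomarker {name!r}")


def _draw_biomarkers(spec: CohortSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Log-normal draws; HMW/LMW adiponectin share a latent Gaussian factor."""
    n = spec.n_subjects
    rho = spec.adiponectin_hmw_lmw_corr
    # Correlate the two isoforms on the log scale via a 2x2 Cholesky factor;
    # all other biomarkers are independent.
    z_shared = rng.standard_normal(n)
    z_hmw = z_shared
    z_lmw = rho * z_shared + np.sqrt(max(0.0, 1.0 - rho * rho)) * rng.standard_normal(n)
    out: dict[str, np.ndarray] = {}
    for name in BIOMARKERS:
        mu, sd = spec.biomarker_params[name]
        if name == "adiponectin_HMW":
            z = z_hmw
        elif name == "adiponectin_LMW":
            z = z_lmw
        else:
            z = rng.standard_normal(n)
        out[name] = np.exp(mu + sd * z)
    return out


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one cohort table; deterministic for a fixed ``spec.seed``.

    Returns a DataFrame with columns :data:`COHORT_COLUMNS`; gender is coded
    0 = female, 1 = male, and ``ipfp_volume`` follows the planted linear
    model plus N(0, noise_sd²) noise.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects

    gender = (rng.random(n) >= spec.female_fraction).astype(int)  # 1 = male
    age = rng.uniform(spec.age_range[0], spec.age_range[1], size=n)

    (lo_mu, lo_sd), (hi_mu, hi_sd), w_hi = spec.bmi_params
    is_high = rng.random(n) < w_hi
    bmi = np.where(
        is_high,
        rng.normal(hi_mu, hi_sd, size=n),
        rng.normal(lo_mu, lo_sd, size=n),
    )
    bmi = np.clip(bmi, 15.0, None)

    biomarkers = _draw_biomarkers(spec, rng)
    num, den = spec.ratio_feature
    ratio = biomarkers[num] / biomarkers[den]

    ec = spec.effect_coefs
    volume = (
        ec.intercept
        + ec.gender_effect * gender
        + ec.bmi_slope * bmi
        + ec.age_slope * age
        + ec.ratio_effect * ratio
        + spec.gender_ratio_interaction * gender * ratio
        + spec.noise_sd * rng.standard_normal(n)
    )
    if np.any(volume <= 0):
        warnings.warn(
            "planted generator produced non-positive IPFP volumes; clipping",
            RuntimeWarning,
            stacklevel=2,
        )
        volume = np.clip(volume, 1.0, None)

    table = pd.DataFrame(
        {
            "subject_id": [f"{spec.id_prefix}{spec.seed}-{i:05d}" for i in range(n)],
            "age": age,
            "gender": gender,
            "bmi": bmi,
            **biomarkers,
            "ipfp_volume": volume,
        }
    )
    return table[list(COHORT_COLUMNS)]


def generate_validation_cohort(spec: CohortSpec | None = None, **overrides) -> pd.DataFrame:
    """Held-out external cohort: smaller, female-majority, higher-severity BMI.

    Defaults emulate an 80-patient clinical-trial cohort (57 F / 23 M) with a
    BMI profile shifted upward relative to the training cohort.  The planted
    volume generator is shared with :func:`generate_cohort` so transfer is
    well defined.  Never use these rows for training.
    """
    base = spec if spec is not None else CohortSpec()
    (lo, hi, w) = base.bmi_params
    shifted_bmi = ((lo[0] + 2.0, lo[1]), (hi[0] + 2.0, hi[1]), w)
    defaults = dict(
        n_subjects=80,
        female_fraction=57 / 80,
        bmi_params=shifted_bmi,
        id_prefix="EXT",
    )
    defaults.update(overrides)
    return generate_cohort(replace(base, **defaults))


def cohort_to_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, enforcing the documented header and invariants."""
    table = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    if table[list(COHORT_COLUMNS[1:])].isna().any().any():
        raise ValueError("cohort CSV contains missing values")
    if not set(table["gender"].unique()) <= {0, 1}:
        raise ValueError("gender must be coded 0 (female) / 1 (male)")
    if (table["ipfp_volume"] <= 0).any():
        raise ValueError("ipfp_volume must be positive")
    return table[list(COHORT_COLUMNS)]
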