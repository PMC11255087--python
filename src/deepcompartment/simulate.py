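"""Virtual haemophilia-A pharmacokinetic studies.

Generates complete simulated FVIII studies with the structure of a sparse
post-dose sampling design: a male demographic population (age, height, weight,
derived fat-free mass), individual two-compartment PK parameters with
lognormal inter-individual variability on CL and V1 (Q and V2 fixed across
subjects), weight-based bolus dosing (50 IU/kg rounded to the nearest 250 IU),
three irregular sampling times drawn around 4, 24 and 48 h and truncated at
0.25 h, and additive Gaussian measurement noise (sigma = 5 IU/dL).

The demographic distributions emulate a male survey population (the study is
self-contained: no external survey download); they are configuration, not
data, and are documented as approximations in the methods note.  The
ground-truth structural model is likewise configurable; its defaults are
plausible FVIII values:

    CL = 0.15 * (FFM/56)^0.75 L/h     V1 = 3.0 * (FFM/56) L
    Q  = 0.15 L/h                      V2 = 0.6 L

with omega_CL = 0.3 and omega_V1 = 0.2 on the log scale.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data import Dataset, Subject
from .exceptions import DataError, InvalidParameterError
from .pk import ConcentrationCurve, DoseRegimen, PKParameters, conc_events

#: Default evaluation grid: five-minute intervals from 0 to 72 h (865 points).
DEFAULT_GRID = np.arange(0, 72 * 12 + 1) / 12.0

# Piecewise-linear median growth curve (age in years -> height in cm) for a
# male population, with knots spanning toddler to adult ages.
_HEIGHT_KNOTS_AGE = np.array([2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0, 18.0, 80.0])
_HEIGHT_KNOTS_CM = np.array([87.0, 102.0, 115.0, 127.0, 138.0, 149.0, 163.0, 173.0,
                             176.0, 176.0])
# BMI floor and median-offset knots (shifted-lognormal BMI by age).
_BMI_FLOOR_AGE = np.array([2.0, 10.0, 18.0, 80.0])
_BMI_FLOOR = np.array([13.5, 14.0, 17.0, 17.0])
_BMI_OFFSET = np.array([2.5, 3.5, 9.0, 9.0])


def fat_free_mass(weight: float, height_cm: float, age: float) -> float:
    """Fat-free mass (kg) from weight (kg), height (cm) and age (years).

    FFM = (0.88 + 0.12 / (1 + (age/13.4)^-12.7)) * 9270 W / (6680 + 216 BMI)
    with BMI = weight / height_m^2.  The first factor is a maturation term
    rising from 0.88 in young children to 1 in adults (midpoint at 13.4 y).
    """
    weight = np.asarray(weight, dtype=float)
    height_cm = np.asarray(height_cm, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(weight <= 0) or np.any(height_cm <= 0) or np.any(age <= 0):
        raise InvalidParameterError(
            "weight, height and age must all be strictly positive"
        )
    bmi = weight / (height_cm / 100.0) ** 2
    maturation = 0.88 + (1.0 - 0.88) / (1.0 + (age / 13.4) ** -12.7)
    return maturation * (9270.0 * weight) / (6680.0 + 216.0 * bmi)


@dataclass(frozen=True)
class DoseRule:
    """Weight-based dosing: per_kg IU/kg rounded to the nearest quantum IU."""

    per_kg: float = 50.0
    quantum: float = 250.0


def assign_dose(weight: float, rule: DoseRule = DoseRule()) -> float:
    """Round(weight * per_kg / quantum) * quantum, half away from zero."""
    if np.any(np.asarray(weight) <= 0):
        raise InvalidParameterError("weight must be strictly positive")
    raw = np.asarray(weight, dtype=float) * rule.per_kg / rule.quantum
    return np.floor(raw + 0.5) * rule.quantum


@dataclass
class PopulationConfig:
    """Everything the study generator needs, with study-design defaults."""

    n: int = 756
    seed: int = 0
    # demographics
    age_range: tuple[float, float] = (2.0, 80.0)
    height_noise_frac: float = 0.035   # SD of height as fraction of the median
    bmi_log_sd: float = 0.35           # log-scale spread of the BMI offset
    # ground-truth structural model (typical values at ffm_ref kg fat-free mass)
    typical_cl: float = 0.15           # L/h
    typical_v1: float = 3.0            # L
    typical_q: float = 0.15            # L/h
    typical_v2: float = 0.6            # L
    ffm_ref: float = 56.0              # kg
    cl_exponent: float = 0.75
    v1_exponent: float = 1.0
    # inter-individual variability (log-scale SDs) and residual noise
    omega_cl: float = 0.3
    omega_v1: float = 0.2
    sigma: float = 5.0                 # additive residual SD, IU/dL
    # design
    dose_rule: DoseRule = field(default_factory=DoseRule)
    obs_means: tuple[float, ...] = (4.0, 24.0, 48.0)
    obs_sds: tuple[float, ...] = (2.0, 5.0, 5.0)
    truncation: float = 0.25           # h; earliest admissible sampling time
    max_resample: int = 100

    def __post_init__(self):
        if self.n < 1:
            raise InvalidParameterError("n must be >= 1")
        if self.sigma < 0 or self.omega_cl < 0 or self.omega_v1 < 0:
            raise InvalidParameterError("noise magnitudes must be non-negative")
        if self.truncation <= 0:
            raise InvalidParameterError("truncation time must be positive")
        if self.dose_rule.quantum <= 0:
            raise InvalidParameterError("dose rounding quantum must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dose_rule"] = asdict(self.dose_rule)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationConfig":
        d = dict(d)
        known = set(cls.__dataclass_fields__)
        unknown = sorted(set(d) - known)
        if unknown:
            raise InvalidParameterError(
                f"unknown configuration keys {unknown}; valid keys: "
                f"{sorted(known)}"
            )
        if "dose_rule" in d and isinstance(d["dose_rule"], dict):
            d["dose_rule"] = DoseRule(**d["dose_rule"])
        for key in ("age_range", "obs_means", "obs_sds"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def generate_covariates(
    n: int, config: PopulationConfig = PopulationConfig(), seed=None
) -> pd.DataFrame:
    """Draw a male demographic table: age (y), height (cm), weight (kg), ffm (kg).

    Age is uniform over the configured range; height follows a piecewise-linear
    growth curve of age with multiplicative Gaussian noise; BMI is a
    shifted lognormal whose floor and median offset depend on age; weight is
    BMI * height_m^2.  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    age = rng.uniform(*config.age_range, size=n)
    height_med = np.interp(age, _HEIGHT_KNOTS_AGE, _HEIGHT_KNOTS_CM)
    height = height_med * (1.0 + config.height_noise_frac * rng.standard_normal(n))
    floor = np.interp(age, _BMI_FLOOR_AGE, _BMI_FLOOR)
    offset_med = np.interp(age, _BMI_FLOOR_AGE, _BMI_OFFSET)
    bmi = floor + offset_med * np.exp(config.bmi_log_sd * rng.standard_normal(n))
    weight = bmi * (height / 100.0) ** 2
    ffm = fat_free_mass(weight, height, age)
    return pd.DataFrame(
        {"age": age, "height": height, "weight": weight, "ffm": ffm}
    )


def sample_observation_times(
    config: PopulationConfig = PopulationConfig(), seed=None, rng=None
) -> np.ndarray:
    """Draw one subject's sampling times around (4, 24, 48) h.

    Independent normals per component (diagonal covariance); any draw below
    the truncation time is redrawn (up to ``max_resample`` tries) and finally
    clamped at the truncation time.  Returned sorted ascending.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    means = np.asarray(config.obs_means)
    sds = np.asarray(config.obs_sds)
    t = rng.normal(means, sds)
    for _ in range(config.max_resample):
        low = t < config.truncation
        if not low.any():
            break
        t[low] = rng.normal(means[low], sds[low])
    return np.sort(np.maximum(t, config.truncation))


@dataclass
class SimulatedStudy:
    """A complete virtual study: covariates, truth, design and observations."""

    config: PopulationConfig
    frame: pd.DataFrame                   # one row per subject: covariates
    true_params: np.ndarray               # (n, 4): CL, V1, Q, V2 per subject
    regimens: list[DoseRegimen]
    obs_times: list[np.ndarray]
    true_obs: list[np.ndarray]            # noise-free concentrations at obs times
    observations: list[np.ndarray]        # noisy observations
    categorical: dict[str, list] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.frame)

    def covariate_names(self) -> list[str]:
        return [c for c in self.frame.columns]

    def to_dataset(self, covariates=None) -> Dataset:
        names = list(covariates) if covariates is not None else self.covariate_names()
        subjects = []
        for i in range(self.n):
            covs = {c: self.frame.iloc[i][c] for c in names}
            subjects.append(
                Subject(
                    id=str(self.frame.index[i]),
                    covariates=covs,
                    regimen=self.regimens[i],
                    obs_times=self.obs_times[i],
                    obs_values=self.observations[i],
                )
            )
        cat = {k: v for k, v in self.categorical.items() if k in names}
        return Dataset(subjects=subjects, categorical=cat)

    def write(self, table_path, meta_path=None) -> None:
        from .data import write_event_table

        write_event_table(self.to_dataset(), table_path)
        if meta_path is not None:
            meta = {
                "config": self.config.to_dict(),
                "categorical": {k: list(v) for k, v in self.categorical.items()},
                "true_params": self.true_params.tolist(),
                "subject_ids": [str(i) for i in self.frame.index],
                **self.metadata,
            }
            with open(meta_path, "w") as fh:
                json.dump(meta, fh, indent=1)


def typical_parameters(ffm, config: PopulationConfig) -> np.ndarray:
    """Ground-truth typical (CL, V1, Q, V2) as a function of fat-free mass."""
    ffm = np.asarray(ffm, dtype=float)
    rel = ffm / config.ffm_ref
    cl = config.typical_cl * rel ** config.cl_exponent
    v1 = config.typical_v1 * rel ** config.v1_exponent
    q = np.full_like(cl, config.typical_q)
    v2 = np.full_like(cl, config.typical_v2)
    return np.column_stack([cl, v1, q, v2])


def simulate_population(config: PopulationConfig = PopulationConfig()) -> SimulatedStudy:
    """Generate one complete study from the configuration.

    Per subject: typical parameters from the structural model at the subject's
    fat-free mass; individual CL and V1 are typical * exp(eta) with
    eta ~ N(0, omega^2) (Q and V2 fixed across subjects); one bolus at t=0 per
    the weight-based dose rule; three truncated-normal sampling times; true
    concentrations from the closed-form two-compartment solution; observations
    are truth plus additive N(0, sigma) noise.  Fully reproducible from
    (config, seed); changing only sigma changes observations but not truth.
    """
    rng = np.random.default_rng(config.seed)
    frame = generate_covariates(config.n, config, seed=rng.integers(2**31))
    typ = typical_parameters(frame["ffm"].to_numpy(), config)
    eta_rng = np.random.default_rng(rng.integers(2**31))
    eta_cl = eta_rng.normal(0.0, config.omega_cl, size=config.n)
    eta_v1 = eta_rng.normal(0.0, config.omega_v1, size=config.n)
    true = typ.copy()
    true[:, 0] *= np.exp(eta_cl)
    true[:, 1] *= np.exp(eta_v1)

    doses = assign_dose(frame["weight"].to_numpy(), config.dose_rule)
    times_rng = np.random.default_rng(rng.integers(2**31))
    noise_rng = np.random.default_rng(rng.integers(2**31))

    regimens, obs_times, true_obs, observations = [], [], [], []
    any_negative = False
    for i in range(config.n):
        reg = DoseRegimen.bolus(float(doses[i]))
        t = sample_observation_times(config, rng=times_rng)
        c = np.real(
            conc_events(
                true[i, 0], true[i, 1], true[i, 2], true[i, 3],
                np.array([0.0]), np.array([doses[i]]), np.array([0.0]), t,
            )
        )
        y = c + noise_rng.normal(0.0, config.sigma, size=t.size)
        any_negative |= bool((y < 0).any())
        regimens.append(reg)
        obs_times.append(t)
        true_obs.append(c)
        observations.append(y)

    frame = frame.copy()
    frame.index = [str(i + 1) for i in range(config.n)]
    return SimulatedStudy(
        config=config,
        frame=frame,
        true_params=true,
        regimens=regimens,
        obs_times=obs_times,
        true_obs=true_obs,
        observations=observations,
        metadata={
            "negative_observations": any_negative,
            "truncation_policy": "resample-then-clamp",
            "times_sorted_per_subject": True,
        },
    )


def augment_noise_covariates(study: SimulatedStudy, seed: int) -> SimulatedStudy:
    """Add two Uniform(0,1) covariates and one equiprobable 5-level categorical
    covariate, independent of everything else.  Returns a new study."""
    for name in ("noise1", "noise2", "noise_cat"):
        if name in study.frame.columns:
            raise DataError(f"covariate name collision: {name!r} already present")
    rng = np.random.default_rng(seed)
    out = copy.copy(study)
    out.frame = study.frame.copy()
    out.frame["noise1"] = rng.uniform(0.0, 1.0, size=study.n)
    out.frame["noise2"] = rng.uniform(0.0, 1.0, size=study.n)
    out.frame["noise_cat"] = rng.integers(1, 6, size=study.n)
    out.categorical = {**study.categorical, "noise_cat": [1, 2, 3, 4, 5]}
    return out


def true_curve(study: SimulatedStudy, subject: int | str,
               grid=DEFAULT_GRID) -> ConcentrationCurve:
    """Noise-free concentration curve of one subject on a time grid
    (default: 5-minute intervals, 0 to 72 h)."""
    if isinstance(subject, str):
        try:
            idx = list(study.frame.index).index(subject)
        except ValueError:
            raise DataError(f"unknown subject {subject!r}") from None
    else:
        idx = int(subject)
        if not 0 <= idx < study.n:
            raise DataError(f"unknown subject index {subject}")
    from .pk import analytic_profile

    pk = PKParameters(*study.true_params[idx])
    return analytic_profile(pk, study.regimens[idx], np.asarray(grid, dtype=float))


def true_curves_matrix(study: SimulatedStudy, indices, grid=DEFAULT_GRID) -> np.ndarray:
    """Noise-free curves for a subject subset, shape (len(indices), len(grid))."""
    grid = np.asarray(grid, dtype=float)
    idx = np.asarray(indices, dtype=int)
    simple = all(
        len(study.regimens[i].events) == 1
        and study.regimens[i].events[0].time == 0.0
        and study.regimens[i].events[0].duration == 0.0
        for i in idx
    )
    if not simple:
        return np.stack([true_curve(study, int(i), grid).values for i in idx])
    p = study.true_params[idx]
    doses = np.array([study.regimens[i].events[0].amount for i in idx])
    return np.real(
        conc_events(
            p[:, 0][:, None], p[:, 1][:, None], p[:, 2][:, None], p[:, 3][:, None],
            np.zeros((idx.size, 1, 1)), doses[:, None, None],
            np.zeros((idx.size, 1, 1)), grid[None, :],
        )
    )
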