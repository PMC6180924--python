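"""Synthetic PET tumor phantoms and survival cohorts.

The phantom generator produces PET-like spherical (optionally ellipsoidal)
lesions on the clinical grid geometry (2.73 x 2.73 mm pixels, 3.27 mm
slices).  Two uptake phenotypes are controlled by a single border-falloff
parameter: ``border_sigma_mm = 0`` gives a sharp plateau edge (the
"spiculated" phenotype), larger values a Gaussian-like falloff.  Additive
truncated-Gaussian noise supplies intratumoral heterogeneity.

The cohort generator draws head-and-neck-like clinical covariates and
censored survival times from an exponential proportional-hazards model whose
linear predictor is a weighted sum of standardized image features, so that
downstream selection and survival statistics can be exercised under a known
ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize

from .volume import ImageVolume

__all__ = ["PhantomSpec", "CohortSpec", "generate_phantom", "generate_cohort",
           "calibrate_uniform_censoring"]


@dataclass
class PhantomSpec:
    """Geometry and intensity parameters of one synthetic lesion.

    ``border_sigma_mm = 0`` produces a binary plateau lesion (before noise);
    positive values make the uptake fall off as
    ``exp(-(d - r)^2 / (2 sigma^2))`` outside the tumor radius.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 32)
    spacing_mm: tuple[float, float, float] = (2.73, 2.73, 3.27)
    tumor_center_mm: tuple[float, float, float] | None = None  # default: grid centre
    tumor_radius_mm: float = 12.0
    axes_scale: tuple[float, float, float] = (1.0, 1.0, 1.0)
    peak_suv: float = 10.0
    border_sigma_mm: float = 2.0
    background_suv: float = 0.5
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        if self.tumor_radius_mm <= 0:
            raise ValueError("tumor radius must be positive")
        if self.peak_suv <= 0:
            raise ValueError("peak SUV must be positive")
        if self.border_sigma_mm < 0 or self.background_suv < 0 or self.noise_sd < 0:
            raise ValueError("sigma, background and noise must be nonnegative")
        if self.tumor_center_mm is None:
            self.tumor_center_mm = tuple(
                (n - 1) / 2.0 * s for n, s in zip(self.grid_shape, self.spacing_mm))

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "PhantomSpec":
        with open(path) as fh:
            d = json.load(fh)
        for k in ("grid_shape", "spacing_mm", "tumor_center_mm", "axes_scale"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        return cls(**d)


def generate_phantom(spec: PhantomSpec) -> ImageVolume:
    """Rasterize the lesion profile onto the grid and add truncated noise.

    Intensity is ``background + (peak - background) * profile(d)`` where d is
    the (ellipsoid-scaled) distance from the tumor centre: profile = 1 inside
    the radius, and decays as a Gaussian of the excess distance outside (a
    step function when sigma = 0).  Gaussian noise of sd ``noise_sd`` is added
    and the result clipped at 0 (SUVs are nonnegative).  Deterministic given
    the seed.
    """
    shape = spec.grid_shape
    center = np.asarray(spec.tumor_center_mm)
    extent = np.asarray([(n - 1) * s for n, s in zip(shape, spec.spacing_mm)])
    r = spec.tumor_radius_mm
    reach = r * np.asarray(spec.axes_scale)
    if np.any(center - reach < 0) or np.any(center + reach > extent):
        raise ValueError(
            f"tumor (centre {tuple(center)} mm, radius {r} mm) does not fit "
            f"inside the grid extent {tuple(extent)} mm")
    coords = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spec.spacing_mm)],
                         indexing="ij")
    d2 = sum(((c - mu) / a) ** 2
             for c, mu, a in zip(coords, center, spec.axes_scale))
    d = np.sqrt(d2)
    profile = np.where(d <= r, 1.0, 0.0)
    if spec.border_sigma_mm > 0:
        outside = d > r
        profile[outside] = np.exp(-((d[outside] - r) ** 2)
                                  / (2.0 * spec.border_sigma_mm**2))
    data = spec.background_suv + (spec.peak_suv - spec.background_suv) * profile
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sd, size=shape)
        np.maximum(data, 0.0, out=data)
    return ImageVolume(data=data, spacing_mm=spec.spacing_mm)


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortSpec:
    """Sampling scheme for a synthetic survival cohort.

    Event times follow an exponential proportional-hazards model: subject i
    has hazard ``baseline_hazard * exp(sum_f beta_f z_if)`` with z the
    column-standardized feature values and beta = ``log_hr_per_feature``.
    Censoring is independent uniform on (0, U) with U calibrated so the
    expected censored fraction equals ``censoring_rate``.

    Covariate defaults mirror a locally-advanced head-and-neck population:
    75% male, age uniform 40-80 years, 65% stage IV, 55% oropharynx primary,
    75% receiving concurrent chemotherapy.
    """

    n_subjects: int = 90
    censoring_rate: float = 0.3
    baseline_hazard: float = 0.02  # events per month
    log_hr_per_feature: dict[str, float] = field(default_factory=dict)
    p_male: float = 0.75
    age_range: tuple[float, float] = (40.0, 80.0)
    p_stage_iv: float = 0.65
    p_oropharynx: float = 0.55
    p_cht: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring rate must lie in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "CohortSpec":
        with open(path) as fh:
            d = json.load(fh)
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        return cls(**d)


def calibrate_uniform_censoring(rates: np.ndarray, target: float) -> float:
    """Upper bound U of Uniform(0, U) censoring hitting the target rate.

    For exponential event times with hazard lambda_i and C ~ U(0, U), the
    probability subject i is censored is (1 - exp(-lambda_i U)) / (lambda_i U)
    ... actually P(T > C) = (1/U) int_0^U exp(-lambda t) dt
    = (1 - exp(-lambda U)) / (lambda U).  U is solved by bisection on the
    cohort-average censoring probability.
    """
    rates = np.asarray(rates, dtype=float)

    def mean_censored(u: float) -> float:
        x = rates * u
        return float(np.mean((1.0 - np.exp(-x)) / x))

    # mean_censored decreases from 1 (u -> 0) to 0 (u -> inf)
    lo, hi = 1e-9, 1.0
    while mean_censored(hi) > target:
        hi *= 2.0
        if hi > 1e12:
            break
    return float(optimize.brentq(lambda u: mean_censored(u) - target, lo, hi))


def generate_cohort(spec: CohortSpec, features: pd.DataFrame) -> pd.DataFrame:
    """Draw covariates and censored survival times for the given feature table.

    ``features`` is indexed by subject (one row per subject, one column per
    feature); every key of ``spec.log_hr_per_feature`` must be a column.
    Returns a CohortTable DataFrame with columns subject_id, time_months,
    event, gender, age, stage, site_group, cht, weight_kg, height_cm, plus
    the feature columns.
    """
    n = spec.n_subjects
    if len(features) != n:
        raise ValueError(f"feature table has {len(features)} rows, spec expects {n}")
    missing = [f for f in spec.log_hr_per_feature if f not in features.columns]
    if missing:
        raise KeyError(f"unknown feature name(s) in log_hr_per_feature: {missing}")

    rng = np.random.default_rng(spec.seed)
    eta = np.zeros(n)
    for name, beta in spec.log_hr_per_feature.items():
        col = features[name].to_numpy(dtype=float)
        sd = col.std(ddof=0)
        if sd == 0:
            raise ValueError(f"feature {name!r} is constant: cannot standardize")
        eta += beta * (col - col.mean()) / sd
    hazards = spec.baseline_hazard * np.exp(eta)
    event_time = rng.exponential(1.0 / hazards)

    if spec.censoring_rate > 0:
        upper = calibrate_uniform_censoring(hazards, spec.censoring_rate)
        censor_time = rng.uniform(0.0, upper, size=n)
        time = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)
    else:
        time, event = event_time, np.ones(n, dtype=int)

    male = rng.random(n) < spec.p_male
    age = rng.uniform(*spec.age_range, size=n)
    stage = np.where(rng.random(n) < spec.p_stage_iv, "IV", "III")
    site = np.where(rng.random(n) < spec.p_oropharynx, "oropharynx", "other")
    cht = np.where(rng.random(n) < spec.p_cht, "yes", "no")
    # anthropometrics for the SUL scaling, sex-dependent means
    weight = np.where(male, rng.normal(80.0, 12.0, n), rng.normal(65.0, 10.0, n))
    height = np.where(male, rng.normal(175.0, 7.0, n), rng.normal(162.0, 6.0, n))

    cohort = pd.DataFrame({
        "subject_id": [f"S{i:04d}" for i in range(n)],
        "time_months": time,
        "event": event,
        "gender": np.where(male, "M", "F"),
        "age": age,
        "stage": stage,
        "site_group": site,
        "cht": cht,
        "weight_kg": np.clip(weight, 40.0, 140.0),
        "height_cm": np.clip(height, 145.0, 200.0),
    })
    cohort = pd.concat([cohort, features.reset_index(drop=True)], axis=1)
    return cohort
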