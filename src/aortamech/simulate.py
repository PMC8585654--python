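"""Synthetic data generators with known ground truth.

Every input the analysis consumes can be generated here with a closed-form
oracle attached, so the full pipeline is testable end to end without any
patient data:

* tensile records follow a Fung-type exponential stress-stiffening law
  ``sigma_t(eps_t) = (A/B)(exp(B*eps_t) - 1)`` — the simplest law with the
  J-shaped stiffening of arterial tissue; ``B -> 0`` is the linear limit
  with modulus ``A``. Parameters default to moduli in the hundreds-of-kPa
  range typical of thoracic aorta in the physiologic window;
* notched-pair records share the tissue law, with the notched specimen's
  slope dropping by a known fraction at a planted critical displacement;
* the cohort table draws patient x segment x direction rows whose growth
  rate follows a sparse linear model with patient random intercepts, with
  configurable missingness (MCAR or MAR conditioned on segment, mirroring
  the fact that small aortic-root specimens yield fewer tests).
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate

from .fracture import NotchedPair
from .mechanics import (
    ForceDisplacementCurve,
    LoadingWindow,
    SpecimenGeometry,
    fung_strain_at_stress,
)

DEFAULT_GEOMETRY = SpecimenGeometry.from_mm(
    width_reads_mm=(5.0, 5.0, 5.0),
    thickness_reads_mm=(2.0, 2.0, 2.0),
    length_reads_mm=(12.0, 12.0, 12.0),
)

SEGMENTS = ("root", "ascending", "arch", "descending")
DIRECTIONS = ("circumferential", "longitudinal")
DISEASE_CLASSES = ("donor", "recipient", "aneurysm", "chronic_dissection")
# marginal class frequencies mirroring a surgical-referral cohort
DISEASE_PROBS = (0.45, 0.10, 0.26, 0.19)


# ---------------------------------------------------------------------------
# Tensile curves


@dataclass(frozen=True)
class TissueModelParams:
    """Fung-type tissue law parameters for one synthetic specimen."""

    A: float = 50e3  # small-strain stiffness scale, Pa
    B: float = 10.0  # stress-stiffening exponent
    geometry: SpecimenGeometry = DEFAULT_GEOMETRY
    noise_sd: float = 0.0  # force noise, fraction of peak force
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.A <= 0 or self.B < 0:
            raise ValueError(f"require A > 0 and B >= 0, got A={self.A}, B={self.B}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class TensileOracle:
    """Closed-form physiologic-window properties of the generating law."""

    A: float
    B: float

    def strain_at_stress(self, sigma_t: float) -> float:
        return fung_strain_at_stress(self.A, self.B, sigma_t)

    def mean_elastic_modulus(self, window: LoadingWindow) -> float:
        e_d = self.strain_at_stress(window.sigma_dia)
        e_s = self.strain_at_stress(window.sigma_sys)
        return (window.sigma_sys - window.sigma_dia) / (e_s - e_d)

    def relative_strain(self, window: LoadingWindow) -> float:
        return self.strain_at_stress(window.sigma_sys) / self.strain_at_stress(
            window.sigma_dia
        )


def _true_stress(A: float, B: float, eps_t: np.ndarray) -> np.ndarray:
    if B == 0.0:
        return A * eps_t
    return (A / B) * np.expm1(B * eps_t)


def analytic_force(params: TissueModelParams, displacement: float | np.ndarray) -> np.ndarray:
    """Noise-free force at a displacement under the tissue law (SI units)."""
    geom = params.geometry
    eps_e = np.asarray(displacement, dtype=float) / geom.L0
    eps_t = np.log1p(eps_e)
    sigma_t = _true_stress(params.A, params.B, eps_t)
    sigma_e = sigma_t / (1.0 + eps_e)
    return sigma_e * geom.A0


def simulate_tensile_curve(
    params: TissueModelParams,
    n_points: int = 200,
    max_eng_strain: float = 1.0,
) -> tuple[ForceDisplacementCurve, TensileOracle]:
    """Synthetic force-displacement record plus its closed-form oracle.

    The true-stress law is mapped back to the raw record through the same
    engineering/true conversions the pipeline inverts, then additive
    Gaussian noise of SD ``noise_sd * peak force`` is applied to the force.
    """
    if n_points < 10:
        raise ValueError("need at least 10 points")
    geom = params.geometry
    disp = np.linspace(0.0, max_eng_strain * geom.L0, n_points)
    force = analytic_force(params, disp)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        force = force + rng.normal(0.0, params.noise_sd * force.max(), size=force.shape)
    return ForceDisplacementCurve(disp, force), TensileOracle(params.A, params.B)


# ---------------------------------------------------------------------------
# Notched pairs


def simulate_notched_pair(
    params: TissueModelParams,
    kink_at: float,
    post_kink_slope_fraction: float = 0.2,
    physiologic_length: float | None = None,
    n_points: int = 200,
    max_eng_strain: float = 1.0,
) -> tuple[NotchedPair, Callable[[str], float]]:
    """A notched/unnotched pair with a planted kink, plus a toughness oracle.

    The unnotched record follows the tissue law; the notched record is
    identical up to ``kink_at`` and thereafter its slope is scaled by
    ``post_kink_slope_fraction`` (crack propagation sheds stiffness). The
    returned oracle maps a normalization (``per_area`` | ``per_volume``) to
    the fracture energy obtained by adaptive quadrature of the analytic
    unnotched force between L_p and the planted kink.
    """
    geom = params.geometry
    span = max_eng_strain * geom.L0
    if not (0.0 < kink_at < span):
        raise ValueError(f"kink_at {kink_at:.6g} m outside the curve span (0, {span:.6g}) m")
    if not (0.0 < post_kink_slope_fraction <= 1.0):
        raise ValueError("post_kink_slope_fraction must lie in (0, 1]")
    L_p = 0.25 * kink_at if physiologic_length is None else physiologic_length

    disp = np.linspace(0.0, span, n_points)
    clean = analytic_force(params, disp)
    f_kink = analytic_force(params, kink_at)
    notched_clean = np.where(
        disp <= kink_at, clean, f_kink + post_kink_slope_fraction * (clean - f_kink)
    )
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        scale_u = params.noise_sd * clean.max()
        scale_n = params.noise_sd * notched_clean.max()
        unnotched = clean + rng.normal(0.0, scale_u, clean.shape)
        notched = notched_clean + rng.normal(0.0, scale_n, notched_clean.shape)
    else:
        unnotched, notched = clean, notched_clean

    pair = NotchedPair(
        notched_curve=ForceDisplacementCurve(disp, notched),
        unnotched_curve=ForceDisplacementCurve(disp, unnotched),
        geometry=geom,
        physiologic_length=L_p,
    )

    def gamma_oracle(normalization: str = "per_volume") -> float:
        work, _ = integrate.quad(
            lambda l: float(analytic_force(params, l)), L_p, kink_at, limit=200
        )
        gamma = work / (geom.W0 * geom.T0)
        if normalization == "per_volume":
            gamma /= geom.L0
        elif normalization != "per_area":
            raise ValueError(f"unknown normalization {normalization!r}")
        return gamma

    return pair, gamma_oracle


# ---------------------------------------------------------------------------
# Cohort tables


DEFAULT_GROWTH_BETA: dict[str, float] = {
    # sparse truth on the growth scale (mm/y); everything absent is zero
    "Intercept": -8.88,
    "radius": 0.40,
    "eps_rel": 3.64,
    "disease_class[chronic_dissection]": 6.97,
    "segment[ascending]": 1.34,
    "segment[arch]": 1.81,
    "segment[descending]": 2.45,
}

# mechanical-property submodels (kPa, J/m^3, dimensionless): per-segment
# baselines, a longitudinal offset, a disease offset, patient SD, residual SD
_EM_MODEL = dict(
    base={"root": 900.0, "ascending": 597.0, "arch": 455.0, "descending": 586.0},
    longitudinal=-166.8, diseased=0.0, patient_sd=100.0, resid_sd=150.0,
)
_TOUGH_MODEL = dict(
    base={"root": 800.0, "ascending": 711.0, "arch": 670.0, "descending": 877.0},
    longitudinal=-201.2, diseased=-431.7, patient_sd=100.0, resid_sd=150.0,
)
_EPSREL_MODEL = dict(
    base={"root": 1.10, "ascending": 1.112, "arch": 1.123, "descending": 1.12},
    longitudinal=-0.01, diseased=0.09, patient_sd=0.05, resid_sd=0.12,
)


@dataclass(frozen=True)
class CohortSimParams:
    """Study conditions for the synthetic patient x segment x direction cohort."""

    n_patients: int = 200
    segments: tuple[str, ...] = SEGMENTS
    directions: tuple[str, ...] = DIRECTIONS
    growth_beta: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROWTH_BETA)
    )
    intercept_sd: float = 1.0  # patient random-intercept SD, mm/y
    resid_sd: float = 1.0  # residual SD, mm/y
    n_decoys: int = 10
    missing_fraction: float = 0.2
    missing_mechanism: Literal["mcar", "mar_segment"] = "mcar"
    missing_columns: tuple[str, ...] = ("E_M", "toughness", "eps_rel")
    seed: int | None = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.missing_fraction < 1.0):
            raise ValueError("missing_fraction must lie in [0, 1)")
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")


@dataclass(frozen=True)
class CohortTruth:
    """Ground truth behind a simulated cohort table."""

    beta: dict[str, float]  # named coefficients on design columns
    patient_intercepts: pd.Series  # indexed by patient id, mm/y
    missing_mask: pd.DataFrame  # True where a cell was blanked
    linear_predictor: pd.Series  # X beta per row, before intercepts/noise
    params: CohortSimParams

    def to_json(self) -> str:
        """Lossless text serialization (beta, intercepts, mask)."""
        payload = {
            "beta": self.beta,
            "patient_intercepts": {
                str(k): v for k, v in self.patient_intercepts.items()
            },
            "missing_mask": self.missing_mask.to_dict(orient="list"),
            "linear_predictor": self.linear_predictor.tolist(),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str, params: CohortSimParams) -> "CohortTruth":
        payload = json.loads(text)
        return cls(
            beta=payload["beta"],
            patient_intercepts=pd.Series(payload["patient_intercepts"]),
            missing_mask=pd.DataFrame(payload["missing_mask"]),
            linear_predictor=pd.Series(payload["linear_predictor"]),
            params=params,
        )


def cohort_candidates(params: CohortSimParams) -> list[str]:
    """The candidate-predictor list the selection pipeline screens."""
    named = ["sex", "age", "radius", "segment", "disease_class",
             "eps_rel", "toughness", "E_M", "direction", "ctd"]
    return named + [f"decoy{i:02d}" for i in range(1, params.n_decoys + 1)]


def _mechanical_column(
    model: dict, seg: np.ndarray, longi: np.ndarray, diseased: np.ndarray,
    patient_idx: np.ndarray, rng: np.random.Generator, n_patients: int
) -> np.ndarray:
    base = np.array([model["base"][s] for s in seg])
    u = rng.normal(0.0, model["patient_sd"], n_patients)
    return (
        base
        + model["longitudinal"] * longi
        + model["diseased"] * diseased
        + u[patient_idx]
        + rng.normal(0.0, model["resid_sd"], seg.size)
    )


def simulate_cohort(params: CohortSimParams) -> tuple[pd.DataFrame, CohortTruth]:
    """Simulate a cohort table and its ground truth.

    Growth rate is ``X beta + u_patient + eps`` with the sparse default
    truth concentrated on radius, relative strain, chronic dissection and
    segment; mechanical properties carry their own segment/direction/disease
    structure so they behave like real measured covariates rather than white
    noise. Decoy predictors are iid standard normal.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_patients
    rows_per = len(params.segments) * len(params.directions)
    total = n * rows_per

    patients = np.array([f"P{i:04d}" for i in range(n)])
    patient_idx = np.repeat(np.arange(n), rows_per)
    seg = np.tile(np.repeat(params.segments, len(params.directions)), n)
    direction = np.tile(params.directions, n * len(params.segments))

    sex = rng.choice(["female", "male"], size=n, p=[0.32, 0.68])
    age = np.clip(rng.normal(46.7, 17.1, n), 18, 90)
    disease = rng.choice(DISEASE_CLASSES, size=n, p=DISEASE_PROBS)
    ctd = (rng.random(n) < 0.19).astype(int)

    seg_radius_base = {"root": 17.0, "ascending": 16.0, "arch": 14.0, "descending": 12.0}
    diseased_p = np.isin(disease, ["aneurysm", "chronic_dissection"])
    radius = (
        np.array([seg_radius_base[s] for s in seg])
        + 6.0 * diseased_p[patient_idx]
        + rng.normal(0.0, 2.0, n)[patient_idx]
        + rng.normal(0.0, 1.0, total)
    )

    longi = (direction == "longitudinal").astype(float)
    diseased_row = diseased_p[patient_idx].astype(float)
    E_M = _mechanical_column(_EM_MODEL, seg, longi, diseased_row, patient_idx, rng, n)
    tough = _mechanical_column(_TOUGH_MODEL, seg, longi, diseased_row, patient_idx, rng, n)
    eps_rel = _mechanical_column(_EPSREL_MODEL, seg, longi, diseased_row, patient_idx, rng, n)

    table = pd.DataFrame(
        {
            "patient": patients[patient_idx],
            "segment": seg,
            "direction": direction,
            "sex": sex[patient_idx],
            "age": age[patient_idx],
            "ctd": ctd[patient_idx],
            "disease_class": disease[patient_idx],
            "radius": radius,
            "E_M": E_M,
            "toughness": tough,
            "eps_rel": eps_rel,
        }
    )
    for i in range(1, params.n_decoys + 1):
        table[f"decoy{i:02d}"] = rng.normal(0.0, 1.0, total)

    # response: X beta + patient intercept + residual
    beta = dict(params.growth_beta)
    xb = np.full(total, beta.get("Intercept", 0.0))
    for name, b in beta.items():
        if name == "Intercept":
            continue
        if "[" in name:
            var, level = name[:-1].split("[", 1)
            xb += b * (table[var].astype(str) == level).to_numpy(dtype=float)
        else:
            xb += b * table[name].to_numpy(dtype=float)
    u = rng.normal(0.0, params.intercept_sd, n)
    growth = xb + u[patient_idx] + rng.normal(0.0, params.resid_sd, total)
    table["growth_rate"] = growth

    # missingness on the measured mechanical columns
    mask = pd.DataFrame(False, index=table.index, columns=list(params.missing_columns))
    if params.missing_fraction > 0:
        if params.missing_mechanism == "mcar":
            p_row = np.full(total, params.missing_fraction)
        else:  # mar_segment: root specimens are smaller, fewer tests succeed
            is_root = (seg == "root").astype(float)
            n_seg = len(params.segments)
            p_other = params.missing_fraction * n_seg / (n_seg + 1.0)
            p_row = p_other * (1.0 + is_root)
        for col in params.missing_columns:
            hit = rng.random(total) < p_row
            mask[col] = hit
            table.loc[hit, col] = np.nan

    truth = CohortTruth(
        beta=beta,
        patient_intercepts=pd.Series(u, index=patients),
        missing_mask=mask,
        linear_predictor=pd.Series(xb, index=table.index),
        params=params,
    )
    return table, truth


def true_growth_variables(params: CohortSimParams) -> set[str]:
    """Variables with nonzero truth in the growth model, at variable granularity."""
    out = set()
    for name, b in params.growth_beta.items():
        if name == "Intercept" or b == 0.0:
            continue
        out.add(name.split("[", 1)[0] if "[" in name else name)
    return out
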