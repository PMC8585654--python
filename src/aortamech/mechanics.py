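"""Uniaxial tensile mechanics of aortic wall specimens.

Raw force-displacement records from quasistatic uniaxial tension tests are
converted to engineering and then true stress-strain curves (assuming an
incompressible wall), and mechanical properties are evaluated in the
physiologic loading window defined by Laplace-law wall stresses at diastolic
and systolic pressure:

* mean elastic modulus ``E_M`` -- the secant slope of the true stress-true
  strain curve between the diastolic and systolic wall stresses;
* relative strain ``eps_rel`` -- the ratio of true strain at systolic stress
  to true strain at diastolic stress, a dimensionless distensibility index.

All internal computation is in SI units (m, N, Pa); pressures given in mmHg
are converted with 1 mmHg = 133.322 Pa.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

MMHG_TO_PA = 133.322
"""Pressure conversion factor, Pa per mmHg."""

Direction = Literal["circumferential", "longitudinal"]

_DIRECTION_FACTOR = {"circumferential": 1, "longitudinal": 2}


class MalformedCurveError(ValueError):
    """A force-displacement record violates its ordering preconditions."""


class GeometryError(ValueError):
    """Specimen geometry is physically inadmissible."""


class StressRangeError(ValueError):
    """A requested stress lies outside the span a curve achieves."""


class WindowError(ValueError):
    """The diastolic/systolic loading window is degenerate."""


class GaugeLengthWarning(UserWarning):
    """Gauge length is below twice the specimen width (shear/necking risk)."""


def _triplicate(name: str, reads: Sequence[float]) -> np.ndarray:
    arr = np.asarray(reads, dtype=float)
    if arr.shape != (3,):
        raise GeometryError(f"{name} requires exactly three caliper reads, got {arr.shape}")
    if not np.all(arr > 0):
        raise GeometryError(f"{name} reads must be positive, got {arr.tolist()}")
    return arr


@dataclass(frozen=True)
class SpecimenGeometry:
    """Triplicate-averaged specimen dimensions (SI meters).

    Width and thickness are measured with digital calipers at three points
    and averaged; the initial gauge length likewise. The reference
    cross-section ``A0 = W0 * T0`` normalizes force to engineering stress.

    A warning (not an error) is issued when the gauge length is less than
    twice the width, the minimum aspect ratio for clean uniaxial loading.
    """

    width_reads: tuple[float, float, float]
    thickness_reads: tuple[float, float, float]
    length_reads: tuple[float, float, float]

    def __post_init__(self) -> None:
        _triplicate("width", self.width_reads)
        _triplicate("thickness", self.thickness_reads)
        _triplicate("length", self.length_reads)
        if self.L0 < 2.0 * self.W0:
            warnings.warn(
                f"gauge length {self.L0 * 1e3:.2f} mm is below twice the width "
                f"{self.W0 * 1e3:.2f} mm; shear deformation near the grips may "
                "contaminate the record",
                GaugeLengthWarning,
                stacklevel=2,
            )

    @property
    def W0(self) -> float:
        return float(np.mean(self.width_reads))

    @property
    def T0(self) -> float:
        return float(np.mean(self.thickness_reads))

    @property
    def L0(self) -> float:
        return float(np.mean(self.length_reads))

    @property
    def A0(self) -> float:
        """Undeformed cross-sectional area W0*T0 (m^2)."""
        return self.W0 * self.T0

    @classmethod
    def from_mm(
        cls,
        width_reads_mm: Sequence[float],
        thickness_reads_mm: Sequence[float],
        length_reads_mm: Sequence[float],
    ) -> "SpecimenGeometry":
        """Build from caliper reads given in millimetres."""
        to_m = lambda xs: tuple(float(x) * 1e-3 for x in xs)  # noqa: E731
        return cls(to_m(width_reads_mm), to_m(thickness_reads_mm), to_m(length_reads_mm))


@dataclass(frozen=True)
class ForceDisplacementCurve:
    """An ordered uniaxial tension record: displacement (m), force (N)."""

    displacement: np.ndarray
    force: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.displacement, dtype=float)
        f = np.asarray(self.force, dtype=float)
        if d.ndim != 1 or d.shape != f.shape:
            raise MalformedCurveError("displacement and force must be 1-D and equal length")
        if d.size < 3:
            raise MalformedCurveError(f"need at least 3 points, got {d.size}")
        if d[0] < 0:
            raise MalformedCurveError("first displacement must be >= 0")
        if not np.all(np.diff(d) > 0):
            raise MalformedCurveError("displacement must be strictly increasing")
        object.__setattr__(self, "displacement", d)
        object.__setattr__(self, "force", f)

    def __len__(self) -> int:
        return int(self.displacement.size)


@dataclass(frozen=True)
class StressStrainCurve:
    """Paired engineering and true stress-strain sequences for one specimen.

    True quantities follow from incompressibility of the wall:
    ``sigma_t = sigma_e * (1 + eps_e)`` and ``eps_t = ln(1 + eps_e)``.
    """

    eng_strain: np.ndarray
    eng_stress: np.ndarray
    geometry: SpecimenGeometry
    true_strain: np.ndarray | None = None
    true_stress: np.ndarray | None = None

    def __post_init__(self) -> None:
        e = np.asarray(self.eng_strain, dtype=float)
        s = np.asarray(self.eng_stress, dtype=float)
        if not np.all(np.diff(e) > 0):
            raise MalformedCurveError("engineering strain must be strictly increasing")
        object.__setattr__(self, "eng_strain", e)
        object.__setattr__(self, "eng_stress", s)

    @property
    def has_true(self) -> bool:
        return self.true_strain is not None and self.true_stress is not None


@dataclass(frozen=True)
class LoadingWindow:
    """Physiologic Laplace-stress window for one specimen direction.

    Wall stress from the thin-walled Laplace law ``sigma = r*p / (c*t)`` with
    direction factor c=1 (circumferential) or c=2 (longitudinal); the
    circumferential stress is twice the longitudinal one at any pressure.
    """

    p_sys: float  # Pa
    p_dia: float  # Pa
    radius: float  # m
    thickness: float  # m
    direction: Direction = "circumferential"

    def __post_init__(self) -> None:
        if not (self.p_sys > self.p_dia > 0):
            raise WindowError(
                f"require p_sys > p_dia > 0, got {self.p_sys:.1f}/{self.p_dia:.1f} Pa"
            )
        if self.radius <= 0 or self.thickness <= 0:
            raise WindowError("radius and thickness must be positive")
        if self.direction not in _DIRECTION_FACTOR:
            raise WindowError(f"unknown direction {self.direction!r}")

    @property
    def c(self) -> int:
        return _DIRECTION_FACTOR[self.direction]

    @property
    def sigma_sys(self) -> float:
        return laplace_stress(self.radius, self.thickness, self.p_sys, self.direction)

    @property
    def sigma_dia(self) -> float:
        return laplace_stress(self.radius, self.thickness, self.p_dia, self.direction)

    @classmethod
    def from_mmhg(
        cls,
        p_sys_mmhg: float = 120.0,
        p_dia_mmhg: float = 80.0,
        *,
        radius_mm: float,
        thickness_mm: float,
        direction: Direction = "circumferential",
    ) -> "LoadingWindow":
        """Clinical-units constructor; defaults to the donor-control 120/80 mmHg."""
        return cls(
            p_sys=p_sys_mmhg * MMHG_TO_PA,
            p_dia=p_dia_mmhg * MMHG_TO_PA,
            radius=radius_mm * 1e-3,
            thickness=thickness_mm * 1e-3,
            direction=direction,
        )


@dataclass(frozen=True)
class MechanicalSummary:
    """Physiologic-window properties of a single specimen."""

    E_M: float  # Pa
    eps_dia: float
    eps_sys: float
    eps_rel: float
    direction: Direction
    segment: str = ""


def engineering_stress_strain(
    curve: ForceDisplacementCurve, geom: SpecimenGeometry
) -> StressStrainCurve:
    """Normalize a force-displacement record by the undeformed geometry.

    sigma_e = F / A0, eps_e = D / L0, pointwise.
    """
    if geom.A0 <= 0:
        raise GeometryError("cross-section A0 must be positive")
    return StressStrainCurve(
        eng_strain=curve.displacement / geom.L0,
        eng_stress=curve.force / geom.A0,
        geometry=geom,
    )


def to_true(curve: StressStrainCurve) -> StressStrainCurve:
    """Fill the true stress/strain columns assuming incompressibility.

    sigma_t = sigma_e * (1 + eps_e), eps_t = ln(1 + eps_e).
    """
    e = curve.eng_strain
    if np.any(e <= -1.0):
        raise ValueError("engineering strain <= -1 is unphysical (zero/negative length)")
    return StressStrainCurve(
        eng_strain=e,
        eng_stress=curve.eng_stress,
        geometry=curve.geometry,
        true_strain=np.log1p(e),
        true_stress=curve.eng_stress * (1.0 + e),
    )


def laplace_stress(r: float, t: float, p: float, direction: Direction) -> float:
    """Thin-walled Laplace wall stress sigma = r*p / (c*t), SI units."""
    if r <= 0 or t <= 0 or p <= 0:
        raise ValueError(f"r, t, p must all be positive, got r={r}, t={t}, p={p}")
    try:
        c = _DIRECTION_FACTOR[direction]
    except KeyError:
        raise ValueError(f"unknown direction {direction!r}") from None
    return r * p / (c * t)


def _curve_columns(
    curve: StressStrainCurve, use_true: bool
) -> tuple[np.ndarray, np.ndarray]:
    if use_true:
        if not curve.has_true:
            raise ValueError("true columns not filled; call to_true() first")
        return curve.true_stress, curve.true_strain
    return curve.eng_stress, curve.eng_strain


def strain_at_stress(
    curve: StressStrainCurve, sigma: float, *, use_true: bool = True
) -> float:
    """Strain at which the curve first reaches stress ``sigma``.

    Piecewise-linear interpolation of strain against stress; if the stress
    sequence is locally non-monotone the first upward crossing is used.
    """
    stress, strain = _curve_columns(curve, use_true)
    lo, hi = float(np.min(stress)), float(np.max(stress))
    if not (lo <= sigma <= hi):
        raise StressRangeError(
            f"stress {sigma:.6g} Pa outside the curve's achievable span "
            f"[{lo:.6g}, {hi:.6g}] Pa"
        )
    # first index where the segment [i, i+1] brackets sigma from below
    for i in range(len(stress) - 1):
        s0, s1 = stress[i], stress[i + 1]
        if s0 <= sigma <= s1 and s1 > s0:
            w = (sigma - s0) / (s1 - s0)
            return float(strain[i] + w * (strain[i + 1] - strain[i]))
        if s0 == sigma:
            return float(strain[i])
    if stress[-1] == sigma:
        return float(strain[-1])
    raise StressRangeError(
        f"no upward crossing of {sigma:.6g} Pa found on the curve"
    )


def mean_elastic_modulus(
    curve: StressStrainCurve, window: LoadingWindow, *, use_true: bool = True
) -> float:
    """Secant slope of the stress-strain curve over the physiologic window.

    E_M = (sigma_sys - sigma_dia) / (eps(sigma_sys) - eps(sigma_dia)),
    evaluated on the true stress-true strain curve by default.
    """
    s_dia, s_sys = window.sigma_dia, window.sigma_sys
    if s_sys <= s_dia:
        raise WindowError(
            f"degenerate window: sigma_sys {s_sys:.6g} <= sigma_dia {s_dia:.6g}"
        )
    e_dia = strain_at_stress(curve, s_dia, use_true=use_true)
    e_sys = strain_at_stress(curve, s_sys, use_true=use_true)
    de = e_sys - e_dia
    if de == 0.0:
        raise ZeroDivisionError("zero strain difference across the window (singular curve)")
    return (s_sys - s_dia) / de


def relative_strain(
    curve: StressStrainCurve,
    window: LoadingWindow,
    *,
    use_true: bool = True,
    convention: Literal["systolic_over_diastolic", "diastolic_over_systolic"]
    = "systolic_over_diastolic",
) -> float:
    """Distensibility index: eps(sigma_sys) / eps(sigma_dia).

    The inverted convention (``diastolic_over_systolic``) is exposed for
    sensitivity analysis; the default follows the formula as printed.
    """
    e_dia = strain_at_stress(curve, window.sigma_dia, use_true=use_true)
    e_sys = strain_at_stress(curve, window.sigma_sys, use_true=use_true)
    if convention == "systolic_over_diastolic":
        num, den = e_sys, e_dia
    else:
        num, den = e_dia, e_sys
    if den == 0.0:
        raise ZeroDivisionError("zero strain in the denominator of the relative-strain ratio")
    return num / den


def summarize(
    curve: ForceDisplacementCurve,
    geom: SpecimenGeometry,
    window: LoadingWindow,
    *,
    segment: str = "",
    use_true: bool = True,
) -> MechanicalSummary:
    """Full per-specimen pipeline: raw record -> physiologic-window summary."""
    ss = to_true(engineering_stress_strain(curve, geom))
    eps_dia = strain_at_stress(ss, window.sigma_dia, use_true=use_true)
    eps_sys = strain_at_stress(ss, window.sigma_sys, use_true=use_true)
    return MechanicalSummary(
        E_M=mean_elastic_modulus(ss, window, use_true=use_true),
        eps_dia=eps_dia,
        eps_sys=eps_sys,
        eps_rel=relative_strain(ss, window, use_true=use_true),
        direction=window.direction,
        segment=segment,
    )


def fung_strain_at_stress(A: float, B: float, sigma: float) -> float:
    """Closed-form inverse of the Fung-type law sigma(eps) = (A/B)(e^{B eps}-1).

    Independent oracle for the interpolation route; B=0 is the linear limit
    sigma = A*eps.
    """
    if A <= 0 or B < 0:
        raise ValueError("require A > 0 and B >= 0")
    if B == 0.0:
        return sigma / A
    return math.log1p(B * sigma / A) / B
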